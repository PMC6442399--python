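"""Study configuration: analysis constants and layout declarations."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

from .types import ConfigError


@dataclass
class StudyConfig:
    """Tunable analysis parameters with their documented defaults.

    threshold_k
        SD multiplier used when deriving the per-endpoint noise threshold
        from DMSO-well variability (default 3).
    min_threshold
        Lower bound on the noise threshold in % response units, guarding
        degenerate (zero-variance) control data.
    floor_quantile
        Quantile of baseline |response| pooled across substances used as the
        data-derived floor of the noise threshold.
    baseline_points
        Number of lowest-concentration points defining the per-curve baseline.
    interference_tolerance / aroer_dilution_factor
        Fold cutoffs (POD ratios) for counter-screen interference labelling
        and the aromatase-vs-ER-antagonism comparison; both default to 3-fold,
        about one half-log dilution step.
    imputation_pod
        POD in ug/mL assigned to inactive/inconclusive cells of the profile
        matrix (default 1000).
    perplexity / tsne_iterations
        2-D embedding configuration (defaults 30 and 5000).
    pattern_correction
        Plate pattern correction hook: "none" or "median_polish".
    first_two_columns_empty
        Declares the plate layout in which columns 1-2 carry no sample.
    zscore_on
        Whether ranking Z-scores are computed over active cells only
        ("active") or over the whole wAUC column ("all").
    """

    threshold_k: float = 3.0
    min_threshold: float = 1.0
    floor_quantile: float = 0.95
    baseline_points: int = 2
    interference_tolerance: float = 3.0
    aroer_dilution_factor: float = 3.0
    imputation_pod: float = 1000.0
    perplexity: float = 30.0
    tsne_iterations: int = 5000
    seed: int = 0
    pattern_correction: str = "none"
    first_two_columns_empty: bool = True
    zscore_on: str = "active"

    def validate(self) -> "StudyConfig":
        if self.threshold_k <= 0:
            raise ConfigError("threshold_k (noise SD multiplier) must be positive")
        if self.min_threshold <= 0:
            raise ConfigError("min_threshold must be positive")
        if not 0.0 < self.floor_quantile <= 1.0:
            raise ConfigError("floor_quantile must lie in (0, 1]")
        if self.baseline_points < 1:
            raise ConfigError("baseline_points must be >= 1")
        if self.interference_tolerance <= 0 or self.aroer_dilution_factor <= 0:
            raise ConfigError("fold cutoffs must be positive")
        if self.imputation_pod <= 0:
            raise ConfigError("imputation_pod must be positive")
        if self.perplexity <= 0:
            raise ConfigError("perplexity must be positive")
        if self.tsne_iterations < 250:
            raise ConfigError("tsne_iterations must be >= 250")
        if self.pattern_correction not in ("none", "median_polish"):
            raise ConfigError("pattern_correction must be 'none' or 'median_polish'")
        if self.zscore_on not in ("active", "all"):
            raise ConfigError("zscore_on must be 'active' or 'all'")
        return self


VALID_KEYS = tuple(f.name for f in dataclasses.fields(StudyConfig))


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Load a YAML key-value configuration file; unset keys take defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: configuration must be a key-value mapping")
    unknown = sorted(set(data) - set(VALID_KEYS))
    if unknown:
        raise ConfigError(
            f"unknown configuration keys {unknown}; valid keys are {sorted(VALID_KEYS)}"
        )
    return StudyConfig(**data).validate()
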