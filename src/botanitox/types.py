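"""Core record types shared across the pipeline.

The screening workflow moves through a small set of in-memory records:
raw plate wells -> normalized concentration-response curves -> per-curve
activity metrics -> one call per substance x endpoint -> profile matrices.
Collections of these records travel as pandas DataFrames (see
:mod:`botanitox.io` for the table schemas); the dataclasses here carry the
per-record invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

INCREASE = "increase"
DECREASE = "decrease"
DIRECTIONS = (INCREASE, DECREASE)

ROLE_SUBSTANCE = "substance"
ROLE_DMSO = "dmso"
ROLE_POSITIVE = "positive_control"
ROLE_EMPTY = "empty"
ROLES = (ROLE_SUBSTANCE, ROLE_DMSO, ROLE_POSITIVE, ROLE_EMPTY)

LABEL_ACTIVE = "active"
LABEL_INACTIVE = "inactive"
LABEL_INCONCLUSIVE = "inconclusive"

FLAG_INTERFERENCE = "interference"
FLAG_AROER = "aroer_confounded"
FLAG_EXCLUDED = "excluded"


class BotanitoxError(Exception):
    """Base class for package errors."""


class FormatError(BotanitoxError):
    """A table or file does not conform to the expected schema."""


class IntegrityError(BotanitoxError):
    """Data violate a study-level invariant (duplicates, missing cells...)."""


class ConfigError(BotanitoxError):
    """Invalid or unknown configuration."""


class DegeneratePlateError(BotanitoxError):
    """Plate controls cannot define a response scale (V_pos == V_DMSO)."""


@dataclass(frozen=True)
class EndpointSpec:
    """One assay readout: its biological category and direction of effect."""

    endpoint_id: str
    effect_category: str = "other"
    direction: str = INCREASE
    is_counter_screen: bool = False
    paired_primary: Optional[str] = None
    timepoint: Optional[float] = None  # hours; real-time assays only
    family: Optional[str] = None  # groups real-time timepoints of one assay

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}, got {self.direction!r}")
        if self.is_counter_screen and self.paired_primary is None:
            raise ValueError("a counter screen must name its paired primary endpoint")


@dataclass(frozen=True)
class SubstanceSpec:
    """One test article (a botanical lot or a purported active constituent)."""

    substance_id: str
    group: str
    formulation: str = "extract"  # extract | constituent | oil | powder | other
    lot_id: Optional[str] = None
    excluded: bool = False  # autofluorescence-style exclusion flag


@dataclass
class ResponseCurve:
    """Normalized % response versus log10 concentration for one run.

    Responses are stored on the internal "effect-positive" scale: curves for
    decrease-direction endpoints are sign-flipped at normalization time so all
    downstream math treats effect as a positive response; the sign is restored
    on reported wAUC / Emax values.
    """

    substance_id: str
    endpoint_id: str
    run_index: int
    log10_concentration: np.ndarray
    response: np.ndarray
    direction: str = INCREASE

    def __post_init__(self) -> None:
        self.log10_concentration = np.asarray(self.log10_concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.log10_concentration.shape != self.response.shape:
            raise ValueError("concentration and response vectors must have equal length")
        if self.log10_concentration.size < 2:
            raise ValueError("a response curve needs at least 2 points")
        if np.any(np.diff(self.log10_concentration) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("responses must be finite")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")

    @property
    def concentration(self) -> np.ndarray:
        """Tested concentrations in ug/mL."""
        return 10.0 ** self.log10_concentration

    @property
    def n_points(self) -> int:
        return int(self.response.size)

    def with_response(self, response: np.ndarray) -> "ResponseCurve":
        return replace(self, response=np.asarray(response, dtype=float))


@dataclass(frozen=True)
class NoiseThreshold:
    """Per-endpoint noise level used by the curve filter.

    value = max(k * SD(DMSO responses), data_floor, configured minimum),
    in % response units.
    """

    endpoint_id: str
    value: float
    sd_dmso: float
    k: float
    data_floor: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("noise threshold must be positive")


@dataclass(frozen=True)
class CurveMetrics:
    """Activity parameters extracted from one filtered curve.

    ``significant`` holds exactly when |wauc| > 0, which holds exactly when a
    POD exists. Potency fields are ``None`` for non-significant curves.
    """

    substance_id: str
    endpoint_id: str
    run_index: int
    wauc: float
    pod: Optional[float]  # ug/mL
    ec50: Optional[float]  # ug/mL
    emax: Optional[float]  # % response, signed per endpoint direction
    significant: bool


@dataclass(frozen=True)
class EndpointCall:
    """Replicate-majority activity call for one substance x endpoint."""

    substance_id: str
    endpoint_id: str
    label: str  # active | inactive | inconclusive
    n_significant: int
    n_runs: int
    median_pod: Optional[float]
    median_ec50: Optional[float]
    median_emax: Optional[float]
    median_wauc: float
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.label not in (LABEL_ACTIVE, LABEL_INACTIVE, LABEL_INCONCLUSIVE):
            raise ValueError(f"unknown label {self.label!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.label != LABEL_ACTIVE and self.median_pod is not None:
            raise ValueError("potency medians are only assigned to active calls")

    def with_label(self, label: str, extra_flags: frozenset = frozenset()) -> "EndpointCall":
        """Relabel, dropping potency medians unless the call stays active."""
        keep = label == LABEL_ACTIVE
        return replace(
            self,
            label=label,
            flags=self.flags | extra_flags,
            median_pod=self.median_pod if keep else None,
            median_ec50=self.median_ec50 if keep else None,
            median_emax=self.median_emax if keep else None,
        )

    def with_flags(self, extra_flags: frozenset) -> "EndpointCall":
        return replace(self, flags=self.flags | frozenset(extra_flags))
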