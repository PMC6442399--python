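"""Synthetic screening study with known Hill-curve ground truth.

Emulates the raw material of a botanical qHTS screen: 384-well plates whose
first two columns are empty, DMSO-only and positive-control wells, a
titration series per substance, three replicate runs, endpoints with
direction labels, and botanical groups containing several lots plus
purported active constituents whose true responses are amplified relative to
their parent extracts. Every downstream stage of the pipeline can be tested
against the generating truths without any external data.

Plate layout (one plate holds up to 16 substances):

* columns 1-2: empty (declared study layout);
* columns 3 .. 2+dilution_points: the titration series, ascending
  concentration left to right, one substance per row A-P;
* column 23: 16 DMSO-only wells; column 24: 16 positive-control wells;
* remaining columns: empty.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Tuple, Union

import numpy as np
import pandas as pd

from .io import ROW_LETTERS, WELL_COLUMNS, endpoints_to_frame, substances_to_frame
from .types import (
    DECREASE,
    INCREASE,
    ROLE_DMSO,
    ROLE_EMPTY,
    ROLE_POSITIVE,
    ROLE_SUBSTANCE,
    EndpointSpec,
    SubstanceSpec,
)


@dataclass(frozen=True)
class HillTruth:
    """Generating Hill parameters for one substance x endpoint.

    ``top`` is the true maximal % response (Emax), signed per the endpoint's
    direction of effect; inactive truths have top = 0 exactly.
    """

    substance_id: str
    endpoint_id: str
    top: float
    ec50_true: float
    hill_coefficient: float
    active_true: bool

    def __post_init__(self) -> None:
        if not self.active_true and self.top != 0.0:
            raise ValueError("inactive truths must have top = 0")
        if self.active_true:
            if self.ec50_true <= 0:
                raise ValueError("ec50_true must be positive")
            if self.hill_coefficient <= 0:
                raise ValueError("hill coefficient must be positive")


@dataclass
class SimulationDesign:
    """Configurable study design.

    Defaults mirror the screening design this package targets: ~19 botanical
    groups of several lots plus one constituent each (~90 substances),
    20 endpoints, a 15-point third-log titration, and three replicate runs.
    Noise is additive Gaussian on the % response scale (``noise_sd``) before
    back-conversion to raw signal; control-well raw SDs default to the same
    noise level expressed in signal units.
    """

    n_groups: int = 19
    lots_per_group: int = 4
    constituents_per_group: int = 1
    n_endpoints: int = 20
    n_counter_screens: int = 0
    dilution_points: int = 15
    dilution_step: float = 10.0 ** (1.0 / 3.0)
    top_concentration: float = 500.0  # ug/mL
    runs: int = 3
    noise_sd: float = 5.0  # % response units
    dmso_signal_mean: float = 1000.0
    dmso_signal_sd: Optional[float] = None  # default: noise_sd in signal units
    positive_signal_mean: float = 3000.0
    positive_signal_sd: Optional[float] = None
    plate_pattern_amplitude: float = 0.0  # signal units; 0 disables
    active_fraction: float = 0.3
    fraction_decrease: float = 0.4
    lot_jitter: float = 0.15  # SD of log-normal lot-to-lot variability
    constituent_potency_shift: float = 4.0  # fold decrease in EC50
    constituent_efficacy_boost: float = 1.25  # fold increase in |top|
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution_points < 4:
            raise ValueError("dilution_points must be >= 4")
        if self.dilution_points > 20:
            raise ValueError(
                "dilution_points > 20 does not fit the 384-well layout "
                "(columns 3-22 hold the titration)"
            )
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        for name in ("noise_sd", "lot_jitter", "plate_pattern_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dmso_signal_sd", "positive_signal_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.positive_signal_mean == self.dmso_signal_mean:
            raise ValueError("positive and DMSO signal means must differ")

    @property
    def signal_span(self) -> float:
        return self.positive_signal_mean - self.dmso_signal_mean

    def control_sds(self) -> Tuple[float, float]:
        default = abs(self.signal_span) * self.noise_sd / 100.0
        dmso = default if self.dmso_signal_sd is None else self.dmso_signal_sd
        pos = default if self.positive_signal_sd is None else self.positive_signal_sd
        return dmso, pos


class StudyTables(NamedTuple):
    wells: pd.DataFrame
    truths: pd.DataFrame
    substances: pd.DataFrame
    endpoints: pd.DataFrame


def concentration_series(design: SimulationDesign) -> np.ndarray:
    """Tested concentrations in ug/mL, ascending."""
    k = np.arange(design.dilution_points - 1, -1, -1, dtype=float)
    return design.top_concentration / design.dilution_step ** k


def hill_response(
    concentration: Union[float, np.ndarray], truth: HillTruth
) -> Union[float, np.ndarray]:
    """True % response ``top * c^h / (ec50^h + c^h)`` at the given concentration."""
    c = np.asarray(concentration, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be positive")
    if not truth.active_true or truth.top == 0.0:
        out = np.zeros_like(c)
    else:
        ch = c ** truth.hill_coefficient
        out = truth.top * ch / (truth.ec50_true ** truth.hill_coefficient + ch)
    return float(out) if np.isscalar(concentration) else out


def _make_substances(design: SimulationDesign) -> List[SubstanceSpec]:
    subs: List[SubstanceSpec] = []
    for g in range(1, design.n_groups + 1):
        group = f"grp{g:02d}"
        for lot in range(1, design.lots_per_group + 1):
            subs.append(
                SubstanceSpec(f"{group}-lot{lot}", group, "extract", lot_id=f"L{lot}")
            )
        for c in range(1, design.constituents_per_group + 1):
            subs.append(SubstanceSpec(f"{group}-const{c}", group, "constituent"))
    return subs


def _make_endpoints(design: SimulationDesign, rng: np.random.Generator) -> List[EndpointSpec]:
    categories = ("stress response", "nuclear receptor", "genotoxicity", "cell viability")
    eps: List[EndpointSpec] = []
    for i in range(1, design.n_endpoints + 1):
        direction = DECREASE if rng.random() < design.fraction_decrease else INCREASE
        eps.append(
            EndpointSpec(
                endpoint_id=f"ep{i:02d}",
                effect_category=categories[(i - 1) % len(categories)],
                direction=direction,
            )
        )
    for i in range(1, design.n_counter_screens + 1):
        eps.append(
            EndpointSpec(
                endpoint_id=f"ctr{i:02d}",
                effect_category="cell viability",
                direction=DECREASE,
                is_counter_screen=True,
                paired_primary=f"ep{i:02d}",
            )
        )
    return eps


def _make_truths(
    design: SimulationDesign,
    substances: List[SubstanceSpec],
    endpoints: List[EndpointSpec],
    rng: np.random.Generator,
) -> List[HillTruth]:
    conc = concentration_series(design)
    log_lo, log_hi = math.log10(conc[0]), math.log10(conc[-1])
    # EC50s sit >= 2 decades above the lowest tested concentration so the two
    # lowest points lie on the baseline plateau, as in a designed titration.
    ec_lo, ec_hi = log_lo + 2.0, log_hi - 0.7
    if ec_lo >= ec_hi:  # narrow ranges: fall back to the central half-decade
        mid = 0.5 * (log_lo + log_hi)
        ec_lo, ec_hi = mid - 0.25, mid + 0.25

    truths: List[HillTruth] = []
    for endpoint in endpoints:
        sign = -1.0 if endpoint.direction == DECREASE else 1.0
        p_active = design.active_fraction * (0.25 if endpoint.is_counter_screen else 1.0)
        for g in range(1, design.n_groups + 1):
            group = f"grp{g:02d}"
            active = rng.random() < p_active
            base_top = rng.uniform(40.0, 120.0)
            base_log_ec50 = rng.uniform(ec_lo, ec_hi)
            base_h = rng.uniform(0.8, 2.5)
            for sub in substances:
                if sub.group != group:
                    continue
                jitter_top = math.exp(rng.normal(0.0, design.lot_jitter))
                jitter_ec = math.exp(rng.normal(0.0, design.lot_jitter))
                if not active:
                    truths.append(HillTruth(sub.substance_id, endpoint.endpoint_id,
                                            0.0, math.nan, math.nan, False))
                    continue
                top = base_top * jitter_top
                ec50 = 10.0 ** base_log_ec50 * jitter_ec
                if sub.formulation == "constituent":
                    top = min(top * design.constituent_efficacy_boost, 150.0)
                    ec50 = ec50 / design.constituent_potency_shift
                ec50 = float(np.clip(ec50, conc[0] * 2.0, conc[-1] / 2.0))
                truths.append(
                    HillTruth(sub.substance_id, endpoint.endpoint_id,
                              sign * top, ec50, base_h, True)
                )
    return truths


def truths_to_frame(truths: List[HillTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "substance_id": t.substance_id,
                "endpoint_id": t.endpoint_id,
                "top": t.top,
                "ec50_true": t.ec50_true,
                "hill_coefficient": t.hill_coefficient,
                "active_true": t.active_true,
            }
            for t in truths
        ]
    )


def frame_to_truths(frame: pd.DataFrame) -> List[HillTruth]:
    return [
        HillTruth(
            substance_id=str(r["substance_id"]),
            endpoint_id=str(r["endpoint_id"]),
            top=float(r["top"]),
            ec50_true=float(r["ec50_true"]),
            hill_coefficient=float(r["hill_coefficient"]),
            active_true=bool(r["active_true"]),
        )
        for r in frame.to_dict("records")
    ]


def generate_study(design: SimulationDesign) -> StudyTables:
    """Generate raw plate reads plus ground-truth and annotation tables.

    Raw substance signal is
    ``dmso_mean + span * (hill_response + noise) / 100 + pattern(column)``
    where ``span = positive_mean - dmso_mean`` and the optional pattern is a
    smooth (linear) additive column gradient. Identical seeds reproduce
    identical tables bit for bit.
    """
    rng = np.random.default_rng(design.seed)
    substances = _make_substances(design)
    endpoints = _make_endpoints(design, rng)
    truths = _make_truths(design, substances, endpoints, rng)
    truth_by_key: Dict[Tuple[str, str], HillTruth] = {
        (t.substance_id, t.endpoint_id): t for t in truths
    }
    conc = concentration_series(design)
    npoints = design.dilution_points
    dmso_sd, pos_sd = design.control_sds()
    span = design.signal_span
    amp = design.plate_pattern_amplitude

    def pattern(col: np.ndarray) -> np.ndarray:
        if amp == 0.0:
            return np.zeros_like(col, dtype=float)
        return amp * (col.astype(float) - 12.5) / 11.5

    chunks = [substances[i : i + 16] for i in range(0, len(substances), 16)]
    records: Dict[str, list] = {c: [] for c in WELL_COLUMNS}

    def emit(plate_id, rows, cols, roles, sub_ids, lot_ids, concs, run, endpoint_id, raws):
        n = len(rows)
        records["plate_id"].extend([plate_id] * n)
        records["row"].extend(rows)
        records["col"].extend(cols)
        records["role"].extend(roles)
        records["substance_id"].extend(sub_ids)
        records["lot_id"].extend(lot_ids)
        records["concentration"].extend(concs)
        records["run_index"].extend([run] * n)
        records["endpoint_id"].extend([endpoint_id] * n)
        records["raw_value"].extend(raws)

    for endpoint in endpoints:
        eid = endpoint.endpoint_id
        for run in range(1, design.runs + 1):
            for ci, chunk in enumerate(chunks, start=1):
                plate_id = f"{eid}-r{run}-p{ci:02d}"
                # substance titration wells
                for slot, sub in enumerate(chunk):
                    truth = truth_by_key[(sub.substance_id, eid)]
                    resp = hill_response(conc, truth) + rng.normal(0.0, design.noise_sd, npoints)
                    cols = np.arange(3, 3 + npoints)
                    raw = design.dmso_signal_mean + span * resp / 100.0 + pattern(cols)
                    emit(
                        plate_id,
                        [ROW_LETTERS[slot]] * npoints,
                        cols.tolist(),
                        [ROLE_SUBSTANCE] * npoints,
                        [sub.substance_id] * npoints,
                        [sub.lot_id] * npoints,
                        conc.tolist(),
                        run, eid,
                        raw.tolist(),
                    )
                # controls: 16 DMSO wells (col 23), 16 positive wells (col 24)
                dmso_raw = rng.normal(design.dmso_signal_mean, dmso_sd, 16) + pattern(np.full(16, 23))
                pos_raw = rng.normal(design.positive_signal_mean, pos_sd, 16) + pattern(np.full(16, 24))
                for col, role, raw in ((23, ROLE_DMSO, dmso_raw), (24, ROLE_POSITIVE, pos_raw)):
                    emit(
                        plate_id,
                        list(ROW_LETTERS),
                        [col] * 16,
                        [role] * 16,
                        [None] * 16,
                        [None] * 16,
                        [np.nan] * 16,
                        run, eid,
                        raw.tolist(),
                    )
                # declared-empty wells: columns 1-2 (physically empty, raw 0)
                for col in (1, 2):
                    emit(
                        plate_id,
                        list(ROW_LETTERS),
                        [col] * 16,
                        [ROLE_EMPTY] * 16,
                        [None] * 16,
                        [None] * 16,
                        [np.nan] * 16,
                        run, eid,
                        [0.0] * 16,
                    )

    wells = pd.DataFrame(records)[WELL_COLUMNS]
    return StudyTables(
        wells=wells,
        truths=truths_to_frame(truths),
        substances=substances_to_frame(substances),
        endpoints=endpoints_to_frame(endpoints),
    )


def truth_calls(
    truths: Union[pd.DataFrame, List[HillTruth]],
    design: SimulationDesign,
    threshold: float,
) -> pd.DataFrame:
    """Expected activity labels and analytic PODs for a given noise threshold.

    A truth is expected "active" when its |response| reaches the threshold
    within the tested range; its analytic POD solves
    ``|top| c^h / (ec50^h + c^h) = threshold``, i.e.
    ``POD = ec50 * (threshold / (|top| - threshold))^(1/h)``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(truths, pd.DataFrame):
        truths = frame_to_truths(truths)
    cmax = float(concentration_series(design)[-1])
    rows = []
    for t in truths:
        pod = math.nan
        label = "inactive"
        if t.active_true and abs(t.top) > threshold:
            top_at_cmax = abs(hill_response(cmax, t))
            if top_at_cmax >= threshold:
                label = "active"
                pod = t.ec50_true * (threshold / (abs(t.top) - threshold)) ** (
                    1.0 / t.hill_coefficient
                )
        rows.append(
            {
                "substance_id": t.substance_id,
                "endpoint_id": t.endpoint_id,
                "expected_label": label,
                "pod_true": pod,
            }
        )
    return pd.DataFrame(rows)
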