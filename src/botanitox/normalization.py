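"""Raw well reads -> percent response curves.

Each plate read is normalized to its own plate controls,

    % Response = (V_substance - V_DMSO) / (V_pos - V_DMSO) * 100,

where V_DMSO and V_pos are the medians of the DMSO-only and
positive-control wells of that plate. Each curve's baseline is then rescaled
to 0% (default estimator: median response of the two lowest tested
concentrations), and decrease-direction endpoints are sign-flipped so that
downstream math treats effect as a positive response (the sign is restored on
reported wAUC/Emax). A pluggable pattern-correction hook can remove smooth
additive plate gradients before normalization.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, NamedTuple, Optional, Union

import numpy as np
import pandas as pd

from .types import (
    DECREASE,
    ROLE_DMSO,
    ROLE_EMPTY,
    ROLE_POSITIVE,
    ROLE_SUBSTANCE,
    ConfigError,
    DegeneratePlateError,
    EndpointSpec,
    IntegrityError,
    ResponseCurve,
)


@dataclass(frozen=True)
class NormalizationContext:
    """Per-plate control summary defining the % response scale."""

    plate_id: str
    endpoint_id: str
    run_index: int
    v_dmso: float
    v_pos: float
    n_dmso_wells: int
    n_pos_wells: int

    def __post_init__(self) -> None:
        if self.n_dmso_wells < 2 or self.n_pos_wells < 2:
            raise IntegrityError(
                f"plate {self.plate_id}: need >= 2 DMSO and >= 2 positive-control wells"
            )
        if self.v_pos == self.v_dmso:
            raise DegeneratePlateError(
                f"plate {self.plate_id}: V_pos == V_DMSO, response scale undefined"
            )


def percent_response(
    raw: Union[float, np.ndarray], ctx: NormalizationContext
) -> Union[float, np.ndarray]:
    """Percent response of a raw read relative to the plate controls."""
    return (np.asarray(raw, dtype=float) - ctx.v_dmso) / (ctx.v_pos - ctx.v_dmso) * 100.0


def plate_context(plate_wells: pd.DataFrame) -> NormalizationContext:
    """Summarize the control wells of one plate x endpoint x run."""
    for col in ("plate_id", "endpoint_id", "run_index"):
        if plate_wells[col].nunique() != 1:
            raise IntegrityError(f"plate_context expects a single {col}")
    dmso = plate_wells.loc[plate_wells["role"] == ROLE_DMSO, "raw_value"]
    pos = plate_wells.loc[plate_wells["role"] == ROLE_POSITIVE, "raw_value"]
    return NormalizationContext(
        plate_id=str(plate_wells["plate_id"].iloc[0]),
        endpoint_id=str(plate_wells["endpoint_id"].iloc[0]),
        run_index=int(plate_wells["run_index"].iloc[0]),
        v_dmso=float(dmso.median()),
        v_pos=float(pos.median()),
        n_dmso_wells=int(dmso.size),
        n_pos_wells=int(pos.size),
    )


def rescale_baseline(
    curve: ResponseCurve,
    baseline_estimator: Optional[Callable[[ResponseCurve], float]] = None,
    n_baseline_points: int = 2,
) -> ResponseCurve:
    """Shift a curve so its baseline is 0%.

    The default estimator is the median response of the ``n_baseline_points``
    lowest tested concentrations. A curve whose baseline estimate is already
    zero is returned unchanged; the operation is idempotent.
    """
    if baseline_estimator is None:
        baseline = float(np.median(curve.response[:n_baseline_points]))
    else:
        baseline = float(baseline_estimator(curve))
    if baseline == 0.0:
        return curve
    return curve.with_response(curve.response - baseline)


def pattern_correct(plate_wells: pd.DataFrame, method: str = "none") -> pd.DataFrame:
    """Remove an additive row/column pattern from one plate's raw reads.

    ``none`` is the identity. ``median_polish`` estimates additive row and
    column effects from the plate's baseline wells -- the DMSO wells plus
    each substance's lowest tested concentration -- removes them from every
    non-empty well (interpolating the column effect linearly across columns
    without baseline coverage), and restores the plate-wide DMSO median.
    """
    if method == "none":
        return plate_wells
    if method != "median_polish":
        raise ConfigError(f"unknown pattern correction method {method!r}; "
                          "valid methods: none, median_polish")

    df = plate_wells.reset_index(drop=True).copy()
    raw = df["raw_value"].to_numpy(dtype=float)
    nonempty = (df["role"] != ROLE_EMPTY).to_numpy()
    is_dmso = (df["role"] == ROLE_DMSO).to_numpy()

    is_sub = (df["role"] == ROLE_SUBSTANCE).to_numpy()
    lowest = np.zeros(len(df), dtype=bool)
    if is_sub.any():
        conc_min = df.loc[is_sub].groupby("substance_id")["concentration"].transform("min")
        lowest[is_sub] = (
            df.loc[is_sub, "concentration"].to_numpy() == conc_min.to_numpy()
        )
    baseline = is_dmso | lowest
    if not baseline.any():
        return plate_wells

    dmso_median_before = float(np.median(raw[is_dmso])) if is_dmso.any() else None
    grand = float(np.median(raw[baseline]))

    # column effects first: baseline wells within one column share the column
    # effect directly, whereas a row mixes several columns' effects
    cols = df["col"].to_numpy(dtype=float)
    known_cols = np.unique(cols[baseline])
    col_effects = np.array(
        [float(np.median(raw[baseline & (cols == c)])) - grand for c in known_cols]
    )
    if known_cols.size >= 2:
        # linear interpolation inside the covered range, linear extrapolation
        # from the two nearest covered columns at the edges
        all_cols = np.unique(cols[nonempty])
        effect_for = {}
        for c in all_cols:
            if c <= known_cols[0]:
                x0, x1 = known_cols[:2]
                y0, y1 = col_effects[:2]
            elif c >= known_cols[-1]:
                x0, x1 = known_cols[-2:]
                y0, y1 = col_effects[-2:]
            else:
                i = int(np.searchsorted(known_cols, c))
                x0, x1 = known_cols[i - 1], known_cols[i]
                y0, y1 = col_effects[i - 1], col_effects[i]
            effect_for[c] = y0 + (y1 - y0) * (c - x0) / (x1 - x0)
        for c, eff in effect_for.items():
            raw[nonempty & (cols == c)] -= eff
    elif known_cols.size == 1:
        raw[nonempty] -= col_effects[0]

    rows = df["row"].to_numpy()
    for letter in np.unique(rows[baseline]):
        sel = baseline & (rows == letter)
        effect = float(np.median(raw[sel])) - grand
        raw[nonempty & (rows == letter)] -= effect

    if dmso_median_before is not None:
        raw[nonempty] += dmso_median_before - float(np.median(raw[is_dmso]))

    df["raw_value"] = raw
    return df


class NormalizedStudy(NamedTuple):
    curves: List[ResponseCurve]
    dmso_responses: Dict[str, np.ndarray]  # endpoint -> pooled DMSO % responses
    frame: pd.DataFrame  # long table incl. pre-rescale percent response
    failed: List[tuple]  # (substance, endpoint, run) with too few points


def normalize_study(
    wells: pd.DataFrame,
    endpoints: Dict[str, EndpointSpec],
    pattern_method: str = "none",
    n_baseline_points: int = 2,
) -> NormalizedStudy:
    """Normalize a well table into per-run response curves.

    Returns curves on the internal effect-positive scale (baseline-rescaled,
    decrease endpoints flipped), the pooled normalized DMSO responses per
    endpoint (for noise-threshold derivation), and a long frame carrying both
    the plain percent response (``percent_response``) and the processed
    response (``response``) of every substance well. Curves with fewer than 4
    points are reported in ``failed`` and excluded.
    """
    curve_rows: List[pd.DataFrame] = []
    dmso_acc: Dict[str, List[np.ndarray]] = {}

    for (plate_id, endpoint_id, run_index), plate in wells.groupby(
        ["plate_id", "endpoint_id", "run_index"], sort=True
    ):
        if endpoint_id not in endpoints:
            raise IntegrityError(f"no EndpointSpec for endpoint {endpoint_id!r}")
        spec = endpoints[endpoint_id]
        sign = -1.0 if spec.direction == DECREASE else 1.0
        plate = pattern_correct(plate, pattern_method)
        ctx = plate_context(plate)

        dmso_mask = plate["role"] == ROLE_DMSO
        dmso_acc.setdefault(endpoint_id, []).append(
            sign * np.asarray(percent_response(plate.loc[dmso_mask, "raw_value"].to_numpy(), ctx))
        )

        sub = plate[plate["role"] == ROLE_SUBSTANCE]
        if sub.empty:
            continue
        pr = np.asarray(percent_response(sub["raw_value"].to_numpy(), ctx))
        curve_rows.append(
            pd.DataFrame(
                {
                    "substance_id": sub["substance_id"].to_numpy(),
                    "endpoint_id": endpoint_id,
                    "run_index": run_index,
                    "concentration": sub["concentration"].to_numpy(),
                    "percent_response": pr,
                    "flipped_response": sign * pr,
                }
            )
        )

    dmso_responses = {
        eid: np.concatenate(chunks) for eid, chunks in sorted(dmso_acc.items())
    }
    if not curve_rows:
        empty = pd.DataFrame(
            columns=["substance_id", "endpoint_id", "run_index",
                     "concentration", "percent_response", "response"]
        )
        return NormalizedStudy([], dmso_responses, empty, [])

    long = pd.concat(curve_rows, ignore_index=True)
    curves: List[ResponseCurve] = []
    failed: List[tuple] = []
    out_frames: List[pd.DataFrame] = []
    for (sub_id, endpoint_id, run_index), grp in long.groupby(
        ["substance_id", "endpoint_id", "run_index"], sort=True
    ):
        grp = grp.sort_values("concentration")
        if len(grp) < 4:
            failed.append((sub_id, endpoint_id, int(run_index)))
            continue
        curve = ResponseCurve(
            substance_id=str(sub_id),
            endpoint_id=str(endpoint_id),
            run_index=int(run_index),
            log10_concentration=np.log10(grp["concentration"].to_numpy(dtype=float)),
            response=grp["flipped_response"].to_numpy(dtype=float),
            direction=endpoints[str(endpoint_id)].direction,
        )
        curve = rescale_baseline(curve, n_baseline_points=n_baseline_points)
        curves.append(curve)
        out = grp[["substance_id", "endpoint_id", "run_index",
                   "concentration", "percent_response"]].copy()
        out["response"] = curve.response
        out_frames.append(out)

    frame = pd.concat(out_frames, ignore_index=True) if out_frames else long
    return NormalizedStudy(curves, dmso_responses, frame, failed)


def curves_to_frame(curves: List[ResponseCurve]) -> pd.DataFrame:
    """Long table (substance, endpoint, run, concentration, response)."""
    parts = [
        pd.DataFrame(
            {
                "substance_id": c.substance_id,
                "endpoint_id": c.endpoint_id,
                "run_index": c.run_index,
                "concentration": c.concentration,
                "response": c.response,
                "direction": c.direction,
            }
        )
        for c in curves
    ]
    cols = ["substance_id", "endpoint_id", "run_index", "concentration", "response", "direction"]
    return pd.concat(parts, ignore_index=True)[cols] if parts else pd.DataFrame(columns=cols)


def frame_to_curves(
    frame: pd.DataFrame, endpoints: Optional[Dict[str, EndpointSpec]] = None
) -> List[ResponseCurve]:
    curves = []
    for (sub_id, endpoint_id, run_index), grp in frame.groupby(
        ["substance_id", "endpoint_id", "run_index"], sort=True
    ):
        grp = grp.sort_values("concentration")
        if endpoints is not None and str(endpoint_id) in endpoints:
            direction = endpoints[str(endpoint_id)].direction
        elif "direction" in grp.columns:
            direction = str(grp["direction"].iloc[0])
        else:
            direction = "increase"
        curves.append(
            ResponseCurve(
                substance_id=str(sub_id),
                endpoint_id=str(endpoint_id),
                run_index=int(run_index),
                log10_concentration=np.log10(grp["concentration"].to_numpy(dtype=float)),
                response=grp["response"].to_numpy(dtype=float),
                direction=direction,
            )
        )
    return curves
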