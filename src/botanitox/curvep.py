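"""Noise filtering of concentration-response curves and activity parameters.

Each normalized curve is cleaned against a per-endpoint noise threshold and
summarized by four activity parameters:

* wAUC -- the trapezoidal integral of the filtered response over log10
  concentration, normalized by ``100 * (log10 c_max - log10 c_min)`` so a
  full-range 100% response gives exactly 1; signed per the endpoint's
  direction of effect. A curve with no above-threshold response has
  wAUC = 0 exactly, and |wAUC| > 0 defines a significant response.
* POD -- the concentration at which the response first equals the noise
  threshold (log10-linear interpolation on the pre-zeroing magnitudes).
* EC50 / Emax -- the concentration of half-maximal response and the maximal
  response of the filtered curve.

The filter is deliberately simple and monotone: (1) isolated single-point
spikes are replaced by the mean of their neighbors, iterated to a fixpoint;
(2) sub-threshold responses are set to 0; (3) a weak monotone envelope is
enforced in the direction of effect -- a small (< threshold) drop below the
running maximum is clipped to the running maximum, while a larger loss of
response is treated as noise beyond recovery and zeroes the remainder of the
curve.
"""
from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    DECREASE,
    CurveMetrics,
    IntegrityError,
    NoiseThreshold,
    ResponseCurve,
)


def derive_threshold(
    dmso_responses: np.ndarray,
    curves: Sequence[ResponseCurve],
    k: float = 3.0,
    *,
    floor_quantile: float = 0.95,
    n_baseline_points: int = 2,
    min_value: float = 1.0,
    endpoint_id: str = "",
) -> NoiseThreshold:
    """Noise level from DMSO-well variability and the substance data.

    value = max(k * SD(DMSO responses), data_floor, min_value) where the
    data floor is the ``floor_quantile`` quantile of |response| at the
    ``n_baseline_points`` lowest concentrations pooled across all substance
    curves. ``min_value`` guards degenerate zero-variance input.
    """
    dmso = np.asarray(dmso_responses, dtype=float)
    if dmso.size < 8:
        raise IntegrityError(
            f"need at least 8 DMSO response values to derive a noise threshold, got {dmso.size}"
        )
    if k <= 0:
        raise ValueError("SD multiplier k must be positive")
    sd = float(np.std(dmso, ddof=1))
    pooled = [np.abs(c.response[:n_baseline_points]) for c in curves]
    floor = float(np.quantile(np.concatenate(pooled), floor_quantile)) if pooled else 0.0
    return NoiseThreshold(
        endpoint_id=endpoint_id,
        value=max(k * sd, floor, min_value),
        sd_dmso=sd,
        k=k,
        data_floor=floor,
    )


def remove_spikes(response: np.ndarray, t: float) -> np.ndarray:
    """Replace isolated interior spikes by their neighbor mean, to fixpoint.

    A spike is an interior point differing from both neighbors by more than
    ``t`` with opposite-signed jumps in and out (a one-point peak or dip).
    """
    r = np.array(response, dtype=float)
    changed = True
    while changed:
        changed = False
        for i in range(1, r.size - 1):
            d_prev = r[i] - r[i - 1]
            d_next = r[i] - r[i + 1]
            if abs(d_prev) > t and abs(d_next) > t and d_prev * d_next > 0:
                r[i] = 0.5 * (r[i - 1] + r[i + 1])
                changed = True
    return r


def _zero_and_envelope(despiked: np.ndarray, t: float) -> np.ndarray:
    r = despiked.copy()
    r[np.abs(r) < t] = 0.0
    running_max = 0.0
    for i in range(r.size):
        if r[i] >= running_max:
            running_max = r[i]
        else:
            if running_max - r[i] < t:
                r[i] = running_max
            else:
                r[i:] = 0.0
                break
    return r


def filter_curve(curve: ResponseCurve, threshold: NoiseThreshold) -> ResponseCurve:
    """Apply spike removal, sub-threshold zeroing, and the monotone envelope."""
    despiked = remove_spikes(curve.response, threshold.value)
    return curve.with_response(_zero_and_envelope(despiked, threshold.value))


def compute_wauc(filtered: ResponseCurve) -> float:
    """Range-normalized trapezoidal activity integral of a filtered curve."""
    x = filtered.log10_concentration
    y = filtered.response
    if x.size < 2:
        raise ValueError("wAUC needs at least 2 points")
    wauc = float(np.trapezoid(y, x)) / (100.0 * (x[-1] - x[0]))
    if filtered.direction == DECREASE:
        wauc = -wauc
    return wauc


def compute_pod(
    filtered: ResponseCurve,
    threshold: NoiseThreshold,
    prefilter_response: Optional[np.ndarray] = None,
) -> Optional[float]:
    """Concentration (ug/mL) where the response first equals the threshold.

    Absent when the filtered curve never reaches the threshold. Interpolation
    is linear in log10 concentration on the pre-zeroing magnitudes
    (``prefilter_response``, defaulting to the filtered responses) so a curve
    crossing between grid points gets a between-grid POD; a first point
    already above threshold returns the lowest tested concentration. Ties and
    flat segments resolve to the lowest qualifying concentration.
    """
    t = threshold.value
    y = filtered.response
    nonzero = np.flatnonzero(y != 0.0)
    if nonzero.size == 0:
        return None
    i = int(nonzero[0])
    x = filtered.log10_concentration
    if i == 0:
        return float(10.0 ** x[0])
    m = np.abs(prefilter_response if prefilter_response is not None else y)
    m0, m1 = float(m[i - 1]), float(m[i])
    if m1 <= m0 or m0 >= t:
        return float(10.0 ** x[i - 1]) if m0 >= t else float(10.0 ** x[i])
    frac = (t - m0) / (m1 - m0)
    frac = min(max(frac, 0.0), 1.0)
    return float(10.0 ** (x[i - 1] + frac * (x[i] - x[i - 1])))


def compute_ec50_emax(
    filtered: ResponseCurve,
) -> Tuple[Optional[float], Optional[float]]:
    """(EC50 in ug/mL, Emax in %) of a filtered curve; (None, None) if all-zero.

    Emax is the response of maximal magnitude; EC50 is the concentration
    (log10-linear interpolation) where the response first reaches Emax/2.
    """
    y = filtered.response
    if not np.any(y != 0.0):
        return None, None
    x = filtered.log10_concentration
    i_emax = int(np.argmax(np.abs(y)))
    emax = float(y[i_emax])
    half = emax / 2.0
    above = np.flatnonzero(y >= half) if emax > 0 else np.flatnonzero(y <= half)
    i = int(above[0])
    if i == 0:
        return float(10.0 ** x[0]), emax
    y0, y1 = float(y[i - 1]), float(y[i])
    if y1 == y0:
        return float(10.0 ** x[i]), emax
    frac = (half - y0) / (y1 - y0)
    frac = min(max(frac, 0.0), 1.0)
    return float(10.0 ** (x[i - 1] + frac * (x[i] - x[i - 1]))), emax


def process_curve(curve: ResponseCurve, threshold: NoiseThreshold) -> CurveMetrics:
    """Filter one curve and extract wAUC, POD, EC50, Emax and significance.

    By construction ``significant``, ``|wAUC| > 0`` and "POD present" are
    equivalent.
    """
    despiked = remove_spikes(curve.response, threshold.value)
    filtered = curve.with_response(_zero_and_envelope(despiked, threshold.value))
    wauc = compute_wauc(filtered)
    significant = wauc != 0.0
    if significant:
        pod = compute_pod(filtered, threshold, prefilter_response=despiked)
        ec50, emax = compute_ec50_emax(filtered)
        if emax is not None and curve.direction == DECREASE:
            emax = -emax
    else:
        pod = ec50 = emax = None
    return CurveMetrics(
        substance_id=curve.substance_id,
        endpoint_id=curve.endpoint_id,
        run_index=curve.run_index,
        wauc=wauc,
        pod=pod,
        ec50=ec50,
        emax=emax,
        significant=significant,
    )


def process_curves(
    curves: Iterable[ResponseCurve], thresholds: dict
) -> List[CurveMetrics]:
    """Process curves against their per-endpoint thresholds."""
    out = []
    for curve in curves:
        if curve.endpoint_id not in thresholds:
            raise IntegrityError(f"no noise threshold for endpoint {curve.endpoint_id!r}")
        out.append(process_curve(curve, thresholds[curve.endpoint_id]))
    return out


METRICS_COLUMNS = [
    "substance_id", "endpoint_id", "run_index",
    "wauc", "pod", "ec50", "emax", "significant",
]


def metrics_to_frame(metrics: Iterable[CurveMetrics]) -> pd.DataFrame:
    rows = [
        {
            "substance_id": m.substance_id,
            "endpoint_id": m.endpoint_id,
            "run_index": m.run_index,
            "wauc": m.wauc,
            "pod": m.pod,
            "ec50": m.ec50,
            "emax": m.emax,
            "significant": m.significant,
        }
        for m in metrics
    ]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def frame_to_metrics(frame: pd.DataFrame) -> List[CurveMetrics]:
    def opt(v):
        return None if pd.isna(v) else float(v)

    return [
        CurveMetrics(
            substance_id=str(r["substance_id"]),
            endpoint_id=str(r["endpoint_id"]),
            run_index=int(r["run_index"]),
            wauc=float(r["wauc"]),
            pod=opt(r["pod"]),
            ec50=opt(r["ec50"]),
            emax=opt(r["emax"]),
            significant=bool(r["significant"]),
        )
        for r in frame.to_dict("records")
    ]
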