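"""Aggregate per-run curve metrics into one activity call per substance x endpoint.

A substance is called active on an endpoint when more than half of its
replicate curves show a significant response (two of three runs in the
standard design). Potency parameters (POD, EC50, Emax) are summarized as the
median over the runs in which they were assigned; inactive calls carry no
potency values. Active calls can subsequently be relabeled inconclusive when
a paired counter screen suggests assay interference, real-time cytotoxicity
time points can be integrated into a single summary call, and the
aromatase-vs-ER-antagonism POD comparison can add a confounding flag.
"""
from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    FLAG_AROER,
    FLAG_INTERFERENCE,
    LABEL_ACTIVE,
    LABEL_INACTIVE,
    LABEL_INCONCLUSIVE,
    CurveMetrics,
    EndpointCall,
    EndpointSpec,
    IntegrityError,
)


def _median_present(values: Iterable[Optional[float]]) -> Optional[float]:
    present = [v for v in values if v is not None and not np.isnan(v)]
    if not present:
        return None
    return float(np.median(present))


def call_endpoint(
    metrics: Sequence[CurveMetrics], n_runs: Optional[int] = None
) -> EndpointCall:
    """Majority-rule call over the replicate runs of one substance x endpoint.

    ``n_runs`` may exceed ``len(metrics)`` when some runs failed to yield a
    usable curve; failed runs count as non-significant.
    """
    if not metrics:
        raise IntegrityError("call_endpoint needs at least one run")
    subs = {m.substance_id for m in metrics}
    eps = {m.endpoint_id for m in metrics}
    if len(subs) != 1 or len(eps) != 1:
        raise IntegrityError(
            f"call_endpoint received mixed substances {subs} / endpoints {eps}"
        )
    n = max(len(metrics), n_runs or 0)
    n_significant = sum(1 for m in metrics if m.significant)
    active = n_significant / n > 0.5
    median_wauc = float(np.median([m.wauc for m in metrics]))
    return EndpointCall(
        substance_id=metrics[0].substance_id,
        endpoint_id=metrics[0].endpoint_id,
        label=LABEL_ACTIVE if active else LABEL_INACTIVE,
        n_significant=n_significant,
        n_runs=n,
        median_pod=_median_present(m.pod for m in metrics) if active else None,
        median_ec50=_median_present(m.ec50 for m in metrics) if active else None,
        median_emax=_median_present(m.emax for m in metrics) if active else None,
        median_wauc=median_wauc,
    )


def flag_interference(
    call: EndpointCall,
    counter_calls: Sequence[EndpointCall],
    tolerance: float = 3.0,
) -> EndpointCall:
    """Relabel an active call inconclusive when a paired counter screen is
    active within ``tolerance``-fold of the primary POD. Idempotent; inactive
    calls are never relabeled."""
    if call.label != LABEL_ACTIVE or call.median_pod is None:
        return call
    for counter in counter_calls:
        if counter.label == LABEL_ACTIVE and counter.median_pod is not None:
            if counter.median_pod <= tolerance * call.median_pod:
                return call.with_label(LABEL_INCONCLUSIVE, frozenset({FLAG_INTERFERENCE}))
    return call


def integrate_cytotox(
    calls: Sequence[EndpointCall], family: Optional[str] = None
) -> EndpointCall:
    """Summarize real-time cytotoxicity calls across time points.

    The summary wAUC is the sum of the per-timepoint median wAUCs; the
    summary POD is the most potent (minimum) POD across active time points;
    the summary is active when any time point is active. EC50/Emax are taken
    from the time point achieving the minimum POD.
    """
    if not calls:
        raise IntegrityError("integrate_cytotox needs at least one timepoint call")
    subs = {c.substance_id for c in calls}
    if len(subs) != 1:
        raise IntegrityError(f"integrate_cytotox received mixed substances {subs}")
    family = family or calls[0].endpoint_id
    wauc_sum = float(np.sum([c.median_wauc for c in calls]))
    active_calls = [c for c in calls if c.label == LABEL_ACTIVE and c.median_pod is not None]
    any_active = any(c.label == LABEL_ACTIVE for c in calls)
    if active_calls:
        best = min(active_calls, key=lambda c: c.median_pod)
        pod, ec50, emax = best.median_pod, best.median_ec50, best.median_emax
    else:
        pod = ec50 = emax = None
    flags = frozenset().union(*(c.flags for c in calls))
    return EndpointCall(
        substance_id=calls[0].substance_id,
        endpoint_id=family,
        label=LABEL_ACTIVE if any_active else LABEL_INACTIVE,
        n_significant=sum(c.n_significant for c in calls),
        n_runs=sum(c.n_runs for c in calls),
        median_pod=pod if any_active else None,
        median_ec50=ec50 if any_active else None,
        median_emax=emax if any_active else None,
        median_wauc=wauc_sum,
        flags=flags,
    )


def flag_aroer(
    aromatase_call: EndpointCall,
    er_antagonism_call: EndpointCall,
    dilution_factor: float = 3.0,
) -> EndpointCall:
    """Flag aromatase-inhibition activity that ER antagonism may explain.

    When both calls are active and the ER-antagonism POD lies within
    ``dilution_factor``-fold of the aromatase POD, the aromatase call gains
    the ``aroer_confounded`` flag; otherwise it is returned unchanged.
    """
    if aromatase_call.substance_id != er_antagonism_call.substance_id:
        raise IntegrityError("AroER comparison requires calls for the same substance")
    if (
        aromatase_call.label == LABEL_ACTIVE
        and er_antagonism_call.label == LABEL_ACTIVE
        and aromatase_call.median_pod is not None
        and er_antagonism_call.median_pod is not None
        and er_antagonism_call.median_pod <= dilution_factor * aromatase_call.median_pod
    ):
        return aromatase_call.with_flags(frozenset({FLAG_AROER}))
    return aromatase_call


def call_study(
    metrics: Sequence[CurveMetrics],
    endpoints: Dict[str, EndpointSpec],
    *,
    n_runs: Optional[int] = None,
    interference_tolerance: float = 3.0,
    aroer_pair: Optional[tuple] = None,
    aroer_dilution_factor: float = 3.0,
) -> List[EndpointCall]:
    """Call every substance x endpoint, then apply the counter-screen and
    AroER rules across endpoints.

    ``aroer_pair`` optionally names ``(aromatase_endpoint, er_antagonism_endpoint)``.
    """
    grouped: Dict[tuple, List[CurveMetrics]] = {}
    for m in metrics:
        grouped.setdefault((m.substance_id, m.endpoint_id), []).append(m)
    calls: Dict[tuple, EndpointCall] = {
        key: call_endpoint(sorted(runs, key=lambda m: m.run_index), n_runs=n_runs)
        for key, runs in sorted(grouped.items())
    }

    counters_for: Dict[str, List[str]] = {}
    for eid, spec in endpoints.items():
        if spec.is_counter_screen and spec.paired_primary:
            counters_for.setdefault(spec.paired_primary, []).append(eid)
    for (sub, eid), call in list(calls.items()):
        counter_ids = counters_for.get(eid, [])
        counter_calls = [
            calls[(sub, cid)] for cid in counter_ids if (sub, cid) in calls
        ]
        if counter_calls:
            calls[(sub, eid)] = flag_interference(
                call, counter_calls, tolerance=interference_tolerance
            )

    if aroer_pair is not None:
        arom_id, er_id = aroer_pair
        for (sub, eid) in list(calls):
            if eid == arom_id and (sub, er_id) in calls:
                calls[(sub, eid)] = flag_aroer(
                    calls[(sub, eid)], calls[(sub, er_id)],
                    dilution_factor=aroer_dilution_factor,
                )
    return list(calls.values())


CALL_COLUMNS = [
    "substance_id", "endpoint_id", "label", "n_significant", "n_runs",
    "median_pod", "median_ec50", "median_emax", "median_wauc", "flags",
]


def calls_to_frame(calls: Iterable[EndpointCall]) -> pd.DataFrame:
    rows = [
        {
            "substance_id": c.substance_id,
            "endpoint_id": c.endpoint_id,
            "label": c.label,
            "n_significant": c.n_significant,
            "n_runs": c.n_runs,
            "median_pod": c.median_pod,
            "median_ec50": c.median_ec50,
            "median_emax": c.median_emax,
            "median_wauc": c.median_wauc,
            "flags": ";".join(sorted(c.flags)),
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def frame_to_calls(frame: pd.DataFrame) -> List[EndpointCall]:
    def opt(v):
        return None if pd.isna(v) else float(v)

    calls = []
    for r in frame.to_dict("records"):
        flags = r.get("flags")
        flagset = frozenset(str(flags).split(";")) if isinstance(flags, str) and flags else frozenset()
        calls.append(
            EndpointCall(
                substance_id=str(r["substance_id"]),
                endpoint_id=str(r["endpoint_id"]),
                label=str(r["label"]),
                n_significant=int(r["n_significant"]),
                n_runs=int(r["n_runs"]),
                median_pod=opt(r["median_pod"]),
                median_ec50=opt(r["median_ec50"]),
                median_emax=opt(r["median_emax"]),
                median_wauc=float(r["median_wauc"]),
                flags=flagset,
            )
        )
    return calls
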