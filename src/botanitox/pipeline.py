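"""End-to-end orchestration: simulated plates -> result tables.

Chains the stage modules with a single :class:`~botanitox.config.StudyConfig`
so that a whole study can be run (and reproduced bit-for-bit from a seed) in
one call. Each stage remains individually usable; this module only wires
them together.
"""
from __future__ import annotations

from typing import Dict, Optional

import pandas as pd

from . import activity_calls, curvep, normalization, profiling, synthetic_data
from .config import StudyConfig
from .io import frame_to_endpoints, frame_to_substances
from .types import EndpointSpec


def derive_thresholds(
    normalized: normalization.NormalizedStudy,
    endpoints: Dict[str, EndpointSpec],
    config: StudyConfig,
) -> Dict[str, curvep.NoiseThreshold]:
    by_endpoint: Dict[str, list] = {}
    for curve in normalized.curves:
        by_endpoint.setdefault(curve.endpoint_id, []).append(curve)
    thresholds = {}
    for eid in sorted(endpoints):
        if eid not in normalized.dmso_responses:
            continue
        thresholds[eid] = curvep.derive_threshold(
            normalized.dmso_responses[eid],
            by_endpoint.get(eid, []),
            k=config.threshold_k,
            floor_quantile=config.floor_quantile,
            n_baseline_points=config.baseline_points,
            min_value=config.min_threshold,
            endpoint_id=eid,
        )
    return thresholds


def run_pipeline(
    design: synthetic_data.SimulationDesign,
    config: Optional[StudyConfig] = None,
) -> Dict[str, pd.DataFrame]:
    """Simulate a study and run every analysis stage.

    Returns a dict of result tables: curves, thresholds, metrics, calls,
    pod_matrix, wauc_matrix, cluster orders, correlations, group correlation
    curves, enrichment, rankings, embedding, plus the generating truth table.
    """
    config = (config or StudyConfig()).validate()
    study = synthetic_data.generate_study(design)
    endpoints = frame_to_endpoints(study.endpoints)
    substances = frame_to_substances(study.substances)

    normalized = normalization.normalize_study(
        study.wells, endpoints,
        pattern_method=config.pattern_correction,
        n_baseline_points=config.baseline_points,
    )
    thresholds = derive_thresholds(normalized, endpoints, config)
    metrics = curvep.process_curves(normalized.curves, thresholds)
    calls = activity_calls.call_study(
        metrics, endpoints,
        n_runs=design.runs,
        interference_tolerance=config.interference_tolerance,
        aroer_dilution_factor=config.aroer_dilution_factor,
    )
    matrices = profiling.build_matrices(
        calls, substances, endpoints, imputation_pod=config.imputation_pod
    )
    clusters = profiling.cluster_orders(matrices.log10_pod)
    corr = profiling.pairwise_correlation(matrices)
    activity = profiling.substance_activity(calls, endpoints)
    group_curves = profiling.group_correlation_curves(corr, matrices.groups, activity)
    coarse = {s.substance_id: s.group for s in substances if not s.excluded}
    fine = {
        s.substance_id: f"{s.group}:{'const' if s.formulation == 'constituent' else 'extract'}"
        for s in substances
        if not s.excluded
    }
    enrichment = profiling.endpoint_enrichment(matrices, coarse)
    enrichment_fine = profiling.endpoint_enrichment(matrices, coarse, fine)
    rankings = profiling.rank_substances(
        matrices, calls, endpoints, zscore_on=config.zscore_on
    )
    embedding = profiling.embed_2d(
        matrices,
        perplexity=config.perplexity,
        iterations=config.tsne_iterations,
        seed=config.seed,
    )

    thresholds_frame = pd.DataFrame(
        [
            {"endpoint_id": t.endpoint_id, "value": t.value, "sd_dmso": t.sd_dmso,
             "k": t.k, "data_floor": t.data_floor}
            for t in thresholds.values()
        ]
    )
    return {
        "truths": study.truths,
        "substances": study.substances,
        "endpoints": study.endpoints,
        "curves": normalized.frame,
        "thresholds": thresholds_frame,
        "metrics": curvep.metrics_to_frame(metrics),
        "calls": activity_calls.calls_to_frame(calls),
        "pod_matrix": matrices.log10_pod.rename_axis("substance_id").reset_index(),
        "wauc_matrix": matrices.wauc.rename_axis("substance_id").reset_index(),
        "cluster_rows": pd.DataFrame({"substance_id": clusters.row_order}),
        "cluster_cols": pd.DataFrame({"endpoint_id": clusters.col_order}),
        "correlations": corr.rename_axis("substance_id").reset_index(),
        "group_correlation_curves": group_curves,
        "enrichment": enrichment,
        "enrichment_fine": enrichment_fine,
        "rankings": rankings,
        "embedding": embedding.reset_index(),
    }
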