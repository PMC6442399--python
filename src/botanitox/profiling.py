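"""Bioactivity profile analytics over the substances x endpoints matrices.

Two matrices drive everything downstream:

* ``log10_pod`` -- substances x primary endpoints, log10 of the median POD
  for active calls and log10 of the imputation POD (default 1000 ug/mL) for
  inactive or inconclusive calls;
* ``wauc`` -- substances x all assay readouts (counter screens included),
  the median wAUC for active calls and 0 otherwise.

On top of these sit hierarchical clustering for heatmap ordering, pairwise
Spearman correlation with the screening-specific assignment rules, one-way
ANOVA F-value / F-ratio enrichment of endpoints across botanical groups,
three substance-ranking schemes, and a 2-D t-SNE embedding of wAUC profiles.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.manifold import TSNE

from .types import (
    LABEL_ACTIVE,
    ConfigError,
    EndpointCall,
    EndpointSpec,
    IntegrityError,
    SubstanceSpec,
)


@dataclass
class ProfileMatrices:
    """Imputed POD and wAUC profile matrices plus the substance -> group map."""

    log10_pod: pd.DataFrame  # substances x primary endpoints
    wauc: pd.DataFrame  # substances x all assay readouts
    groups: pd.Series  # substance_id -> group
    imputation_pod: float

    @property
    def substances(self) -> List[str]:
        return list(self.log10_pod.index)


def build_matrices(
    calls: Sequence[EndpointCall],
    substances: Sequence[SubstanceSpec],
    endpoints: Mapping[str, EndpointSpec],
    imputation_pod: float = 1000.0,
) -> ProfileMatrices:
    """Assemble the profile matrices from one call per substance x endpoint.

    Active cells carry log10(median POD); inactive and inconclusive cells
    carry log10(imputation POD). The wAUC matrix keeps a column for every
    assay readout including counter screens; non-active cells are 0.
    Excluded substances are dropped. Missing (substance, endpoint) cells are
    an integrity error.
    """
    kept = [s for s in substances if not s.excluded]
    sub_ids = [s.substance_id for s in kept]
    all_eids = list(endpoints)
    primary_eids = [e for e in all_eids if not endpoints[e].is_counter_screen]

    call_map = {(c.substance_id, c.endpoint_id): c for c in calls}
    missing = [
        (s, e) for s in sub_ids for e in all_eids if (s, e) not in call_map
    ]
    if missing:
        raise IntegrityError(
            f"missing calls for {len(missing)} substance x endpoint pair(s), "
            f"e.g. {missing[:5]}"
        )

    log_imp = np.log10(imputation_pod)
    pod = pd.DataFrame(log_imp, index=sub_ids, columns=primary_eids, dtype=float)
    wauc = pd.DataFrame(0.0, index=sub_ids, columns=all_eids, dtype=float)
    for s in sub_ids:
        for e in all_eids:
            c = call_map[(s, e)]
            if c.label == LABEL_ACTIVE:
                wauc.loc[s, e] = c.median_wauc
                if e in pod.columns and c.median_pod is not None:
                    pod.loc[s, e] = np.log10(c.median_pod)
    groups = pd.Series({s.substance_id: s.group for s in kept}, name="group")
    return ProfileMatrices(pod, wauc, groups.loc[sub_ids], imputation_pod)


@dataclass
class ClusterResult:
    row_order: List[str]
    col_order: List[str]
    row_linkage: Optional[np.ndarray]
    col_linkage: Optional[np.ndarray]


def _linkage_order(values: np.ndarray, labels: List[str]) -> Tuple[List[str], Optional[np.ndarray]]:
    if len(labels) < 2:
        return list(labels), None
    # lexicographic pre-sort of labels makes tie-breaking deterministic
    order = np.argsort(np.asarray(labels, dtype=object))
    values = values[order]
    labels_sorted = [labels[i] for i in order]
    Z = linkage(values, method="average", metric="euclidean")
    leaves = leaves_list(Z)
    return [labels_sorted[i] for i in leaves], Z


def cluster_orders(matrix: pd.DataFrame) -> ClusterResult:
    """Heatmap row/column orders by UPGMA (average-linkage, Euclidean)."""
    row_order, row_Z = _linkage_order(matrix.to_numpy(dtype=float), list(matrix.index))
    col_order, col_Z = _linkage_order(matrix.to_numpy(dtype=float).T, list(matrix.columns))
    return ClusterResult(row_order, col_order, row_Z, col_Z)


def pairwise_correlation(matrices: ProfileMatrices) -> pd.DataFrame:
    """Substance x substance Spearman correlation of wAUC profiles.

    After the raw rank correlation: negative values are set to 0; pairs for
    which the rank correlation is undefined because a profile is constant get
    1 when both substances have all-zero responses and 0 otherwise; the
    diagonal is 1.
    """
    W = matrices.wauc.to_numpy(dtype=float)
    ids = list(matrices.wauc.index)
    n = len(ids)
    ranks = np.vstack([rankdata(row) for row in W]) if n else np.empty((0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(ranks) if n > 1 else np.ones((n, n))
    corr = np.atleast_2d(np.asarray(corr, dtype=float))

    zero = np.all(W == 0.0, axis=1)
    constant = np.ptp(W, axis=1) == 0.0
    for i in range(n):
        for j in range(n):
            if constant[i] or constant[j]:
                corr[i, j] = 1.0 if (zero[i] and zero[j]) else 0.0
    corr[corr < 0.0] = 0.0
    corr = np.clip(corr, 0.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=ids, columns=ids)


def substance_activity(calls: Sequence[EndpointCall], endpoints: Mapping[str, EndpointSpec]) -> pd.DataFrame:
    """Per-substance activity summary: active primary endpoint count and total |wAUC|."""
    rows: Dict[str, Dict[str, float]] = {}
    for c in calls:
        rec = rows.setdefault(c.substance_id, {"n_active": 0, "sum_wauc": 0.0})
        spec = endpoints.get(c.endpoint_id)
        if c.label == LABEL_ACTIVE:
            rec["sum_wauc"] += c.median_wauc
            if spec is not None and not spec.is_counter_screen:
                rec["n_active"] += 1
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "substance_id"
    return out.sort_index()


def most_active_lots(
    groups: pd.Series, activity: pd.DataFrame
) -> Dict[str, str]:
    """The most active substance of each group: highest active-endpoint
    count, ties by larger |sum wAUC|, then lexicographic id."""
    best: Dict[str, str] = {}
    for sub in sorted(groups.index):
        g = groups[sub]
        n_act = float(activity["n_active"].get(sub, 0))
        mag = abs(float(activity["sum_wauc"].get(sub, 0.0)))
        key = (n_act, mag)
        if g not in best or key > best[g][0]:
            best[g] = (key, sub)
    return {g: sub for g, (key, sub) in best.items()}


def group_correlation_curves(
    corr: pd.DataFrame,
    groups: pd.Series,
    activity: pd.DataFrame,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Within- and between-group cumulative correlation distributions.

    For every group with at least ``min_group_size`` members: the within
    distribution pools the correlations of all unordered member pairs; the
    between distribution pairs each member with the most active lot of every
    other group (emitted per comparator group, plus a pooled curve with
    ``other_group = "(all)"``). Values are sorted ascending with cumulative
    fractions.
    """
    sizes = groups.value_counts()
    qualifying = sorted(sizes[sizes >= min_group_size].index)
    if not qualifying:
        warnings.warn("no group has enough members for correlation curves")
        return pd.DataFrame(columns=["group", "kind", "other_group", "value", "cum_fraction"])

    best = most_active_lots(groups, activity)
    rows: List[dict] = []

    def emit(group: str, kind: str, other: str, values: List[float]) -> None:
        values = sorted(values)
        n = len(values)
        for i, v in enumerate(values, start=1):
            rows.append(
                {"group": group, "kind": kind, "other_group": other,
                 "value": v, "cum_fraction": i / n}
            )

    for g in qualifying:
        members = sorted(groups.index[groups == g])
        within = [
            float(corr.loc[a, b])
            for i, a in enumerate(members)
            for b in members[i + 1 :]
        ]
        emit(g, "within", g, within)
        pooled: List[float] = []
        for h in sorted(set(groups) - {g}):
            comparator = best.get(h)
            if comparator is None:
                continue
            vals = [float(corr.loc[m, comparator]) for m in members]
            emit(g, "between", h, vals)
            pooled.extend(vals)
        if pooled:
            emit(g, "between", "(all)", pooled)
    return pd.DataFrame(rows, columns=["group", "kind", "other_group", "value", "cum_fraction"])


def one_way_f(values: np.ndarray, labels: np.ndarray) -> Tuple[float, str]:
    """Classical one-way ANOVA F statistic with degenerate-case flags.

    Returns (F, flag) where flag is "" normally, "infinite" when the
    within-group variance is zero but groups differ, and "degenerate" when
    all values are identical (0/0).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    grand = values.mean()
    ssb = 0.0
    ssw = 0.0
    for g in uniq:
        x = values[labels == g]
        ssb += x.size * (x.mean() - grand) ** 2
        ssw += float(np.sum((x - x.mean()) ** 2))
    df1 = uniq.size - 1
    df2 = values.size - uniq.size
    if df2 <= 0:
        raise ValueError("one-way ANOVA needs more observations than groups")
    if ssw == 0.0:
        return (float("nan"), "degenerate") if ssb == 0.0 else (float("inf"), "infinite")
    return (ssb / df1) / (ssw / df2), ""


def endpoint_enrichment(
    matrices: ProfileMatrices,
    coarse_groups: Mapping[str, str],
    fine_groups: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Rank endpoints by the one-way ANOVA F over botanical groups.

    ``coarse_groups`` maps substance -> group for the substances entering the
    analysis; ``fine_groups``, when given (e.g. splitting extracts from
    constituents), yields F-value 2 and the F-ratio = F2/F1, and the ranking
    is then by F-ratio. Infinite Fs rank first, degenerate (no-variance) ones
    last; ranks are dense with ties shared.
    """
    subs = [s for s in matrices.log10_pod.index if s in coarse_groups]
    if len({coarse_groups[s] for s in subs}) < 2:
        raise ValueError("endpoint enrichment needs at least 2 groups")
    coarse = np.asarray([coarse_groups[s] for s in subs])
    fine = None
    if fine_groups is not None:
        if any(s not in fine_groups for s in subs):
            raise IntegrityError("fine_groups must cover every substance in coarse_groups")
        fine = np.asarray([fine_groups[s] for s in subs])

    rows = []
    for eid in matrices.log10_pod.columns:
        values = matrices.log10_pod.loc[subs, eid].to_numpy(dtype=float)
        f1, flag1 = one_way_f(values, coarse)
        f2 = f_ratio = np.nan
        flag = flag1
        if fine is not None:
            f2, flag2 = one_way_f(values, fine)
            flag = flag1 or flag2
            if np.isfinite(f1) and np.isfinite(f2) and f1 > 0:
                f_ratio = f2 / f1
        rows.append(
            {"endpoint_id": eid, "f_value_1": f1, "f_value_2": f2,
             "f_ratio": f_ratio, "flag": flag}
        )
    out = pd.DataFrame(rows)
    rank_on = "f_ratio" if fine is not None else "f_value_1"
    sort_key = out[rank_on].replace(float("inf"), np.finfo(float).max)
    sort_key = sort_key.fillna(-np.inf)  # degenerate endpoints rank last
    out["rank"] = sort_key.rank(method="dense", ascending=False).astype(int)
    return out.sort_values(["rank", "endpoint_id"]).reset_index(drop=True)


RANK_SCHEMES = ("n_active", "min_pod", "sum_z_wauc")


def rank_substances(
    matrices: ProfileMatrices,
    calls: Sequence[EndpointCall],
    endpoints: Mapping[str, EndpointSpec],
    scheme: Optional[str] = None,
    zscore_on: str = "active",
) -> pd.DataFrame:
    """Rank substances by overall activity under three schemes.

    * ``n_active`` -- number of active primary endpoints (rank 1 = most);
    * ``min_pod`` -- most potent POD over the active primary endpoints
      (imputation POD when none; rank 1 = most potent);
    * ``sum_z_wauc`` -- sum over the active primary endpoints of the
      per-endpoint Z-scored wAUC (Z computed across the substance set; rank 1
      = largest sum). With ``zscore_on="active"`` the Z-scores are computed
      over the active cells of each endpoint; ``"all"`` uses every cell.

    Ranks are dense; ties share a rank.
    """
    if scheme is not None and scheme not in RANK_SCHEMES:
        raise ConfigError(f"unknown ranking scheme {scheme!r}; valid: {RANK_SCHEMES}")
    if zscore_on not in ("active", "all"):
        raise ConfigError("zscore_on must be 'active' or 'all'")

    sub_ids = list(matrices.log10_pod.index)
    primary = [e for e in matrices.wauc.columns if not endpoints[e].is_counter_screen]
    active = pd.DataFrame(False, index=sub_ids, columns=primary)
    pods = pd.DataFrame(np.nan, index=sub_ids, columns=primary)
    for c in calls:
        if c.substance_id in active.index and c.endpoint_id in active.columns:
            if c.label == LABEL_ACTIVE:
                active.loc[c.substance_id, c.endpoint_id] = True
                if c.median_pod is not None:
                    pods.loc[c.substance_id, c.endpoint_id] = c.median_pod

    w = matrices.wauc[primary]
    z = pd.DataFrame(0.0, index=sub_ids, columns=primary)
    for e in primary:
        cells = active[e] if zscore_on == "active" else pd.Series(True, index=sub_ids)
        vals = w.loc[cells[cells].index, e]
        if len(vals) >= 2 and float(vals.std(ddof=0)) > 0:
            z.loc[vals.index, e] = (vals - vals.mean()) / vals.std(ddof=0)

    n_active = active.sum(axis=1).astype(int)
    min_pod = pods.min(axis=1).fillna(matrices.imputation_pod)
    sum_z = (z * active).sum(axis=1)
    degenerate = len(sub_ids) < 2

    out = pd.DataFrame(
        {
            "substance_id": sub_ids,
            "n_active": n_active.to_numpy(),
            "min_pod": min_pod.to_numpy(),
            "sum_z_wauc": 0.0 if degenerate else sum_z.to_numpy(),
            "z_degenerate": degenerate,
        }
    )
    out["rank_n_active"] = out["n_active"].rank(method="dense", ascending=False).astype(int)
    out["rank_min_pod"] = out["min_pod"].rank(method="dense", ascending=True).astype(int)
    out["rank_sum_z_wauc"] = out["sum_z_wauc"].rank(method="dense", ascending=False).astype(int)
    if scheme is not None:
        out = out.sort_values([f"rank_{scheme}", "substance_id"]).reset_index(drop=True)
    return out


def embed_2d(
    matrices: ProfileMatrices,
    perplexity: float = 30.0,
    iterations: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D t-SNE of the wAUC profiles on a precomputed Euclidean distance
    matrix; no PCA preselection. A fixed seed reproduces coordinates exactly.
    Perplexity is reduced with a warning when the substance set is too small
    for the requested value."""
    ids = list(matrices.wauc.index)
    n = len(ids)
    if n < 4:
        raise ValueError("2-D embedding needs at least 4 substances")
    max_perplexity = (n - 2) / 3.0
    if perplexity > max_perplexity:
        warnings.warn(
            f"perplexity {perplexity} too large for {n} substances; using {max_perplexity:.2f}"
        )
        perplexity = max_perplexity
    from scipy.spatial.distance import pdist

    dist = squareform(pdist(matrices.wauc.to_numpy(dtype=float), metric="euclidean"))
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        max_iter=iterations,
        random_state=seed,
        method="exact" if n < 2000 else "barnes_hut",
    )
    coords = tsne.fit_transform(dist)
    return pd.DataFrame(coords, index=ids, columns=["tsne1", "tsne2"]).rename_axis(
        "substance_id"
    )
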