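"""K-means profiling of per-animal relative-abundance vectors.

Samples are clustered on their (ASV-level by default) relative-abundance
vectors with best-of-restarts Lloyd k-means.  The number of clusters is
picked from the within-cluster sum-of-squared-errors (SSE) curve at the
sharpest elbow — the k maximising the second forward difference of SSE —
unless the caller fixes k.  Cluster ids are canonicalised (decreasing size,
ties broken by the lexicographically smallest member) so reports are
deterministic across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .feature_table import RelativeAbundanceTable


class ClusteringError(ValueError):
    pass


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series                 # sample -> cluster id (1-based)
    sse_by_k: dict[int, float]
    n_restarts: int
    seed: int
    composition: pd.DataFrame | None = field(default=None, repr=False)


def _canonicalize(labels: np.ndarray, sample_ids: list[str]) -> pd.Series:
    order = sorted(
        np.unique(labels),
        key=lambda c: (-(labels == c).sum(),
                       min(s for s, l in zip(sample_ids, labels) if l == c)))
    remap = {old: new + 1 for new, old in enumerate(order)}
    return pd.Series([remap[l] for l in labels], index=sample_ids,
                     name="cluster")


def elbow_k(sse_by_k: dict[int, float]) -> int:
    """k at the maximum second forward difference of the SSE curve."""
    ks = sorted(sse_by_k)
    if len(ks) < 3:
        return ks[-1]
    interior = ks[1:-1]
    curvature = {k: sse_by_k[k - 1] - 2 * sse_by_k[k] + sse_by_k[k + 1]
                 for k in interior
                 if (k - 1) in sse_by_k and (k + 1) in sse_by_k}
    if not curvature:
        return ks[len(ks) // 2]
    return max(curvature, key=lambda k: (curvature[k], -k))


def kmeans_profile(relab: RelativeAbundanceTable | pd.DataFrame,
                   meta: pd.Series | None = None,
                   k: int | None = None,
                   k_range: range = range(1, 11),
                   n_restarts: int = 50,
                   seed: int = 0,
                   standardize: bool = False) -> ClusterResult:
    """Cluster samples by their abundance profiles.

    ``k=None`` selects k from the SSE elbow over ``k_range``; a fixed ``k``
    is honoured directly (its SSE curve is still computed for reporting).
    ``standardize`` z-scores features first (off by default — percentages
    are left on their natural scale).
    """
    values = relab.values if isinstance(relab, RelativeAbundanceTable) else relab
    X = values.to_numpy(dtype=float).T  # samples x features
    sample_ids = list(values.columns)
    n = X.shape[0]
    ks = [kk for kk in k_range if 1 <= kk <= n]
    if k is not None and k > n:
        raise ClusteringError(f"k={k} exceeds n={n} samples")
    if not ks and k is None:
        raise ClusteringError("k_range contains no feasible k")
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    if k is not None and k not in ks:
        ks = sorted(set(ks) | {k})
    sse_by_k: dict[int, float] = {}
    models: dict[int, KMeans] = {}
    for kk in ks:
        km = KMeans(n_clusters=kk, n_init=n_restarts, init="k-means++",
                    random_state=seed, algorithm="lloyd").fit(X)
        sse_by_k[kk] = float(km.inertia_)
        models[kk] = km
    chosen = k if k is not None else elbow_k(sse_by_k)
    assignments = _canonicalize(models[chosen].labels_, sample_ids)
    result = ClusterResult(k=chosen, assignments=assignments,
                           sse_by_k=sse_by_k, n_restarts=n_restarts,
                           seed=seed)
    if meta is not None:
        result.composition = composition_report(result, meta)
    return result


def composition_report(result: ClusterResult, meta: pd.Series) -> pd.DataFrame:
    """Cluster × group contingency counts with an ``exclusive`` flag.

    A cluster is exclusive when all its members come from a single group.
    """
    groups = meta.reindex(result.assignments.index)
    if groups.isna().any():
        missing = list(result.assignments.index[groups.isna()])
        raise ClusteringError(f"metadata missing sample(s): {missing}")
    table = pd.crosstab(result.assignments, groups)
    table.index.name = "cluster"
    table["size"] = table.sum(axis=1)
    table["exclusive"] = (table.drop(columns="size") > 0).sum(axis=1) == 1
    return table
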