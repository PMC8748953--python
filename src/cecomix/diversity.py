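"""Alpha diversity, beta-diversity dissimilarities, PCoA, and ANOSIM.

Alpha metrics follow the conventions of the classic QIIME-era scripts:
Shannon H in bits (log base 2), Simpson's index D = 1 − Σ p_i², Simpson's
evenness E = (1/Σ p_i²)/S_obs, bias-corrected Chao1
S_obs + F1(F1−1)/(2(F2+1)), and Faith's PD over the whole tree (root edge
included).  All nonzero ASVs count toward S_obs here, classified or not.

ANOSIM is implemented in-package so that the permutation stream is seeded
and reproducible; the statistic is the classic rank-based
R = (mean between-group rank − mean within-group rank) / (n(n−1)/4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import chao1

from .feature_table import FeatureTable, RelativeAbundanceTable


class DiversityError(ValueError):
    """Raised on invalid diversity inputs (missing tips, bad matrices …)."""


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _alpha_one(counts: np.ndarray) -> dict[str, float]:
    counts = np.asarray(counts, dtype=np.int64)
    present = counts[counts > 0]
    s_obs = int(present.size)
    if s_obs == 0:
        return {"observed_asvs": 0, "chao1": 0.0, "shannon_H": 0.0,
                "simpson_D": 0.0, "simpson_E": np.nan}
    p = present / present.sum()
    shannon = float(-(p * np.log2(p)).sum())
    dominance = float((p ** 2).sum())
    return {
        "observed_asvs": s_obs,
        "chao1": float(chao1(counts, bias_corrected=True)),
        "shannon_H": shannon,
        "simpson_D": 1.0 - dominance,
        "simpson_E": (1.0 / dominance) / s_obs,
    }


def alpha_diversity(table: FeatureTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample alpha diversity metrics (rows = samples).

    Raw counts are used directly; no pseudo-count or rarefaction.  Faith's PD
    is included only when ``tree`` is given; the tree must contain every ASV
    present in any sample as a tip.
    """
    rows = {s: _alpha_one(table.counts[s].to_numpy()) for s in table.sample_ids}
    result = pd.DataFrame.from_dict(rows, orient="index")
    if tree is not None:
        _check_tips(table, tree)
        result["faith_pd"] = pd.Series(_faith_pd(table, tree))
    result.index.name = "sample_id"
    return result


def _faith_pd(table: FeatureTable, tree: TreeNode) -> dict[str, float]:
    """Faith's PD per sample, whole-tree convention: every edge whose
    subtree contains a present tip contributes, the root's own edge
    included when it carries a length."""
    below: dict[int, frozenset[str]] = {}
    edges: list[tuple[frozenset[str], float]] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            tips = frozenset([node.name])
        else:
            tips = frozenset().union(*(below[id(c)] for c in node.children))
        below[id(node)] = tips
        if node.length:
            edges.append((tips, float(node.length)))
    out = {}
    for s in table.sample_ids:
        present = frozenset(table.counts.index[table.counts[s] > 0])
        out[s] = sum(length for tips, length in edges if tips & present)
    return out


def _check_tips(table: FeatureTable, tree: TreeNode) -> None:
    tips = {t.name for t in tree.tips()}
    present = table.counts.index[(table.counts > 0).any(axis=1)]
    missing = [a for a in present if a not in tips]
    if missing:
        raise DiversityError(f"tree is missing tip(s) for ASV(s): {missing[:5]}")


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(data: RelativeAbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples.

    ``data`` is taxon × sample; by convention the caller passes per-sample
    relative abundances (library-size normalised), but raw counts are
    accepted.  BC(x, y) = 1 − 2·Σ min(x_i, y_i) / (Σ x_i + Σ y_i).
    """
    values = data.values if isinstance(data, RelativeAbundanceTable) else data
    X = values.to_numpy(dtype=float).T  # samples × taxa
    ids = list(values.columns)
    if X.shape[0] < 2:
        raise DiversityError("need at least 2 samples")
    if (X.sum(axis=1) <= 0).any():
        bad = [ids[i] for i in np.where(X.sum(axis=1) <= 0)[0]]
        raise DiversityError(f"all-zero sample(s): {bad}")
    condensed = pdist(X, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=ids)


def unifrac(table: FeatureTable, tree: TreeNode, weighted: bool = False,
            normalized: bool = True) -> DistanceMatrix:
    """Unweighted or weighted UniFrac distances between samples.

    The tree must be rooted (bifurcating root); the weighted variant is
    normalised so distances stay comparable across samples of different
    depth.  Presence for the unweighted variant is count > 0 exactly.
    """
    if len(tree.children) > 2:
        raise DiversityError(
            "tree appears unrooted (root has >2 children); root it first")
    _check_tips(table, tree)
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    dm = beta_diversity(metric, table.counts.to_numpy().T,
                        ids=table.sample_ids, taxa=table.asv_ids,
                        tree=tree, validate=True, **kwargs)
    return dm


# ---------------------------------------------------------------------------
# Principal coordinates analysis
# ---------------------------------------------------------------------------

@dataclass
class PCoAResult:
    """Classical-scaling ordination: coordinates plus the full eigenvalue
    spectrum (negative eigenvalues are reported, not dropped)."""

    coordinates: pd.DataFrame        # samples × axes (positive axes only)
    eigenvalues: np.ndarray          # all eigenvalues, descending
    percent_explained: np.ndarray    # of the positive-eigenvalue total


def pcoa(dm: DistanceMatrix | np.ndarray, n_axes: int | None = None) -> PCoAResult:
    """Classical multidimensional scaling of a distance matrix.

    Double-centres −D²/2 and eigendecomposes; axes are ordered by descending
    eigenvalue and coordinates are returned for positive eigenvalues only.
    """
    if isinstance(dm, DistanceMatrix):
        D = dm.data
        ids = list(dm.ids)
    else:
        D = np.asarray(dm, dtype=float)
        ids = [f"s{i}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DiversityError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise DiversityError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-12
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    total_pos = eigvals[pos].sum()
    percent = (100.0 * eigvals / total_pos) if total_pos > 0 else np.zeros(n)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=cols),
        eigenvalues=eigvals,
        percent_explained=percent,
    )


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int


def anosim(dm: DistanceMatrix, meta: pd.Series, n_permutations: int = 999,
           seed: int = 0) -> AnosimResult:
    """Analysis of similarities on a distance matrix with group labels.

    Off-diagonal distances are ranked with average ranks on ties;
    R = (r̄_between − r̄_within) / (n(n−1)/4).  The permutation p-value is
    (1 + #{R_perm ≥ R_obs}) / (n_permutations + 1) with labels permuted by a
    seeded generator, so results are reproducible.
    """
    ids = list(dm.ids)
    groups = meta.reindex(ids)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise DiversityError(f"metadata missing sample(s): {missing}")
    labels, counts = np.unique(groups.to_numpy(), return_counts=True)
    if len(labels) < 2:
        raise DiversityError("ANOSIM needs at least 2 groups")
    if (counts < 2).any():
        small = [str(l) for l, c in zip(labels, counts) if c < 2]
        raise DiversityError(f"group(s) of size < 2: {small}")
    n = len(ids)
    condensed = squareform(dm.data, checks=False)
    ranks = rankdata(condensed)
    denom = n * (n - 1) / 4.0
    codes = pd.factorize(groups.to_numpy())[0]
    iu, ju = np.triu_indices(n, k=1)

    def _r(c: np.ndarray) -> float:
        within = c[iu] == c[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = _r(codes)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        if _r(rng.permutation(codes)) >= r_obs:
            count_ge += 1
    p = (1 + count_ge) / (n_permutations + 1)
    return AnosimResult(R=float(r_obs), p=float(p),
                        n_permutations=n_permutations, seed=seed)
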