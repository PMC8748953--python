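"""Conditional parametric/non-parametric group comparisons with FDR control.

The framework applied to every taxon (and to any per-sample scalar):

1. shift every value by 1e-13 (so zero-heavy abundance data can be logged);
2. if any group has zero variance, go straight to Kruskal–Wallis on the
   shifted data;
3. otherwise test each group for normality (Shapiro–Wilk) and the groups
   jointly for homoscedasticity (Brown–Forsythe, i.e. median-centred
   Levene); if every group is normal and variances are homogeneous, run a
   one-way ANOVA on the shifted data;
4. otherwise log10-transform the shifted data and retest; if the transform
   rescues the assumptions, run the ANOVA on the logged data;
5. otherwise run Kruskal–Wallis on the shifted (NOT logged) data.

"Non-normal and/or heteroscedastic" is read strictly: ANY group's
Shapiro–Wilk p < alpha OR the Brown–Forsythe p < alpha trips the condition.
Significant omnibus results get pairwise post-hoc comparisons in the same
family as the omnibus test (two-sample t after ANOVA, rank-sum after KW) on
the analysed scale, corrected with the Benjamini–Krieger–Yekutieli two-stage
step-up; main-effect p-values across features are corrected with plain
Benjamini–Hochberg.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .feature_table import RelativeAbundanceTable

#: Additive shift applied to abundance data before any testing.
SHIFT = 1e-13

DEGENERATE = "degenerate"


class GroupStatsError(ValueError):
    pass


@dataclass
class PosthocComparison:
    group_a: str
    group_b: str
    p: float
    q_bky: float = np.nan
    reject: bool = False


@dataclass
class MainEffectResult:
    """Per-feature record of the conditional test path and its outcome."""

    feature: str
    shift_applied: bool
    log_applied: bool
    zero_variance_group: bool
    normality_p: dict[str, float | None]     # None marks a degenerate group
    homoscedasticity_p: float
    test_used: str                           # "anova" | "kruskal-wallis"
    statistic: float
    p_main: float
    q_main: float = np.nan
    posthoc: list[PosthocComparison] = field(default_factory=list)


def shift_transform(values) -> np.ndarray:
    """Add exactly 1e-13 to every value (not idempotent by design)."""
    return np.asarray(values, dtype=float) + SHIFT


def _group_arrays(values: pd.Series, meta: pd.Series) -> dict[str, np.ndarray]:
    values = pd.Series(values)
    groups = meta.reindex(values.index)
    if groups.isna().any():
        missing = list(values.index[groups.isna()])
        raise GroupStatsError(f"samples without group label: {missing}")
    out = {}
    for g in pd.unique(groups):
        out[str(g)] = values[groups == g].to_numpy(dtype=float)
    if len(out) < 2:
        raise GroupStatsError("need at least 2 groups")
    return out


def assess_assumptions(values: pd.Series, meta: pd.Series
                       ) -> tuple[dict[str, float | None], float]:
    """Shapiro–Wilk p per group plus one Brown–Forsythe p across groups.

    A zero-variance group yields ``None`` in place of a normality p (the
    test is undefined on constant data).  Groups need >= 3 values.
    """
    arrays = _group_arrays(values, meta)
    normality: dict[str, float | None] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g, arr in arrays.items():
            if len(arr) < 3:
                raise GroupStatsError(f"group {g!r} has < 3 values")
            if np.ptp(arr) == 0:
                normality[g] = None
            else:
                normality[g] = float(stats.shapiro(arr).pvalue)
        hom_p = float(stats.levene(*arrays.values(), center="median").pvalue)
    if np.isnan(hom_p):  # all groups (near-)constant
        hom_p = 1.0
    return normality, hom_p


def _assumptions_ok(normality: dict[str, float | None], hom_p: float,
                    alpha: float) -> bool:
    ps = [p for p in normality.values() if p is not None]
    return all(p >= alpha for p in ps) and hom_p >= alpha


def _omnibus(arrays: dict[str, np.ndarray], family: str) -> tuple[float, float]:
    groups = list(arrays.values())
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        # Completely constant data carries no group signal.
        return 0.0, 1.0
    if family == "anova":
        res = stats.f_oneway(*groups)
    else:
        res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def select_and_run_test(values: pd.Series, meta: pd.Series,
                        alpha: float = 0.05, shift: bool = True,
                        feature: str = "") -> MainEffectResult:
    """Run the conditional decision path on one feature.

    ``shift`` applies the 1e-13 transform first (switch it off for data that
    is already strictly positive, e.g. alpha-diversity values).  The decision
    path is a pure function of the data — no randomness anywhere.
    """
    values = pd.Series(values)
    work = pd.Series(shift_transform(values) if shift else
                     np.asarray(values, dtype=float), index=values.index)
    arrays = _group_arrays(work, meta)
    zero_var = any(np.ptp(a) == 0 for a in arrays.values())
    normality, hom_p = assess_assumptions(work, meta)
    log_applied = False
    if zero_var:
        test_used = "kruskal-wallis"
        stat, p = _omnibus(arrays, "kruskal")
    elif _assumptions_ok(normality, hom_p, alpha):
        test_used = "anova"
        stat, p = _omnibus(arrays, "anova")
    else:
        rescued = False
        if (work > 0).all():
            logged = np.log10(work)
            log_norm, log_hom = assess_assumptions(logged, meta)
            if _assumptions_ok(log_norm, log_hom, alpha):
                rescued = True
                log_applied = True
                normality, hom_p = log_norm, log_hom
                arrays = _group_arrays(logged, meta)
                test_used = "anova"
                stat, p = _omnibus(arrays, "anova")
        if not rescued:
            test_used = "kruskal-wallis"
            stat, p = _omnibus(arrays, "kruskal")
    return MainEffectResult(
        feature=feature, shift_applied=shift, log_applied=log_applied,
        zero_variance_group=zero_var, normality_p=normality,
        homoscedasticity_p=hom_p, test_used=test_used,
        statistic=stat, p_main=p)


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------

def _validate_p(p_values) -> np.ndarray:
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise GroupStatsError("empty p-value list")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise GroupStatsError("p-values must lie in [0, 1]")
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = _validate_p(p_values)
    return multipletests(p, method="fdr_bh")[1]


def posthoc_bky(pairwise_p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage linear step-up (Benjamini–Krieger–Yekutieli) at level ``q``.

    Stage 1 runs BH at q' = q/(1+q) to estimate the number of true nulls
    m0 = m − r1; stage 2 reruns BH at level q'·m/m0.  Returns
    ``(reject_flags, adjusted)`` in input order, where ``adjusted <= q`` is
    equivalent to rejection.
    """
    p = _validate_p(pairwise_p)
    m = p.size
    q1 = q / (1.0 + q)
    stage1 = multipletests(p, alpha=q1, method="fdr_bh")[0]
    r1 = int(stage1.sum())
    bh_adj = multipletests(p, method="fdr_bh")[1]
    if r1 == 0:
        return np.zeros(m, dtype=bool), np.minimum(bh_adj * (1 + q), 1.0)
    if r1 == m:
        return np.ones(m, dtype=bool), np.zeros(m)
    m0 = m - r1
    adjusted = np.minimum(bh_adj * m0 / m * (1.0 + q), 1.0)
    return adjusted <= q, adjusted


# ---------------------------------------------------------------------------
# Feature screen
# ---------------------------------------------------------------------------

def _pairwise_posthoc(values: pd.Series, meta: pd.Series, family: str,
                      q: float) -> list[PosthocComparison]:
    arrays = _group_arrays(values, meta)
    pairs = list(itertools.combinations(sorted(arrays), 2))
    raw = []
    for a, b in pairs:
        x, y = arrays[a], arrays[b]
        if np.ptp(np.concatenate([x, y])) == 0:
            raw.append(1.0)
        elif family == "anova":
            raw.append(float(stats.ttest_ind(x, y, equal_var=True).pvalue))
        else:
            raw.append(float(stats.mannwhitneyu(x, y,
                                                alternative="two-sided").pvalue))
    reject, adjusted = posthoc_bky(raw, q=q)
    return [PosthocComparison(a, b, p, qv, bool(r))
            for (a, b), p, qv, r in zip(pairs, raw, adjusted, reject)]


def run_feature_screen(relab: RelativeAbundanceTable | pd.DataFrame,
                       meta: pd.Series, alpha: float = 0.05,
                       fdr: float = 0.05, shift: bool = True
                       ) -> list[MainEffectResult]:
    """Apply the conditional framework to every feature row.

    Main-effect p-values are BH-corrected across the features of this table
    (per rank, so phyla and genera are corrected independently).  Features
    significant at ``alpha`` get pairwise post-hoc comparisons with BKY
    correction at ``fdr``, run on the same scale the omnibus test analysed.
    """
    values = relab.values if isinstance(relab, RelativeAbundanceTable) else relab
    results = [select_and_run_test(values.loc[t], meta, alpha=alpha,
                                   shift=shift, feature=str(t))
               for t in values.index]
    qs = bh_fdr([r.p_main for r in results])
    for r, qv in zip(results, qs):
        r.q_main = float(qv)
        if r.p_main < alpha:
            row = pd.Series(values.loc[r.feature])
            work = pd.Series(shift_transform(row) if shift else
                             row.to_numpy(dtype=float), index=row.index)
            if r.log_applied:
                work = np.log10(work)
            family = "anova" if r.test_used == "anova" else "kruskal"
            r.posthoc = _pairwise_posthoc(work, meta, family, q=fdr)
    return results


def screen_to_frame(results: list[MainEffectResult]) -> pd.DataFrame:
    """Flatten screen results into one row per feature (for TSV export)."""
    rows = []
    for r in results:
        rows.append({
            "feature": r.feature,
            "test_used": r.test_used,
            "log_applied": r.log_applied,
            "zero_variance_group": r.zero_variance_group,
            "homoscedasticity_p": r.homoscedasticity_p,
            "statistic": r.statistic,
            "p_main": r.p_main,
            "q_main": r.q_main,
            "n_posthoc_significant": sum(c.reject for c in r.posthoc),
        })
    return pd.DataFrame(rows).set_index("feature")


def posthoc_to_frame(results: list[MainEffectResult]) -> pd.DataFrame:
    """Long-format post-hoc table (one row per feature × group pair)."""
    rows = []
    for r in results:
        for c in r.posthoc:
            rows.append({"feature": r.feature, "group_a": c.group_a,
                         "group_b": c.group_b, "p": c.p, "q_bky": c.q_bky,
                         "reject": c.reject})
    return pd.DataFrame(rows, columns=["feature", "group_a", "group_b",
                                       "p", "q_bky", "reject"])
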