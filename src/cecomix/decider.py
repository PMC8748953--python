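"""Correlation-method decision tree with outlier-sensitivity analysis.

For a paired (x, y) the decider tests each variable for normality
(Shapiro–Wilk) and the pair for equality of variances (two-sided F-test).
If both are normal and the variances are not unequal it returns Pearson;
otherwise it attempts a log10 rescue of the offending variable(s) — only
when all of a variable's values are strictly positive — and retests.  If
the rescue fails, Spearman's rank correlation on the original values is
used.  Each genus–metabolite pair is correlated twice: once on the full
data and once after IQR outlier removal (union of the points flagged in
either variable); a coefficient that moves by more than 0.2 (strict) is
flagged as outlier-influenced.  BH FDR is applied across the whole grid,
separately for the with- and without-outlier arms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_table import RelativeAbundanceTable
from .group_stats import bh_fdr

#: |r_with − r_without| beyond which a pair is flagged outlier-influenced.
INFLUENCE_THRESHOLD = 0.2

#: Below this n, Spearman p-values come from exact permutation enumeration.
SPEARMAN_EXACT_N = 10


class DeciderError(ValueError):
    pass


@dataclass
class DeciderDecision:
    method: str                  # "pearson" | "spearman"
    x: np.ndarray                # values the correlation is computed on
    y: np.ndarray
    log_x: bool
    log_y: bool
    normal_x: bool
    normal_y: bool
    equal_variance: bool


@dataclass
class ArmResult:
    method: str
    r: float
    p: float
    n: int
    log_x: bool
    log_y: bool


@dataclass
class CorrelationRecord:
    genus: str
    metabolite: str
    with_outliers: ArmResult
    without_outliers: ArmResult | None
    removed_samples: list[str] = field(default_factory=list)
    influenced: bool = False
    evaluable: bool = True
    q_with: float = np.nan
    q_without: float = np.nan


def _shapiro_p(v: np.ndarray) -> float:
    if np.ptp(v) == 0:
        return 0.0  # constant data: treat as maximally non-normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(v).pvalue)


def variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of two variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 and vy == 0:
        return 1.0
    if vy == 0 or vx == 0:
        return 0.0
    f = vx / vy
    dfx, dfy = len(x) - 1, len(y) - 1
    p = 2.0 * min(stats.f.cdf(f, dfx, dfy), stats.f.sf(f, dfx, dfy))
    return float(min(p, 1.0))


def decide_method(x, y, alpha: float = 0.05) -> DeciderDecision:
    """Choose Pearson vs Spearman for one paired sample (n >= 4)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DeciderError("x and y must be 1-D and the same length")
    if len(x) < 4:
        raise DeciderError("need at least 4 paired observations")

    def _assess(a, b):
        na = _shapiro_p(a) >= alpha
        nb = _shapiro_p(b) >= alpha
        ev = variance_f_test(a, b) >= alpha
        return na, nb, ev

    nx, ny, ev = _assess(x, y)
    if nx and ny:
        # Normality is the binding criterion for Pearson.  A variance
        # imbalance between two normal variables triggers a log10
        # stabilisation attempt (possible only on strictly positive data);
        # if the attempt does not leave both variables normal with
        # comparable variances, Pearson runs on the original values.
        if not ev and (x > 0).all() and (y > 0).all():
            xt, yt = np.log10(x), np.log10(y)
            nx2, ny2, ev2 = _assess(xt, yt)
            if nx2 and ny2 and ev2:
                return DeciderDecision("pearson", xt, yt, True, True,
                                       nx2, ny2, ev2)
        return DeciderDecision("pearson", x, y, False, False, nx, ny, ev)
    # Non-normality: attempt log10 on the offending variable(s) when all
    # their values are strictly positive; rescued pairs use Pearson on the
    # transformed values, otherwise Spearman on the originals.
    can_log_x = (not nx) and (x > 0).all()
    can_log_y = (not ny) and (y > 0).all()
    if can_log_x or can_log_y:
        xt = np.log10(x) if can_log_x else x
        yt = np.log10(y) if can_log_y else y
        nx2, ny2, ev2 = _assess(xt, yt)
        if nx2 and ny2:
            return DeciderDecision("pearson", xt, yt, can_log_x, can_log_y,
                                   nx2, ny2, ev2)
    return DeciderDecision("spearman", x, y, False, False, nx, ny, ev)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n."""
    rx = stats.rankdata(x)
    n = len(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / np.sqrt(((rx - rx.mean()) ** 2).sum())
    ryc = ry - ry.mean()
    norm = np.sqrt((ryc ** 2).sum())
    if norm == 0:
        return 1.0
    perms = np.array(list(itertools.permutations(ryc / norm)))
    rhos = perms @ rx
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _correlate(decision: DeciderDecision) -> tuple[float, float]:
    x, y = decision.x, decision.y
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    if decision.method == "pearson":
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    rho = float(stats.spearmanr(x, y).statistic)
    if len(x) < SPEARMAN_EXACT_N:
        return rho, _spearman_exact_p(x, y, rho)
    return rho, float(stats.spearmanr(x, y).pvalue)


def correlation_with_decider(x, y, alpha: float = 0.05) -> ArmResult:
    """Run the decision tree and compute the chosen correlation."""
    d = decide_method(x, y, alpha=alpha)
    r, p = _correlate(d)
    return ArmResult(method=d.method, r=r, p=p, n=len(d.x),
                     log_x=d.log_x, log_y=d.log_y)


# ---------------------------------------------------------------------------
# IQR outlier filtering
# ---------------------------------------------------------------------------

@dataclass
class OutlierFilter:
    kept: np.ndarray
    removed_indices: np.ndarray
    q1: float
    q3: float
    lower: float
    upper: float


def iqr_outlier_filter(values) -> OutlierFilter:
    """Flag values strictly outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use inclusive linear interpolation (the spreadsheet
    convention), i.e. numpy's default percentile method.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 4:
        raise DeciderError("need at least 4 values for outlier filtering")
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    removed = np.where((v < lower) | (v > upper))[0]
    keep = np.setdiff1d(np.arange(len(v)), removed)
    return OutlierFilter(kept=v[keep], removed_indices=removed,
                         q1=float(q1), q3=float(q3),
                         lower=float(lower), upper=float(upper))


def correlate_pair(x, y, sample_ids=None, genus: str = "x",
                   metabolite: str = "y", alpha: float = 0.05
                   ) -> CorrelationRecord:
    """Correlate one pair with and without IQR outliers.

    Outliers are flagged per variable and removed pairwise (union of the
    indices flagged by either variable), so n can shrink in the second arm.
    When nothing is removed the second arm reuses the first arm's result
    exactly, guaranteeing Δr = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(x))]
    arm1 = correlation_with_decider(x, y, alpha=alpha)
    removed = np.union1d(iqr_outlier_filter(x).removed_indices,
                         iqr_outlier_filter(y).removed_indices)
    record = CorrelationRecord(genus=genus, metabolite=metabolite,
                               with_outliers=arm1, without_outliers=None,
                               removed_samples=[sample_ids[i] for i in removed])
    if np.isnan(arm1.r):
        record.evaluable = False
        return record
    if len(removed) == 0:
        record.without_outliers = arm1
        record.influenced = False
        return record
    keep = np.setdiff1d(np.arange(len(x)), removed)
    if len(keep) < 4:
        record.evaluable = False
        return record
    arm2 = correlation_with_decider(x[keep], y[keep], alpha=alpha)
    record.without_outliers = arm2
    if np.isnan(arm2.r):
        record.evaluable = False
        return record
    record.influenced = bool(abs(arm1.r - arm2.r) > INFLUENCE_THRESHOLD)
    return record


def correlate_matrix(genera: RelativeAbundanceTable | pd.DataFrame,
                     metabolites: pd.DataFrame, alpha: float = 0.05,
                     fdr: float = 0.05) -> list[CorrelationRecord]:
    """One record per (genus, metabolite) pair over the shared samples.

    BH FDR at ``fdr`` is applied across all evaluable pairs, separately for
    the with- and without-outlier p-lists.  Influenced records stay in the
    correction.
    """
    gvals = genera.values if isinstance(genera, RelativeAbundanceTable) else genera
    shared = [s for s in gvals.columns if s in metabolites.columns]
    if not shared:
        raise DeciderError("genus and metabolite tables share no samples")
    g = gvals[shared]
    m = metabolites[shared]
    records = []
    for genus in g.index:
        xv = g.loc[genus].to_numpy(dtype=float)
        for met in m.index:
            yv = m.loc[met].to_numpy(dtype=float)
            records.append(correlate_pair(xv, yv, sample_ids=shared,
                                          genus=str(genus),
                                          metabolite=str(met), alpha=alpha))
    for arm, attr in (("with_outliers", "q_with"),
                      ("without_outliers", "q_without")):
        idx = [i for i, r in enumerate(records)
               if r.evaluable and getattr(r, arm) is not None
               and not np.isnan(getattr(r, arm).p)]
        if idx:
            qs = bh_fdr([getattr(records[i], arm).p for i in idx])
            for i, qv in zip(idx, qs):
                setattr(records[i], attr, float(qv))
    return records


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Long-format table with every correlation-record field."""
    rows = []
    for r in records:
        w, wo = r.with_outliers, r.without_outliers
        rows.append({
            "genus": r.genus, "metabolite": r.metabolite,
            "method_with": w.method, "r_with": w.r, "p_with": w.p,
            "n_with": w.n, "log_x_with": w.log_x, "log_y_with": w.log_y,
            "method_without": wo.method if wo else "",
            "r_without": wo.r if wo else np.nan,
            "p_without": wo.p if wo else np.nan,
            "n_without": wo.n if wo else 0,
            "removed_samples": ";".join(r.removed_samples),
            "influenced": r.influenced, "evaluable": r.evaluable,
            "q_with": r.q_with, "q_without": r.q_without,
        })
    return pd.DataFrame(rows)
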