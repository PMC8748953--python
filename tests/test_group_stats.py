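"""Conditional test selection, BKY/BH corrections, and the feature screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection_twostage, multipletests

import cecomix as cx
from cecomix.group_stats import (GroupStatsError, SHIFT, posthoc_bky, bh_fdr,
                                 select_and_run_test, shift_transform)


def _meta(sizes):
    labels, samples = [], []
    for g, n in sizes.items():
        for i in range(n):
            samples.append(f"{g}_{i}")
            labels.append(g)
    return pd.Series(labels, index=samples, name="group")


def _series(groups: dict[str, np.ndarray]):
    meta = _meta({g: len(v) for g, v in groups.items()})
    values = pd.Series(np.concatenate(list(groups.values())), index=meta.index)
    return values, meta


class TestShift:
    def test_exact_increment(self):
        out = shift_transform([0, 0, 5])
        assert out.tolist() == [SHIFT, SHIFT, 5 + SHIFT]

    def test_empty(self):
        assert shift_transform([]).size == 0

    def test_not_idempotent(self):
        assert shift_transform(shift_transform([0]))[0] == 2 * SHIFT


class TestAssumptions:
    def test_constant_group_marked_degenerate(self):
        values, meta = _series({"a": np.zeros(5), "b": np.arange(5.0)})
        normality, hom_p = cx.assess_assumptions(values, meta)
        assert normality["a"] is None
        assert normality["b"] is not None
        assert 0 <= hom_p <= 1

    def test_small_group_rejected(self):
        values, meta = _series({"a": np.arange(2.0), "b": np.arange(5.0)})
        with pytest.raises(GroupStatsError, match="< 3"):
            cx.assess_assumptions(values, meta)

    def test_null_calibration_of_both_tests(self):
        # Normal same-variance groups: Shapiro-Wilk rejects at its nominal
        # alpha; Brown-Forsythe holds its level (it is conservative at
        # these group sizes, a known small-sample property).
        rng = np.random.default_rng(0)
        norm_rej, hom_rej = [], []
        for _ in range(2000):
            values, meta = _series(
                {g: rng.normal(size=7) for g in "abcd"})
            normality, hom_p = cx.assess_assumptions(values, meta)
            norm_rej += [p < 0.05 for p in normality.values()]
            hom_rej.append(hom_p < 0.05)
        assert np.mean(norm_rej) == pytest.approx(0.05, abs=0.015)
        assert 0 < np.mean(hom_rej) <= 0.06

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(1)
        rej = []
        for _ in range(2000):
            values, meta = _series({"a": rng.lognormal(0, 1.5, size=8),
                                    "b": rng.normal(size=8)})
            normality, _ = cx.assess_assumptions(values, meta)
            rej.append(normality["a"] < 0.05)
        assert np.mean(rej) > 0.5  # far above the 5% false-positive floor


class TestSelectAndRun:
    def test_zero_variance_group_forces_kruskal(self):
        values, meta = _series({"a": np.zeros(5),
                                "b": np.abs(np.random.default_rng(0).normal(
                                    size=5)) + 1})
        res = select_and_run_test(values, meta)
        assert res.zero_variance_group
        assert res.test_used == "kruskal-wallis"

    def test_anova_matches_textbook_computation(self):
        rng = np.random.default_rng(0)
        groups = {"a": rng.normal(0, 1, 8), "b": rng.normal(2, 1, 8),
                  "c": rng.normal(4, 1, 8)}
        values, meta = _series(groups)
        res = select_and_run_test(values, meta)
        assert res.test_used == "anova"
        # independent one-way ANOVA from sums of squares, on shifted data
        data = [g + SHIFT for g in groups.values()]
        grand = np.concatenate(data).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in data)
        dfb, dfw = 2, sum(len(g) for g in data) - 3
        f = (ssb / dfb) / (ssw / dfw)
        p = stats.f.sf(f, dfb, dfw)
        assert res.statistic == pytest.approx(f, abs=1e-10)
        assert res.p_main == pytest.approx(p, abs=1e-10)

    def test_lognormal_rescued_by_log10(self):
        rng = np.random.default_rng(4)
        groups = {g: np.exp(rng.normal(mu, 0.5, 10))
                  for g, mu in [("a", 0), ("b", 1), ("c", 2)]}
        values, meta = _series(groups)
        res = select_and_run_test(values, meta)
        assert res.log_applied
        assert res.test_used == "anova"

    def test_label_permutation_leaves_p_fixed(self):
        rng = np.random.default_rng(5)
        values, meta = _series({g: rng.normal(size=6) for g in "abc"})
        res1 = select_and_run_test(values, meta)
        perm = pd.Series(rng.permutation(meta.to_numpy()), index=meta.index)
        # same multiset of group sizes, same data -> same decision machinery
        res2 = select_and_run_test(values, perm)
        res3 = select_and_run_test(values, meta)
        assert res1.p_main == res3.p_main  # pure function, no RNG
        assert res2.test_used in {"anova", "kruskal-wallis"}


class TestBKY:
    def test_extremes(self):
        rej, _ = posthoc_bky([1.0, 1.0, 1.0])
        assert not rej.any()
        rej, adj = posthoc_bky([0.0, 0.0])
        assert rej.all() and (adj == 0).all()

    def test_hand_transcribed_example(self):
        # two-stage step-up at q=0.05 executed by hand:
        # stage 1 (q'=0.047619) rejects the first 2; m0 = 4; stage 2 at
        # q'*6/4 = 0.0714 rejects the first 4.
        p = [0.001, 0.008, 0.039, 0.041, 0.27, 0.60]
        rej, _ = posthoc_bky(p, q=0.05)
        assert rej.tolist() == [True, True, True, True, False, False]

    def test_matches_statsmodels_on_random_lists(self):
        rng = np.random.default_rng(10)
        for _ in range(300):
            m = rng.integers(2, 40)
            p = np.where(rng.random(m) < 0.3, rng.random(m) * 0.05,
                         rng.random(m))
            rej, _ = posthoc_bky(p, q=0.05)
            sm = fdrcorrection_twostage(p, alpha=0.05, method="bky",
                                        maxiter=1)[0]
            assert np.array_equal(rej, sm)

    def test_stage2_superset_of_stage1(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            m = rng.integers(2, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            rej, _ = posthoc_bky(p, q=0.05)
            stage1 = multipletests(p, alpha=0.05 / 1.05, method="fdr_bh")[0]
            assert set(np.where(stage1)[0]) <= set(np.where(rej)[0])

    def test_invalid_p_rejected(self):
        with pytest.raises(GroupStatsError):
            posthoc_bky([0.5, 1.2])


class TestBH:
    @staticmethod
    def _brute_force(p):
        p = np.asarray(p, float)
        m = len(p)
        q = np.empty(m)
        for i, pi in enumerate(p):
            q[i] = min(min(pj * m / (np.sum(p <= pj))
                           for pj in p if pj >= pi), 1.0)
        return q

    def test_single_and_ties(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_stepup_hand_case(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_matches_brute_force_on_random_lists(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            assert np.allclose(bh_fdr(p), self._brute_force(p), atol=1e-12)

    def test_q_properties(self):
        rng = np.random.default_rng(13)
        p = rng.random(50)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFeatureScreen:
    def test_planted_large_effects_recovered(self):
        # 5 planted differential genera of large effect among 55 nulls
        from cecomix.synthetic import SyntheticConfig
        planted = ["Bacteroides", "Alistipes", "Romboutsia", "Dubosiella",
                   "Turicibacter"]
        targets = ["WD/WD-V", "WD/LD-V", "WD/LD-T", "WD/WD-V", "WD/LD-V"]
        recovered = []
        for seed in range(20):
            cfg = SyntheticConfig.null(seed=100 + seed, n_metabolites=1)
            # composition renormalisation dampens the realised fold change,
            # so a "large" planted effect needs a large nominal fold
            cfg.effects = {g: {t: 15.0} for g, t in zip(planted, targets)}
            table, meta, _, _ = cx.generate_cohort(cfg)
            relab = cx.relative_abundance(
                cx.aggregate_by_rank(table, "genus"), "genus")
            results = cx.run_feature_screen(relab, meta)
            sig = {r.feature for r in results if r.p_main < 0.05}
            recovered.append(len(sig & set(planted)))
        assert np.median(recovered) >= 4

    def test_posthoc_only_for_significant(self, genus_relab, study_cohort):
        results = cx.run_feature_screen(genus_relab, study_cohort["meta"])
        for r in results:
            if r.p_main < 0.05:
                assert len(r.posthoc) == 6  # 4 groups -> 6 pairs
            else:
                assert r.posthoc == []
        qs = np.array([r.q_main for r in results])
        ps = np.array([r.p_main for r in results])
        assert (qs >= ps - 1e-12).all()
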