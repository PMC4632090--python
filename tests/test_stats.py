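"""TMM, transforms, paired contrasts, moderation/FDR, selections."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from mirpair import stats, synthetic
from mirpair.stats import (
    ContrastSpec,
    bayes_fdr,
    geometric_mean,
    local_fdr_from_z,
    log_transform,
    moderate_and_fdr,
    paired_contrast,
    paired_deltas,
    presence_filter,
    select_metastasis_specific,
    select_tumor_specific,
    tissue_specific_test,
    tmm_factors,
)


def tmm_oracle(X, logratio_trim=0.3, sum_trim=0.05):
    """Naive re-implementation of the doubly trimmed weighted M-mean."""
    X = np.asarray(X, dtype=float)
    lib = X.sum(axis=0)
    uq = np.array([np.quantile(X[:, j], 0.75) for j in range(X.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    out = np.ones(X.shape[1])
    for s in range(X.shape[1]):
        if s == ref:
            continue
        M, w = [], []
        A = []
        for g in range(X.shape[0]):
            if X[g, s] > 0 and X[g, ref] > 0:
                ps, pr = X[g, s] / lib[s], X[g, ref] / lib[ref]
                M.append(np.log2(ps / pr))
                A.append(0.5 * np.log2(ps * pr))
                w.append((lib[s] - X[g, s]) / (lib[s] * X[g, s])
                         + (lib[ref] - X[g, ref]) / (lib[ref] * X[g, ref]))
        M, A, w = map(np.asarray, (M, A, w))
        n = len(M)
        loM, hiM = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
        loA, hiA = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
        rM, rA = rankdata(M), rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        num = sum(M[k] / w[k] for k in range(n) if keep[k])
        den = sum(1.0 / w[k] for k in range(n) if keep[k])
        out[s] = 2 ** (num / den)
    return out / out[ref]


class TestTMM:
    def test_identical_columns_factor_one(self):
        m = pd.DataFrame({"a": [5.0, 10, 20, 3], "b": [5.0, 10, 20, 3]})
        assert np.allclose(tmm_factors(m), 1.0)

    def test_global_scaling_absorbed_by_library_size(self):
        r = np.random.default_rng(0)
        col = r.integers(1, 200, size=60).astype(float)
        m = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(m), 1.0)

    def test_matches_oracle_on_random_matrices(self):
        r = np.random.default_rng(1)
        for _ in range(20):
            X = r.gamma(2.0, 50.0, size=(50, 4))
            m = pd.DataFrame(X, columns=list("abcd"))
            assert np.allclose(tmm_factors(m).to_numpy(), tmm_oracle(X), atol=1e-8)

    def test_errors(self):
        with pytest.raises(ValueError):
            tmm_factors(pd.DataFrame({"a": [1.0, 2.0]}))
        with pytest.raises(ValueError, match="b"):
            tmm_factors(pd.DataFrame({"a": [1.0, 0.0], "b": [0.0, 1.0]}))


class TestTransforms:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (1.0, 1.0), (255.0, 8.0)])
    def test_log2_closed_forms(self, x, expected):
        out = log_transform(pd.DataFrame({"s": [x]}))
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(pd.DataFrame({"s": [-1.0]}))

    def test_presence_filter_boundary(self):
        m = pd.DataFrame([[1, 1, 0, 0], [1, 1, 1, 0], [2, 3, 4, 5]], dtype=float,
                         index=["two", "three", "four"])
        kept = presence_filter(m, 3)
        assert list(kept.index) == ["three", "four"]

    @pytest.mark.parametrize(
        "values,expected_gm,expected_pct",
        [([0, 0, 0], 0.0, 0.0), ([7.0, 7.0], 7.0, 100.0), ([1.0, 7.0], 3.0, 100.0)],
    )
    def test_geometric_mean_closed_forms(self, values, expected_gm, expected_pct):
        gm, pct = geometric_mean(values)
        assert gm == pytest.approx(expected_gm)
        assert pct == pytest.approx(expected_pct)


class TestPairedContrast:
    def test_all_zero_deltas(self):
        design = synthetic.make_design(5, 1.0, 1.0, seed=9)
        ids = [f"m{i}" for i in range(5)]
        ln = pd.DataFrame(1.0, index=ids, columns=design.sample_ids())
        res = paired_contrast(ln, design, ContrastSpec("M_vs_pCRC"))
        assert np.allclose(res["effect"], 0.0) and np.allclose(res["se"], 0.0)

    def test_matches_ols_normal_equations(self, cohort_design):
        r = np.random.default_rng(2)
        ids = [f"m{i}" for i in range(8)]
        ln = pd.DataFrame(r.normal(5, 1, size=(8, len(cohort_design))),
                          index=ids, columns=cohort_design.sample_ids())
        spec = ContrastSpec("M_vs_pCRC")
        D, covs = paired_deltas(ln, cohort_design, spec)
        res = paired_contrast(ln, cohort_design, spec)
        import statsmodels.api as sm

        X = stats._design_matrix(covs, use_organ=True)
        for m in ids:
            fit = sm.OLS(D.loc[m].to_numpy(), X).fit()
            assert res.loc[m, "effect"] == pytest.approx(fit.params[0], abs=1e-10)
            assert res.loc[m, "se"] == pytest.approx(fit.bse[0], rel=1e-6)

    def test_recovers_planted_effect(self):
        estimates = []
        ids = [f"m{i}" for i in range(60)]
        for seed in range(10):
            design = synthetic.make_design(30, 0.5, 0.4, seed=seed)
            eff = synthetic.plan_effects(60, n_met=0, n_tissue=0, n_tumor_up=0,
                                         n_tumor_down=0, seed=seed)
            eff.met_specific = {0: 0.84}
            tc = synthetic.simulate_counts(ids, design, eff, seed=50 + seed)
            norm = stats.normalize(tc.counts)
            res = paired_contrast(norm.ln, design, ContrastSpec("M_vs_pCRC"))
            estimates.append(res.loc["m0", "effect"])
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert np.mean(estimates) == pytest.approx(0.84, abs=3 * se + 0.05)

    def test_sync_rule_zeroes_time_covariate(self):
        from mirpair.types import Sample, SampleDesign

        samples = []
        for i, gap in enumerate([10, 89, 50, 3]):
            p = f"P{i}"
            samples.append(Sample(f"{p}-pCRC", p, "pCRC", "colon", 0))
            samples.append(Sample(f"{p}-M1", p, "M", "liver", gap))
        design = SampleDesign(samples)
        ln = pd.DataFrame(1.0, index=["m0", "m1", "m2"], columns=[s.sample_id for s in samples])
        _, covs = paired_deltas(ln, design, ContrastSpec("M_vs_pCRC"))
        assert (covs["time_days"] == 0).all()
        # 91-day gap is metachronous
        samples[1] = Sample("P0-M1", "P0", "M", "liver", 91)
        design2 = SampleDesign(samples)
        _, covs2 = paired_deltas(ln, design2, ContrastSpec("M_vs_pCRC"))
        assert covs2.loc["P0-M1|pCRC", "time_days"] == 91


class TestModerationAndFDR:
    def test_bayes_fdr_running_mean_arithmetic(self):
        out = bayes_fdr(np.array([0.01, 0.02, 0.10]))
        assert out == pytest.approx([0.01, 0.015, (0.01 + 0.02 + 0.10) / 3])

    def test_bayes_fdr_monotone_in_lfdr_rank(self, rng):
        lfdr = rng.uniform(0, 1, 500)
        bf = bayes_fdr(lfdr)
        order = np.argsort(lfdr)
        assert np.all(np.diff(bf[order]) >= -1e-12)
        assert np.all((bf >= 0) & (bf <= 1))

    def test_separation_limit_all_significant(self):
        df = pd.DataFrame({"effect": np.full(300, 50.0),
                           "se": np.full(300, 0.01), "df": 20})
        res = moderate_and_fdr(df)
        assert (res.table["bayes_fdr"] < 1e-6).all()

    def test_degenerate_variances_warn(self):
        df = pd.DataFrame({"effect": np.zeros(100), "se": np.full(100, 0.5), "df": 10})
        with pytest.warns(UserWarning, match="degenerate"):
            res = moderate_and_fdr(df)
        assert not res.moderated

    def test_global_null_rarely_called(self):
        fracs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            D = r.normal(0, 0.6, size=(2000, 30))
            df = pd.DataFrame({"effect": D.mean(axis=1),
                               "se": D.std(axis=1, ddof=1) / np.sqrt(30), "df": 29})
            fracs.append((moderate_and_fdr(df).table["bayes_fdr"] <= 0.10).mean())
        assert np.mean(fracs) <= 0.02

    def test_moderation_shrinks_variance_outliers(self):
        r = np.random.default_rng(3)
        se = r.uniform(0.1, 0.3, 400)
        se[0] = 0.01  # an implausibly small sample variance
        df = pd.DataFrame({"effect": np.zeros(400), "se": se, "df": 8})
        res = moderate_and_fdr(df)
        assert abs(res.table["t_mod"].iloc[0]) < 1.0


class TestTissueSpecificTest:
    def test_statistic_arithmetic_from_reported_effects(self):
        # effects +0.84 (M-pCRC) and -0.91 (MN-PN): T = |0.84| - |0.91| = -0.07
        A = pd.DataFrame(np.full((1, 45), 0.84), index=["mir"])
        B = pd.DataFrame(np.full((1, 17), -0.91), index=["mir"])
        res = tissue_specific_test(A, B, n_perm=99, seed=0)
        assert res.table.loc["mir", "T"] == pytest.approx(-0.07)

    def test_null_p_roughly_uniform_over_seeds(self):
        ps = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            A = pd.DataFrame(r.normal(0, 1, size=(1, 20)), index=["m"])
            B = pd.DataFrame(r.normal(0, 1, size=(1, 20)), index=["m"])
            ps.append(tissue_specific_test(A, B, n_perm=199, seed=seed).table["p_perm"].iloc[0])
        assert 0.3 < np.mean(ps) < 0.7
        assert min(ps) < 0.25 and max(ps) > 0.75

    def test_planted_difference_detected_at_fdr_005(self):
        r = np.random.default_rng(4)
        n = 400
        A = pd.DataFrame(r.normal(0, 0.6, size=(n, 20)))
        B = pd.DataFrame(r.normal(0, 0.6, size=(n, 20)))
        A.iloc[:4] += 1.5  # |M-pCRC| = 1.5, |MN-PN| = 0
        res = tissue_specific_test(A, B, n_perm=999, seed=5)
        assert (res.table["bayes_fdr"].iloc[:4] <= 0.05).all()

    def test_untestable_without_normal_pairs(self):
        A = pd.DataFrame(np.zeros((3, 10)))
        B = pd.DataFrame(np.zeros((3, 0)))
        res = tissue_specific_test(A, B)
        assert not res.testable


class TestSelections:
    def _result(self, bayes_fdr_values, effects=None):
        n = len(bayes_fdr_values)
        table = pd.DataFrame({
            "effect": effects if effects is not None else np.ones(n),
            "se": np.ones(n), "df": 10, "t_mod": np.ones(n),
            "lfdr": bayes_fdr_values, "bayes_fdr": bayes_fdr_values,
        }, index=[f"m{i}" for i in range(n)])
        return stats.ContrastResult(table=table)

    def test_empty_stage1_gives_empty_final(self):
        res = self._result([0.5, 0.9])
        tt = tissue_specific_test(pd.DataFrame(np.zeros((2, 5)), index=["m0", "m1"]),
                                  pd.DataFrame(np.zeros((2, 5)), index=["m0", "m1"]),
                                  n_perm=49, seed=0)
        sel = select_metastasis_specific(res, tt)
        assert sel.stage1 == [] and sel.metastasis_specific == []

    def test_discordant_signs_excluded(self):
        a = self._result([0.01, 0.01], effects=[1.0, 1.0])
        b = self._result([0.01, 0.01], effects=[1.0, -1.0])
        gm = pd.Series(10.0, index=["m0", "m1"])
        sel = select_tumor_specific(a, b, gm)
        assert sel.tumor_specific_up == ["m0"] and sel.tumor_specific_down == []

    def test_shortlist_subset_of_up(self):
        a = self._result([0.01] * 4, effects=[1.0, 1.0, -1.0, 1.0])
        b = self._result([0.01] * 4, effects=[1.0, 1.0, -1.0, 1.0])
        gm = pd.Series([5000.0, 10.0, 5000.0, 2000.0], index=[f"m{i}" for i in range(4)])
        sel = select_tumor_specific(a, b, gm)
        assert set(sel.high_expression_shortlist) <= set(sel.tumor_specific_up)
        assert sel.high_expression_shortlist == ["m0", "m3"]

    def test_stage2_removal_without_decoys_is_fdr_limited(self):
        """With no tissue-specific decoys planted, stage 2 should remove
        roughly the stage-1 false-discovery share (nominal q = 0.10), not a
        large fraction of true metastasis-specific calls."""
        removed_fracs = []
        ids = [f"miR-{i:04d}" for i in range(1714)]
        for seed in range(3):
            design = synthetic.make_design(38, 0.6, 0.45, seed=seed)
            eff = synthetic.plan_effects(1714, n_met=8, n_tissue=0, n_tumor_up=0,
                                         n_tumor_down=0, seed=seed,
                                         met_mag=(1.6, 0.1))
            tc = synthetic.simulate_counts(ids, design, eff, seed=30 + seed)
            norm = stats.normalize(stats.presence_filter(tc.counts, 3))
            DA, _ = paired_deltas(norm.ln, design, ContrastSpec("M_vs_pCRC"))
            DB, _ = paired_deltas(norm.ln, design, ContrastSpec("MN_vs_PN"))
            res = moderate_and_fdr(paired_contrast(norm.ln, design, ContrastSpec("M_vs_pCRC")))
            tt = tissue_specific_test(DA, DB, n_perm=999, seed=60 + seed)
            sel = select_metastasis_specific(res, tt)
            if sel.stage1:
                removed_fracs.append(len(sel.tissue_specific_excluded) / len(sel.stage1))
        assert np.mean(removed_fracs) <= 0.25
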