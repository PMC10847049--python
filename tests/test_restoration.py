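import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stressvirome as sv
from stressvirome.model import AbundanceMatrix, ValidationError
from stressvirome.restoration import (
    bh_fdr,
    exclude_outliers,
    hypergeometric_enrichment,
    longitudinal_restoration,
    restoration_contrast,
    restoration_table,
    tukey_pairwise,
    variance_prefilter,
)

GROUPS3 = ["Ctr"] * 4 + ["CtrStress"] * 4 + ["FVTStress"] * 4


class TestOutlierRule:
    def test_extreme_value_removed(self):
        values = [1.0] * 9 + [50.0]  # z of 50 is ~2.85
        kept, removed = exclude_outliers(values)
        assert removed == [50.0] and len(kept) == 9

    def test_homogeneous_values_kept(self):
        kept, removed = exclude_outliers([2.0, 2.0, 2.0, 2.0])
        assert removed == []

    def test_three_values_never_removable(self):
        # in n=3 the largest attainable |z| is (n-1)/sqrt(n) ~ 1.15 < 2.5
        kept, removed = exclude_outliers([1.0, 5.0, 100.0])
        assert removed == []

    def test_at_most_two_removed(self):
        values = [0.0] * 30 + [100.0, 120.0, 140.0]
        kept, removed = exclude_outliers(values)
        assert len(removed) == 2 and set(removed) == {140.0, 120.0}


def _wrap(df):
    """Wrap an arbitrary real-valued frame as a log-scale matrix."""
    return AbundanceMatrix(df, "log")


class TestVariancePrefilter:
    def test_cutoff_boundary(self):
        rng = np.random.default_rng(0)

        def feature_with_variance(v):
            x = rng.normal(size=12)
            x = (x - x.mean()) / x.std(ddof=1)
            return x * np.sqrt(v)

        df = pd.DataFrame(
            [feature_with_variance(0.49), feature_with_variance(0.51)],
            index=["low", "high"],
        )
        out = variance_prefilter(_wrap(df))
        assert out.values.index.tolist() == ["high"]

    def test_constant_feature_removed(self):
        df = pd.DataFrame([[1.0] * 6, [0, 3, -2, 4, 1, -1]], index=["const", "var"])
        out = variance_prefilter(_wrap(df))
        assert "const" not in out.values.index

    def test_zero_cutoff_is_identity(self):
        df = pd.DataFrame([[0, 1, 2], [3, 4, 5.0]], index=["a", "b"])
        assert variance_prefilter(_wrap(df), 0.0).values.index.tolist() == ["a", "b"]


class TestRestorationContrast:
    def test_equal_means_null(self):
        values = [1.0, 1.2, 0.8, 1.0] * 3
        res = restoration_contrast(values, GROUPS3)
        assert res.contrast_estimate == pytest.approx(0.0)
        assert res.p_restoration == pytest.approx(1.0)

    def test_direction_of_restoration(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [1 + 0.001 * rng.normal(size=4), 0.001 * rng.normal(size=4),
             1 + 0.001 * rng.normal(size=4)]
        )
        res = restoration_contrast(values, GROUPS3)
        assert res.contrast_estimate == pytest.approx(1.0, abs=0.01)
        assert res.p_restoration < 1e-6
        assert res.direction == -1  # stress decreased the feature

    def test_df_is_n_minus_three(self):
        res = restoration_contrast(np.arange(12.0), GROUPS3)
        assert res.df == 9

    def test_zero_variance_degenerate(self):
        values = [1.0] * 4 + [0.0] * 4 + [1.0] * 4
        res = restoration_contrast(values, GROUPS3)
        assert res.p_restoration == 0.0

    def test_missing_group_error(self):
        with pytest.raises(ValidationError):
            restoration_contrast([1.0, 2.0, 3.0, 4.0], ["Ctr"] * 2 + ["CtrStress"] * 2)

    def test_weight_scale_invariance(self):
        # contrast t is invariant to rescaling the weights: equivalently,
        # scaling the data scales L and SE together
        rng = np.random.default_rng(1)
        values = rng.normal(size=12)
        r1 = restoration_contrast(values, GROUPS3)
        r2 = restoration_contrast(3.0 * values, GROUPS3)
        assert r1.t_statistic == pytest.approx(r2.t_statistic)
        assert r1.p_restoration == pytest.approx(r2.p_restoration)


class TestTukey:
    def test_identical_groups_p_one(self):
        values = [1.0, 2.0, 3.0, 4.0] * 3
        p = tukey_pairwise(values, GROUPS3)
        assert all(v == pytest.approx(1.0) for v in p.values())

    def test_dominates_unadjusted_contrast_p(self):
        # Tukey adjustment can only increase p relative to the unadjusted
        # pairwise comparison on the same pooled variance and df
        rng = np.random.default_rng(2)
        arr_groups = np.asarray(GROUPS3)
        for _ in range(20):
            values = rng.normal(size=12)
            p = tukey_pairwise(values, GROUPS3)
            by = {g: values[arr_groups == g] for g in set(GROUPS3)}
            df = len(values) - 3
            s2 = sum(((v - v.mean()) ** 2).sum() for v in by.values()) / df
            for (a, b), padj in p.items():
                t = abs(by[a].mean() - by[b].mean()) / np.sqrt(
                    s2 * (1 / len(by[a]) + 1 / len(by[b]))
                )
                t_p = 2 * stats.t.sf(t, df)
                assert padj >= t_p - 1e-12

    def test_familywise_error_under_null(self):
        rng = np.random.default_rng(3)
        groups = ["Ctr"] * 10 + ["CtrStress"] * 10 + ["FVTStress"] * 10
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            values = rng.normal(size=30)
            p = tukey_pairwise(
                values, groups,
                pairs=[("Ctr", "CtrStress"), ("CtrStress", "FVTStress"), ("Ctr", "FVTStress")],
            )
            hits += any(v < 0.05 for v in p.values())
        assert 0.02 <= hits / n_sim <= 0.08


class TestBhFdr:
    def test_hand_computed_step_up(self):
        q = bh_fdr([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_error(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            m = int(rng.integers(1, 100))
            p = rng.uniform(size=m)
            np.testing.assert_allclose(bh_fdr(p), _bh_oracle(p), atol=1e-15)


def _bh_oracle(p):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestRestorationTable:
    def test_matches_per_feature_functions(self, small_design):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            rng.normal(size=(5, 12)), index=[f"f{i}" for i in range(5)],
            columns=small_design.index,
        )
        tab = restoration_table(df, small_design)
        groups = small_design["group"].tolist()
        for fid in df.index:
            res = restoration_contrast(df.loc[fid].to_numpy(), groups, fid)
            assert tab.loc[fid, "t_statistic"] == pytest.approx(res.t_statistic)
            assert tab.loc[fid, "p_restoration"] == pytest.approx(res.p_restoration)
            tk = tukey_pairwise(df.loc[fid].to_numpy(), groups)
            assert tab.loc[fid, "p_ctr_vs_stress"] == pytest.approx(tk[("Ctr", "CtrStress")])
        np.testing.assert_allclose(
            tab["q_value"].to_numpy(), _bh_oracle(tab["p_restoration"].to_numpy())
        )


class TestLongitudinal:
    def _design(self, n_per=6, T=3):
        rows = []
        for g in ("Ctr", "CtrStress", "FVTStress"):
            for k in range(n_per):
                for t in range(T):
                    rows.append(
                        dict(sample_id=f"{g}{k}_T{t}", group=g, subject_id=f"{g}_s{k}",
                             timepoint=f"T{t}", total_mapped_reads=1000)
                    )
        return sv.validate_design(pd.DataFrame(rows))

    def _centered_data(self, design, seed=1, effect=1.0):
        """Residuals centred within subject => estimated subject variance 0."""
        rng = np.random.default_rng(seed)
        T = design["timepoint"].nunique()
        vals = {}
        for sid, sub in design.groupby("subject_id", sort=False):
            e = rng.normal(0, 1, size=T)
            e -= e.mean()
            for (sample, row), ei in zip(sub.iterrows(), e):
                shift = effect if (
                    row["group"] == "CtrStress" and row["timepoint"] == "T2"
                ) else 0.0
                vals[sample] = 2.0 + shift + ei
        return pd.DataFrame({s: [vals[s]] for s in design.index}, index=["feat"])

    def test_reduces_to_cross_sectional_when_subject_variance_zero(self):
        design = self._design()
        df = self._centered_data(design)
        tab = longitudinal_restoration(df, design)
        assert tab["tau2"].iloc[0] == 0.0
        final = [s for s in design.index if design.loc[s, "timepoint"] == "T2"]
        cross = restoration_contrast(
            df[final].iloc[0].to_numpy(), design.loc[final, "group"].tolist()
        )
        assert abs(tab["t_statistic"].iloc[0] - cross.t_statistic) < 1e-6

    def test_subject_offsets_absorbed_in_trend(self):
        # per-subject constant offsets cancel exactly in the within-subject
        # difference-in-differences (group x time) contrast, and are picked
        # up by the subject variance component
        design = self._design()
        rng = np.random.default_rng(7)
        df = self._centered_data(design, seed=2, effect=1.0)
        offsets = {s: rng.normal(0, 5.0) for s in design["subject_id"].unique()}
        shifted = df.copy()
        for sample in design.index:
            shifted[sample] += offsets[design.loc[sample, "subject_id"]]
        plain = longitudinal_restoration(df, design)
        shift = longitudinal_restoration(shifted, design)
        assert shift["trend_estimate"].iloc[0] == pytest.approx(
            plain["trend_estimate"].iloc[0], abs=1e-10
        )
        assert shift["tau2"].iloc[0] > 10 * max(plain["tau2"].iloc[0], 1.0)

    def test_subject_in_two_groups_error(self):
        design = self._design().copy()
        design.loc[design.index[0], "subject_id"] = "FVTStress_s0"
        df = pd.DataFrame(
            np.random.default_rng(0).normal(size=(1, len(design))),
            index=["f"], columns=design.index,
        )
        with pytest.raises(ValidationError):
            longitudinal_restoration(df, design)

    def test_variance_components_match_statsmodels(self):
        import statsmodels.api as sm

        design = self._design(n_per=4)
        rng = np.random.default_rng(9)
        u = {s: rng.normal(0, 1.0) for s in design["subject_id"].unique()}
        y = np.array(
            [
                1.0 + 0.5 * int(design.loc[s, "timepoint"][1]) + u[design.loc[s, "subject_id"]]
                + rng.normal(0, 0.7)
                for s in design.index
            ]
        )
        from stressvirome.restoration import _reml_random_intercept

        cells = sorted(set(zip(design["group"], design["timepoint"])))
        ci = {c: i for i, c in enumerate(cells)}
        X = np.zeros((len(y), len(cells)))
        for i, (g, t) in enumerate(zip(design["group"], design["timepoint"])):
            X[i, ci[(g, t)]] = 1.0
        subj_levels = sorted(design["subject_id"].unique())
        sm_map = {s: i for i, s in enumerate(subj_levels)}
        sidx = np.array([sm_map[s] for s in design["subject_id"]])
        beta, s2, t2, _ = _reml_random_intercept(y, X, sidx, len(subj_levels))

        frame = pd.DataFrame(
            dict(y=y, subj=design["subject_id"].to_numpy(),
                 cell=[f"{g}_{t}" for g, t in zip(design["group"], design["timepoint"])])
        )
        fit = sm.MixedLM.from_formula("y ~ 0 + C(cell)", groups="subj", data=frame).fit(reml=True)
        assert s2 == pytest.approx(fit.scale, rel=1e-4)
        assert t2 == pytest.approx(float(fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6)


class TestEnrichment:
    def test_complete_overlap_probability(self):
        res = hypergeometric_enrichment(set("abcde"), set("abcde"), 10)
        assert res.p_value == pytest.approx(1 / 252)

    def test_term_equals_universe(self):
        res = hypergeometric_enrichment({"a", "b"}, {chr(97 + i) for i in range(10)}, 10)
        assert res.p_value == pytest.approx(1.0)

    def test_oversized_term_error(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"a"}, {str(i) for i in range(11)}, 10)

    def test_matches_pmf_summation(self):
        rng = np.random.default_rng(10)
        universe = [str(i) for i in range(40)]
        for _ in range(50):
            term = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            query = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            res = hypergeometric_enrichment(query, term, 40)
            k = len(query & term)
            oracle = sum(
                stats.hypergeom.pmf(x, 40, len(term), len(query))
                for x in range(k, min(len(term), len(query)) + 1)
            )
            assert res.p_value == pytest.approx(oracle, abs=1e-12)
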