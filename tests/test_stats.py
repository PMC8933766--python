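"""Welch tests, PCA, PERMANOVA, screening and regression against oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from mjdmri import stats as st
from mjdmri import synth

from conftest import SEED

METABOLITES = sorted(synth.MOUSE_METABOLITE_MEANS)


class TestWelch:
    def test_identical_samples(self):
        res = st.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # means 2 / 3.5, variances 1 / 3.5 -> frozen arithmetic oracle
        res = st.welch_t([1, 2, 3], [1, 2, 3, 4, 5, 6])
        assert res.statistic == pytest.approx(-1.5666989036, abs=1e-9)
        assert res.df == pytest.approx(6.7977528090, abs=1e-9)
        assert res.p_value == pytest.approx(0.1624347874, abs=1e-9)

    def test_volumes_at_reported_group_summaries_are_significant(self, rng):
        """Group volumes generated at the reported means/SDs give p < 1e-4."""
        hits = 0
        for _ in range(40):
            wt = rng.normal(49.62, 3.19, 27)
            mjd = rng.normal(20.73, 1.39, 27)
            hits += st.welch_t(wt, mjd).p_value < 1e-4
        assert hits >= 38

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            st.welch_t([1.0], [1.0, 2.0])


class TestPca:
    def test_single_direction_explains_everything(self):
        t = np.linspace(0, 1, 10)
        df = pd.DataFrame({"a": 2 * t, "b": -t, "c": 3 * t})
        res = st.run_pca(df, ["a", "b", "c"], scale=False)
        assert res.variance_explained[0] == pytest.approx(100.0)

    def test_matches_brute_force_eigendecomposition(self):
        X = np.array([[2, 0, 1], [4, 1, 3], [1, 5, 2], [7, 2, 2], [3, 3, 9]], float)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        res = st.run_pca(df, ["a", "b", "c"], scale=False)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        got = res.variance_explained / 100 * eig.sum()
        assert np.allclose(got, eig, atol=1e-10)

    def test_matches_sklearn(self, mouse_cohort):
        from sklearn.decomposition import PCA

        res = st.run_pca(mouse_cohort, METABOLITES, scale=False)
        sk = PCA().fit(mouse_cohort[METABOLITES].to_numpy())
        assert np.allclose(res.variance_explained,
                           100 * sk.explained_variance_ratio_, atol=1e-8)

    def test_loadings_are_orthonormal(self, mouse_cohort):
        L = st.run_pca(mouse_cohort, METABOLITES).loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)

    def test_groups_separate_along_pc1(self, mouse_cohort):
        """Group-shifted metabolites put WT and MJD in distinct score clusters."""
        from sklearn.metrics import silhouette_score

        res = st.run_pca(mouse_cohort, METABOLITES)
        labels = (mouse_cohort["group"] == "MJD").to_numpy()
        assert silhouette_score(res.scores[:, :1], labels) > 0

    def test_variance_invariant_to_variable_order(self, mouse_cohort):
        a = st.run_pca(mouse_cohort, METABOLITES)
        b = st.run_pca(mouse_cohort, METABOLITES[::-1])
        assert np.allclose(a.variance_explained, b.variance_explained, atol=1e-10)

    def test_missing_values_are_refused(self, mouse_cohort):
        with pytest.raises(ValueError, match="missing"):
            st.run_pca(mouse_cohort, METABOLITES + ["rotarod_accel_s"])


class TestPermanova:
    def test_univariate_equals_anova_f(self, rng):
        for _ in range(20):
            n = int(rng.integers(9, 24))
            y = rng.normal(size=n)
            g = rng.choice(list("abc"), size=n)
            if min((g == l).sum() for l in set(g)) < 2 or len(set(g)) < 2:
                continue
            df = pd.DataFrame({"y": y, "grp": g})
            res = st.permanova(df, ["y"], "grp", n_permutations=49, seed=SEED)
            expected = sps.f_oneway(*[y[g == l] for l in sorted(set(g))]).statistic
            assert res.pseudo_F == pytest.approx(expected, abs=1e-10)

    def test_matches_scikit_bio(self, mouse_cohort):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        from scipy.spatial.distance import pdist, squareform

        sub = mouse_cohort.head(30)
        dm = skbio_stats.DistanceMatrix(squareform(pdist(sub[METABOLITES])))
        ref = skbio_stats.permanova(dm, sub["group"].to_numpy(), permutations=99)
        res = st.permanova(sub, METABOLITES, "group", n_permutations=99, seed=SEED)
        assert res.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-8)

    def test_partition_adds_up_and_p_in_range(self, mouse_cohort):
        res = st.permanova(mouse_cohort, METABOLITES, "group",
                           n_permutations=199, seed=SEED)
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within)
        assert 1 / 200 <= res.permutation_p <= 1.0
        assert res.permutation_p == 1 / 200  # strong group shift -> minimal p

    def test_invariant_to_response_column_order(self, mouse_cohort):
        a = st.permanova(mouse_cohort, METABOLITES, "group", 99, seed=SEED)
        b = st.permanova(mouse_cohort, METABOLITES[::-1], "group", 99, seed=SEED)
        assert a.pseudo_F == pytest.approx(b.pseudo_F, abs=1e-12)

    def test_constant_responses_rejected(self):
        df = pd.DataFrame({"grp": list("aabb"), "y": [1.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            st.permanova(df, ["y"], "grp", 99, seed=SEED)


class TestScreen:
    def test_uncorrelated_candidates_all_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("wxyz"))
        kept, log = st.screen_collinearity(df, ["x", "y", "z"], "w")
        assert kept == ["x", "y", "z"]
        assert log.empty

    def test_three_mutually_collinear_keep_exactly_one(self, rng):
        base = rng.normal(size=120)
        df = pd.DataFrame({
            "a": base + 0.1 * rng.normal(size=120),
            "b": base + 0.1 * rng.normal(size=120),
            "c": base + 0.1 * rng.normal(size=120),
        })
        df["out"] = 2 * base + rng.normal(size=120)
        kept, log = st.screen_collinearity(df, ["a", "b", "c"], "out")
        assert len(kept) == 1
        # brute-force: the survivor must beat every partner it faced on AIC
        aics = {v: st.aic_univariate(df[v].to_numpy(), df["out"].to_numpy())[0]
                for v in "abc"}
        assert kept[0] == min(aics, key=aics.get)

    def test_human_cohort_drops_duration_and_cag(self):
        tab = synth.make_cohort(
            synth.human_cohort_spec({"control": 2, "MJD": 200}, seed=SEED)
        )
        mjd = tab[tab["group"] == "MJD"]
        kept, log = st.screen_collinearity(
            mjd, ["age_of_onset", "disease_duration", "cag_repeats", "sara"],
            "gm_volume_ml",
        )
        assert set(kept) == {"age_of_onset", "sara"}
        assert set(log["dropped"]) == {"disease_duration", "cag_repeats"}

    def test_zero_variance_candidate_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 10, "y": np.arange(10.0), "out": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            st.screen_collinearity(df, ["x", "y"], "out")


class TestGroupAgeSexModel:
    def test_recovers_generated_age_slopes(self):
        tab = synth.make_cohort(
            synth.human_cohort_spec({"control": 200, "MJD": 200}, seed=SEED + 3)
        )
        res = st.fit_group_age_sex_model(tab, "gm_volume_ml")
        s = res.stratum_slopes.set_index(["group", "sex"])
        assert s.loc[("MJD", "all"), "age_slope"] == pytest.approx(-0.72, rel=0.12)
        assert s.loc[("control", "all"), "age_slope"] == pytest.approx(-0.39, rel=0.12)

    def test_null_sex_effect_is_dropped(self):
        """Sex (generated with zero effect on GM) is removed by the rule."""
        dropped = 0
        for seed in range(20):
            spec = synth.human_cohort_spec({"control": 60, "MJD": 60}, seed=seed)
            spec.covariate_effects["csf"]["age_slope"] = {
                "control": {"M": 0.0, "F": 0.0}, "MJD": {"M": 0.1, "F": 0.1},
            }
            tab = synth.make_cohort(spec)
            res = st.fit_group_age_sex_model(tab, "gm_volume_ml")
            dropped += "sex" not in res.retained
        assert dropped >= 18

    def test_group_term_always_retained(self, human_cohort):
        res = st.fit_group_age_sex_model(human_cohort, "wm_volume_ml")
        assert "group" in res.retained

    def test_adjusted_p_never_below_raw(self, human_cohort):
        res = st.fit_group_age_sex_model(human_cohort, "gm_volume_ml")
        t = res.terms[res.terms["term"] != "const"]
        assert (t["p_adj"] >= t["p_raw"] - 1e-15).all()

    def test_too_few_subjects_rejected(self, human_cohort):
        with pytest.raises(ValueError, match=">= 10"):
            st.fit_group_age_sex_model(human_cohort.head(5), "gm_volume_ml")


class TestBehaviourRegression:
    def test_exact_linear_relation(self):
        df = pd.DataFrame({"m": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        res = st.regress_behaviour(df, "m", "b")
        assert res.r_squared == pytest.approx(1.0)
        assert res.terms.set_index("term").loc["m", "beta"] == pytest.approx(2.0)

    def test_four_point_hand_oracle(self):
        # closed-form least squares on (0,1),(1,3),(2,2),(3,6)
        df = pd.DataFrame({"m": [0.0, 1, 2, 3], "b": [1.0, 3, 2, 6]})
        res = st.regress_behaviour(df, "m", "b")
        t = res.terms.set_index("term")
        assert t.loc["m", "beta"] == pytest.approx(1.4)
        assert t.loc["const", "beta"] == pytest.approx(0.9)
        assert res.r_squared == pytest.approx(0.7)

    def test_r2_envelope_at_study_scale(self):
        """Rotarod ~ NAA at n ~ 22 lands in the weak-to-moderate r^2 regime."""
        inside = 0
        for seed in range(30):
            spec = synth.mouse_cohort_spec(n_per_group=6, seed=seed)
            tab = synth.make_cohort(spec)  # 24 animals with rotarod data
            res = st.regress_behaviour(tab, "NAA", "rotarod_accel_s")
            inside += 0.05 <= res.r_squared <= 0.75
        assert inside >= 24

    def test_zero_variance_predictor_rejected(self):
        df = pd.DataFrame({"m": [1.0] * 5, "b": np.arange(5.0)})
        with pytest.raises(ValueError, match="zero variance"):
            st.regress_behaviour(df, "m", "b")


class TestBonferroni:
    def test_definition(self):
        assert np.allclose(st.adjust_bonferroni([0.01, 0.04], 2), [0.02, 0.08])

    def test_single_p_unchanged(self):
        assert st.adjust_bonferroni([0.3]) == pytest.approx([0.3])

    @given(hst.lists(hst.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_never_below_raw_and_capped(self, ps):
        adj = st.adjust_bonferroni(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            st.adjust_bonferroni([1.5])


def test_welch_type_one_error_calibrated(rng):
    """Type-I error at alpha = 0.05 stays within [0.03, 0.07] (500 nulls)."""
    rej = 0
    for _ in range(500):
        rej += st.welch_t(rng.normal(size=12), rng.normal(size=12)).p_value < 0.05
    assert 0.03 <= rej / 500 <= 0.07
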