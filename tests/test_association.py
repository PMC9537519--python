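"""Score-test behaviour, weighting identities, weighted Cox contracts and
effective-test thresholds."""

import numpy as np
import pandas as pd
import pytest

import cnvmod as cm
from cnvmod.association import _expected_affected_proportion, _stratum_codes
from cnvmod.types import DELETION, DUPLICATION

from conftest import ONE_STEP_FIXTURES, make_subject_frame


def fixture_frame(name):
    rows = ONE_STEP_FIXTURES[name]
    g = np.array([r[0] for r in rows], float)
    delta = np.array([r[1] for r in rows], float)
    ages = np.array([r[2] for r in rows], float)
    return g, delta, ages


class TestRetroScoreTest:
    def test_monomorphic_genotype_gives_null_result(self):
        df = make_subject_frame([1] * 10, [1, 0] * 5, [50] * 10)
        res = cm.retro_score_test(np.ones(10), df)
        assert res.score_u == 0.0 and res.p_value == 1.0 and np.isnan(res.hr)

    def test_too_few_carriers_raises(self):
        df = make_subject_frame([0] * 10, [1, 0] * 5, [50] * 10)
        with pytest.raises(ValueError, match="carriers"):
            cm.retro_score_test(np.zeros(10), df)

    def test_stratum_relabelling_invariance(self):
        g, delta, ages = fixture_frame("risk_increasing")
        df = make_subject_frame(g, delta, ages)
        df["country"] = ["UK", "US"] * 10
        base = cm.retro_score_test(g, df)
        relabelled = df.copy()
        relabelled["country"] = relabelled["country"].map({"UK": "ZZ", "US": "AA"})
        again = cm.retro_score_test(g, relabelled)
        assert again.score_u == pytest.approx(base.score_u)
        assert again.p_value == pytest.approx(base.p_value)

    def test_family_order_invariance(self):
        g, delta, ages = fixture_frame("risk_increasing")
        df = make_subject_frame(g, delta, ages)
        perm = np.random.default_rng(4).permutation(len(df))
        shuffled = df.iloc[perm].reset_index(drop=True)
        a = cm.retro_score_test(g, df)
        b = cm.retro_score_test(g[perm], shuffled)
        assert b.score_u == pytest.approx(a.score_u)
        assert b.variance_v == pytest.approx(a.variance_v)

    def test_singleton_families_match_unclustered_variance(self):
        g, delta, ages = fixture_frame("risk_increasing")
        df = make_subject_frame(g, delta, ages, one_per_family=True)
        res = cm.retro_score_test(g, df, cm.RetroTestSpec(strata_cols=()))
        # independent recomputation of the unclustered sum of squared scores
        spec = cm.RetroTestSpec()
        lam = spec.incidence.cumulative_hazard(ages)
        resid = delta - lam
        resid_c = resid - resid.mean()
        u = (g - g.mean()) * resid_c
        assert res.variance_v == pytest.approx(np.sum(u**2))
        assert res.score_u == pytest.approx(np.sum(u))

    def test_conflict_excluded_subjects_dropped(self):
        g, delta, ages = fixture_frame("risk_increasing")
        df = make_subject_frame(g, delta, ages)
        g_nan = g.copy()
        g_nan[5] = np.nan
        res = cm.retro_score_test(g_nan, df)
        manual = cm.retro_score_test(
            np.delete(g, 5), df.drop(index=5).reset_index(drop=True)
        )
        assert res.score_u == pytest.approx(manual.score_u)

    def test_p_monotone_in_statistic(self):
        results = []
        for name in ONE_STEP_FIXTURES:
            g, delta, ages = fixture_frame(name)
            r = cm.retro_score_test(g, make_subject_frame(g, delta, ages),
                                    cm.RetroTestSpec(strata_cols=()))
            if r.variance_v > 0:
                results.append((r.score_u**2 / r.variance_v, r.p_value))
        stats_sorted = sorted(results)
        ps = [p for _, p in stats_sorted]
        assert ps == sorted(ps, reverse=True)

    def test_ci_brackets_hr(self):
        for name in ONE_STEP_FIXTURES:
            g, delta, ages = fixture_frame(name)
            r = cm.retro_score_test(g, make_subject_frame(g, delta, ages),
                                    cm.RetroTestSpec(strata_cols=()))
            if np.isfinite(r.hr):
                assert r.ci_low <= r.hr <= r.ci_high

    def test_one_step_tracks_grid_mle_on_fixtures(self, incidence):
        for name in ONE_STEP_FIXTURES:
            g, delta, ages = fixture_frame(name)
            res = cm.retro_score_test(g, make_subject_frame(g, delta, ages),
                                      cm.RetroTestSpec(strata_cols=()))
            mle = cm.retro_mle_grid(g, delta, incidence.cumulative_hazard(ages))
            assert abs(np.log(res.hr) - mle) <= 0.15, name


class TestComputeWeights:
    def test_weight_mapping_from_expected_and_observed(self, incidence):
        # one band: check affected weight = expected/f, unaffected (1-expected)/(1-f)
        n = 40
        delta = np.array([1] * 20 + [0] * 20)
        ages = np.full(n, 50.0)
        df = make_subject_frame(np.zeros(n), delta, ages)
        spec = cm.WeightedCohortSpec(age_band_edges=np.array([18.0, 80.0]))
        w = cm.compute_weights(df, spec)
        expected = _expected_affected_proportion(
            incidence, spec.age_band_edges, np.array([20.0])
        )[0]
        f = 0.5
        assert np.allclose(w[:20], expected / f)
        assert np.allclose(w[20:], (1 - expected) / (1 - f))

    def test_weighted_affected_fraction_equals_expected_in_every_band(self):
        cfg = cm.SimConfig(n_families=2000, ascertainment="clinic",
                           generate_truth_intervals=False, seed=37)
        subjects, _ = cm.simulate_cohort(cfg)
        spec = cm.WeightedCohortSpec()
        w = cm.compute_weights(subjects, spec)
        edges = spec.age_band_edges
        ages = subjects["age_end"].to_numpy()
        aff = subjects["affected"].to_numpy()
        band = np.clip(np.digitize(np.clip(ages, edges[0], edges[-1] - 1e-9), edges) - 1,
                       0, len(edges) - 2)
        expected = _expected_affected_proportion(
            spec.incidence, edges,
            np.bincount(band[~aff], minlength=len(edges) - 1).astype(float),
        )
        for a in range(len(edges) - 1):
            m = band == a
            if m.sum() == 0 or aff[m].all() or not aff[m].any():
                continue
            weighted_fraction = w[m & aff].sum() / w[m].sum()
            assert weighted_fraction == pytest.approx(expected[a], abs=1e-10)

    def test_degenerate_band_gets_unit_weights_with_warning(self):
        n = 10
        df = make_subject_frame(np.zeros(n), np.ones(n), np.full(n, 50.0))
        spec = cm.WeightedCohortSpec(age_band_edges=np.array([18.0, 80.0]))
        with pytest.warns(UserWarning, match="unit weights"):
            w = cm.compute_weights(df, spec)
        assert np.allclose(w, 1.0)


@pytest.fixture(scope="module")
def cohort():
    cfg = cm.SimConfig(
        n_families=1500, n_regions=1, ascertainment="random",
        generate_truth_intervals=False, seed=41,
        mutation_type_probs=(0.6, 0.25, 0.15),
        mutation_type_log_hr={DELETION: np.log(1.4), DUPLICATION: 0.0},
    )
    subjects, _ = cm.simulate_cohort(cfg)
    return subjects


class TestWeightedCohortFit:
    def test_unweighted_unstratified_matches_statsmodels_phreg(self, cohort):
        # independent partial-likelihood implementation as oracle
        import statsmodels.api as sm

        spec = cm.WeightedCohortSpec(strata_cols=(), covariates=())
        res = cm.weighted_cohort_fit(
            cohort, "three_level", weights=np.ones(len(cohort)), spec=spec
        )
        x = pd.get_dummies(cohort["mutation_type"])[[DELETION, DUPLICATION]].astype(float)
        model = sm.PHReg(
            cohort["age_end"], x, status=cohort["affected"].astype(int), ties="breslow"
        )
        fit = model.fit()
        ours = {r.cnv_type: np.log(r.hr) for r in res}
        assert ours[DELETION] == pytest.approx(fit.params[0], abs=1e-4)
        assert ours[DUPLICATION] == pytest.approx(fit.params[1], abs=1e-4)

    def test_clustering_inflates_variance_not_estimate(self, cohort):
        base = cohort.head(600).copy()
        dup = pd.concat([base, base.assign(sample_id=base["sample_id"] + "_b")],
                        ignore_index=True)
        spec = cm.WeightedCohortSpec(strata_cols=(), covariates=())
        w = np.ones(len(dup))
        # two copies in one two-member family
        paired = cm.weighted_cohort_fit(dup, "del_vs_other", weights=w, spec=spec)
        # same rows as singleton families
        solo = dup.copy()
        solo["family_id"] = [f"U{i}" for i in range(len(solo))]
        single = cm.weighted_cohort_fit(solo, "del_vs_other", weights=w, spec=spec)
        assert np.log(paired[0].hr) == pytest.approx(np.log(single[0].hr), abs=1e-8)
        assert paired[0].variance_v >= single[0].variance_v

    def test_dup_coding_excludes_deletions(self, cohort):
        res = cm.weighted_cohort_fit(cohort, "dup_vs_other_excl_del",
                                     spec=cm.WeightedCohortSpec(strata_cols=(), covariates=()))
        assert len(res) == 1 and res[0].cnv_type == DUPLICATION

    def test_missing_exposure_level_raises(self, cohort):
        others = cohort[cohort["mutation_type"] == "other"]
        with pytest.raises(ValueError, match="deletion"):
            cm.weighted_cohort_fit(others, "del_vs_other")


class TestEffectiveTestThreshold:
    @pytest.mark.parametrize(
        "n, display",
        [(6551, 8e-6), (10240, 5e-6), (5094, 1e-5), (8469, 6e-6)],
    )
    def test_printed_thresholds(self, n, display):
        thr = cm.effective_test_threshold(n)
        assert thr.display == pytest.approx(display)
        assert thr.exact == pytest.approx(0.05 / n)

    def test_small_n_exact(self):
        assert cm.effective_test_threshold(10).exact == pytest.approx(5e-3)

    def test_zero_regions_error(self):
        with pytest.raises(ValueError):
            cm.effective_test_threshold(0)


class TestGenomeWideScan:
    def test_scan_counts_effective_tests_and_flags(self, noiseless_cohort):
        subjects, truth, calls, metrics = noiseless_cohort
        gm, _ = cm.run_pipeline(calls, metrics, truth.regions, sample_ids=truth.sample_ids)
        results, thr = cm.genome_wide_scan(gm, subjects, DELETION)
        assert thr.n_tests == len(gm.regions_with_carriers(DELETION))
        for r in results:
            assert 0 < r.p_value <= 1
            assert r.threshold_passed == (r.p_value <= thr.exact)
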