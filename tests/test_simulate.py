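"""Generator contracts: inversion formulas, reproducibility, genotype structure,
onset distribution and the calling-error model."""

import numpy as np
import pandas as pd
import pytest

import cnvmod as cm
from cnvmod.types import DELETION, DUPLICATION, IncidenceTable


class TestSampleOnsetAge:
    def test_constant_hazard_closed_form(self):
        tbl = IncidenceTable([0, 100], [0.02])
        assert cm.sample_onset_age(tbl, 0.0, 0, np.exp(-1)) == pytest.approx(50.0)

    def test_doubled_hazard_halves_time(self):
        tbl = IncidenceTable([0, 100], [0.02])
        assert cm.sample_onset_age(tbl, np.log(2), 1, np.exp(-1)) == pytest.approx(25.0)

    def test_beyond_lifetime_hazard_is_infinite(self):
        tbl = IncidenceTable([0, 80], [0.001])  # total cumulative hazard 0.08
        assert cm.sample_onset_age(tbl, 0.0, 0, 0.5) == np.inf  # -ln(0.5) = 0.69 > 0.08

    def test_u_outside_unit_interval_rejected(self):
        tbl = IncidenceTable([0, 80], [0.01])
        with pytest.raises(ValueError):
            cm.sample_onset_age(tbl, 0.0, 0, 0.0)
        with pytest.raises(ValueError):
            cm.sample_onset_age(tbl, 0.0, 0, 1.0)


class TestSimulateCohort:
    def test_reproducible(self):
        cfg = cm.SimConfig(n_families=60, seed=7)
        a_subj, a_truth = cm.simulate_cohort(cfg)
        b_subj, b_truth = cm.simulate_cohort(cm.SimConfig(n_families=60, seed=7))
        pd.testing.assert_frame_equal(a_subj, b_subj)
        assert np.array_equal(a_truth.genotype, b_truth.genotype)
        assert a_truth.true_cnvs == b_truth.true_cnvs

    def test_null_genotype_frequency_matches_population(self):
        # ~50,000 subjects, beta = 0, random sampling: empirical carrier
        # frequency within 3 binomial SE of the configured 0.2
        cfg = cm.SimConfig(
            n_families=22000, n_regions=1, cnv_frequency=0.2, true_log_hr=0.0,
            ascertainment="random", generate_truth_intervals=False, seed=11,
        )
        _, truth = cm.simulate_cohort(cfg)
        n = truth.genotype.shape[0]
        assert n > 40_000
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(truth.genotype[:, 0].mean() - 0.2) < 3 * se

    def test_zero_hazard_means_no_affected(self):
        cfg = cm.SimConfig(
            n_families=200, incidence=IncidenceTable([0, 80], [0.0]),
            censor_age_range=(25, 79), competing_event_rate=0.0,
            generate_truth_intervals=False, seed=1,
        )
        subjects, _ = cm.simulate_cohort(cfg)
        assert not subjects["affected"].any()

    def test_proband_ascertainment_every_family_has_affected(self):
        cfg = cm.SimConfig(
            n_families=400, ascertainment="proband_affected",
            generate_truth_intervals=False, seed=3,
        )
        subjects, _ = cm.simulate_cohort(cfg)
        assert subjects.groupby("family_id")["affected"].any().all()

    def test_clinic_ascertainment_softer_than_proband(self):
        def frac(asc, seed=5):
            cfg = cm.SimConfig(n_families=3000, ascertainment=asc,
                               generate_truth_intervals=False, seed=seed)
            s, _ = cm.simulate_cohort(cfg)
            return s["affected"].mean()

        assert frac("random") < frac("clinic") < frac("proband_affected")

    def test_age_floor_respected(self):
        cfg = cm.SimConfig(n_families=300, seed=2, generate_truth_intervals=False)
        subjects, _ = cm.simulate_cohort(cfg)
        assert (subjects["age_end"] >= 18).all()

    def test_within_family_genotype_correlation_positive(self):
        cfg = cm.SimConfig(
            n_families=8000, family_size_probs=(0, 1, 0, 0), n_regions=1,
            cnv_frequency=0.2, ascertainment="random",
            generate_truth_intervals=False, seed=13,
        )
        subjects, truth = cm.simulate_cohort(cfg)
        g = truth.genotype[:, 0].astype(float)
        fam = pd.factorize(subjects["family_id"])[0]
        # pair up siblings
        order = np.argsort(fam, kind="stable")
        g = g[order]
        r = np.corrcoef(g[0::2], g[1::2])[0, 1]
        assert r > 0.15

    def test_zero_retention_raises(self):
        cfg = cm.SimConfig(
            n_families=3, ascertainment="proband_affected", seed=0,
            incidence=IncidenceTable([0, 80], [1e-6]),
        )
        with pytest.raises(ValueError, match="n_families"):
            cm.simulate_cohort(cfg)

    def test_onset_distribution_matches_cumulative_hazard(self, incidence):
        # Kaplan-Meier on a beta=0 cohort tracks 1 - exp(-Lambda0(t))
        from lifelines import KaplanMeierFitter

        cfg = cm.SimConfig(
            n_families=10000, n_regions=1, true_log_hr=0.0, ascertainment="random",
            generate_truth_intervals=False, seed=17, min_age=0.0,
        )
        subjects, _ = cm.simulate_cohort(cfg)
        km = KaplanMeierFitter()
        km.fit(subjects["age_end"], subjects["affected"])
        grid = np.arange(25, 76, 5.0)
        est = 1 - km.survival_function_at_times(grid).to_numpy()
        expect = 1 - np.exp(-incidence.cumulative_hazard(grid))
        assert np.max(np.abs(est - expect)) < 0.02


class TestSimulateCalls:
    def test_perfect_calling_is_identity(self, noiseless_cohort):
        _, truth, calls, _ = noiseless_cohort
        truth_keys = {
            (c.sample_id, c.chrom, c.start, c.end, c.cnv_type)
            for c in truth.true_cnvs + truth.diagnostic_cnvs
        }
        call_keys = {(c.sample_id, c.chrom, c.start, c.end, c.cnv_type) for c in calls}
        assert call_keys == truth_keys
        assert all(truth.call_supported)

    def test_detection_sensitivity_binomial(self):
        cfg = cm.SimConfig(
            n_families=1600, family_size_probs=(0, 1, 0, 0), n_regions=40,
            region_cnv_type=[DELETION] * 40, cnv_frequency=0.2,
            ascertainment="random", seed=23,
            detection_sensitivity={DELETION: 0.6, DUPLICATION: 0.6},
            false_call_rate={DELETION: 0.0, DUPLICATION: 0.0},
            mutation_type_probs=(1.0, 0.0, 0.0),
        )
        _, truth = cm.simulate_cohort(cfg)
        n_true = len(truth.true_cnvs)
        assert n_true > 10_000
        calls, _ = cm.simulate_calls(truth, cfg)
        se = np.sqrt(n_true * 0.6 * 0.4)
        assert abs(len(calls) - 0.6 * n_true) < 3 * se

    def test_qc_failures_draw_high_lrr_sd(self):
        cfg = cm.SimConfig(n_families=80, seed=29, qc_fail_fraction=1.0)
        _, truth = cm.simulate_cohort(cfg)
        _, metrics = cm.simulate_calls(truth, cfg)
        assert all(m.lrr_sd > 0.28 for m in metrics)

    def test_reproducible(self):
        cfg = cm.SimConfig(n_families=50, seed=31)
        _, truth_a = cm.simulate_cohort(cfg)
        calls_a, metrics_a = cm.simulate_calls(truth_a, cfg)
        _, truth_b = cm.simulate_cohort(cfg)
        calls_b, metrics_b = cm.simulate_calls(truth_b, cfg)
        assert calls_a == calls_b and metrics_a == metrics_b
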