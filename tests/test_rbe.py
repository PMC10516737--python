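import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import analyze_experiment
from nrbe.assay import SurvivalPoint
from nrbe.lq import LQParameters, predict_sf
from nrbe.rbe import (
    BeamComposition,
    RBEEstimate,
    contamination_fraction,
    correct_survival_points,
    pure_neutron_dose,
    rbe_dose_partition,
    rbe_sf_division,
    summarize_cohort,
)
from nrbe.synthetic import (
    analytic_truth,
    sas_like_params,
    simulate_experiment,
    true_mixed_sf,
    true_neutron_sf,
)


class TestContaminationFraction:
    def test_override_wins(self):
        comp = BeamComposition(3.41, 1.34, gamma_fraction_override=0.2825)
        assert contamination_fraction(comp) == 0.2825

    def test_dose_rate_ratio(self):
        # 1.34 / (3.41 + 1.34) = 0.28211, close to but not equal to the
        # in-sample 28.25% used for the reference analysis
        comp = BeamComposition(neutron_dose_rate=3.41, gamma_dose_rate=1.34)
        assert contamination_fraction(comp) == pytest.approx(0.28211, abs=5e-6)

    def test_pure_neutron_beam(self):
        assert contamination_fraction(BeamComposition(3.41, 0.0)) == 0.0

    def test_missing_inputs_rejected(self):
        with pytest.raises(ValueError):
            contamination_fraction(BeamComposition())
        with pytest.raises(ValueError):
            contamination_fraction(BeamComposition(neutron_dose_rate=3.41))
        with pytest.raises(ValueError):
            contamination_fraction(BeamComposition(-1.0, 1.0))


class TestPureNeutronDose:
    @pytest.mark.parametrize(
        "beam, expected", [(2.90, 2.08), (3.34, 2.40), (3.15, 2.26), (1.70, 1.22)]
    )
    def test_reference_beam_doses(self, beam, expected):
        assert round(pure_neutron_dose(beam, 0.2825), 2) == expected

    def test_no_contamination_identity(self):
        assert pure_neutron_dose(3.7, 0.0) == 3.7

    def test_full_gamma_rejected(self):
        with pytest.raises(ValueError):
            pure_neutron_dose(2.0, 1.0)


class TestDosePartition:
    @pytest.mark.parametrize(
        "gamma_d10, beam_d10, expected",
        [(5.50, 2.90, 2.25), (9.05, 3.34, 3.38), (7.00, 3.15, 2.70), (2.80, 1.70, 1.90)],
    )
    def test_reference_rbe_values(self, gamma_d10, beam_d10, expected):
        est = rbe_dose_partition(gamma_d10, beam_d10, 0.2825)
        assert round(est.rbe_pure_neutron, 2) == expected

    def test_identical_beams_give_unity(self):
        est = rbe_dose_partition(3.0, 3.0, 0.0)
        assert est.rbe_pure_neutron == pytest.approx(1.0)

    def test_partition_invariants(self):
        est = rbe_dose_partition(5.50, 2.90, 0.2825)
        assert est.contamination_gamma_dose + est.pure_neutron_dose == pytest.approx(
            est.beam_d10, abs=1e-9
        )
        assert est.rbe_beam == pytest.approx(est.gamma_d10 / est.beam_d10, abs=1e-9)

    def test_gamma_swamped_by_contamination_rejected(self):
        with pytest.raises(ValueError, match="non-positive effective gamma dose"):
            rbe_dose_partition(0.5, 2.0, 0.9)

    @given(
        ratio=st.floats(1.05, 5.0),
        f1=st.floats(0.0, 0.8),
        bump=st.floats(0.01, 0.15),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_increasing_in_gamma_fraction(self, ratio, f1, bump):
        # when the gamma D10 exceeds the beam D10, discounting more of the
        # beam as gamma makes the neutron component look more effective
        beam, gamma = 2.0, 2.0 * ratio
        r1 = rbe_dose_partition(gamma, beam, f1).rbe_pure_neutron
        r2 = rbe_dose_partition(gamma, beam, min(f1 + bump, 0.95)).rbe_pure_neutron
        assert r2 > r1


class TestCorrectSurvivalPoints:
    def test_zero_fraction_is_identity(self):
        pts = [SurvivalPoint(2, 0.5, 0.05, 3), SurvivalPoint(4, 0.2, 0.02, 3)]
        out = correct_survival_points(pts, LQParameters(0.3, 0.02), f=0.0)
        assert out == pts

    def test_direct_quotient(self):
        # gamma curve with SF = 0.4 at the contamination dose f*D = 2 Gy
        alpha = -np.log(0.4) / 2.0
        gamma_fit = LQParameters(alpha, 0.0)
        (out,) = correct_survival_points([SurvivalPoint(4.0, 0.04)], gamma_fit, f=0.5)
        assert out.sf == pytest.approx(0.1, abs=1e-12)
        assert out.dose == pytest.approx(2.0)

    def test_never_decreases_survival(self):
        rng = np.random.default_rng(5)
        pts = [SurvivalPoint(d, float(s)) for d, s in zip([2, 4, 6], rng.uniform(0.01, 0.9, 3))]
        out = correct_survival_points(pts, LQParameters(0.4, 0.05), f=0.3)
        for before, after in zip(pts, out):
            assert after.sf >= before.sf

    def test_sd_scaled_by_gamma_survival(self):
        gamma_fit = LQParameters(0.5, 0.0)
        (out,) = correct_survival_points([SurvivalPoint(2.0, 0.3, sd=0.06)], gamma_fit, f=0.5)
        sf_gamma = predict_sf(gamma_fit, 1.0)
        assert out.sd == pytest.approx(0.06 / sf_gamma)

    def test_strained_independence_warns(self):
        with pytest.warns(UserWarning, match="independence assumption strained"):
            correct_survival_points([SurvivalPoint(2.0, 0.95)], LQParameters(0.5, 0.0), f=0.5)

    def test_round_trip_recovers_pure_neutron_curve(self):
        # exact-independence data: corrected SF must equal the generating
        # pure-neutron curve at the pure-neutron dose
        p = sas_like_params(noise_mode="none")
        f = p.gamma_fraction
        gamma_fit = LQParameters(p.gamma_alpha, p.gamma_beta)
        beam_pts = [SurvivalPoint(d, true_mixed_sf(p, d)) for d in (2.0, 4.0, 6.0, 8.0)]
        for pt in correct_survival_points(beam_pts, gamma_fit, f):
            assert pt.sf == pytest.approx(true_neutron_sf(p, pt.dose), abs=1e-10)


class TestSFDivision:
    def test_noise_free_linear_matches_dose_partition(self):
        p = sas_like_params(
            noise_mode="none", gamma_beta=0.0, neutron_beta=0.0, cells_seeded=10**6
        )
        res = analyze_experiment(simulate_experiment(p), p.gamma_fraction)
        r1 = res["dose_partition"].rbe_pure_neutron
        r2 = res["sf_division"].rbe_pure_neutron
        assert abs(r1 - r2) < 1e-6

    def test_zero_fraction_reduces_to_uncorrected_beam_fit(self):
        p = sas_like_params(noise_mode="none", cells_seeded=10**6, gamma_fraction=0.0)
        res = analyze_experiment(simulate_experiment(p), 0.0)
        est = res["sf_division"]
        assert est.rbe_pure_neutron == pytest.approx(
            res["gamma"]["d10"] / res["neutron_beam"]["d10"], rel=1e-9
        )

    def test_partition_invariant_holds_for_implied_beam_d10(self):
        p = sas_like_params(noise_mode="none", cells_seeded=10**6)
        res = analyze_experiment(simulate_experiment(p), p.gamma_fraction)
        est = res["sf_division"]
        assert est.contamination_gamma_dose + est.pure_neutron_dose == pytest.approx(
            est.beam_d10, abs=1e-9
        )

    def test_noisy_estimate_within_monte_carlo_envelope(self):
        """A fresh seeded estimate lies inside the 95% envelope of the
        estimator's own sampling distribution."""
        values = []
        for i in range(150):
            p = sas_like_params(seed=40_000 + i)
            res = analyze_experiment(
                simulate_experiment(p), p.gamma_fraction, drop_unestimable=True
            )
            values.append(res["sf_division"].rbe_pure_neutron)
        lo, hi = np.percentile(values, [2.5, 97.5])
        p = sas_like_params(seed=99_999)
        res = analyze_experiment(simulate_experiment(p), p.gamma_fraction, drop_unestimable=True)
        assert lo <= res["sf_division"].rbe_pure_neutron <= hi
        truth = analytic_truth(p)["rbe_sf_division"]
        assert lo <= truth <= hi


class TestCohortSummary:
    @staticmethod
    def make(line, method, rbe, gamma_d10=5.0):
        return RBEEstimate(
            cell_line=line,
            method=method,
            gamma_d10=gamma_d10,
            beam_d10=2.0,
            contamination_gamma_dose=0.5,
            pure_neutron_dose=1.5,
            rbe_beam=gamma_d10 / 2.0,
            rbe_pure_neutron=rbe,
        )

    def test_reference_cohort_means(self):
        m1 = {"SAS": 2.25, "SCCVII": 3.38, "U87-MG": 2.70, "NB1RG": 1.90}
        m2 = {"SAS": 2.34, "SCCVII": 3.45, "U87-MG": 2.75, "NB1RG": 1.93}
        ests = [self.make(k, "dose_partition", v) for k, v in m1.items()]
        ests += [self.make(k, "sf_division", v) for k, v in m2.items()]
        summary = summarize_cohort(ests)
        assert round(summary.mean_rbe_by_method["dose_partition"], 2) == 2.56
        assert round(summary.mean_rbe_by_method["sf_division"], 2) == 2.62
        lo, hi = summary.percent_difference_range
        assert round(lo, 2) == 1.55
        assert round(hi, 2) == 3.85

    def test_identical_estimates_zero_difference(self):
        ests = [self.make("A", "dose_partition", 2.0), self.make("A", "sf_division", 2.0)]
        summary = summarize_cohort(ests)
        assert summary.percent_difference_range == (0.0, 0.0)

    def test_missing_method_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            summarize_cohort([self.make("A", "dose_partition", 2.0)])

    def test_scatter_pairs_back_the_sensitivity_relation(self):
        ests = [
            self.make("A", "dose_partition", 2.0, gamma_d10=4.0),
            self.make("A", "sf_division", 2.1, gamma_d10=4.0),
        ]
        summary = summarize_cohort(ests)
        assert summary.scatter["dose_partition"] == [(4.0, 2.0)]
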