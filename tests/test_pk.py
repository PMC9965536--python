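import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbbm import (
    ComparisonRow,
    ConcentrationProfile,
    PKMetrics,
    aafe,
    fold_error_summary,
    food_effect_ratio,
    geometric_stats,
    nca,
    numerical_deconvolution,
    ratio_table,
    wagner_nelson,
)


def _exp_profile(c0=100.0, kel=0.1, t_end=48.0, dt=1.0):
    t = np.arange(0.0, t_end + dt / 2, dt)
    return ConcentrationProfile(t, c0 * np.exp(-kel * t))


class TestNCA:
    def test_monoexponential_oracle(self):
        metrics = nca(_exp_profile())
        analytic_auc = 100.0 / 0.1 * (1 - np.exp(-0.1 * 48))
        assert metrics.auc_0_t == pytest.approx(analytic_auc, rel=5e-3)
        assert metrics.t_half == pytest.approx(np.log(2) / 0.1, rel=1e-6)
        assert metrics.auc_0_inf == pytest.approx(1000.0, rel=5e-3)
        assert metrics.cmax == 100.0
        assert metrics.tmax == 0.0

    def test_linearity_in_concentration(self):
        base = nca(_exp_profile())
        doubled = nca(_exp_profile(c0=200.0))
        assert doubled.cmax == pytest.approx(2 * base.cmax)
        assert doubled.auc_0_t == pytest.approx(2 * base.auc_0_t)
        assert doubled.tmax == base.tmax

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            nca(ConcentrationProfile(np.array([0.0]), np.array([1.0])))

    def test_no_terminal_phase_flagged(self):
        t = np.arange(5.0)
        rising = ConcentrationProfile(t, np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        metrics = nca(rising)
        assert metrics.t_half is None
        assert metrics.auc_0_inf is None


class TestGeometricStats:
    def test_decade_values(self):
        gmean, _ = geometric_stats([1.0, 10.0, 100.0])
        assert gmean == pytest.approx(10.0)

    def test_identical_values_zero_cv(self):
        _, cv = geometric_stats([3.0, 3.0, 3.0])
        assert cv == 0.0

    def test_lognormal_moment_identity(self):
        rng = np.random.default_rng(42)
        x = np.exp(rng.normal(0.0, 0.4, 100000))
        _, cv = geometric_stats(x)
        assert cv == pytest.approx(100 * np.sqrt(np.exp(0.16) - 1), rel=0.01)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            geometric_stats([1.0, 0.0])


class TestAAFE:
    def test_perfect_predictions(self):
        assert aafe([(1.0, 1.0), (5.0, 5.0)]) == 1.0

    def test_uniform_twofold(self):
        assert aafe([(2.0, 1.0), (4.0, 2.0)]) == pytest.approx(2.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3)),
            min_size=1, max_size=10,
        )
    )
    def test_swap_invariance_and_floor(self, pairs):
        forward = aafe(pairs)
        swapped = aafe([(o, p) for p, o in pairs])
        assert forward == pytest.approx(swapped, rel=1e-12)
        assert forward >= 1.0
        # Jensen ordering: AAFE >= geometric-mean fold error
        mean_log = abs(np.mean([np.log10(p / o) for p, o in pairs]))
        assert forward >= 10**mean_log - 1e-12

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            aafe([(1.0, 0.0)])


class TestFoldErrorSummary:
    def test_all_exact(self):
        rows = [ComparisonRow("s", 1, "Cmax", 1.0, 1.0) for _ in range(3)]
        s = fold_error_summary(rows)
        assert (s.max_fold_deviation, s.fraction_within_1_25, s.fraction_within_2) == (
            1.0, 1.0, 1.0,
        )

    def test_half_and_double(self):
        rows = [
            ComparisonRow("s", 1, "Cmax", 1.0, 0.5),
            ComparisonRow("s", 1, "Cmax", 1.0, 2.0),
        ]
        s = fold_error_summary(rows)
        assert s.max_fold_deviation == 2.0
        assert s.fraction_within_2 == 1.0
        assert s.fraction_within_1_25 == 0.0


class TestRatioTable:
    def test_printed_iv_ratios(self):
        table = ratio_table([8.44, 93.3], [5.98, 87.8], ["Cmax", "AUC"])
        assert table.ratio_2dp.tolist() == [0.71, 0.94]

    def test_identity_ratio(self):
        table = ratio_table([3.0], [3.0])
        assert table.ratio_2dp.tolist() == [1.0]

    def test_zero_observed_flagged(self):
        table = ratio_table([0.0, 1.0], [1.0, 1.0])
        assert bool(table.flagged_zero_observed[0])
        assert np.isnan(table.ratio_pred_obs[0])


class TestWagnerNelson:
    def test_first_order_input_recovery(self):
        ka, kel = 1.0, 0.1
        t = np.linspace(0.0, 72.0, 721)
        conc = ka / (ka - kel) * (np.exp(-kel * t) - np.exp(-ka * t))
        _, f = wagner_nelson(ConcentrationProfile(t, conc), kel)
        f2 = np.interp(2.0, t, f)
        assert f2 == pytest.approx(1 - np.exp(-2.0), rel=0.01)

    def test_iv_bolus_jumps_to_one(self):
        kel = 0.1
        t = np.linspace(0.0, 72.0, 721)
        _, f = wagner_nelson(ConcentrationProfile(t, np.exp(-kel * t)), kel)
        # trapezoidal AUC makes this exact only to grid accuracy
        assert f[0] == pytest.approx(1.0, rel=1e-4)

    def test_noisy_profile_monotone_recovery(self):
        ka, kel = 1.0, 0.1
        rng = np.random.default_rng(3)
        t = np.linspace(0.0, 72.0, 289)
        clean = ka / (ka - kel) * (np.exp(-kel * t) - np.exp(-ka * t))
        noisy = clean * np.exp(rng.normal(0, 0.05, t.shape))
        _, f = wagner_nelson(ConcentrationProfile(t, noisy), kel)
        truth = 1 - np.exp(-ka * t)
        assert np.all(np.diff(f) >= 0)
        assert np.sqrt(np.mean((f - truth) ** 2)) < 0.05

    def test_invalid_kel(self):
        with pytest.raises(ValueError):
            wagner_nelson(_exp_profile(), 0.0)


class TestDeconvolution:
    @staticmethod
    def _uir(kel=0.05, v=25.0, t_end=48.0, n=2401):
        t = np.linspace(0.0, t_end, n)
        return ConcentrationProfile(t, 1.0 / v * np.exp(-kel * t) * 1000.0)

    def test_square_pulse_round_trip(self):
        kel, v = 0.05, 25.0
        cl = kel * v
        t = np.linspace(0.0, 48.0, 481)
        rate = 25.0  # mg/h for 2 h -> 50 mg
        conc = np.where(
            t <= 2.0,
            rate / cl * (1 - np.exp(-kel * t)),
            rate / cl * (1 - np.exp(-kel * 2.0)) * np.exp(-kel * (t - 2.0)),
        ) * 1000.0
        mids, r = numerical_deconvolution(
            ConcentrationProfile(t, conc), self._uir(kel, v)
        )
        mass = np.sum(r * np.diff(t))
        assert mass == pytest.approx(50.0, rel=0.01)
        # the recovered rate is concentrated in the first 2 h
        assert np.sum(r[mids <= 2.2] * np.diff(t)[mids <= 2.2]) / mass > 0.95

    def test_zero_profile_zero_input(self):
        t = np.linspace(0.0, 24.0, 97)
        mids, r = numerical_deconvolution(
            ConcentrationProfile(t, np.zeros_like(t)), self._uir()
        )
        assert np.all(r == 0.0)

    def test_cross_method_agreement_with_wagner_nelson(self):
        """First-order input: cumulative input from impulse-response
        deconvolution matches the Wagner-Nelson fraction within 3%."""
        ka, kel, v = 0.8, 0.05, 25.0
        t = np.linspace(0.0, 72.0, 721)
        dose = 100.0
        conc = dose * ka / (v * (ka - kel)) * (
            np.exp(-kel * t) - np.exp(-ka * t)
        ) * 1000.0
        profile = ConcentrationProfile(t, conc)
        mids, r = numerical_deconvolution(profile, self._uir(kel, v, t_end=72.0))
        cum = np.cumsum(r * np.diff(t)) / dose  # cumulative at interval ends
        _, f_wn = wagner_nelson(profile, kel)
        assert np.max(np.abs(cum - f_wn[1:])) < 0.03

    def test_short_uir_rejected(self):
        t = np.linspace(0.0, 48.0, 49)
        with pytest.raises(ValueError):
            numerical_deconvolution(
                ConcentrationProfile(t, np.ones_like(t)),
                self._uir(t_end=10.0),
            )


class TestFoodEffectRatio:
    @staticmethod
    def _metrics(cmax, auc):
        return PKMetrics(cmax=cmax, tmax=4.0, auc_0_t=auc, auc_0_inf=auc, t_half=15.0)

    def test_identical_metrics_unity(self):
        m = self._metrics(1.0, 10.0)
        assert food_effect_ratio(m, m) == (1.0, 1.0)

    def test_printed_predicted_ratio(self):
        """Predicted 200 mg fed vs fasted Cmax 1.0 / 0.36 = 2.78."""
        fed = self._metrics(1.0, 31.9)
        fasted = self._metrics(0.36, 10.9)
        cmax_ratio, auc_ratio = food_effect_ratio(fed, fasted)
        assert cmax_ratio == pytest.approx(2.78, abs=0.005)
        assert auc_ratio == pytest.approx(31.9 / 10.9, rel=1e-9)
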