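import pytest
from hypothesis import given, settings, strategies as st

from pbbm import (
    GeneratorSpec,
    MediumComposition,
    MicellePartition,
    SolubilityMeasurement,
    build_physiology,
    calibration_measurements,
    default_assay_media,
    fit_logkmw,
    fraction_unbound_dissolved,
    gen_solubility_dataset,
    predict_solubility_table,
    regional_luminal_solubility,
    total_solubility,
)
from pbbm.micelle import InfeasibleSolubilityWarning

SIVA = MicellePartition(0.019, 4.559)  # platform-fitted constants


class TestTotalSolubility:
    def test_no_micelles_reduces_to_aqueous(self, compound):
        for ph in (1.8, 5.4, 6.5, 7.4):
            assert total_solubility(ph, 0.0, SIVA, compound) == pytest.approx(
                compound.aqueous_solubility(ph)
            )

    def test_frozen_point_value(self, compound):
        # hand evaluation of the solubilization-capacity form at the
        # platform constants: S_aq(6.5) + S0*(f_n*10^0.019+f_i*10^4.559)*C*v_w
        assert total_solubility(6.5, 0.003, SIVA, compound) == pytest.approx(
            1.5901e-4, rel=1e-3
        )

    def test_monotone_in_bile(self, compound):
        s3 = total_solubility(6.5, 0.003, SIVA, compound)
        s15 = total_solubility(6.5, 0.015, SIVA, compound)
        assert s15 > s3

    def test_negative_bile_rejected(self, compound):
        with pytest.raises(ValueError):
            total_solubility(6.5, -0.001, SIVA, compound)


class TestFractionUnbound:
    def test_unity_without_micelles(self, compound):
        assert fraction_unbound_dissolved(6.5, 0.0, SIVA, compound) == 1.0

    def test_frozen_point_value(self, compound):
        assert fraction_unbound_dissolved(6.5, 0.003, SIVA, compound) == pytest.approx(
            0.96276, rel=1e-4
        )

    def test_monotone_decreasing_in_bile(self, compound):
        fus = [
            fraction_unbound_dissolved(6.5, c, SIVA, compound)
            for c in (0.0, 0.003, 0.015, 0.05)
        ]
        assert all(a > b for a, b in zip(fus, fus[1:]))

    @settings(max_examples=100, deadline=None)
    @given(
        ph=st.floats(2.0, 9.0),
        c_bs=st.floats(0.0, 0.05),
        lkn=st.floats(-2.0, 8.0),
        lki=st.floats(-2.0, 6.0),
    )
    def test_saturation_identity(self, compound, ph, c_bs, lkn, lki):
        """S_total * fu == S_aq holds algebraically for any partition."""
        part = MicellePartition(lkn, lki)
        s_tot = total_solubility(ph, c_bs, part, compound)
        fu = fraction_unbound_dissolved(ph, c_bs, part, compound)
        assert s_tot * fu == pytest.approx(compound.aqueous_solubility(ph), rel=1e-10)


class TestFitLogKmw:
    def test_noiseless_two_media_round_trip(self, compound):
        true = MicellePartition(0.5, 4.2)
        media = [default_assay_media()[2], default_assay_media()[3]]  # pH5/3mM, pH4.8/15mM
        data = gen_solubility_dataset(true, media, GeneratorSpec(seed=0, cv=0.0), compound)
        fit = fit_logkmw(data, compound)
        assert fit.logk_neutral == pytest.approx(0.5, abs=1e-6)
        assert fit.logk_ion == pytest.approx(4.2, abs=1e-6)

    def test_calibration_pair_reproduced_within_1pct(self, compound, partition):
        for meas in calibration_measurements("oa_ch"):
            pred = total_solubility(meas.pH, meas.medium.bile_molar, partition, compound)
            assert pred == pytest.approx(meas.mean_mg_per_ml, rel=0.01)
        assert partition.fit_residual < 1e-8

    def test_single_medium_underdetermined(self, compound):
        meas = calibration_measurements("oa_ch")[:1]
        with pytest.raises(ValueError):
            fit_logkmw(meas, compound)

    def test_identical_conditions_degenerate(self, compound):
        medium = MediumComposition("m", 6.5, 3.0)
        data = [
            SolubilityMeasurement(medium, [200.0, 210.0]),
            SolubilityMeasurement(medium, [190.0, 205.0]),
        ]
        with pytest.raises(ValueError):
            fit_logkmw(data, compound)

    def test_subaqueous_observation_warns_and_floors(self, compound):
        media = default_assay_media()[:2]
        data = [
            SolubilityMeasurement(media[0], [0.01]),  # far below S_aq in µg/mL
            SolubilityMeasurement(media[1], [0.01]),
        ]
        with pytest.warns(InfeasibleSolubilityWarning):
            fit = fit_logkmw(data, compound)
        assert fit.logk_ion == -6.0
        assert fit.logk_neutral == -6.0

    def test_vw_convention_robustness(self, compound):
        """The predicted fed:fasted solubility ratio does not depend on
        the micellar molar-volume convention when the fit and the
        prediction share it."""
        meas = calibration_measurements("oa_ch")
        ratios = []
        for v_w in (0.018, 0.025, 1.0):
            part = fit_logkmw(meas, compound, v_w=v_w)
            fed = total_solubility(5.4, 0.015, part, compound, v_w=v_w)
            fasted = total_solubility(6.4, 0.003, part, compound, v_w=v_w)
            ratios.append(fed / fasted)
        assert ratios[0] == pytest.approx(ratios[1], rel=1e-8)
        assert ratios[0] == pytest.approx(ratios[2], rel=1e-8)


class TestPredictionTable:
    @pytest.mark.parametrize(
        "observed,predicted,expected",
        [(0.17, 0.2, 1.18), (0.52, 0.51, 0.98), (0.4, 0.4, 1.0)],
    )
    def test_rendered_ratios(self, observed, predicted, expected):
        # ratio arithmetic at render rounding (2 decimals)
        assert round(predicted / observed, 2) == pytest.approx(expected)

    def test_table_shape_and_ratio(self, compound, partition):
        meas = calibration_measurements("oa_ch")
        table = predict_solubility_table(
            partition, [m.medium for m in meas], [m.mean_mg_per_ml for m in meas],
            compound,
        )
        assert list(table.columns[:3]) == ["label", "observed_mg_mL", "predicted_mg_mL"]
        assert table.ratio_2dp.tolist() == [1.0, 1.0]  # exact calibration fit

    def test_length_mismatch(self, compound, partition):
        with pytest.raises(ValueError):
            predict_solubility_table(partition, [], [0.17], compound)


class TestRegionalSolubility:
    def test_length_and_zero_bile(self, compound, partition):
        phys = build_physiology("fasted")
        s = regional_luminal_solubility(phys, partition, compound)
        assert len(s) == len(phys)
        # stomach has no bile: aqueous solubility only
        assert s[0] == pytest.approx(compound.aqueous_solubility(phys[0].luminal_pH))

    def test_fed_duodenum_exceeds_fasted(self, compound, partition):
        fed = regional_luminal_solubility(build_physiology("fed"), partition, compound)
        fasted = regional_luminal_solubility(
            build_physiology("fasted"), partition, compound
        )
        assert fed[1] / fasted[1] > 2.0  # strong positive food effect on solubility

    def test_empty_physiology_rejected(self, compound, partition):
        with pytest.raises(ValueError):
            regional_luminal_solubility([], partition, compound)
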