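import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from ppikit.inhibition import (
    InhibitionSeries,
    dose_response_table,
    henderson_fit,
    morrison_fraction,
    percent_residual_activity,
)
from ppikit.synth import generate_titration

from conftest import (
    ENZYME,
    ENZYME_CU,
    K_CAT,
    K_UNCAT,
    KI_CSA,
    KI_CU_LOOSE,
    KI_CU_TIGHT,
    binding_fraction_oracle,
    make_titration_design,
)


class TestMorrisonFraction:
    def test_no_inhibitor(self):
        assert morrison_fraction(ENZYME, 0.0, KI_CSA) == pytest.approx(1.0)

    def test_classical_limit_at_ki(self):
        # E -> 0: fraction tends to Ki/(Ki + I); at I = Ki that is 1/2
        a = morrison_fraction(1e-15, KI_CSA, KI_CSA)
        assert a == pytest.approx(0.5, rel=1e-6)

    def test_study_saturating_point(self):
        # 120 nM CsA against 4.34 nM enzyme, Ki 18.75 nM
        a = morrison_fraction(ENZYME, 120e-9, KI_CSA)
        assert a == pytest.approx(0.139, abs=5e-4)

    @pytest.mark.parametrize(
        "enzyme,inhibitor,ki",
        [
            (ENZYME, 120e-9, KI_CSA),
            (ENZYME, 5e-9, KI_CSA),
            (ENZYME_CU, 10e-6, KI_CU_LOOSE),
            (ENZYME_CU, 25e-9, KI_CU_TIGHT),
            (1e-9, 1e-9, 1e-9),
        ],
    )
    def test_against_equilibrium_oracle(self, enzyme, inhibitor, ki):
        # independent brute-force solution of the binding equilibrium
        expected = binding_fraction_oracle(enzyme, inhibitor, ki)
        assert morrison_fraction(enzyme, inhibitor, ki) == pytest.approx(
            expected, rel=1e-10
        )

    def test_vectorized(self):
        conc = np.array([0.0, 10e-9, 120e-9])
        a = morrison_fraction(ENZYME, conc, KI_CSA)
        assert a.shape == (3,)
        assert np.all(np.diff(a) < 0)

    @given(
        log_i1=st.floats(-12, -3),
        log_i2=st.floats(-12, -3),
        log_ki=st.floats(-10, -4),
    )
    @settings(max_examples=50)
    def test_monotone_decreasing_in_inhibitor(self, log_i1, log_i2, log_ki):
        lo, hi = sorted((10**log_i1, 10**log_i2))
        a_lo = morrison_fraction(ENZYME, hi, 10**log_ki)
        a_hi = morrison_fraction(ENZYME, lo, 10**log_ki)
        assert a_lo <= a_hi + 1e-12
        assert 0.0 <= a_lo <= 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            morrison_fraction(ENZYME, -1e-9, KI_CSA)
        with pytest.raises(ValueError):
            morrison_fraction(0.0, 1e-9, KI_CSA)


class TestHendersonFit:
    def test_exact_recovery_csa(self, csa_design):
        series = generate_titration(csa_design)
        res = henderson_fit(series)
        assert res.ki == pytest.approx(KI_CSA, rel=1e-12)
        assert res.enzyme_est == pytest.approx(ENZYME, rel=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.variant == "enzymatic-rate"

    def test_exact_recovery_cu_loose(self):
        design = make_titration_design(
            KI_CU_LOOSE, ENZYME_CU, [c * 1e-6 for c in (1, 2, 5, 10, 20, 40, 70, 100)]
        )
        res = henderson_fit(generate_titration(design))
        assert res.ki == pytest.approx(KI_CU_LOOSE, rel=1e-10)

    def test_exact_recovery_cu_tight(self):
        design = make_titration_design(
            KI_CU_TIGHT, ENZYME_CU, [c * 1e-9 for c in (1, 2, 5, 10, 25, 50, 100, 200)]
        )
        res = henderson_fit(generate_titration(design))
        assert res.ki == pytest.approx(KI_CU_TIGHT, rel=1e-10)

    @pytest.mark.parametrize("ratio", [1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3])
    def test_exactness_across_ki_over_e_ratios(self, ratio):
        # Henderson is an algebraic rearrangement of Morrison: exact on
        # noiseless data from loose to tight binding
        enzyme = 10e-9
        ki = ratio * enzyme
        concs = tuple(f * max(ki, enzyme) for f in (0.2, 0.5, 1, 2, 5, 10, 20, 50))
        design = make_titration_design(ki, enzyme, concs)
        res = henderson_fit(generate_titration(design))
        assert res.ki == pytest.approx(ki, rel=1e-9)
        assert res.enzyme_est == pytest.approx(enzyme, rel=1e-6)

    def test_morrison_nonlinear_fit_consistency(self, csa_design):
        # dual-route check: direct nonlinear fit of the Morrison model
        # to (I, a) agrees with the Henderson slope on noiseless data
        series = generate_titration(csa_design)
        a_obs = (series.rate_constants - series.ku) / (series.k0 - series.ku)

        def model(i, ki, e):
            from ppikit.inhibition import morrison_fraction as mf

            return np.array([mf(e, x, ki) for x in i])

        popt, _ = curve_fit(
            model, series.concentrations, a_obs, p0=(1e-8, 1e-9),
            bounds=([1e-12, 1e-12], [1e-3, 1e-6]),
        )
        henderson = henderson_fit(series)
        assert henderson.ki == pytest.approx(popt[0], rel=0.01)

    def test_flat_series_rejected(self):
        series = InhibitionSeries(
            inhibitor_name="FK506",
            concentrations=np.array([1e-6, 5e-6, 10e-6, 20e-6]),
            rate_constants=np.full(4, K_CAT),
            k0=K_CAT,
            ku=K_UNCAT,
        )
        with pytest.raises(ValueError, match="inhibition signal"):
            henderson_fit(series)

    def test_zero_conc_points_excluded(self, csa_design):
        design = make_titration_design(
            KI_CSA, ENZYME, [0.0] + [c * 1e-9 for c in (5, 10, 20, 40, 60, 80, 100, 120)]
        )
        series = generate_titration(design)
        res = henderson_fit(series)
        assert res.n_used == 8
        assert res.ki == pytest.approx(KI_CSA, rel=1e-10)

    def test_raw_variant_biased_with_background(self, csa_design):
        # using raw k/k0 with a non-negligible uncatalysed background
        # distorts the estimate; the enzymatic-rate variant does not
        series = generate_titration(csa_design)
        raw = henderson_fit(series, variant="raw-rate")
        enz = henderson_fit(series, variant="enzymatic-rate")
        assert abs(raw.ki - KI_CSA) > abs(enz.ki - KI_CSA)

    def test_unknown_variant_rejected(self, csa_design):
        series = generate_titration(csa_design)
        with pytest.raises(ValueError, match="variant"):
            henderson_fit(series, variant="bogus")

    def test_noise_robustness_median_within_5pct(self, csa_design):
        # seeded: 2% Gaussian noise on rates, 500 replicate titrations
        from dataclasses import replace

        from ppikit.synth import NoiseSpec

        sd = 0.02 * (K_CAT - K_UNCAT)
        kis = []
        for seed in range(500):
            design = replace(csa_design, noise=NoiseSpec(sd_abs=sd, seed=seed))
            try:
                kis.append(henderson_fit(generate_titration(design)).ki)
            except ValueError:
                continue
        assert len(kis) > 450
        assert np.median(kis) == pytest.approx(KI_CSA, rel=0.05)


class TestPercentResidualActivity:
    def test_uninhibited(self):
        assert percent_residual_activity(K_CAT, K_CAT, K_UNCAT).percent == 100.0

    def test_fully_inhibited(self):
        # the complete-loss-at-saturating-CsA condition
        res = percent_residual_activity(K_UNCAT, K_CAT, K_UNCAT)
        assert res.percent == 0.0
        assert not res.clipped

    def test_twenty_percent(self):
        k = K_UNCAT + 0.2 * (K_CAT - K_UNCAT)
        assert percent_residual_activity(k, K_CAT, K_UNCAT).percent == pytest.approx(20.0)

    def test_clipping_flag(self):
        res = percent_residual_activity(K_CAT * 1.5, K_CAT, K_UNCAT)
        assert res.percent == 100.0
        assert res.clipped

    def test_bad_references_rejected(self):
        with pytest.raises(ValueError):
            percent_residual_activity(0.02, 0.015, 0.015)


class TestDoseResponseTable:
    def test_matches_morrison_fraction(self, csa_design):
        series = generate_titration(csa_design)
        table = dose_response_table(series)
        expected = 100.0 * np.array(
            [
                morrison_fraction(ENZYME, c, KI_CSA)
                for c in series.concentrations
            ]
        )
        np.testing.assert_allclose(table["percent_residual"].to_numpy(), expected, rtol=1e-9)

    def test_zero_conc_row_is_100(self):
        design = make_titration_design(
            KI_CSA, ENZYME, [0.0, 5e-9, 10e-9, 20e-9, 40e-9]
        )
        table = dose_response_table(generate_titration(design))
        assert table.loc[0, "percent_residual"] == pytest.approx(100.0)

    def test_equal_replicates_sd_zero(self, csa_design):
        table = dose_response_table(generate_titration(csa_design))
        assert np.allclose(table["sd"].to_numpy(), 0.0)

    def test_monotone_decreasing_residual(self, csa_design):
        table = dose_response_table(generate_titration(csa_design))
        assert np.all(np.diff(table["percent_residual"].to_numpy()) < 0)
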