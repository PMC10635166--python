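"""OER-modified LQ survival: closed forms, FLASH integral, aggregation."""

import warnings
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flashspheroid as fs

SP = fs.SurvivalParams()  # alpha0=beta0=0.44, m=2.6, K=1.9, kr=3e-2, a=8, b=200
TUMOR = fs.CellTypeParams(label="tumor", Sm=4.2, cp=0.8e-4, k_ROS=0.8e-3)


class TestOer:
    @pytest.mark.parametrize("p, expected", [
        (0.0, 1.0),                 # anoxic: no enhancement
        (1.9, (2.6 + 1) / 2),       # half-saturation point
        (1e9, 2.6),                 # saturates at m
    ])
    def test_values(self, p, expected):
        assert fs.oer(p, SP) == pytest.approx(expected, rel=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            fs.oer(-1.0, SP)

    @given(p=st.floats(min_value=0.0, max_value=1e4),
           dp=st.floats(min_value=1e-6, max_value=100.0))
    @settings(derandomize=True, max_examples=100)
    def test_monotone_increasing_in_range(self, p, dp):
        lo, hi = fs.oer(p, SP), fs.oer(p + dp, SP)
        assert 1.0 <= lo < hi < SP.m

    def test_inverted_orientation(self):
        spi = replace(SP, oer_inverted=True)
        assert fs.oer(0.0, spi) == pytest.approx(SP.m)
        assert fs.oer(1e9, spi) == pytest.approx(1.0, rel=1e-6)


class TestLqCoefficients:
    def test_anoxic(self):
        assert fs.lq_coefficients(0.0, SP) == pytest.approx((0.44, 0.44))

    def test_fully_oxygenated_limit(self):
        a, b = fs.lq_coefficients(1e12, SP)
        assert a == pytest.approx(0.44 * 2.6, rel=1e-9)
        assert b == pytest.approx(0.44 * 2.6**2, rel=1e-9)

    def test_beta_scales_with_oer_squared(self):
        o = fs.oer(10.0, SP)
        _, b = fs.lq_coefficients(10.0, SP)
        assert b / SP.beta0 == pytest.approx(o**2, rel=1e-12)


class TestConvSurvival:
    def test_zero_dose(self):
        assert fs.conv_log_survival(50.0, 0.0, SP) == 0.0

    def test_anoxic_10Gy(self):
        # alpha0*10 + beta0*100 with OER(0) = 1
        assert fs.conv_log_survival(0.0, 10.0, SP) == pytest.approx(-48.4)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            fs.conv_log_survival(50.0, -1.0, SP)


class TestFlashSurvival:
    def test_collapses_to_conv_without_depletion(self, fig1_profile):
        model = fs.ModelParams(S_ROD=0.0, dose=10.0, dose_rate=90.0)
        sp0 = replace(SP, kr=0.0)
        for r in (0.1, 0.3, 0.45):
            lf = fs.flash_log_survival(fig1_profile, r, model, TUMOR, sp0)
            lc = fs.conv_log_survival(float(fig1_profile.ps_at(r)), 10.0, sp0)
            assert lf == pytest.approx(lc, abs=1e-10)

    def test_matches_analytic_antiderivative(self, fig1_bundle, fig1_profile):
        model, _, _ = fig1_bundle  # S_ROD = 160
        for r in (0.05, 0.3, 0.4, 0.5):
            lf = fs.flash_log_survival(fig1_profile, r, model, TUMOR, SP,
                                       include_ros=False)
            la = fs.flash_log_survival_analytic(fig1_profile, r, model, SP)
            assert lf == pytest.approx(la, rel=1e-8)

    def test_sigmoid_relief_rate(self):
        # at ΔROS = 0 the relief is kr/(1+e^a) ≈ 1e-5/s — essentially off
        assert fs.ros_relief_rate(0.0, SP) == pytest.approx(
            SP.kr / (1 + np.exp(8.0)), rel=1e-12)
        assert fs.ros_relief_rate(0.0, SP) < 2e-5
        assert fs.ros_relief_rate(-1.0, SP) == pytest.approx(SP.kr, rel=1e-9)
        d = np.linspace(-0.1, 0.05, 50)
        assert np.all(np.diff(fs.ros_relief_rate(d, SP)) < 0)

    def test_ros_term_only_raises_survival(self, fig1_bundle, fig1_profile):
        model, cell, _ = fig1_bundle
        model = replace(model, S_ROD=15.3)
        for r in (0.3, 0.45):
            without = fs.flash_log_survival(fig1_profile, r, model, cell, SP,
                                            include_ros=False)
            with_ros = fs.flash_log_survival(fig1_profile, r, model, cell, SP,
                                             include_ros=True)
            assert with_ros >= without

    def test_zero_dose_window(self, fig1_profile):
        model = fs.ModelParams(S_ROD=160.0, dose=0.0, dose_rate=90.0)
        assert fs.flash_log_survival(fig1_profile, 0.4, model, TUMOR, SP) == 0.0

    def test_kill_integral_dose_rate_invariant_at_fixed_lrod(self, fig1_profile):
        # with S_ROD = L_ROD·Ḋ and T = D/Ḋ, substituting u = Ḋ·t shows the
        # depletion kill integral depends on dose only — without rediffusion,
        # oxygen lost per unit dose is rate-independent
        sp0 = replace(SP, kr=0.0)
        r = 0.45
        ref = None
        for rate in (90.0, 9.0, 0.9):
            model = fs.ModelParams(L_ROD=0.17, dose=10.0, dose_rate=rate)
            lf = fs.flash_log_survival(fig1_profile, r, model, TUMOR, sp0)
            ref = lf if ref is None else ref
            assert lf == pytest.approx(ref, rel=1e-10)

    def test_flash_converges_to_conv_as_srod_vanishes(self, fig1_profile):
        # the conventional limit is reached through S_ROD -> 0 at fixed rate
        sp0 = replace(SP, kr=0.0)
        r = 0.45
        lc = fs.conv_log_survival(float(fig1_profile.ps_at(r)), 10.0, sp0)
        gaps = []
        for srod in (160.0, 16.0, 1.6, 0.16):
            model = fs.ModelParams(S_ROD=srod, dose=10.0, dose_rate=90.0)
            lf = fs.flash_log_survival(fig1_profile, r, model, TUMOR, sp0)
            gaps.append(abs(lf - lc))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-3 * abs(lc)


class TestSpheroidSurvival:
    def test_zero_dose_full_survival(self, fig1_bundle):
        model, cell, sp = fig1_bundle
        res = fs.spheroid_survival(replace(model, dose=0.0), cell, sp, n_r=50)
        assert res.overall_sf_conv == pytest.approx(1.0)
        assert res.overall_sf_flash == pytest.approx(1.0)

    def test_pointwise_flash_sparing(self, fig1_bundle, fig1_profile):
        model, cell, sp = fig1_bundle
        res = fs.spheroid_survival(model, cell, replace(sp, kr=0.0),
                                   profile=fig1_profile, include_ros=False,
                                   n_r=100)
        assert np.all(res.log10_sf_flash >= res.log10_sf_conv - 1e-12)
        assert np.all(res.log10_sf_conv <= 0)
        assert 0 < res.overall_sf_conv <= 1

    def test_core_indistinguishable_when_kr_zero(self, fig1_bundle, fig1_profile):
        model, cell, sp = fig1_bundle
        res = fs.spheroid_survival(model, cell, replace(sp, kr=0.0),
                                   profile=fig1_profile, include_ros=False,
                                   n_r=200)
        core = res.r_grid < fig1_profile.r0
        assert core.any()
        np.testing.assert_allclose(res.log10_sf_flash[core],
                                   res.log10_sf_conv[core], atol=1e-12)

    def test_fully_anoxic_spheroid_equal_modes(self, flat_profile):
        prof = flat_profile(0.0)
        model = fs.ModelParams(S_ROD=160.0)
        res = fs.spheroid_survival(model, TUMOR, replace(SP, kr=0.0),
                                   profile=prof, include_ros=False, n_r=50)
        np.testing.assert_allclose(res.log10_sf_flash, res.log10_sf_conv,
                                   atol=1e-14)

    def test_flash_overall_never_below_conv_across_doses(self, fig1_bundle,
                                                         fig1_profile):
        model, cell, sp = fig1_bundle
        for dose in (5.0, 10.0, 15.0, 20.0):
            res = fs.spheroid_survival(replace(model, dose=dose), cell, sp,
                                       profile=fig1_profile, n_r=60)
            assert res.overall_sf_flash >= res.overall_sf_conv

    def test_csv_and_summary_export(self, fig1_bundle, fig1_profile, tmp_path):
        model, cell, sp = fig1_bundle
        res = fs.spheroid_survival(model, cell, sp, profile=fig1_profile,
                                   n_r=20)
        res.to_csv(tmp_path / "s.csv")
        res.summary_json(tmp_path / "s.json")
        assert (tmp_path / "s.csv").read_text().startswith("r_mm,")
        assert "overall_sf_flash" in (tmp_path / "s.json").read_text()


class TestDifferentialResponse:
    def test_healthy_cells_gain_more_from_flash(self):
        """The headline effect: at S_ROD = 15.3 mmHg/s and 10 Gy, healthy
        tissue keeps a larger FLASH/CONV survival ratio than tumor."""
        mt, tum, sp = fs.preset("table1-tumor")
        mh, hea, _ = fs.preset("table1-healthy")
        rt = fs.spheroid_survival(mt, tum, sp, n_r=100)
        rh = fs.spheroid_survival(mh, hea, sp, n_r=100)
        ratio_tumor = rt.overall_sf_flash / rt.overall_sf_conv
        ratio_healthy = rh.overall_sf_flash / rh.overall_sf_conv
        assert ratio_healthy > ratio_tumor > 1.0
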