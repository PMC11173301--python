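"""Stern-Volmer, segmented and Lehrer quenching analyses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fxrspec as fx
from fxrspec.errors import FitError, ValidationError


def _linear_titration(ksv=1e5, f0=1000.0, concs=None):
    return fx.gen_sv_titration(ksv, f0=f0, concs=concs, noise_cv=0.0)


class TestInnerFilter:
    def test_zero_absorbance_identity(self):
        tit = _linear_titration()
        np.testing.assert_array_equal(fx.inner_filter_correct(tit).F, tit.F)

    def test_analytic_correction_factor(self):
        tit = fx.QuenchTitration(
            ligand_conc=[0.0, 1e-6],
            F=[100.0, 100.0],
            A_ex=[0.0, 0.10],
            A_em=[0.0, 0.06],
        )
        corrected = fx.inner_filter_correct(tit)
        # 100 * 10**((0.10+0.06)/2) = 120.2264...
        assert corrected.F[1] == pytest.approx(120.2264435, abs=1e-4)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_monotone_in_total_absorbance(self, a1, a2):
        base = fx.QuenchTitration(
            ligand_conc=[0.0, 1e-6], F=[100.0, 100.0],
            A_ex=[0.0, min(a1, a2)], A_em=[0.0, 0.0],
        )
        more = fx.QuenchTitration(
            ligand_conc=[0.0, 1e-6], F=[100.0, 100.0],
            A_ex=[0.0, max(a1, a2)], A_em=[0.0, 0.0],
        )
        assert (
            fx.inner_filter_correct(more).F[1]
            >= fx.inner_filter_correct(base).F[1]
        )

    def test_double_correction_refused(self):
        tit = fx.inner_filter_correct(_linear_titration())
        with pytest.raises(ValidationError, match="already"):
            fx.inner_filter_correct(tit)

    def test_uniform_absorbance_scales_by_power_of_ten(self):
        n = 10
        tit = fx.QuenchTitration(
            ligand_conc=np.linspace(0, 9e-6, n),
            F=np.full(n, 50.0),
            A_ex=np.full(n, 0.3),
            A_em=np.full(n, 0.3),
        )
        np.testing.assert_allclose(
            fx.inner_filter_correct(tit).F, 50.0 * 10**0.3, rtol=1e-15
        )


class TestSternVolmer:
    def test_exact_linear_input(self):
        fit = fx.stern_volmer_fit(_linear_titration(ksv=1e5))
        assert fit.ksv == pytest.approx(1e5, rel=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_derived_rate_and_affinity(self):
        # measured low-range slope for the stronger quencher: 117,050 L/mol
        fit = fx.stern_volmer_fit(_linear_titration(ksv=117050.0))
        assert fit.kq == pytest.approx(2.34e13, rel=5e-3)
        assert fit.kd == pytest.approx(8.54e-6, rel=5e-4)

    def test_parameter_recovery_under_noise(self, recovery_seeds):
        truth = 131160.0
        estimates = [
            fx.stern_volmer_fit(
                fx.gen_sv_titration(truth, noise_cv=0.01, seed=int(s))
            ).ksv
            for s in recovery_seeds
        ]
        assert np.median(estimates) == pytest.approx(truth, rel=0.02)

    def test_identities_hold_to_machine_precision(self):
        for ksv in (1e4, 117050.0, 2e6):
            fit = fx.stern_volmer_fit(_linear_titration(ksv=ksv))
            assert fit.kd * fit.ksv == pytest.approx(1.0, rel=1e-15)
            assert fit.kq * 5e-9 == pytest.approx(fit.ksv, rel=1e-15)

    def test_invariant_under_uniform_rescaling(self):
        tit = fx.gen_sv_titration(117050.0, noise_cv=0.02, seed=11)
        scaled = tit.copy(F=tit.F * 37.5)
        assert fx.stern_volmer_fit(scaled).ksv == pytest.approx(
            fx.stern_volmer_fit(tit).ksv, rel=1e-12
        )

    def test_too_few_points_is_an_error(self):
        tit = fx.QuenchTitration(
            ligand_conc=[0.0, 1e-6, 2e-6], F=[100.0, 90.0, 80.0]
        )
        with pytest.raises(FitError):
            fx.stern_volmer_fit(tit)

    def test_missing_f0_is_an_error(self):
        tit = fx.QuenchTitration(
            ligand_conc=[1e-6, 2e-6, 3e-6, 4e-6], F=[90.0, 80.0, 72.0, 65.0]
        )
        with pytest.raises(ValidationError, match="F0"):
            fx.stern_volmer_fit(tit)

    def test_forced_unit_intercept(self):
        fit = fx.stern_volmer_fit(
            _linear_titration(ksv=1e5), force_unit_intercept=True
        )
        assert fit.intercept == 1.0
        assert fit.ksv == pytest.approx(1e5, rel=1e-9)


class TestSegmented:
    def test_purely_linear_data_flagged_unimodal(self):
        seg = fx.segmented_sv_fit(_linear_titration(ksv=1e5))
        assert seg.unimodal
        assert seg.breakpoint is None
        assert seg.low.ksv == pytest.approx(seg.high.ksv, rel=1e-12)
        assert seg.low.ksv == pytest.approx(1e5, rel=1e-6)

    def test_noisy_linear_data_rarely_reports_a_breakpoint(self, recovery_seeds):
        # the F-test gate runs at alpha=0.05 (Bonferroni over splits), so a
        # small fraction of false breakpoints on noisy linear data is the
        # expected price of the significance level
        flags = [
            fx.segmented_sv_fit(
                fx.gen_sv_titration(117050.0, noise_cv=0.02, seed=int(s))
            ).unimodal
            for s in recovery_seeds
        ]
        assert sum(flags) >= 85

    def test_piecewise_construction_recovered_to_4_sig_figs(self):
        # the two measured regime slopes joined at the 1 uM grid point
        q = fx.DEFAULT_CONC_GRID_M
        bp = 1e-6
        ratio = np.where(
            q <= bp, 1 + 117050.0 * q, 1 + 117050.0 * bp + 13780.0 * (q - bp)
        )
        tit = fx.QuenchTitration(
            ligand_conc=np.concatenate([[0.0], q]),
            F=np.concatenate([[1.0], 1.0 / ratio]) * 1000.0,
        )
        seg = fx.segmented_sv_fit(tit)
        assert not seg.unimodal
        assert seg.low.ksv == pytest.approx(117050.0, rel=1e-4)
        assert seg.high.ksv == pytest.approx(13780.0, rel=1e-4)
        assert seg.breakpoint == pytest.approx(1e-6, rel=1e-6)

    def test_breakpoint_respects_segment_ranges(self):
        tit = fx.gen_two_site_titration(fx.TwoSiteTruth(noise_cv=0.01, seed=7))
        seg = fx.segmented_sv_fit(tit)
        assert not seg.unimodal
        assert seg.low.conc_range[1] < seg.breakpoint <= seg.high.conc_range[0]
        assert seg.low.n_points >= 3 and seg.high.n_points >= 3

    def test_too_few_points_is_an_error(self):
        tit = _linear_titration(concs=np.array([1, 2, 3, 4, 5]) * 1e-6)
        with pytest.raises(FitError):
            fx.segmented_sv_fit(tit, min_points_per_segment=3)


class TestLehrer:
    def test_reduces_to_stern_volmer_at_full_accessibility(self):
        tit = fx.gen_lehrer_titration(
            fx.LehrerTruth(fa=1.0, ksv=117050.0, noise_cv=0.0)
        )
        lehrer = fx.lehrer_fit(tit)
        sv = fx.stern_volmer_fit(tit)
        assert lehrer.fa == pytest.approx(1.0, abs=1e-6)
        assert lehrer.ksv == pytest.approx(sv.ksv, rel=1e-6)

    def test_closed_form_point(self):
        # fa=0.44, [Q] = 1/Ksv: F0/(F0-F) = 2/fa so F/F0 = 1 - fa/2 = 0.78
        truth = fx.LehrerTruth(fa=0.44, ksv=117050.0, noise_cv=0.0)
        tit = fx.gen_lehrer_titration(
            truth, concs=np.array([0.5, 1.0, 2.0, 4.0]) / truth.ksv
        )
        q_index = 2  # 1/Ksv is the second nonzero concentration
        assert tit.F[q_index] / tit.F0 == pytest.approx(0.78, abs=1e-12)
        fit = fx.lehrer_fit(tit)
        assert fit.fa == pytest.approx(0.44, abs=1e-6)
        assert fit.ksv == pytest.approx(117050.0, rel=1e-6)

    def test_direct_and_linearized_agree_noiseless(self):
        tit = fx.gen_lehrer_titration(fx.LehrerTruth(noise_cv=0.0))
        direct = fx.lehrer_fit(tit, method="direct")
        linearized = fx.lehrer_fit(tit, method="linearized")
        assert direct.fa == pytest.approx(linearized.fa, rel=1e-6)
        assert direct.ksv == pytest.approx(linearized.ksv, rel=1e-6)

    def test_recovery_under_noise(self, recovery_seeds):
        truth = fx.LehrerTruth(fa=0.44, ksv=117050.0, noise_cv=0.01)
        estimates = [
            fx.lehrer_fit(fx.gen_lehrer_titration(truth, seed=int(s))).fa
            for s in recovery_seeds
        ]
        assert abs(np.median(estimates) - 0.44) <= 0.05

    def test_unquenched_points_excluded_with_warning(self):
        tit = fx.QuenchTitration(
            ligand_conc=np.array([0, 1, 2, 4, 8, 16, 32]) * 1e-6,
            F=np.array([100.0, 101.0, 92.0, 85.0, 75.0, 64.0, 55.0]),
        )
        with pytest.warns(UserWarning, match="excluded 1"):
            fit = fx.lehrer_fit(tit)
        assert 0 < fit.fa <= 1

    def test_all_points_unquenched_is_an_error(self):
        tit = fx.QuenchTitration(
            ligand_conc=np.array([0, 1, 2, 4, 8]) * 1e-6,
            F=np.array([100.0, 100.5, 101.0, 102.0, 103.0]),
        )
        with pytest.raises(FitError), pytest.warns(UserWarning):
            fx.lehrer_fit(tit)


class TestMechanismAndAffinity:
    @pytest.mark.parametrize("ksv", [117050.0, 131160.0, 13780.0, 24690.0])
    def test_measured_constants_classify_static(self, ksv):
        assert fx.mechanism_call(ksv, 5e-9).call == "static"

    def test_slow_quencher_leaves_dynamic_open(self):
        call = fx.mechanism_call(10.0, 5e-9)
        assert call.kq == pytest.approx(2e9)
        assert call.call == "dynamic-possible"

    def test_threshold_boundary_is_strict(self):
        # Kq exactly at the diffusion limit does not qualify as static
        assert fx.mechanism_call(1e10, 1.0, threshold=1e10).call == "dynamic-possible"

    @pytest.mark.parametrize(
    "ksv, kd_uM",
        [(117050.0, 8.543), (24690.0, 40.50), (1e6, 1.0)],
    )
    def test_reciprocal_dissociation_constant(self, ksv, kd_uM):
        assert fx.dissociation_constant(ksv) * 1e6 == pytest.approx(kd_uM, rel=1e-3)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fx.dissociation_constant(0.0)
        with pytest.raises(ValidationError):
            fx.mechanism_call(-5.0, 5e-9)
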