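"""CD secondary-structure unmixing and thermal-unfolding fits."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fxrspec as fx
from fxrspec.cdtherm import two_state_signal
from fxrspec.errors import UnitsError, ValidationError


def _mre_spectrum(basis, fractions, scale=1.0):
    y = scale * basis.matrix(basis.wavelength) @ np.asarray(fractions)
    return fx.CDSpectrum(
        x=basis.wavelength, y=y, units="MRE", conc=0.147, path=0.2
    )


class TestSecondaryStructure:
    def test_pure_helix_identity(self, basis):
        result = fx.estimate_secondary_structure(
            _mre_spectrum(basis, [1.0, 0.0, 0.0]), basis
        )
        assert result.f_helix == pytest.approx(1.0, abs=1e-9)
        assert result.residual == pytest.approx(0.0, abs=1e-6)

    def test_constructed_mixture_recovered_exactly(self, basis):
        # apo-like composition: 59% helix
        result = fx.estimate_secondary_structure(
            _mre_spectrum(basis, [0.59, 0.20, 0.21]), basis
        )
        np.testing.assert_allclose(
            result.as_array(), [0.59, 0.20, 0.21], atol=1e-6
        )

    @given(
        a=st.floats(0.0, 1.0),
        b=st.floats(0.0, 1.0),
        scale=st.floats(-2.0, 2.0),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_fractions_always_on_simplex(self, basis, a, b, scale, seed):
        # arbitrary (even unphysical) spectra must still yield a simplex point
        rng = np.random.default_rng(seed)
        y = scale * 1e4 * rng.normal(size=basis.wavelength.size) + a * 1e4 - b * 1e4
        spec = fx.CDSpectrum(
            x=basis.wavelength, y=y, units="MRE", conc=0.147, path=0.2
        )
        result = fx.estimate_secondary_structure(spec, basis)
        fractions = result.as_array()
        assert np.all(fractions >= 0) and np.all(fractions <= 1)
        assert fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_scale_sensitivity_shows_in_residual_not_fractions_sum(self, basis):
        spec = _mre_spectrum(basis, [0.59, 0.20, 0.21])
        doubled = spec.copy(y=2 * spec.y)
        r1 = fx.estimate_secondary_structure(spec, basis)
        r2 = fx.estimate_secondary_structure(doubled, basis)
        assert r2.residual > r1.residual + 1.0   # misfit absorbed by residual
        assert r2.as_array().sum() == pytest.approx(1.0, abs=1e-9)

    def test_mdeg_input_refused(self, basis):
        cd = fx.gen_cd_spectrum(fx.CDTruth(noise_sd=0.0))
        with pytest.raises(UnitsError):
            fx.estimate_secondary_structure(cd, basis)

    def test_grid_coverage_gap_is_an_error(self, basis):
        spec = fx.CDSpectrum(
            x=[190.0, 200.0, 210.0], y=[0.0, 0.0, 0.0], units="MRE",
            conc=0.147, path=0.2,
        )
        with pytest.raises(ValidationError, match="covered"):
            fx.estimate_secondary_structure(spec, basis)

    def test_noisy_recovery_of_bound_state_helix(self, recovery_seeds, basis):
        clean = fx.gen_cd_spectrum(
            fx.CDTruth(fractions=(0.68, 0.16, 0.16), noise_sd=0.0)
        )
        span = float(clean.y.max() - clean.y.min())
        estimates = []
        for seed in recovery_seeds[:50]:
            cd = fx.gen_cd_spectrum(
                fx.CDTruth(fractions=(0.68, 0.16, 0.16), noise_sd=0.02 * span),
                seed=int(seed),
            )
            estimates.append(
                fx.estimate_secondary_structure(fx.mdeg_to_mre(cd), basis).f_helix
            )
        assert abs(np.median(estimates) - 0.68) <= 0.03


class TestMeltFit:
    def test_noiseless_recovery_across_parameter_grid(self):
        for tm in (45.0, 50.0, 55.0, 60.0):
            for dh in (1.5e5, 3.0e5, 5.0e5):
                melt = fx.gen_melt(fx.MeltTruth(tm_C=tm, dh_app=dh, noise_cv=0.0))
                fit = fx.fit_melt_two_state(melt)
                assert not fit.no_transition
                assert fit.tm_C == pytest.approx(tm, abs=0.01)

    def test_signal_at_midpoint_is_baseline_average(self):
        # flat baselines 0 and 1; Tm on a grid point
        melt = fx.gen_melt(fx.MeltTruth(tm_C=51.0, noise_cv=0.0))
        idx = int(np.argmin(np.abs(melt.temperature - 51.0)))
        assert melt.signal[idx] == pytest.approx(0.5, abs=1e-12)

    def test_noisy_recovery_of_ligand_bound_midpoint(self, recovery_seeds):
        truth = fx.MeltTruth(tm_C=53.84, noise_cv=0.02)
        estimates = []
        for seed in recovery_seeds:
            fit = fx.fit_melt_two_state(fx.gen_melt(truth, seed=int(seed)))
            if not fit.no_transition:
                estimates.append(fit.tm_C)
        assert len(estimates) >= 95
        assert abs(np.median(estimates) - 53.84) <= 0.5

    def test_flat_signal_flags_no_transition(self):
        melt = fx.MeltCurve(
            temperature=np.arange(15.0, 73.0, 3.0), signal=np.full(20, 0.7)
        )
        fit = fx.fit_melt_two_state(melt)
        assert fit.no_transition
        assert np.isnan(fit.tm_C)

    def test_sloped_baselines_recovered(self):
        truth = fx.MeltTruth(
            tm_C=52.0,
            native_baseline=(-8000.0, 12.0),
            unfolded_baseline=(-2000.0, 5.0),
            noise_cv=0.0,
        )
        fit = fx.fit_melt_two_state(fx.gen_melt(truth))
        assert fit.tm_C == pytest.approx(52.0, abs=0.01)
        assert fit.native_baseline[1] == pytest.approx(12.0, rel=0.05)


class TestDerivativeTm:
    def test_symmetric_sigmoid_center_recovered(self):
        melt = fx.gen_melt(fx.MeltTruth(tm_C=53.84, noise_cv=0.0))
        assert fx.tm_by_derivative(melt) == pytest.approx(53.84, abs=0.5)

    def test_agrees_with_two_state_fit_on_noiseless_curves(self):
        for tm in (45.7, 50.2, 53.84, 58.9):
            melt = fx.gen_melt(fx.MeltTruth(tm_C=tm, noise_cv=0.0))
            fit = fx.fit_melt_two_state(melt)
            assert abs(fx.tm_by_derivative(melt) - fit.tm_C) <= 0.5

    def test_monotone_linear_signal_has_no_transition(self):
        temps = np.arange(15.0, 73.0, 3.0)
        melt = fx.MeltCurve(temperature=temps, signal=0.01 * temps + 0.3)
        assert fx.tm_by_derivative(melt) is None

    def test_flat_signal_has_no_transition(self):
        temps = np.arange(15.0, 73.0, 3.0)
        melt = fx.MeltCurve(temperature=temps, signal=np.full(temps.size, 1.0))
        assert fx.tm_by_derivative(melt) is None


class TestDeltaTm:
    def _fit(self, tm, wavelength=210.0):
        truth = fx.MeltTruth(tm_C=tm, noise_cv=0.0, wavelength=wavelength)
        return fx.fit_melt_two_state(fx.gen_melt(truth))

    def test_stabilizing_shift(self):
        # bound-state midpoints at 225 nm: 55.25 vs apo 52.54
        shift = fx.delta_tm(self._fit(52.54, 225.0), self._fit(55.25, 225.0))
        assert shift == pytest.approx(2.71, abs=0.02)

    def test_destabilizing_shift(self):
        shift = fx.delta_tm(self._fit(51.18, 210.0), self._fit(49.81, 210.0))
        assert shift == pytest.approx(-1.37, abs=0.02)

    def test_identity(self):
        fit = self._fit(51.18)
        assert fx.delta_tm(fit, fit) == 0.0

    def test_wavelength_mismatch_is_an_error(self):
        with pytest.raises(ValidationError, match="wavelength"):
            fx.delta_tm(self._fit(51.18, 210.0), self._fit(55.25, 225.0))


def test_two_state_signal_midpoint_equals_half_occupancy():
    # K(Tm) == 1 regardless of dH, so S(Tm) is the baseline midpoint
    for dh in (1e5, 3e5, 6e5):
        assert two_state_signal(np.array([50.0]), 50.0, dh, 0, 0, 1, 0)[
            0
        ] == pytest.approx(0.5, abs=1e-12)
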