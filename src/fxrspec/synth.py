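"""Seeded generators for synthetic titrations, spectra and melting curves.

Each generator is the documented inverse of one analysis operation, so that
noiseless generation followed by analysis recovers the generating parameters
to numerical precision; the noisy versions provide ground truth for the
recovery experiments.  Defaults emulate the study conditions: 1 uM protein
titrated with ligand from 0.1 to 40 uM, tryptophan emission excited at
280 nm and read at 345 nm, synchronous scans at delta-lambda 60 nm, CD in a
0.2 cm cell at 5 uM protein, melts from 15 to 72 degC in 3-degree steps.

Noise model: multiplicative Gaussian (a coefficient of variation) for
fluorescence and melt signals, additive Gaussian in mdeg for CD spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdtherm import BasisSet, two_state_signal
from .errors import ValidationError
from .spectra import mre_to_mdeg
from .types import CDSpectrum, MeltCurve, QuenchTitration, Spectrum

#: Ligand concentration grid used in the titrations (mol/L): 0.1-40 uM.
DEFAULT_CONC_GRID_M = np.array([0.1, 0.3, 0.5, 1, 3, 5, 10, 20, 40]) * 1e-6

#: Melt temperature grid: 15-72 degC in 3-degree steps (20 points).
DEFAULT_MELT_GRID_C = np.arange(15.0, 73.0, 3.0)

#: CD protein load for the default cell: ~5 uM of a ~29 kDa domain, g/L.
DEFAULT_CD_CONC_G_L = 0.147
DEFAULT_CD_PATH_CM = 0.2

_EMISSION_GRID = np.arange(300.0, 401.0, 1.0)
_SYNCHRONOUS_GRID = np.arange(260.0, 321.0, 1.0)
# Gaussian band parameters (center nm, sigma nm) for the two fluorophores
_TRP_EMISSION = (345.0, 22.0)
_TYR_EMISSION = (303.0, 14.0)
_TRP_SYNCHRONOUS = (285.0, 8.0)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _mult_noise(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    if cv < 0:
        raise ValidationError("noise_cv must be non-negative")
    if cv == 0:
        return np.ones(shape)
    return 1.0 + rng.normal(0.0, cv, size=shape)


def _check_concs(concs: np.ndarray) -> np.ndarray:
    concs = np.asarray(concs, dtype=float)
    if np.any(concs <= 0) or not np.all(np.diff(concs) > 0):
        raise ValidationError("concs must be positive and strictly increasing")
    return concs


# ---------------------------------------------------------------------------
# ground-truth parameter bundles
# ---------------------------------------------------------------------------

@dataclass
class TwoSiteTruth:
    """Two independent binding sites: a tight site read out through the
    exact (tight-binding) occupancy quadratic and a weak site in the
    free-ligand regime.  Per-site quenching is multiplicative with
    efficiencies q1 and q2 (plausible placeholders; the real per-residue
    efficiencies of the two tryptophans are unknown)."""

    protein_conc: float = 1e-6
    kd1: float = 50e-9
    q1: float = 0.45
    kd2: float = 40e-6
    q2: float = 0.5
    F0: float = 1000.0
    noise_cv: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.kd1 < self.kd2:
            raise ValidationError("site 1 must be tighter than site 2 (kd1 < kd2)")
        for name in ("q1", "q2"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.F0 <= 0 or self.protein_conc <= 0:
            raise ValidationError("F0 and protein_conc must be positive")


@dataclass
class LehrerTruth:
    """Accessible-fraction quenching model parameters."""

    fa: float = 0.44
    ksv: float = 117050.0
    F0: float = 1000.0
    noise_cv: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fa <= 1:
            raise ValidationError("fa must lie in (0, 1]")
        if self.ksv <= 0 or self.F0 <= 0:
            raise ValidationError("ksv and F0 must be positive")


@dataclass
class CDTruth:
    """Secondary-structure composition for a synthetic CD spectrum."""

    fractions: tuple[float, float, float] = (0.59, 0.20, 0.21)
    scale: float = 1.0
    noise_sd: float = 0.2       # additive, mdeg
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size != 3 or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValidationError("fractions must be a 3-simplex point")
        if self.scale <= 0 or self.noise_sd < 0:
            raise ValidationError("scale must be positive and noise_sd >= 0")


@dataclass
class MeltTruth:
    """Two-state unfolding parameters for a synthetic melting curve."""

    tm_C: float = 51.18
    dh_app: float = 3.0e5       # J/mol
    native_baseline: tuple[float, float] = (0.0, 0.0)
    unfolded_baseline: tuple[float, float] = (1.0, 0.0)
    noise_cv: float = 0.01
    seed: int | None = None
    wavelength: float = 210.0

    def __post_init__(self) -> None:
        if self.dh_app <= 0:
            raise ValidationError("dh_app must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be non-negative")


# ---------------------------------------------------------------------------
# occupancy math
# ---------------------------------------------------------------------------

def tight_binding_occupancy(protein: float, ligand: float, kd: float) -> float:
    """Fraction of protein bound from the exact 1:1 mass-balance quadratic.

    theta = [(P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)] / (2 P), valid in
    the tight-binding regime where ligand depletion matters.
    """
    if protein <= 0 or kd < 0 or ligand < 0:
        raise ValidationError("protein > 0, ligand >= 0 and kd >= 0 required")
    s = protein + ligand + kd
    disc = s * s - 4.0 * protein * ligand
    assert disc >= -1e-30, "mass-balance discriminant must be non-negative"
    # conjugate form of (s - sqrt(disc)) / (2 P): avoids the catastrophic
    # cancellation of the textbook expression when bound << total
    return 2.0 * ligand / (s + np.sqrt(max(disc, 0.0)))


# ---------------------------------------------------------------------------
# titration generators
# ---------------------------------------------------------------------------

def _assemble_titration(
    concs: np.ndarray,
    f_over_f0: np.ndarray,
    f0: float,
    noise_cv: float,
    seed,
    protein_conc: float = 1e-6,
) -> QuenchTitration:
    rng = _rng(seed)
    full_conc = np.concatenate([[0.0], concs])
    full_ratio = np.concatenate([[1.0], f_over_f0])
    f = f0 * full_ratio * _mult_noise(rng, full_conc.shape, noise_cv)
    return QuenchTitration(
        ligand_conc=full_conc, F=f, protein_conc=protein_conc
    )


def gen_sv_titration(
    ksv: float,
    f0: float = 1000.0,
    concs=None,
    noise_cv: float = 0.0,
    seed=None,
    protein_conc: float = 1e-6,
) -> QuenchTitration:
    """Ideal static-quenching titration: F = F0 / (1 + Ksv [Q])."""
    if ksv <= 0 or f0 <= 0:
        raise ValidationError("ksv and f0 must be positive")
    concs = _check_concs(DEFAULT_CONC_GRID_M if concs is None else concs)
    ratio = 1.0 / (1.0 + ksv * concs)
    return _assemble_titration(concs, ratio, f0, noise_cv, seed, protein_conc)


def gen_two_site_titration(
    truth: TwoSiteTruth, concs=None, seed=None
) -> QuenchTitration:
    """Two-site quenching titration.

    Site-1 occupancy comes from the exact tight-binding quadratic; the
    remaining free ligand (floored at zero) populates site 2 through the
    simple isotherm theta2 = L_free/(L_free + Kd2).  The two quenching
    contributions multiply: F = F0 (1 - q1 theta1)(1 - q2 theta2).
    """
    concs = _check_concs(DEFAULT_CONC_GRID_M if concs is None else concs)
    p = truth.protein_conc
    theta1 = np.array([tight_binding_occupancy(p, L, truth.kd1) for L in concs])
    l_free = np.maximum(concs - theta1 * p, 0.0)
    theta2 = l_free / (l_free + truth.kd2)
    ratio = (1.0 - truth.q1 * theta1) * (1.0 - truth.q2 * theta2)
    return _assemble_titration(
        concs,
        ratio,
        truth.F0,
        truth.noise_cv,
        truth.seed if seed is None else seed,
        protein_conc=p,
    )


def gen_lehrer_titration(
    truth: LehrerTruth, concs=None, seed=None
) -> QuenchTitration:
    """Accessible-fraction titration: F = F0 (1 - fa Ksv [Q]/(1 + Ksv [Q]))."""
    concs = _check_concs(DEFAULT_CONC_GRID_M if concs is None else concs)
    ratio = 1.0 - truth.fa * truth.ksv * concs / (1.0 + truth.ksv * concs)
    return _assemble_titration(
        concs,
        ratio,
        truth.F0,
        truth.noise_cv,
        truth.seed if seed is None else seed,
    )


# ---------------------------------------------------------------------------
# CD and melt generators
# ---------------------------------------------------------------------------

def gen_cd_spectrum(
    truth: CDTruth,
    basis: BasisSet | None = None,
    seed=None,
    conc_g_l: float = DEFAULT_CD_CONC_G_L,
    path_cm: float = DEFAULT_CD_PATH_CM,
) -> CDSpectrum:
    """Synthetic far-UV CD spectrum in raw mdeg units.

    The MRE mixture ``scale * (f . basis)`` is converted back to mdeg with
    the stated concentration and path length, then additive mdeg noise is
    applied, so an analysis pipeline must run the mdeg-to-MRE conversion
    before unmixing (exercising the full chain).
    """
    basis = basis if basis is not None else BasisSet.default()
    rng = _rng(truth.seed if seed is None else seed)
    f = np.asarray(truth.fractions, dtype=float)
    mre = truth.scale * basis.matrix(basis.wavelength) @ f
    clean = CDSpectrum(
        x=basis.wavelength,
        y=mre,
        units="MRE",
        conc=conc_g_l,
        path=path_cm,
    )
    noisy = mre_to_mdeg(clean)
    if truth.noise_sd > 0:
        noisy.y = noisy.y + rng.normal(0.0, truth.noise_sd, size=noisy.y.shape)
    return noisy


def gen_melt(truth: MeltTruth, temps=None, seed=None) -> MeltCurve:
    """Synthetic two-state melting curve with multiplicative noise."""
    temps = np.asarray(
        DEFAULT_MELT_GRID_C if temps is None else temps, dtype=float
    )
    if not (temps[0] <= truth.tm_C <= temps[-1]):
        raise ValidationError(
            f"tm_C={truth.tm_C} lies outside the temperature grid "
            f"[{temps[0]}, {temps[-1]}]"
        )
    rng = _rng(truth.seed if seed is None else seed)
    signal = two_state_signal(
        temps,
        truth.tm_C,
        truth.dh_app,
        *truth.native_baseline,
        *truth.unfolded_baseline,
    )
    signal = signal * _mult_noise(rng, signal.shape, truth.noise_cv)
    return MeltCurve(temperature=temps, signal=signal, wavelength=truth.wavelength)


# ---------------------------------------------------------------------------
# band-model spectra
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


def gen_emission_spectrum(
    trp_amp: float,
    tyr_amp: float = 0.0,
    seed=None,
    synchronous: bool = False,
    noise_cv: float = 0.0,
) -> Spectrum:
    """Two-band tryptophan + tyrosine emission spectrum.

    Emission mode: Gaussian bands at 345 nm (Trp) and 303 nm (Tyr) on the
    300-400 nm grid.  Synchronous mode emulates the delta-lambda = 60 nm
    scan, which selects the tryptophan signal only: a single band on the
    260-320 nm grid whose amplitude tracks ``trp_amp``.
    """
    if trp_amp < 0 or tyr_amp < 0:
        raise ValidationError("band amplitudes must be non-negative")
    rng = _rng(seed)
    if synchronous:
        x = _SYNCHRONOUS_GRID
        y = trp_amp * _gauss(x, *_TRP_SYNCHRONOUS)
        kind = "synchronous"
    else:
        x = _EMISSION_GRID
        y = trp_amp * _gauss(x, *_TRP_EMISSION) + tyr_amp * _gauss(
            x, *_TYR_EMISSION
        )
        kind = "emission"
    y = y * _mult_noise(rng, y.shape, noise_cv)
    return Spectrum(x=x.copy(), y=y, kind=kind, meta={"delta_lambda_nm": 60.0}
                    if synchronous else {"excitation_nm": 280.0})
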