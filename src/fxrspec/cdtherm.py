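"""Circular-dichroism structure analysis and thermal unfolding.

Secondary-structure content is estimated by unmixing a far-UV MRE spectrum
(200-240 nm) onto a fixed three-component reference basis (helix, sheet,
coil) under non-negativity and sum-to-one constraints.  With only three
components the constrained least-squares problem is solved exactly by
enumerating the seven possible support sets and solving the
equality-constrained normal equations on each.

Thermal unfolding is modelled as an apparent two-state transition

    S(T) = [N(T) + U(T) K(T)] / [1 + K(T)],
    K(T) = exp[-(dH_app/R) (1/T - 1/Tm)]    (T in kelvin),

with linear native and unfolded baselines N and U.  dH_app is a nuisance
steepness parameter; because the unfolding of this protein is irreversible,
Tm is reported as an apparent midpoint and dH_app is never interpreted
thermodynamically.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import FitError, UnitsError, ValidationError
from .spectra import mdeg_to_mre  # noqa: F401  (re-exported convenience)
from .types import CDSpectrum, MeltCurve

R_GAS = 8.31446261815324  # J mol^-1 K^-1
_T0K = 273.15

STRUCTURE_COMPONENTS = ("helix", "sheet", "coil")


# ---------------------------------------------------------------------------
# reference basis
# ---------------------------------------------------------------------------

@dataclass
class BasisSet:
    """Reference MRE curves for helix, sheet and coil on a shared grid."""

    wavelength: np.ndarray
    helix: np.ndarray
    sheet: np.ndarray
    coil: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        for name in STRUCTURE_COMPONENTS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.wavelength.shape:
                raise ValidationError(f"basis component {name!r} grid mismatch")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"basis component {name!r} is not finite")
            setattr(self, name, arr)
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValidationError("basis wavelengths must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "BasisSet":
        """Load a ``wavelength_nm,helix,sheet,coil`` CSV with '#' comments."""
        text = Path(path).read_text(encoding="utf-8")
        provenance = " ".join(
            line.lstrip("#").strip()
            for line in text.splitlines()
            if line.startswith("#")
        )
        frame = pd.read_csv(path, comment="#")
        return cls(
            wavelength=frame["wavelength_nm"].to_numpy(),
            helix=frame["helix"].to_numpy(),
            sheet=frame["sheet"].to_numpy(),
            coil=frame["coil"].to_numpy(),
            provenance=provenance,
        )

    @classmethod
    def default(cls) -> "BasisSet":
        """The packaged synthetic three-component basis (200-240 nm, 0.5 nm)."""
        with resources.as_file(
            resources.files("fxrspec").joinpath("data/cd_basis_v1.csv")
        ) as path:
            return cls.from_csv(path)

    def matrix(self, grid: np.ndarray) -> np.ndarray:
        """Basis curves interpolated onto ``grid`` as a (len(grid), 3) matrix."""
        grid = np.asarray(grid, dtype=float)
        if grid[0] < self.wavelength[0] or grid[-1] > self.wavelength[-1]:
            raise ValidationError(
                f"requested grid [{grid[0]}, {grid[-1]}] nm not covered by basis "
                f"[{self.wavelength[0]}, {self.wavelength[-1]}] nm"
            )
        return np.column_stack(
            [
                np.interp(grid, self.wavelength, getattr(self, name))
                for name in STRUCTURE_COMPONENTS
            ]
        )


@dataclass
class StructureFractions:
    """Helix/sheet/coil fractions (non-negative, summing to one)."""

    f_helix: float
    f_sheet: float
    f_coil: float
    residual: float
    method: str = "constrained-ls"

    def as_array(self) -> np.ndarray:
        return np.array([self.f_helix, self.f_sheet, self.f_coil])

    def to_dict(self) -> dict[str, Any]:
        return {
            "f_helix": self.f_helix,
            "f_sheet": self.f_sheet,
            "f_coil": self.f_coil,
            "residual": self.residual,
            "method": self.method,
        }


def _simplex_lstsq(A: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact min ||A f - y|| s.t. f >= 0, sum f = 1, for small column counts.

    Enumerates support subsets; on each, solves the equality-constrained
    normal equations via a bordered KKT system and keeps the best feasible
    solution.
    """
    p = A.shape[1]
    best_f, best_rss = None, np.inf
    for size in range(1, p + 1):
        for support in combinations(range(p), size):
            As = A[:, support]
            k = len(support)
            kkt = np.zeros((k + 1, k + 1))
            kkt[:k, :k] = As.T @ As
            kkt[:k, k] = 1.0
            kkt[k, :k] = 1.0
            rhs = np.concatenate([As.T @ y, [1.0]])
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            fs = sol[:k]
            if np.any(fs < -1e-10):
                continue
            resid = y - As @ fs
            rss = float(resid @ resid)
            if best_f is None or rss < best_rss - 1e-12 * max(1.0, best_rss):
                f = np.zeros(p)
                f[list(support)] = fs
                best_f, best_rss = f, rss
    assert best_f is not None  # singletons are always feasible
    best_f = np.clip(best_f, 0.0, None)
    best_f /= best_f.sum()
    return best_f, best_rss


class SecondaryStructureEstimator(TransformerMixin, BaseEstimator):
    """Constrained unmixing of MRE spectra onto a helix/sheet/coil basis.

    Parameters
    ----------
    basis : BasisSet or None
        Reference curves; ``None`` loads the packaged default basis.
    wavelengths : array-like or None
        The wavelength grid of the feature columns of ``X``.  ``None`` means
        the basis grid itself.

    The transform maps each row of ``X`` (an MRE spectrum sampled on
    ``wavelengths``) to its (f_helix, f_sheet, f_coil) coordinates.  The
    estimator is deliberately scale-sensitive: spectra are not normalized,
    so a doubled spectrum changes the residual, not the constraint.
    """

    def __init__(self, basis: BasisSet | None = None, wavelengths=None):
        self.basis = basis
        self.wavelengths = wavelengths

    def fit(self, X=None, y=None):
        basis = self.basis if self.basis is not None else BasisSet.default()
        grid = (
            np.asarray(self.wavelengths, dtype=float)
            if self.wavelengths is not None
            else basis.wavelength
        )
        self.grid_ = grid
        self.basis_matrix_ = basis.matrix(grid)
        self.n_features_in_ = grid.size
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "basis_matrix_")
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValidationError(
                f"X has {X.shape[1]} wavelengths, estimator expects "
                f"{self.n_features_in_}"
            )
        return np.vstack([_simplex_lstsq(self.basis_matrix_, row)[0] for row in X])

    def unmix(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Like :meth:`transform` but also returns per-row residual norms."""
        check_is_fitted(self, "basis_matrix_")
        X = check_array(X, ensure_2d=True, dtype=float)
        fracs, resids = [], []
        for row in X:
            f, rss = _simplex_lstsq(self.basis_matrix_, row)
            fracs.append(f)
            resids.append(np.sqrt(rss))
        return np.vstack(fracs), np.asarray(resids)


def estimate_secondary_structure(
    spectrum: CDSpectrum, basis: BasisSet | None = None
) -> StructureFractions:
    """Estimate helix/sheet/coil fractions from an MRE spectrum."""
    if spectrum.units != "MRE":
        raise UnitsError(
            "spectrum must be in MRE units; apply mdeg_to_mre first"
        )
    est = SecondaryStructureEstimator(basis=basis, wavelengths=spectrum.x).fit()
    fractions, residuals = est.unmix(spectrum.y[None, :])
    return StructureFractions(
        f_helix=float(fractions[0, 0]),
        f_sheet=float(fractions[0, 1]),
        f_coil=float(fractions[0, 2]),
        residual=float(residuals[0]),
    )


# ---------------------------------------------------------------------------
# thermal unfolding
# ---------------------------------------------------------------------------

@dataclass
class MeltFit:
    """Apparent two-state unfolding fit."""

    tm_C: float
    dh_app: float                       # J/mol, apparent van 't Hoff
    native_baseline: tuple[float, float]    # intercept, slope (per degC)
    unfolded_baseline: tuple[float, float]
    se_tm: float
    method: str = "two-state"
    no_transition: bool = False
    wavelength: float = 210.0
    rss: float = float("nan")

    def to_dict(self) -> dict[str, Any]:
        return {
            "tm_C": self.tm_C,
            "se_tm": self.se_tm,
            "dh_app_J_mol": self.dh_app,
            "native_baseline": list(self.native_baseline),
            "unfolded_baseline": list(self.unfolded_baseline),
            "method": self.method,
            "no_transition": self.no_transition,
            "wavelength_nm": self.wavelength,
            "rss": self.rss,
        }


def two_state_signal(
    temp_C: np.ndarray,
    tm_C: float,
    dh_app: float,
    n0: float,
    n1: float,
    u0: float,
    u1: float,
) -> np.ndarray:
    """Two-state melt signal with linear baselines (temperatures in degC)."""
    t = np.asarray(temp_C, dtype=float)
    tk = t + _T0K
    k = np.exp(-(dh_app / R_GAS) * (1.0 / tk - 1.0 / (tm_C + _T0K)))
    native = n0 + n1 * t
    unfolded = u0 + u1 * t
    return (native + unfolded * k) / (1.0 + k)


class TwoStateMeltModel(BaseEstimator):
    """Nonlinear two-state melt fit following the scikit-learn protocol.

    ``fit(X, y)`` takes the temperature column (degC) and the CD signal;
    fitted attributes are ``tm_``, ``dh_app_``, ``native_baseline_``,
    ``unfolded_baseline_``, ``se_tm_``, ``rss_`` and ``no_transition_``.
    Initialization is deterministic: Tm from the derivative extremum,
    baselines from OLS on the first and last three points.
    """

    def __init__(self, dh_init: float = 3.0e5, max_nfev: int = 40000):
        self.dh_init = dh_init
        self.max_nfev = max_nfev

    def fit(self, X, y):
        X = check_array(X, ensure_2d=True, dtype=float)
        if X.shape[1] != 1:
            raise ValidationError("X must be a single temperature column")
        t = X[:, 0]
        y = np.asarray(y, dtype=float).ravel()
        if y.size != t.size:
            raise ValidationError("X and y length mismatch")
        if t.size < 8:
            raise FitError("melt fit needs at least 8 points")

        self.n_features_in_ = 1
        tm0 = _derivative_tm(t, y, smooth_halfwidth=1)
        if tm0 is None:
            self._flag_no_transition(t)
            return self

        def _edge_line(idx: np.ndarray) -> tuple[float, float]:
            coeff = np.polyfit(t[idx], y[idx], 1)
            return float(coeff[1]), float(coeff[0])

        n0, n1 = _edge_line(np.arange(3))
        u0, u1 = _edge_line(np.arange(t.size - 3, t.size))
        p0 = [tm0, self.dh_init, n0, n1, u0, u1]
        lo = [t[0] - 10.0, 1e3, -np.inf, -np.inf, -np.inf, -np.inf]
        hi = [t[-1] + 10.0, 1e8, np.inf, np.inf, np.inf, np.inf]
        try:
            popt, pcov = optimize.curve_fit(
                two_state_signal, t, y, p0=p0, bounds=(lo, hi),
                max_nfev=self.max_nfev,
            )
        except RuntimeError as exc:
            raise FitError(
                f"two-state melt fit did not converge (start Tm={tm0:.2f} degC, "
                f"dH={self.dh_init:.3g} J/mol): {exc}"
            ) from exc
        tm = float(popt[0])
        if not (t[0] <= tm <= t[-1]):
            self._flag_no_transition(t)
            return self
        resid = y - two_state_signal(t, *popt)
        self.tm_ = tm
        self.dh_app_ = float(popt[1])
        self.native_baseline_ = (float(popt[2]), float(popt[3]))
        self.unfolded_baseline_ = (float(popt[4]), float(popt[5]))
        self.se_tm_ = float(np.sqrt(max(pcov[0, 0], 0.0)))
        self.rss_ = float(resid @ resid)
        self.no_transition_ = False
        return self

    def _flag_no_transition(self, t: np.ndarray) -> None:
        self.tm_ = float("nan")
        self.dh_app_ = float("nan")
        self.native_baseline_ = (float("nan"), float("nan"))
        self.unfolded_baseline_ = (float("nan"), float("nan"))
        self.se_tm_ = float("nan")
        self.rss_ = float("nan")
        self.no_transition_ = True

    def predict(self, X):
        check_is_fitted(self, "tm_")
        if self.no_transition_:
            raise FitError("no transition was found; nothing to predict")
        X = check_array(X, ensure_2d=True, dtype=float)
        return two_state_signal(
            X[:, 0],
            self.tm_,
            self.dh_app_,
            *self.native_baseline_,
            *self.unfolded_baseline_,
        )


def _derivative_tm(
    t: np.ndarray, y: np.ndarray, smooth_halfwidth: int = 1
) -> float | None:
    """Midpoint from the extremal central-difference derivative.

    Boxcar-smooths the signal, takes central differences on the interior
    points, and refines the extremum with a local parabola.  Returns ``None``
    when no transition stands out (flat or purely linear traces, where the
    derivative magnitude is nearly uniform).
    """
    if smooth_halfwidth > 0:
        w = 2 * smooth_halfwidth + 1
        padded = np.pad(y, smooth_halfwidth, mode="edge")
        ys = np.convolve(padded, np.ones(w) / w, mode="valid")
    else:
        ys = y
    d = (ys[2:] - ys[:-2]) / (t[2:] - t[:-2])
    mag = np.abs(d)
    dmax = float(mag.max())
    dmed = float(np.median(mag))
    # flat (dmax == 0) and purely linear (uniform derivative, ratio ~ 1)
    # traces carry no transition; a genuine sigmoid peaks well above the
    # baseline derivative even when broad (ratio >~ 2.7 for the widest
    # transitions resolvable on a 3-degree grid)
    if dmax <= 0:
        return None
    if dmed > 0 and dmax < 2.0 * dmed:
        return None
    i = int(np.argmax(mag)) + 1  # index into t
    if 1 <= i - 1 and i + 1 <= t.size - 2:
        ti = t[i - 1 : i + 2]
        di = mag[i - 2 : i + 1]
        a, b, _ = np.polyfit(ti, di, 2)
        if a < 0:
            vertex = -b / (2 * a)
            if ti[0] <= vertex <= ti[-1]:
                return float(vertex)
    return float(t[i])


def tm_by_derivative(melt: MeltCurve, smooth_halfwidth: int = 1) -> float | None:
    """Model-free melting midpoint; ``None`` when no transition is detected."""
    return _derivative_tm(melt.temperature, melt.signal, smooth_halfwidth)


def fit_melt_two_state(melt: MeltCurve, dh_init: float = 3.0e5) -> MeltFit:
    """Fit the apparent two-state unfolding model to a melting curve."""
    model = TwoStateMeltModel(dh_init=dh_init)
    model.fit(melt.temperature[:, None], melt.signal)
    return MeltFit(
        tm_C=model.tm_,
        dh_app=model.dh_app_,
        native_baseline=model.native_baseline_,
        unfolded_baseline=model.unfolded_baseline_,
        se_tm=model.se_tm_,
        method="two-state",
        no_transition=model.no_transition_,
        wavelength=melt.wavelength,
        rss=model.rss_,
    )


def delta_tm(apo: MeltFit, holo: MeltFit) -> float:
    """Ligand-induced midpoint shift, holo - apo (degC); positive stabilizes."""
    if apo.wavelength != holo.wavelength:
        raise ValidationError(
            f"wavelength mismatch: {apo.wavelength} vs {holo.wavelength} nm"
        )
    if apo.no_transition or holo.no_transition:
        raise ValidationError("both fits must contain a transition")
    return holo.tm_C - apo.tm_C
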