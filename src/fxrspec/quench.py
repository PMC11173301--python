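"""Fluorescence-quenching analysis.

The observable is the ratio F0/F of unquenched to quenched tryptophan
emission as a function of ligand concentration [Q].  Three models are
fitted:

classical Stern-Volmer
    F0/F = 1 + Ksv [Q].  Under a static (complex-forming) mechanism Ksv is
    the association constant, so Kd = 1/Ksv; the apparent bimolecular rate
    Kq = Ksv/tau (tau = fluorophore lifetime) diagnoses the mechanism:
    values far above the diffusion limit (~1e10 L mol^-1 s^-1) rule out
    purely collisional quenching.

segmented Stern-Volmer
    two independent lines joined at a breakpoint concentration, for plots
    with two linear regimes (e.g. a tight site that saturates at the 1:1
    protein:ligand point followed by a weaker site).

Lehrer (modified Stern-Volmer)
    F0/(F0 - F) = 1/([Q] Ksv fa) + 1/fa, where fa is the fraction of the
    fluorophores accessible to the quencher.  Equivalently
    F = F0 (1 - fa Ksv [Q] / (1 + Ksv [Q])), the form used by the direct
    nonlinear fit.

Estimators follow the scikit-learn protocol (``fit(X, y)`` with X the
ligand-concentration column in mol/L); the module-level functions are thin
wrappers that accept :class:`~fxrspec.types.QuenchTitration` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import FitError, ValidationError
from .types import DEFAULT_TAU_S, QuenchTitration

#: Diffusion-limited bimolecular quenching rate, L mol^-1 s^-1.  Apparent
#: rates above this value indicate static (complex-forming) quenching.
DIFFUSION_LIMIT = 1e10


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------

@dataclass
class SVFit:
    """Classical Stern-Volmer fit result (units embedded on serialization)."""

    ksv: float                 # L mol^-1
    intercept: float           # dimensionless, ~1
    kq: float                  # L mol^-1 s^-1
    kd: float                  # mol/L
    se_ksv: float
    se_intercept: float
    r2: float
    n_points: int
    conc_range: tuple[float, float]   # mol/L

    def to_dict(self) -> dict[str, Any]:
        return {
            "ksv": self.ksv,
            "ksv_units": "L mol^-1",
            "se_ksv": self.se_ksv,
            "intercept": self.intercept,
            "se_intercept": self.se_intercept,
            "kq": self.kq,
            "kq_units": "L mol^-1 s^-1",
            "kd": self.kd,
            "kd_units": "mol L^-1",
            "r2": self.r2,
            "n": self.n_points,
            "range": list(self.conc_range),
            "range_units": "mol L^-1",
        }


@dataclass
class SegmentedSVFit:
    """Two-segment Stern-Volmer fit with a data-driven breakpoint."""

    low: SVFit
    high: SVFit
    breakpoint: float | None          # mol/L; None when unimodal
    pooled_rss: float
    breakpoint_grid: list[float] = field(default_factory=list)
    unimodal: bool = False
    f_stat: float = float("nan")
    p_value: float = float("nan")

    def to_dict(self) -> dict[str, Any]:
        return {
            "unimodal": self.unimodal,
            "breakpoint": self.breakpoint,
            "breakpoint_units": "mol L^-1",
            "pooled_rss": self.pooled_rss,
            "f_stat": self.f_stat,
            "p_value": self.p_value,
            "low": self.low.to_dict(),
            "high": self.high.to_dict(),
        }


@dataclass
class LehrerFit:
    """Modified Stern-Volmer fit: accessible fraction fa and Ksv."""

    fa: float
    ksv: float
    se_fa: float
    se_ksv: float
    method: str        # "direct" | "linearized"

    def to_dict(self) -> dict[str, Any]:
        return {
            "fa": self.fa,
            "se_fa": self.se_fa,
            "ksv": self.ksv,
            "ksv_units": "L mol^-1",
            "se_ksv": self.se_ksv,
            "method": self.method,
        }


@dataclass
class MechanismCall:
    """Static-vs-dynamic quenching classification from the apparent rate."""

    kq: float
    threshold: float
    call: str          # "static" | "dynamic-possible"

    def to_dict(self) -> dict[str, Any]:
        return {
            "kq": self.kq,
            "kq_units": "L mol^-1 s^-1",
            "threshold": self.threshold,
            "call": self.call,
        }


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _column(X: Any) -> np.ndarray:
    X = check_array(X, ensure_2d=True, dtype=float)
    if X.shape[1] != 1:
        raise ValidationError("X must be a single ligand-concentration column")
    return X[:, 0]


def _ols_line(x: np.ndarray, y: np.ndarray, force_unit_intercept: bool):
    """OLS of y on x; returns slope, intercept, their SEs, r2, rss."""
    n = x.size
    if force_unit_intercept:
        yy = y - 1.0
        sxx = float(np.dot(x, x))
        if sxx == 0:
            raise FitError("degenerate design: all concentrations zero")
        slope = float(np.dot(x, yy)) / sxx
        resid = yy - slope * x
        rss = float(np.dot(resid, resid))
        dof = max(n - 1, 1)
        se_slope = float(np.sqrt(rss / dof / sxx))
        intercept, se_intercept = 1.0, 0.0
    else:
        xm, ym = x.mean(), y.mean()
        dx = x - xm
        sxx = float(np.dot(dx, dx))
        if sxx == 0:
            raise FitError("degenerate design: concentrations are all equal")
        slope = float(np.dot(dx, y - ym)) / sxx
        intercept = float(ym - slope * xm)
        resid = y - (intercept + slope * x)
        rss = float(np.dot(resid, resid))
        dof = max(n - 2, 1)
        s2 = rss / dof
        se_slope = float(np.sqrt(s2 / sxx))
        se_intercept = float(np.sqrt(s2 * (1.0 / n + xm**2 / sxx)))
    tss = float(np.dot(y - y.mean(), y - y.mean()))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return slope, intercept, se_slope, se_intercept, r2, rss


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

class SternVolmerRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least-squares Stern-Volmer regression.

    Parameters
    ----------
    tau : float, default 5e-9
        Fluorophore lifetime in seconds, used to derive the apparent
        bimolecular rate ``kq_ = ksv_ / tau``.
    force_unit_intercept : bool, default False
        Constrain the intercept of F0/F vs [Q] to exactly 1.

    Attributes
    ----------
    ksv_ : float          slope, L mol^-1
    intercept_ : float    dimensionless intercept (1.0 when constrained)
    kq_ : float           ksv_/tau, L mol^-1 s^-1
    kd_ : float           1/ksv_, mol/L
    se_ksv_, se_intercept_, r2_, rss_, n_points_, conc_range_
    """

    def __init__(self, tau: float = DEFAULT_TAU_S, force_unit_intercept: bool = False):
        self.tau = tau
        self.force_unit_intercept = force_unit_intercept

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != x.size:
            raise ValidationError("X and y length mismatch")
        if x.size < 3:
            raise FitError("Stern-Volmer regression needs at least 3 points")
        if np.any(x < 0):
            raise ValidationError("ligand concentrations must be non-negative")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        slope, intercept, se_s, se_i, r2, rss = _ols_line(
            x, y, self.force_unit_intercept
        )
        if slope <= 0:
            warnings.warn(
                "non-positive Stern-Volmer slope: no quenching trend in data",
                stacklevel=2,
            )
        self.ksv_ = slope
        self.intercept_ = intercept
        self.se_ksv_ = se_s
        self.se_intercept_ = se_i
        self.r2_ = r2
        self.rss_ = rss
        self.kq_ = slope / self.tau
        self.kd_ = 1.0 / slope if slope > 0 else float("nan")
        self.n_points_ = int(x.size)
        self.conc_range_ = (float(x.min()), float(x.max()))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "ksv_")
        return self.intercept_ + self.ksv_ * _column(X)

    def result_(self) -> SVFit:
        check_is_fitted(self, "ksv_")
        return SVFit(
            ksv=self.ksv_,
            intercept=self.intercept_,
            kq=self.kq_,
            kd=self.kd_,
            se_ksv=self.se_ksv_,
            se_intercept=self.se_intercept_,
            r2=self.r2_,
            n_points=self.n_points_,
            conc_range=self.conc_range_,
        )


class SegmentedSternVolmer(RegressorMixin, BaseEstimator):
    """Two-segment Stern-Volmer regression with exhaustive breakpoint search.

    Every admissible split of the concentration-ordered points into a low and
    a high segment (each with at least ``min_points_per_segment`` points) is
    scored by the pooled residual sum of squares of two independent OLS
    lines; the minimum wins, ties going to the lower breakpoint.  The
    two-segment model must beat the single line in an F-test at level
    ``alpha`` (Bonferroni-corrected over the candidate splits, since the
    breakpoint is itself selected); otherwise the fit is flagged unimodal.

    The reported breakpoint is the concentration where the two fitted lines
    intersect, clipped to the gap between the boundary concentrations (the
    geometric mean of the gap is used if the lines are near-parallel).
    """

    def __init__(
        self,
        tau: float = DEFAULT_TAU_S,
        min_points_per_segment: int = 3,
        alpha: float = 0.05,
        force_unit_intercept: bool = False,
    ):
        self.tau = tau
        self.min_points_per_segment = min_points_per_segment
        self.alpha = alpha
        self.force_unit_intercept = force_unit_intercept

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float).ravel()
        m = int(self.min_points_per_segment)
        if m < 2:
            raise ValidationError("min_points_per_segment must be >= 2")
        n = x.size
        if n < 2 * m:
            raise FitError(
                f"segmented fit needs at least {2 * m} points, got {n}"
            )
        if not np.all(np.diff(x) > 0):
            raise ValidationError("concentrations must be strictly increasing")

        def _sub(lo: int, hi: int) -> SternVolmerRegressor:
            est = SternVolmerRegressor(
                tau=self.tau, force_unit_intercept=self.force_unit_intercept
            )
            return est.fit(x[lo:hi, None], y[lo:hi])

        single = _sub(0, n)
        best: tuple[float, int] | None = None
        candidates: list[float] = []
        for k in range(m, n - m + 1):
            low = _sub(0, k)
            high = _sub(k, n)
            rss = low.rss_ + high.rss_
            candidates.append(float(0.5 * (x[k - 1] + x[k])))
            if best is None or rss < best[0] - 1e-15 * max(1.0, best[0]):
                best = (rss, k)
        assert best is not None
        rss2, k = best
        low = _sub(0, k)
        high = _sub(k, n)
        rss1 = single.rss_

        n_candidates = len(candidates)
        scale = float(np.dot(y - y.mean(), y - y.mean()))
        dof2 = n - 4
        if rss1 <= 1e-12 * max(scale, 1e-300):
            # the single line already explains everything
            unimodal, f_stat, p_value = True, 0.0, 1.0
        elif rss2 <= 1e-12 * rss1 or dof2 <= 0:
            unimodal, f_stat, p_value = False, float("inf"), 0.0
        else:
            f_stat = ((rss1 - rss2) / 2.0) / (rss2 / dof2)
            p_value = float(stats.f.sf(f_stat, 2, dof2))
            unimodal = p_value > self.alpha / n_candidates

        self.single_ = single
        self.breakpoint_grid_ = candidates
        if unimodal:
            self.unimodal_ = True
            self.breakpoint_ = None
            self.low_ = single
            self.high_ = single
            self.pooled_rss_ = rss1
        else:
            self.unimodal_ = False
            self.low_ = low
            self.high_ = high
            self.pooled_rss_ = rss2
            c_lo, c_hi = float(x[k - 1]), float(x[k])
            dslope = low.ksv_ - high.ksv_
            if abs(dslope) > 1e-12 * max(abs(low.ksv_), abs(high.ksv_), 1.0):
                bp = (high.intercept_ - low.intercept_) / dslope
            else:
                bp = float("nan")
            tol = 1e-9
            if not np.isfinite(bp) or not (
                c_lo * (1 + tol) < bp <= c_hi * (1 + tol)
            ):
                bp = float(np.sqrt(c_lo * c_hi))  # near-parallel fallback
            self.breakpoint_ = float(np.clip(bp, np.nextafter(c_lo, c_hi), c_hi))
        self.f_stat_ = f_stat
        self.p_value_ = p_value
        self.split_index_ = None if unimodal else k
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "unimodal_")
        x = _column(X)
        if self.unimodal_ or self.breakpoint_ is None:
            return self.single_.predict(x[:, None])
        out = np.empty_like(x)
        lo = x < self.breakpoint_
        out[lo] = self.low_.predict(x[lo, None])
        out[~lo] = self.high_.predict(x[~lo, None])
        return out

    def result_(self) -> SegmentedSVFit:
        check_is_fitted(self, "unimodal_")
        return SegmentedSVFit(
            low=self.low_.result_(),
            high=self.high_.result_(),
            breakpoint=self.breakpoint_,
            pooled_rss=self.pooled_rss_,
            breakpoint_grid=list(self.breakpoint_grid_),
            unimodal=self.unimodal_,
            f_stat=self.f_stat_,
            p_value=self.p_value_,
        )


class LehrerRegressor(RegressorMixin, BaseEstimator):
    """Modified Stern-Volmer (accessible-fraction) regression.

    Expects ``y = F/F0`` (normalized emission) against the ligand
    concentration column.  ``method="direct"`` fits the hyperbolic model
    ``F/F0 = 1 - fa*Ksv*[Q]/(1 + Ksv*[Q])`` by nonlinear least squares
    (initialized from the linearized solution); ``method="linearized"``
    performs OLS of F0/(F0-F) against 1/[Q], the classical double-reciprocal
    form.  Points with no measurable quenching (F >= F0 at [Q] > 0) are
    excluded with a warning.
    """

    def __init__(self, method: str = "direct"):
        self.method = method

    @staticmethod
    def _model(q: np.ndarray, fa: float, ksv: float) -> np.ndarray:
        return 1.0 - fa * ksv * q / (1.0 + ksv * q)

    def _linearized(self, q: np.ndarray, y: np.ndarray):
        u = 1.0 / q
        v = 1.0 / (1.0 - y)           # == F0/(F0-F)
        um, vm = u.mean(), v.mean()
        du = u - um
        suu = float(np.dot(du, du))
        if suu == 0:
            raise FitError("degenerate design for linearized Lehrer fit")
        slope = float(np.dot(du, v - vm)) / suu   # 1/(Ksv*fa)
        inter = float(vm - slope * um)            # 1/fa
        if inter <= 0 or slope <= 0:
            raise FitError(
                "linearized Lehrer fit produced non-physical parameters "
                f"(intercept={inter:.3g}, slope={slope:.3g})"
            )
        nn = q.size
        resid = v - (inter + slope * u)
        rss = float(np.dot(resid, resid))
        dof = max(nn - 2, 1)
        s2 = rss / dof
        var_slope = s2 / suu
        var_inter = s2 * (1.0 / nn + um**2 / suu)
        cov_si = -s2 * um / suu
        fa = 1.0 / inter
        ksv = inter / slope
        # delta method on (slope, intercept) -> (fa, ksv)
        se_fa = float(np.sqrt(var_inter) / inter**2)
        g = np.array([-inter / slope**2, 1.0 / slope])
        cov = np.array([[var_slope, cov_si], [cov_si, var_inter]])
        se_ksv = float(np.sqrt(g @ cov @ g))
        return fa, ksv, se_fa, se_ksv

    def fit(self, X, y):
        if self.method not in ("direct", "linearized"):
            raise ValidationError(f"unknown method {self.method!r}")
        q = _column(X)
        y = np.asarray(y, dtype=float).ravel()
        if y.size != q.size:
            raise ValidationError("X and y length mismatch")
        if np.any(q <= 0):
            raise ValidationError(
                "Lehrer regression requires strictly positive ligand "
                "concentrations (normalize F0 out before fitting)"
            )
        keep = y < 1.0
        n_dropped = int(np.sum(~keep))
        if n_dropped:
            warnings.warn(
                f"excluded {n_dropped} point(s) with F >= F0 (no quenching)",
                stacklevel=2,
            )
        q, y = q[keep], y[keep]
        if q.size < 4:
            raise FitError("Lehrer regression needs at least 4 quenched points")

        if self.method == "linearized":
            fa, ksv, se_fa, se_ksv = self._linearized(q, y)
        else:
            heuristic = (
                float(np.clip(1.0 - np.min(y), 1e-3, 1.0)),
                1.0 / float(np.median(q)),
            )
            try:
                fa_lin, ksv_lin, _, _ = self._linearized(q, y)
                p0 = (
                    float(np.clip(fa_lin, 1e-6, 1.0)),
                    float(np.clip(ksv_lin, 0.01 / q.max(), 100.0 / q.min())),
                )
            except FitError:
                # double-reciprocal prefit can fail on noisy low-quenching
                # points; fall back to asymptote/scale heuristics
                p0 = heuristic
            popt = pcov = None
            last_exc: Exception | None = None
            for start in (p0, heuristic):
                try:
                    popt, pcov = optimize.curve_fit(
                        self._model,
                        q,
                        y,
                        p0=start,
                        bounds=([1e-12, 1e-12], [1.0, np.inf]),
                        maxfev=20000,
                    )
                    break
                except (RuntimeError, ValueError, optimize.OptimizeWarning) as exc:
                    last_exc = exc
            if popt is None:
                raise FitError(
                    f"direct Lehrer fit did not converge: {last_exc}"
                ) from last_exc
            fa, ksv = float(popt[0]), float(popt[1])
            perr = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
            se_fa, se_ksv = float(perr[0]), float(perr[1])
        self.fa_ = fa
        self.ksv_ = ksv
        self.se_fa_ = se_fa
        self.se_ksv_ = se_ksv
        self.n_points_ = int(q.size)
        self.n_excluded_ = n_dropped
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "fa_")
        return self._model(_column(X), self.fa_, self.ksv_)

    def result_(self) -> LehrerFit:
        check_is_fitted(self, "fa_")
        return LehrerFit(
            fa=self.fa_,
            ksv=self.ksv_,
            se_fa=self.se_fa_,
            se_ksv=self.se_ksv_,
            method=self.method,
        )


# ---------------------------------------------------------------------------
# titration-level wrappers
# ---------------------------------------------------------------------------

def inner_filter_correct(titration: QuenchTitration) -> QuenchTitration:
    """Apply the multiplicative inner-filter correction.

    F_corr = F_obs * 10**((A_ex + A_em)/2) per point, with A_ex/A_em the
    absorbances at the excitation and emission wavelengths.  A ``corrected``
    flag prevents accidental double application.
    """
    if titration.corrected:
        raise ValidationError("titration is already inner-filter corrected")
    if np.any(titration.A_ex < 0) or np.any(titration.A_em < 0):
        raise ValidationError("absorbances must be non-negative")
    factor = np.power(10.0, (titration.A_ex + titration.A_em) / 2.0)
    return titration.copy(F=titration.F * factor, corrected=True)


def _ratio_data(
    titration: QuenchTitration, conc_range: tuple[float, float] | None = None
):
    """Nonzero concentrations and F0/F ratios, optionally range-restricted."""
    f0 = titration.F0  # raises if no zero-ligand point
    q = titration.ligand_conc
    f = titration.F
    mask = q > 0
    if conc_range is not None:
        lo, hi = conc_range
        mask &= (q >= lo) & (q <= hi)
    return q[mask], f0 / f[mask], f[mask] / f0


def stern_volmer_fit(
    titration: QuenchTitration,
    conc_range: tuple[float, float] | None = None,
    force_unit_intercept: bool = False,
) -> SVFit:
    """Classical Stern-Volmer analysis of a titration.

    Fits F0/F against [Q] by OLS over the (optionally restricted)
    concentration range and derives Kq = Ksv/tau and Kd = 1/Ksv.
    """
    q, ratio, _ = _ratio_data(titration, conc_range)
    if q.size < 3:
        raise FitError("need at least 3 nonzero-concentration points in range")
    est = SternVolmerRegressor(
        tau=titration.tau, force_unit_intercept=force_unit_intercept
    )
    return est.fit(q[:, None], ratio).result_()


def segmented_sv_fit(
    titration: QuenchTitration,
    min_points_per_segment: int = 3,
    alpha: float = 0.05,
    force_unit_intercept: bool = False,
) -> SegmentedSVFit:
    """Two-segment Stern-Volmer analysis with breakpoint detection."""
    q, ratio, _ = _ratio_data(titration)
    est = SegmentedSternVolmer(
        tau=titration.tau,
        min_points_per_segment=min_points_per_segment,
        alpha=alpha,
        force_unit_intercept=force_unit_intercept,
    )
    return est.fit(q[:, None], ratio).result_()


def lehrer_fit(titration: QuenchTitration, method: str = "direct") -> LehrerFit:
    """Accessible-fraction (modified Stern-Volmer) analysis of a titration."""
    q, _, f_over_f0 = _ratio_data(titration)
    est = LehrerRegressor(method=method)
    return est.fit(q[:, None], f_over_f0).result_()


def mechanism_call(
    ksv: float, tau: float = DEFAULT_TAU_S, threshold: float = DIFFUSION_LIMIT
) -> MechanismCall:
    """Classify the quenching mechanism from the apparent bimolecular rate.

    ``static`` iff Kq = Ksv/tau strictly exceeds the diffusion-limit
    threshold; at or below it, dynamic quenching cannot be excluded.
    """
    if ksv <= 0 or tau <= 0 or threshold <= 0:
        raise ValidationError("ksv, tau and threshold must be positive")
    kq = ksv / tau
    return MechanismCall(
        kq=kq,
        threshold=threshold,
        call="static" if kq > threshold else "dynamic-possible",
    )


def dissociation_constant(ksv: float) -> float:
    """Kd = 1/Ksv (mol/L), valid under static, 1:1 complex formation."""
    if ksv <= 0:
        raise ValidationError("ksv must be positive")
    return 1.0 / ksv
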