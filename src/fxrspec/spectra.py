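"""Pointwise spectral arithmetic and unit conversions.

Wavelength grids must match exactly for arithmetic between spectra; no
resampling or smoothing is ever performed implicitly.
"""

from __future__ import annotations

import numpy as np

from .errors import GridMismatchError, UnitsError, ValidationError
from .types import CDSpectrum, Spectrum


def subtract_blank(sample: Spectrum, blank: Spectrum, blank_id: str = "blank") -> Spectrum:
    """Subtract a blank spectrum point-by-point.

    The two spectra must share an identical wavelength grid; the result keeps
    the sample's metadata plus a provenance note naming the blank.
    """
    if sample.x.size != blank.x.size or not np.array_equal(sample.x, blank.x):
        raise GridMismatchError(
            "sample and blank wavelength grids differ; no implicit resampling"
        )
    out = sample.copy()
    out.y = sample.y - blank.y
    out.meta = {**sample.meta, "blank_subtracted": blank_id}
    return out


def mdeg_to_mre(cd: CDSpectrum) -> CDSpectrum:
    """Convert raw ellipticity (mdeg) to mean residue ellipticity.

    Uses the standard convention

        [theta] = theta_mdeg * MRW / (10 * l_cm * c_gL)

    in deg cm^2 dmol^-1. Requires ``conc`` (g/L) and ``path`` (cm) metadata;
    refuses to convert a spectrum that is already in MRE units.
    """
    if cd.units == "MRE":
        raise UnitsError("spectrum is already in MRE units")
    if cd.conc is None or cd.conc <= 0:
        raise ValidationError("conc (g/L) must be set and positive")
    if cd.path is None or cd.path <= 0:
        raise ValidationError("path (cm) must be set and positive")
    factor = cd.mrw / (10.0 * cd.path * cd.conc)
    out = cd.copy()
    out.y = cd.y * factor
    out.units = "MRE"
    out.meta = {**cd.meta, "mre_factor": factor}
    return out


def mre_to_mdeg(cd: CDSpectrum) -> CDSpectrum:
    """Inverse of :func:`mdeg_to_mre` (used by the synthetic generator)."""
    if cd.units == "mdeg":
        raise UnitsError("spectrum is already in mdeg units")
    if cd.conc is None or cd.conc <= 0:
        raise ValidationError("conc (g/L) must be set and positive")
    if cd.path is None or cd.path <= 0:
        raise ValidationError("path (cm) must be set and positive")
    factor = 10.0 * cd.path * cd.conc / cd.mrw
    out = cd.copy()
    out.y = cd.y * factor
    out.units = "mdeg"
    return out


def band_intensity(spectrum: Spectrum, center: float, halfwidth: float = 0.0) -> float:
    """Intensity of a spectral band.

    Returns the maximum of ``y`` inside ``[center - halfwidth,
    center + halfwidth]``; with ``halfwidth == 0`` the value is linearly
    interpolated at ``center``. The window must lie inside the recorded range.
    """
    if halfwidth < 0:
        raise ValidationError("halfwidth must be non-negative")
    lo, hi = center - halfwidth, center + halfwidth
    if lo < spectrum.x[0] or hi > spectrum.x[-1]:
        raise ValidationError(
            f"window [{lo}, {hi}] nm outside spectrum range "
            f"[{spectrum.x[0]}, {spectrum.x[-1]}] nm"
        )
    if halfwidth == 0:
        return float(np.interp(center, spectrum.x, spectrum.y))
    mask = (spectrum.x >= lo) & (spectrum.x <= hi)
    if not np.any(mask):
        # window straddles grid points without containing one
        return float(np.interp(center, spectrum.x, spectrum.y))
    return float(np.max(spectrum.y[mask]))
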