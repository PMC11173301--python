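"""Core containers for spectra, quenching titrations and melting curves.

Conventions
-----------
* all ligand and protein concentrations are mol/L internally,
* fluorophore lifetimes are seconds,
* temperatures are degrees Celsius at the interface (melt math converts to
  kelvin internally),
* CD signal is either raw millidegrees (``mdeg``) or mean residue ellipticity
  (``MRE``, deg cm^2 dmol^-1); the :class:`CDSpectrum` carries a units flag so
  the conversion can never be applied twice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import ValidationError

SPECTRUM_KINDS = ("emission", "synchronous", "cd")

#: Mean residue weight (g/mol) of the FXR ligand-binding domain construct used
#: throughout; overridable per spectrum.
DEFAULT_MRW = 117.53

#: Default tryptophan fluorescence lifetime, seconds.
DEFAULT_TAU_S = 5e-9


def _as_float_array(values: Any, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class Spectrum:
    """A single wavelength-intensity trace.

    Parameters
    ----------
    x : array-like
        Wavelengths in nm, strictly increasing, length >= 2.
    y : array-like
        Intensity (arbitrary fluorescence units, or mdeg for CD).
    kind : {"emission", "synchronous", "cd"}
    meta : dict
        Free-form acquisition metadata (excitation wavelength, delta-lambda,
        temperature, slit width, path length, ...).
    """

    x: np.ndarray
    y: np.ndarray
    kind: str = "emission"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = _as_float_array(self.x, "x")
        self.y = _as_float_array(self.y, "y")
        if self.kind not in SPECTRUM_KINDS:
            raise ValidationError(
                f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}"
            )
        if self.x.size != self.y.size:
            raise ValidationError("x and y must have equal length")
        if self.x.size < 2:
            raise ValidationError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.x) > 0):
            raise ValidationError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.x.size)

    def copy(self, **changes: Any) -> "Spectrum":
        out = replace(self, **changes)
        out.meta = dict(changes.get("meta", self.meta))
        return out


@dataclass
class CDSpectrum(Spectrum):
    """Circular-dichroism spectrum with unit bookkeeping.

    ``units`` is ``"mdeg"`` for raw ellipticity or ``"MRE"`` for mean residue
    ellipticity; ``conc`` (g/L), ``path`` (cm) and ``mrw`` (g/mol) are needed
    for the conversion.
    """

    units: str = "mdeg"
    mrw: float = DEFAULT_MRW
    conc: float | None = None
    path: float | None = None

    def __post_init__(self) -> None:
        self.kind = "cd"
        super().__post_init__()
        if self.units not in ("mdeg", "MRE"):
            raise ValidationError(f"units must be 'mdeg' or 'MRE', got {self.units!r}")
        for name in ("conc", "path"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValidationError(f"{name} must be positive when set")
        if self.mrw <= 0:
            raise ValidationError("mrw must be positive")


@dataclass
class QuenchTitration:
    """A fluorescence-quenching titration at a fixed protein concentration.

    ``ligand_conc`` must be strictly increasing; a leading zero-concentration
    point, when present, defines the unquenched intensity F0.  ``A_ex`` and
    ``A_em`` are the sample absorbances at the excitation and emission
    wavelengths used for the inner-filter correction.
    """

    ligand_conc: np.ndarray
    F: np.ndarray
    protein_conc: float = 1e-6
    tau: float = DEFAULT_TAU_S
    A_ex: np.ndarray | None = None
    A_em: np.ndarray | None = None
    corrected: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand_conc = _as_float_array(self.ligand_conc, "ligand_conc")
        self.F = _as_float_array(self.F, "F")
        n = self.ligand_conc.size
        if self.F.size != n:
            raise ValidationError("ligand_conc and F must have equal length")
        if n < 2:
            raise ValidationError("a titration needs at least 2 points")
        if np.any(self.ligand_conc < 0):
            raise ValidationError("ligand concentrations must be non-negative")
        if not np.all(np.diff(self.ligand_conc) > 0):
            raise ValidationError("ligand concentrations must be strictly increasing")
        if np.any(self.F <= 0):
            raise ValidationError("fluorescence intensities must be positive")
        if self.protein_conc <= 0:
            raise ValidationError("protein_conc must be positive")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        for name in ("A_ex", "A_em"):
            value = getattr(self, name)
            if value is None:
                setattr(self, name, np.zeros(n))
            else:
                arr = _as_float_array(value, name)
                if arr.size != n:
                    raise ValidationError(f"{name} must match the number of points")
                if np.any(arr < 0):
                    raise ValidationError(f"{name} must be non-negative")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return int(self.ligand_conc.size)

    @property
    def has_f0(self) -> bool:
        return bool(self.ligand_conc[0] == 0.0)

    @property
    def F0(self) -> float:
        """Unquenched intensity, taken from the zero-ligand point."""
        if not self.has_f0:
            raise ValidationError(
                "titration has no zero-ligand point; F0 is undefined"
            )
        return float(self.F[0])

    def copy(self, **changes: Any) -> "QuenchTitration":
        out = replace(self, **changes)
        out.meta = dict(changes.get("meta", self.meta))
        return out


@dataclass
class MeltCurve:
    """CD signal versus temperature at one fixed wavelength."""

    temperature: np.ndarray
    signal: np.ndarray
    wavelength: float = 210.0
    meta: dict[str, Any] = field(default_factory=dict)

    #: acquisition limits, degrees Celsius
    TEMP_MIN = -10.0
    TEMP_MAX = 120.0

    def __post_init__(self) -> None:
        self.temperature = _as_float_array(self.temperature, "temperature")
        self.signal = _as_float_array(self.signal, "signal")
        if self.temperature.size != self.signal.size:
            raise ValidationError("temperature and signal must have equal length")
        if self.temperature.size < 8:
            raise ValidationError("a melting curve needs at least 8 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if (
            self.temperature[0] < self.TEMP_MIN
            or self.temperature[-1] > self.TEMP_MAX
        ):
            raise ValidationError(
                f"temperatures must lie within [{self.TEMP_MIN}, {self.TEMP_MAX}] degC"
            )
        if self.wavelength <= 0:
            raise ValidationError("wavelength must be positive")

    def __len__(self) -> int:
        return int(self.temperature.size)
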