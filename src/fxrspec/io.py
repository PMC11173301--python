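"""Readers and writers for the package's delimited-text formats.

Three CSV schemas are supported (header names exact, UTF-8, "." decimal).
Metadata rides in ``# key = value`` comment lines above the header:

``spectrum``
    ``wavelength_nm,intensity``; optional meta keys include ``kind``,
    ``units``, ``conc_g_L``, ``path_cm``, ``mrw`` (a ``kind`` of ``cd`` plus
    CD meta yields a :class:`~fxrspec.types.CDSpectrum`).
``titration``
    ``ligand_conc_M,F[,A_ex,A_em]`` with ``protein_conc_M`` and ``tau_s``
    (and optionally ``corrected``) in the comment header.
``melt``
    ``temperature_C,signal[,wavelength_nm]``.

A minimal JCAMP-DX reader handles single-block ``XYDATA=(X++(Y..Y))``
records with ``XFACTOR``/``YFACTOR`` scaling.
"""

from __future__ import annotations

import io as _io
import math
from pathlib import Path
from typing import Any, TextIO, Union

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .types import CDSpectrum, MeltCurve, QuenchTitration, Spectrum

Source = Union[str, Path, TextIO]

_SCHEMAS = {
    "spectrum": ("wavelength_nm", "intensity"),
    "titration": ("ligand_conc_M", "F"),
    "melt": ("temperature_C", "signal"),
}

_FLOAT_FMT = "%.17g"


def _read_text(source: Source) -> str:
    if hasattr(source, "read"):
        return source.read()
    return Path(source).read_text(encoding="utf-8")


def _parse_meta_lines(text: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        if not line.startswith("#"):
            continue
        body = line.lstrip("#").strip()
        if "=" in body:
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
    return meta


def _coerce_meta(meta: dict[str, str]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, value in meta.items():
        if value.lower() in ("true", "false"):
            out[key] = value.lower() == "true"
            continue
        try:
            out[key] = float(value)
        except ValueError:
            out[key] = value
    return out


def _load_frame(text: str, schema: str) -> tuple[pd.DataFrame, dict[str, Any]]:
    meta = _coerce_meta(_parse_meta_lines(text))
    try:
        frame = pd.read_csv(_io.StringIO(text), comment="#", dtype=str)
    except Exception as exc:  # malformed CSV entirely
        raise ParseError(f"could not parse CSV: {exc}") from exc
    mandatory = _SCHEMAS[schema]
    for column in mandatory:
        if column not in frame.columns:
            raise SchemaError(
                f"{schema} table is missing mandatory column {column!r}"
            )
    numeric = {}
    for column in frame.columns:
        values = pd.to_numeric(frame[column], errors="coerce")
        bad = values.index[values.isna() & frame[column].notna()]
        if len(bad):
            raise ParseError(
                f"non-numeric value in column {column!r} at row {int(bad[0])}"
            )
        numeric[column] = values.to_numpy(dtype=float)
    return pd.DataFrame(numeric), meta


def read_table(
    source: Source, schema: str
) -> Spectrum | CDSpectrum | QuenchTitration | MeltCurve:
    """Read a delimited table into a validated typed object.

    Parameters
    ----------
    source : path or open text file
    schema : {"spectrum", "titration", "melt"}
    """
    if schema not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {list(_SCHEMAS)}")
    frame, meta = _load_frame(_read_text(source), schema)

    if schema == "spectrum":
        order = np.argsort(frame["wavelength_nm"].to_numpy())
        x = frame["wavelength_nm"].to_numpy()[order]
        y = frame["intensity"].to_numpy()[order]
        kind = str(meta.pop("kind", "emission"))
        if kind == "cd":
            return CDSpectrum(
                x=x,
                y=y,
                units=str(meta.pop("units", "mdeg")),
                mrw=float(meta.pop("mrw", 117.53)),
                conc=meta.pop("conc_g_L", None),
                path=meta.pop("path_cm", None),
                meta=meta,
            )
        return Spectrum(x=x, y=y, kind=kind, meta=meta)

    if schema == "titration":
        # deliberately no re-sorting: out-of-order concentrations are a
        # validation error, not something to fix silently
        n = len(frame)
        return QuenchTitration(
            ligand_conc=frame["ligand_conc_M"].to_numpy(),
            F=frame["F"].to_numpy(),
            A_ex=frame["A_ex"].to_numpy() if "A_ex" in frame else np.zeros(n),
            A_em=frame["A_em"].to_numpy() if "A_em" in frame else np.zeros(n),
            protein_conc=float(meta.pop("protein_conc_M", 1e-6)),
            tau=float(meta.pop("tau_s", 5e-9)),
            corrected=bool(meta.pop("corrected", False)),
            meta=meta,
        )

    order = np.argsort(frame["temperature_C"].to_numpy())
    wavelength = 210.0
    if "wavelength_nm" in frame:
        wavelength = float(frame["wavelength_nm"].to_numpy()[0])
    elif "wavelength_nm" in meta:
        wavelength = float(meta.pop("wavelength_nm"))
    return MeltCurve(
        temperature=frame["temperature_C"].to_numpy()[order],
        signal=frame["signal"].to_numpy()[order],
        wavelength=wavelength,
        meta=meta,
    )


def _meta_header(meta: dict[str, Any]) -> str:
    lines = []
    for key, value in meta.items():
        if isinstance(value, float):
            value = _FLOAT_FMT % value
        lines.append(f"# {key} = {value}")
    return "\n".join(lines) + ("\n" if lines else "")


def write_table(
    obj: Spectrum | CDSpectrum | QuenchTitration | MeltCurve, target: Source
) -> None:
    """Write a typed object back to its CSV schema (lossless to 1e-12 relative)."""
    meta: dict[str, Any]
    if isinstance(obj, CDSpectrum):
        frame = pd.DataFrame({"wavelength_nm": obj.x, "intensity": obj.y})
        meta = {"kind": "cd", "units": obj.units, "mrw": obj.mrw, **obj.meta}
        if obj.conc is not None:
            meta["conc_g_L"] = obj.conc
        if obj.path is not None:
            meta["path_cm"] = obj.path
    elif isinstance(obj, Spectrum):
        frame = pd.DataFrame({"wavelength_nm": obj.x, "intensity": obj.y})
        meta = {"kind": obj.kind, **obj.meta}
    elif isinstance(obj, QuenchTitration):
        frame = pd.DataFrame(
            {
                "ligand_conc_M": obj.ligand_conc,
                "F": obj.F,
                "A_ex": obj.A_ex,
                "A_em": obj.A_em,
            }
        )
        meta = {
            "protein_conc_M": obj.protein_conc,
            "tau_s": obj.tau,
            "corrected": obj.corrected,
            **obj.meta,
        }
    elif isinstance(obj, MeltCurve):
        frame = pd.DataFrame(
            {
                "temperature_C": obj.temperature,
                "signal": obj.signal,
                "wavelength_nm": np.full(len(obj), obj.wavelength),
            }
        )
        meta = dict(obj.meta)
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")

    text = _meta_header(meta) + frame.to_csv(index=False, float_format=_FLOAT_FMT)
    if hasattr(target, "write"):
        target.write(text)
    else:
        Path(target).write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# Minimal JCAMP-DX support (read-only)
# ---------------------------------------------------------------------------

def read_jcamp(source: Source, kind: str = "emission") -> Spectrum:
    """Read a single-block JCAMP-DX record with ``XYDATA=(X++(Y..Y))``.

    Honors XUNITS/YUNITS (stored as metadata), XFACTOR/YFACTOR scaling and
    FIRSTX/LASTX/NPOINTS; each data line is ``x y1 y2 ...`` with the x value
    of subsequent ys advancing by the implied grid step.
    """
    text = _read_text(source)
    fields: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                if value.replace(" ", "") != "(X++(Y..Y))":
                    raise ParseError(f"unsupported XYDATA form {value!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            fields[key] = value
            in_data = False
        elif in_data:
            data_lines.append(line)
    if not data_lines:
        raise ParseError("no XYDATA block found")

    def _field(name: str, default: float | None = None) -> float:
        if name in fields:
            try:
                return float(fields[name])
            except ValueError as exc:
                raise ParseError(f"bad numeric field ##{name}={fields[name]!r}") from exc
        if default is None:
            raise ParseError(f"missing mandatory field ##{name}")
        return default

    xfactor = _field("XFACTOR", 1.0)
    yfactor = _field("YFACTOR", 1.0)
    firstx = _field("FIRSTX")
    lastx = _field("LASTX")
    npoints = int(_field("NPOINTS"))
    if npoints < 2:
        raise ParseError("NPOINTS must be >= 2")
    step = (lastx - firstx) / (npoints - 1)

    xs: list[float] = []
    ys: list[float] = []
    for line in data_lines:
        tokens = line.replace(",", " ").split()
        try:
            values = [float(tok) for tok in tokens]
        except ValueError as exc:
            raise ParseError(f"non-numeric token in data line {line!r}") from exc
        if len(values) < 2:
            raise ParseError(f"data line {line!r} has no y values")
        x0 = values[0] * xfactor
        for j, yval in enumerate(values[1:]):
            xs.append(x0 + j * step)
            ys.append(yval * yfactor)
    if len(xs) != npoints:
        raise ParseError(f"expected {npoints} points, decoded {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if not math.isclose(x[-1], lastx * 1.0, rel_tol=0, abs_tol=abs(step) * 0.51 + 1e-12):
        raise ParseError("decoded x range disagrees with FIRSTX/LASTX")
    if step < 0:  # descending records are normalized to increasing x
        x = x[::-1]
        y = y[::-1]
    meta = {
        "xunits": fields.get("XUNITS", ""),
        "yunits": fields.get("YUNITS", ""),
        "title": fields.get("TITLE", ""),
    }
    try:
        return Spectrum(x=x, y=y, kind=kind, meta=meta)
    except ValidationError as exc:
        raise ParseError(f"JCAMP record is not a valid spectrum: {exc}") from exc
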