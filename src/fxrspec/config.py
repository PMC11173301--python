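"""Config-driven pipeline: validation, execution, reporting.

A pipeline config is a single YAML document.  Each dataset names either an
``input`` CSV (with its ``schema``) or a ``generator`` block (kind +
parameters), plus the list of analyses to run on it.  A ``seed`` is
mandatory as soon as any generator is used; per-dataset child seeds are
derived deterministically from it, so two runs of the same config+seed are
byte-identical up to the report timestamp.

Example
-------
::

    seed: 17
    output_dir: out
    datasets:
      - name: caf_titration
        generator: {kind: sv, params: {ksv: 117050.0, noise_cv: 0.01}}
        analyses: [sv, segmented, lehrer]
    sv_arithmetic:
      tau_s: 5.0e-9
      ksv_values: {caf_low: 117050.0, caf_high: 13780.0}
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .cdtherm import BasisSet, estimate_secondary_structure, fit_melt_two_state, tm_by_derivative
from .errors import FxrSpecError
from .io import read_table, write_table
from .quench import lehrer_fit, mechanism_call, segmented_sv_fit, stern_volmer_fit
from .spectra import mdeg_to_mre
from .synth import (
    CDTruth,
    LehrerTruth,
    MeltTruth,
    TwoSiteTruth,
    gen_cd_spectrum,
    gen_lehrer_titration,
    gen_melt,
    gen_sv_titration,
    gen_two_site_titration,
)
from .types import CDSpectrum, MeltCurve, QuenchTitration

logger = logging.getLogger("fxrspec")

REPORT_SCHEMA_VERSION = 1

Analysis = Literal["sv", "segmented", "lehrer", "cd", "melt"]
GeneratorKind = Literal["sv", "two_site", "lehrer", "cd", "melt"]
SchemaName = Literal["spectrum", "titration", "melt"]


class GeneratorBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: GeneratorKind
    params: dict[str, Any] = Field(default_factory=dict)


class DatasetConfig(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)
    name: str
    input: Optional[str] = None
    table_schema: Optional[SchemaName] = Field(None, alias="schema")
    generator: Optional[GeneratorBlock] = None
    analyses: list[Analysis]
    tau_s: Optional[float] = None
    alpha: float = 0.05
    lehrer_method: Literal["direct", "linearized"] = "direct"
    basis_path: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "DatasetConfig":
        if (self.input is None) == (self.generator is None):
            raise ValueError(
                f"dataset {self.name!r} must define exactly one of "
                "'input' or 'generator'"
            )
        if self.input is not None and self.table_schema is None:
            raise ValueError(
                f"dataset {self.name!r}: 'schema' is required with 'input'"
            )
        if not self.analyses:
            raise ValueError(f"dataset {self.name!r} requests no analyses")
        return self


class ArithmeticBlock(BaseModel):
    """Derive Kq and Kd (and the mechanism call) from given Ksv values."""

    model_config = ConfigDict(extra="forbid")
    tau_s: float = 5e-9
    threshold: float = 1e10
    ksv_values: dict[str, float]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: Optional[int] = None
    output_dir: str = "fxrspec_out"
    log_level: str = "INFO"
    datasets: list[DatasetConfig] = Field(default_factory=list)
    sv_arithmetic: Optional[ArithmeticBlock] = None

    @model_validator(mode="after")
    def _seed_with_generators(self) -> "PipelineConfig":
        if self.seed is None and any(d.generator for d in self.datasets):
            raise ValueError(
                "'seed' is mandatory when any dataset uses a generator"
            )
        return self


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise FxrSpecError(f"config {path} is not a YAML mapping")
    return PipelineConfig.model_validate(raw)


def validate_config(path: str | Path) -> list[str]:
    """Return a list of human-readable schema violations (empty == valid)."""
    try:
        text = Path(path).read_text(encoding="utf-8")
    except OSError as exc:
        raise FxrSpecError(f"cannot read config {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        return [f"not valid YAML: {exc}"]
    if not isinstance(raw, dict):
        return ["config must be a YAML mapping"]
    try:
        PipelineConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        diagnostics = []
        for err in getattr(exc, "errors", lambda: [])():
            loc = ".".join(str(part) for part in err["loc"]) or "<root>"
            got = err.get("input")
            suffix = f" (got {got!r})" if got is not None and not isinstance(got, dict) else ""
            diagnostics.append(f"{loc}: {err['msg']}{suffix}")
        return diagnostics or [str(exc)]
    return []


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

_GENERATORS = {
    "sv": lambda params, seed: gen_sv_titration(**params, seed=seed),
    "two_site": lambda params, seed: gen_two_site_titration(
        TwoSiteTruth(**params), seed=seed
    ),
    "lehrer": lambda params, seed: gen_lehrer_titration(
        LehrerTruth(**params), seed=seed
    ),
    "cd": lambda params, seed: gen_cd_spectrum(
        CDTruth(
            **{
                **params,
                **(
                    {"fractions": tuple(params["fractions"])}
                    if "fractions" in params
                    else {}
                ),
            }
        ),
        seed=seed,
    ),
    "melt": lambda params, seed: gen_melt(
        MeltTruth(
            **{
                **params,
                **(
                    {
                        key: tuple(params[key])
                        for key in ("native_baseline", "unfolded_baseline")
                        if key in params
                    }
                ),
            }
        ),
        seed=seed,
    ),
}


def _build_dataset(ds: DatasetConfig, seed: int | None):
    if ds.generator is not None:
        return _GENERATORS[ds.generator.kind](dict(ds.generator.params), seed)
    return read_table(ds.input, ds.table_schema)


def _analyze(ds: DatasetConfig, data) -> dict[str, Any]:
    results: dict[str, Any] = {}
    basis = BasisSet.from_csv(ds.basis_path) if ds.basis_path else None
    for analysis in ds.analyses:
        try:
            if analysis in ("sv", "segmented", "lehrer"):
                if not isinstance(data, QuenchTitration):
                    raise FxrSpecError(
                        f"analysis {analysis!r} needs a titration dataset"
                    )
                if ds.tau_s is not None:
                    data = data.copy(tau=ds.tau_s)
                if analysis == "sv":
                    fit = stern_volmer_fit(data)
                    out = fit.to_dict()
                    out["mechanism"] = mechanism_call(fit.ksv, data.tau).to_dict()
                elif analysis == "segmented":
                    out = segmented_sv_fit(data, alpha=ds.alpha).to_dict()
                else:
                    out = lehrer_fit(data, method=ds.lehrer_method).to_dict()
            elif analysis == "cd":
                if not isinstance(data, CDSpectrum):
                    raise FxrSpecError("analysis 'cd' needs a CD spectrum dataset")
                spectrum = mdeg_to_mre(data) if data.units == "mdeg" else data
                out = estimate_secondary_structure(spectrum, basis=basis).to_dict()
            elif analysis == "melt":
                if not isinstance(data, MeltCurve):
                    raise FxrSpecError("analysis 'melt' needs a melt dataset")
                out = fit_melt_two_state(data).to_dict()
                out["tm_derivative_C"] = tm_by_derivative(data)
            else:  # pragma: no cover - schema prevents this
                raise FxrSpecError(f"unknown analysis {analysis!r}")
            results[analysis] = out
        except Exception as exc:  # recorded; independent stages still run
            logger.error("dataset %s / %s failed: %s", ds.name, analysis, exc)
            results[analysis] = {"error": str(exc)}
    return results


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Execute all configured stages; returns (and writes) the JSON report.

    Stage failures are recorded in the report and do not stop independent
    stages; the function raises only on configuration-level problems.
    """
    seed = config.seed if seed is None else seed
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "datasets").mkdir(exist_ok=True)

    config_bytes = json.dumps(
        config.model_dump(mode="json"), sort_keys=True
    ).encode()
    report: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
        "config_sha256": hashlib.sha256(config_bytes).hexdigest(),
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "datasets": {},
        "warnings": [],
    }

    child_seeds = None
    if seed is not None:
        child_seeds = np.random.default_rng(seed).integers(
            0, 2**31 - 1, size=max(len(config.datasets), 1)
        )

    for index, ds in enumerate(config.datasets):
        ds_seed = int(child_seeds[index]) if child_seeds is not None else None
        try:
            data = _build_dataset(ds, ds_seed)
        except Exception as exc:  # recorded; independent stages still run
            logger.error("dataset %s could not be built: %s", ds.name, exc)
            report["datasets"][ds.name] = {"error": str(exc)}
            continue
        write_table(data, out / "datasets" / f"{ds.name}.csv")
        report["datasets"][ds.name] = _analyze(ds, data)

    if config.sv_arithmetic is not None:
        block = config.sv_arithmetic
        arithmetic = {}
        for label, ksv in block.ksv_values.items():
            call = mechanism_call(ksv, block.tau_s, block.threshold)
            arithmetic[label] = {
                "ksv": ksv,
                "kq": call.kq,
                "kd": 1.0 / ksv,
                "mechanism": call.call,
            }
        report["sv_arithmetic"] = arithmetic

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report
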