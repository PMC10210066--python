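"""Configuration and CSV I/O.

CSV dialects (header row, UTF-8, dot decimal separator, concentrations in
molar scientific notation):

* ``kinetics``: ``time_s, signal_au``
* ``titration``: ``competitor_conc_M, transferred_eq`` (equivalents per
  protein) -- extra columns are preserved as annotations
* ``results``: ``estimator, neg_log_kd, uncertainty, model, constants_set,
  inputs_digest``

Run configurations are YAML, schema-validated with unknown keys rejected;
every run records the resolved constant set and a content digest of the
configuration so results are traceable to their inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError as PydanticValidationError

from . import constants
from .assays import KineticTrace
from .errors import ConfigError, ValidationError
from .system import CompetitorLigand, MultiSiteReceptor, SystemDefinition

__all__ = [
    "LigandSpec",
    "ReceptorSpec",
    "RunConfig",
    "load_config",
    "read_titration_csv",
    "write_trace_csv",
    "write_results_csv",
]


class LigandSpec(BaseModel):
    """One competitor in a run configuration.

    Either a packaged ``name`` (constants looked up) or explicit
    ``kd``/``stoich``; ``total_conc`` is always required.
    """

    model_config = ConfigDict(extra="forbid")

    total_conc: float
    name: str | None = None
    kd: float | None = None
    stoich: int = 1

    def build(self) -> CompetitorLigand:
        if self.total_conc < 0:
            raise ConfigError("ligand total_conc must be >= 0")
        if self.name is not None:
            return constants.competitor(self.name, self.total_conc)
        if self.kd is None:
            raise ConfigError("ligand needs either a packaged name or an explicit kd")
        return CompetitorLigand(kd=self.kd, stoich=self.stoich,
                                total_conc=self.total_conc)


class ReceptorSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    total_conc: float
    constants_set: str = "mt2_ref32"
    site_kds: tuple[float, ...] | None = None

    def build(self) -> MultiSiteReceptor:
        if self.site_kds is not None:
            return MultiSiteReceptor(site_kds=self.site_kds,
                                     total_conc=self.total_conc, label="custom")
        return constants.receptor(self.constants_set, self.total_conc)


class RunConfig(BaseModel):
    """Validated description of one analysis run."""

    model_config = ConfigDict(extra="forbid")

    receptor: ReceptorSpec
    ligands: tuple[LigandSpec, ...] = ()
    total_metal: float | None = None  # default: n_sites * receptor total
    estimators: tuple[Literal["stepwise", "cooperative", "ci_based"], ...] = (
        "stepwise",
    )
    seed: int = 0
    out_dir: str = "results"
    verbosity: int = 1

    def to_system(self) -> SystemDefinition:
        receptor = self.receptor.build()
        total = (
            self.total_metal
            if self.total_metal is not None
            else receptor.n_sites * receptor.total_conc
        )
        return SystemDefinition(
            receptors=(receptor,),
            ligands=tuple(lig.build() for lig in self.ligands),
            total_metal=total,
        )

    @property
    def constants_set(self) -> str:
        return self.receptor.constants_set if self.receptor.site_kds is None else "custom"

    def digest(self) -> str:
        raw = json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        return hashlib.sha1(raw).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` naming the offending fields on any schema
    violation; unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError("config must be a YAML mapping")
    try:
        cfg = RunConfig.model_validate(data)
    except PydanticValidationError as exc:
        fields = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {fields}") from exc
    # fail fast on unknown constant/competitor names and bad concentrations
    try:
        cfg.to_system()
    except PydanticValidationError as exc:
        raise ConfigError(f"invalid configuration values: {exc}") from exc
    return cfg


_DIALECTS = {
    "kinetics": ("time_s", "signal_au"),
    "titration": ("competitor_conc_M", "transferred_eq"),
}


def read_titration_csv(
    path: str | Path, dialect: Literal["kinetics", "titration"] = "titration"
):
    """Read a kinetics or titration CSV with typed, row-addressed validation.

    Returns a :class:`KineticTrace` for the ``kinetics`` dialect and a
    :class:`pandas.DataFrame` (extra columns preserved) for ``titration``.
    """
    if dialect not in _DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}; use {sorted(_DIALECTS)}")
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    required = _DIALECTS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or df.index[coerced.isna()].tolist()
            raise ValidationError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"row(s) {rows[:5]}"
            )
        df[col] = coerced
    if dialect == "kinetics":
        return KineticTrace(
            time=df["time_s"].to_numpy(), signal=df["signal_au"].to_numpy()
        )
    return df


def write_trace_csv(trace: KineticTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "signal_au": trace.signal}).to_csv(
        path, index=False, float_format="%.10e"
    )


def write_results_csv(rows: list[dict], path: str | Path) -> None:
    """Write an estimate table in the ``results`` dialect.

    Every row must carry a model tag, inputs digest and constant-set name
    (the reproducibility contract); -logK_d values are reported to two
    decimals.
    """
    required = {"estimator", "neg_log_kd", "uncertainty", "model",
                "constants_set", "inputs_digest"}
    for i, row in enumerate(rows):
        missing = required - row.keys()
        if missing:
            raise ValidationError(f"result row {i} missing fields {sorted(missing)}")
    df = pd.DataFrame(rows)
    df["neg_log_kd"] = np.round(df["neg_log_kd"].astype(float), 2)
    df["uncertainty"] = np.round(df["uncertainty"].astype(float), 2)
    df.to_csv(path, index=False)
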