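"""Readers, writers and run configuration.

One canonical long-format CSV dialect carries time courses: comma-separated,
UTF-8, '.' decimal separator, exact header
``setup_id,strain,replicate,time_h,analyte,value,unit`` with analytes in
{Fe2, NO3, NO2, N2O} and values in mM.  No sniffing — fixtures are
bit-exact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .kinetics import ANALYTES, KineticParams, NoiseModel, TimeCourse

__all__ = ["HEADER", "read_timecourse", "write_timecourse", "RunConfig", "provenance"]

HEADER = ["setup_id", "strain", "replicate", "time_h", "analyte", "value", "unit"]

_KEY = ["setup_id", "replicate", "time_h", "analyte"]


def read_timecourse(path: Union[str, Path]) -> TimeCourse:
    """Read and validate one setup's long-format time-course CSV.

    Rejects (naming the offending rows): header mismatch, more than one
    setup, unknown analytes, negative / non-finite values, wrong unit,
    duplicate (setup_id, replicate, time_h, analyte) keys, and time grids
    that differ between replicate series.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"setup_id": str, "strain": str, "analyte": str, "unit": str})
    if list(df.columns) != HEADER:
        raise ValueError(
            f"{path}: header must be exactly {','.join(HEADER)}, got {','.join(df.columns)}"
        )
    if df.empty:
        raise ValueError(f"{path}: no data rows")

    def rows(mask) -> list[int]:
        # +2: 1-based with the header line
        return [int(i) + 2 for i in df.index[mask]]

    bad = ~df["analyte"].isin(ANALYTES)
    if bad.any():
        raise ValueError(
            f"{path}: unknown analyte(s) {sorted(df.loc[bad, 'analyte'].unique())} "
            f"at row(s) {rows(bad)}; allowed: {list(ANALYTES)}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values.fillna(0.0)) | (values < 0)
    if bad.any():
        raise ValueError(
            f"{path}: non-numeric, non-finite or negative value(s) at row(s) {rows(bad)}"
        )
    df["value"] = values
    bad = df["unit"] != "mM"
    if bad.any():
        raise ValueError(f"{path}: unit must be 'mM' at row(s) {rows(bad)}")
    dup = df.duplicated(subset=_KEY, keep=False)
    if dup.any():
        raise ValueError(f"{path}: duplicate {tuple(_KEY)} key(s) at row(s) {rows(dup)}")
    setups = df["setup_id"].unique()
    if len(setups) != 1:
        raise ValueError(f"{path}: expected a single setup per file, found {sorted(setups)}")
    strains = df["strain"].unique()
    if len(strains) != 1:
        raise ValueError(f"{path}: expected a single strain per file, found {sorted(strains)}")

    grids = {
        key: tuple(sorted(g["time_h"]))
        for key, g in df.groupby(["replicate", "analyte"])
    }
    if len(set(grids.values())) > 1:
        detail = "; ".join(f"{k}: {len(v)} points" for k, v in sorted(grids.items()))
        raise ValueError(f"{path}: ragged time grids across replicate series ({detail})")

    data = df[["replicate", "time_h", "analyte", "value", "unit"]].reset_index(drop=True)
    return TimeCourse(setup_id=str(setups[0]), strain=str(strains[0]), data=data)


def write_timecourse(tc: TimeCourse, path: Union[str, Path]) -> None:
    """Write a TimeCourse in the canonical CSV dialect (round-trips with
    :func:`read_timecourse`)."""
    df = tc.data.copy()
    df.insert(0, "strain", tc.strain)
    df.insert(0, "setup_id", tc.setup_id)
    df = df.sort_values(_KEY, kind="stable")
    df.to_csv(path, index=False, lineterminator="\n")


class NoiseConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sigma_rel: float = 0.03
    sigma_abs: dict[str, float] = Field(
        default_factory=lambda: {"Fe2": 0.05, "NO3": 0.05, "NO2": 0.02, "N2O": 0.01}
    )
    n_replicates: int = 3

    def build(self, seed: int) -> NoiseModel:
        return NoiseModel(
            sigma_rel=self.sigma_rel, sigma_abs=self.sigma_abs,
            n_replicates=self.n_replicates, seed=seed,
        )


class RunConfig(BaseModel):
    """Schema-validated run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    t_start: float = 0.0
    t_end: float = 240.0
    params: dict[str, float] = Field(default_factory=dict)  # KineticParams overrides
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    times: list[float] = Field(default_factory=lambda: [0, 18, 48, 96, 144, 192, 240])
    bootstrap_B: int = 1000
    strain: str = "synthetic"
    fe_setup_carbon_multiplier: float = 1.0

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def kinetic_params(self) -> KineticParams:
        return KineticParams(**self.params)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


def provenance(config: Optional[RunConfig] = None, seed: Optional[int] = None,
               inputs: Optional[list[str]] = None, **extra) -> dict:
    """Provenance record embedded in every output artifact."""
    rec = {"software": "nrfopart", "version": __version__}
    if config is not None:
        rec["config_hash"] = config.config_hash()
        rec["seed"] = config.seed
    if seed is not None:
        rec["seed"] = seed
    if inputs:
        rec["inputs"] = list(inputs)
    rec.update(extra)
    return rec
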