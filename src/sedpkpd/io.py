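"""Dataset file format, validation and run configuration.

Datasets are comma-delimited text with NONMEM-convention columns:

    ID, TIME, AMT, RATE, DV, CMT, EVID, MDV, BLQ, WT, PMA, PNA, SEX, ARM,
    SURG, TSURG

* ``EVID`` 1 marks dose records (AMT/RATE filled, DV missing); 0 marks
  observations (DV filled, AMT missing).
* ``CMT`` identifies the compartment / observation class: 1 = sedative
  central compartment, 2 = 1-OH midazolam metabolite, 3 = COMFORT-B score,
  4 = propofol (virtual K-PD compartment, dose records only).
* ``ARM`` is 'clonidine' or 'midazolam'; together with CMT it determines
  which residual-error model an observation belongs to.
* Time is hours from the first sedative dose of the subject; missing
  numerics are written as '.' (read back as NaN; empty cells also accepted).

Units follow the package convention: h, kg, ug, ug/h, ng/mL.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

COLUMNS = ["ID", "TIME", "AMT", "RATE", "DV", "CMT", "EVID", "MDV", "BLQ",
           "WT", "PMA", "PNA", "SEX", "ARM", "SURG", "TSURG"]

_NUMERIC = [c for c in COLUMNS if c not in ("ARM", "SEX")]

# compartment codes
CMT_CENTRAL = 1
CMT_METABOLITE = 2
CMT_SCORE = 3
CMT_PROPOFOL = 4

# observation-class codes (residual-error classes)
OBS_CLON_CONC = 0
OBS_MID_CONC = 1
OBS_M1_CONC = 2
OBS_SCORE = 3

ARMS = ("clonidine", "midazolam")


def observation_class(ds: pd.DataFrame) -> pd.Series:
    """Observation-class code per row (NaN on dose records)."""
    cls = pd.Series(np.nan, index=ds.index)
    obs = ds["EVID"] == 0
    cls[obs & (ds["CMT"] == CMT_CENTRAL) & (ds["ARM"] == "clonidine")] = OBS_CLON_CONC
    cls[obs & (ds["CMT"] == CMT_CENTRAL) & (ds["ARM"] == "midazolam")] = OBS_MID_CONC
    cls[obs & (ds["CMT"] == CMT_METABOLITE)] = OBS_M1_CONC
    cls[obs & (ds["CMT"] == CMT_SCORE)] = OBS_SCORE
    return cls


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_dataset(ds: pd.DataFrame) -> ValidationReport:
    """Structural checks: monotone times, orphan doses, known classes."""
    rep = ValidationReport()
    missing = [c for c in COLUMNS if c not in ds.columns]
    if missing:
        rep.errors.append(f"missing columns: {missing}")
        return rep
    for sid, grp in ds.groupby("ID", sort=False):
        t = grp["TIME"].to_numpy(float)
        if np.any(np.diff(t) < 0):
            rep.errors.append(f"subject {sid}: times not nondecreasing")
        if np.any(t < 0):
            rep.errors.append(f"subject {sid}: negative time")
        obs = grp[grp["EVID"] == 0]
        dose = grp[grp["EVID"] == 1]
        if obs.empty:
            rep.warnings.append(f"subject {sid}: no observations")
        if dose.empty and (observation_class(obs) != OBS_SCORE).any():
            rep.errors.append(f"subject {sid}: concentration observations "
                              f"without any dose record")
        if obs["AMT"].notna().any():
            rep.errors.append(f"subject {sid}: observation rows carry AMT")
        if dose["DV"].notna().any():
            rep.errors.append(f"subject {sid}: dose rows carry DV")
    bad_arm = ~ds["ARM"].isin(ARMS)
    if bad_arm.any():
        rep.errors.append(f"unknown ARM values: {sorted(ds.loc[bad_arm, 'ARM'].unique())}")
    obs_rows = ds["EVID"] == 0
    unknown = obs_rows & observation_class(ds).isna()
    if unknown.any():
        rep.errors.append(f"unknown observation class on rows {list(ds.index[unknown])}")
    return rep


def read_dataset(path, validate: bool = True):
    """Read a dataset file; returns (DataFrame, ValidationReport).

    Raises ``ValueError`` with the line number on malformed rows and on
    validation errors when ``validate`` is set.
    """
    path = Path(path)
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     skipinitialspace=True)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in _NUMERIC:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise ValueError(f"{path}: malformed numeric value in column {c} "
                             f"at line {line}") from None
    rep = validate_dataset(df)
    if validate and not rep.ok:
        raise ValueError(f"{path}: invalid dataset: " + "; ".join(rep.errors))
    return df, rep


def write_dataset(ds: pd.DataFrame, path) -> None:
    """Write a dataset with '.' for missing numerics (NONMEM dialect)."""
    out = ds[COLUMNS].copy()
    out.to_csv(path, index=False, na_rep=".")


@dataclass
class RunConfig:
    """Configuration of a pipeline run (paths, seeds, model settings)."""

    command: str = ""
    dataset: str | None = None
    output_dir: str = "results"
    seed: int = 1
    model: str = "clonidine_pk"
    n_resamples: int = 200
    n_sim: int = 200
    n_subjects: int = 28
    settings: dict = field(default_factory=dict)
    regimen: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        if not isinstance(cfg.seed, int) or cfg.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        return cfg

    def content_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
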