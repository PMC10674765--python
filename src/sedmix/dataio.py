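"""Longitudinal dataset container and NONMEM-style CSV dialect.

The single interchange object of the pipeline is :class:`LongitudinalDataset`:
an event table in the classic ``ID,TIME,AMT,DV,DVID,EVID,MDV`` layout plus a
per-subject covariate table.  Conventions:

* time in minutes since the (single) dose; dose amounts in ng; concentrations
  in ng/mL; BIS on its native 0-100 scale,
* ``EVID=1`` marks dose rows, ``EVID=0`` observation rows,
* ``DVID=1`` concentration observations, ``DVID=2`` BIS observations,
* ``MDV=1`` rows are carried through I/O but excluded from any likelihood
  (used for below-quantification-limit concentrations),
* missing cells are written as ``"."``.

Covariates (age group label, age, body weight, sex) are repeated on every row
of a subject when written to CSV (wide-in-long convention) and collapsed back
to one row per subject on reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import DataFormatError, ValidationError

__all__ = [
    "ObsType",
    "EventRow",
    "LongitudinalDataset",
    "read_dataset",
    "write_dataset",
    "load_config",
    "get_logger",
    "EVENT_COLUMNS",
    "COVARIATE_COLUMNS",
]

EVENT_COLUMNS = ["ID", "TIME", "AMT", "DV", "DVID", "EVID", "MDV"]
COVARIATE_COLUMNS = ["GROUP", "AGE", "WEIGHT", "SEX"]


class ObsType(IntEnum):
    """Observation type flag (the DVID column)."""

    CONC = 1
    BIS = 2


@dataclass(frozen=True)
class EventRow:
    """One dosing or observation event.

    Exactly one of ``amount`` (dose rows) and ``observation`` (observation
    rows) is present.
    """

    subject_id: str
    time: float
    amount: Optional[float] = None
    observation: Optional[float] = None
    obs_type: Optional[ObsType] = None
    mdv: bool = False

    @property
    def is_dose(self) -> bool:
        return self.amount is not None

    def __post_init__(self) -> None:
        if (self.amount is None) == (self.observation is None):
            raise ValidationError(
                f"subject {self.subject_id} t={self.time}: exactly one of amount/observation must be set"
            )
        if self.time < 0:
            raise ValidationError(f"subject {self.subject_id}: negative time {self.time}")
        if self.observation is not None:
            if self.obs_type is None:
                raise ValidationError(f"subject {self.subject_id}: observation without obs_type")
            _check_observation_range(self.observation, self.obs_type, f"subject {self.subject_id} t={self.time}")


def _check_observation_range(value: float, obs_type: ObsType, where: str) -> None:
    if obs_type == ObsType.BIS and not (0.0 <= value <= 100.0):
        raise ValidationError(f"{where}: BIS value {value} outside [0, 100]")
    if obs_type == ObsType.CONC and value < 0:
        raise ValidationError(f"{where}: negative concentration {value}")


class LongitudinalDataset:
    """Dose/observation events grouped by subject, plus subject covariates.

    Parameters
    ----------
    events : pandas.DataFrame
        Columns ``ID,TIME,AMT,DV,DVID,EVID,MDV``.  NaN encodes a missing cell.
    covariates : pandas.DataFrame, optional
        One row per subject; columns ``ID`` plus any of
        ``GROUP, AGE, WEIGHT, SEX``.
    """

    def __init__(self, events: pd.DataFrame, covariates: Optional[pd.DataFrame] = None, validate: bool = True):
        events = events.copy()
        missing = [c for c in EVENT_COLUMNS if c not in events.columns]
        if missing:
            raise DataFormatError(f"event table missing required column(s): {', '.join(missing)}")
        events = events[EVENT_COLUMNS].sort_values(["ID", "TIME", "EVID"], kind="stable", ascending=[True, True, False])
        events = events.reset_index(drop=True)
        self.events = events
        if covariates is None:
            covariates = pd.DataFrame({"ID": events["ID"].unique()})
        self.covariates = covariates.reset_index(drop=True)
        if validate:
            self.validate()

    # -- queries -----------------------------------------------------------
    @property
    def subject_ids(self) -> np.ndarray:
        return self.events["ID"].unique()

    @property
    def n_subjects(self) -> int:
        return int(self.events["ID"].nunique())

    def observations(self, obs_type: Optional[ObsType] = None, include_mdv: bool = False) -> pd.DataFrame:
        """Observation rows (EVID=0), optionally one DVID, excluding MDV=1 by default."""
        obs = self.events[self.events["EVID"] == 0]
        if not include_mdv:
            obs = obs[obs["MDV"] == 0]
        if obs_type is not None:
            obs = obs[obs["DVID"] == int(obs_type)]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.events[self.events["EVID"] == 1]

    def dose_per_subject(self) -> pd.Series:
        """Total dose (ng) per subject; the design has a single bolus."""
        return self.doses().groupby("ID")["AMT"].sum()

    def n_observations(self, obs_type: Optional[ObsType] = None) -> int:
        return len(self.observations(obs_type))

    def obs_counts(self) -> pd.Series:
        """Likelihood-contributing observation count per subject."""
        return self.observations().groupby("ID").size()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        ev = self.events
        for idx, row in ev.iterrows():
            is_dose = row["EVID"] == 1
            if row["TIME"] < 0:
                raise ValidationError(f"row {idx}: negative time {row['TIME']}")
            if is_dose:
                if pd.isna(row["AMT"]) or row["AMT"] <= 0:
                    raise ValidationError(f"row {idx}: dose row with missing or non-positive AMT")
            else:
                if pd.isna(row["DV"]) and row["MDV"] != 1:
                    raise ValidationError(f"row {idx}: observation row without DV must have MDV=1")
                if not pd.isna(row["DV"]):
                    if row["DVID"] not in (1, 2):
                        raise ValidationError(f"row {idx}: DVID must be 1 (CONC) or 2 (BIS)")
                    _check_observation_range(row["DV"], ObsType(int(row["DVID"])), f"row {idx}")
        doses = self.doses()
        for sid in self.subject_ids:
            sd = doses[doses["ID"] == sid]
            if len(sd) == 0:
                raise ValidationError(f"subject {sid} has no dose row")
            if not (sd["TIME"] == 0).any():
                raise ValidationError(f"subject {sid} has no dose at time 0")
        cov_ids = set(self.covariates["ID"])
        extra = set(self.subject_ids) - cov_ids
        if extra:
            raise ValidationError(f"subjects missing from covariate table: {sorted(extra)!r}")

    # -- equality (round-trip checks) -------------------------------------
    def equals(self, other: "LongitudinalDataset") -> bool:
        ev_a = self.events.reset_index(drop=True)
        ev_b = other.events.reset_index(drop=True)
        if not ev_a.equals(ev_b):
            return False
        cov_cols = ["ID"] + [c for c in COVARIATE_COLUMNS if c in self.covariates.columns]
        cov_cols_b = ["ID"] + [c for c in COVARIATE_COLUMNS if c in other.covariates.columns]
        if cov_cols != cov_cols_b:
            return False
        a = self.covariates[cov_cols].sort_values("ID").reset_index(drop=True)
        b = other.covariates[cov_cols_b].sort_values("ID").reset_index(drop=True)
        return a.equals(b)


_DEFAULT_DIALECT: Mapping[str, str] = {c: c for c in EVENT_COLUMNS}


def read_dataset(path, dialect: Optional[Mapping[str, str]] = None) -> LongitudinalDataset:
    """Read a NONMEM-style CSV into a validated :class:`LongitudinalDataset`.

    Parameters
    ----------
    path : path-like
    dialect : mapping, optional
        Maps canonical column names (``ID``, ``TIME``, ...) to the names used
        in the file; identity by default.
    """
    mapping = dict(_DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(path, na_values=["."], dtype={mapping["ID"]: str},
                     float_precision="round_trip")
    missing = [canon for canon, col in mapping.items() if col not in df.columns]
    if missing:
        raise DataFormatError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")
    rename = {col: canon for canon, col in mapping.items()}
    df = df.rename(columns=rename)
    for col in ("TIME", "AMT", "DV"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("DVID", "EVID", "MDV"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    cov_present = [c for c in COVARIATE_COLUMNS if c in df.columns]
    covariates = None
    if cov_present:
        covariates = df.groupby("ID", sort=True)[cov_present].first().reset_index()
    return LongitudinalDataset(df[EVENT_COLUMNS], covariates)


def write_dataset(ds: LongitudinalDataset, path) -> None:
    """Write the canonical CSV (``ID,TIME,AMT,DV,DVID,EVID,MDV`` + covariates).

    Missing cells are encoded as ``"."``; floats are written with ``repr``
    precision so that :func:`read_dataset` inverts the write bit-exactly.
    """
    path = Path(path)
    out = ds.events.copy()
    cov_cols = [c for c in COVARIATE_COLUMNS if c in ds.covariates.columns]
    if cov_cols:
        out = out.merge(ds.covariates[["ID"] + cov_cols], on="ID", how="left")
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep=".")


def load_config(path) -> dict:
    """Load a (possibly nested) key-value configuration file (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


_LOG_FORMAT = "%(asctime)s %(levelname)s [%(name)s] %(message)s"


def get_logger(name: str) -> logging.Logger:
    """Module-tagged logger with timestamped, level-prefixed lines."""
    logger = logging.getLogger(f"sedmix.{name}")
    if not logging.getLogger("sedmix").handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        root = logging.getLogger("sedmix")
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logger
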