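"""Reading and writing the NONMEM-style rectangular dosing/observation CSV.

Columns: ``ID, TIME, AMT, RATE, EVID, DV, MDV, WT, SEX, CRCL``.

Semantics follow the usual population-PK conventions: ``EVID == 1`` rows are
zero-order infusion doses (``AMT`` mg at rate ``RATE`` mg/h, so the duration
is ``AMT / RATE``); ``EVID == 0`` rows are observations with ``DV`` the
natural-log plasma concentration (mg/l) unless ``MDV == 1``. ``SEX`` is coded
0 = male, 1 = female. Covariates (``WT``, ``SEX``, ``CRCL``) are constant
within a subject.

Because ``DV`` carries log-scale values, each written dataset gets a small
JSON sidecar (``<file>.meta.json``) recording the DV scale and units so the
file is self-describing; the reader checks it when present.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pbpk_core import DoseEvent
from .physiology import Individual

__all__ = ["COLUMNS", "Subject", "read_dataset", "write_dataset",
           "subjects_to_frame", "frame_to_subjects"]

COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "MDV", "WT", "SEX", "CRCL"]
SEX_CODES = {0: "male", 1: "female"}
SEX_TO_CODE = {v: k for k, v in SEX_CODES.items()}


@dataclass
class Subject:
    """One subject's covariates, dosing history and log-scale observations."""

    individual: Individual
    doses: list[DoseEvent]
    obs_times: np.ndarray
    dv: np.ndarray  # natural-log plasma concentration

    def __post_init__(self) -> None:
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        if self.obs_times.shape != self.dv.shape:
            raise ValueError("obs_times and dv must have matching shapes")
        order = np.argsort(self.obs_times, kind="stable")
        self.obs_times = self.obs_times[order]
        self.dv = self.dv[order]

    @property
    def n_obs(self) -> int:
        return int(self.obs_times.size)


def subjects_to_frame(subjects: list[Subject]) -> pd.DataFrame:
    """Flatten subjects into the rectangular dataset layout."""
    rows = []
    for s in subjects:
        ind = s.individual
        sex = SEX_TO_CODE[ind.sex]
        for d in s.doses:
            rows.append((s.individual.id, d.t_start, d.amount, d.rate, 1,
                         np.nan, 1, ind.weight, sex, ind.crcl))
        for t, y in zip(s.obs_times, s.dv):
            rows.append((s.individual.id, t, 0.0, 0.0, 0, y, 0,
                         ind.weight, sex, ind.crcl))
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(["ID", "TIME", "EVID"], kind="stable",
                          ascending=[True, True, False]).reset_index(drop=True)


def frame_to_subjects(df: pd.DataFrame) -> list[Subject]:
    """Parse a rectangular dataset into :class:`Subject` records."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    subjects = []
    for sid, grp in df.groupby("ID", sort=True):
        wt = float(grp["WT"].iloc[0])
        sex_code = int(grp["SEX"].iloc[0])
        if sex_code not in SEX_CODES:
            raise ValueError(f"subject {sid!r}: unknown SEX code {sex_code}")
        ind = Individual(id=str(sid), weight=wt, sex=SEX_CODES[sex_code],
                         crcl=float(grp["CRCL"].iloc[0]))
        doses = []
        for _, row in grp[grp["EVID"] == 1].iterrows():
            amt, rate = float(row["AMT"]), float(row["RATE"])
            if amt <= 0 or rate <= 0:
                raise ValueError(f"subject {sid!r}: dose row needs AMT > 0 and RATE > 0")
            doses.append(DoseEvent(amount=amt, t_start=float(row["TIME"]),
                                   duration=amt / rate))
        obs = grp[(grp["EVID"] == 0) & (grp["MDV"] == 0)]
        subjects.append(Subject(
            individual=ind, doses=doses,
            obs_times=obs["TIME"].to_numpy(dtype=float),
            dv=obs["DV"].to_numpy(dtype=float),
        ))
    return subjects


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_dataset(data: list[Subject] | pd.DataFrame, path: str | Path) -> Path:
    """Write the dataset CSV plus its metadata sidecar; returns the CSV path."""
    path = Path(path)
    df = data if isinstance(data, pd.DataFrame) else subjects_to_frame(data)
    df.to_csv(path, index=False, float_format="%.17g")  # lossless round-trip
    meta = {"dv_scale": "natural_log", "dv_units": "mg/l",
            "time_units": "h", "sex_codes": {str(k): v for k, v in SEX_CODES.items()}}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1), encoding="utf-8")
    return path


def read_dataset(path: str | Path, as_frame: bool = False):
    """Read a dataset CSV; returns subjects (default) or the raw frame."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        if meta.get("dv_scale") not in (None, "natural_log"):
            raise ValueError(
                f"dataset {path.name} declares DV scale {meta['dv_scale']!r}; "
                "this reader expects natural-log concentrations"
            )
    return df if as_frame else frame_to_subjects(df)
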