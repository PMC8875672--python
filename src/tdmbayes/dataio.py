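"""Read and write NONMEM-style TDM datasets.

A dataset is a CSV with columns ID, TIME, EVID, AMT, CMT, RATE, II, ADDL,
DV, WT, HT, AGE, SEX, SCR (header case-insensitive). Missing numeric cells
are "." or empty. SEX is coded 0 = male, 1 = female. Within a patient, rows
are ordered by time with doses before same-time observations (an
observation at a dose time sees the post-dose-start concentration).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import PatientCovariates
from .pkmodels import EventRecord
from .priors import DRUGS, UnsupportedDrugError, get_default_prior

__all__ = [
    "REQUIRED_COLUMNS",
    "TDMDataset",
    "DatasetSchemaError",
    "read_dataset",
    "write_dataset",
    "get_sample_data",
]

REQUIRED_COLUMNS = ["ID", "TIME", "EVID", "AMT", "CMT", "RATE", "II", "ADDL",
                    "DV", "WT", "HT", "AGE", "SEX", "SCR"]


class DatasetSchemaError(ValueError):
    """The file does not conform to the dataset schema."""


@dataclass
class TDMDataset:
    """Per-patient covariates and event records for one drug."""

    drug: str
    covariates: dict[int, PatientCovariates] = field(default_factory=dict)
    events: dict[int, list[EventRecord]] = field(default_factory=dict)

    @property
    def ids(self) -> list[int]:
        return list(self.events)

    def patient(self, pid: int) -> "TDMDataset":
        """Single-patient view."""
        return TDMDataset(self.drug, {pid: self.covariates[pid]},
                          {pid: self.events[pid]})

    def single(self) -> tuple[PatientCovariates, list[EventRecord]]:
        """Covariates and events of the only patient in the dataset."""
        if len(self.events) != 1:
            raise ValueError(f"expected exactly one patient, found {len(self.events)}")
        pid = next(iter(self.events))
        return self.covariates[pid], self.events[pid]

    def observations(self, pid: int) -> tuple[np.ndarray, np.ndarray]:
        obs = [(ev.time, ev.dv) for ev in self.events[pid] if ev.evid == 0]
        if not obs:
            return np.empty(0), np.empty(0)
        t, dv = zip(*obs)
        return np.asarray(t, float), np.asarray(dv, float)

    def validate(self) -> None:
        for pid, evs in self.events.items():
            if pid not in self.covariates:
                raise DatasetSchemaError(f"patient {pid}: missing covariates")
            if not any(ev.evid == 1 for ev in evs):
                raise DatasetSchemaError(f"patient {pid}: no dose rows")
            for ev in evs:
                if ev.evid == 0 and ev.dv is None:
                    raise DatasetSchemaError(
                        f"patient {pid}: observation at t={ev.time} without DV")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TDMDataset):
            return NotImplemented
        return (self.drug == other.drug and self.covariates == other.covariates
                and self.events == other.events)


_SEX_CODE = {0: "male", 1: "female"}
_SEX_NAME = {"male": 0, "female": 1}


def _num(row, col):
    v = row[col]
    return None if pd.isna(v) else float(v)


def read_dataset(path, drug: str) -> TDMDataset:
    """Parse a dataset CSV. Raises DatasetSchemaError / ValueError on
    malformed input, naming the offending column or row."""
    prior = get_default_prior(drug)  # validates the drug name
    df = pd.read_csv(path, na_values=["."], skipinitialspace=True,
                     float_precision="round_trip")
    df.columns = [str(c).strip().upper() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetSchemaError(f"missing required column(s): {', '.join(missing)}")

    ds = TDMDataset(drug=prior.drug)
    for i, row in df.iterrows():
        rowno = i + 2  # 1-based with header
        evid = row["EVID"]
        if pd.isna(evid) or int(evid) not in (0, 1):
            raise ValueError(f"row {rowno}: EVID must be 0 or 1, got {evid!r}")
        evid = int(evid)
        pid = int(row["ID"])
        time = float(row["TIME"])
        amt = _num(row, "AMT")
        if evid == 1 and (amt is None or amt <= 0):
            raise ValueError(f"row {rowno}: dose row requires AMT > 0")
        if pid not in ds.covariates:
            sex_raw = row["SEX"]
            if pd.isna(sex_raw) or int(sex_raw) not in _SEX_CODE:
                raise ValueError(
                    f"row {rowno}: SEX must be 0 (male) or 1 (female), got {sex_raw!r}")
            ds.covariates[pid] = PatientCovariates(
                weight=float(row["WT"]), height=float(row["HT"]),
                age=float(row["AGE"]), sex=_SEX_CODE[int(sex_raw)],
                scr=float(row["SCR"]))
            ds.events[pid] = []
        try:
            ev = EventRecord(
                id=pid, time=time, evid=evid,
                amt=amt if evid == 1 else None,
                cmt=int(row["CMT"]) if not pd.isna(row["CMT"]) else 1,
                rate=_num(row, "RATE") or 0.0,
                ii=_num(row, "II") or 0.0,
                addl=int(row["ADDL"]) if not pd.isna(row["ADDL"]) else 0,
                dv=_num(row, "DV") if evid == 0 else None)
        except ValueError as exc:
            raise ValueError(f"row {rowno}: {exc}") from exc
        ds.events[pid].append(ev)
    for pid in ds.events:
        # doses precede same-time observations
        ds.events[pid].sort(key=lambda ev: (ev.time, -ev.evid))
    ds.validate()
    return ds


def _fmt(x) -> str:
    if x is None:
        return "."
    return format(float(x), ".17g")


def write_dataset(ds: TDMDataset, path) -> None:
    """Write a dataset CSV that ``read_dataset`` parses back bit-exactly."""
    lines = [",".join(REQUIRED_COLUMNS)]
    for pid in ds.events:
        cov = ds.covariates[pid]
        for ev in sorted(ds.events[pid], key=lambda e: (e.time, -e.evid)):
            lines.append(",".join([
                str(pid), _fmt(ev.time), str(ev.evid), _fmt(ev.amt), str(ev.cmt),
                _fmt(ev.rate), _fmt(ev.ii), str(ev.addl), _fmt(ev.dv),
                _fmt(cov.weight), _fmt(cov.height), _fmt(cov.age),
                str(_SEX_NAME[cov.sex]), _fmt(cov.scr)]))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# packaged examples
# ---------------------------------------------------------------------------

# Regimens for the supported drugs: amount (mg), infusion / zero-order input
# rate (mg/h; 0 = oral bolus), dosing interval (h), and the default
# peak/trough sampling times within an interval.
SAMPLE_REGIMENS = {
    "amikacin": dict(amt=500.0, rate=1000.0, ii=8.0, peak=1.0, trough=8.0),
    "vancomycin": dict(amt=1000.0, rate=500.0, ii=12.0, peak=2.0, trough=12.0),
    "theophylline": dict(amt=200.0, rate=0.0, ii=12.0, peak=4.0, trough=12.0),
    "phenytoin": dict(amt=100.0, rate=50.0, ii=8.0, peak=2.0, trough=8.0),
}

# Plausible peak/trough observations (mg/L) after the first dose for a
# typical 65 kg adult, precomputed from the prior typical values and rounded.
_SAMPLE_DV = {
    "amikacin": (30.5, 6.8),
    "vancomycin": (39.6, 10.3),
    "theophylline": (4.2, 3.8),
    "phenytoin": (1.6, 1.1),
}


def get_sample_data(drug: str) -> TDMDataset:
    """Small packaged single-patient dataset for the drug's label regimen."""
    key = str(drug).strip().lower()
    if key not in SAMPLE_REGIMENS:
        raise UnsupportedDrugError(drug)
    reg = SAMPLE_REGIMENS[key]
    peak_dv, trough_dv = _SAMPLE_DV[key]
    cov = PatientCovariates(weight=65.1, height=165.1, age=50.2, sex="male", scr=1.1)
    events = [
        EventRecord(id=1, time=0.0, evid=1, amt=reg["amt"], rate=reg["rate"],
                    ii=reg["ii"], addl=0),
        EventRecord(id=1, time=reg["peak"], evid=0, dv=peak_dv),
        EventRecord(id=1, time=reg["trough"], evid=0, dv=trough_dv),
    ]
    return TDMDataset(drug=key, covariates={1: cov}, events={1: events})
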