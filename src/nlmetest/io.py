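"""Flat-table cohort round-tripping.

The on-disk convention is a NONMEM-style dataset: one row per observation
with columns ID, TIME, DV, TRT, BMMS (order free, names case-insensitive),
either comma- or whitespace-delimited. Rows with missing DV are not
emitted. The round trip is lossless for these five fields.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Subject, Visit

REQUIRED = ("ID", "TIME", "DV", "TRT", "BMMS")

__all__ = ["read_cohort", "write_cohort", "cohort_to_frame",
           "cohort_from_frame"]


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for s in cohort.subjects:
        for v in s.visits:
            if v.score is None or (isinstance(v.score, float)
                                   and np.isnan(v.score)):
                continue
            rows.append((s.id, v.time, v.score, s.trt, s.bmms))
    return pd.DataFrame(rows, columns=list(REQUIRED))


def cohort_from_frame(df: pd.DataFrame, provenance: str = "file") -> Cohort:
    upper = {c.upper(): c for c in df.columns}
    missing = [c for c in REQUIRED if c not in upper]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={upper[c]: c for c in REQUIRED})[list(REQUIRED)]
    for col in REQUIRED:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in column {col}: {exc}") from exc
    bad_trt = sorted(set(df["TRT"].unique()) - {0, 1})
    if bad_trt:
        raise ValueError(f"TRT must be 0 or 1; found {bad_trt}")
    dup = df.duplicated(subset=["ID", "TIME"])
    if dup.any():
        i = int(np.flatnonzero(dup.values)[0])
        raise ValueError(
            f"duplicate (ID, TIME) at data row {i + 1}: "
            f"ID={df['ID'].iloc[i]:g}, TIME={df['TIME'].iloc[i]:g}")
    subjects = []
    for sid, grp in df.groupby("ID", sort=False):
        grp = grp.sort_values("TIME", kind="stable")
        trt_vals = grp["TRT"].unique()
        if len(trt_vals) > 1:
            raise ValueError(f"subject {sid:g} has inconsistent TRT values")
        visits = [Visit(float(t), float(dv))
                  for t, dv in zip(grp["TIME"], grp["DV"])]
        subjects.append(Subject(id=int(sid), bmms=float(grp["BMMS"].iloc[0]),
                                trt=int(trt_vals[0]), visits=visits,
                                truth=None))
    cohort = Cohort(subjects=subjects,
                    meta={"provenance": provenance,
                          "allocated": bool((df["TRT"] == 1).any())})
    cohort.validate()
    return cohort


def write_cohort(cohort: Cohort, path, sep: str = ",") -> None:
    df = cohort_to_frame(cohort)
    df.to_csv(path, index=False, sep="," if sep == "," else " ")


def read_cohort(path) -> Cohort:
    """Read a cohort table; the delimiter (comma vs whitespace) is sniffed
    from the header line."""
    text = Path(path).read_text()
    header = text.lstrip().splitlines()[0] if text.strip() else ""
    if not header:
        raise ValueError(f"{path}: empty file")
    sep = "," if "," in header else r"\s+"
    df = pd.read_csv(_io.StringIO(text), sep=sep)
    return cohort_from_frame(df)
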