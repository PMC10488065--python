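"""Plain-CSV interchange for cohort tables, traces and endpoint bundles.

The cohort CSV has one row per patient (booleans as 0/1, categorical
levels as literal strings, the postoperative creatinine series encoded
as ``hours:value`` pairs joined by ``;``).  Traces use a long format
(patient_id, t_s, map_mmHg, hpi_index with empty cells for cases
without an index channel).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from twamatch.cohort import PatientRecord, VitalTrace
from twamatch.hemodynamics import HypotensionSummary

_BOOL_COLS = (
    "sex_male",
    "emergency",
    "chf",
    "copd",
    "diabetes",
    "hypertension",
    "ace_inhibitor",
    "beta_blocker",
    "ccb",
    "diuretic",
    "at1_antagonist",
    "epidural",
)


def encode_creatinine_series(series: Sequence[tuple[float, float]]) -> str:
    return ";".join(f"{h:g}:{v:.6g}" for h, v in series)


def parse_creatinine_series(text: str) -> list[tuple[float, float]]:
    if not text or (isinstance(text, float) and np.isnan(text)):
        return []
    out = []
    for item in str(text).split(";"):
        h, v = item.split(":")
        out.append((float(h), float(v)))
    return out


def cohort_to_dataframe(records: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {k: v for k, v in r.__dict__.items() if k != "postop_creatinine_series"}
        d["postop_creatinine_series"] = encode_creatinine_series(
            r.postop_creatinine_series
        )
        rows.append(d)
    df = pd.DataFrame(rows).set_index("patient_id")
    for col in _BOOL_COLS:
        df[col] = df[col].astype(int)
    return df


def write_cohort_csv(records_or_df, path: str | Path) -> None:
    df = (
        records_or_df
        if isinstance(records_or_df, pd.DataFrame)
        else cohort_to_dataframe(records_or_df)
    )
    df.to_csv(path)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="patient_id", dtype={"patient_id": str})
    df.index = df.index.astype(str)
    df["postop_creatinine_series"] = df["postop_creatinine_series"].fillna("")
    return df


def traces_to_dataframe(traces: Sequence[VitalTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": tr.patient_id,
                    "t_s": tr.t,
                    "map_mmHg": tr.map_mmHg,
                    "hpi_index": tr.hpi_index if tr.hpi_index is not None else np.nan,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_traces_csv(traces: Sequence[VitalTrace], path: str | Path) -> None:
    traces_to_dataframe(traces).to_csv(path, index=False, float_format="%.6g")


def read_traces_csv(path: str | Path) -> list[VitalTrace]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    traces = []
    for pid, grp in df.groupby("patient_id", sort=True):
        grp = grp.sort_values("t_s")
        idx = grp["hpi_index"].to_numpy()
        traces.append(
            VitalTrace(
                patient_id=str(pid),
                t=grp["t_s"].to_numpy(),
                map_mmHg=grp["map_mmHg"].to_numpy(),
                hpi_index=None if np.isnan(idx).all() else idx,
            )
        )
    return traces


def summaries_to_dataframe(summaries: Sequence[HypotensionSummary]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in summaries]).set_index("patient_id")
    return df


def write_summaries_csv(summaries, path: str | Path) -> None:
    df = (
        summaries
        if isinstance(summaries, pd.DataFrame)
        else summaries_to_dataframe(summaries)
    )
    df.to_csv(path)


def read_summaries_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="patient_id")
    df.index = df.index.astype(str)
    return df
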