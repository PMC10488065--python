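"""End-to-end orchestration: simulate -> metrics -> match -> compare.

One config and one seed reproduce the whole run byte-for-byte.  Each
stage writes its interchange CSVs into the output directory and the run
closes with a JSON manifest recording the configuration hash, cohort and
matching counts, the post-matching balance, and per-group endpoint
summaries.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from twamatch.cohort import GROUP_TREATED, generate_cohort
from twamatch.config import SimConfig
from twamatch.errors import TwamatchError
from twamatch.hemodynamics import EventParams, summarize_patient
from twamatch.io import (
    cohort_to_dataframe,
    parse_creatinine_series,
    summaries_to_dataframe,
    write_cohort_csv,
    write_summaries_csv,
    write_traces_csv,
)
from twamatch.outcomes import build_comparison_table, classify_aki, comparison_rows_to_frame
from twamatch.psm import (
    MATCHING_COVARIATES,
    MatchResult,
    balance_table,
    build_design_matrix,
    fit_propensity,
    match_caliper,
)

ENDPOINT_FIELDS = ("twa_65", "twa_60", "twa_55", "n_events_65", "cum_duration_65_min")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    n_total: int
    n_treated: int
    n_matched_pairs: int
    caliper: float
    max_abs_smd_after: float
    endpoint_summary: dict
    software_version: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def compute_summaries(traces, event_params: EventParams = EventParams()) -> pd.DataFrame:
    return summaries_to_dataframe(
        [summarize_patient(tr, event_params) for tr in traces]
    )


def match_cohort(
    cohort: pd.DataFrame,
    caliper_sd: float = 0.1,
    covariates: Sequence[str] = MATCHING_COVARIATES,
) -> MatchResult:
    """Fit the propensity model on the cohort table and match 1:1.

    Attaches before/after balance tables computed on the raw covariate
    columns (multi-level categoricals expanded per level).
    """
    treated = (cohort["group"] == GROUP_TREATED).to_numpy()
    X = build_design_matrix(cohort, covariates)
    model = fit_propensity(X, treated)
    result = match_caliper(model, treated, caliper_sd=caliper_sd, ids=cohort.index)
    bal_cov = cohort[list(covariates)]
    result.balance_before = balance_table(bal_cov, treated)
    result.balance_after = balance_table(bal_cov, treated, pairs=result.pairs)
    return result


def _endpoint_summary(cohort: pd.DataFrame, summaries: pd.DataFrame, ids) -> dict:
    sub = summaries.loc[list(ids)]
    groups = cohort.loc[list(ids), "group"]
    out: dict = {}
    for label, grp in sub.groupby(groups):
        stats = {}
        for fieldname in ENDPOINT_FIELDS:
            q1, med, q3 = np.percentile(grp[fieldname].astype(float), [25, 50, 75])
            stats[fieldname] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
        alarms = grp["n_alarms_ge85"].dropna()
        if len(alarms):
            q1, med, q3 = np.percentile(alarms.astype(float), [25, 50, 75])
            stats["n_alarms_ge85"] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
        out[str(label)] = stats
    return out


def add_aki_column(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach the AKI classification derived from the creatinine series."""
    cohort = cohort.copy()
    flags = []
    for pid, row in cohort.iterrows():
        series = parse_creatinine_series(row["postop_creatinine_series"])
        flags.append(classify_aki(row["preop_creatinine"], series, patient_id=str(pid)).aki)
    cohort["aki"] = np.asarray(flags, dtype=int)
    return cohort


def run_all(
    config: SimConfig | str | Path,
    seed: Optional[int] = None,
    out_dir: str | Path = "twamatch_run",
    caliper_sd: float = 0.1,
    event_params: EventParams = EventParams(),
) -> RunManifest:
    """Execute the four stages in order and write all artifacts.

    Any stage failure removes the partial outputs and re-raises with a
    stage label.  Identical config + seed reproduce identical outputs.
    """
    from twamatch import __version__

    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    if seed is not None:
        config = config.replace(seed=int(seed))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "simulate"
    try:
        records, traces = generate_cohort(config)
        cohort = add_aki_column(cohort_to_dataframe(records))
        _write("cohort.csv", lambda p: write_cohort_csv(cohort, p))
        _write("traces.csv", lambda p: write_traces_csv(traces, p))

        stage = "metrics"
        summaries = compute_summaries(traces, event_params)
        _write("endpoints.csv", lambda p: write_summaries_csv(summaries, p))

        stage = "match"
        match = match_cohort(cohort, caliper_sd=caliper_sd)
        pairs_df = pd.DataFrame(match.pairs, columns=["treated_id", "control_id"])
        pairs_df["score_t"] = [match.scores[t] for t, _ in match.pairs]
        pairs_df["score_c"] = [match.scores[c] for _, c in match.pairs]
        _write("pairs.csv", lambda p: pairs_df.to_csv(p, index=False))
        bal = match.balance_before.table.rename(columns={"smd": "smd_before"})[
            ["smd_before"]
        ].join(match.balance_after.table.rename(columns={"smd": "smd_after"})[["smd_after"]])
        _write("balance.csv", lambda p: bal.to_csv(p))

        stage = "compare"
        variables = list(MATCHING_COVARIATES) + ["aki"]
        rows_un = build_comparison_table(cohort, variables=variables)
        matched_ids = match.matched_ids()
        rows_m = build_comparison_table(cohort, variables=variables, matched_ids=matched_ids)
        _write(
            "comparison_unmatched.csv",
            lambda p: comparison_rows_to_frame(rows_un).to_csv(p, index=False),
        )
        _write(
            "comparison_matched.csv",
            lambda p: comparison_rows_to_frame(rows_m).to_csv(p, index=False),
        )
        endo = summaries.join(cohort[["group"]])
        rows_endo = build_comparison_table(
            endo,
            variables=list(ENDPOINT_FIELDS),
            matched_ids=matched_ids,
        )
        _write(
            "endpoints_matched.csv",
            lambda p: comparison_rows_to_frame(rows_endo).to_csv(p, index=False),
        )

        manifest = RunManifest(
            config_hash=config.config_hash(),
            seed=config.seed,
            n_total=len(cohort),
            n_treated=int((cohort["group"] == GROUP_TREATED).sum()),
            n_matched_pairs=match.n_pairs,
            caliper=caliper_sd,
            max_abs_smd_after=match.balance_after.max_abs_smd,
            endpoint_summary=_endpoint_summary(cohort, summaries, matched_ids),
            software_version=__version__,
        )
        _write("manifest.json", lambda p: p.write_text(manifest.to_json()))
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise TwamatchError(f"[stage: {stage}] {exc}") from exc
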