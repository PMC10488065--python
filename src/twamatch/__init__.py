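"""Propensity-score-matched evaluation of intraoperative hypotension burden.

The package covers the full analysis chain used in observational studies of
advanced hemodynamic monitoring: per-patient hypotension endpoints computed
from fixed-interval mean-arterial-pressure (MAP) series (time-weighted
average of the MAP deficit below a threshold, episode counts, cumulative
duration, alarm counts), greedy 1:1 caliper propensity-score matching with
standardized-mean-difference balance diagnostics, normality-gated two-sample
comparison tables, a creatinine-based acute-kidney-injury classifier, and a
synthetic cohort generator that reproduces the confounding structure such
studies must remove (emergency status, epidural use, case duration and ASA
class all driving the choice of monitoring).
"""

from twamatch.config import SimConfig
from twamatch.cohort import (
    PatientRecord,
    VitalTrace,
    generate_cohort,
    generate_creatinine_series,
    generate_map_trace,
)
from twamatch.hemodynamics import (
    EventParams,
    HypotensionSummary,
    count_alarms,
    cumulative_duration_below,
    detect_episodes,
    prevented_events,
    summarize_patient,
    twa_below,
)
from twamatch.psm import (
    BalanceTable,
    MatchResult,
    PropensityModel,
    balance_table,
    fit_propensity,
    match_caliper,
    smd_binary,
    smd_continuous,
)
from twamatch.outcomes import (
    AKIOutcome,
    ComparisonRow,
    build_comparison_table,
    choose_test,
    classify_aki,
    exact_count_test,
    rank_sum_test,
)
from twamatch.pipeline import RunManifest, run_all

__version__ = "0.1.0"

__all__ = [
    "SimConfig",
    "PatientRecord",
    "VitalTrace",
    "generate_cohort",
    "generate_creatinine_series",
    "generate_map_trace",
    "EventParams",
    "HypotensionSummary",
    "count_alarms",
    "cumulative_duration_below",
    "detect_episodes",
    "prevented_events",
    "summarize_patient",
    "twa_below",
    "BalanceTable",
    "MatchResult",
    "PropensityModel",
    "balance_table",
    "fit_propensity",
    "match_caliper",
    "smd_binary",
    "smd_continuous",
    "AKIOutcome",
    "ComparisonRow",
    "build_comparison_table",
    "choose_test",
    "classify_aki",
    "exact_count_test",
    "rank_sum_test",
    "RunManifest",
    "run_all",
]
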