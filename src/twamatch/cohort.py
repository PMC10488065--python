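"""Synthetic perioperative cohort generator.

Emulates the data structure of a single-center registry of major
non-cardiac surgery under invasive arterial monitoring: a covariate table
(demographics, ASA physical status, comorbidities, antihypertensive
medication, surgical covariates), a confounded assignment of each case to
predictive ("HPI") or standard ("non-HPI") monitoring, a fixed-interval
MAP trace per case with stochastic hypotensive episodes, an alarm-index
channel for the treated arm, and a postoperative creatinine trajectory
tied to the realized hypotension burden.

Group assignment is Bernoulli on a logistic linear predictor over the
covariates, so that emergency cases end up predominantly in the standard
arm while epidural and long elective cases favor the predictive arm —
exactly the selection pattern a propensity analysis must remove.  The
treatment effect is mechanistic, not assigned post hoc: the treated arm's
episode process runs at a reduced rate and duration, and each incipient
episode is independently averted (alarm recorded, no MAP dip) with a
configurable probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit, logit

from twamatch.config import SimConfig
from twamatch.errors import DegenerateCohortError, TraceValidationError

GROUP_TREATED = "HPI"
GROUP_CONTROL = "non-HPI"

SURGICAL_APPROACHES = ("laparoscopy", "laparotomy", "combined", "other")

#: Alarm-index runs are planted at this level (above the alarm threshold
#: of 85); background index noise is kept strictly below the threshold.
_ALARM_INDEX_LEVEL = 92.0
_INDEX_BACKGROUND_MAX = 80.0


@dataclass
class PatientRecord:
    """One row of the cohort table: covariates, group label, outcomes."""

    patient_id: str
    age: float
    sex_male: bool
    bsa: float
    bmi: float
    asa_class: int
    emergency: bool
    chf: bool
    copd: bool
    diabetes: bool
    hypertension: bool
    ace_inhibitor: bool
    beta_blocker: bool
    ccb: bool
    diuretic: bool
    at1_antagonist: bool
    preop_hb: float
    preop_creatinine: float
    surgical_approach: str
    duration_min: float
    epidural: bool
    map_induction: float
    hr_induction: float
    spo2_induction: float
    group: str
    postop_creatinine_series: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.asa_class not in (2, 3, 4):
            raise ValueError("asa_class must be 2, 3 or 4")
        if self.duration_min <= 30:
            raise ValueError("duration_min must exceed 30 (inclusion rule)")
        if self.preop_creatinine <= 0:
            raise ValueError("creatinine must be positive")
        if self.surgical_approach not in SURGICAL_APPROACHES:
            raise ValueError(f"unknown surgical approach {self.surgical_approach!r}")
        if self.group not in (GROUP_TREATED, GROUP_CONTROL):
            raise ValueError(f"unknown group label {self.group!r}")


@dataclass
class VitalTrace:
    """Fixed-interval MAP (and optional alarm-index) series for one case.

    ``t`` holds seconds from the start of invasive monitoring, uniformly
    spaced; ``hpi_index`` is present only for cases under predictive
    monitoring and lives on the same time grid.
    """

    patient_id: str
    t: np.ndarray
    map_mmHg: np.ndarray
    hpi_index: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.map_mmHg = np.asarray(self.map_mmHg, dtype=float)
        if self.hpi_index is not None:
            self.hpi_index = np.asarray(self.hpi_index, dtype=float)
        self.validate()

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def monitoring_time_min(self) -> float:
        """Full trace span, first to last sample plus one interval."""
        return (len(self.t) * self.dt) / 60.0

    def validate(self) -> None:
        if self.t.size < 2:
            raise TraceValidationError("trace must contain at least two samples")
        if self.map_mmHg.shape != self.t.shape:
            raise TraceValidationError("t and map_mmHg lengths differ")
        if self.hpi_index is not None and self.hpi_index.shape != self.t.shape:
            raise TraceValidationError("hpi_index length differs from t")
        deltas = np.diff(self.t)
        if not np.all(deltas > 0):
            raise TraceValidationError("t must be strictly increasing")
        if not np.allclose(deltas, deltas[0], rtol=0, atol=1e-6):
            raise TraceValidationError("t must be uniformly spaced")
        if not np.all(np.isfinite(self.map_mmHg)):
            raise TraceValidationError("map_mmHg must be finite")
        if self.map_mmHg.min() < 20 or self.map_mmHg.max() > 200:
            raise TraceValidationError("map_mmHg outside physiological range [20, 200]")


def generate_map_trace(
    duration_min: float,
    baseline: float,
    episodes: Sequence[tuple[float, float, float]],
    interval_s: float,
    noise_sd: float,
    rng: np.random.Generator,
    *,
    drift_amplitude: float = 0.0,
    ramp_s: float = 30.0,
    patient_id: str = "trace",
) -> VitalTrace:
    """Synthesize one MAP trace: baseline + slow drift + noise − episodes.

    Each episode ``(start_s, duration_s, depth_mmHg)`` subtracts a
    flat-topped deficit with raised-cosine onset and offset ramps inside
    its window.  Overlapping episodes are merged by taking the deepest
    per-sample deficit.  The result is clipped to [20, 200] mmHg.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    duration_s = duration_min * 60.0
    n = max(2, int(round(duration_s / interval_s)))
    t = np.arange(n) * interval_s

    values = np.full(n, baseline, dtype=float)
    if drift_amplitude > 0:
        # two incommensurate slow sinusoids; periods 25-70 min
        for _ in range(2):
            period = rng.uniform(25.0, 70.0) * 60.0
            phase = rng.uniform(0, 2 * np.pi)
            values += (drift_amplitude / 2.0) * np.sin(2 * np.pi * t / period + phase)
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=n)

    deficit = np.zeros(n)
    for start_s, dur_s, depth in episodes:
        if depth <= 0:
            raise ValueError("episode depth must be positive")
        if start_s < 0 or start_s + dur_s > duration_s + interval_s:
            raise ValueError("episode extends outside the monitored window")
        u = t - start_s
        w = np.zeros(n)
        inside = (u >= 0) & (u <= dur_s)
        r = min(ramp_s, dur_s / 2.0)
        ui = u[inside]
        wi = np.ones(ui.size)
        if r > 0:
            onset = ui < r
            offset = ui > dur_s - r
            wi[onset] = 0.5 * (1 - np.cos(np.pi * ui[onset] / r))
            wi[offset] = 0.5 * (1 - np.cos(np.pi * (dur_s - ui[offset]) / r))
        w[inside] = wi
        deficit = np.maximum(deficit, depth * w)  # deepest episode wins per sample

    values = np.clip(values - deficit, 20.0, 200.0)
    return VitalTrace(patient_id=patient_id, t=t, map_mmHg=values)


def generate_creatinine_series(
    record: PatientRecord,
    twa65: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Draw a postoperative creatinine trajectory (one value per 24 h, 7 d).

    The AKI event indicator is Bernoulli with probability
    ``expit(logit(aki_base_prob) + aki_twa_slope * twa65)``.  When AKI is
    drawn the series contains a rise of more than 0.3 mg/dL above
    baseline within 48 h; otherwise every value stays below both the
    absolute-rise and the 1.5x-baseline criterion.
    """
    baseline = record.preop_creatinine
    if baseline <= 0:
        raise ValueError("baseline creatinine must be positive")
    if config.aki_base_prob <= 0.0:
        p_aki = 0.0
    elif config.aki_base_prob >= 1.0:
        p_aki = 1.0
    else:
        p_aki = float(expit(logit(config.aki_base_prob) + config.aki_twa_slope * twa65))
    is_aki = bool(rng.random() < p_aki)

    hours = 24.0 * np.arange(1, 8)
    if is_aki:
        peak_hour = float(rng.choice([24.0, 48.0]))
        peak = baseline + 0.35 + rng.exponential(0.4)
        series = []
        for h in hours:
            if h < peak_hour:
                v = baseline + (peak - baseline) * 0.6
            elif h == peak_hour:
                v = peak
            else:
                # exponential recovery toward baseline
                v = baseline + (peak - baseline) * np.exp(-(h - peak_hour) / 72.0)
            series.append((float(h), float(max(v, 0.05))))
        return series

    # non-AKI: fluctuate around baseline, strictly inside both criteria
    cap = min(baseline + 0.25, 1.45 * baseline)
    values = baseline * (1.0 + rng.normal(0.0, 0.05, size=hours.size))
    values = np.clip(values, 0.05, cap - 1e-9)
    return [(float(h), float(v)) for h, v in zip(hours, values)]


def _assignment_value(name: str, cov: dict[str, np.ndarray]) -> np.ndarray:
    if name == "duration_h":
        return cov["duration_min"] / 60.0
    if name in cov:
        return cov[name].astype(float)
    raise KeyError(f"unknown assignment covariate {name!r}")


def generate_cohort(config: SimConfig) -> tuple[list[PatientRecord], list[VitalTrace]]:
    """Generate a full synthetic cohort: records and one trace per patient.

    Deterministic for a fixed config (including seed).  Raises
    :class:`DegenerateCohortError` when the assignment model leaves one
    arm empty.
    """
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss)

    # --- covariates (marginals loosely matching a perioperative registry)
    cov: dict[str, np.ndarray] = {}
    cov["age"] = np.round(np.clip(rng.normal(69.0, 10.0, n), 25, 95), 0)
    cov["sex_male"] = rng.random(n) < 0.63
    cov["bmi"] = np.round(np.clip(rng.normal(27.5, 4.5, n), 16, 50), 1)
    cov["bsa"] = np.round(np.clip(rng.normal(1.98, 0.20, n), 1.3, 2.6), 2)
    cov["asa_class"] = rng.choice([2, 3, 4], size=n, p=[0.275, 0.63, 0.095])
    cov["emergency"] = rng.random(n) < 0.17
    cov["chf"] = rng.random(n) < 0.08
    cov["copd"] = rng.random(n) < 0.135
    cov["diabetes"] = rng.random(n) < 0.215
    cov["hypertension"] = rng.random(n) < 0.64
    cov["ace_inhibitor"] = rng.random(n) < 0.245
    cov["beta_blocker"] = rng.random(n) < 0.385
    cov["ccb"] = rng.random(n) < 0.195
    cov["diuretic"] = rng.random(n) < 0.22
    cov["at1_antagonist"] = rng.random(n) < 0.235
    cov["preop_hb"] = np.round(np.clip(rng.normal(12.6, 2.1, n), 6, 18), 1)
    cov["preop_creatinine"] = np.round(
        np.clip(rng.lognormal(np.log(0.95), 0.30, n), 0.4, 6.0), 2
    )
    cov["surgical_approach"] = rng.choice(
        SURGICAL_APPROACHES, size=n, p=[0.21, 0.44, 0.06, 0.29]
    )
    cov["duration_min"] = np.round(
        np.clip(rng.lognormal(np.log(180.0), 0.50, n), 45, 720), 0
    )
    # epidural use tracks open-abdomen approaches
    p_epi = np.where(
        np.isin(cov["surgical_approach"], ("laparotomy", "combined")), 0.75, 0.25
    )
    cov["epidural"] = rng.random(n) < p_epi
    cov["map_induction"] = np.round(np.clip(rng.normal(95.0, 13.0, n), 60, 150), 0)
    cov["hr_induction"] = np.round(np.clip(rng.normal(78.0, 13.0, n), 40, 140), 0)
    cov["spo2_induction"] = np.round(np.clip(rng.normal(97.0, 1.7, n), 85, 100), 0)

    # --- confounded group assignment
    coeffs = dict(config.assignment_coefficients)
    lp = np.full(n, float(coeffs.pop("intercept", 0.0)))
    for name, weight in coeffs.items():
        lp += float(weight) * _assignment_value(name, cov)
    treated = rng.random(n) < expit(lp)
    if treated.all() or not treated.any():
        raise DegenerateCohortError(
            "assignment model produced an empty arm; "
            "soften assignment_coefficients or enlarge the cohort"
        )

    # --- per-patient stochastic processes (child streams keep patient
    #     traces independent of cohort size-ordering effects)
    child_seeds = ss.spawn(n)
    mult = config.treatment_effect_multiplier
    records: list[PatientRecord] = []
    traces: list[VitalTrace] = []
    from twamatch.hemodynamics import twa_below  # local import avoids a cycle

    for i in range(n):
        prng = np.random.default_rng(child_seeds[i])
        pid = f"P{i + 1:04d}"
        is_treated = bool(treated[i])
        dur_min = float(cov["duration_min"][i])
        dur_s = dur_min * 60.0
        rate_h = config.episode_rate_per_hour * (mult if is_treated else 1.0)
        mean_dur_min = config.episode_duration_mean * (mult if is_treated else 1.0)

        n_ep = prng.poisson(rate_h * dur_min / 60.0)
        starts = np.sort(prng.uniform(0.0, max(dur_s - 60.0, 1.0), size=n_ep))
        lengths = np.clip(prng.exponential(mean_dur_min * 60.0, size=n_ep), 60.0, 900.0)
        lengths = np.minimum(lengths, dur_s - starts)
        depths = np.clip(prng.gamma(4.0, config.episode_depth_mean / 4.0, size=n_ep), 8.0, 60.0)
        incipient = list(zip(starts, lengths, depths))

        if is_treated:
            averted = prng.random(n_ep) < config.alarm_aversion_prob
        else:
            averted = np.zeros(n_ep, dtype=bool)
        realized = [ep for ep, av in zip(incipient, averted) if not av]

        baseline = float(np.clip(prng.normal(config.map_baseline_mean, config.map_baseline_sd), 68.0, 110.0))
        trace = generate_map_trace(
            dur_min,
            baseline,
            realized,
            config.sample_interval_s,
            config.map_noise_sd,
            prng,
            drift_amplitude=config.map_drift_amplitude,
            patient_id=pid,
        )

        if is_treated:
            idx = np.clip(prng.normal(25.0, 10.0, size=trace.t.size), 0.0, _INDEX_BACKGROUND_MAX)
            for start_s, _, _ in incipient:
                a0 = max(0.0, start_s - config.alarm_lead_s)
                sel = (trace.t >= a0) & (trace.t < start_s + 1e-9)
                if not sel.any():  # episode at the very start of the case
                    sel = trace.t <= trace.t[0]
                idx[sel] = _ALARM_INDEX_LEVEL + prng.uniform(-2.0, 5.0)
            trace.hpi_index = idx

        record = PatientRecord(
            patient_id=pid,
            age=float(cov["age"][i]),
            sex_male=bool(cov["sex_male"][i]),
            bsa=float(cov["bsa"][i]),
            bmi=float(cov["bmi"][i]),
            asa_class=int(cov["asa_class"][i]),
            emergency=bool(cov["emergency"][i]),
            chf=bool(cov["chf"][i]),
            copd=bool(cov["copd"][i]),
            diabetes=bool(cov["diabetes"][i]),
            hypertension=bool(cov["hypertension"][i]),
            ace_inhibitor=bool(cov["ace_inhibitor"][i]),
            beta_blocker=bool(cov["beta_blocker"][i]),
            ccb=bool(cov["ccb"][i]),
            diuretic=bool(cov["diuretic"][i]),
            at1_antagonist=bool(cov["at1_antagonist"][i]),
            preop_hb=float(cov["preop_hb"][i]),
            preop_creatinine=float(cov["preop_creatinine"][i]),
            surgical_approach=str(cov["surgical_approach"][i]),
            duration_min=dur_min,
            epidural=bool(cov["epidural"][i]),
            map_induction=float(cov["map_induction"][i]),
            hr_induction=float(cov["hr_induction"][i]),
            spo2_induction=float(cov["spo2_induction"][i]),
            group=GROUP_TREATED if is_treated else GROUP_CONTROL,
        )
        twa65 = twa_below(trace, 65.0)
        record.postop_creatinine_series = generate_creatinine_series(
            record, twa65, config, prng
        )
        records.append(record)
        traces.append(trace)

    return records, traces
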