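"""Simulation configuration.

``SimConfig`` holds every knob of the synthetic cohort generator: cohort
size, sampling interval of the arterial-pressure channel, the log-odds
weights that confound group assignment, the hypotensive-episode process,
the alarm channel of the treated group, and the creatinine/AKI outcome
model.  Defaults emulate a perioperative registry in which roughly a
quarter of cases receive predictive monitoring, assignment is driven by
emergency status, epidural use, case duration and ASA class, and the
treated group carries a genuinely lower hypotension burden.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: Log-odds weights of the monitoring-assignment model.  Keys:
#: ``intercept`` plus covariate names; ``duration_h`` is case duration in
#: hours and ``asa_class`` the raw ordinal grade (2-4).  Emergency cases
#: are pushed strongly toward standard monitoring, epidural/long cases
#: toward predictive monitoring — the confounding pattern the matching
#: stage must remove.
DEFAULT_ASSIGNMENT_COEFFICIENTS: dict[str, float] = {
    "intercept": -1.1,
    "emergency": -3.0,
    "epidural": 1.3,
    "duration_h": 0.45,
    "asa_class": -0.6,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_patients:
        Cohort size (>= 4 so both arms can be non-empty).
    seed:
        Root seed; identical configs reproduce bit-identical cohorts.
    sample_interval_s:
        Spacing of the MAP (and alarm-index) samples, seconds.
    assignment_coefficients:
        Covariate -> log-odds weight map of the treatment-assignment
        model (see :data:`DEFAULT_ASSIGNMENT_COEFFICIENTS`).
    episode_rate_per_hour:
        Baseline arrival rate of hypotensive episodes (homogeneous
        Poisson over the case).
    episode_depth_mean:
        Mean MAP drop (mmHg) at the floor of an episode.
    episode_duration_mean:
        Mean episode length, minutes.
    treatment_effect_multiplier:
        Factor in (0, 1] applied to both episode rate and duration in
        the treated arm; 1.0 switches the effect off.
    alarm_lead_s:
        How far ahead of an incipient episode the alarm-index run is
        planted, seconds.
    alarm_aversion_prob:
        Probability that an alarmed incipient episode is averted
        (alarm recorded, no MAP dip).
    aki_base_prob:
        AKI probability at zero hypotension burden.
    aki_twa_slope:
        Log-odds increment of AKI per mmHg of TWA below 65 mmHg.
    map_baseline_mean / map_baseline_sd:
        Between-patient distribution of the non-hypotensive MAP level.
    map_noise_sd:
        Within-trace Gaussian measurement noise, mmHg.
    map_drift_amplitude:
        Amplitude of the slow within-case MAP drift, mmHg.
    """

    n_patients: int = 800
    seed: int = 0
    sample_interval_s: float = 30.0
    assignment_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ASSIGNMENT_COEFFICIENTS)
    )
    episode_rate_per_hour: float = 1.5
    episode_depth_mean: float = 25.0
    episode_duration_mean: float = 2.5
    treatment_effect_multiplier: float = 0.9
    alarm_lead_s: float = 300.0
    alarm_aversion_prob: float = 0.3
    aki_base_prob: float = 0.08
    aki_twa_slope: float = 1.5
    map_baseline_mean: float = 85.0
    map_baseline_sd: float = 7.0
    map_noise_sd: float = 3.0
    map_drift_amplitude: float = 4.0

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")
        if not (0.0 < self.treatment_effect_multiplier <= 1.0):
            raise ValueError("treatment_effect_multiplier must be in (0, 1]")
        if self.episode_rate_per_hour <= 0:
            raise ValueError("episode_rate_per_hour must be positive")
        if self.episode_duration_mean <= 0 or self.episode_depth_mean <= 0:
            raise ValueError("episode duration/depth means must be positive")
        for name in ("alarm_aversion_prob", "aki_base_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1]")
        if self.map_noise_sd < 0 or self.map_drift_amplitude < 0:
            raise ValueError("noise/drift magnitudes must be non-negative")

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["assignment_coefficients"] = dict(self.assignment_coefficients)
        return d

    def config_hash(self) -> str:
        """Stable hash of the full configuration (reproducibility stamp)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
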