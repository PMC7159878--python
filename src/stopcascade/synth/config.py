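"""Configuration for the stop-signal simulator.

The defaults emulate the pooled behavioural regime of a standard manual
stop-signal study: 25% stop trials, a +/-50 ms SSD staircase converging on
P(respond|stop) ~ 0.5, a 1 s response deadline, 2.5 s trials, two-channel
hand EMG at 2 kHz, and a temporal cascade in which the stop command reaches
the muscle ~160 ms after the Stop signal while the behavioural stopping
latency is ~60 ms longer due to electromechanical/ballistic delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class RaceParams:
    """Ex-Gaussian finish-time parameters of the go and stop racers (seconds)
    plus the trigger-failure probability ``p_tf``.

    ``mu_go/sigma_go/tau_go`` describe the time from the Go cue at which the
    go process would cross the response threshold; ``mu_stop/...`` describe
    the central stop latency from the Stop signal.
    """

    mu_go: float = 0.340
    sigma_go: float = 0.050
    tau_go: float = 0.080
    mu_stop: float = 0.105
    sigma_stop: float = 0.020
    tau_stop: float = 0.032
    p_tf: float = 0.04

    def validate(self) -> None:
        for name in ("mu_go", "sigma_go", "tau_go", "mu_stop", "sigma_stop", "tau_stop", "p_tf"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValueError(f"race parameter {name!r} must be finite, got {v!r}")
        if self.sigma_go <= 0 or self.sigma_stop <= 0:
            raise ValueError("sigma_go and sigma_stop must be positive")
        if self.tau_go < 0 or self.tau_stop < 0:
            raise ValueError("tau_go and tau_stop must be non-negative")
        if not 0.0 <= self.p_tf <= 1.0:
            raise ValueError(f"p_tf must be in [0, 1], got {self.p_tf}")


@dataclass
class SimConfig:
    """All tunable constants of the synthetic stop-signal session."""

    n_trials: int = 600
    prop_stop: float = 0.25
    ssd_start: float = 200.0        # ms
    ssd_step: float = 50.0          # ms
    deadline: float = 1000.0        # ms, response window after Go
    trial_length: float = 2500.0    # ms, including inter-trial interval
    fix_ms: float = 500.0           # fixation -> Go cue interval; epoch origin is fixation
    epoch_ms: float = 2000.0        # EMG epoch length recorded from fixation
    fs_emg: float = 2000.0          # Hz
    fs_eeg: float = 512.0           # Hz
    race: RaceParams = field(default_factory=RaceParams)
    ballistic_ms: float = 0.0       # uncancellable stage before the response threshold
    conduction_ms: float = 23.0     # corticospinal conduction delay
    electromech_ms: float = 60.0    # threshold crossing -> registered keypress
    emg_rise_ms: float = 110.0      # envelope rise time (onset -> peak)
    emg_decay_ms: float = 40.0      # envelope decay constant after an untruncated peak
    emg_trunc_decay_ms: float = 10.0  # decay constant after cancellation truncates the drive
    emg_peak_mv: float = 0.5
    noise_sd_mv: float = 0.01
    line_amp_mv: float = 0.02       # 60 Hz mains contamination
    press_threshold_mv: float = 0.45
    beta_freq: float = 20.0         # Hz, within 13-30
    beta_lead_ms: float = 40.0      # burst peak precedes muscle cancellation by this much
    beta_burst_amp: float = 6.0     # burst amplitude relative to unit-SD background
    eeg_epoch_half_ms: float = 1500.0
    mep_base_mv: float = 0.4
    mep_log_sd: float = 0.25
    mep_suppression_onset_ms: float = 140.0
    mep_suppression_factor: float = 0.6
    mep_contam_frac: float = 0.05   # fraction of trials with pre-TMS EMG contamination
    seed: int = 0

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0.0 < self.prop_stop < 1.0:
            raise ValueError(f"prop_stop must be in (0, 1), got {self.prop_stop}")
        if self.ssd_step <= 0:
            raise ValueError("ssd_step must be positive")
        for name in ("ssd_start", "deadline", "trial_length", "fix_ms", "epoch_ms",
                     "ballistic_ms", "conduction_ms", "electromech_ms", "emg_rise_ms",
                     "emg_decay_ms", "emg_trunc_decay_ms", "beta_lead_ms",
                     "mep_suppression_onset_ms"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"duration {name!r} must be non-negative and finite, got {v!r}")
        if self.fs_emg <= 0 or self.fs_eeg <= 0:
            raise ValueError("sampling rates must be positive")
        if not self.press_threshold_mv < self.emg_peak_mv:
            raise ValueError("press_threshold_mv must be below emg_peak_mv")
        if not 13.0 <= self.beta_freq <= 30.0:
            raise ValueError(f"beta_freq must lie in the beta band 13-30 Hz, got {self.beta_freq}")
        # the envelope rise must be resolvable (>= 4 samples)
        if self.emg_rise_ms * self.fs_emg / 1000.0 < 4:
            raise ValueError("fs_emg too low to represent the EMG burst rise (< 4 samples)")
        self.race.validate()

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        race = d.pop("race", {})
        if isinstance(race, RaceParams):
            rp = race
        else:
            rp = RaceParams(**race)
        return cls(race=rp, **d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
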