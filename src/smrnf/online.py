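"""Closed-loop neurofeedback engine.

Streaming (causal) band power at the feedback electrode, baseline threshold
calibration, the MOVE/STILL/ARTIFACT gating rule shared by the rolling-ball
(3D) and bar (2D) paradigms, and sham replay where the display is driven by
a donor's stream while the subject's own EEG is still recorded.

Gating rule: the display advances only when SMR power is strictly above the
subject's baseline-mean threshold AND neither artifact-control band (Theta,
Beta) is strictly above its mean+1SD threshold; an artifact freezes the
display ("red") and takes precedence over reward.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import butter, sosfilt

from .core import BETA, SMR, THETA, BandDefinition, EEGRecording

__all__ = [
    "FeedbackState",
    "BandPowerStream",
    "ThresholdSet",
    "FeedbackParams",
    "FeedbackTrace",
    "streaming_band_power",
    "calibrate",
    "gate",
    "run_feedback",
    "feedback_metrics",
]

DEFAULT_BANDS = (SMR, THETA, BETA)


class FeedbackState(str, Enum):
    MOVE = "MOVE"
    STILL = "STILL"
    ARTIFACT = "ARTIFACT"


@dataclass
class BandPowerStream:
    """Per-band power (uV^2) at uniform ticks from one channel.

    ``warm_up`` flags ticks whose trailing window is not yet filled; they are
    emitted (the display runs from t=0) but excluded from calibration.
    """

    timestamps: np.ndarray  # seconds, uniform at update_interval
    power: dict  # band name -> np.ndarray of uV^2 per tick
    update_interval: float
    source_channel: str
    warm_up: np.ndarray = None  # boolean per tick

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.power.values()}
        if len(lengths) != 1 or lengths.pop() != len(self.timestamps):
            raise ValueError("all bands must have one value per tick")
        if self.warm_up is None:
            self.warm_up = np.zeros(len(self.timestamps), dtype=bool)
        for v in self.power.values():
            if np.any(np.asarray(v) < 0):
                raise ValueError("band power must be >= 0")

    @property
    def n_ticks(self) -> int:
        return len(self.timestamps)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"t": self.timestamps, "warm_up": self.warm_up,
                             **{k.lower(): v for k, v in self.power.items()}})


@dataclass(frozen=True)
class ThresholdSet:
    """Per-subject calibration output, derived only from the baseline run."""

    smr_threshold: float
    theta_threshold: float
    beta_threshold: float
    subject_id: str = "S00"
    source: str = "baseline"

    def __post_init__(self) -> None:
        if min(self.smr_threshold, self.theta_threshold, self.beta_threshold) <= 0:
            raise ValueError("thresholds must be positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"smr_threshold": self.smr_threshold,
                       "theta_threshold": self.theta_threshold,
                       "beta_threshold": self.beta_threshold,
                       "subject_id": self.subject_id, "source": self.source}, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ThresholdSet":
        with open(path) as fh:
            return cls(**json.load(fh))


def _causal_envelope_power(x: np.ndarray, band: BandDefinition, fs: float) -> np.ndarray:
    """Per-sample causal complex-demodulation power.

    The signal is mixed down by a complex exponential at the band centre and
    low-pass filtered causally: the order-4 Butterworth at half the
    bandwidth is applied twice forward, which reproduces the magnitude
    response of the offline zero-phase (forward-backward) filter — the
    envelope only sees the magnitude, so online and offline power agree on
    stationary input.  The doubled magnitude recovers the in-band
    amplitude: a sinusoid of amplitude A in band yields power A^2/2 at
    steady state.
    """
    t = np.arange(x.size) / fs
    mixed = x * np.exp(-2j * np.pi * band.f_center * t)
    from .offline import DEMOD_ENBW_CORRECTION

    cutoff = band.bandwidth / 2.0 * DEMOD_ENBW_CORRECTION
    sos = butter(4, cutoff, fs=fs, output="sos")
    z = sosfilt(sos, sosfilt(sos, mixed))
    env = 2.0 * np.abs(z)
    return env**2 / 2.0


def streaming_band_power(
    rec: EEGRecording,
    bands=DEFAULT_BANDS,
    window: float = 1.0,
    update_interval: float = 0.25,
    channel: str | None = None,
) -> BandPowerStream:
    """Causal per-band power at the feedback channel at uniform ticks.

    At tick t the value is the mean demodulated power over the trailing
    ``window`` seconds, using only samples at or before t (causality is
    exact: perturbing later samples cannot change earlier ticks).
    """
    if window < update_interval:
        raise ValueError("window must be >= update_interval")
    if window > rec.duration:
        raise ValueError("window longer than the run")
    channel = channel or rec.montage.feedback_channel
    fs = rec.sample_rate
    x = rec.channel(channel)
    win_n = int(round(window * fs))
    step_n = int(round(update_interval * fs))
    tick_idx = np.arange(step_n, rec.n_samples + 1, step_n) - 1  # last sample of each tick
    power: dict[str, np.ndarray] = {}
    for band in bands:
        band.validate_for_rate(fs)
        p = _causal_envelope_power(x, band, fs)
        csum = np.concatenate([[0.0], np.cumsum(p)])
        starts = np.maximum(tick_idx + 1 - win_n, 0)
        means = (csum[tick_idx + 1] - csum[starts]) / (tick_idx + 1 - starts)
        power[band.name] = np.maximum(means, 0.0)
    timestamps = (tick_idx + 1) / fs
    warm_up = timestamps < window
    return BandPowerStream(timestamps=timestamps, power=power,
                           update_interval=update_interval,
                           source_channel=channel, warm_up=warm_up)


def calibrate(baseline_stream: BandPowerStream, subject_id: str = "S00") -> ThresholdSet:
    """Thresholds from the baseline run: SMR mean; Theta/Beta mean + 1 SD.

    The SD is the sample standard deviation (n-1 denominator); warm-up ticks
    are excluded.
    """
    keep = ~baseline_stream.warm_up
    if not keep.any():
        raise ValueError("baseline stream has no post-warm-up ticks")

    def _stat(name: str, with_sd: bool) -> float:
        v = np.asarray(baseline_stream.power[name])[keep]
        thr = float(np.mean(v))
        if with_sd and v.size > 1:
            thr += float(np.std(v, ddof=1))
        return thr

    return ThresholdSet(
        smr_threshold=_stat("SMR", False),
        theta_threshold=_stat("Theta", True),
        beta_threshold=_stat("Beta", True),
        subject_id=subject_id,
        source=f"baseline:{baseline_stream.source_channel}",
    )


def gate(smr: float, theta: float, beta: float, thr: ThresholdSet) -> FeedbackState:
    """One tick of the gating rule.

    ARTIFACT (display frozen, shown red) whenever Theta or Beta strictly
    exceeds its threshold — artifact control takes precedence over reward.
    Otherwise MOVE iff SMR strictly exceeds its threshold, else STILL.
    Values exactly at threshold do not trigger ("exceeded" is strict).
    """
    if min(smr, theta, beta) < 0 or not np.isfinite([smr, theta, beta]).all():
        raise ValueError("band powers must be finite and >= 0")
    if theta > thr.theta_threshold or beta > thr.beta_threshold:
        return FeedbackState.ARTIFACT
    if smr > thr.smr_threshold:
        return FeedbackState.MOVE
    return FeedbackState.STILL


@dataclass(frozen=True)
class FeedbackParams:
    """Display dynamics (values the original hardware setup did not report)."""

    ball_speed: float = 1.0  # distance units per second while MOVE
    bar_step: float = 1.0  # height units per tick
    bar_min: float = 0.05  # floor > 0: the bar never fully disappears
    bar_max: float = 10.0


@dataclass
class FeedbackTrace:
    """Gating states plus the cumulative displayed quantity per tick."""

    timestamps: np.ndarray
    states: list  # FeedbackState per tick
    cumulative: np.ndarray  # ball distance (non-decreasing) or bar height
    paradigm: str  # "ball" | "bar"
    mode: str  # "real" | "sham"
    subject_stream: BandPowerStream = None
    display_stream: BandPowerStream = None

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"tick": np.arange(len(self.states)),
                           "t": self.timestamps,
                           "state": [s.value for s in self.states],
                           "cumulative": self.cumulative})
        if self.subject_stream is not None:
            for name, v in self.subject_stream.power.items():
                df[name.lower()] = v[: len(df)]
        return df


def run_feedback(
    rec: EEGRecording,
    thr: ThresholdSet,
    paradigm: str = "ball",
    mode: str = "real",
    donor_stream: BandPowerStream | None = None,
    params: FeedbackParams | None = None,
    *,
    window: float = 1.0,
    update_interval: float = 0.25,
) -> FeedbackTrace:
    """Run one feedback run through the display loop.

    In real mode the display is gated on the subject's own stream; in sham
    mode it is gated on the donor's stream (the subject's EEG is still
    computed and carried in the trace for offline analysis).  The ball
    accumulates distance at constant speed during MOVE ticks; the bar gains
    a step per MOVE tick, loses one per STILL tick, freezes on ARTIFACT, and
    is clamped to [bar_min, bar_max].
    """
    if paradigm not in ("ball", "bar"):
        raise ValueError(f"unknown paradigm {paradigm!r}")
    if mode not in ("real", "sham"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or FeedbackParams()
    subject_stream = streaming_band_power(rec, window=window, update_interval=update_interval)
    if mode == "sham":
        if donor_stream is None:
            raise ValueError("sham mode requires a donor_stream")
        if donor_stream.n_ticks < subject_stream.n_ticks:
            raise ValueError("donor stream shorter than the subject's run")
        display = donor_stream
    else:
        display = subject_stream

    n = subject_stream.n_ticks
    states: list[FeedbackState] = []
    cumulative = np.empty(n)
    ball_distance = 0.0
    bar_height = params.bar_min
    for k in range(n):
        s = gate(display.power["SMR"][k], display.power["Theta"][k],
                 display.power["Beta"][k], thr)
        states.append(s)
        if paradigm == "ball":
            if s is FeedbackState.MOVE:
                ball_distance += params.ball_speed * update_interval
            cumulative[k] = ball_distance
        else:
            if s is FeedbackState.MOVE:
                bar_height += params.bar_step
            elif s is FeedbackState.STILL:
                bar_height -= params.bar_step
            bar_height = float(np.clip(bar_height, params.bar_min, params.bar_max))
            cumulative[k] = bar_height
    return FeedbackTrace(timestamps=subject_stream.timestamps, states=states,
                         cumulative=cumulative, paradigm=paradigm, mode=mode,
                         subject_stream=subject_stream, display_stream=display)


def feedback_metrics(trace: FeedbackTrace) -> dict:
    """Per-run summary: state fractions (summing to 1) and final quantity."""
    n = len(trace.states)
    if n == 0:
        raise ValueError("empty trace")
    counts = {s: 0 for s in FeedbackState}
    for s in trace.states:
        counts[s] += 1
    return {
        "fraction_move": counts[FeedbackState.MOVE] / n,
        "fraction_still": counts[FeedbackState.STILL] / n,
        "fraction_artifact": counts[FeedbackState.ARTIFACT] / n,
        "final_quantity": float(trace.cumulative[-1]),
        "n_ticks": n,
    }
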