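"""Synthetic multi-subject EEG study generator.

Generates sessions with the statistical structure the downstream analysis
assumes: 1/f background noise with spatial correlation, narrowband
oscillators for SMR/Theta/Beta with band-specific scalp topographies, a
linear per-run SMR amplitude multiplier that models within-session learning,
and blink/muscle artifact events logged as ground truth.

Every output is a pure function of its seed and parameters: the same
profile/design simulated twice yields bitwise-identical data, and a study's
sessions can therefore be regenerated lazily instead of held in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    BETA,
    SMR,
    THETA,
    ArtifactEvent,
    BandDefinition,
    EEGRecording,
    Montage,
    SessionLayout,
)

__all__ = [
    "SubjectProfile",
    "StudyDesign",
    "StudyDataset",
    "make_background",
    "add_band_oscillation",
    "inject_artifacts",
    "simulate_subject_session",
    "simulate_study",
    "band_topography",
    "blink_topography",
]

GROUPS = ("3D", "2D")
CONDITIONS = ("real", "sham")

#: Default source amplitudes (uV) of the three narrowband oscillators.
DEFAULT_BAND_AMPLITUDES = {"SMR": 3.0, "Theta": 3.0, "Beta": 2.0}
#: Default broadband background RMS per channel (uV).
DEFAULT_BACKGROUND_RMS = 10.0
#: Mastoid reference channels carry only low-amplitude background so that the
#: linked-mastoid conversion is well defined and nearly neutral.
MASTOID_RMS_FRACTION = 0.2


def band_topography(montage: Montage, band_name: str) -> np.ndarray:
    """Per-channel gain of a band's source over the montage.

    SMR is centred on the sensorimotor strip (max at Cz, the feedback site),
    Theta is frontal-dominant, Beta diffuse.  EOG channels carry no cortical
    oscillation; mastoids almost none.
    """
    gains = {
        "SMR": {"F3": 0.5, "Fz": 0.5, "F4": 0.5, "C3": 0.8, "Cz": 1.0, "C4": 0.8,
                "CPz": 0.8, "P3": 0.5, "Pz": 0.5, "P4": 0.5, "O1": 0.3, "O2": 0.3},
        "Theta": {"F3": 1.0, "Fz": 1.0, "F4": 1.0, "C3": 0.6, "Cz": 0.7, "C4": 0.6,
                  "CPz": 0.5, "P3": 0.4, "Pz": 0.4, "P4": 0.4, "O1": 0.3, "O2": 0.3},
        "Beta": {"F3": 0.8, "Fz": 0.8, "F4": 0.8, "C3": 0.8, "Cz": 0.8, "C4": 0.8,
                 "CPz": 0.8, "P3": 0.8, "Pz": 0.8, "P4": 0.8, "O1": 0.8, "O2": 0.8},
    }[band_name]
    topo = np.zeros(montage.n_channels)
    for label, g in gains.items():
        if label in montage.all_labels:  # montages may be reduced subsets
            topo[montage.index(label)] = g
    for label in montage.ref_labels:
        topo[montage.index(label)] = 0.05
    return topo


def blink_topography(montage: Montage) -> np.ndarray:
    """Blink transient gain: strongest on EOG, frontal-dominant on scalp."""
    topo = np.zeros(montage.n_channels)
    scalp = {"F3": 0.6, "Fz": 0.6, "F4": 0.6, "C3": 0.2, "Cz": 0.2, "C4": 0.2,
             "CPz": 0.12, "P3": 0.06, "Pz": 0.06, "P4": 0.06, "O1": 0.02, "O2": 0.02}
    for label, g in scalp.items():
        if label in montage.all_labels:
            topo[montage.index(label)] = g
    for label in montage.eog_labels:
        topo[montage.index(label)] = 1.0
    for label in montage.ref_labels:
        topo[montage.index(label)] = 0.02
    return topo


def _shaped_noise(n_series: int, n_samples: int, sample_rate: float,
                  exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise whose PSD follows 1/f**exponent above 1 Hz.

    Generated by shaping a white spectrum in the frequency domain; the
    spectrum is flattened below 1 Hz so the high-pass stage downstream has no
    pathological drift to fight and the log-log slope is defined over the
    1-40 Hz fitting range.
    """
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = np.maximum(freqs[nz], 1.0) ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    spec = rng.standard_normal((n_series, freqs.size)) + 1j * rng.standard_normal((n_series, freqs.size))
    x = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    rms = x.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return x / rms


def make_background(
    duration: float,
    montage: Montage | None = None,
    noise_exponent: float = 1.0,
    rng_seed: int | np.random.SeedSequence = 0,
    *,
    sample_rate: float = 256.0,
    rms: float = DEFAULT_BACKGROUND_RMS,
    spatial_corr: float = 0.3,
    run_label: str = "baseline",
    subject_id: str = "S00",
) -> EEGRecording:
    """Spatially correlated 1/f background EEG.

    Each channel is a mixture ``sqrt(c)*shared + sqrt(1-c)*own`` of a common
    and a private noise series (``c = spatial_corr``), so neighbouring
    electrodes covary; every channel is scaled to ``rms`` microvolts
    (mastoids to a fraction of that).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if noise_exponent < 0:
        raise ValueError("noise_exponent must be >= 0")
    if not (0.0 <= spatial_corr < 1.0):
        raise ValueError("spatial_corr must be in [0, 1)")
    montage = montage or Montage()
    rng = np.random.default_rng(rng_seed)
    n_samples = int(round(duration * sample_rate))
    series = _shaped_noise(montage.n_channels + 1, n_samples, sample_rate, noise_exponent, rng)
    shared, own = series[0], series[1:]
    data = np.sqrt(spatial_corr) * shared + np.sqrt(1.0 - spatial_corr) * own
    data *= rms / data.std(axis=1, keepdims=True)
    for label in montage.ref_labels:
        data[montage.index(label)] *= MASTOID_RMS_FRACTION
    return EEGRecording(data=data, sample_rate=sample_rate, montage=montage,
                        run_label=run_label, subject_id=subject_id)


def add_band_oscillation(
    rec: EEGRecording,
    band: BandDefinition,
    amplitude: float,
    topography: np.ndarray | None = None,
    envelope: np.ndarray | None = None,
    *,
    freq: float | None = None,
    phase: float = 0.0,
) -> EEGRecording:
    """Add ``amplitude * topography * envelope * sin(2*pi*f*t + phase)``.

    Narrowband by default: ``f = band.f_center``.  Additive and
    phase-coherent, so adding twice with amplitudes a and b equals adding
    once with a+b.
    """
    band.validate_for_rate(rec.sample_rate)
    f = band.f_center if freq is None else freq
    if not (band.f_lo <= f <= band.f_hi):
        raise ValueError(f"frequency {f} Hz outside band {band.name}")
    topo = np.ones(rec.n_channels) if topography is None else np.asarray(topography, dtype=float)
    if topo.shape != (rec.n_channels,):
        raise ValueError("topography length must equal channel count")
    env = np.ones(rec.n_samples) if envelope is None else np.asarray(envelope, dtype=float)
    if env.shape != (rec.n_samples,):
        raise ValueError("envelope length must equal sample count")
    out = rec.copy()
    wave = np.sin(2.0 * np.pi * f * rec.times + phase)
    out.data += amplitude * topo[:, None] * (env * wave)[None, :]
    return out


def _blink_waveform(sample_rate: float, duration: float = 0.4) -> np.ndarray:
    n = int(round(duration * sample_rate))
    return np.sin(np.pi * np.arange(n) / n)  # half-sine pulse


def inject_artifacts(
    rec: EEGRecording,
    blink_rate: float = 0.0,
    muscle_burst_rate: float = 0.0,
    rng_seed: int | np.random.SeedSequence = 0,
    *,
    blink_times: list[float] | None = None,
    muscle_times: list[float] | None = None,
    blink_peak: float = 150.0,
    blink_duration: float = 0.4,
    muscle_rms: float = 30.0,
    muscle_duration: float = 0.5,
) -> EEGRecording:
    """Inject blink and muscle artifacts, logging every event.

    Blinks are frontal-dominant half-sine transients (default 400 ms, 150 uV
    peak on the EOG channels); muscle bursts are Hann-tapered broadband
    20-40 Hz noise (default 500 ms, 30 uV RMS) with diffuse topography.
    Event counts are Poisson with the given per-minute rates unless explicit
    onset lists are supplied (for exact tests).
    """
    if blink_rate < 0 or muscle_burst_rate < 0:
        raise ValueError("artifact rates must be >= 0")
    rng = np.random.default_rng(rng_seed)
    out = rec.copy()
    fs, dur = rec.sample_rate, rec.duration

    def _onsets(rate: float, explicit: list[float] | None, event_dur: float) -> np.ndarray:
        if explicit is not None:
            return np.asarray(explicit, dtype=float)
        n = rng.poisson(rate * dur / 60.0)
        return rng.uniform(0.0, max(dur - event_dur, 0.0), size=n)

    blink_topo = blink_topography(rec.montage)
    pulse = blink_peak * _blink_waveform(fs, blink_duration)
    for onset in np.sort(_onsets(blink_rate, blink_times, blink_duration)):
        i0 = int(round(onset * fs))
        seg = pulse[: max(0, min(len(pulse), rec.n_samples - i0))]
        if seg.size == 0:
            continue
        out.data[:, i0:i0 + seg.size] += blink_topo[:, None] * seg[None, :]
        out.event_log.append(ArtifactEvent(onset=i0 / fs, duration=seg.size / fs, kind="blink"))

    from scipy.signal import butter, sosfiltfilt

    n_burst = int(round(muscle_duration * fs))
    sos = butter(4, [20.0, 40.0], btype="bandpass", fs=fs, output="sos")
    taper = np.hanning(n_burst)
    scalp_idx = rec.montage.eeg_indices
    for onset in np.sort(_onsets(muscle_burst_rate, muscle_times, muscle_duration)):
        i0 = int(round(onset * fs))
        n_here = max(0, min(n_burst, rec.n_samples - i0))
        if n_here == 0:
            continue
        noise = sosfiltfilt(sos, rng.standard_normal(n_burst))
        noise *= muscle_rms / noise.std()
        gains = rng.uniform(0.5, 1.0, size=len(scalp_idx))
        burst = (noise * taper)[:n_here]
        out.data[scalp_idx, i0:i0 + n_here] += gains[:, None] * burst[None, :]
        out.event_log.append(ArtifactEvent(onset=i0 / fs, duration=n_here / fs, kind="muscle"))
    return out


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one subject's session.

    ``smr_run_slope`` is the fractional SMR source-amplitude increase per
    feedback run: run r (1..6) uses amplitude multiplier ``1 + slope*r``,
    the baseline run multiplier 1.  Theta/Beta slopes default to zero.
    """

    subject_id: str
    group: str = "3D"
    condition: str = "real"
    baseline_band_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES))
    smr_run_slope: float = 0.0
    theta_run_slope: float = 0.0
    beta_run_slope: float = 0.0
    blink_rate: float = 4.0  # events/min
    muscle_burst_rate: float = 2.0  # events/min
    noise_exponent: float = 1.0
    background_rms: float = DEFAULT_BACKGROUND_RMS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS or self.condition not in CONDITIONS:
            raise ValueError(f"unknown group/condition {self.group}/{self.condition}")
        if any(a < 0 for a in self.baseline_band_amplitudes.values()):
            raise ValueError("band amplitudes must be >= 0")
        if self.blink_rate < 0 or self.muscle_burst_rate < 0:
            raise ValueError("artifact rates must be >= 0")
        for r in range(7):
            for slope in (self.smr_run_slope, self.theta_run_slope, self.beta_run_slope):
                if 1.0 + slope * r <= 0.0:
                    raise ValueError(f"amplitude multiplier non-positive at run {r}")

    def band_multiplier(self, band_name: str, run_index: int) -> float:
        """Closed-form amplitude multiplier for run 0 (baseline) .. 6."""
        slope = {"SMR": self.smr_run_slope, "Theta": self.theta_run_slope,
                 "Beta": self.beta_run_slope}[band_name]
        return 1.0 if run_index == 0 else 1.0 + slope * run_index


def simulate_subject_session(
    profile: SubjectProfile,
    layout: SessionLayout | None = None,
    montage: Montage | None = None,
) -> list[EEGRecording]:
    """Simulate all runs of one subject (baseline first), deterministically.

    Per-run child seeds are spawned from ``profile.rng_seed`` so runs are
    independent but the whole session is reproducible bitwise.
    """
    layout = layout or SessionLayout()
    montage = montage or Montage()
    children = np.random.SeedSequence(profile.rng_seed).spawn(layout.n_runs)
    runs = []
    for r, child in enumerate(children):
        seeds = child.spawn(3)
        rec = make_background(
            layout.run_duration, montage, profile.noise_exponent, seeds[0],
            sample_rate=layout.sample_rate, rms=profile.background_rms,
            run_label=layout.run_label(r), subject_id=profile.subject_id,
        )
        phase_rng = np.random.default_rng(seeds[1])
        for band in (SMR, THETA, BETA):
            amp = profile.baseline_band_amplitudes.get(band.name, 0.0)
            amp *= profile.band_multiplier(band.name, r)
            rec = add_band_oscillation(
                rec, band, amp, band_topography(montage, band.name),
                phase=phase_rng.uniform(0.0, 2.0 * np.pi),
            )
        rec = inject_artifacts(rec, profile.blink_rate, profile.muscle_burst_rate, seeds[2])
        runs.append(rec)
    return runs


@dataclass(frozen=True)
class StudyDesign:
    """Study-level generative design: cell sizes, group learning slopes.

    ``n_per_cell`` may be an int (balanced) or a ``{(group, condition): n}``
    mapping (the original cohort was 13/15/17/16).  Group slopes default to
    SMR amplitude growth of 2.5%/run in 3D (so SMR *power* grows ~5%/run)
    and none in 2D; per-subject slopes are normal around the group slope and
    baseline amplitudes log-normal around their defaults.
    """

    n_per_cell: int | dict = 4
    group_slopes: dict = field(default_factory=lambda: {"3D": 0.025, "2D": 0.0})
    slope_sd: float = 0.01
    amp_log_sd: float = 0.2
    blink_rate: float = 4.0
    muscle_burst_rate: float = 2.0
    noise_exponent: float = 1.0
    sham_donor_policy: str = "rotate-within-group"
    master_seed: int = 0

    def cell_size(self, group: str, condition: str) -> int:
        if isinstance(self.n_per_cell, dict):
            return int(self.n_per_cell[(group, condition)])
        return int(self.n_per_cell)


@dataclass
class StudyDataset:
    """Profiles + design table for a simulated study; sessions are lazy.

    Recordings are regenerated on demand from per-subject seeds (cheap and
    deterministic), so a full-size study never needs to fit in memory.
    """

    design: StudyDesign
    layout: SessionLayout
    montage: Montage
    profiles: dict  # subject_id -> SubjectProfile
    design_table: pd.DataFrame
    donor_map: dict  # sham subject_id -> donor subject_id

    @property
    def subject_ids(self) -> list[str]:
        return list(self.profiles)

    def session(self, subject_id: str) -> list[EEGRecording]:
        return simulate_subject_session(self.profiles[subject_id], self.layout, self.montage)

    def iter_sessions(self):
        for sid in self.subject_ids:
            yield sid, self.session(sid)


def simulate_study(
    design: StudyDesign | None = None,
    layout: SessionLayout | None = None,
    montage: Montage | None = None,
) -> StudyDataset:
    """Draw a full study's subject profiles and design table.

    Per-subject seeds, slopes and baseline amplitudes are derived
    deterministically from ``design.master_seed``; the design table records
    the true per-subject parameters for recovery tests.  Sham subjects are
    paired with a real-condition donor of the same group by a seeded
    rotation (the donor's session supplies the displayed feedback).
    """
    design = design or StudyDesign()
    layout = layout or SessionLayout()
    montage = montage or Montage()
    root = np.random.SeedSequence(design.master_seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])

    profiles: dict[str, SubjectProfile] = {}
    rows = []
    counter = 0
    for group in GROUPS:
        for condition in CONDITIONS:
            for _ in range(design.cell_size(group, condition)):
                counter += 1
                sid = f"S{counter:03d}"
                slope = param_rng.normal(design.group_slopes[group], design.slope_sd)
                # keep every run's amplitude multiplier positive
                slope = float(np.clip(slope, -0.16, None))
                amps = {
                    name: float(a * np.exp(param_rng.normal(0.0, design.amp_log_sd)))
                    for name, a in DEFAULT_BAND_AMPLITUDES.items()
                }
                seed = int(param_rng.integers(0, 2**31 - 1))
                profiles[sid] = SubjectProfile(
                    subject_id=sid, group=group, condition=condition,
                    baseline_band_amplitudes=amps, smr_run_slope=slope,
                    blink_rate=design.blink_rate,
                    muscle_burst_rate=design.muscle_burst_rate,
                    noise_exponent=design.noise_exponent, rng_seed=seed,
                )
                rows.append({
                    "subject_id": sid, "group": group, "condition": condition,
                    "true_baseline_amp": amps["SMR"], "true_slope": slope,
                    "seed": seed,
                })
    table = pd.DataFrame(rows)

    donor_map: dict[str, str] = {}
    if design.sham_donor_policy == "rotate-within-group":
        donor_rng = np.random.default_rng(root.spawn(2)[1])
        for group in GROUPS:
            shams = table.query("group == @group and condition == 'sham'")["subject_id"].tolist()
            reals = table.query("group == @group and condition == 'real'")["subject_id"].tolist()
            if reals:
                reals = list(donor_rng.permutation(reals))
                for i, sid in enumerate(shams):
                    donor_map[sid] = reals[i % len(reals)]
    else:
        raise ValueError(f"unknown sham_donor_policy {design.sham_donor_policy!r}")

    return StudyDataset(design=design, layout=layout, montage=montage,
                        profiles=profiles, design_table=table, donor_map=donor_map)
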