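"""End-to-end experiment runner: config, staged pipeline, manifest, fixtures.

`run_study` executes synth -> online (calibration + feedback traces) ->
offline (power table + exclusions) -> stats (report) into an output
directory, recording every artifact with a checksum in a RunManifest.
Stages are resumable: outputs already on disk are reused, and everything is
a pure function of the config, so identical config + seed reproduce
identical checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CANONICAL_BANDS, Montage, SessionLayout
from .edf import write_edf
from .offline import (RejectionCriteria, compute_power_table,
                      exclude_outlier_subjects)
from .online import FeedbackParams, calibrate, run_feedback, streaming_band_power
from .report import report_to_markdown, study_report
from .lmm import simulate_power_table
from .synth import StudyDesign, simulate_study

__all__ = ["StudyConfig", "RunManifest", "run_study", "make_fixtures"]

FIXTURE_KINDS = ("gating-truth-table", "rejection-toy", "sinusoid-bank",
                 "null-study", "effect-study")


@dataclass
class StudyConfig:
    """Everything needed to reproduce a simulated study end to end."""

    # design / layout
    n_per_cell: int | dict = 4
    run_duration: float = 180.0
    sample_rate: float = 256.0
    group_slopes: dict = field(default_factory=lambda: {"3D": 0.025, "2D": 0.0})
    slope_sd: float = 0.01
    blink_rate: float = 4.0
    muscle_burst_rate: float = 2.0
    # online
    window: float = 1.0
    update_interval: float = 0.25
    ball_speed: float = 1.0
    bar_step: float = 1.0
    bar_min: float = 0.05
    bar_max: float = 10.0
    # offline
    with_ica: bool = True
    ica_threshold: float = 0.7
    criteria: dict = field(default_factory=dict)
    channels: tuple = ("Cz",)
    # stats
    log_power: bool = False
    outlier_k_sd: float = 3.0
    # bookkeeping
    master_seed: int = 0
    write_edf_files: bool = True

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        if isinstance(d["n_per_cell"], dict):
            d["n_per_cell"] = {f"{g}/{c}": n for (g, c), n in d["n_per_cell"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if isinstance(d.get("n_per_cell"), dict):
            d["n_per_cell"] = {tuple(k.split("/")): v for k, v in d["n_per_cell"].items()}
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    @property
    def layout(self) -> SessionLayout:
        return SessionLayout(run_duration=self.run_duration,
                             sample_rate=self.sample_rate)

    @property
    def design(self) -> StudyDesign:
        return StudyDesign(n_per_cell=self.n_per_cell,
                           group_slopes=dict(self.group_slopes),
                           slope_sd=self.slope_sd, blink_rate=self.blink_rate,
                           muscle_burst_rate=self.muscle_burst_rate,
                           master_seed=self.master_seed)

    @property
    def rejection_criteria(self) -> RejectionCriteria:
        return RejectionCriteria(**self.criteria)

    @property
    def feedback_params(self) -> FeedbackParams:
        return FeedbackParams(ball_speed=self.ball_speed, bar_step=self.bar_step,
                              bar_min=self.bar_min, bar_max=self.bar_max)


@dataclass
class RunManifest:
    """Per-stage outputs with checksums, seeds and warnings."""

    config_path: str = ""
    master_seed: int = 0
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, path: Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.stages.setdefault(stage, {})[str(path)] = digest

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config": self.config_path, "master_seed": self.master_seed,
                       "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                       "stages": self.stages, "warnings": self.warnings}, fh, indent=2)


def run_study(config: StudyConfig, out_dir, resume: bool = True) -> RunManifest:
    """Run the full simulated experiment into ``out_dir``.

    Stage outputs: design.csv + per-run EDFs (synth), thresholds JSON +
    feedback-trace CSVs (online), power.csv + exclusions.csv (offline),
    report.md + per-band ANOVA CSVs (stats).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(master_seed=config.master_seed)
    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    manifest.config_path = str(config_path)
    manifest.record("config", config_path)

    montage = Montage()
    dataset = simulate_study(config.design, config.layout, montage)

    # --- synth -------------------------------------------------------------
    design_path = out / "design.csv"
    if not (resume and design_path.exists()):
        dataset.design_table.to_csv(design_path, index=False)
    manifest.record("synth", design_path)
    edf_dir = out / "edf"
    if config.write_edf_files:
        edf_dir.mkdir(exist_ok=True)

    # --- online + offline (one pass per subject keeps memory flat) ---------
    online_dir = out / "online"
    online_dir.mkdir(exist_ok=True)
    bands = list(CANONICAL_BANDS.values())
    power_path = out / "power.csv"
    donor_streams: dict[str, list] = {}

    def subject_feedback_streams(sid):
        if sid not in donor_streams:
            session = dataset.session(sid)
            donor_streams[sid] = [
                streaming_band_power(r, window=config.window,
                                     update_interval=config.update_interval)
                for r in session[1:]
            ]
        return donor_streams[sid]

    if not (resume and power_path.exists()):
        tables = []
        for sid, session in dataset.iter_sessions():
            profile = dataset.profiles[sid]
            if config.write_edf_files:
                for rec in session:
                    p = edf_dir / f"{sid}_{rec.run_label}.edf"
                    write_edf(rec, p)
                    manifest.record("synth", p)
            baseline_stream = streaming_band_power(
                session[0], window=config.window,
                update_interval=config.update_interval)
            thr = calibrate(baseline_stream, subject_id=sid)
            thr_path = online_dir / f"{sid}_thresholds.json"
            thr.to_json(thr_path)
            manifest.record("online", thr_path)
            paradigm = "ball" if profile.group == "3D" else "bar"
            donors = (subject_feedback_streams(dataset.donor_map[sid])
                      if profile.condition == "sham" else None)
            for k, rec in enumerate(session[1:]):
                trace = run_feedback(
                    rec, thr, paradigm=paradigm, mode=profile.condition,
                    donor_stream=donors[k] if donors else None,
                    params=config.feedback_params, window=config.window,
                    update_interval=config.update_interval)
                trace_path = online_dir / f"{sid}_{rec.run_label}_trace.csv"
                trace.to_frame().to_csv(trace_path, index=False)
                manifest.record("online", trace_path)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                tables.append(compute_power_table(
                    session, bands, subject_id=sid, group=profile.group,
                    condition=profile.condition, channels=config.channels,
                    criteria=config.rejection_criteria,
                    with_ica=config.with_ica,
                    ica_threshold=config.ica_threshold,
                    ica_seed=config.master_seed))
            manifest.warnings.extend(f"{sid}: {w.message}" for w in caught)
        pd.concat(tables, ignore_index=True).to_csv(power_path, index=False)
    manifest.record("offline", power_path)

    power_table = pd.read_csv(power_path)
    filtered, exclusions = exclude_outlier_subjects(power_table,
                                                    k_sd=config.outlier_k_sd,
                                                    channel=config.channels[0])
    excl_path = out / "exclusions.csv"
    exclusions.to_csv(excl_path, index=False)
    manifest.record("offline", excl_path)

    # --- stats --------------------------------------------------------------
    report = study_report(filtered, channel=config.channels[0],
                          config_echo={"master_seed": config.master_seed})
    for band, entry in report["bands"].items():
        if "anova" not in entry:
            manifest.warnings.append(f"{band}: {entry.get('anova_error', 'no fit')}")
            continue
        anova_path = out / f"anova_{band.lower()}.csv"
        entry["anova"].to_csv(anova_path)
        manifest.record("stats", anova_path)
    report_path = out / "report.md"
    report_path.write_text(report_to_markdown(report))
    manifest.record("stats", report_path)

    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# Deterministic fixture generation for tests and demos
# ---------------------------------------------------------------------------

def make_fixtures(kind: str, seed: int, out_dir) -> dict:
    """Write small deterministic inputs with machine-readable expectations.

    Returns a dict of the paths written.  Kinds: gating-truth-table (8-row
    band-power CSV with expected states), rejection-toy (10-s EDF with one
    planted violation per criterion + expected mask), sinusoid-bank (EDFs of
    known sinusoids + closed-form powers), null-study / effect-study
    (generative power tables + truth JSON).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "gating-truth-table":
        return _fixture_gating(out)
    if kind == "rejection-toy":
        return _fixture_rejection_toy(out, seed)
    if kind == "sinusoid-bank":
        return _fixture_sinusoid_bank(out)
    if kind == "null-study":
        return _fixture_power_study(out, seed, {"3D": 0.0, "2D": 0.0}, "null_study")
    if kind == "effect-study":
        return _fixture_power_study(out, seed, {"3D": 0.23, "2D": 0.0}, "effect_study")
    raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")


def _fixture_gating(out: Path) -> dict:
    from .online import ThresholdSet, gate

    thr = ThresholdSet(smr_threshold=1.0, theta_threshold=1.0, beta_threshold=1.0)
    rows = []
    for smr_hi in (0, 1):
        for theta_hi in (0, 1):
            for beta_hi in (0, 1):
                smr, theta, beta = (2.0 if smr_hi else 0.5,
                                    2.0 if theta_hi else 0.5,
                                    2.0 if beta_hi else 0.5)
                rows.append({"smr": smr, "theta": theta, "beta": beta,
                             "expected_state": gate(smr, theta, beta, thr).value})
    path = out / "gating_truth_table.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    thr_path = out / "gating_thresholds.json"
    thr.to_json(thr_path)
    return {"table": str(path), "thresholds": str(thr_path)}


def _fixture_rejection_toy(out: Path, seed: int) -> dict:
    from .offline import reject_artifacts_reference
    from .synth import make_background

    rec = make_background(10.0, noise_exponent=1.0, rng_seed=seed, rms=5.0)
    fs = int(rec.sample_rate)
    cz = rec.montage.index("Cz")
    rec.data[cz, 1 * fs] += 400.0           # voltage step + amplitude violation
    rec.data[cz, 3 * fs: 3 * fs + fs // 4] += 150.0  # segment range violation
    rec.data[rec.montage.index("Pz"), 5 * fs] = 125.0  # amplitude only
    rec.data[rec.montage.index("O1"), 7 * fs: 7 * fs + fs // 2] = 0.0  # flat line
    edf_path = out / "rejection_toy.edf"
    write_edf(rec, edf_path)
    mask = reject_artifacts_reference(rec)
    mask_path = out / "rejection_toy_expected_mask.json"
    mask.to_json(mask_path)
    return {"edf": str(edf_path), "expected_mask": str(mask_path)}


def _fixture_sinusoid_bank(out: Path) -> dict:
    from .core import EEGRecording
    from .synth import add_band_oscillation

    montage = Montage()
    rows = []
    paths = {}
    for band_name, amp in (("SMR", 10.0), ("Theta", 6.0), ("Beta", 4.0)):
        band = CANONICAL_BANDS[band_name]
        rec = EEGRecording(np.zeros((montage.n_channels, 256 * 10)), 256.0, montage)
        rec = add_band_oscillation(rec, band, amp)
        p = out / f"sinusoid_{band_name.lower()}.edf"
        write_edf(rec, p)
        paths[band_name] = str(p)
        rows.append({"band": band_name, "freq": band.f_center, "amplitude": amp,
                     "expected_power": amp**2 / 2.0})
    table = out / "sinusoid_expected_power.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    paths["expected"] = str(table)
    return paths


def _fixture_power_study(out: Path, seed: int, slopes: dict, stem: str) -> dict:
    table = simulate_power_table(n_per_cell=15, group_slopes=slopes, seed=seed)
    table_path = out / f"{stem}_power.csv"
    table.to_csv(table_path, index=False)
    truth_path = out / f"{stem}_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"group_slopes": slopes, "n_per_cell": 15, "seed": seed}, fh)
    return {"power": str(table_path), "truth": str(truth_path)}
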