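"""Study-level reporting: per-run group trends, ANOVA tables, figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .lmm import PowerTrendModel, post_test_per_group

__all__ = ["group_run_summary", "linear_trend", "study_report", "plot_group_trends"]


def group_run_summary(table: pd.DataFrame, band: str = "SMR",
                      channel: str = "Cz", runs=tuple(range(1, 7))) -> pd.DataFrame:
    """Per-group, per-run mean power with standard error across subjects."""
    df = table[(table["band"] == band) & (table["channel"] == channel)
               & table["run"].isin(runs)].dropna(subset=["mean_power"])
    out = (df.groupby(["group", "run"])["mean_power"]
           .agg(mean="mean", sd="std", n="count").reset_index())
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out


def linear_trend(runs: np.ndarray, values: np.ndarray) -> dict:
    """Least-squares line through (run, value) points with its R^2."""
    runs = np.asarray(runs, float)
    values = np.asarray(values, float)
    slope, intercept = np.polyfit(runs, values, 1)
    fitted = slope * runs + intercept
    ss_res = float(((values - fitted) ** 2).sum())
    ss_tot = float(((values - values.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"slope": float(slope), "intercept": float(intercept), "r2": r2}


def study_report(power_table: pd.DataFrame, bands=("SMR", "Theta", "Beta"),
                 channel: str = "Cz", exclusion_report: pd.DataFrame | None = None,
                 config_echo: dict | None = None,
                 with_post_tests: bool = True) -> dict:
    """Assemble the study's endpoint report.

    Per band: group/run mean +- SE table, per-group linear trendline with
    R^2 (fit on the group-mean-per-run points, as trend figures are drawn),
    the full mixed-model Type I ANOVA, and per-group post-test ANOVAs.
    """
    report: dict = {"bands": {}, "config": config_echo or {}}
    if exclusion_report is not None:
        report["exclusions"] = exclusion_report.to_dict("records")
    for band in bands:
        entry: dict = {}
        summary = group_run_summary(power_table, band, channel)
        entry["group_run_means"] = summary
        entry["trends"] = {
            g: linear_trend(sub["run"], sub["mean"])
            for g, sub in summary.groupby("group")
        }
        try:
            fit = PowerTrendModel.from_power_table(power_table, band=band,
                                                   channel=channel).fit()
            entry["anova"] = fit.anova()
            entry["fit"] = fit
        except ValueError as err:  # e.g. too few subjects per cell
            entry["anova_error"] = str(err)
        if with_post_tests and "fit" in entry:
            entry["post_tests"] = {
                g: post_test_per_group(power_table, g, band=band,
                                       channel=channel).anova()
                for g in sorted(power_table["group"].unique())
            }
        report["bands"][band] = entry
    return report


def report_to_markdown(report: dict) -> str:
    lines = ["# Neurofeedback study report", ""]
    if report.get("exclusions"):
        lines.append("## Outlier exclusions (>= 3 SD session-mean power)")
        for row in report["exclusions"]:
            lines.append(f"- {row['subject_id']} ({row['band']}, z = {row['z']:.2f})")
        lines.append("")
    for band, entry in report["bands"].items():
        lines.append(f"## {band} power at Cz")
        lines.append("")
        lines.append("Group trendlines (group-mean power per run):")
        for g, tr in entry["trends"].items():
            lines.append(f"- {g}: slope {tr['slope']:.4f} uV^2/run, R^2 = {tr['r2']:.3f}")
        lines.append("")
        if "anova_error" in entry:
            lines.append(f"Mixed model not estimable: {entry['anova_error']}")
            lines.append("")
            continue
        lines.append("Type I ANOVA (Satterthwaite):")
        lines.append("")
        lines.append(entry["anova"].round(4).to_markdown())
        if "post_tests" in entry:
            for g, an in entry["post_tests"].items():
                lines.append("")
                lines.append(f"Post-test, {g} group:")
                lines.append("")
                lines.append(an.round(4).to_markdown())
        lines.append("")
    return "\n".join(lines)


def plot_group_trends(power_table: pd.DataFrame, band: str = "SMR",
                      channel: str = "Cz", ax=None):
    """Group mean +- SE per feedback run with linear trendlines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    summary = group_run_summary(power_table, band, channel)
    for g, sub in summary.groupby("group"):
        ax.errorbar(sub["run"], sub["mean"], yerr=sub["se"], marker="o",
                    capsize=3, label=f"{g}")
        tr = linear_trend(sub["run"], sub["mean"])
        xs = np.array([sub["run"].min(), sub["run"].max()])
        ax.plot(xs, tr["slope"] * xs + tr["intercept"], "--", alpha=0.6)
    ax.set_xlabel("feedback run")
    ax.set_ylabel(f"{band} power at {channel} (uV$^2$)")
    ax.legend(title="group")
    return ax
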