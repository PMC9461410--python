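"""End-to-end orchestration: simulate -> classify -> preprocess -> include ->
analyze -> panel, with a machine-readable report.

Every analysis constant (72 h window, 5 h gap limit, 5 h smoothing window,
38.9 degC fever cut, 0.05 family-wise alpha over 6 comparisons) lives in
``AnalysisConstants`` so sensitivity runs can vary each one.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import diffstats, io, panel as panel_mod, questionnaire as q_mod
from .exceptions import VaxwatchError
from .inclusion import apply_inclusion, inclusion_frame
from .preprocessing import preprocess_stream
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


class StageError(VaxwatchError):
    """Wraps a stage failure with the stage name for actionable errors."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


class AnalysisConstants(BaseModel):
    post_window_h: int = 72
    gap_limit_h: int = 5
    smooth_window_h: int = 5
    fever_threshold_c: float = 38.9
    alpha: float = 0.05
    m_comparisons: int = 6
    baseline_days: int = 7


class RunConfig(BaseModel):
    """Either a simulation config or the three input CSV paths."""

    simulation: Optional[SimulationConfig] = None
    roster: Optional[str] = None
    wearable: Optional[str] = None
    questionnaire: Optional[str] = None
    channels: tuple[str, ...] = ("heart_rate", "stress")
    out_dir: str = "vaxwatch_out"
    seed: int = 0
    constants: AnalysisConstants = AnalysisConstants()

    @model_validator(mode="after")
    def _check(self):
        if self.simulation is None and not (self.roster and self.wearable and self.questionnaire):
            raise ValueError(
                "provide either a simulation config or all three input CSV paths"
            )
        return self


def classify_cohort(
    participants: dict,
    questionnaires: dict,
    constants: AnalysisConstants = AnalysisConstants(),
) -> tuple[dict[str, str], dict[str, frozenset], list[str]]:
    """Tier every classifiable participant.

    Returns (tier by participant, new-symptom set by participant, ids of
    participants lacking the baseline or post questionnaire).
    """
    tiers: dict[str, str] = {}
    new_symptoms: dict[str, frozenset] = {}
    unclassifiable: list[str] = []
    for pid, part in participants.items():
        entries = q_mod.dedupe_daily(questionnaires.get(pid, []))
        baseline, post = q_mod.split_entries(
            entries,
            part.vaccination_time,
            baseline_days=constants.baseline_days,
            post_hours=constants.post_window_h,
        )
        if baseline is None or not post:
            unclassifiable.append(pid)
            continue
        tier = q_mod.classify_reaction(post, baseline)
        tiers[pid] = tier.label
        collected = frozenset().union(*(e.symptoms for e in post)) - baseline.symptoms
        new_symptoms[pid] = frozenset(s for s in collected if s in q_mod.VOCABULARY)
    return tiers, new_symptoms, unclassifiable


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the report dict (also written to out_dir)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    constants = config.constants

    # ---- stage: inputs -------------------------------------------------
    try:
        if config.simulation is not None:
            sim = config.simulation.model_copy(update={"seed": config.seed})
            simulate_dataset(sim, out_dir, channels=config.channels)
            roster_path = out_dir / "roster.csv"
            wearable_path = out_dir / "wearable.csv"
            questionnaire_path = out_dir / "questionnaire.csv"
        else:
            roster_path = Path(config.roster)
            wearable_path = Path(config.wearable)
            questionnaire_path = Path(config.questionnaire)
        violations = io.validate_inputs(roster_path, wearable_path, questionnaire_path)
        if violations:
            raise VaxwatchError("input validation failed:\n" + "\n".join(violations))
        participants = io.read_roster(roster_path)
        wearable = io.read_wearable(wearable_path)
        questionnaires = io.read_questionnaires(questionnaire_path)
    except VaxwatchError as exc:
        raise StageError("inputs", str(exc)) from exc

    # ---- stage: classify ----------------------------------------------
    try:
        tiers, new_symptoms, unclassifiable = classify_cohort(
            participants, questionnaires, constants
        )
        proportions = q_mod.cohort_symptom_proportions(new_symptoms)
        tier_table = pd.DataFrame(
            {
                "participant_id": sorted(tiers),
                "dose": [participants[p].dose for p in sorted(tiers)],
                "tier": [tiers[p] for p in sorted(tiers)],
            }
        )
        meta = pd.DataFrame(
            {
                "participant_id": sorted(tiers),
                "tier": [tiers[p] for p in sorted(tiers)],
                "sex": [participants[p].sex for p in sorted(tiers)],
                "age": [participants[p].age for p in sorted(tiers)],
                "underlying_condition": [
                    participants[p].underlying_condition for p in sorted(tiers)
                ],
            }
        )
        crosstab = q_mod.tier_crosstab(meta) if len(meta) else pd.DataFrame()
        tier_table.to_csv(out_dir / "tiers.csv", index=False)
        proportions.to_csv(out_dir / "proportions.csv", index=False)
        if len(crosstab):
            crosstab.to_csv(out_dir / "crosstab.csv", index=False)
    except VaxwatchError as exc:
        raise StageError("classify", str(exc)) from exc

    # ---- stage: preprocess ---------------------------------------------
    try:
        interp: dict[str, dict] = {}
        matched: dict[str, dict] = {}
        hourly_records = []
        for (pid, channel), group in wearable.groupby(["participant_id", "channel"]):
            if pid not in participants:
                continue
            interpolated, smoothed, diff = preprocess_stream(
                group,
                participants[pid].vaccination_time,
                max_gap=constants.gap_limit_h,
                smooth_window=constants.smooth_window_h,
            )
            interp.setdefault(pid, {})[channel] = interpolated
            matched.setdefault(channel, {})[pid] = diff
            hourly_records.append((interpolated, "interpolated"))
            hourly_records.append((smoothed, "smoothed"))
        io.hourly_frame(hourly_records).to_csv(out_dir / "hourly.csv", index=False)
        all_diffs = [d for by_pid in matched.values() for d in by_pid.values()]
        io.diffs_frame(all_diffs).to_csv(out_dir / "diffs.csv", index=False)
    except VaxwatchError as exc:
        raise StageError("preprocess", str(exc)) from exc

    # ---- stage: inclusion ----------------------------------------------
    try:
        decisions = []
        for pid in sorted(participants):
            entries = q_mod.dedupe_daily(questionnaires.get(pid, []))
            decisions.append(
                apply_inclusion(
                    participants[pid],
                    entries,
                    interp.get(pid, {}),
                    baseline_days=constants.baseline_days,
                    post_hours=constants.post_window_h,
                )
            )
        inclusion_df = inclusion_frame(decisions)
        inclusion_df.to_csv(out_dir / "inclusion.csv", index=False)
        included = {d.participant_id for d in decisions if d.included}
        if not included:
            raise VaxwatchError("no participants satisfy the inclusion criteria")
    except VaxwatchError as exc:
        raise StageError("inclusion", str(exc)) from exc

    # ---- stage: analyze ------------------------------------------------
    try:
        analyze_report = {}
        curve_rows = []
        wm_rows = []
        test_rows = []
        for channel in config.channels:
            diffs_ch = {
                pid: d
                for pid, d in matched.get(channel, {}).items()
                if pid in included and pid in tiers
            }
            if not diffs_ch:
                continue
            curves = diffstats.cohort_curve(diffs_ch, tiers, channel)
            summaries = diffstats.window_mean(
                diffs_ch, tiers, channel, window=(0, constants.post_window_h)
            )
            tests = diffstats.pairwise_welch(summaries)
            peaks = {}
            for stratum, curve in curves.items():
                if curve.table.empty or curve.table["mean"].isna().all():
                    continue
                tbl = curve.table.assign(stratum=stratum, channel=channel)
                curve_rows.append(tbl)
                peak_hour, peak_value, return_hour = diffstats.peak_and_return(curve)
                peaks[stratum] = {
                    "peak_hour": peak_hour,
                    "peak_value": round(peak_value, 2),
                    "return_hour": return_hour,
                }
            for stratum, s in summaries.items():
                wm_rows.append(
                    {
                        "channel": channel,
                        "stratum": stratum,
                        "mean": s.mean,
                        "ci_low": s.ci_low,
                        "ci_high": s.ci_high,
                        "n": s.n,
                    }
                )
            for res in tests:
                test_rows.append(
                    {
                        "channel": channel,
                        "group_a": res.group_a,
                        "group_b": res.group_b,
                        "t": res.t,
                        "df": res.df,
                        "p": res.p,
                    }
                )
            analyze_report[channel] = {
                "peaks": peaks,
                "window_means": {
                    s.stratum: {
                        "mean": None if np.isnan(s.mean) else round(s.mean, 2),
                        "n": s.n,
                    }
                    for s in summaries.values()
                },
            }
        if curve_rows:
            pd.concat(curve_rows, ignore_index=True).to_csv(out_dir / "curves.csv", index=False)
        pd.DataFrame(wm_rows).to_csv(out_dir / "window_means.csv", index=False)
        pd.DataFrame(test_rows).to_csv(out_dir / "tests.csv", index=False)
    except VaxwatchError as exc:
        raise StageError("analyze", str(exc)) from exc

    # ---- stage: panel --------------------------------------------------
    try:
        threshold = panel_mod.bonferroni_threshold(
            constants.alpha, constants.m_comparisons, decimals=3
        )
        panel_report = {}
        for channel in config.channels:
            series_ch = {
                pid: by_ch[channel]
                for pid, by_ch in interp.items()
                if channel in by_ch and pid in included and pid in tiers
            }
            if not series_ch:
                continue
            panel_report[channel] = {}
            for subset, asympt in (("all", False), ("asymptomatic", True)):
                try:
                    built = panel_mod.build_panel(
                        series_ch, participants, tiers, asymptomatic_only=asympt
                    )
                except ValueError as exc:
                    logger.warning("skipping %s/%s panel: %s", channel, subset, exc)
                    continue
                for window in ((0, constants.post_window_h), (24, constants.post_window_h)):
                    try:
                        fit = panel_mod.fit_mixed_panel(
                            built, panel_mod.PanelSpec(window=window)
                        )
                    except ValueError as exc:
                        logger.warning(
                            "skipping %s/%s %s fit: %s", channel, subset, window, exc
                        )
                        continue
                    key = f"{window[0]}-{window[1]}h"
                    entry = fit.to_dict()
                    entry["significant_at_bonferroni"] = bool(
                        fit.p_one_sided_post < threshold
                    )
                    panel_report[channel].setdefault(subset, {})[key] = entry
        panel_report["bonferroni_threshold"] = threshold
        with open(out_dir / "panel_fits.json", "w") as fh:
            json.dump(panel_report, fh, indent=2, sort_keys=True)
    except VaxwatchError as exc:
        raise StageError("panel", str(exc)) from exc

    # ---- report ---------------------------------------------------------
    report = {
        "seed": config.seed,
        "n_participants": len(participants),
        "n_included": len(included),
        "unclassifiable": sorted(unclassifiable),
        "tiers": {t: int((tier_table["tier"] == t).sum()) for t in ("none", "mild", "severe")},
        "crosstab": crosstab.to_dict(orient="records") if len(crosstab) else [],
        "proportions": proportions[proportions["k"] > 0].to_dict(orient="records"),
        "wearables": analyze_report,
        "panel": panel_report,
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_text_report(report, out_dir / "report.txt")
    return report


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["vaxwatch pipeline report", "=" * 30]
    lines.append(f"participants: {report['n_participants']} "
                 f"(included: {report['n_included']})")
    lines.append("tier counts: " + ", ".join(f"{k}={v}" for k, v in report["tiers"].items()))
    for channel, section in report["wearables"].items():
        lines.append(f"\n[{channel}]")
        for stratum, peak in section["peaks"].items():
            lines.append(
                f"  {stratum}: peak {peak['peak_value']:+.2f} at h{peak['peak_hour']}, "
                f"return at {peak['return_hour']}"
            )
    thr = report["panel"].get("bonferroni_threshold")
    lines.append(f"\nBonferroni threshold: {thr}")
    path.write_text("\n".join(lines) + "\n")
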