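"""End-to-end pipeline: simulate -> preprocess -> GLM -> group -> behavior -> power.

`run_subject` carries one synthetic subject through behavior and fNIRS
simulation, quality control, TDDR, Beer-Lambert conversion, and the
AR(1) GLM.  `run_pipeline` loops subjects, assembles the group effect
table (ROI x chroma x condition cells plus behavioral covariates), fits
the random-intercept mixed models and channel-wise FDR contrasts, runs
the behavioral analyses, and evaluates the design's power calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior_stats, glm, group, power, preprocess, synth_behavior, synth_fnirs
from .config import PipelineConfig
from .montage import Montage, build_default_montage
from .schedule import (CONDITIONS, ExperimentSchedule, build_schedule,
                       compute_layout, schedule_to_events)
from .stimuli import compare_complexity, generate_stimulus_set, score_set

CHROMAS = ("hbo", "hbr")


@dataclass
class SubjectResult:
    subject_id: str
    schedule: ExperimentSchedule
    records: list
    trial_table: pd.DataFrame
    quality: list
    subject_excluded: bool
    glm_results: dict                  # chroma -> SubjectGlmResult
    roi_effects: dict                  # chroma -> DataFrame (roi_group x condition)
    contrasts: dict                    # (chroma, contrast name) -> DataFrame
    truth: synth_fnirs.GroundTruth = field(default=None, repr=False)


def _truncate_schedule(schedule: ExperimentSchedule, n_blocks: int) -> ExperimentSchedule:
    if n_blocks >= 4:
        return schedule
    trials = [t for t in schedule.trials if t.block <= n_blocks]
    return ExperimentSchedule(trials=trials, rng_seed=schedule.rng_seed,
                              block_break_s=schedule.block_break_s)


def run_subject(config: PipelineConfig, subject_index: int,
                stimulus_set=None, montage: Montage | None = None,
                truth: synth_fnirs.GroundTruth | None = None,
                apply_tddr: bool = True) -> SubjectResult:
    """Simulate and analyze a single subject end to end."""
    sid = f"sub-{subject_index + 1:02d}"
    if stimulus_set is None:
        stimulus_set = generate_stimulus_set(
            config.stimulus_seed if config.stimulus_seed is not None
            else config.stage_seed("stimuli"))
    montage = montage or build_default_montage()
    truth = truth or synth_fnirs.default_ground_truth(montage)

    schedule = build_schedule(config.stage_seed("schedule", subject_index), stimulus_set)
    schedule = _truncate_schedule(schedule, config.n_blocks)
    profile = synth_behavior.default_profile()
    records = synth_behavior.simulate_responses(
        profile, schedule, config.stage_seed("behavior", subject_index), subject_id=sid)
    rts = [r.rt_ms / 1000.0 if r.responded else None for r in records]
    rts = [rt if rt is not None else 10.0 for rt in rts]
    events = schedule_to_events(schedule, response_times_s=rts)
    layout = compute_layout()
    trial_table = behavior_stats.build_trial_table(schedule, records, layout)

    rec, truth = synth_fnirs.simulate_recording(
        montage, events, truth, config.stage_seed("fnirs", subject_index))

    quality = preprocess.compute_channel_quality(rec.intensity, rec.fs, montage)
    quality, excluded = preprocess.apply_quality_exclusion(
        quality, sci_threshold=config.sci_threshold, cv_rule=config.cv_rule)
    kept_mask = np.array([q.kept for q in quality])

    od = preprocess.intensity_to_od(rec.intensity)
    if apply_tddr:
        od = preprocess.tddr(od, rec.fs)
    hbo, hbr, long_idx = preprocess.modified_beer_lambert(
        od, montage, channel_mask=kept_mask, which="long")
    s_hbo, s_hbr, _ = preprocess.modified_beer_lambert(od, montage, which="short")

    n = od.shape[0]
    design = glm.make_design_matrix(
        events, n, rec.fs,
        short_hbo=s_hbo.mean(axis=1), short_hbr=s_hbr.mean(axis=1),
        heart_rate=rec.aux.get("heart_rate"), spo2=rec.aux.get("spo2"),
        cutoff_hz=config.glm_cutoff_hz)
    channel_ids = [montage.channels[i].channel_id for i in long_idx]
    glm_results = {
        "hbo": glm.fit_ar1_glm(hbo, design, channel_ids),
        "hbr": glm.fit_ar1_glm(hbr, design, channel_ids),
    }
    roi_effects = {ch: glm.roi_aggregate(glm_results[ch], montage) for ch in CHROMAS}
    contrasts = {}
    for ch in CHROMAS:
        for spec in (glm.SYMMETRY_CONTRAST, glm.LOAD_CONTRAST, glm.INTERACTION_CONTRAST):
            contrasts[(ch, spec.name)] = glm.compute_contrast(glm_results[ch], spec)
    return SubjectResult(subject_id=sid, schedule=schedule, records=records,
                         trial_table=trial_table, quality=quality,
                         subject_excluded=excluded, glm_results=glm_results,
                         roi_effects=roi_effects, contrasts=contrasts, truth=truth)


def group_effect_table(subjects: list[SubjectResult]) -> pd.DataFrame:
    """Long table: subject x ROI group x chroma x probe/load cell -> effect (µM)."""
    rows = []
    cov = {}
    for s in subjects:
        c = behavior_stats.accuracy_covariates(s.trial_table)
        cov[s.subject_id] = c.iloc[0]
        for chroma in CHROMAS:
            roi = s.roi_effects[chroma]
            for _, r in roi.iterrows():
                for cond in CONDITIONS:
                    sym, load = cond.split("_")
                    rows.append({
                        "subject": s.subject_id, "unit": r["roi_group"],
                        "chroma": chroma, "probe": sym, "load": load,
                        "effect": r[cond],
                        "acc_sym_minus_asym": cov[s.subject_id]["acc_sym_minus_asym"],
                        "acc_low_minus_high": cov[s.subject_id]["acc_low_minus_high"],
                    })
    return pd.DataFrame(rows)


def run_group_inference(subjects: list[SubjectResult],
                        config: PipelineConfig) -> dict:
    """ROI mixed models and channel-wise FDR contrast maps."""
    table = group_effect_table(subjects)
    lme_fits = {}
    for (unit, chroma), sub in table.groupby(["unit", "chroma"]):
        if sub["effect"].isna().any():
            continue
        lme_fits[(unit, chroma)] = group.fit_random_intercept_lme(sub)
    contrast_maps = {}
    for spec_name in (glm.INTERACTION_CONTRAST.name, glm.SYMMETRY_CONTRAST.name):
        rows = []
        for s in subjects:
            for chroma in CHROMAS:
                cm = s.contrasts[(chroma, spec_name)]
                for _, r in cm.iterrows():
                    rows.append({"subject": s.subject_id, "channel_id": r["channel_id"],
                                 "chroma": chroma, "effect": r["effect"]})
        contrast_maps[spec_name] = group.group_channel_contrast(
            pd.DataFrame(rows), alpha=config.fdr_alpha)
    return {"effect_table": table, "lme_fits": lme_fits,
            "contrast_maps": contrast_maps}


def run_behavior_stats(subjects: list[SubjectResult]) -> dict:
    table = pd.concat([s.trial_table for s in subjects], ignore_index=True)
    filtered, removed = behavior_stats.filter_rt_outliers(
        table.rename(columns={"subject": "subject_id"}))
    filtered = filtered.rename(columns={"subject_id": "subject"})
    acc = table.assign(acc=table["correct"].astype(float) * 100)
    anova_acc = behavior_stats.rm_anova(acc, "acc", ["symmetry", "load"])
    rt_tab = filtered[filtered["correct"]]
    anova_rt = behavior_stats.rm_anova(rt_tab, "rt_ms", ["symmetry", "load"])
    pairwise = behavior_stats.pairwise_comparisons(acc, "acc", ["symmetry", "load"])
    covariates = behavior_stats.accuracy_covariates(table)
    return {"trial_table": table, "rt_removed": removed,
            "anova_accuracy": anova_acc, "anova_rt": anova_rt,
            "pairwise_accuracy": pairwise, "covariates": covariates}


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run the full default pipeline; optionally write CSV outputs.

    Returns a bundle with per-subject results, group inference,
    behavioral statistics, stimulus complexity comparison, and the
    design's power numbers, stamped with the config hash and seed.
    """
    stim_seed = (config.stimulus_seed if config.stimulus_seed is not None
                 else config.stage_seed("stimuli"))
    stimulus_set = generate_stimulus_set(stim_seed)
    scores = score_set(stimulus_set, config.encoder_settings or None)
    complexity = compare_complexity(stimulus_set, scores)
    montage = build_default_montage()
    truth = synth_fnirs.default_ground_truth(montage)
    subjects = [run_subject(config, i, stimulus_set, montage, truth)
                for i in range(config.n_subjects)]
    group_res = run_group_inference(subjects, config)
    behav = run_behavior_stats(subjects)
    pw = config.power
    power_res = {
        "required_n": power.required_n(pw["target_power"], m=pw["m"], f=pw["f"],
                                       rho=pw["rho"], alpha=pw["alpha"],
                                       epsilon=pw["epsilon"]),
        "power_at_26": power.rm_power(power.PowerSpec(
            n=26, m=pw["m"], f=pw["f"], rho=pw["rho"], alpha=pw["alpha"],
            epsilon=pw["epsilon"])),
    }
    bundle = {"config_hash": config.config_hash(), "seed": config.seed,
              "subjects": subjects, "group": group_res, "behavior": behav,
              "complexity": complexity, "power": power_res}
    if out_dir is not None:
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        behav["trial_table"].to_csv(out / "trial_table.csv", index=False)
        behav["anova_accuracy"].to_csv(out / "anova_accuracy.csv", index=False)
        behav["anova_rt"].to_csv(out / "anova_rt.csv", index=False)
        group_res["effect_table"].to_csv(out / "group_effects.csv", index=False)
        for name, cm in group_res["contrast_maps"].items():
            safe = name.replace(" ", "_").replace("/", "-")
            cm.to_csv(out / f"contrast_{safe}.csv", index=False)
    return bundle
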