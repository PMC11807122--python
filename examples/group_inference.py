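"""Group-level mixed-model inference on a small synthetic cohort.

Simulates 8 subjects end to end, pools ROI-level condition effects, and
fits the random-intercept LME (effect ~ probe * load) per ROI group,
reporting the probe x load interaction, ICC, and Nakagawa R².  Channel-
wise symmetry contrasts are FDR-corrected across the 100 long channels.
"""

from symwm.config import PipelineConfig
from symwm.montage import (CONTROL_ROI_GROUPS, TASK_ROI_GROUPS,
                           build_default_montage)
from symwm.pipeline import run_group_inference, run_subject
from symwm.stimuli import generate_stimulus_set
from symwm.synth_fnirs import default_ground_truth

cfg = PipelineConfig(seed=21, n_subjects=8, n_blocks=1)
stimulus_set = generate_stimulus_set(cfg.stage_seed("stimuli"))
montage = build_default_montage()
truth = default_ground_truth(montage)
subjects = [run_subject(cfg, i, stimulus_set, montage, truth)
            for i in range(cfg.n_subjects)]
grp = run_group_inference(subjects, cfg)

print("probe x load interaction per ROI group (HbO):")
for (unit, chroma), fit in sorted(grp["lme_fits"].items()):
    if chroma != "hbo":
        continue
    fe = fit.fixed_effects.set_index("term")
    beta = fe.loc["probe[sym]:load[high]", "beta"]
    p = fe.loc["probe[sym]:load[high]", "p"]
    tag = ("planted" if unit in TASK_ROI_GROUPS
           else "control" if unit in CONTROL_ROI_GROUPS else "")
    print(f"  {unit:13s} beta = {beta:6.2f} µM  p = {p:8.2e}  "
          f"ICC = {fit.icc:.2f}  R²m/R²c = {fit.r2_marginal:.2f}/"
          f"{fit.r2_conditional:.2f}  {tag}")

cm = grp["contrast_maps"]["symmetry x load"]
sig = cm[(cm["chroma"] == "hbo") & cm["significant"]]
print(f"\nchannel-wise interaction map: {len(sig)} of 100 long channels "
      "significant after BH-FDR (q < 0.05)")
print("-> the planted interaction appears in dlPFC/OFC/PPC/LOC and in "
      "their channels, not in the motor or early-visual controls.")
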