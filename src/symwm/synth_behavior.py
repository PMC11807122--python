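"""Synthetic trial-level responses for the delayed matching-to-sample task.

Responses carry the statistical structure the behavioral analysis
assumes: condition-dependent accuracy (symmetry x load cells), errors
concentrated near the target with extra mass on displayed distractor
locations, and lognormal condition-shifted reaction times truncated at
the 10 s response window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import ExperimentSchedule, N_ANCHORS, RESPONSE_WINDOW_S

# Calibration anchors: the study's group accuracy marginals (percent) and the
# pairwise symmetry advantage per load, from which the 2x2 cell means follow.
ACC_LOW_MEAN = 65.61
ACC_HIGH_MEAN = 32.51
SYM_ADVANTAGE_LOW = 3.11    # sym - asym accuracy difference at low load
SYM_ADVANTAGE_HIGH = 11.05  # at high load

# Reaction-time cell means and SDs (ms) for correct trials.
RT_CELLS_MS = {
    ("sym", "low"): (1183.439, 440.243),
    ("asym", "low"): (1246.709, 477.828),
    ("sym", "high"): (1283.717, 535.512),
    ("asym", "high"): (1409.002, 540.977),
}

CELLS = (("sym", "low"), ("sym", "high"), ("asym", "low"), ("asym", "high"))


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """meanlog/sdlog of a lognormal with the given arithmetic mean and SD."""
    sdlog2 = math.log(1.0 + (sd / mean) ** 2)
    meanlog = math.log(mean) - sdlog2 / 2.0
    return meanlog, math.sqrt(sdlog2)


@dataclass
class SubjectProfile:
    """Generative parameters for one simulated subject.

    ``p_correct`` maps (symmetry, load) cells to hit probabilities.  On
    error trials the chosen anchor follows a wrapped von-Mises-like
    kernel of concentration ``angular_kappa[cell]`` around the target,
    plus ``distractor_confusion_weight`` extra mass on anchors that
    hosted a displayed distractor.  Reaction times are lognormal per
    cell (``rt_meanlog``/``rt_sdlog``), truncated to
    [rt_floor_ms, 10000].
    """

    p_correct: dict[tuple[str, str], float]
    rt_meanlog: dict[tuple[str, str], float]
    rt_sdlog: dict[tuple[str, str], float]
    angular_kappa: dict[tuple[str, str], float]
    distractor_confusion_weight: float = 2.0
    rt_floor_ms: float = 150.0
    lapse_probability: float = 0.0

    def __post_init__(self):
        for cell, p in self.p_correct.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p_correct[{cell}] outside [0,1]")
        for cell, s in self.rt_sdlog.items():
            if s <= 0:
                raise ValueError(f"rt_sdlog[{cell}] must be > 0")


def default_profile() -> SubjectProfile:
    """Profile calibrated to the group-level accuracy and RT statistics.

    Cell accuracies interpolate the reported load marginals and the
    per-load symmetry advantages; RT lognormal parameters are moment
    matched to the per-cell mean/SD.  Error concentration is lower for
    asymmetric probes so that erroneous responses land farther from the
    target, mirroring the observed error-geometry asymmetry.
    """
    acc = {
        ("sym", "low"): ACC_LOW_MEAN + SYM_ADVANTAGE_LOW / 2,
        ("asym", "low"): ACC_LOW_MEAN - SYM_ADVANTAGE_LOW / 2,
        ("sym", "high"): ACC_HIGH_MEAN + SYM_ADVANTAGE_HIGH / 2,
        ("asym", "high"): ACC_HIGH_MEAN - SYM_ADVANTAGE_HIGH / 2,
    }
    p_correct = {cell: v / 100.0 for cell, v in acc.items()}
    meanlog, sdlog = {}, {}
    for cell, (m, s) in RT_CELLS_MS.items():
        ml, sl = _lognormal_params(m, s)
        meanlog[cell], sdlog[cell] = ml, sl
    kappa = {
        ("sym", "low"): 1.5, ("sym", "high"): 1.5,
        ("asym", "low"): 0.8, ("asym", "high"): 0.8,
    }
    return SubjectProfile(p_correct=p_correct, rt_meanlog=meanlog,
                          rt_sdlog=sdlog, angular_kappa=kappa)


@dataclass
class ResponseRecord:
    subject_id: str
    block: int
    trial_index: int
    chosen_anchor: int
    rt_ms: float
    correct: bool
    responded: bool = True


def _truncated_lognormal(rng, meanlog, sdlog, lo, hi, max_tries=100):
    for _ in range(max_tries):
        x = rng.lognormal(meanlog, sdlog)
        if lo <= x <= hi:
            return x
    return float(np.clip(rng.lognormal(meanlog, sdlog), lo, hi))


def simulate_responses(profile: SubjectProfile, schedule: ExperimentSchedule,
                       rng_seed: int, subject_id: str = "sub-01"
                       ) -> list[ResponseRecord]:
    """Simulate one subject's responses to a schedule (deterministic per seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 7001]))
    records: list[ResponseRecord] = []
    anchor_idx = np.arange(N_ANCHORS)
    for tr in schedule.trials:
        cell = (tr.symmetry_label, tr.load_label)
        if profile.lapse_probability > 0 and rng.random() < profile.lapse_probability:
            records.append(ResponseRecord(subject_id, tr.block, tr.trial_index,
                                          chosen_anchor=-1, rt_ms=float("nan"),
                                          correct=False, responded=False))
            continue
        if rng.random() < profile.p_correct[cell]:
            chosen = tr.target_anchor
        else:
            # wrapped angular kernel around the target over the 11 other
            # anchors, plus confusion mass on displayed distractor anchors
            delta = (anchor_idx - tr.target_anchor) * (2 * np.pi / N_ANCHORS)
            w = np.exp(profile.angular_kappa[cell] * np.cos(delta))
            distractor_anchors = [a for sid, a in tr.item_locations.items()
                                  if sid != tr.probe_id]
            w[distractor_anchors] += profile.distractor_confusion_weight * w[distractor_anchors].mean() \
                if distractor_anchors else 0.0
            w[tr.target_anchor] = 0.0
            chosen = int(rng.choice(anchor_idx, p=w / w.sum()))
        rt = _truncated_lognormal(rng, profile.rt_meanlog[cell], profile.rt_sdlog[cell],
                                  profile.rt_floor_ms, RESPONSE_WINDOW_S * 1000.0)
        records.append(ResponseRecord(subject_id, tr.block, tr.trial_index,
                                      chosen_anchor=chosen, rt_ms=float(rt),
                                      correct=chosen == tr.target_anchor))
    return records


def records_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
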