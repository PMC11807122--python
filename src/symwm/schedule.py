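"""Delayed matching-to-sample task geometry, trial schedule, and GLM events.

The task presents 2 or 4 stimuli at vertices of a dodecagon (radius 200
px) for 250 ms, imposes a 2 s maintenance delay, and probes one encoded
item's location within a 10 s response window.  The experiment runs 4
blocks of 72 trials (288 total) with 30 s block breaks and intertrial
intervals drawn from {2, 4, 6, 8, 10} s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stimuli import StimulusSet

N_ANCHORS = 12
ITI_CHOICES_S = (2.0, 4.0, 6.0, 8.0, 10.0)
ENCODE_S = 0.250
MAINTAIN_S = 2.000
RESPONSE_WINDOW_S = 10.0
BLOCK_BREAK_S = 30.0
N_BLOCKS = 4
TRIALS_PER_BLOCK = 72
EVENT_DURATION_S = 0.250

CONDITIONS = ("sym_low", "sym_high", "asym_low", "asym_high")


@dataclass(frozen=True)
class LocationLayout:
    """12 response anchors on a circle around the screen center.

    Anchor 0 sits at 12 o'clock and indices run clockwise in screen
    coordinates (y increases downward), 30 degrees apart.
    """

    center: tuple[float, float] = (960.0, 540.0)
    radius: float = 200.0
    square_size: float = 75.0
    anchors: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        k = np.arange(N_ANCHORS)
        theta = np.deg2rad(-90.0 + 30.0 * k)
        xy = np.column_stack([
            self.center[0] + self.radius * np.cos(theta),
            self.center[1] + self.radius * np.sin(theta),
        ])
        object.__setattr__(self, "anchors", xy)

    def anchor(self, index: int) -> np.ndarray:
        return self.anchors[index]


def compute_layout(center: tuple[float, float] = (960.0, 540.0),
                   radius: float = 200.0) -> LocationLayout:
    """Dodecagon anchor layout with the given center and radius (pixels)."""
    return LocationLayout(center=center, radius=radius)


@dataclass
class TrialSpec:
    block: int
    trial_index: int
    load: int                      # 2 (low) or 4 (high)
    iti_s: float
    probe_id: str
    probe_class: str               # symmetry class of the probe stimulus
    distractor_ids: list[str]
    item_locations: dict[str, int]  # stimulus id -> anchor index
    target_anchor: int

    @property
    def load_label(self) -> str:
        return "low" if self.load == 2 else "high"

    @property
    def symmetry_label(self) -> str:
        return "asym" if self.probe_class == "asymmetric" else "sym"

    @property
    def condition(self) -> str:
        return f"{self.symmetry_label}_{self.load_label}"


@dataclass
class ExperimentSchedule:
    trials: list[TrialSpec]
    rng_seed: int
    block_break_s: float = BLOCK_BREAK_S

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "block": t.block, "trial_index": t.trial_index, "load": t.load,
                "iti_s": t.iti_s, "probe_id": t.probe_id,
                "probe_class": t.probe_class, "condition": t.condition,
                "distractor_ids": ";".join(t.distractor_ids),
                "item_locations": ";".join(f"{k}:{v}" for k, v in t.item_locations.items()),
                "target_anchor": t.target_anchor,
            })
        return pd.DataFrame(rows)


def _assign_loads(rng: np.random.Generator, classes: list[str]) -> list[int]:
    # balance load within each symmetry stratum so load x symmetry is
    # exactly crossed per block (18 per cell of the 2x2)
    loads = np.empty(len(classes), dtype=int)
    cls = np.array([c == "asymmetric" for c in classes])
    for is_asym in (True, False):
        idx = np.flatnonzero(cls == is_asym)
        half = len(idx) // 2
        pattern = np.array([2] * half + [4] * (len(idx) - half))
        rng.shuffle(pattern)
        loads[idx] = pattern
    return loads.tolist()


def build_schedule(rng_seed: int, stimulus_set: StimulusSet,
                   iti_balanced: bool = False) -> ExperimentSchedule:
    """Build the 288-trial schedule for one subject.

    Each of the 72 stimuli serves as probe exactly once per block (in
    random order), giving 36 symmetric / 36 asymmetric probes per block
    with loads balanced 18/18 within each symmetry stratum.  Distractor
    symmetry classes are constrained so the encoded-item pool is exactly
    50% symmetric per block.  ITIs are drawn uniformly from
    {2, 4, 6, 8, 10} s (``iti_balanced`` cycles them evenly instead).
    """
    if len(stimulus_set) != 72:
        raise ValueError("stimulus set must contain 72 stimuli")
    sym_ids = [s.stimulus_id for s in stimulus_set.stimuli if s.symmetry_class != "asymmetric"]
    asym_ids = [s.stimulus_id for s in stimulus_set.stimuli if s.symmetry_class == "asymmetric"]
    if len(sym_ids) != 36 or len(asym_ids) != 36:
        raise ValueError("stimulus set must be 36 symmetric / 36 asymmetric")
    cls_of = {s.stimulus_id: s.symmetry_class for s in stimulus_set.stimuli}

    rng = np.random.default_rng(np.random.SeedSequence([int(rng_seed), 2024]))
    trials: list[TrialSpec] = []
    all_ids = stimulus_set.ids()
    trial_counter = 0
    for block in range(1, N_BLOCKS + 1):
        order = list(all_ids)
        rng.shuffle(order)
        classes = [cls_of[i] for i in order]
        loads = _assign_loads(rng, classes)
        # distractor symmetry pool: exactly half symmetric per block.
        n_distract = sum(l - 1 for l in loads)
        d_pool = np.array([True] * (n_distract // 2) + [False] * (n_distract - n_distract // 2))
        rng.shuffle(d_pool)
        if iti_balanced:
            itis = np.tile(ITI_CHOICES_S, TRIALS_PER_BLOCK // len(ITI_CHOICES_S) + 1)[:TRIALS_PER_BLOCK].copy()
            rng.shuffle(itis)
        else:
            itis = rng.choice(ITI_CHOICES_S, size=TRIALS_PER_BLOCK, replace=True)
        d_cursor = 0
        for i, probe_id in enumerate(order):
            load = loads[i]
            n_d = load - 1
            want_sym = d_pool[d_cursor:d_cursor + n_d]
            d_cursor += n_d
            distractors: list[str] = []
            for ws in want_sym:
                pool = sym_ids if ws else asym_ids
                while True:
                    cand = pool[rng.integers(len(pool))]
                    if cand != probe_id and cand not in distractors:
                        break
                distractors.append(cand)
            anchors = rng.choice(N_ANCHORS, size=load, replace=False)
            items = [probe_id] + distractors
            item_locations = {sid: int(a) for sid, a in zip(items, anchors)}
            trials.append(TrialSpec(
                block=block, trial_index=trial_counter, load=load,
                iti_s=float(itis[i]), probe_id=probe_id,
                probe_class=cls_of[probe_id], distractor_ids=distractors,
                item_locations=item_locations,
                target_anchor=item_locations[probe_id],
            ))
            trial_counter += 1
    return ExperimentSchedule(trials=trials, rng_seed=rng_seed)


def schedule_to_events(schedule: ExperimentSchedule,
                       response_times_s: list[float] | None = None,
                       start_offset_s: float = 0.0) -> pd.DataFrame:
    """Encoding-onset event stream (onset_s, duration_s, condition).

    One event per trial at the encoding-phase onset, 250 ms duration,
    labelled by probe symmetry x load.  Onsets accumulate ITIs, the
    encode and maintenance phases, the response period, and 30 s block
    breaks.  ``response_times_s`` (per trial, seconds) shortens the
    response period; when absent the full 10 s window is charged.
    """
    if response_times_s is not None and len(response_times_s) != len(schedule.trials):
        raise ValueError("response_times_s must have one entry per trial")
    rows = []
    t = float(start_offset_s)
    prev_block = None
    for i, tr in enumerate(schedule.trials):
        if prev_block is not None and tr.block != prev_block:
            t += schedule.block_break_s
        prev_block = tr.block
        t += tr.iti_s
        rows.append({"onset_s": t, "duration_s": EVENT_DURATION_S, "condition": tr.condition})
        resp = RESPONSE_WINDOW_S if response_times_s is None else min(
            float(response_times_s[i]), RESPONSE_WINDOW_S)
        t += ENCODE_S + MAINTAIN_S + resp
    events = pd.DataFrame(rows)
    if not events["onset_s"].is_monotonic_increasing:
        raise RuntimeError("event onsets must be strictly increasing")
    return events


def write_events_tsv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, sep="\t", index=False, header=False)
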