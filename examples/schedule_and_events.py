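"""Build a subject's trial schedule and the event stream the GLM consumes.

Shows the dodecagon geometry, the 4x72 balanced trial structure, and
how trial timing (ITIs, encode/maintain phases, responses, block
breaks) turns into 250 ms encoding-onset events.
"""

import numpy as np

from symwm.schedule import build_schedule, compute_layout, schedule_to_events
from symwm.stimuli import generate_stimulus_set

layout = compute_layout()
d01 = np.linalg.norm(layout.anchor(0) - layout.anchor(1))
print(f"12 anchors on a 200 px circle; adjacent anchors {d01:.1f} px apart "
      f"(chord of 30 degrees)")

stimulus_set = generate_stimulus_set(7)
schedule = build_schedule(3, stimulus_set)
df = schedule.to_frame()
print(f"\n{len(schedule)} trials in {df['block'].nunique()} blocks; "
      f"per-block condition counts:")
print(df.groupby(['block', 'condition']).size().unstack().to_string())

events = schedule_to_events(schedule)
print(f"\n{len(events)} events, duration {events['duration_s'].iloc[0]} s each; "
      f"first onset {events['onset_s'].iloc[0]:.1f} s, "
      f"last {events['onset_s'].iloc[-1]:.1f} s")
print("-> each trial contributes one encoding-onset event labelled by "
      "probe symmetry x load; the 2x2 crossing is exactly balanced "
      "(18 trials per cell per block) by construction.")
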