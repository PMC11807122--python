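"""Generate the 72-stimulus set and compare compression-based complexity.

Symmetric 6x6 grids are redundant and compress into smaller JPEG files
than asymmetric grids with the same number of black cells; the Welch
t-test quantifies that separation.
"""

from symwm import stimuli

stimulus_set = stimuli.generate_stimulus_set(rng_seed=7)
scores = stimuli.score_set(stimulus_set)
res = stimuli.compare_complexity(stimulus_set, scores)

print(f"stimuli: {len(stimulus_set)} "
      f"({len(stimulus_set.by_class('asymmetric'))} asymmetric, "
      f"12 per symmetry axis), all with 18/36 black cells")
print(f"mean JPEG bytes  asymmetric: {res['mean_asymmetric']:.1f}  "
      f"symmetric: {res['mean_symmetric']:.1f}")
print(f"Welch t({res['df']:.1f}) = {res['t']:.2f}, p = {res['p']:.4f}")
print("-> asymmetric stimuli carry more non-redundant structure: larger "
      "compressed files mean higher visual complexity.")
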