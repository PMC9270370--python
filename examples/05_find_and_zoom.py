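"""Predict mitosis from bud growth and zoom in on it.

A coarse 3-min brightfield search watches every bud; when one has reached
its size threshold and grown over each of the last three frames, the engine
switches that position to 30 s imaging with RFP added for 20 min, capturing
the nuclear separation, then resumes the search.  Prints the episodes and
whether each one imaged the separation of the cell that triggered it.
"""

from eventscope.validation import find_and_zoom_study, mitosis_rule_study

rule = mitosis_rule_study(seed=1)
print(f"divisions observed           : {rule['n_divisions']}")
print(f"trigger lead (coarse frames) : {sorted(set(rule['leads_frames']))}")
zoom = find_and_zoom_study(seed=1)
print(f"zoom episodes                : {zoom['n_episodes']} "
      f"(30 s cadence exact: {zoom['zoom_spacing_exact']})")
print(f"all episodes image the separation: "
      f"{zoom['all_episodes_capture_separation']}")
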