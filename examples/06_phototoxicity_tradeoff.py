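"""Why adaptive sampling exists: the phototoxicity/sampling trade-off.

From the same 12-cell colony and seed, runs (a) a naive MDA acquiring a
fluorescence frame every 25 s for 3 h, and (b) the adaptive stress protocol
that only bursts around each stimulus.  The naive run's photodose arrests
growth; the adaptive run preserves it.
"""

from eventscope.validation import phototoxicity_ab_study

r = phototoxicity_ab_study(seed=1)
print(f"naive 25 s MDA   : final/initial = {r['naive_final_over_initial']:.2f}"
      "  (growth arrested)")
print(f"adaptive protocol: final/initial = "
      f"{r['adaptive_final_over_initial']:.2f}  (growth preserved)")
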