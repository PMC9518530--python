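"""Generate a study-shaped synthetic panel: 17 regions x 27 indicators.

The generator emulates a provincial emergency-resilience data
situation: four capacity dimensions (resistance, restore, adaptability,
collaborative), three negative-attribute indicators, heterogeneous
measurement scales, a handful of missing cells, and spatially
structured latent quality.
"""

import numpy as np

from emresilience import SyntheticSpec, make_panel, validate_panel

panel, coords = make_panel(SyntheticSpec(seed=42))

print(f"panel: {panel.n_regions} regions x {panel.n_indicators} indicators")
print(f"missing cells: {int(panel.missing_mask.sum())} "
      "(sparse gaps, at most one per indicator)")
print(f"validation issues: {validate_panel(panel)}")

spans = np.nanmax(panel.values, axis=0) - np.nanmin(panel.values, axis=0)
print(f"column span ratio (largest/smallest): {spans.max() / spans.min():.0f}")
print("-> scales are wildly heterogeneous (counts vs percentages vs 10^4 Yuan),")
print("   which is why min-max standardization precedes any comparison.")

negatives = [d.code for d in panel.scheme if d.attribute == "negative"]
print(f"negative-attribute indicators (larger raw value = worse): {negatives}")
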