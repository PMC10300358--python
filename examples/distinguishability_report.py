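"""Species distinguishability accounting.

Recomputes the headline panel tallies from the packaged 28-species status
table and cross-checks the visual-distinguishability proxy against the
panel's configured look-alike pairs.
"""

import json

import meltid as m
from meltid.evaluate import panel_tallies, visual_distinguishability
from meltid.io_mic import read_species_status_table

tallies = panel_tallies(read_species_status_table())
print(json.dumps(tallies, indent=2))
# visual_total: species an inspector could separate by signature shape alone;
# dl_total: species the classifier separates; combined_total is their union,
# recomputed from flags rather than copied from any headline number.

panel = m.build_default_panel(seed=1)
report = visual_distinguishability(panel)
confusable = report[~report.distinguishable].species.tolist()
print("visually confusable species in the simulated panel:")
for name in confusable:
    print(f"  {name}")
# These are exactly the three configured pairs: tiger shark / giant
# shovelnose ray, the two Mobula rays, and silky / blue shark.
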