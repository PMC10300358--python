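"""Simulate the default two-channel melt-curve corpus.

Builds the 28-species shark/ray panel, generates the 390-run training corpus
(130 specimens x 3 replicates, with the packaged 33-run failure manifest)
plus 68 single-run test specimens, and prints what was made.
"""

import meltid as m
from meltid.design import default_design, generate_corpus

panel = m.build_default_panel(seed=1)
design = default_design(panel, seed=0)
train, test, truth = generate_corpus(panel, design, m.AcquisitionGrid(n_points=512),
                                     m.NoiseModel())

print(f"panel: {len(panel)} species, "
      f"{sum(p.cites_listed for p in panel)} CITES-listed")
print(f"training corpus: {len(train)} runs from "
      f"{truth[truth.subset == 'train'].specimen_id.nunique()} specimens")
print(f"test corpus: {len(test)} single-run specimens")
print("injected failures:",
      truth[truth.injected_failure != 'none'].injected_failure
      .value_counts().to_dict())

# Each run is a BS1/BS2 raw curve pair; BS1 always ends in the internal
# ThermaMark trough near 84 degC used later for temperature correction.
run = train[0]
print(f"example run {run.run_id}: {run.species_name}, "
      f"{len(run.bs1_curve.temperatures)} points per channel, "
      f"condition={run.sample_condition}")
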