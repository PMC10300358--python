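"""Derivative signatures and marker-based temperature correction.

Simulates one run with a deliberate +1.5 degC instrument temperature offset,
extracts the derivative signature, detects the internal marker trough, and
shows that correction moves the species transitions back to their true
melting temperatures.
"""

import numpy as np

import meltid as m
from meltid.signatures import derivative_signature, detect_tm_marker, process_run

panel = m.build_default_panel(seed=1)
species = panel[0]
grid = m.AcquisitionGrid(n_points=1024)

offset = 1.5
run = m.RunRecord(
    "demo-r1", "demo", species.species_name, 1, "fresh",
    m.simulate_curve(species.bs1, grid, m.NoiseModel.zero(), 0,
                     temperature_offset=offset),
    m.simulate_curve(species.bs2, grid, m.NoiseModel.zero(), 0, "BS2",
                     temperature_offset=offset))

raw_sig = derivative_signature(run.bs1_curve)
marker = detect_tm_marker(raw_sig)
print(f"true transition tms: {[round(c.tm, 2) for c in species.bs1.components]}")
print(f"marker trough detected at {marker:.2f} degC "
      f"(nominal {m.MARKER_TM}, injected offset +{offset})")

corrected = process_run(run)
half = grid.n_points // 2
trough = grid.temperatures[np.argmin(corrected.bs1.values[:half])]
print(f"deepest BS1 species trough after correction: {trough:.2f} degC")
# The corrected trough matches one of the true tms to within a grid step:
# the rigid marker shift removed the instrument drift from both channels.
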