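"""Default 28-species shark/ray signature panel.

Species identities, CITES status and per-segment amplification behaviour come
from the packaged status table; the generative melting parameters standing in
for each species' probe-target transitions are drawn deterministically from a
seed.  Three look-alike pairs are configured to share parameters, emulating
species whose mini-barcode sequences produce (near-)identical signatures:

* tiger shark / giant shovelnose ray — identical in both segments,
* giant oceanic manta ray / giant devil ray — identical in both segments,
* silky shark / blue shark — identical BS1, BS2 differing by a 0.2 degC
  shift of a single transition.
"""

from __future__ import annotations

import copy

import numpy as np

from .io_mic import read_species_status_table
from .meltsim import MeltComponent, SegmentModel, SpeciesSignatureModel

__all__ = ["LOOKALIKE_PAIRS", "build_default_panel"]

#: Species pairs expected to remain mutually confusable by any classifier.
LOOKALIKE_PAIRS: tuple[tuple[str, str], ...] = (
    ("Galeocerdo cuvier", "Glaucostegus typus"),
    ("Mobula birostris", "Mobula mobular"),
    ("Carcharhinus falciformis", "Prionace glauca"),
)

_TM_SLOTS = np.linspace(46.5, 78.5, 14)
_BASE_FAILURE_PROB = 0.02
_ELEVATED_FAILURE_PROB = 0.35


def _draw_segment(rng: np.random.Generator, marker: bool) -> SegmentModel:
    n = int(rng.integers(2, 5))
    slots = rng.choice(len(_TM_SLOTS), size=n, replace=False)
    comps = []
    for s in sorted(slots):
        tm = float(_TM_SLOTS[s] + rng.uniform(-0.5, 0.5))
        width = float(rng.uniform(0.35, 0.6))
        amplitude = float(rng.uniform(0.6, 1.2))
        comps.append(MeltComponent(tm=tm, width=width, amplitude=amplitude))
    return SegmentModel(components=comps, includes_tm_marker=marker)


def build_default_panel(seed: int) -> list[SpeciesSignatureModel]:
    """Build the default panel, in status-table (report) order."""
    table = read_species_status_table()
    rng = np.random.default_rng(seed)
    panel: list[SpeciesSignatureModel] = []
    for row in table.itertuples(index=False):
        panel.append(SpeciesSignatureModel(
            species_name=row.species,
            english_name=row.english_name,
            cites_listed=bool(row.cites_listed),
            group=row.group,
            bs1=_draw_segment(rng, marker=True),
            bs2=_draw_segment(rng, marker=False),
            bs1_failure_prob=_BASE_FAILURE_PROB if row.amplifies_bs1 else _ELEVATED_FAILURE_PROB,
            bs2_failure_prob=_BASE_FAILURE_PROB if row.amplifies_bs2 else _ELEVATED_FAILURE_PROB,
        ))

    by_name = {m.species_name: m for m in panel}
    for a, b in LOOKALIKE_PAIRS[:2]:  # fully identical pairs
        by_name[b].bs1 = copy.deepcopy(by_name[a].bs1)
        by_name[b].bs2 = copy.deepcopy(by_name[a].bs2)
    silky, blue = (by_name[n] for n in LOOKALIKE_PAIRS[2])
    blue.bs1 = copy.deepcopy(silky.bs1)
    blue.bs2 = copy.deepcopy(silky.bs2)
    # near-identical BS2: one transition nudged by 0.2 degC
    c0 = blue.bs2.components[0]
    blue.bs2.components[0] = MeltComponent(tm=c0.tm + 0.2, width=c0.width,
                                           amplitude=c0.amplitude)
    return panel
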