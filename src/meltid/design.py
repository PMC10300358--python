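"""Corpus design: specimen allocation, failure injection, corpus generation.

The default training corpus mirrors the structure of the study data this
package emulates: 130 specimens spread over 28 species (sampling was
opportunistic, so counts are unequal — here 9 commonly traded species carry
6 specimens each and the remaining 19 carry 4), three replicate runs per
specimen (390 runs), plus 68 independent single-run test specimens covering
every species.  A packaged manifest injects exactly 33 failed runs —
hybridization failures and inconsistent replicates — concentrated on the
species whose segments amplify unreliably, so that quality-control filtering
retains 357 runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meltsim import (AcquisitionGrid, NoiseModel, RunRecord,
                      SpeciesSignatureModel, simulate_run)

__all__ = ["CorpusDesign", "default_design", "default_allocation",
           "default_test_allocation", "default_failure_manifest",
           "generate_corpus"]

_SIX_SPECIMEN_SPECIES = (
    "Alopias pelagicus", "Carcharhinus falciformis", "Sphyrna lewini",
    "Carcharhinus sorrah", "Prionace glauca", "Stegostoma fasciatum",
    "Gymnura poecilura", "Himantura imbricata", "Telatrygon zugei",
)
_EXTRA_TEST_SPECIES = _SIX_SPECIMEN_SPECIES + (
    "Alopias superciliosus", "Neotrygon orientalis", "Rhynchobatus australiae",
)

# (species, specimen ordinal within species, replicate, failure mode);
# at most one failure per specimen so replicate-consistency checks can
# adjudicate unambiguously.
_FAILURE_PLAN: tuple[tuple[str, int, int, str], ...] = (
    ("Carcharhinus longimanus", 1, 1, "hybridization_bs1"),
    ("Carcharhinus longimanus", 2, 2, "hybridization_bs1"),
    ("Isurus oxyrinchus", 1, 1, "hybridization_bs1"),
    ("Isurus oxyrinchus", 2, 2, "hybridization_bs1"),
    ("Lamna nasus", 1, 1, "hybridization_bs1"),
    ("Lamna nasus", 2, 2, "hybridization_bs1"),
    ("Pristis pristis", 1, 1, "hybridization_bs1"),
    ("Pristis pristis", 2, 2, "hybridization_bs1"),
    ("Rhynchobatus laevis", 1, 1, "hybridization_bs1"),
    ("Rhynchobatus laevis", 2, 2, "hybridization_bs1"),
    ("Glaucostegus typus", 1, 1, "hybridization_bs1"),
    ("Glaucostegus typus", 2, 2, "hybridization_bs1"),
    ("Galeocerdo cuvier", 1, 1, "hybridization_bs1"),
    ("Galeocerdo cuvier", 2, 2, "hybridization_bs1"),
    ("Carcharhinus falciformis", 1, 1, "hybridization_bs2"),
    ("Carcharhinus falciformis", 2, 2, "hybridization_bs2"),
    ("Carcharhinus falciformis", 3, 3, "hybridization_bs2"),
    ("Prionace glauca", 1, 1, "hybridization_bs2"),
    ("Prionace glauca", 2, 2, "hybridization_bs2"),
    ("Prionace glauca", 3, 3, "hybridization_bs2"),
    ("Carcharhinus brevipinna", 1, 1, "hybridization_bs2"),
    ("Carcharhinus brevipinna", 2, 2, "hybridization_bs2"),
    ("Glaucostegus typus", 3, 1, "hybridization_bs2"),
    ("Galeocerdo cuvier", 3, 1, "hybridization_bs2"),
    ("Isurus oxyrinchus", 3, 2, "inconsistent"),
    ("Rhynchobatus laevis", 3, 1, "inconsistent"),
    ("Glaucostegus typus", 4, 2, "inconsistent"),
    ("Galeocerdo cuvier", 4, 3, "inconsistent"),
    ("Carcharhinus sorrah", 1, 2, "inconsistent"),
    ("Stegostoma fasciatum", 1, 3, "inconsistent"),
    ("Sphyrna lewini", 1, 1, "inconsistent"),
    ("Sphyrna mokarran", 1, 2, "inconsistent"),
    ("Mobula birostris", 1, 1, "inconsistent"),
)


def default_allocation(species_names: list[str]) -> dict[str, int]:
    """Training specimens per species (sums to 130 on the default panel)."""
    return {s: 6 if s in _SIX_SPECIMEN_SPECIES else 4 for s in species_names}


def default_test_allocation(species_names: list[str]) -> dict[str, int]:
    """Single-run test specimens per species (sums to 68 on the default panel)."""
    return {s: 3 if s in _EXTRA_TEST_SPECIES else 2 for s in species_names}


@dataclass
class CorpusDesign:
    specimens_per_species: dict[str, int]
    test_specimens_per_species: dict[str, int]
    replicates: int = 3
    failure_manifest: dict[str, str] = field(default_factory=dict)  # run_id -> mode
    seed: int = 0
    #: pin every run not named in the manifest to a clean simulation, so the
    #: corpus contains exactly the manifest's failures
    pin_unlisted_to_none: bool = True

    @property
    def n_training_runs(self) -> int:
        return sum(self.specimens_per_species.values()) * self.replicates

    @property
    def n_test_runs(self) -> int:
        return sum(self.test_specimens_per_species.values())


def _specimen_table(design: CorpusDesign) -> pd.DataFrame:
    rows = []
    i = 0
    for species, n in design.specimens_per_species.items():
        for ordinal in range(1, n + 1):
            i += 1
            rows.append({"specimen_id": f"SP{i:03d}", "species": species,
                         "ordinal": ordinal,
                         "condition": "processed" if i % 2 == 0 else "fresh"})
    return pd.DataFrame(rows)


def default_design(panel: list[SpeciesSignatureModel], seed: int = 0) -> CorpusDesign:
    names = [m.species_name for m in panel]
    design = CorpusDesign(specimens_per_species=default_allocation(names),
                          test_specimens_per_species=default_test_allocation(names),
                          seed=seed)
    spec = _specimen_table(design)
    manifest = {}
    for species, ordinal, replicate, mode in _FAILURE_PLAN:
        row = spec[(spec.species == species) & (spec.ordinal == ordinal)]
        if row.empty:
            raise ValueError(f"failure plan references absent specimen: "
                             f"{species} #{ordinal}")
        manifest[f"{row.specimen_id.iloc[0]}-r{replicate}"] = mode
    design.failure_manifest = manifest
    return design


def generate_corpus(panel: list[SpeciesSignatureModel], design: CorpusDesign,
                    grid: AcquisitionGrid | None = None,
                    noise: NoiseModel | None = None,
                    ) -> tuple[list[RunRecord], list[RunRecord], pd.DataFrame]:
    """Simulate the full training + test corpus.

    Returns (training runs, test runs, truth manifest).  Output is a pure
    function of (panel, design, grid, noise).
    """
    grid = grid or AcquisitionGrid()
    noise = noise or NoiseModel()
    by_name = {m.species_name: m for m in panel}
    missing = set(design.specimens_per_species) - set(by_name)
    if missing:
        raise ValueError(f"design references species absent from panel: {sorted(missing)}")

    spec = _specimen_table(design)
    valid_ids = {f"{r.specimen_id}-r{k}" for r in spec.itertuples()
                 for k in range(1, design.replicates + 1)}
    bad = set(design.failure_manifest) - valid_ids
    if bad:
        raise ValueError(f"failure manifest references absent runs: {sorted(bad)}")

    train: list[RunRecord] = []
    idx = 0
    for row in spec.itertuples(index=False):
        for k in range(1, design.replicates + 1):
            run_id = f"{row.specimen_id}-r{k}"
            pinned = design.failure_manifest.get(
                run_id, "none" if design.pin_unlisted_to_none else None)
            rng = np.random.default_rng([design.seed, idx])
            train.append(simulate_run(by_name[row.species], run_id=run_id,
                                      specimen_id=row.specimen_id, replicate=k,
                                      sample_condition=row.condition,
                                      grid=grid, noise=noise, seed=rng,
                                      pinned_failure=pinned))
            idx += 1

    test: list[RunRecord] = []
    j = 0
    for species, n in design.test_specimens_per_species.items():
        for _ in range(n):
            j += 1
            specimen_id = f"TS{j:03d}"
            rng = np.random.default_rng([design.seed, idx])
            test.append(simulate_run(by_name[species], run_id=f"{specimen_id}-r1",
                                     specimen_id=specimen_id, replicate=1,
                                     sample_condition="processed" if j % 2 == 0 else "fresh",
                                     grid=grid, noise=noise, seed=rng,
                                     pinned_failure="none"))
            idx += 1

    truth = pd.DataFrame(
        [{"run_id": r.run_id, "specimen_id": r.specimen_id,
          "species": r.species_name, "replicate": r.replicate,
          "condition": r.sample_condition, "injected_failure": r.injected_failure,
          "subset": subset}
         for subset, runs in (("train", train), ("test", test)) for r in runs])
    return train, test, truth
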