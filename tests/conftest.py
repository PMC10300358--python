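import numpy as np
import pytest

import meltid as m
from meltid.design import default_design, generate_corpus
from meltid.qc import filter_corpus
from meltid.signatures import process_run


@pytest.fixture(scope="session")
def panel():
    return m.build_default_panel(1)


@pytest.fixture(scope="session")
def small_grid():
    return m.AcquisitionGrid(n_points=256)


@pytest.fixture(scope="session")
def desk_grid():
    """Reduced-resolution acquisition grid used for end-to-end tests."""
    return m.AcquisitionGrid(n_points=512)


@pytest.fixture(scope="session")
def desk_corpus(panel, desk_grid):
    """Default 390+68-run corpus at desk resolution, processed and filtered."""
    design = default_design(panel, seed=3)
    train, test, truth = generate_corpus(panel, design, desk_grid, m.NoiseModel())
    processed_train = [process_run(r) for r in train]
    processed_test = [process_run(r) for r in test]
    retained, report = filter_corpus(processed_train)
    return {"design": design, "truth": truth,
            "train_runs": train, "test_runs": test,
            "processed_train": processed_train, "processed_test": processed_test,
            "retained": retained, "report": report}


@pytest.fixture()
def two_species(panel):
    """A well-separated two-species sub-panel (no look-alikes)."""
    by = {p.species_name: p for p in panel}
    return [by["Alopias pelagicus"], by["Sphyrna lewini"]]


def simulate_small_corpus(models, grid, noise, n_specimens=4, replicates=3, seed=0,
                          failures=None):
    """Tiny labelled corpus helper used across test modules."""
    runs = []
    failures = failures or {}
    idx = 0
    for mi, model in enumerate(models):
        for s in range(n_specimens):
            sid = f"S{mi}{s:02d}"
            for k in range(1, replicates + 1):
                rid = f"{sid}-r{k}"
                runs.append(m.simulate_run(
                    model, run_id=rid, specimen_id=sid, replicate=k,
                    sample_condition="fresh", grid=grid, noise=noise,
                    seed=np.random.default_rng([seed, idx]),
                    pinned_failure=failures.get(rid, "none")))
                idx += 1
    return runs
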