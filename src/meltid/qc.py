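"""Run-level quality control: hybridization-failure and replicate filtering.

Two rules, applied in order, mirror how ambiguous qPCR runs are discarded
before training a classifier:

1. Hybridization failure.  A BS1 signature whose only trough is the internal
   temperature marker means the probes never hybridized: after masking a
   band around the marker, the residual signature energy is compared to the
   marker trough's energy.  A BS2 signature is failed when its total energy
   collapses relative to the corpus median (BS2 has no marker to reference).
2. Replicate inconsistency.  Within a specimen, signatures that disagree
   with their sibling replicates (correlation distance above a threshold)
   are removed by iterative outlier rejection; singleton specimens are never
   flagged by this rule.

Both thresholds are properties of this package's noise model — the energy
ratios of clean, degraded and failed runs are separated by more than an
order of magnitude, so the defaults recover injected failures exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .meltsim import MARKER_TM
from .signatures import ProcessedRun

__all__ = ["QCThresholds", "QCReport", "flag_hybridization_failure",
           "flag_replicate_inconsistency", "filter_corpus"]

_STATUSES = ("pass", "fail_hybridization_bs1", "fail_hybridization_bs2",
             "fail_inconsistent")


@dataclass(frozen=True)
class QCThresholds:
    theta_h: float = 0.05      # relative energy, hybridization rule
    theta_c: float = 0.2       # correlation distance, consistency rule
    marker_mask_halfwidth: float = 1.5  # degC masked around the marker trough
    reference_tm: float = MARKER_TM


@dataclass
class QCReport:
    statuses: pd.DataFrame          # run_id, specimen_id, species, condition, status
    n_input: int
    n_retained: int
    removals_by_cause: dict[str, int] = field(default_factory=dict)
    condition_reliability: pd.DataFrame | None = None
    species_amplification: pd.DataFrame | None = None

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def _energy(values: np.ndarray) -> float:
    return float(np.sum(np.square(values)))


def flag_hybridization_failure(run: ProcessedRun, median_bs2_energy: float,
                               thresholds: QCThresholds | None = None,
                               ) -> tuple[bool, bool]:
    """Per-segment hybridization-failure flags for one run."""
    th = thresholds or QCThresholds()
    if not run.tm_ok:
        return True, False  # no marker at all: BS1 never hybridized usably
    temps = run.bs1.grid.temperatures
    mask = np.abs(temps - th.reference_tm) <= th.marker_mask_halfwidth
    marker_energy = _energy(run.bs1.values[mask])
    residual = _energy(run.bs1.values[~mask])
    bs1_fail = marker_energy > 0 and residual < th.theta_h * marker_energy
    bs2_fail = _energy(run.bs2.values) < th.theta_h * median_bs2_energy
    return bool(bs1_fail), bool(bs2_fail)


def _merged(run: ProcessedRun) -> np.ndarray:
    return np.concatenate([run.bs1.values, run.bs2.values])


def _corr_distance(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0.0 or sb == 0.0:
        return 0.0 if sa == sb else 1.0
    return float(1.0 - np.corrcoef(a, b)[0, 1])


def flag_replicate_inconsistency(specimen_runs: list[ProcessedRun],
                                 theta_c: float = 0.2) -> set[str]:
    """Run ids of replicates inconsistent with their specimen's siblings.

    Iterative rejection: while any surviving pair disagrees beyond
    ``theta_c``, drop the run with the largest mean distance to the others
    (ties by run id).  With two survivors no side can be adjudicated and
    both are flagged.
    """
    if len(specimen_runs) < 2:
        return set()
    active = sorted(specimen_runs, key=lambda r: r.run_id)
    vecs = {r.run_id: _merged(r) for r in active}
    flagged: set[str] = set()
    while len(active) >= 2:
        ids = [r.run_id for r in active]
        dists = np.zeros((len(ids), len(ids)))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = _corr_distance(vecs[ids[i]], vecs[ids[j]])
                dists[i, j] = dists[j, i] = d
        if dists.max() <= theta_c:
            break
        if len(active) == 2:
            flagged.update(ids)
            break
        worst = int(np.argmax(dists.mean(axis=1)))
        flagged.add(ids[worst])
        active = [r for r in active if r.run_id != ids[worst]]
    return flagged


def filter_corpus(runs: list[ProcessedRun],
                  thresholds: QCThresholds | None = None,
                  ) -> tuple[list[ProcessedRun], QCReport]:
    """Apply both QC rules; return retained runs and the tally report."""
    if not runs:
        raise ValueError("cannot QC an empty corpus")
    th = thresholds or QCThresholds()
    median_bs2 = float(np.median([_energy(r.bs2.values) for r in runs]))

    status: dict[str, str] = {}
    survivors: list[ProcessedRun] = []
    for run in runs:
        bs1_fail, bs2_fail = flag_hybridization_failure(run, median_bs2, th)
        if bs1_fail:
            status[run.run_id] = "fail_hybridization_bs1"
        elif bs2_fail:
            status[run.run_id] = "fail_hybridization_bs2"
        else:
            survivors.append(run)

    by_specimen: dict[str, list[ProcessedRun]] = {}
    for run in survivors:
        by_specimen.setdefault(run.specimen_id, []).append(run)
    for specimen_runs in by_specimen.values():
        for rid in flag_replicate_inconsistency(specimen_runs, th.theta_c):
            status[rid] = "fail_inconsistent"

    rows, retained = [], []
    for run in runs:
        st = status.get(run.run_id, "pass")
        if st == "pass":
            retained.append(run)
        rows.append({"run_id": run.run_id, "specimen_id": run.specimen_id,
                     "species": run.species_name, "condition": run.sample_condition,
                     "status": st})
    frame = pd.DataFrame(rows)

    removals = {s: int((frame.status == s).sum()) for s in _STATUSES[1:]}
    cond = (frame.assign(reliable=frame.status == "pass")
            .groupby("condition")["reliable"]
            .agg(passed="sum", total="count"))
    cond["rate_percent"] = (100.0 * cond.passed / cond.total).round(1)

    amp_rows = []
    for species, grp in frame.groupby("species", dropna=False):
        amp_rows.append({
            "species": species,
            "amplifies_bs1": (grp.status == "fail_hybridization_bs1").mean() < 0.5,
            "amplifies_bs2": (grp.status == "fail_hybridization_bs2").mean() < 0.5,
        })
    report = QCReport(statuses=frame, n_input=len(runs), n_retained=len(retained),
                      removals_by_cause=removals,
                      condition_reliability=cond.reset_index(),
                      species_amplification=pd.DataFrame(amp_rows))
    return retained, report
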