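"""Evaluation: confusion matrix, accuracy, distinguishability accounting.

Two complementary notions of species distinguishability are reported:

* *visual* — a reproducible proxy for side-by-side curve comparison: a
  species is visually indistinguishable when some other species' noise-free
  mean signature lies within a small correlation distance in BOTH barcode
  segments (one clearly different segment suffices for a human).
* *deep learning* — from held-out predictions: a species is distinguishable
  when none of its specimens are misassigned and no other species' specimen
  is assigned to it; a correctly assigned species whose winning score margin
  ever drops below 0.1 carries a misassignment-risk flag.

Panel tallies are recomputed from the status-table flags rather than
hard-coded, including the visual/DL union, so internal inconsistencies in a
transcribed table surface as numbers instead of being silently reproduced.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .classifier import Prediction
from .meltsim import AcquisitionGrid, SpeciesSignatureModel
from .signatures import analytic_derivative

__all__ = ["confusion_matrix", "accuracy", "dl_distinguishability",
           "visual_distinguishability", "panel_tallies"]


def confusion_matrix(truth: list[str], predicted: list[str],
                     labels: list[str]) -> pd.DataFrame:
    """True-by-predicted count table in a fixed (report-order) label set."""
    if len(truth) != len(predicted):
        raise ValueError("truth and prediction lists differ in length")
    unknown = (set(truth) | set(predicted)) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the panel: {sorted(unknown)}")
    counts = _sk_confusion(truth, predicted, labels=labels)
    return pd.DataFrame(counts, index=pd.Index(labels, name="true"),
                        columns=pd.Index(labels, name="predicted"))


def accuracy(cm: pd.DataFrame) -> float:
    """Percent correct, to two decimals (e.g. 54 of 68 -> 79.41)."""
    total = int(cm.to_numpy().sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return round(100.0 * float(np.trace(cm.to_numpy())) / total, 2)


def dl_distinguishability(predictions: list[Prediction], truth: dict[str, str],
                          panel_species: list[str],
                          risk_margin: float = 0.1) -> pd.DataFrame:
    """Per-species classifier distinguishability from held-out predictions."""
    rows = []
    pred_by_run = {p.run_id: p for p in predictions}
    missing = set(pred_by_run) - set(truth)
    if missing:
        raise ValueError(f"predictions without truth labels: {sorted(missing)[:3]}")
    for species in panel_species:
        runs = [rid for rid, sp in truth.items() if sp == species]
        if not runs:
            rows.append({"species": species, "status": "unassessed",
                         "distinguishable": False, "misassignment_risk": False})
            continue
        out_wrong = any(pred_by_run[r].predicted != species for r in runs)
        in_wrong = any(p.predicted == species and truth[p.run_id] != species
                       for p in predictions)
        ok = not (out_wrong or in_wrong)
        risk = ok and any(pred_by_run[r].margin < risk_margin for r in runs)
        rows.append({"species": species,
                     "status": "distinguishable" if ok else "indistinguishable",
                     "distinguishable": ok, "misassignment_risk": risk})
    return pd.DataFrame(rows)


def visual_distinguishability(panel: list[SpeciesSignatureModel],
                              grid: AcquisitionGrid | None = None,
                              delta: float = 0.05) -> pd.DataFrame:
    """Pairwise-distance proxy for visual signature comparison (symmetric)."""
    if len(panel) < 2:
        return pd.DataFrame([{"species": m.species_name, "distinguishable": True}
                             for m in panel])
    grid = grid or AcquisitionGrid(n_points=1019)
    sigs = {m.species_name: (analytic_derivative(m.bs1, grid),
                             analytic_derivative(m.bs2, grid)) for m in panel}

    def dist(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0 if np.std(a) == np.std(b) else 1.0
        return float(1.0 - np.corrcoef(a, b)[0, 1])

    rows = []
    names = [m.species_name for m in panel]
    for s in names:
        confusable = any(
            dist(sigs[s][0], sigs[o][0]) < delta and dist(sigs[s][1], sigs[o][1]) < delta
            for o in names if o != s)
        rows.append({"species": s, "distinguishable": not confusable})
    return pd.DataFrame(rows)


def panel_tallies(table: pd.DataFrame) -> dict[str, int]:
    """Recompute headline counts from a 28-species status table's flags."""
    if len(table) != 28:
        raise ValueError("panel tallies expect the 28-species status table")
    cites = table.cites_listed
    visual = table.visual_distinguishable
    dl = table.dl_distinguishable
    combined = visual | dl
    return {
        "n_species": int(len(table)),
        "visual_total": int(visual.sum()),
        "dl_total": int(dl.sum()),
        "combined_total": int(combined.sum()),
        "cites_total": int(cites.sum()),
        "cites_sharks": int((cites & (table.group == "shark")).sum()),
        "cites_rays": int((cites & (table.group == "ray")).sum()),
        "visual_and_cites": int((visual & cites).sum()),
        "combined_and_cites": int((combined & cites).sum()),
        "dl_misassignment_risk": int(table.dl_misassignment_risk.sum()),
    }
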