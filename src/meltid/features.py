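"""Classifier inputs: two-segment feature fusion and variable importance.

Each run contributes one row: the BS1 and BS2 derivative signatures
concatenated on the canonical grid (2 x 4,076 = 8,152 values at defaults).
Replicates enter as independent rows; the specimen id is carried alongside
so that leak-aware (group-by-specimen) splitting remains possible.  A run
whose failed segment was retained by QC keeps that half of the vector as
zeros rather than being dropped, so single-segment species stay
classifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signatures import ProcessedRun, Signature

__all__ = ["FeatureMatrix", "merge_segments", "build_matrix", "variable_importance"]


@dataclass
class FeatureMatrix:
    run_ids: list[str]
    specimen_ids: list[str]
    labels: list[str | None]
    feature_names: list[str]
    values: np.ndarray  # runs x features

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.run_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape does not match ids/names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing values")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(indices)
        return FeatureMatrix([self.run_ids[i] for i in idx],
                             [self.specimen_ids[i] for i in idx],
                             [self.labels[i] for i in idx],
                             self.feature_names, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, columns=self.feature_names)
        frame.insert(0, "species", self.labels)
        frame.insert(0, "specimen_id", self.specimen_ids)
        frame.insert(0, "run_id", self.run_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        meta = ["run_id", "specimen_id", "species"]
        names = [c for c in frame.columns if c not in meta]
        labels = [None if pd.isna(s) else s for s in frame["species"]]
        return cls(list(frame["run_id"]), list(frame["specimen_id"]), labels,
                   names, frame[names].to_numpy(dtype=float))


def _grids_match(a: Signature, b: Signature) -> bool:
    return (a.grid.n_points == b.grid.n_points
            and np.isclose(a.grid.t_min, b.grid.t_min)
            and np.isclose(a.grid.t_max, b.grid.t_max))


def merge_segments(bs1: Signature, bs2: Signature) -> np.ndarray:
    """Concatenate [BS1 | BS2] signature values into one feature vector."""
    if not _grids_match(bs1, bs2):
        raise ValueError("cannot merge signatures on different grids")
    return np.concatenate([bs1.values, bs2.values])


def feature_names_for(bs1: Signature) -> list[str]:
    temps = bs1.grid.temperatures
    return [f"BS1@{t:.3f}" for t in temps] + [f"BS2@{t:.3f}" for t in temps]


def build_matrix(runs: list[ProcessedRun]) -> FeatureMatrix:
    """One row per run, ordered by run id; feature names encode segment and
    grid temperature."""
    if not runs:
        raise ValueError("no runs to featurize")
    ordered = sorted(runs, key=lambda r: r.run_id)
    ids = [r.run_id for r in ordered]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate run ids: {dupes}")
    rows = [merge_segments(r.bs1, r.bs2) for r in ordered]
    return FeatureMatrix(ids, [r.specimen_id for r in ordered],
                         [r.species_name for r in ordered],
                         feature_names_for(ordered[0].bs1), np.vstack(rows))


def variable_importance(model, feature_names: list[str]) -> pd.DataFrame:
    """Garson-style per-feature importance from first-layer weights.

    relative = sum over first-layer units of |weight|, scaled = relative/max,
    percentage = scaled normalized to sum to 100; sorted descending.
    """
    weights = getattr(model, "weights", None)
    if not weights:
        raise ValueError("model has no trained weights")
    w1 = np.abs(np.asarray(weights[0]))
    if w1.shape[0] != len(feature_names):
        raise ValueError("model input width does not match feature names")
    relative = w1.sum(axis=1)
    scaled = relative / relative.max() if relative.max() > 0 else relative
    pct = 100.0 * scaled / scaled.sum() if scaled.sum() > 0 else scaled
    table = pd.DataFrame({"feature": feature_names, "relative_importance": relative,
                          "scaled_importance": scaled, "percentage": pct})
    return table.sort_values("relative_importance", ascending=False,
                             kind="stable").reset_index(drop=True)
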