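"""Readers and writers for instrument-style melt-curve exports.

Layout mirrors the CSV export of a two-channel real-time PCR thermocycler:
one file per optical channel whose first column is temperature and whose
remaining columns are one fluorescence trace per run, plus a metadata
manifest (run_id, specimen_id, species, replicate, condition).  The packaged
28-species status table (CITES listing, per-segment amplification and
distinguishability flags) is read through :func:`read_species_status_table`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .meltsim import RawMeltCurve, RunRecord

__all__ = ["MeltExportError", "read_melt_export", "write_melt_export",
           "read_species_status_table"]

_FLAG_COLUMNS = ["cites_listed", "amplifies_bs1", "amplifies_bs2",
                 "visual_distinguishable", "dl_distinguishable",
                 "dl_misassignment_risk"]


class MeltExportError(ValueError):
    """Malformed or inconsistent melt-curve export files."""


def write_melt_export(runs: list[RunRecord], bs1_path, bs2_path, metadata_path) -> None:
    """Write a run collection as channel CSVs plus a metadata manifest."""
    if not runs:
        raise MeltExportError("no runs to write")
    for channel, path in (("bs1_curve", bs1_path), ("bs2_curve", bs2_path)):
        curves = {r.run_id: getattr(r, channel).fluorescence for r in runs}
        temps = getattr(runs[0], channel).temperatures
        frame = pd.DataFrame({"temperature": np.round(temps, 3), **curves})
        frame.to_csv(path, index=False, float_format="%.6f")
    meta = pd.DataFrame([{"run_id": r.run_id, "specimen_id": r.specimen_id,
                          "species": r.species_name if r.species_name else "",
                          "replicate": r.replicate,
                          "condition": r.sample_condition} for r in runs])
    meta.to_csv(metadata_path, index=False)


def read_melt_export(bs1_path, bs2_path, metadata_path) -> list[RunRecord]:
    """Load a channel-file pair plus metadata back into run records."""
    bs1 = pd.read_csv(bs1_path)
    bs2 = pd.read_csv(bs2_path)
    meta = pd.read_csv(metadata_path, dtype={"run_id": str, "specimen_id": str})
    for name, frame in (("BS1", bs1), ("BS2", bs2)):
        if frame.columns[0] != "temperature":
            raise MeltExportError(f"{name} file must start with a temperature column")
        if np.any(np.diff(frame["temperature"].to_numpy()) <= 0):
            raise MeltExportError(f"{name} temperatures are not strictly increasing")
    runs = []
    for row in meta.itertuples(index=False):
        rid = row.run_id
        for name, frame in (("BS1", bs1), ("BS2", bs2)):
            if rid not in frame.columns:
                raise MeltExportError(f"run {rid!r} missing from {name} channel file")
        species = getattr(row, "species", "")
        runs.append(RunRecord(
            run_id=rid, specimen_id=row.specimen_id,
            species_name=None if pd.isna(species) or species == "" else species,
            replicate=int(row.replicate), sample_condition=row.condition,
            bs1_curve=RawMeltCurve(bs1["temperature"].to_numpy(),
                                   bs1[rid].to_numpy(), "BS1"),
            bs2_curve=RawMeltCurve(bs2["temperature"].to_numpy(),
                                   bs2[rid].to_numpy(), "BS2")))
    return runs


def read_species_status_table(path: str | Path | None = None) -> pd.DataFrame:
    """Read the 28-species status table (packaged copy when ``path`` is None).

    Yes/No flag columns are parsed to booleans; anything other than exactly
    28 unique species rows is rejected.
    """
    if path is None:
        with resources.files("meltid.data").joinpath("species_status.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"species", "english_name", "group", *_FLAG_COLUMNS}
    if missing := required - set(table.columns):
        raise MeltExportError(f"status table missing columns: {sorted(missing)}")
    if len(table) != 28 or table["species"].nunique() != 28:
        raise MeltExportError(f"status table must have 28 unique species rows, "
                              f"got {len(table)}")
    for col in _FLAG_COLUMNS:
        vals = table[col].astype(str).str.strip().str.lower()
        if not vals.isin(["yes", "no"]).all():
            raise MeltExportError(f"column {col} must be Yes/No")
        table[col] = vals == "yes"
    return table
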