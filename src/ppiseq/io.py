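"""Tabular schemas shared across the pipeline.

The central flat format mirrors the published per-trajectory table: one row
per double barcode per growth culture, with read counts at each sampled
generation as wide columns::

    PPI_pair  barcode_pair  Bait  Prey  Condition  Methotrexate_selection
    Replicate  Reads_0_generations ... Reads_12_generations
    [Reads_*_generations_corrected]  [Fitness  Likelihood  Trajectory_used]
"""

from __future__ import annotations

import re

import pandas as pd

from .barcode_io import CountTable, DoubleBarcodeLibrary

GENERATIONS = (0, 3, 6, 9, 12)

KEY_COLUMNS = [
    "PPI_pair",
    "barcode_pair",
    "Bait",
    "Prey",
    "Condition",
    "Methotrexate_selection",
    "Replicate",
]

CULTURE_COLUMNS = ["Condition", "Methotrexate_selection", "Replicate"]

_READS_RE = re.compile(r"^Reads_(\d+)_generations(_corrected)?$")


def reads_column(generation: int, corrected: bool = False) -> str:
    suffix = "_corrected" if corrected else ""
    return f"Reads_{generation}_generations{suffix}"


def reads_columns(df: pd.DataFrame, corrected: bool = False) -> list[str]:
    """Read-count columns present in ``df``, ordered by generation."""
    cols = []
    for c in df.columns:
        m = _READS_RE.match(c)
        if m and bool(m.group(2)) == corrected:
            cols.append((int(m.group(1)), c))
    return [c for _, c in sorted(cols)]


def generations_of(df: pd.DataFrame, corrected: bool = False) -> list[int]:
    return [int(_READS_RE.match(c).group(1)) for c in reads_columns(df, corrected)]


def count_table_to_trajectories(
    table: CountTable, library: DoubleBarcodeLibrary
) -> pd.DataFrame:
    """Pivot a per-sample :class:`CountTable` into the flat trajectory schema."""
    ent = library.entries.set_index("entry_id")
    rows = []
    cultures = table.samples.groupby(CULTURE_COLUMNS_SAMPLES, sort=False)
    for (condition, mtx, replicate), grp in cultures:
        by_gen = {
            int(g): sid for sid, g in zip(grp.index, grp["generation"])
        }
        block = pd.DataFrame(index=table.counts.index)
        block["PPI_pair"] = (
            ent.loc[block.index, "bait"] + ":" + ent.loc[block.index, "prey"]
        ).to_numpy()
        block["barcode_pair"] = block.index
        block["Bait"] = ent.loc[block.index, "bait"].to_numpy()
        block["Prey"] = ent.loc[block.index, "prey"].to_numpy()
        block["Condition"] = condition
        block["Methotrexate_selection"] = mtx
        block["Replicate"] = replicate
        for g in sorted(by_gen):
            block[reads_column(g)] = table.counts[by_gen[g]].to_numpy()
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


CULTURE_COLUMNS_SAMPLES = ["condition", "mtx", "replicate"]


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "Methotrexate_selection" in df.columns:
        df["Methotrexate_selection"] = df["Methotrexate_selection"].map(_to_bool)
    if "Trajectory_used" in df.columns:
        df["Trajectory_used"] = df["Trajectory_used"].map(_to_bool)
    return df


def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _to_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes", "+", "mtx+")
    return bool(v)
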