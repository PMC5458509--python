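"""PCR-chimera rate estimation and count correction.

During amplification a small fraction of reads re-pair barcode halves from
two different template molecules.  Under random re-pairing the expected
number of chimeric reads landing on pair (i, j) in a sample with
barcode-half marginals R_i. (reads whose first half is i) and R_.j is

    C_ij = eps * R_i. * R_.j / R_..

where eps is the per-read chimera rate and R_.. the sample total.  The rate
is estimated from "off-target" pairs — combinations whose halves each exist
in the designed library but which were never constructed, and which can
therefore only arise by chimerism (or matching error):

    eps_hat = off_target_reads / ((1 - inside) * total_reads)

with ``inside`` the probability that a random re-pairing lands on a
designed pair (sum of p_i * q_j over designed (i, j)).  When the library is
a complete cross of all halves, ``inside`` is ~1 and the rate is not
identifiable from counts; it must then be supplied by configuration.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcode_io import CountTable, DoubleBarcodeLibrary
from . import io as _io


class ChimeraRateUnidentifiable(ValueError):
    """The designed library covers the whole half-barcode cross.

    Every chimeric read then lands on a designed pair, so no off-target
    signal exists; supply the rate explicitly (e.g. from a spike-in or a
    prior experiment).
    """


def _check_rate(rate: float) -> float:
    rate = float(rate)
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"chimera rate must be in [0, 1), got {rate}")
    return rate


def expected_chimeric_reads(
    counts: Sequence[float], b1: Sequence, b2: Sequence
) -> np.ndarray:
    """Expected chimeric reads per designed pair at rate eps = 1.

    ``counts`` are the observed reads per designed pair; ``b1``/``b2`` the
    half-barcode labels of each pair.  Multiply by eps to get C_ij.
    """
    df = pd.DataFrame({"b1": list(b1), "b2": list(b2), "n": np.asarray(counts, float)})
    total = df["n"].sum()
    if total <= 0:
        return np.zeros(len(df))
    m1 = df.groupby("b1")["n"].sum()
    m2 = df.groupby("b2")["n"].sum()
    return (m1[df["b1"]].to_numpy() * m2[df["b2"]].to_numpy()) / total


def designed_cross_fraction(
    counts: Sequence[float],
    b1: Sequence,
    b2: Sequence,
    designed: set[tuple] | None = None,
    off_target: pd.DataFrame | None = None,
) -> float:
    """Probability that a random half re-pairing lands on a designed pair.

    Marginal half frequencies are computed from all observed reads
    (designed plus off-target, if given), since chimerism preserves them.
    """
    df = pd.DataFrame({"b1": list(b1), "b2": list(b2), "n": np.asarray(counts, float)})
    if designed is None:
        designed = set(zip(df["b1"], df["b2"]))
    if off_target is not None and len(off_target):
        extra = off_target.rename(columns={"barcode1": "b1", "barcode2": "b2", "count": "n"})
        df = pd.concat([df, extra[["b1", "b2", "n"]]], ignore_index=True)
    total = df["n"].sum()
    if total <= 0:
        return 1.0
    p = df.groupby("b1")["n"].sum() / total
    q = df.groupby("b2")["n"].sum() / total
    return float(sum(p.get(i, 0.0) * q.get(j, 0.0) for i, j in designed))


def estimate_chimera_rate(
    counts: Sequence[float],
    b1: Sequence,
    b2: Sequence,
    off_target: pd.DataFrame,
    min_outside: float = 1e-6,
) -> float:
    """Estimate the per-read chimera rate from off-target pair counts.

    Parameters
    ----------
    counts, b1, b2
        Observed reads per designed pair and the half labels of each pair.
    off_target
        DataFrame with columns ``barcode1, barcode2, count``: parsed pairs
        whose halves are both in the library but whose combination is not
        designed.
    min_outside
        Identifiability floor on (1 - inside); below it the rate cannot be
        estimated and :class:`ChimeraRateUnidentifiable` is raised.
    """
    counts = np.asarray(counts, dtype=float)
    off_total = float(off_target["count"].sum()) if len(off_target) else 0.0
    total = counts.sum() + off_total
    if total <= 0:
        return 0.0
    inside = designed_cross_fraction(counts, b1, b2, off_target=off_target)
    outside = 1.0 - inside
    if outside < min_outside:
        raise ChimeraRateUnidentifiable(
            "designed library covers the half-barcode cross; "
            "supply the chimera rate explicitly"
        )
    rate = off_total / (outside * total)
    return float(min(rate, 1.0 - 1e-12))


def correct_sample_counts(
    counts: Sequence[float], b1: Sequence, b2: Sequence, rate: float
) -> np.ndarray:
    """Subtract expected chimeric reads from one sample's designed counts.

    Returns integer counts: ``round(max(0, raw - eps * R_i. R_.j / R_..))``.
    Corrected counts never exceed the raw counts.
    """
    rate = _check_rate(rate)
    raw = np.asarray(counts, dtype=float)
    expected = rate * expected_chimeric_reads(raw, b1, b2)
    return np.rint(np.maximum(0.0, raw - expected)).astype(np.int64)


def correct_counts(
    table: CountTable,
    library: DoubleBarcodeLibrary,
    rate: float | Mapping[str, float],
) -> CountTable:
    """Chimera-correct every sample column of a :class:`CountTable`."""
    ent = library.entries.set_index("entry_id").loc[table.counts.index]
    corrected = table.counts.copy()
    for sample in table.counts.columns:
        r = rate[sample] if isinstance(rate, Mapping) else rate
        corrected[sample] = correct_sample_counts(
            table.counts[sample].to_numpy(), ent["barcode1"], ent["barcode2"], r
        )
    return CountTable(corrected, table.samples, table.unmatched, table.off_target)


def estimate_rate_from_table(table: CountTable, library: DoubleBarcodeLibrary) -> float:
    """Global chimera-rate estimate pooled over all samples of a table."""
    ent = library.entries.set_index("entry_id").loc[table.counts.index]
    pooled = table.counts.sum(axis=1).to_numpy()
    off = table.off_target
    if len(off):
        off = off.groupby(["barcode1", "barcode2"], as_index=False)["count"].sum()
    return estimate_chimera_rate(pooled, ent["barcode1"], ent["barcode2"], off)


def correct_trajectories(
    df: pd.DataFrame,
    rate: float,
    bait_col: str = "Bait",
    prey_col: str = "Prey",
    bait_bc: str | None = None,
    prey_bc: str | None = None,
) -> pd.DataFrame:
    """Add ``Reads_*_generations_corrected`` columns to a trajectory table.

    Each (Condition, Methotrexate_selection, Replicate, generation)
    combination is one sequencing sample; marginals for the re-pairing
    model are taken over barcode halves within that sample.  When explicit
    half-barcode columns are not present, halves are identified by the
    bait/prey construct plus the within-construct barcode index encoded in
    ``barcode_pair`` (falling back to the construct labels alone).
    """
    rate = _check_rate(rate)
    out = df.copy()
    b1 = out[bait_bc] if bait_bc and bait_bc in out else out[bait_col]
    b2 = out[prey_bc] if prey_bc and prey_bc in out else out[prey_col]
    if "barcode_pair" in out.columns and (bait_bc is None or bait_bc not in out):
        split = out["barcode_pair"].astype(str).str.split("|", expand=True)
        if split.shape[1] == 2:
            b1, b2 = split[0], split[1]
    groups = out.groupby(_io.CULTURE_COLUMNS, sort=False).indices
    for col in _io.reads_columns(out):
        gen = int(col.split("_")[1])
        new = np.zeros(len(out), dtype=np.int64)
        for _, idx in groups.items():
            new[idx] = correct_sample_counts(
                out[col].to_numpy()[idx], b1.iloc[idx], b2.iloc[idx], rate
            )
        out[_io.reads_column(gen, corrected=True)] = new
    return out
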