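"""Parsing and tabulation of double-barcode sequencing reads.

Each amplicon read carries two 38-bp random barcodes (one inherited from
each haploid parent) separated by a loxP scar, flanked by a pair of short
multiplexing tags that identify the sequencing sample.  This module turns a
stream of such reads into a per-lineage, per-sample count table:

1. structural parsing + quality filtering of the two barcode regions,
2. assignment of the tag pair to a sample,
3. unique-best Hamming matching of the barcode pair against the designed
   library (at most ``max_mismatch`` substitutions over the 76-bp
   concatenation; ties are treated as unassignable).

Reads that fail any step are tallied per sample under a rejection reason so
that matched + rejected always equals reads processed.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

BARCODE_LENGTH = 38

# Degenerate flank alternatives tolerate one substitution in the fixed
# 4-mer at either end of each barcode.  The internal AA..AA..TT spacers are
# exact; the four random segments are 4-7 nt each.
_BC1_CORE = (
    r"(?:.ACC|T.CC|TA.C|TAC.)"
    r"[ACGTN]{4,7}?AA[ACGTN]{4,7}?AA[ACGTN]{4,7}?TT[ACGTN]{4,7}?"
    r"(?:.TAA|A.AA|AT.A|ATA.)"
)
# Alternate first-barcode flank; accepts zero or one arbitrary character
# before the final CA (the published form contains a stray separator there).
_BC1_ALT = r"GTACTAACGGCTAATTTGGTGCC.?CA"
_BC2_CORE = (
    r"(?:.TAT|T.AT|TT.T|TTA.)"
    r"[ACGTN]{4,7}?AA[ACGTN]{4,7}?AA[ACGTN]{4,7}?TT[ACGTN]{4,7}?"
    r"(?:.GTA|G.TA|GG.A|GGT.)"
)

BARCODE1_RE = re.compile(f"(?:{_BC1_CORE})|(?:{_BC1_ALT})")
BARCODE2_RE = re.compile(_BC2_CORE)

#: loxP site separating the two barcodes in the recombined locus.
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

REJECTION_REASONS = (
    "malformed_read",
    "quality_fail",
    "pattern1_fail",
    "pattern2_fail",
    "tag_fail",
    "no_match",
    "ambiguous",
)


@dataclass(frozen=True)
class AmpliconLayout:
    """Fixed offsets of the tag and barcode regions within a read.

    The default layout is ``tag1 | barcode1 | loxP | barcode2 | tag2`` with
    6-nt tags, matching the synthetic reads produced by
    :mod:`ppiseq.simulate`.  Real designs differ only in these offsets.
    """

    tag_length: int = 6
    spacer: str = LOXP
    barcode_length: int = BARCODE_LENGTH

    @property
    def bc1_slice(self) -> slice:
        start = self.tag_length
        return slice(start, start + self.barcode_length)

    @property
    def bc2_slice(self) -> slice:
        start = self.tag_length + self.barcode_length + len(self.spacer)
        return slice(start, start + self.barcode_length)

    @property
    def tag1_slice(self) -> slice:
        return slice(0, self.tag_length)

    @property
    def tag2_slice(self) -> slice:
        start = self.tag_length + 2 * self.barcode_length + len(self.spacer)
        return slice(start, start + self.tag_length)

    @property
    def read_length(self) -> int:
        return 2 * self.tag_length + 2 * self.barcode_length + len(self.spacer)


@dataclass(frozen=True)
class BarcodeRead:
    """A sequencing read with Phred qualities and (optionally) known tags."""

    sequence: str
    quality: Sequence[int]
    tags: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality must have equal length")
        if any(q < 0 for q in self.quality):
            raise ValueError("Phred quality scores must be >= 0")


@dataclass(frozen=True)
class ParseOutcome:
    barcode1: str | None
    barcode2: str | None
    reason: str | None

    @property
    def ok(self) -> bool:
        return self.reason is None


@dataclass(frozen=True)
class SampleInfo:
    """Metadata for one sequencing sample of the pooled growth assay."""

    condition: str
    mtx: bool
    replicate: int
    generation: int

    def __post_init__(self) -> None:
        if self.generation not in (0, 3, 6, 9, 12):
            raise ValueError(f"generation must be in {{0,3,6,9,12}}, got {self.generation}")
        if self.replicate not in (1, 2, 3):
            raise ValueError(f"replicate must be 1, 2 or 3, got {self.replicate}")


class DoubleBarcodeLibrary:
    """The designed (barcode1, barcode2) -> genotype-pair map.

    Parameters
    ----------
    entries
        DataFrame with columns ``entry_id, barcode1, barcode2, bait, prey,
        is_control``.  Barcode pairs must be unique; control entries carry
        no bait/prey construct (empty strings are accepted).
    """

    def __init__(self, entries: pd.DataFrame):
        required = {"entry_id", "barcode1", "barcode2", "bait", "prey", "is_control"}
        missing = required - set(entries.columns)
        if missing:
            raise ValueError(f"library table missing columns: {sorted(missing)}")
        if len(entries) == 0:
            raise ValueError("library must contain at least one entry")
        if entries["entry_id"].duplicated().any():
            raise ValueError("duplicate entry ids in library")
        pairs = entries["barcode1"] + entries["barcode2"]
        if pairs.duplicated().any():
            raise ValueError("duplicate (barcode1, barcode2) pairs in library")
        for col in ("barcode1", "barcode2"):
            bad = entries[col].str.len() != BARCODE_LENGTH
            if bad.any():
                raise ValueError(f"{col}: all barcodes must be {BARCODE_LENGTH} bp")
        self.entries = entries.reset_index(drop=True)
        self._exact = dict(zip(pairs, self.entries["entry_id"]))
        self._encoded = _encode(pairs.tolist())
        self._ids = self.entries["entry_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def barcode1_set(self) -> frozenset[str]:
        return frozenset(self.entries["barcode1"])

    @property
    def barcode2_set(self) -> frozenset[str]:
        return frozenset(self.entries["barcode2"])

    @classmethod
    def from_tsv(cls, path) -> "DoubleBarcodeLibrary":
        df = pd.read_csv(path, sep="\t", dtype={"entry_id": str, "bait": str, "prey": str})
        df["is_control"] = df["is_control"].astype(bool)
        return cls(df)

    def to_tsv(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


def _encode(seqs: list[str]) -> np.ndarray:
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), len(seqs[0])
    )


def parse_double_barcode(
    read: BarcodeRead,
    min_mean_quality: float = 30.0,
    layout: AmpliconLayout | None = None,
) -> ParseOutcome:
    """Isolate and validate the two 38-bp barcode regions of a read.

    A read passes iff the mean Phred quality over *each* barcode region is
    strictly greater than ``min_mean_quality`` and each region matches its
    structural pattern.  Failures carry a reason tag (``malformed_read``,
    ``quality_fail``, ``pattern1_fail`` or ``pattern2_fail``).
    """
    layout = layout or AmpliconLayout()
    if len(read.sequence) < layout.read_length:
        return ParseOutcome(None, None, "malformed_read")
    bc1 = read.sequence[layout.bc1_slice]
    bc2 = read.sequence[layout.bc2_slice]
    qual = np.asarray(read.quality, dtype=float)
    if (
        qual[layout.bc1_slice].mean() <= min_mean_quality
        or qual[layout.bc2_slice].mean() <= min_mean_quality
    ):
        return ParseOutcome(None, None, "quality_fail")
    if not BARCODE1_RE.search(bc1):
        return ParseOutcome(None, None, "pattern1_fail")
    if not BARCODE2_RE.search(bc2):
        return ParseOutcome(None, None, "pattern2_fail")
    return ParseOutcome(bc1, bc2, None)


def match_to_library(
    barcode1: str,
    barcode2: str,
    library: DoubleBarcodeLibrary,
    max_mismatch: int = 2,
) -> str | None:
    """Assign a parsed barcode pair to the unique closest designed entry.

    Returns the entry id whose 76-bp concatenated double barcode lies within
    Hamming distance ``max_mismatch`` of the query, or ``None`` when no
    entry is close enough or when two entries tie at the minimal distance.
    """
    key = barcode1 + barcode2
    hit = library._exact.get(key)
    if hit is not None:
        return hit
    if max_mismatch <= 0:
        return None
    query = _encode([key])[0]
    if query.shape[0] != library._encoded.shape[1]:
        return None
    dists = (library._encoded != query).sum(axis=1)
    best = dists.min()
    if best > max_mismatch:
        return None
    idx = np.flatnonzero(dists == best)
    if len(idx) > 1:
        return None  # ambiguous
    return str(library._ids[idx[0]])


@dataclass
class CountTable:
    """Per-entry, per-sample read counts plus rejection bookkeeping.

    Attributes
    ----------
    counts
        DataFrame indexed by library ``entry_id`` with one column per
        sample id.
    samples
        DataFrame indexed by sample id with columns
        ``condition, mtx, replicate, generation``.
    unmatched
        DataFrame indexed by sample id (plus ``_unassigned`` for reads
        whose tags matched no sample) with one column per rejection reason.
    off_target
        Long DataFrame (``sample, barcode1, barcode2, count``) of parsed
        pairs whose halves each occur in the library but whose combination
        is not designed — the observable footprint of PCR chimeras.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    unmatched: pd.DataFrame
    off_target: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["sample", "barcode1", "barcode2", "count"]
        )
    )

    def total_processed(self, sample: str) -> int:
        matched = int(self.counts[sample].sum()) if sample in self.counts else 0
        rejected = int(self.unmatched.loc[sample].sum()) if sample in self.unmatched.index else 0
        return matched + rejected


def _sample_frame(samples: Mapping[str, SampleInfo]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": {k: v.condition for k, v in samples.items()},
            "mtx": {k: v.mtx for k, v in samples.items()},
            "replicate": {k: v.replicate for k, v in samples.items()},
            "generation": {k: v.generation for k, v in samples.items()},
        }
    )


def demultiplex_and_tabulate(
    reads: Iterable[BarcodeRead],
    library: DoubleBarcodeLibrary,
    samples: Mapping[tuple[str, str], str],
    sample_info: Mapping[str, SampleInfo],
    max_mismatch: int = 2,
    min_mean_quality: float = 30.0,
    layout: AmpliconLayout | None = None,
) -> CountTable:
    """Stream reads into a :class:`CountTable`.

    ``samples`` maps a (tag1, tag2) pair to a sample id; ``sample_info``
    supplies the metadata per sample id.  Memory use is O(library + table),
    independent of the number of reads.
    """
    layout = layout or AmpliconLayout()
    sample_ids = list(sample_info)
    counts = {s: np.zeros(len(library), dtype=np.int64) for s in sample_ids}
    entry_index = {e: i for i, e in enumerate(library.entries["entry_id"])}
    reject_rows = sample_ids + ["_unassigned"]
    rejected = {s: dict.fromkeys(REJECTION_REASONS, 0) for s in reject_rows}
    bc1_set = library.barcode1_set
    bc2_set = library.barcode2_set
    off_target: dict[tuple[str, str, str], int] = {}

    for read in reads:
        if read.tags is not None:
            tags = read.tags
        elif len(read.sequence) >= layout.read_length:
            tags = (read.sequence[layout.tag1_slice], read.sequence[layout.tag2_slice])
        else:
            rejected["_unassigned"]["malformed_read"] += 1
            continue
        sample = samples.get(tags)
        if sample is None:
            rejected["_unassigned"]["tag_fail"] += 1
            continue
        outcome = parse_double_barcode(read, min_mean_quality, layout)
        if not outcome.ok:
            rejected[sample][outcome.reason] += 1
            continue
        entry = match_to_library(outcome.barcode1, outcome.barcode2, library, max_mismatch)
        if entry is None:
            dists1 = outcome.barcode1 in bc1_set
            dists2 = outcome.barcode2 in bc2_set
            if dists1 and dists2:
                key = (sample, outcome.barcode1, outcome.barcode2)
                off_target[key] = off_target.get(key, 0) + 1
            rejected[sample]["no_match"] += 1
            continue
        counts[sample][entry_index[entry]] += 1

    count_df = pd.DataFrame(counts, index=library.entries["entry_id"].to_numpy())
    count_df.index.name = "entry_id"
    unmatched = pd.DataFrame.from_dict(rejected, orient="index").loc[reject_rows]
    unmatched.index.name = "sample"
    off_df = pd.DataFrame(
        [(s, b1, b2, n) for (s, b1, b2), n in sorted(off_target.items())],
        columns=["sample", "barcode1", "barcode2", "count"],
    )
    return CountTable(count_df, _sample_frame(sample_info), unmatched, off_df)


def read_fastq(path) -> Iterator[BarcodeRead]:
    """Yield :class:`BarcodeRead` from a plain or gzipped FASTQ file."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield BarcodeRead(
                str(record.seq),
                tuple(record.letter_annotations["phred_quality"]),
            )


def read_sample_sheet(path) -> tuple[dict[tuple[str, str], str], dict[str, SampleInfo]]:
    """Read a tag sheet: tag1, tag2, condition, mtx, replicate, generation.

    Sample ids are synthesized as ``condition[+/-]MTX_r<rep>_g<gen>``.
    """
    df = pd.read_csv(path, sep="\t")
    tag_map: dict[tuple[str, str], str] = {}
    info: dict[str, SampleInfo] = {}
    for row in df.itertuples(index=False):
        mtx = bool(row.mtx) if not isinstance(row.mtx, str) else row.mtx.lower() in ("true", "1", "+")
        sid = f"{row.condition}{'+' if mtx else '-'}MTX_r{row.replicate}_g{row.generation}"
        tag_map[(row.tag1, row.tag2)] = sid
        info[sid] = SampleInfo(row.condition, mtx, int(row.replicate), int(row.generation))
    return tag_map, info
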