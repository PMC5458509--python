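"""Read parsing, library matching and demultiplexed tabulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ppiseq import barcode_io as bio
from ppiseq import simulate


LAYOUT = bio.AmpliconLayout()


def _make_read(bc1: str, bc2: str, quality: int = 40, tags=("AAAAAA", "CCCCCC")) -> bio.BarcodeRead:
    seq = f"{tags[0]}{bc1}{LAYOUT.spacer}{bc2}{tags[1]}"
    return bio.BarcodeRead(seq, [quality] * len(seq))


@pytest.fixture(scope="module")
def barcodes():
    rng = np.random.default_rng(3)
    return simulate.generate_barcodes(4, 1, rng), simulate.generate_barcodes(4, 2, rng)


class TestParse:
    def test_accepts_well_formed_read(self, barcodes):
        b1, b2 = barcodes[0][0], barcodes[1][0]
        out = bio.parse_double_barcode(_make_read(b1, b2))
        assert out.ok and (out.barcode1, out.barcode2) == (b1, b2)
        # idempotent: re-parsing gives the identical outcome
        assert bio.parse_double_barcode(_make_read(b1, b2)) == out

    @pytest.mark.parametrize("quality,ok", [(29, False), (30, False), (31, True)])
    def test_mean_quality_must_exceed_threshold(self, barcodes, quality, ok):
        read = _make_read(barcodes[0][0], barcodes[1][0], quality=quality)
        out = bio.parse_double_barcode(read, min_mean_quality=30)
        assert out.ok is ok
        if not ok:
            assert out.reason == "quality_fail"

    def test_missing_internal_spacers_fail_pattern(self, barcodes):
        # replace the AA..AA..TT spacers with G runs: structurally invalid
        bad1 = "TACC" + "G" * 30 + "ATAA"
        assert bio.BARCODE1_RE.search(bad1) is None  # oracle: direct regex
        out = bio.parse_double_barcode(_make_read(bad1, barcodes[1][0]))
        assert out.reason == "pattern1_fail"
        bad2 = "TTAT" + "G" * 30 + "GGTA"
        out = bio.parse_double_barcode(_make_read(barcodes[0][0], bad2))
        assert out.reason == "pattern2_fail"

    def test_alternate_first_flank_accepted(self, barcodes):
        alt = "GTACTAACGGCTAATTTGGTGCCCA" + "G" * 13
        assert len(alt) == 38
        out = bio.parse_double_barcode(_make_read(alt, barcodes[1][0]))
        assert out.ok

    def test_short_read_is_malformed(self):
        read = bio.BarcodeRead("ACGT", [40] * 4)
        assert bio.parse_double_barcode(read).reason == "malformed_read"

    def test_mismatched_quality_length_rejected(self):
        with pytest.raises(ValueError):
            bio.BarcodeRead("ACGT", [40] * 3)


class TestMatch:
    def test_exact_and_two_mismatches(self, small_library):
        entry = small_library.entries.iloc[3]
        assert bio.match_to_library(entry.barcode1, entry.barcode2, small_library) == entry.entry_id
        # two substitutions inside the first random segment of barcode1
        mut = list(entry.barcode1)
        for pos in (5, 6):
            mut[pos] = "A" if mut[pos] != "A" else "C"
        assert bio.match_to_library("".join(mut), entry.barcode2, small_library) == entry.entry_id

    def test_distant_query_unmatched(self, small_library):
        rng = np.random.default_rng(0)
        q1 = "".join(rng.choice(list("ACGT"), 38))
        q2 = "".join(rng.choice(list("ACGT"), 38))
        # oracle: exhaustive Hamming distance to every designed pair
        query = q1 + q2
        dists = [
            sum(a != b for a, b in zip(query, e.barcode1 + e.barcode2))
            for e in small_library.entries.itertuples(index=False)
        ]
        assert min(dists) > 2
        assert bio.match_to_library(q1, q2, small_library) is None

    def test_tie_is_ambiguous(self):
        rng = np.random.default_rng(1)
        b1a, b1b = simulate.generate_barcodes(2, 1, rng)
        (b2,) = simulate.generate_barcodes(1, 2, rng)
        # two entries whose barcode1 differ at exactly two positions around
        # a query equidistant from both
        base = list(b1a)
        alt = list(b1a)
        alt[6] = "A" if base[6] != "A" else "C"
        alt[7] = "A" if base[7] != "A" else "C"
        lib = bio.DoubleBarcodeLibrary(
            pd.DataFrame(
                {
                    "entry_id": ["e1", "e2"],
                    "barcode1": ["".join(base), "".join(alt)],
                    "barcode2": [b2, b2],
                    "bait": ["x", "y"],
                    "prey": ["p", "p"],
                    "is_control": [False, False],
                }
            )
        )
        query = list(base)
        query[6] = alt[6]  # distance 1 from both entries
        assert bio.match_to_library("".join(query), b2, lib, max_mismatch=2) is None

    def test_assignment_invariant_to_library_order(self, small_library):
        shuffled = bio.DoubleBarcodeLibrary(
            small_library.entries.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        for e in small_library.entries.itertuples(index=False):
            mut = "A" + e.barcode1[1:]
            assert bio.match_to_library(mut, e.barcode2, small_library) == bio.match_to_library(
                mut, e.barcode2, shuffled
            )

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            bio.DoubleBarcodeLibrary(
                pd.DataFrame(columns=["entry_id", "barcode1", "barcode2", "bait", "prey", "is_control"])
            )


class TestDemultiplex:
    @pytest.fixture()
    def sample_maps(self):
        info = {"s1": bio.SampleInfo("DMSO", True, 1, 0)}
        return {("AAAAAA", "CCCCCC"): "s1"}, info

    def test_uniform_reads_tally_and_conservation(self, small_library, sample_maps):
        tag_map, info = sample_maps
        rng = np.random.default_rng(42)
        entries = small_library.entries.iloc[:10]
        picks = rng.integers(0, 10, size=1000)
        reads = [
            _make_read(entries.iloc[i].barcode1, entries.iloc[i].barcode2) for i in picks
        ]
        table = bio.demultiplex_and_tabulate(reads, small_library, tag_map, info)
        expected = np.bincount(picks, minlength=10)  # oracle: generator tally
        got = table.counts["s1"].to_numpy()[:10]
        assert np.array_equal(got, expected)
        assert table.counts["s1"].sum() == 1000
        assert table.total_processed("s1") == 1000

    def test_unknown_tag_counted_as_tag_fail(self, small_library, sample_maps):
        tag_map, info = sample_maps
        e = small_library.entries.iloc[0]
        reads = [_make_read(e.barcode1, e.barcode2, tags=("GGGGGG", "GGGGGG"))]
        table = bio.demultiplex_and_tabulate(reads, small_library, tag_map, info)
        assert table.unmatched.loc["_unassigned", "tag_fail"] == 1
        assert table.counts.to_numpy().sum() == 0

    def test_zero_reads_gives_empty_table(self, small_library, sample_maps):
        tag_map, info = sample_maps
        table = bio.demultiplex_and_tabulate([], small_library, tag_map, info)
        assert table.counts.to_numpy().sum() == 0
        assert table.unmatched.to_numpy().sum() == 0


class TestFastqRoundTrip:
    def test_simulator_fastq_reproduces_count_matrix(self, sparse_chimeric_sim, tmp_path):
        """Error-free synthetic FASTQ tabulates back to the simulator's own
        observed read matrix, with chimeric off-library reads conserved in
        the off-target ledger."""
        res = sparse_chimeric_sim
        paths = simulate.emit_fastq(res, tmp_path, seed=1)
        library = res.to_library()
        tag_map, info = simulate.sample_tags(res)
        reads = (r for p in paths for r in bio.read_fastq(p))
        table = bio.demultiplex_and_tabulate(reads, library, tag_map, info)
        obs = np.rint(res.reads_observed).astype(int)
        for k, sid in enumerate(info):
            assert np.array_equal(table.counts[sid].to_numpy(), obs[:, k])
            # conservation: matched + rejected = reads emitted
            off_k = res.off_target.loc[res.off_target["sample_idx"] == k, "count"].sum()
            assert table.total_processed(sid) == obs[:, k].sum() + off_k
        # off-target chimeras are recovered read-for-read
        assert table.off_target["count"].sum() == res.off_target["count"].sum()

    def test_low_quality_reads_all_rejected(self, small_sim, tmp_path):
        paths = simulate.emit_fastq(small_sim, tmp_path, quality=20, seed=2)
        library = small_sim.to_library()
        tag_map, info = simulate.sample_tags(small_sim)
        reads = (r for p in paths for r in bio.read_fastq(p))
        table = bio.demultiplex_and_tabulate(reads, library, tag_map, info)
        assert table.counts.to_numpy().sum() == 0
        assert (table.unmatched["quality_fail"] > 0).any()
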