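"""CIGAR-based window reconstruction, checked against a per-base oracle."""

import numpy as np
import pytest

from histract import (ReadObservation, Rejection, ScanFilters, classify_allele,
                      orient_to_coding, reconstruct_segment, scan_alignment)
from histract.read_reconstruction import ReconstructedSegment

# ---------------------------------------------------------------------------
# Independent oracle: expand the CIGAR base by base into explicit
# query<->reference correspondences, then apply the window rules directly.
# ---------------------------------------------------------------------------


def oracle_reconstruct(read, locus):
    ws, we = locus.window_start, locus.window_end
    ref, qpos = read.reference_start, 0
    events = []  # per-base: ("M", ref_pos, base) | ("I", anchor, base) | ("D", ref_pos)
    aligned_ref = set()
    for op, length in read.cigar:
        for _ in range(length):
            if op in "M=X":
                events.append(("M", ref, read.seq[qpos]))
                aligned_ref.add(ref)
                ref += 1
                qpos += 1
            elif op == "I":
                events.append(("I", ref - 1, read.seq[qpos]))
                qpos += 1
            elif op == "D":
                events.append(("D", ref))
                aligned_ref.add(ref)
                ref += 1
            elif op == "N":
                if ws <= ref < we:
                    return Rejection(read.read_name, "spliced-over-window")
                ref += 1
            elif op == "S":
                qpos += 1
    if not ({ws, we - 1} <= aligned_ref):
        return Rejection(read.read_name, "non-spanning")
    out, ins, dele = [], 0, 0
    for ev in events:
        if ev[0] == "M" and ws <= ev[1] < we:
            out.append(ev[2])
        elif ev[0] == "I" and ws <= ev[1] <= we - 1:
            out.append(ev[2])
            ins += 1
        elif ev[0] == "D" and ws <= ev[1] < we:
            dele += 1
    return ReconstructedSegment(read.read_name, "".join(out), True, ins, dele)


def _read(cigar, ref_start, seq, **kw):
    return ReadObservation(read_name="r", reference_start=ref_start,
                           cigar=tuple(cigar), seq=seq, **kw)


class TestReconstructSegment:
    def test_all_match_identity(self, locus):
        read = _read([("M", 36)], locus.window_start, locus.reference_window_seq)
        seg = reconstruct_segment(read, locus)
        assert seg.nt_window == locus.reference_window_seq
        assert seg.inserted_bases == seg.deleted_bases == 0

    def test_deletion_of_one_repeat_unit(self, locus):
        ref = locus.reference_window_seq
        # delete reference-strand bases 10..12 of the window (one CCA unit
        # of the coding strand); window shrinks by 3
        seq = ref[:10] + ref[13:]
        read = _read([("M", 10), ("D", 3), ("M", 23)], locus.window_start, seq)
        seg = reconstruct_segment(read, locus)
        assert len(seg.nt_window) == 33 and seg.deleted_bases == 3
        allele = classify_allele(orient_to_coding(seg, locus), locus)
        assert allele.k == -1

    def test_insertion_of_one_repeat_unit(self, locus):
        ref = locus.reference_window_seq
        seq = ref[:10] + "TGG" + ref[10:]  # CCA on the coding strand
        read = _read([("M", 10), ("I", 3), ("M", 26)], locus.window_start, seq)
        seg = reconstruct_segment(read, locus)
        assert len(seg.nt_window) == 39 and seg.inserted_bases == 3
        allele = classify_allele(orient_to_coding(seg, locus), locus)
        assert allele.k == 1

    def test_clipped_read_is_non_spanning(self, locus):
        # aligned span starts 4 bases inside the window
        read = _read([("S", 10), ("M", 26)], locus.window_start + 4, "A" * 36)
        result = reconstruct_segment(read, locus)
        assert isinstance(result, Rejection) and result.reason == "non-spanning"

    def test_unmapped_read_rejected(self, locus):
        read = _read([("M", 36)], locus.window_start,
                     locus.reference_window_seq, flags=0x4)
        result = reconstruct_segment(read, locus)
        assert isinstance(result, Rejection) and result.reason == "unmapped"

    def test_splice_over_window_rejected(self, locus):
        read = _read([("M", 10), ("N", 10), ("M", 26)],
                     locus.window_start, "A" * 36)
        result = reconstruct_segment(read, locus)
        assert isinstance(result, Rejection)
        assert result.reason == "spliced-over-window"

    def test_malformed_cigar_length_raises(self, locus):
        read = _read([("M", 40)], locus.window_start, "A" * 36)
        with pytest.raises(ValueError):
            reconstruct_segment(read, locus)

    def test_insertion_anchored_before_window_excluded(self, locus):
        ws = locus.window_start
        seq = "AAA" + "GGG" + locus.reference_window_seq
        read = _read([("M", 3), ("I", 3), ("M", 36)], ws - 3, seq)
        seg = reconstruct_segment(read, locus)
        assert seg.inserted_bases == 0 and seg.nt_window == locus.reference_window_seq

    def test_insertion_at_last_window_base_included(self, locus):
        seq = locus.reference_window_seq + "GGG" + "AAA"
        read = _read([("M", 36), ("I", 3), ("M", 3)], locus.window_start, seq)
        seg = reconstruct_segment(read, locus)
        assert seg.inserted_bases == 3

    def test_length_conservation(self, locus):
        for read in _random_reads(np.random.default_rng(11), locus, 50):
            seg = reconstruct_segment(read, locus)
            if isinstance(seg, ReconstructedSegment):
                assert len(seg.nt_window) == (locus.window_length
                                              - seg.deleted_bases + seg.inserted_bases)


def test_orient_to_coding(locus):
    seg = ReconstructedSegment("r", "GTGGTG", True, 0, 0)
    assert orient_to_coding(seg, locus) == "CACCAC"  # minus-strand locus
    ref_seg = ReconstructedSegment("r", locus.reference_window_seq, True, 0, 0)
    from histract import translate
    assert translate(orient_to_coding(ref_seg, locus)) == "SHHHHHHHHRHP"


# ---------------------------------------------------------------------------
# Randomised oracle equivalence
# ---------------------------------------------------------------------------

def _random_reads(rng, locus, n):
    """Random reads with ops in {M, I, D, S} placed around the window."""
    ws = locus.window_start
    for i in range(n):
        ops = []
        if rng.random() < 0.3:
            ops.append(("S", int(rng.integers(1, 8))))
        ops.append(("M", int(rng.integers(1, 30))))
        for _ in range(int(rng.integers(0, 4))):
            ops.append((["I", "D"][int(rng.integers(0, 2))], int(rng.integers(1, 5))))
            ops.append(("M", int(rng.integers(1, 30))))
        if rng.random() < 0.3:
            ops.append(("S", int(rng.integers(1, 8))))
        qlen = sum(n_ for op, n_ in ops if op in "MIS")
        seq = "".join(rng.choice(list("ACGT"), size=qlen))
        start = int(rng.integers(max(0, ws - 40), ws + 20))
        yield ReadObservation(read_name=f"rand{i}", reference_start=start,
                              cigar=tuple(ops), seq=seq)


def test_oracle_equivalence_on_random_cigars(locus):
    rng = np.random.default_rng(20260920)
    n_segments = 0
    for read in _random_reads(rng, locus, 400):
        got = reconstruct_segment(read, locus)
        expected = oracle_reconstruct(read, locus)
        assert type(got) is type(expected)
        if isinstance(got, ReconstructedSegment):
            n_segments += 1
            assert got.nt_window == expected.nt_window
            assert got.inserted_bases == expected.inserted_bases
            assert got.deleted_bases == expected.deleted_bases
        else:
            assert got.reason == expected.reason
    assert n_segments > 20  # the sample exercises the accepting path


# ---------------------------------------------------------------------------
# Alignment scanning
# ---------------------------------------------------------------------------

def test_scan_alignment_tallies_filters(locus):
    good = [_read([("M", 36)], locus.window_start, locus.reference_window_seq,
                  mapq=60) for _ in range(7)]
    low_mapq = [_read([("M", 36)], locus.window_start,
                      locus.reference_window_seq, mapq=5) for _ in range(3)]
    segments, report = scan_alignment(good + low_mapq, locus,
                                      ScanFilters(min_mapq=20))
    assert len(segments) == 7
    assert report.filtered_mapq == 3
    assert report.reconstructed == 7
    assert report.seen == 10


def test_scan_alignment_counts_unmapped(locus):
    unmapped = _read([("M", 36)], locus.window_start,
                     locus.reference_window_seq, flags=0x4)
    segments, report = scan_alignment([unmapped], locus)
    assert segments == [] and report.unmapped == 1


def test_scan_alignment_skips_secondary_duplicate(locus):
    reads = [
        _read([("M", 36)], locus.window_start, locus.reference_window_seq, flags=0x100),
        _read([("M", 36)], locus.window_start, locus.reference_window_seq, flags=0x400),
        _read([("M", 36)], locus.window_start, locus.reference_window_seq, flags=0x800),
    ]
    segments, report = scan_alignment(reads, locus)
    assert segments == []
    assert (report.filtered_secondary, report.filtered_duplicate,
            report.filtered_supplementary) == (1, 1, 1)
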