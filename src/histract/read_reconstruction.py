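"""Per-read sequence reconstruction over the locus window.

The core of the genotyping path: each aligned read's CIGAR is walked while
tracking the (reference, query) position pair, and the bases the read
places inside the analysis window are collected — deletions shorten the
reconstructed window, insertions anchored strictly inside it lengthen it.
Only *spanning* reads, whose aligned footprint covers both terminal window
bases, yield a measurable repeat length; all others are rejected with an
explicit reason and tallied in the :class:`ScanReport`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam

from .locus_model import LocusSpec, reverse_complement

__all__ = [
    "ReadObservation",
    "ReconstructedSegment",
    "Rejection",
    "ScanFilters",
    "ScanReport",
    "reconstruct_segment",
    "orient_to_coding",
    "scan_alignment",
    "read_from_pysam",
    "write_segments_tsv",
]

# ops that consume the query sequence / the reference
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MDN=X")
_ALL_OPS = set("MIDNSHP=X")


@dataclass(frozen=True)
class ReadObservation:
    """One aligned read, as stored in SAM (sequence in reference-strand orientation)."""

    read_name: str
    reference_start: int
    cigar: tuple[tuple[str, int], ...]
    seq: str
    flags: int = 0
    mapq: int = 60
    base_qualities: tuple[int, ...] | None = None
    sample_id: str | None = None

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & 0x4)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & 0x100)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & 0x800)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & 0x400)

    def validate(self) -> None:
        if not self.is_unmapped and not self.cigar:
            raise ValueError(f"{self.read_name}: mapped read with empty CIGAR")
        if self.reference_start < 0:
            raise ValueError(f"{self.read_name}: negative reference_start")
        for op, length in self.cigar:
            if op not in _ALL_OPS or length <= 0:
                raise ValueError(f"{self.read_name}: malformed CIGAR op {op}{length}")
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.read_name}: CIGAR consumes {qlen} query bases "
                f"but sequence has {len(self.seq)}"
            )


@dataclass(frozen=True)
class ReconstructedSegment:
    """A read's bases over the locus window, reference-strand orientation."""

    read_name: str
    nt_window: str
    spans_window: bool
    inserted_bases: int
    deleted_bases: int
    sample_id: str | None = None


@dataclass(frozen=True)
class Rejection:
    read_name: str
    reason: str  # "unmapped" | "non-spanning" | "spliced-over-window"


def reconstruct_segment(read: ReadObservation, locus: LocusSpec) -> ReconstructedSegment | Rejection:
    """Rebuild a read's window sequence from its CIGAR.

    Walks the CIGAR maintaining (reference_pos, query_pos).  M/=/X bases
    whose reference position lies in the window are copied; D/N advance
    the reference copying nothing (D inside the window counts as deleted
    bases; N overlapping the window rejects the read — a spliced
    alignment over a coding tract is not interpretable); an insertion is
    copied iff its anchor (the preceding aligned reference base) lies
    strictly inside the window, i.e. in ``[window_start, window_end-1)``
    extended to include the final window base.  Reads whose aligned
    (M/=/X/D) footprint does not cover both terminal window bases are
    rejected as non-spanning: their repeat length cannot be measured.
    """
    read.validate()
    if read.is_unmapped:
        return Rejection(read.read_name, "unmapped")

    ws, we = locus.window_start, locus.window_end
    ref = read.reference_start
    qpos = 0
    out: list[str] = []
    inserted = deleted = 0
    covered_left = covered_right = False

    for op, length in read.cigar:
        if op in "M=X":
            lo, hi = max(ref, ws), min(ref + length, we)
            if lo < hi:
                out.append(read.seq[qpos + (lo - ref): qpos + (hi - ref)])
            if ref <= ws < ref + length:
                covered_left = True
            if ref <= we - 1 < ref + length:
                covered_right = True
            ref += length
            qpos += length
        elif op == "I":
            # anchored between ref-1 and ref; copy iff the preceding
            # aligned base is a window base
            if ws <= ref - 1 <= we - 1:
                out.append(read.seq[qpos: qpos + length])
                inserted += length
            qpos += length
        elif op == "D":
            deleted += max(0, min(ref + length, we) - max(ref, ws))
            if ref <= ws < ref + length:
                covered_left = True
            if ref <= we - 1 < ref + length:
                covered_right = True
            ref += length
        elif op == "N":
            if max(ref, ws) < min(ref + length, we):
                return Rejection(read.read_name, "spliced-over-window")
            ref += length
        elif op == "S":
            qpos += length
        # H and P consume nothing relevant

    if not (covered_left and covered_right):
        return Rejection(read.read_name, "non-spanning")

    nt_window = "".join(out)
    assert len(nt_window) == locus.window_length - deleted + inserted
    return ReconstructedSegment(
        read_name=read.read_name,
        nt_window=nt_window,
        spans_window=True,
        inserted_bases=inserted,
        deleted_bases=deleted,
        sample_id=read.sample_id,
    )


def orient_to_coding(segment: ReconstructedSegment, locus: LocusSpec) -> str:
    """Return the segment's window sequence in coding-sense orientation."""
    if not segment.spans_window:
        raise ValueError(f"{segment.read_name}: segment does not span the window")
    if locus.strand == "minus":
        return reverse_complement(segment.nt_window)
    return segment.nt_window


# ---------------------------------------------------------------------------
# Alignment scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanFilters:
    """Read-level QC applied before reconstruction."""

    min_mapq: int = 20
    min_mean_base_quality: float | None = None


@dataclass
class ScanReport:
    """Audit trail of a scan: every read is accounted for exactly once."""

    seen: int = 0
    unmapped: int = 0
    filtered_secondary: int = 0
    filtered_supplementary: int = 0
    filtered_duplicate: int = 0
    filtered_mapq: int = 0
    filtered_base_quality: int = 0
    non_spanning: int = 0
    spliced_over_window: int = 0
    off_contig: int = 0
    reconstructed: int = 0
    filters: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def read_from_pysam(rec: pysam.AlignedSegment, sample_id: str | None = None) -> ReadObservation:
    """Convert a pysam record; the sample is taken from the RG tag when present."""
    if sample_id is None and rec.has_tag("RG"):
        sample_id = str(rec.get_tag("RG"))
    cigar = tuple((op, length) for op, length in
                  ((c[0], c[1]) for c in _cigar_pairs(rec)))
    return ReadObservation(
        read_name=rec.query_name or "",
        reference_start=max(rec.reference_start, 0),
        cigar=cigar,
        seq=(rec.query_sequence or "").upper(),
        flags=rec.flag,
        mapq=rec.mapping_quality,
        base_qualities=tuple(rec.query_qualities) if rec.query_qualities is not None else None,
        sample_id=sample_id,
    )


_CIGAR_CODES = "MIDNSHP=X"


def _cigar_pairs(rec: pysam.AlignedSegment):
    for code, length in (rec.cigartuples or ()):
        yield _CIGAR_CODES[code], length


def scan_alignment(
    alignment: str | Path | Iterable[ReadObservation],
    locus: LocusSpec,
    filters: ScanFilters | None = None,
) -> tuple[list[tuple[ReconstructedSegment, str]], ScanReport]:
    """Scan a SAM/BAM source (or an iterable of reads) over the locus window.

    Returns ``(segments, report)`` where each element of ``segments`` is a
    ``(ReconstructedSegment, coding_sense_sequence)`` pair for one read
    that passed all filters and spans the window.
    """
    filters = filters or ScanFilters()
    report = ScanReport(filters={"min_mapq": filters.min_mapq,
                                 "min_mean_base_quality": filters.min_mean_base_quality})
    segments: list[tuple[ReconstructedSegment, str]] = []

    for idx, read in enumerate(_iter_reads(alignment, locus)):
        report.seen += 1
        if read is None:          # mapped to a different contig
            report.off_contig += 1
            continue
        if read.is_unmapped:
            report.unmapped += 1
            continue
        if read.is_secondary:
            report.filtered_secondary += 1
            continue
        if read.is_supplementary:
            report.filtered_supplementary += 1
            continue
        if read.is_duplicate:
            report.filtered_duplicate += 1
            continue
        if read.mapq < filters.min_mapq:
            report.filtered_mapq += 1
            continue
        if (filters.min_mean_base_quality is not None
                and read.base_qualities
                and sum(read.base_qualities) / len(read.base_qualities)
                < filters.min_mean_base_quality):
            report.filtered_base_quality += 1
            continue
        try:
            result = reconstruct_segment(read, locus)
        except ValueError as exc:
            raise ValueError(f"malformed record #{idx}: {exc}") from exc
        if isinstance(result, Rejection):
            if result.reason == "non-spanning":
                report.non_spanning += 1
            elif result.reason == "spliced-over-window":
                report.spliced_over_window += 1
            else:
                report.unmapped += 1
            continue
        report.reconstructed += 1
        segments.append((result, orient_to_coding(result, locus)))

    return segments, report


def _iter_reads(alignment, locus: LocusSpec):
    if isinstance(alignment, (str, Path)):
        with pysam.AlignmentFile(str(alignment), check_sq=False) as af:
            for rec in af:
                if (not rec.is_unmapped
                        and rec.reference_name is not None
                        and rec.reference_name != locus.contig_name):
                    yield None
                else:
                    yield read_from_pysam(rec)
    else:
        yield from alignment


def write_segments_tsv(segments: list[tuple[ReconstructedSegment, str]], path: str | Path) -> None:
    """Per-read TSV: read name, coding-sense sequence, inserted/deleted counts."""
    rows = [
        {"read_name": seg.read_name, "sample_id": seg.sample_id,
         "coding_seq": coding, "inserted": seg.inserted_bases, "deleted": seg.deleted_bases}
        for seg, coding in segments
    ]
    pd.DataFrame(rows, columns=["read_name", "sample_id", "coding_seq",
                                "inserted", "deleted"]).to_csv(path, sep="\t", index=False)
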