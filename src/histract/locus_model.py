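"""Repeat-locus model: coordinates, strand orientation and translation.

A single coding locus is described by a :class:`LocusSpec`: an analysis
window on the reference genome (0-based, half-open), the strand of the
coding sequence, the cDNA coordinate of the first coding-sense base of the
window, and the position of the tract-interrupting SNV.  The window is
chosen so that it starts and ends on codon boundaries and contains at
least one anchor codon on each side of the repeat tract, so that the
length of the tract can be measured unambiguously from any read that
spans the window.

cDNA (``c.``) positions are 1-based, codon ``n`` spanning
``c.(3n-2)..3n``; genomic coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml
from Bio.Seq import Seq
from pyfaidx import Fasta

__all__ = [
    "LocusSpec",
    "toy_locus",
    "TOY_FLANK",
    "cdna_to_window_offset",
    "window_offset_to_cdna",
    "reverse_complement",
    "translate",
    "load_locus",
    "write_locus",
]

_NUCLEOTIDES = set("ACGTN")


@dataclass(frozen=True)
class LocusSpec:
    """One configured repeat locus.

    ``reference_window_seq`` is stored in reference-strand orientation;
    for a minus-strand locus the coding-sense window is its reverse
    complement.
    """

    contig_name: str
    window_start: int
    window_end: int
    strand: str  # "plus" | "minus"
    window_cdna_start: int
    reference_window_seq: str
    tract_aa_start: int
    tract_aa_end: int
    repeat_unit_cdna: str
    snv_cdna_pos: int
    snv_ref: str
    snv_alt: str
    translation_table: int = 1

    def __post_init__(self) -> None:
        wlen = self.window_end - self.window_start
        if wlen <= 0 or wlen != len(self.reference_window_seq):
            raise ValueError("window bounds inconsistent with reference_window_seq")
        if wlen % 3 != 0:
            raise ValueError("window length must be a multiple of 3")
        if self.window_cdna_start % 3 != 1:
            raise ValueError("window must start on a codon boundary (c. pos ≡ 1 mod 3)")
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"strand must be 'plus' or 'minus', got {self.strand!r}")
        first_codon = (self.window_cdna_start + 2) // 3
        last_codon = (self.window_cdna_start + wlen - 1) // 3
        if not (first_codon <= self.tract_aa_start - 1 and self.tract_aa_end + 1 <= last_codon):
            raise ValueError("window must contain an anchor codon on each side of the tract")
        if not (self.window_cdna_start <= self.snv_cdna_pos < self.window_cdna_start + wlen):
            raise ValueError("SNV position lies outside the window's cDNA span")

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start

    @property
    def coding_window_seq(self) -> str:
        """Window sequence in coding-sense orientation."""
        if self.strand == "minus":
            return reverse_complement(self.reference_window_seq)
        return self.reference_window_seq

    @property
    def first_codon(self) -> int:
        return (self.window_cdna_start + 2) // 3

    @property
    def last_codon(self) -> int:
        return (self.window_cdna_start + self.window_length - 1) // 3

    @property
    def reference_protein(self) -> str:
        return translate(self.coding_window_seq, table=self.translation_table)


def cdna_to_window_offset(pos: int, locus: LocusSpec) -> int:
    """Map a 1-based cDNA position to a 0-based offset into the coding-sense window."""
    if not (locus.window_cdna_start <= pos < locus.window_cdna_start + locus.window_length):
        raise ValueError(
            f"cDNA position {pos} outside window "
            f"c.{locus.window_cdna_start}..c.{locus.window_cdna_start + locus.window_length - 1}"
        )
    return pos - locus.window_cdna_start


def window_offset_to_cdna(offset: int, locus: LocusSpec) -> int:
    """Inverse of :func:`cdna_to_window_offset`."""
    if not (0 <= offset < locus.window_length):
        raise ValueError(f"offset {offset} outside window of length {locus.window_length}")
    return locus.window_cdna_start + offset


def reverse_complement(seq: str) -> str:
    """Reverse complement over the alphabet {A,C,G,T,N}."""
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return str(Seq(seq).reverse_complement())


def translate(seq: str, *, table: int = 1) -> str:
    """Translate an in-frame nucleotide string; codons containing N yield 'X'.

    Stop codons are rendered '*'.  A length that is not a multiple of 3 is
    a frame error, not silently truncated.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return str(Seq(seq).translate(table=table))


# ---------------------------------------------------------------------------
# Built-in toy locus
# ---------------------------------------------------------------------------
#
# A minimal minus-strand locus encoding the tract: cDNA codons 64..75 are
# Ser, His x 8 (residues 65-72), Arg (73, so c.218 = G), His (74), Pro (75);
# the analysis window spans c.190..c.225.  The CCA-unit run in the coding
# sequence is c.195..c.215 and cannot be 3'-shifted past c.215 (c.216_218 is
# CCG), so repeat-unit edits normalise to c.213_215 / c.207_215.  The locus
# is deliberately on the minus strand so the reverse-complement step of the
# genotyping path is exercised by default.

_TOY_CODING_WINDOW = "TCG" + "CAC" * 8 + "CGC" + "CAC" + "CCC"

#: flank length placed on each side of the window in the toy reference contig
TOY_FLANK = 80


def toy_locus(flank: int = TOY_FLANK) -> LocusSpec:
    """The built-in minus-strand toy locus (window c.190..c.225, 36 nt)."""
    return LocusSpec(
        contig_name="toy_contig",
        window_start=flank,
        window_end=flank + len(_TOY_CODING_WINDOW),
        strand="minus",
        window_cdna_start=190,
        reference_window_seq=str(Seq(_TOY_CODING_WINDOW).reverse_complement()),
        tract_aa_start=65,
        tract_aa_end=74,
        repeat_unit_cdna="CCA",
        snv_cdna_pos=218,
        snv_ref="G",
        snv_alt="A",
    )


# ---------------------------------------------------------------------------
# Configuration I/O
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = (
    "contig_name", "window_start", "window_end", "strand", "window_cdna_start",
    "tract_aa_start", "tract_aa_end", "repeat_unit_cdna",
    "snv_cdna_pos", "snv_ref", "snv_alt", "translation_table",
)


def load_locus(config_path: str | Path, fasta_path: str | Path) -> LocusSpec:
    """Load a locus from a YAML/JSON config plus a reference FASTA.

    The window sequence is read from the FASTA rather than duplicated in
    the config, so the two cannot drift apart.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    missing = [k for k in _CONFIG_FIELDS if k not in cfg and k != "translation_table"]
    if missing:
        raise ValueError(f"locus config missing fields: {missing}")
    fasta = Fasta(str(fasta_path))
    if cfg["contig_name"] not in fasta:
        raise ValueError(f"contig {cfg['contig_name']!r} not found in {fasta_path}")
    window_seq = str(fasta[cfg["contig_name"]][cfg["window_start"]:cfg["window_end"]]).upper()
    return LocusSpec(reference_window_seq=window_seq,
                     **{k: cfg[k] for k in _CONFIG_FIELDS if k in cfg})


def write_locus(locus: LocusSpec, config_path: str | Path) -> None:
    """Write the locus configuration (without the sequence) as YAML."""
    cfg = {k: getattr(locus, k) for k in _CONFIG_FIELDS}
    with open(config_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
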