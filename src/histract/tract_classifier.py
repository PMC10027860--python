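"""Allele classification and nomenclature for the repeat tract.

A coding-sense window sequence is classified into one of three outcomes:

* :class:`TractAllele` — an in-frame allele with a net change of ``k``
  repeat trinucleotide units, an SNV state at the interrupting position,
  a run-length descriptor of the tract residues (``8His1Arg1His``), a
  short name (``WT^A``, ``-1His``, ``+1His^Arg`` ...) and an HGVS-style
  cDNA name with the dup/del placed at the most-3' legal position;
* :class:`FrameshiftAllele` — the window indel is not a multiple of 3;
* :class:`UnresolvedAllele` — the anchor codons flanking the tract do not
  match the reference (alignment slippage out of the tract) or the SNV
  base cannot be read.

Short names use the Unicode minus sign, matching the published spelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.SeqUtils import seq3

from .locus_model import LocusSpec, cdna_to_window_offset, translate

__all__ = [
    "TractDescriptor",
    "TractAllele",
    "FrameshiftAllele",
    "UnresolvedAllele",
    "MINUS",
    "describe_tract",
    "classify_allele",
    "short_name",
    "hgvs_name",
    "repeat_run_cdna",
]

#: Unicode minus used in printed short names ("−1His")
MINUS = "−"

_RUN_RE = re.compile(r"(\d+)([A-Z][a-z]{2})")
_AA3_TO_1 = {}


def _aa1(three: str) -> str:
    if not _AA3_TO_1:
        for aa in "ACDEFGHIKLMNPQRSTVWY*X":
            _AA3_TO_1[seq3(aa)] = aa
    return _AA3_TO_1[three]


@dataclass(frozen=True)
class TractDescriptor:
    """Run-length encoding of the tract residues, e.g. ``8His1Arg1His``."""

    runs: tuple[tuple[str, int], ...]

    @property
    def text(self) -> str:
        return "".join(f"{count}{seq3(residue)}" for residue, count in self.runs)

    @property
    def total(self) -> int:
        return sum(count for _, count in self.runs)

    @property
    def is_empty(self) -> bool:
        return not self.runs

    @classmethod
    def from_text(cls, text: str) -> "TractDescriptor":
        runs = tuple((_aa1(m.group(2)), int(m.group(1))) for m in _RUN_RE.finditer(text))
        if "".join(f"{c}{seq3(r)}" for r, c in runs) != text:
            raise ValueError(f"unparseable descriptor text: {text!r}")
        return cls(runs)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class TractAllele:
    """An in-frame classified tract allele."""

    k: int
    snv: str  # "G" | "A"
    descriptor: TractDescriptor
    short_name: str
    hgvs_c: str
    in_frame: bool = True
    canonical: bool = True
    read_support: int = 0

    @property
    def key(self) -> tuple:
        """Identity used when tallying read-level observations."""
        return (self.k, self.snv, self.descriptor.text)


@dataclass(frozen=True)
class FrameshiftAllele:
    """Window indel whose length is not a multiple of 3."""

    delta: int
    read_support: int = 0

    @property
    def key(self) -> tuple:
        return ("frameshift", self.delta)


@dataclass(frozen=True)
class UnresolvedAllele:
    """A spanning read that cannot be interpreted as a tract allele."""

    reason: str

    @property
    def key(self) -> tuple:
        return ("unresolved", self.reason)


def describe_tract(aa_seq: str) -> TractDescriptor:
    """Maximal run-length encoding of an amino-acid string."""
    runs: list[tuple[str, int]] = []
    for residue in aa_seq:
        if runs and runs[-1][0] == residue:
            runs[-1] = (residue, runs[-1][1] + 1)
        else:
            runs.append((residue, 1))
    return TractDescriptor(tuple(runs))


def short_name(k: int, snv: str) -> str:
    """Short allele name: WT^A / WT^G for k=0, else ±kHis with ^Arg iff snv=G."""
    if snv not in ("G", "A"):
        raise ValueError(f"snv state must be 'G' or 'A', got {snv!r}")
    if k == 0:
        return f"WT^{snv}"
    sign = "+" if k > 0 else MINUS
    suffix = "^Arg" if snv == "G" else ""
    return f"{sign}{abs(k)}His{suffix}"


def parse_short_name(name: str) -> tuple[int, str]:
    """Inverse of :func:`short_name`; accepts ASCII '-' as well as '−'."""
    if name in ("WT^A", "WT^G"):
        return 0, name[-1]
    m = re.fullmatch(rf"([+\-{MINUS}])(\d+)His(\^Arg)?", name)
    if not m:
        raise ValueError(f"unknown short allele name: {name!r}")
    k = int(m.group(2)) * (1 if m.group(1) == "+" else -1)
    return k, ("G" if m.group(3) else "A")


def repeat_run_cdna(locus: LocusSpec) -> tuple[int, int]:
    """Locate the maximal repeat-unit run in the coding window.

    Returns 1-based cDNA positions ``(start, end)`` of the longest run of
    ``repeat_unit_cdna`` copies (the most-3' one on ties).  HGVS dup/del
    names are anchored at the 3' end of this run.
    """
    coding = locus.coding_window_seq
    unit = locus.repeat_unit_cdna
    u = len(unit)
    best = None
    for s in range(len(coding)):
        m = 0
        while coding[s + m * u: s + (m + 1) * u] == unit:
            m += 1
        if m and (best is None or m >= best[1]):
            best = (s, m)
    if best is None:
        raise ValueError("repeat unit not found in coding window")
    s, m = best
    return (locus.window_cdna_start + s, locus.window_cdna_start + s + m * u - 1)


def hgvs_name(k: int, snv: str, locus: LocusSpec) -> str:
    """HGVS-style cDNA name for a whole-unit repeat edit combined with the SNV.

    The dup/del of ``|k|`` units is placed at the most-3' legal position in
    the reference repeat run (the HGVS 3' rule); when an indel and the SNV
    co-occur on one allele the two are bracketed: ``c.[213_215delCCA;218G>A]``.
    """
    if snv not in ("G", "A"):
        raise ValueError(f"snv state must be 'G' or 'A', got {snv!r}")
    pos = locus.snv_cdna_pos
    snv_part = f"{pos}{locus.snv_ref}>{locus.snv_alt}" if snv == locus.snv_alt else f"{pos}{locus.snv_ref}"
    if k == 0:
        return f"c.{snv_part}"
    run_start, run_end = repeat_run_cdna(locus)
    u = len(locus.repeat_unit_cdna)
    span = abs(k) * u
    if span > run_end - run_start + 1:
        raise ValueError(f"edit of {abs(k)} units exceeds the reference repeat run")
    a, b = run_end - span + 1, run_end
    kind = "dup" if k > 0 else "del"
    indel = f"{a}_{b}{kind}{locus.repeat_unit_cdna * abs(k)}"
    return f"c.[{indel};{snv_part}]"


def classify_allele(
    coding_seq: str, locus: LocusSpec
) -> TractAllele | FrameshiftAllele | UnresolvedAllele:
    """Classify a coding-sense window sequence into a tract allele.

    The net length change must be a whole number of codons, the anchor
    codons flanking the tract must translate to the reference residues,
    and the SNV base is read at the window offset of the SNV cDNA
    position shifted by ``3k`` (the repeat edit lies 5' of the SNV).
    """
    wlen = locus.window_length
    delta = len(coding_seq) - wlen
    if delta % 3 != 0:
        return FrameshiftAllele(delta)
    k = delta // 3

    ref_protein = locus.reference_protein
    n_pre = locus.tract_aa_start - locus.first_codon
    n_post = locus.last_codon - locus.tract_aa_end
    try:
        protein = translate(coding_seq, table=locus.translation_table)
    except ValueError:
        return UnresolvedAllele("untranslatable")
    if len(protein) < n_pre + n_post:
        return UnresolvedAllele("window-too-short")
    if protein[:n_pre] != ref_protein[:n_pre] or (
            n_post and protein[-n_post:] != ref_protein[-n_post:]):
        return UnresolvedAllele("anchor-mismatch")

    tract = protein[n_pre: len(protein) - n_post] if n_post else protein[n_pre:]
    if "X" in tract:
        return UnresolvedAllele("ambiguous-base-in-tract")
    descriptor = describe_tract(tract)

    snv_offset = cdna_to_window_offset(locus.snv_cdna_pos, locus) + 3 * k
    if not (0 <= snv_offset < len(coding_seq)):
        return UnresolvedAllele("snv-position-removed")
    snv = coding_seq[snv_offset]
    if snv not in (locus.snv_ref, locus.snv_alt):
        return UnresolvedAllele(f"unexpected-snv-base-{snv}")
    snv_state = "A" if snv == locus.snv_alt else "G"

    canonical = _is_canonical(descriptor, k, snv_state)
    return TractAllele(
        k=k,
        snv=snv_state,
        descriptor=descriptor,
        short_name=short_name(k, snv_state),
        hgvs_c=hgvs_name(k, snv_state, locus),
        canonical=canonical,
    )


def _is_canonical(descriptor: TractDescriptor, k: int, snv: str) -> bool:
    """Whether the descriptor matches the pure repeat-edit expectation.

    snv=A alleles are a single uninterrupted His run of 10+k; snv=G
    alleles are (8+k)His 1Arg 1His.  Reads carrying additional base-call
    errors in the tract fail this test and are kept as distinct,
    non-canonical alleles so that noise never merges into a true allele.
    """
    if snv == "A":
        return descriptor.runs == (("H", 10 + k),)
    return descriptor.runs == (("H", 8 + k), ("R", 1), ("H", 1))
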