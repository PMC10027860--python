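"""Diploid genotype calling from read-level allele observations.

Calling is a deliberately simple, fully auditable threshold rule rather
than a likelihood model: an allele is *supported* when it reaches both an
absolute read count and a fraction of the sample's spanning reads.  One
supported allele is a homozygous call — provided it also carries enough
of the spanning reads that a hidden second allele is implausible — two a
heterozygous call, more than two a "complex" flag, and none (or too few
spanning reads) a no-call.  Read support is pooled per (k, snv) class,
the locus's two measurable segregating features, so isolated base-call
errors elsewhere in the tract neither spawn phantom alleles nor erode
support for the true ones.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .locus_model import LocusSpec
from .read_reconstruction import ScanFilters, scan_alignment
from .tract_classifier import (FrameshiftAllele, TractAllele, UnresolvedAllele,
                               classify_allele)

__all__ = [
    "GenotypeThresholds",
    "GenotypeCall",
    "call_genotype",
    "genotype_coding_seqs",
    "genotype_alignment",
    "write_genotypes_tsv",
]


@dataclass(frozen=True)
class GenotypeThresholds:
    """Support thresholds for the calling rule (all echoed in output)."""

    min_spanning: int = 10
    min_reads: int = 3
    min_fraction: float = 0.2
    #: a hom call requires the single supported allele to carry at least
    #: this fraction of spanning reads; a lone supported allele below it
    #: (allelic imbalance, e.g. a heterozygote whose second allele just
    #: missed min_fraction) yields a no_call instead of a silent undercall
    min_hom_fraction: float = 0.8


@dataclass
class GenotypeCall:
    sample_id: str
    zygosity: str  # "hom" | "het" | "complex" | "no_call"
    alleles: list  # TractAllele (or FrameshiftAllele) with read_support filled
    spanning_reads: int
    reasons: list[str] = field(default_factory=list)
    thresholds: GenotypeThresholds = field(default_factory=GenotypeThresholds)

    @property
    def allele_names(self) -> tuple[str, ...]:
        names = tuple(
            a.short_name if hasattr(a, "short_name") else f"fs({a.delta:+d})"
            for a in self.alleles
        )
        if self.zygosity == "hom":
            return (names[0], names[0])
        return names

    @property
    def support_fractions(self) -> tuple[float, ...]:
        if self.spanning_reads == 0:
            return tuple(0.0 for _ in self.alleles)
        return tuple(a.read_support / self.spanning_reads for a in self.alleles)


def _sort_key(item):
    allele, count = item
    if isinstance(allele, str):
        name = allele
    else:
        name = getattr(allele, "short_name", None) or repr(allele.key)
    return (-count, name)


def call_genotype(
    observations: Mapping,
    thresholds: GenotypeThresholds | None = None,
    *,
    spanning_reads: int | None = None,
    sample_id: str = "",
) -> GenotypeCall:
    """Collapse an allele→read-count map into a diploid genotype call.

    ``observations`` maps classified alleles (or short-name strings, for
    count-table input) to non-negative read counts.  ``spanning_reads``
    defaults to the sum of counts; in the pipeline it also includes
    spanning reads that classified as unresolved.
    """
    thresholds = thresholds or GenotypeThresholds()
    if any(c < 0 for c in observations.values()):
        raise ValueError("negative read counts in observations")
    total = sum(observations.values())
    spanning = total if spanning_reads is None else spanning_reads
    if spanning < total:
        raise ValueError("spanning_reads cannot be smaller than the summed counts")

    if spanning < thresholds.min_spanning:
        return GenotypeCall(sample_id, "no_call", [], spanning,
                            [f"spanning reads {spanning} < min_spanning "
                             f"{thresholds.min_spanning}"], thresholds)

    supported = [
        (allele, count) for allele, count in observations.items()
        if count >= thresholds.min_reads and count / spanning >= thresholds.min_fraction
    ]
    supported.sort(key=_sort_key)
    alleles = [_with_support(a, c) for a, c in supported]

    if not supported:
        return GenotypeCall(sample_id, "no_call", [], spanning,
                            ["no allele meets support thresholds"], thresholds)
    if len(supported) == 1:
        fraction = supported[0][1] / spanning
        if fraction < thresholds.min_hom_fraction:
            return GenotypeCall(
                sample_id, "no_call", alleles, spanning,
                [f"allelic imbalance: single supported allele at fraction "
                 f"{fraction:.2f} < min_hom_fraction "
                 f"{thresholds.min_hom_fraction}"], thresholds)
        return GenotypeCall(sample_id, "hom", alleles, spanning, [], thresholds)
    if len(supported) == 2:
        return GenotypeCall(sample_id, "het", alleles, spanning, [], thresholds)
    return GenotypeCall(sample_id, "complex", alleles, spanning,
                        [f"{len(supported)} alleles meet support thresholds"], thresholds)


def _with_support(allele, count: int):
    if isinstance(allele, str):
        return _NamedAllele(allele, count)
    try:
        from dataclasses import replace
        return replace(allele, read_support=count)
    except TypeError:
        return allele


@dataclass(frozen=True)
class _NamedAllele:
    """Wrapper so bare short-name keys behave like alleles in a call."""

    short_name: str
    read_support: int

    @property
    def key(self):
        return (self.short_name,)


def genotype_coding_seqs(
    coding_seqs: Iterable[str],
    locus: LocusSpec,
    thresholds: GenotypeThresholds | None = None,
    *,
    sample_id: str = "",
) -> GenotypeCall:
    """Classify each spanning read's coding sequence and call the genotype.

    Frameshift alleles participate in calling (a real frameshift allele is
    reportable); unresolved reads count toward spanning depth only.
    """
    # support is pooled per (k, snv) class -- the two measurable
    # segregating features of the locus; the class descriptor is the
    # majority descriptor among its reads, so isolated base-call errors
    # in the tract neither spawn phantom alleles nor erode support
    class_counts: Counter = Counter()
    descriptor_votes: dict[tuple, Counter] = {}
    fs_counts: Counter = Counter()
    spanning = 0
    unresolved = 0
    for seq in coding_seqs:
        spanning += 1
        allele = classify_allele(seq, locus)
        if isinstance(allele, UnresolvedAllele):
            unresolved += 1
        elif isinstance(allele, FrameshiftAllele):
            fs_counts[allele.delta] += 1
        else:
            cls = (allele.k, allele.snv)
            class_counts[cls] += 1
            descriptor_votes.setdefault(cls, Counter())[allele] += 1
    observations: dict = {}
    for cls, count in class_counts.items():
        representative = max(descriptor_votes[cls].items(),
                             key=lambda kv: (kv[1], kv[0].canonical))[0]
        observations[representative] = count
    for delta, count in fs_counts.items():
        observations[FrameshiftAllele(delta)] = count
    call = call_genotype(observations, thresholds,
                         spanning_reads=spanning, sample_id=sample_id)
    if unresolved:
        call.reasons.append(f"{unresolved} unresolved spanning reads")
    return call


def genotype_alignment(
    alignment: str | Path,
    locus: LocusSpec,
    thresholds: GenotypeThresholds | None = None,
    filters: ScanFilters | None = None,
) -> tuple[list[GenotypeCall], "pd.DataFrame"]:
    """End-to-end: scan a SAM/BAM file, group reads by sample, call genotypes.

    The sample of each read is its read-group (RG) tag; reads without one
    fall into a single sample named after the file stem.  Returns the calls
    plus a per-sample QC DataFrame.
    """
    segments, report = scan_alignment(alignment, locus, filters)
    default_sample = Path(str(alignment)).stem
    by_sample: dict[str, list[str]] = {}
    for seg, coding in segments:
        by_sample.setdefault(seg.sample_id or default_sample, []).append(coding)

    calls = [
        genotype_coding_seqs(seqs, locus, thresholds, sample_id=sid)
        for sid, seqs in sorted(by_sample.items())
    ]
    qc = pd.DataFrame(
        {"sample_id": [c.sample_id for c in calls],
         "zygosity": [c.zygosity for c in calls],
         "alleles": ["/".join(c.allele_names) for c in calls],
         "spanning_reads": [c.spanning_reads for c in calls],
         "reasons": ["; ".join(c.reasons) for c in calls]}
    )
    return calls, qc


def write_genotypes_tsv(calls: list[GenotypeCall], path: str | Path,
                        qc_json: str | Path | None = None) -> None:
    rows = []
    for c in calls:
        rows.append({
            "sample_id": c.sample_id,
            "zygosity": c.zygosity,
            "genotype": "/".join(c.allele_names) if c.alleles else ".",
            "spanning_reads": c.spanning_reads,
            "allele_support": ",".join(str(a.read_support) for a in c.alleles),
            "reasons": "; ".join(c.reasons),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if qc_json is not None:
        qc = {
            "thresholds": vars(calls[0].thresholds) if calls else {},
            "n_samples": len(calls),
            "n_no_call": sum(c.zygosity == "no_call" for c in calls),
        }
        with open(qc_json, "w") as fh:
            json.dump(qc, fh, indent=2)
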