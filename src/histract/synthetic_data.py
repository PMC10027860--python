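"""Synthetic data: allele sequences, simulated aligned reads, count fixtures.

The simulator emulates what the genotyping path consumes — aligned short
reads over the repeat locus from diploid samples — without an aligner in
the loop: reads are emitted pre-aligned with the true CIGAR of the
haplotype they were drawn from.  It models per-base substitution errors,
soft-clipped read ends and non-spanning placements; it deliberately does
not model PCR stutter at the homopolymer, so recovery rates measured on
its output are an upper bound for real homopolymer data.

The module also ships the published cohort count tables (allele counts in
333 index cases, baseline characteristics, mouse penetrance counts and
population-database frequencies) as plain fixtures for the statistics
layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .locus_model import (LocusSpec, TOY_FLANK, reverse_complement, toy_locus,
                          write_locus)
from .tract_classifier import (MINUS, classify_allele, parse_short_name,
                               repeat_run_cdna)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "build_allele_sequence",
    "build_reference_contig",
    "simulate_reads",
    "emit_toy_locus",
    "emit_paper_fixtures",
    "TABLE2_ALLELE_COUNTS",
    "TABLE2_N_INDIVIDUALS",
    "TABLE1_COHORT",
    "MOUSE_PENETRANCE",
    "GNOMAD_FREQUENCIES",
]

# ---------------------------------------------------------------------------
# Published count tables (inputs to the statistics layer)
# ---------------------------------------------------------------------------

TABLE2_N_INDIVIDUALS = 333

#: allele counts over 666 chromosomes in the index-case cohort
TABLE2_ALLELE_COUNTS: dict[str, int] = {
    "+1His": 4,
    "+1His^Arg": 1,
    "WT^A": 537,
    "WT^G": 99,
    f"{MINUS}1His": 22,
    f"{MINUS}1His^Arg": 0,   # not found in this cohort
    f"{MINUS}3His": 0,       # not found in this cohort
    f"{MINUS}3His^Arg": 3,
}

#: baseline cohort characteristics (category counts over 333 index cases)
TABLE1_COHORT: dict = {
    "n": 333,
    "male": 249,
    "family_history": 30,
    "sievers": {
        "Type 0": 44,
        "Type 1, R-L": 227,
        "Type 1, R-NC": 38,
        "Type 1, L-NC": 9,
        "Type 2": 5,
        "Type 1, Not determined": 1,
        "Not determined": 9,
    },
}

#: aortic-valve phenotype penetrance in mouse lines: group -> (affected, total)
MOUSE_PENETRANCE: dict[str, tuple[int, int]] = {
    "null_hom": (3, 11),
    "minus1his_hom": (4, 23),
    "hexapeptide_hom": (5, 52),
    "wildtype": (0, 21),
    "minus1his_het": (0, 43),
}

#: population-database allele frequencies (reference-only values)
GNOMAD_FREQUENCIES: dict[str, float] = {
    "dup1unit": 4.25e-3,
    "del1unit": 7.78e-4,
    "del3units": 3.29e-3,
    "snv_alt": 7.53e-1,
}


# ---------------------------------------------------------------------------
# Allele sequence construction
# ---------------------------------------------------------------------------

def build_allele_sequence(short_name: str, locus: LocusSpec) -> str:
    """Coding-sense window sequence for a named allele.

    Inserts/deletes ``|k|`` repeat units at the 3' end of the reference
    repeat run and sets the SNV base per the ``^Arg`` suffix; the inverse
    of classification, and asserted to round-trip through it.
    """
    k, snv = parse_short_name(short_name)
    coding = list(locus.coding_window_seq)
    run_start, run_end = repeat_run_cdna(locus)
    run_end_off = run_end - locus.window_cdna_start
    unit = locus.repeat_unit_cdna
    u = len(unit)
    if run_end >= locus.snv_cdna_pos:
        raise ValueError("repeat run is not 5' of the SNV position")
    if k > 0:
        coding[run_end_off + 1: run_end_off + 1] = list(unit * k)
    elif k < 0:
        span = -k * u
        if span > run_end - run_start + 1:
            raise ValueError(f"cannot delete {-k} units from the reference run")
        del coding[run_end_off - span + 1: run_end_off + 1]
    snv_off = (locus.snv_cdna_pos - locus.window_cdna_start) + 3 * k
    coding[snv_off] = locus.snv_alt if snv == "A" else locus.snv_ref
    seq = "".join(coding)

    check = classify_allele(seq, locus)
    assert getattr(check, "k", None) == k and getattr(check, "snv", None) == snv, \
        f"allele construction for {short_name!r} does not round-trip"
    return seq


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated cohort.

    ``coverage`` is the mean number of *spanning* reads per sample; the
    simulator emits ``round(coverage / (1 - nonspanning_prob))`` reads and
    places each one non-spanning with probability ``nonspanning_prob``.
    """

    samples: tuple[tuple[str, str, str], ...]  # (sample_id, allele_1, allele_2)
    locus: LocusSpec = field(default_factory=toy_locus)
    coverage: float = 30.0
    read_length: int = 100
    base_error_rate: float = 0.01
    softclip_prob: float = 0.1
    nonspanning_prob: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.read_length <= self.locus.window_length + 6:
            raise ValueError("read_length must exceed window length + 6")
        for p in (self.base_error_rate, self.softclip_prob, self.nonspanning_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.nonspanning_prob >= 1.0:
            raise ValueError("nonspanning_prob must be < 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not self.samples:
            raise ValueError("at least one sample required")


@dataclass
class SimulationResult:
    sam_path: Path
    fasta_path: Path
    truth_reads: pd.DataFrame
    truth_genotypes: pd.DataFrame
    locus: LocusSpec


def build_reference_contig(locus: LocusSpec, right_flank: int = TOY_FLANK) -> str:
    """Reference-strand contig: deterministic flanks around the locus window.

    Flank sequence is fixed (independent of any simulation seed) so the
    reference genome is the same object across runs.
    """
    rng = np.random.default_rng(0x0A11E1E)
    left = "".join(rng.choice(list("ACGT"), size=locus.window_start))
    right = "".join(rng.choice(list("ACGT"), size=right_flank))
    return left + locus.reference_window_seq + right


def _haplotype_alignment(allele: str, locus: LocusSpec, contig_len: int):
    """Haplotype contig sequence plus its contig-level alignment ops.

    Ops are (op, length) with op in {M, I, D} over the whole reference
    contig, in reference-strand order.
    """
    coding = build_allele_sequence(allele, locus)
    k = (len(coding) - locus.window_length) // 3
    vw = reverse_complement(coding) if locus.strand == "minus" else coding

    run_start, run_end = repeat_run_cdna(locus)
    run_end_off = run_end - locus.window_cdna_start
    u = len(locus.repeat_unit_cdna)
    L = locus.window_length
    if k > 0:
        c_pre, c_post = run_end_off + 1, L - run_end_off - 1
        mid = ("I", k * u)
    elif k < 0:
        span = -k * u
        c_pre, c_post = run_end_off - span + 1, L - run_end_off - 1
        mid = ("D", span)
    else:
        c_pre, c_post, mid = L, 0, None

    left = locus.window_start
    right = contig_len - locus.window_end
    if mid is None:
        ops = [("M", left + L + right)]
    elif locus.strand == "minus":
        ops = [("M", left + c_post), mid, ("M", c_pre + right)]
    else:
        ops = [("M", left + c_pre), mid, ("M", c_post + right)]

    return vw, ops


def _extract_read_cigar(ops, h0: int, h1: int):
    """Sub-alignment of a haplotype interval [h0, h1): (ref_start, cigar)."""
    ref = hap = 0
    out: list[tuple[str, int]] = []
    ref_start = None
    for op, ln in ops:
        if op == "M":
            lo, hi = max(hap, h0), min(hap + ln, h1)
            if lo < hi:
                if ref_start is None:
                    ref_start = ref + (lo - hap)
                out.append(("M", hi - lo))
            ref += ln
            hap += ln
        elif op == "I":
            lo, hi = max(hap, h0), min(hap + ln, h1)
            if lo < hi:
                out.append(("I", hi - lo))
            hap += ln
        elif op == "D":
            if h0 < hap < h1 and out:
                out.append(("D", ln))
            ref += ln
        if hap >= h1:
            break
    while out and out[-1][0] == "D":
        out.pop()
    merged: list[tuple[str, int]] = []
    for op, ln in out:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    assert ref_start is not None
    return ref_start, merged


def simulate_reads(config: SimulationConfig, out_dir: str | Path) -> SimulationResult:
    """Emit reference FASTA, read-group-tagged SAM and truth tables.

    Deterministic under ``config.seed``: per-sample random streams are
    spawned from a single root seed in sample order, so the same
    configuration always produces byte-identical output.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locus = config.locus

    ref_contig = build_reference_contig(locus)
    fasta_path = out_dir / "reference.fa"
    _write_fasta(fasta_path, locus.contig_name, ref_contig)

    # per-allele haplotype contigs and alignments, built lazily
    hap_cache: dict[str, tuple[str, list[tuple[str, int]]]] = {}

    def haplotype(allele: str):
        if allele not in hap_cache:
            vw, ops = _haplotype_alignment(allele, locus, len(ref_contig))
            hap_contig = (ref_contig[:locus.window_start] + vw
                          + ref_contig[locus.window_end:])
            hap_cache[allele] = (hap_contig, ops)
        return hap_cache[allele]

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.contig_name, "LN": len(ref_contig)}],
        "RG": [{"ID": sid, "SM": sid} for sid, _, _ in config.samples],
    }

    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.samples))
    n_reads = max(1, round(config.coverage / (1.0 - config.nonspanning_prob)))
    Lr = config.read_length
    ws, we = locus.window_start, locus.window_end

    truth_rows = []
    geno_rows = []
    sam_path = out_dir / "reads.sam"
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as sam:
        for (sid, a1, a2), ss in zip(config.samples, streams):
            rng = np.random.default_rng(ss)
            geno_rows.append({"sample_id": sid, "allele_1": a1, "allele_2": a2})
            for i in range(n_reads):
                allele = a1 if rng.random() < 0.5 else a2
                hap_contig, ops = haplotype(allele)
                k = (len(hap_contig) - len(ref_contig)) // 3
                hw_end = we + 3 * k  # hap offset one past the window
                nonspanning = rng.random() < config.nonspanning_prob

                if nonspanning:
                    # start just inside the window: misses the left boundary
                    h0 = int(rng.integers(ws + 1, ws + 6))
                else:
                    lo = max(0, hw_end - Lr)
                    hi = min(ws, len(hap_contig) - Lr)
                    h0 = int(rng.integers(lo, hi + 1))
                h1 = min(h0 + Lr, len(hap_contig))

                ref_start, cigar = _extract_read_cigar(ops, h0, h1)
                seq = list(hap_contig[h0:h1])
                n_err = 0
                err_mask = rng.random(len(seq)) < config.base_error_rate
                for j in np.flatnonzero(err_mask):
                    alts = [b for b in "ACGT" if b != seq[j]]
                    seq[j] = alts[int(rng.integers(0, 3))]
                    n_err += 1

                # soft clips, each end independently; never clip into the window
                if rng.random() < config.softclip_prob:
                    c = int(rng.integers(3, 11))
                    first = cigar[0]
                    if first[0] == "M" and first[1] > c and ref_start + c <= ws:
                        cigar = [("S", c), ("M", first[1] - c)] + cigar[1:]
                        ref_start += c
                if rng.random() < config.softclip_prob:
                    c = int(rng.integers(3, 11))
                    last = cigar[-1]
                    end_ref = ref_start + sum(n for op, n in cigar if op in "MD")
                    if last[0] == "M" and last[1] > c and end_ref - c >= we:
                        cigar = cigar[:-1] + [("M", last[1] - c), ("S", c)]

                rec = pysam.AlignedSegment(header=pysam.AlignmentHeader.from_dict(header))
                rec.query_name = f"{sid}_r{i:05d}"
                rec.flag = 0 if rng.random() < 0.5 else 16
                rec.reference_id = 0
                rec.reference_start = ref_start
                rec.mapping_quality = 60
                rec.cigarstring = "".join(f"{n}{op}" for op, n in cigar)
                rec.query_sequence = "".join(seq)
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                rec.set_tag("RG", sid, "Z")
                sam.write(rec)

                truth_rows.append({
                    "sample_id": sid, "read_name": rec.query_name,
                    "true_allele": allele, "n_errors": n_err,
                    "spanning": not nonspanning,
                })

    truth_reads = pd.DataFrame(truth_rows)
    truth_genotypes = pd.DataFrame(geno_rows)
    truth_reads.to_csv(out_dir / "truth_reads.tsv", sep="\t", index=False)
    truth_genotypes.to_csv(out_dir / "truth_genotypes.tsv", sep="\t", index=False)
    return SimulationResult(sam_path, fasta_path, truth_reads, truth_genotypes, locus)


def _write_fasta(path: Path, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i:i + width] + "\n")


def emit_toy_locus(out_dir: str | Path) -> tuple[Path, Path]:
    """Write the built-in toy locus as FASTA + YAML config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    locus = toy_locus()
    fasta_path = out_dir / "toy_reference.fa"
    _write_fasta(fasta_path, locus.contig_name, build_reference_contig(locus))
    config_path = out_dir / "toy_locus.yaml"
    write_locus(locus, config_path)
    return config_path, fasta_path


def draw_cohort_samples(
    n_samples: int,
    seed: int,
    allele_counts: dict[str, int] | None = None,
) -> tuple[tuple[str, str, str], ...]:
    """Random diploid genotypes with alleles drawn at cohort proportions.

    Alleles are sampled independently per chromosome with probabilities
    proportional to ``allele_counts`` (default: the published cohort
    spectrum), i.e. assuming Hardy–Weinberg proportions.
    """
    counts = allele_counts or {a: c for a, c in TABLE2_ALLELE_COUNTS.items() if c}
    names = sorted(counts)
    total = sum(counts.values())
    probs = [counts[a] / total for a in names]
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n_samples):
        a1, a2 = rng.choice(names, size=2, p=probs)
        samples.append((f"sample{i:04d}", str(a1), str(a2)))
    return tuple(samples)


# ---------------------------------------------------------------------------
# Fixture emission
# ---------------------------------------------------------------------------

def emit_paper_fixtures(out_dir: str | Path) -> dict[str, Path]:
    """Write the published count tables as TSV fixtures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = out_dir / "cohort_allele_counts.tsv"
    pd.DataFrame(
        [{"allele": a, "count": c} for a, c in TABLE2_ALLELE_COUNTS.items()]
    ).to_csv(p, sep="\t", index=False)
    paths["allele_counts"] = p

    p = out_dir / "cohort_baseline_counts.tsv"
    rows = [{"category": "patients", "count": TABLE1_COHORT["n"]},
            {"category": "male", "count": TABLE1_COHORT["male"]},
            {"category": "family_history", "count": TABLE1_COHORT["family_history"]}]
    rows += [{"category": f"sievers:{k}", "count": v}
             for k, v in TABLE1_COHORT["sievers"].items()]
    pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
    paths["baseline_counts"] = p

    p = out_dir / "mouse_penetrance_counts.tsv"
    pd.DataFrame(
        [{"group": g, "affected": a, "total": t}
         for g, (a, t) in MOUSE_PENETRANCE.items()]
    ).to_csv(p, sep="\t", index=False)
    paths["penetrance_counts"] = p

    p = out_dir / "population_db_frequencies.tsv"
    pd.DataFrame(
        [{"variation": k, "allele_frequency": v}
         for k, v in GNOMAD_FREQUENCIES.items()]
    ).to_csv(p, sep="\t", index=False)
    paths["population_frequencies"] = p
    return paths
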