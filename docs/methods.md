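# Methods

## Locus model

A locus is an analysis window on the reference genome (0-based, half-open)
containing a coding trinucleotide repeat. The window must start and end on
codon boundaries and include at least one *anchor codon* on each side of
the repeat tract; cDNA (`c.`) positions are 1-based with codon *n*
spanning `c.(3n−2)..3n`. The built-in toy locus encodes codons 64–75 as
Ser, His×8 (residues 65–72), Arg (codon 73, so `c.218 = G`), His (74),
Pro (75), with the window at `c.190..c.225` (36 nt). The CCA-unit run in
the coding sequence is `c.195..c.215`; the trinucleotide immediately 3′ of
it (`c.216_218 = CCG`) breaks the repeat, so unit-wise 3′ normalization
places single-unit edits at `c.213_215` and the three-unit deletion at
`c.207_215`. The toy locus is deliberately on the minus strand so the
reverse-complement step of the genotyping path is exercised by default.
It is a constructed stand-in, not the true human sequence (which the
associated study does not print); it is constrained so that the published
variant names are reproduced exactly, and that constraint is asserted by
test rather than assumed.

Translation uses the standard genetic code (Biopython); a codon containing
`N` translates to `X`, and alleles with `X` in the tract are classified
unresolved rather than guessed.

## Read reconstruction

For each mapped read the CIGAR is walked while tracking the
(reference, query) position pair. `M/=/X` bases with reference position in
the window are copied; `D` advances the reference and counts deleted bases
inside the window; an insertion is copied iff its anchor (the preceding
aligned reference base) is a window base — an insertion anchored
immediately before the window is excluded, one anchored at the final
window base included (half-open convention, deterministic). `S/H/P`
contribute nothing; an `N` (splice) overlapping the window rejects the
read, since a spliced alignment across a coding tract is not
interpretable. A read is *spanning*, hence usable, only if its aligned
(`M/=/X/D`) footprint covers both terminal window bases; the invariant
`len(segment) = window − deleted + inserted` holds for every accepted
read and is asserted against a naive per-base alignment-expansion oracle
on randomized CIGARs.

Default read filters: skip unmapped, secondary, supplementary and
duplicate-flagged reads; minimum mapping quality 20; no per-base quality
filtering (an optional mean-window-quality threshold exists). Every
filtered read is tallied by reason in a `ScanReport` so scans are
auditable.

## Allele classification

A coding-sense window sequence whose length difference from the reference
is not a multiple of 3 is a frameshift allele; it is retained, reported
separately, and excluded from tract-allele frequency tables. Otherwise
`k = Δ/3` repeat units. The anchor codons must translate to the reference
residues (else the read is unresolved — alignment slippage out of the
tract); the residues between the anchors give the run-length descriptor.
The SNV state is read from the nucleotide at the window offset of the SNV
position shifted by `3k` (the repeat edit always lies 5′ of the SNV);
alleles whose edit removes the SNV base, or with an unexpected base there,
are unresolved. Short names follow the published scheme (`WT^A`, `WT^G`,
`±kHis` with `^Arg` iff the interrupting arginine is retained; minus
rendered with U+2212). HGVS-style cDNA names place the dup/del at the
most-3′ legal *unit-aligned* position in the reference repeat run and
bracket co-occurring changes (`c.[213_215delCCA;218G>A]`). Note that
base-wise 3′ shifting could slide an edit further inside a period-3
region; the unit-wise rule is the one that reproduces the published
names and is validated by enumerating unit-aligned placements.

## Genotype calling

Read support is pooled per `(k, snv)` class — the locus's two measurable
segregating features. Reads with isolated base-call errors elsewhere in
the tract keep their class, so noise neither spawns phantom alleles nor
erodes support; the class descriptor reported is the majority descriptor
among its reads. No merging across `(k, snv)` classes is performed.

The calling rule is thresholds only, no likelihoods:

| parameter | default | meaning |
|---|---|---|
| `min_spanning` | 10 | spanning reads below this → no-call |
| `min_reads` | 3 | absolute support for an allele |
| `min_fraction` | 0.2 | support as fraction of spanning reads |
| `min_hom_fraction` | 0.8 | fraction a lone supported allele needs for a hom call |

One supported allele → hom, two → het, more → complex, none → no-call.
The `min_hom_fraction` guard exists because a heterozygote can, by the
luck of the per-read coin flip, leave its minority allele just below
`min_fraction` (e.g. 6 of 31 reads); without the guard such samples
become confident — and wrong — homozygous calls. With it they are
no-calls flagged "allelic imbalance": at the simulator's default
conditions a 30-seed sweep of 200-sample cohorts produced zero wrong
confident calls, with at worst 2 no-calls per run. A true homozygote is
essentially never caught by the guard, since only anchor-codon errors
(~6% of reads at 1% base error) remove reads from its class. Ties in
support are broken by higher count, then lexicographic short name, so
calls are deterministic.

## Cohort statistics

Allele frequencies are counts over `2 × n` chromosomes; the count sum is
validated, never renormalised. Percent text rounds half up at 2 decimals
(penetrance at 0 decimals), with the raw fraction always carried
alongside — published tables of this kind often contain entries
inconsistent with any single rounding rule, so formatted strings are
presentation, not data. Fisher's exact 2×2 test uses the probability-mass
two-sided definition (sum of tables with point probability ≤ observed;
scipy's implementation, cross-checked exhaustively against integer
enumeration for all tables with margins ≤ 12). The odds ratio is the
sample odds ratio `ad/bc` with explicit markers for empty denominators.
`binomial_vs_reference` provides the exact binomial tail test for
comparing a cohort proportion against a published population proportion
whose underlying counts are unavailable; with only a printed reference
proportion the original test construction cannot be reconstructed, so no
specific published p-value is claimed.

## Simulator

The simulator emits pre-aligned reads (the true CIGAR of the generating
haplotype) — no aligner in the loop, matching a pipeline that consumes
existing alignments. Per sample: `round(coverage/(1 − nonspanning_prob))`
reads, each drawn from one of the two haplotypes by fair coin; placed
uniformly among spanning positions, or (with probability
`nonspanning_prob`) starting inside the window so the left boundary is
missed; per-base substitution errors at `base_error_rate`; each read end
independently soft-clipped with probability `softclip_prob` (clips never
cross into the window, so clipping changes records, not spanning status).
Defaults — coverage 30 spanning reads, read length 100 nt, 1% base error,
10% clip, 20% non-spanning — represent a well-covered short-read panel
locus. Base qualities are constant (Q40); there is no quality modeling
and, deliberately, no PCR-stutter model for the homopolymer: stutter
rates would have to be invented, and an unvalidated stutter model would
only manufacture false confidence. Recovery rates measured on simulated
data are therefore an upper bound on real homopolymer performance; the
flanking contig sequence is random with a fixed internal seed, so the
reference FASTA is identical across runs while read sampling follows the
user seed (one root seed, per-sample child streams spawned in sample
order; same configuration → byte-identical SAM).

Cohort simulations draw each chromosome independently at the published
cohort's allele proportions (Hardy–Weinberg), 200 samples for genotype
recovery and 300 for frequency recovery — sizes at which the binomial
99% bounds used for checking are informative while a full run stays
under a minute.

## Known limitations

- Exactly one locus per run; no transcript models, no genome-wide scan.
- No realignment or local assembly; the input alignments are trusted.
- Thresholds are declared, not learned; there is no likelihood model or
  population prior.
- The toy locus reproduces the published nomenclature but is not the true
  human sequence; analyses of real data must supply the real locus as
  FASTA + config.
- Frameshift alleles are detected and reported but not HGVS-named.
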