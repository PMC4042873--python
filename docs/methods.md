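# Methods

This note documents the models and procedures `uarna` implements, the
defaults it ships, and the choices made where the method description in
the field leaves details open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## PASS reads and poly(A) sites

A 3′-end read evidences cleavage/polyadenylation only through tail
adenosines the genome cannot explain. For a read with 3′ soft-clipped tail
`T` (read orientation), the reference continuation past the alignment end
is read strand-aware (reverse-complemented upstream of the alignment start
for minus-strand reads), and `k` = length of the longest prefix of `T`
matching it base for base (`N` never matches). The read is PASS iff

* the non-genomic suffix `T[k:]` contains ≥ `min_nongenomic_a` As
  (default **2**), and
* the A fraction of the whole tail is ≥ `min_a_fraction` (default
  **0.8**) — this purity screen removes adapter/mismatch soft clips that
  are not poly(A) tails; the ≥2-As rule alone would admit any long clip
  with two stray As.

The poly(A) site is the 3′-most aligned base advanced past the `k`
templated bases. Where the chromosome ends mid-tail, the remaining bases
count as non-genomic. This longest-templated-prefix rule is deterministic,
strand-symmetric, and reduces to the intuitive "non-genomic As" notion
without depending on aligner internals.

Sites are clustered per chromosome and strand by single linkage with a
**24 bp** window (configurable; recorded in output metadata). The
representative position is the member with the highest pooled read count,
ties broken 5′-most (strand-aware); per-sample counts are summed, so reads
are conserved exactly. No internal-priming filter (genomic A-rich
stretches) is applied; the option space is deliberately left to
configuration because the appropriate stringency is protocol-dependent.

## Gene regions and assignment

Transcripts sharing a gene identifier are merged to the gene's maximal
span; the analysis is gene-level throughout (no isoform or alternative-TSS
resolution). Each gene's 3′ end is extended by **4000 bp** iff no other
same-strand gene's native span intersects the would-be extension interval
— all-or-nothing, clipped at chromosome edges, and computed from native
spans so the operation is idempotent. The uaRNA window is the **2000 bp**
immediately upstream of the TSS on the antisense strand, half-open at the
TSS.

Assignment uses the poly(A) site as the coordinate (the site, not the read
body, is the biological observation; an `any_overlap` mode is available).
Sense strictly precedes uaRNA: a site inside exactly one sense region on
its strand is sense; inside several, ambiguous (excluded from all counts
and reported); only a site in a uaRNA window that is sense-assignable
nowhere becomes uaRNA, going to the window gene with the nearest TSS
(lexicographic tie-break). The 3′ extension counts as sense territory for
this exclusion rule by default (`sense_includes_extension`), since a read
in the extension is genic under the extension's own rationale; the flag
exposes the alternative.

RPM normalizes by **total PASS reads** of the library (not assigned
reads), so assignment choices do not leak into the normalizer.

## Differential statistics

Per gene, reads are pooled per condition into `[[ua_t, s_t], [ua_r, s_r]]`
and tested with the two-sided Fisher exact test, probability-mass method:
p = sum of hypergeometric probabilities (margins fixed) not exceeding the
observed table's probability, with a 1e-7 relative tolerance absorbing
floating-point ties. The implementation evaluates the whole support from a
log-factorial table; the test suite pins it against an independent
exhaustive enumeration in exact integer arithmetic over every table with
N ≤ 120 and random tables to N = 500 (|Δp| ≤ 1e-10). Genes with zero
uaRNA reads in both samples are NC with p = 1 (nothing to test). With a
zero cell the odds ratio is degenerate (0/∞), and the UP/DN direction
follows the sign of the cross-product `ua_t·s_r − ua_r·s_t` instead.

Calls use unadjusted p < **alpha = 0.05**; a Benjamini–Hochberg column is
emitted for reference but never used for calls, matching the pooled
two-sample design of the method. Replicate-aware count models (dispersion
estimation) are out of scope by the same token: reads are pooled per
condition.

The global summary is χ² = (n_UP − n_DN)²/(n_UP + n_DN), a 1-df
goodness-of-fit against a 50:50 split, upper tail, no continuity
correction (the asymmetry in question is directional and the counts are
large enough that Yates' correction would only bias the headline
statistic). The 1-df tail equals erfc(√(χ²/2)); the suite checks the
implementation against this closed form at 1e-12 relative.

Log2 expression changes use RPM plus a pseudocount of **0.5 reads**
converted to RPM per sample — enough to keep zero-RPM genes finite, and
irrelevant to the CDF curves because those are restricted to genes with
≥ **20** reads of the plotted category across both samples. The ≥20-read
filter applies only to CDF curves, not to the UP/DN counting.

## Profiles

Distance from TSS is (TSS − site) for + genes and (site − TSS) for −
genes, strictly positive upstream, binned half-open. Nucleotide profiles
are reported on the transcribed strand of the cleaved RNA (offset 0 = the
cleavage site), so poly(A)-signal motifs appear upstream of 0; sites near
chromosome edges contribute only their in-range offsets and N is excluded
with renormalization. The antisense TSS metagene is per-base uaRNA
poly(A)-site RPM over [−span, 0), span **2000 bp**, aggregated over genes
with uaRNA detected in either sample, smoothed by lowess —
tricube-weighted local *linear* regression, fraction **0.3**, **0**
robustness iterations (local linear is exact on linear profiles, which
the tests exploit as an oracle). All smoothing parameters are recorded in
output metadata.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes —
not sequencing chemistry. It draws an i.i.d. uniform-base genome;
non-overlapping genes with ≥ 7 kb intergenic gaps (so 4 kb extensions and
2 kb windows never collide by construction); per-gene expression
λ ~ lognormal(0, **0.75**); 1–3 sense poly(A) sites at the gene 3′ end and
1–2 antisense sites uniform in the 2 kb window for the **30%** of genes
with detectable uaRNA, at a baseline uaRNA:sense ratio of **0.08**;
Poisson (optionally negative-binomial) counts scaled to **2×10⁵** reads
per library — a desk-scale stand-in for the several-million-read libraries
such experiments produce; **15%** non-PASS reads (templated, single-A or
empty tails), **2%** background reads at random positions, and planted
UP/DN genes whose uaRNA expectation is multiplied/divided by **fold = 4**
in the test condition.

The detectable-uaRNA fraction, baseline ratio and expression spread were
fixed once from an a-priori power calculation: at 2×10⁵ reads over 1000
genes a gene at median expression receives ~160 sense and ~13 uaRNA PASS
reads per library, which gives Fisher's test high power for a fourfold
uaRNA shift while keeping the null conservative — the regime the method
operates in at full depth, shrunk to desk scale. They are biologically
plausible for promoter-proximal antisense transcripts (low abundance
relative to mRNA, detectable at a minority of promoters at this depth).

By default the generator rewrites the `tail_len_max` bases downstream of
every designated cleavage position (including background sites) to non-A
on the transcribed strand, so truth labels match the PASS rule *exactly*
and calling can be scored at sensitivity = specificity = 1;
`p_templated_context > 0` instead plants genomic As that exercise the
templated-prefix logic at the cost of exact truth. An optional AATAAA
motif is written at a configurable offset upstream of every sense/uaRNA
site (background sites excluded, as spurious cleavage lacks a canonical
signal). All randomness flows through one PCG64 generator, so a seed
fixes the dataset bit for bit; emitted reads are always consistent with
the emitted genome because sequence edits precede read synthesis.

What the generator does **not** model — sequencing error, alignment
ambiguity, PCR duplicates, internal priming, overlapping or nested genes,
isoform structure, chained gene extensions — bounds what green tests mean:
they certify the bookkeeping, the exact statistics and the recoverability
of planted effects under clean mappings, not robustness to mapping
artifacts on real genomes.

## Numerical and degenerate-input choices

* Coordinates 0-based half-open everywhere; BED native, GTF converted on
  load; strand ∈ {+, −} enforced.
* Fisher p for degenerate margins (empty row/column pair) is 1; p is
  clipped into (0, 1].
* Enrichment with n_DN = 0 reports an infinite ratio with χ² still
  defined; with nothing called, ratio is NaN and p = 1, flagged.
* Clustering ties break 5′-most on the site's own strand, making the
  whole pipeline exactly invariant under reverse-complementing the genome
  and flipping all strands (checked end to end in the suite).
* Empty CDF categories are omitted with a warning; a run with no uaRNA
  reads anywhere skips the metagene with a warning rather than failing.

## Problem sizes used by the checks

The acceptance script and the heavier tests run the full pipeline at the
generator's default desk scale (1000 genes, two libraries of 2×10⁵ reads)
and at smaller geometries (120–400 genes) for profile and symmetry
checks; these sizes were chosen as the package's own reference conditions
so that a complete verification run stays in the minutes range on one
core.
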