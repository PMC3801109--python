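# Methods

This note documents the models and procedures implemented in `somaclone`,
the assumptions behind them, the tunable parameters, and what the bundled
synthetic data can and cannot demonstrate.

## The scientific setting

A somatic-cell-nuclear-transfer (SCNT) clone shares its nuclear genome with
the somatic donor; its mitochondria descend from the enucleated oocyte.
Whole-genome sequencing of such a pair therefore expects (i) a small number
of post-cloning *de novo* nuclear variants, (ii) a wholesale mitochondrial
haplotype difference, (iii) essentially no copy-number or structural
differences, and (iv) comparable telomere content. The package implements
the paired analysis that quantifies each of these from short-read data, and
a generator that plants all four phenomena with known truth.

## Synthetic-data generator

**Genome model.** A uniform-random reference with `n_autosomes` diploid
autosomes, one haploid chrX (both individuals male; haploid dosage stands in
for full X/Y modelling) and one haploid chrM. Haplotypes are stored as
sparse edits (SNVs and length-changing ops) against the reference; each
materializes together with a block table mapping haplotype to reference
coordinates, which is how reads acquire truth alignments — including
small-indel CIGARs — without an external aligner. Reads whose alignment
would cross a structural junction are emitted unmapped, as an aligner would
clip or reject them; this creates a small, realistic coverage dip at
junctions.

**Planted events.** Germline heterozygous SNVs at `germline_het_rate`
(default 10⁻³/bp). Clone-only somatic SNVs at `somatic_snv_rate` (default
3.77/Mb of nuclear reference) and indels (1–10 bp, default 3.04/Mb),
heterozygous on one haplotype; positions are re-drawn on collision with
germline sites and logged. Substitutions are transition-biased with
ts:tv = 2:1 (`transition_fraction = 2/3`), reproducing the A>G / C>T excess
that deep genome comparisons report. The clone chrM is replaced by a
haplotype at `mito_divergence` (default 0.005/bp ≈ 80 differences on a
16.5 kb genome — the scale of an unrelated oocyte donor within a breed).
CNVs are realized per their total copy number (0, 1, 3, 4) as deletions or
tandem duplications; SVs (DEL/INS/CTX) are realized on **both** haplotypes.
The homozygous choice is a power decision made before testing: a fragment
spans a junction informatively only over `insert − 2·read_length ≈ 65 bp`,
so a heterozygous event at 20× yields Poisson(≈3.3) supporting pairs —
below any sensible support threshold — while a homozygous event doubles it.
CTX is realized as a copy of a donor-chromosome segment inserted into the
middle of the next autosome; both insertion junctions produce
inter-chromosomal pairs, so one planted translocation may legitimately
yield two junction clusters.

**Telomeres.** Each nuclear chromosome end is overwritten with a perfect
(TTAGGG)ₙ / (CCCTAA)ₙ tract of per-sample length. Real telomeres are
neither perfect nor uniform across chromosome arms; the estimator is
therefore validated only for *relative* comparisons.

**Reads.** 2×100 bp pairs; fragment lengths Normal(265, 20) floored at
20 bp. The 265/20 insert model matches a TruSeq-era short-insert library as
seen by the alignment-level tools (nominal gel selection for such libraries
is ~280 bp; both numbers are configurable).
Fragments shorter than the read length cause adapter read-through into the
(placeholder, configurable) index/universal adapters. Per-base Phred
qualities decline linearly 38→30 (SD 3) along the read — enough structure
to exercise the quality criteria without modelling a specific instrument.
Sequencing errors are injected at a flat `base_error_rate` (10⁻³),
ambiguous bases at 2×10⁻⁴, and `duplicate_fraction` (2%) of fragments are
emitted twice with fresh errors (PCR duplicates). Each haplotype is sampled
at `coverage/2`, so diploid chromosomes reach full coverage and chrX/chrM
half. chrM is sampled linearly; the circular origin is under-covered by
about one insert length, a documented simplification (real mtDNA is
massively over-covered, which the depth cap would exclude anyway).

## Read QC

The four criteria (fail if any): N fraction **strictly greater** than 10%;
arithmetic mean Phred **strictly under** 15; bases under Phred 15 exceeding
10%; a read suffix of ≥10 bp equal to the head of the mate-appropriate
adapter (mate 1 vs the index adapter, mate 2 vs the reverse complement of
the universal adapter). "More than 10 bp" is read as match length ≥ 10,
the common practice; `adapter_match_strict` flips it to > 10. Filtering is
pair-level (either mate fails ⇒ drop the pair) because all downstream
stages are pair-based. Quality encoding is fixed to Phred+33; apparent
Phred+64 input is rejected, not auto-detected. Duplicate removal operates
on alignments, after QC, keeping the highest-summed-quality pair per
(reference, mate-1 start, mate-2 start, orientation) group, ties to the
first name.

## Genotyping

Per-site likelihoods use P(base|allele) = 1−ε for a match and ε/3
otherwise, ε = 10^(−Q/10); a heterozygote averages its two alleles. Priors:
θ = 0.001 on 0/1, θ/2 on 1/1, remainder on 0/0. A call requires depth in
[5, 200], a posterior-best genotype other than 0/0, and genotype quality
−10·log₁₀(1−posterior) ≥ 10 — the closest modern mapping of a "consensus
quality 10" threshold. The model is biallelic; tri-allelic columns use the
two most frequent alleles and log the event. The vectorized genome-scale
path and the scalar per-column path are the same mathematics and are
cross-checked against each other and against an independent enumeration
oracle in the tests. Indels are called by support fraction: ≥ 1/4 of
spanning depth (aligned depth plus deletion-carrying reads) calls the
allele, ≥ 3/4 calls it homozygous — an intentionally simple surrogate for a
realignment-based caller, with both fractions exposed in `CallerConfig`.

The callable ("sufficiently covered") region is the exact set of positions
with depth in [5, 200], computed per sample.

## Somatic subtraction and the Fisher filter

A clone call is a somatic candidate iff (i) the donor has no call with the
same alternate allele at that position, (ii) the donor site is callable
(uncallable sites are reported as *unresolvable*, not somatic), and
(iii) the donor pileup's allele fraction for that alternate is at most
`max_donor_alt_fraction = 0.05`. Guard (iii) exists because a germline
heterozygote whose donor allele sampling lands away from 1/2 (15 alt /
1 ref at depth 16 on one side, 1 alt / 11 ref on the other) produces *no
confident donor genotype* while the allele is plainly present; production
paired callers classify such sites germline via the normal sample's
allele fraction, and without the guard they leak through as "somatic" at
a rate of a few per thousand germline heterozygotes. The 5% threshold is
the conventional normal-sample cutoff of paired somatic callers.

Candidates then face a two-sided Fisher exact test on
[[clone_ref, clone_alt], [donor_ref, donor_alt]]; candidates with p > 0.05
are filtered out (keeping sites whose allele counts genuinely differ
between samples). The p-value is computed by exact integer hypergeometric
enumeration — all tables with the observed margins whose probability is at
most the observed table's, using the 1+10⁻⁷ relative tie rule shared by R
and SciPy so that independent implementations agree to float precision.
Degenerate tables (an empty margin) are dropped with a reason.

chrM is not diploid: its events are labelled homoplasmic when the allele
fraction is ≥ 0.9, else heteroplasmic. Compartments (autosomal / sex /
mitochondrial) come from chromosome names, with a configurable alias table.

Coding effects translate reference and alternate codons strand-aware under
the standard code; a change string like "K811E" is emitted for
nonsynonymous SNVs. Indels inside a CDS are flagged (`in_cds`) but not
frame-annotated. A reference CDS with an internal stop is warned about and
annotated NA.

## Mutation rate and spectrum

The rate divides somatic SNVs inside the callable region by the callable
base count, using the **intersection** of clone and donor masks (somatic
detection requires both) — reported to two decimals per Mb. The headline
rate is **nuclear**: clone/donor chrM differences reflect oocyte lineage
divergence, not post-cloning mutation, so counting them in a "somatic
mutation rate" would be wrong at any scale and catastrophically so at desk
scale (80 mitochondrial differences against a few-Mb denominator). Indels
are excluded from the rate (the headline per-Mb figure pairs with the SNV
count). The spectrum reports the 12 directed substitution types, their
6-type strand-symmetrized collapse (an exact partition, asserted in tests)
and the transition fraction.

## CNV segmentation

Reads are counted into 100 bp bins by leftmost aligned base, clone = case,
donor = control. Within a segment every read is a case read with
probability p; the segment log-likelihood is k_c·ln p̂ + k_n·ln(1−p̂) and
the criterion is −2·Σ logL + λ·(#segments)·ln N with λ = 2 and N the total
read count of the whole input (both samples, all chromosomes). Merging is
greedy from single bins — a window-local pass over `initial_window = 200`
bins, then a global pass — always taking the adjacent merge with the
largest BIC decrease; segments never span chromosome boundaries.

Pure pairwise merging has a known local minimum: a short noise segment
(z ≈ 5) can resist merging into *either* neighbour, because each single
merge buys back only one penalty term, while merging with *both*
neighbours — removing two segments — still lowers the BIC. A three-way
merge pass alternates with pairwise merging until stable; it optimizes the
same objective and removes these false segments without touching real
signal (a 50 kb half-depth deletion at 20× carries ΔlogL in the hundreds
versus a penalty of ~30). Breakpoints stay at bin resolution throughout.

States come from library-size-normalized log₂ ratios with strict
thresholds (< −0.2 deleted, > +0.2 duplicated); a pseudocount of 0.5 is
added to both sums only when either is zero, and flagged. Because case and
control are clone and donor, every non-neutral call *is* a clone/donor
difference; no further subtraction applies. The expected log₂ for a
single-copy deletion is −1 plus a small library-size term (≈ +0.03 when
the deletion is 5% of the genome), which is why recovery is asserted
within ±0.15.

## SV detection

An insert model (mean, SD) is fitted from properly oriented
intra-chromosomal pairs with the top and bottom 1% of spans trimmed; the
SD is corrected for the trim (a 1% two-sided trim of a Normal shrinks the
SD by the factor √(1 − 2zφ(z)/0.98), z = Φ⁻¹(0.99) ≈ 0.9346) and clamped
to ≥ 1. Pairs are classified: different chromosomes → CTX; same-strand
mates → ITX; apparent insert beyond mean ± 3·SD → DEL/INS; else
concordant. Same-type signals within an insert-sized window cluster; a
call needs support ≥ 4 pairs (the deep-WGS-faithful value 10 is a config
away), intra-chromosomal size ≥ 1000 bp, and score ≥ 80, where the score
is the Poisson tail surprise −10·log₁₀ P(Poisson(μ) ≥ support) under the
genome-wide background rate of that signal type. DEL size is the median
apparent insert minus the model mean; INS size is the insert deficit, which
also bounds what is detectable — a novel insertion longer than
insert − 2·read_length leaves no informative pairs, only a coverage dip.
Somatic SVs are clone calls with no donor call of the same type within
1000 bp on both breakpoints (anti-monotone in the window, by construction).

## Telomere estimation

For each k = 1..6 the estimator counts reads containing (TTAGGG)ₖ as an
exact tandem substring, both strands, each read once per k; containment
nests, so counts are non-increasing in k. Controls are base-composition
permutations of the motif (GGGATT — the classical control — and GTAGTG;
neither is a rotation of the telomeric repeat, nor is either's reverse
complement, so they cannot fire inside real tracts). The normalized value
divides the telomeric fraction at the reported k (default 4: high enough
that chance hits vanish, low enough that a 100 bp read holds the 24 bp
tandem with margin) by the mean control fraction at `k_control = 1`. The
control denominator deliberately uses a *low* multiplicity: a 24 bp
control tandem has expectation ~4⁻²⁴ per position, i.e. exactly zero
observed counts at any feasible scale, which would leave a same-k
normalization undefined; at k = 1 the permuted motifs give a stable
per-sample background that tracks sequencing quality, which is the point
of the control. Mismatches within the tandem are not tolerated (a
non-goal). Only between-sample ratios are meaningful.

## Orchestration and reporting

`run_pipeline` runs simulate → QC → duplicate removal → pileup/genotype →
somatic subtraction → rates → CNV → SV → telomere → summary, deterministic
under the seed (summary JSON is byte-identical across re-runs). The
summary's totals are computed only from event streams, so compartment
breakdowns sum to totals by construction; percentages are rounded half-up
to one decimal. The "twin column" workflow is just a second simulated pair
through the same code path. Genes for coding-effect annotation come either
from a GFF3 or from deterministic synthetic single-CDS models tiling the
nuclear chromosomes.

## Problem sizes and what the tests show

Unit and acceptance tests run on 0.5–10 Mb genomes at 20–40×: identity
nulls on ~1.2 Mb × 10 replicates, rate recovery on 10 Mb, CNV recovery on
1.1 Mb × 20 replicates, SV recovery on 1.5 Mb at 40×, telomere tracts of
0/2/5/10 kb. These sizes were chosen as the smallest at which the planted
effects are statistically unambiguous (Poisson bands, scan statistics and
junction-span power as above). Passing them shows the machinery is correct
and calibrated on idealized data — uniform coverage, perfect truth
alignments, flat error rate, no mapping ambiguity or GC bias. It does not
show robustness to repeat-mediated mismapping, coverage waviness, indel
realignment artefacts, or contamination, which dominate error budgets on
real genomes.

## Known limitations

- Alignment is by construction (truth); the BWA/GATK realignment and
  recalibration steps of a real pipeline have no effect surface here and
  are out of scope.
- The genotyper is biallelic and diploid (chrM handled by allele
  fraction); no multi-sample joint calling.
- The CNV segmenter implements the stated binomial/BIC idea, not the
  published tool's exact multi-scale scheme; its "multiplicity" and
  "paired" options have no analogue here.
- The SV score formula is this package's Poisson surprise, calibrated to
  the same ≥ 80 threshold scale, not the published tool's formula.
- Telomere estimates are relative; interstitial telomeric repeats and
  degenerate repeats are not modelled.
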