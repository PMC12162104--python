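# Methods

## Selfing accumulation model

The model tracks expected counts of spontaneous mutations in a single-seed
descent pedigree. Per generation, `N_het = diploid_bp × mu` new heterozygous
mutations arise (`diploid_bp` is twice the haploid callable or assembly
size; `mu` is per site per generation). Transmission probabilities at each
selfing step are ½ heterozygous / ¼ homozygous / ¼ lost — except a
mutation's **first** transmission, which is ½ heterozygous / ½ lost with no
direct fixation. This asymmetry is implied by the recursion itself (new
mutations enter `I_het` with factor ½ and only `I_het` feeds `I_hom`), and
only this reading reproduces the closed forms

    I_het(x) = N_het (1 − 2^−x)
    I_hom(x) = ¼ N_het [(x−1) − (1 − 2^−(x−1))]

which the tests verify to 1e-12 relative error. The Monte-Carlo
gene-dropping simulator (`expectation.gene_dropping`) implements the same
per-mutation transmission chain and agrees with the recursion within
sampling error at 20,000 replicates; it is the independent check used
before any expectation is reported.

Assumptions: no selection, no attrition of treated lines, no site
depletion (`N_het` constant), rates uniform across the genome. Generation 0
is the treated founder and contributes no inherited mutations; "seven
generations of self-fertilization" maps to T = 7.

Default rates come from mutation-accumulation estimates in *Arabidopsis
thaliana*: 6.53e-9 substitutions/site/generation, 0.45e-9 (1–3 bp indels)
plus 0.5e-9 (>3 bp indels), summed to 0.95e-9 for the combined indel
expectation. Fold enrichments are reported truncated toward zero for
display (e.g. 488.7/3.50 = 139.6 → 139); the full-precision ratio is always
available from `fold_enrichment`.

## Isolation pipeline

Order of operations: callable masking → hard filters → diversity-window
filter (parent only) → parent difference regions → subtraction → panel
exclusion → privacy filter. Choices where the procedure is underdetermined:

- **Coordinates.** VCF 1-based; BED and all interval logic 0-based
  half-open. An indel/SV occupies its full reference span
  `[pos−1, pos−1+len(ref))`; a variant is callable only if that whole span
  is callable.
- **Diversity windows** are tumbling 100-bp windows anchored at position 1;
  ">2% diversity per 100 bp" is read as more than 2 SNVs per window, and a
  violating window loses all its SNVs. Tumbling (rather than sliding)
  windows are deterministic and O(n); window size and threshold are
  arguments.
- **Privacy** is keyed on the full `(chrom, pos, ref, alt)` allele, not
  position: two lines hit at the same site by different changes are
  independent events and both are kept.
- **Per-sample failures** (DP out of [5, 158], GQ < 9, het allele-balance
  deviation > 0.1) invalidate the genotype, not the site; site-level rules
  (QUAL ≥ 30, missingness ≤ 30%, heterozygote proportion ≤ 10%) are then
  re-evaluated on the updated genotypes. A linked-read threshold profile
  (DP ∈ [5, 78], balance deviation 0.2) is provided.
- Every filter is a pure subset operation and idempotent; `FilterReport`
  conserves counts at each step (input − removed = surviving), which the
  suite asserts.

## Spectrum and context statistics

Substitutions are collapsed with their reverse complements into six classes
keyed on an A or C reference base. Ts/Tv counts A↔G and C↔T (collapsed
classes A→G\*, C→T\*) as transitions; a set with zero transversions is
reported undefined rather than infinite.

Context analysis uses forward-strand focal changes only (e.g. literal C→T
records; G→A neighborhoods are not reverse-complement-pooled by default, so
the focal set is a subset of C→T\*). Controls are sampled 1:1 per mutation:
a uniform draw among positions within ±100 bp carrying the same reference
base, excluding the focal position itself; mutations with no eligible
position are dropped from the analysis and counted. Per flanking position
the relative entropy is the Kullback–Leibler divergence
Σ_b p_m(b) log2(p_m(b)/p_c(b)) with zero-`p_m` terms contributing 0 (an
optional pseudocount is available for small samples); signed per-base terms
(sign of p_m − p_c) support logo rendering with inverted underrepresented
letters. The per-position deviance is the independence G-test on the 2×4
set-by-base table with df = 3 — equivalent to the position-effect deviance
of a single-position log-linear model; its null distribution is verified
χ²(3) by simulation and its type-I error at α = 0.05 is calibrated within
[0.035, 0.065] over 1,000 null replicates.

k-mer composition counts overlapping windows on the forward strand,
excluding any window containing a non-ACGT character from both numerator
and denominator.

## Coding effects

Consequence precedence (splice > start/stop > missense/synonymous > intron
> flank > intergenic) follows standard annotation practice; the
upstream/downstream flank defaults to 5 kb. Minus-strand genes are
evaluated on the reverse complement; CDS indels are frameshift when
`length % 3 ≠ 0`, else in-frame. "Nonsynonymous" = missense + start-lost +
stop-gained + stop-lost.

The phylogenetic-constraint test is consumed, never computed: callers
supply per-variant p-values, aligned-sequence counts and an
allele-unseen-elsewhere flag. Deleterious requires p strictly below
α/n_tests (α = 0.05, n_tests = tested codons) **and** ≥ 10 aligned
sequences **and** the allele unseen in other species; everything else is
tolerated. Displayed thresholds truncate (not round) the exact value at two
significant digits, the unique rule reproducing all three published group
thresholds (0.05/611 = 8.18e-5 → 8.1e-5); the exact value is used for
labelling.

Load windows divide deleterious/tolerated nonsynonymous counts by covered
codons (CDS bp in the tumbling window / 3, optionally intersected with the
callable mask). Load–phenotype association offers Spearman (default) and
Pearson with two-sided p-values via scipy.

## Synthetic-data generator

What it emulates, with defaults:

- genome: 2 Mb over 2 chromosomes at GC = 0.44 (a barley-like composition,
  scaled from 4.2 Gb so the full pipeline runs in seconds); 15% uncallable
  (repeat / N-stretch / high-copy, N-stretches written as N) plus a small
  separate low-complexity mask.
- 11 mutagenized lines; induced SNVs per line Poisson(200) with collapsed
  spectrum (0.791 C→T\*, remainder uniform — the observed induced C→T\*
  fraction); induced indels Poisson(45) with 1-bp fractions 0.283
  (insertions) / 0.364 (deletions) and 41.7% insertions, the observed
  induced indel mix. The induced SNV:indel ratio mirrors the observed
  2,122:489 per line.
- CC-context enrichment: for C→T (and mirrored G→A) draws the {C followed
  by C} site pool is chosen with odds multiplied by
  `cc_context_enrichment` (default 8). The observed in-context fraction is
  not published, so the default is a free parameter chosen to produce an
  unambiguous +1-position logo signal; at enrichment 1 the in-context
  fraction provably equals the genome's conditional dinucleotide frequency,
  which a k-mer-oracle test asserts.
- induced variants are emitted homozygous by default: M5 single-seed
  descent fixes most mutations, and surviving het calls in a single-sample
  VCF would not pass the site heterozygosity filter — so homozygous truth
  is the condition under which pipeline sensitivity is meaningfully
  measured (`induced_het_fraction` is configurable).
- spontaneous mutations per line: Poisson with means from the accumulation
  model applied to the toy genome (so they are ~0 at 2 Mb, exactly as the
  model predicts).
- parent heterogeneity: 500 homozygous differences from reference,
  inherited by every line; 85% SNVs, 15% 1-bp indels.
- landraces: 13 samples, 5,000 segregating sites with allele counts from
  the neutral 1/i SFS; the class spectrum fixes E[Ts/Tv] = 1.74 exactly
  (transition mass 1.74/2.74, two thirds of it C→T\*), while
  `cpg_enrichment` (default 10) governs only CpG placement of C→T\* draws —
  class frequencies, not placement context, determine Ts/Tv, so the ratio
  is parameterized directly.
- genotyping panel: 100 positions drawn from the landrace sites, mimicking
  array markers ascertained from standing variation.

What it does **not** emulate: linkage and recombination, demography,
coverage-dependent genotyping error, mapping artifacts, multi-allelic
sites, and real structural-variant calling. Passing the recovery tests
therefore shows the filter logic is correct under the stated statistical
structure, not that a real caller's error modes are handled.

All randomness flows from one `numpy` Generator seeded by the config;
identical configs give byte-identical FASTA/BED/VCF/GFF3/TSV outputs
(asserted in the suite).

## Problem sizes used by the test suite

Deterministic model checks run at full published genome sizes (they are
closed-form). Stochastic recoveries use a 2 Mb genome with ≥ 10,000 induced
SNVs and ≥ 5,000 induced indels (11 lines at Poisson means 1000/500) and
50,000 landrace sites — sizes at which three binomial standard errors are
tight enough to detect parameter errors of a few percent — and the
gene-dropping oracle runs 20,000 replicates. The whole suite completes in
well under a minute on one core.

## Known limitations

- The published per-line indel table sums to 2,509 while the pooled text
  total is 5,376 (platform/caller pooling differs); `reference_data`
  carries both, and the fold-enrichment default uses the pooled total over
  11 lines.
- The induced indel rate per site per generation implied by the observed
  counts depends on an unstated site-count convention and is therefore
  exposed only through the free-form `fold_enrichment` calculator, not
  asserted.
- Context RE with a zero control frequency and non-zero mutation frequency
  is reported infinite unless a pseudocount is supplied.
- `classify_effect` assumes single-transcript, non-overlapping gene models
  (the generator's output); overlapping isoforms would need a precedence
  rule across transcripts.
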