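# barleymut

Tools for characterizing chemically induced mutations in resequenced,
self-fertilizing crop lines — built around the sodium-azide mutagenesis
setting in barley (*Hordeum vulgare*), where a mutagenized founder is carried
through single-seed descent and each M5 line is compared against its
untreated parent and the reference assembly.

The package is aimed at researchers running mutation-breeding or
mutation-accumulation experiments who need to (1) decide how many of the
variants they see could have arisen spontaneously, (2) isolate the variants
the mutagen actually induced from a background of variety heterogeneity and
standing variation, and (3) describe what those mutations look like and what
they do to genes.

## What it computes

**Spontaneous expectation under selfing.** Each generation supplies
N_het = diploid_bp × μ new heterozygous mutations; under selfing a
heterozygous mutation is transmitted heterozygous (½), fixed homozygous (¼)
or lost (¼), with a new mutation's first transmission surviving only
heterozygous (½). The expected inherited counts follow

    I_het(x) = ½·N_het + ½·I_het(x−1),   I_het(0) = 0
    I_hom(x) = I_hom(x−1) + ¼·I_het(x−1), I_hom(x<2) = 0

and the expected load of a generation-T individual is
I_het(T) + I_hom(T) = N_het·[(1−2⁻ᵀ) + ¼((T−1) − (1−2⁻⁽ᵀ⁻¹⁾))].
A Monte-Carlo gene-dropping simulator provides an independent check.

**De novo isolation.** A two-part filter chain: callable-region masking
(repeats, N stretches, high-copy regions, optionally low-complexity
sequence), genotype/site hard filters (QUAL, GQ, DP bounds, heterozygote
allele balance, missingness and heterozygosity proportions), a 100-bp
diversity-window filter on the parent, subtraction of parent-vs-reference
difference regions, genotyping-panel exclusion, SV supporting-read filters,
and a privacy filter keeping alleles seen in exactly one line. Landrace
cohorts are stratified into rare (allele count ≤ 2) and common (≥ 3) sites.

**Spectrum and context.** Reverse-complement-collapsed substitution classes
(C→T\* = C→T plus G→A), Ts/Tv, signed indel-length histograms, genome k-mer
composition, and flanking-base analysis of a focal change against
matched-base controls sampled within ±100 bp: per-position relative entropy
(sequence-logo letter heights) and a per-position G-test (deviance, df = 3).

**Coding effects.** Consequence classification against gene models
(splice > start/stop > missense/synonymous > intron > flank > intergenic),
CC/GG motif flags, Bonferroni thresholds over tested codons for an external
phylogenetic-constraint test's p-values, deleterious/tolerated labelling,
amino-acid-change tables, per-10-Mb deleterious-load windows, and
load-vs-phenotype correlations.

**Synthetic data.** `barleymut.simulate` generates complete toy studies —
reference FASTA, masks, gene models, parent/line/landrace VCFs and a
ground-truth table — with configurable spectrum, CC-context enrichment,
indel-length mix, SFS-structured landrace cohorts and spontaneous mutations
drawn from the expectation model, so the whole pipeline is testable against
known truth.

## Worked example

```python
from barleymut.expectation import SelfingModelParams, accumulate, expected_indels, display_fold
from barleymut import reference_data as rd

params = SelfingModelParams(diploid_bp=8_451_211_438, mu=6.53e-9, generations=7)
res = accumulate(params)
print(round(res.total))                     # 124  expected spontaneous SNVs per M5:7 individual
print(round(expected_indels(1_641_188_610, 7), 1))   # 3.5  expected indels, callable region
print(round(expected_indels(8_451_211_438, 7)))      # 18   expected indels, whole genome

mean_snv = rd.mean_snv_per_line()           # 2121.7 observed SNVs per line
exp_callable = accumulate(SelfingModelParams(1_641_188_610, 6.53e-9, 7)).total
print(round(mean_snv / exp_callable))       # 88   fold increase over spontaneous, callable basis
print(display_fold(mean_snv, res.total))    # 17   fold increase, whole-genome basis
```

A ~124-SNV spontaneous expectation against ~2,122 observed SNVs per line is
what makes the observed variants attributable to the mutagen rather than to
ordinary mutation accumulation.

The shell interface mirrors the library:

```sh
barleymut simulate --outdir sim --seed 3
barleymut isolate --parent sim/parent.vcf --lines sim/line_M01.vcf ... \
    --mask sim/mask_repeat.bed --mask sim/mask_N_stretch.bed --mask sim/mask_high_copy.bed \
    --panel sim/panel.tsv --reference sim/reference.fa --outdir iso
barleymut context --vcf sim/line_M01.vcf --reference sim/reference.fa --change C:T --seed 1
```

On a simulated dataset the `context` table shows the planted signal: the +1
flanking position carries the largest relative entropy (C overrepresented,
G-test p ≈ 3e-5) — the CC-dinucleotide preference of sodium azide.

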