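"""Expected spontaneous mutation accumulation under repeated self-fertilization.

A mutation-accumulation experiment in a selfing crop proceeds by single-seed
descent: each generation, every heterozygous mutation carried by the selfed
parent is transmitted to the single descendant as heterozygous, becomes fixed
homozygous, or is lost.  The expected per-individual mutation count after T
generations therefore decomposes into an inherited-heterozygous and an
inherited-homozygous component, each driven by the per-generation supply of
new heterozygous mutations

    N_het = diploid_bp * mu

where ``diploid_bp`` is twice the haploid genome (or callable-region) size and
``mu`` the per-site per-generation mutation rate.  The recursion used here is

    I_het(0) = 0
    I_het(1) = 0.5 * N_het
    I_het(x) = 0.5 * N_het + 0.5 * I_het(x-1)      for x >= 2

    I_hom(x) = 0                                    for x < 2
    I_hom(x) = I_hom(x-1) + 0.25 * I_het(x-1)       for x >= 2

with total(T) = I_het(T) + I_hom(T).  Note the asymmetry: a brand-new
heterozygous mutation survives its first selfing transmission with
probability 0.5 (or is lost), while a mutation already inherited as
heterozygous additionally fixes homozygous with probability 0.25 at each
subsequent transmission.  Closed forms (constant N_het):

    I_het(x) = N_het * (1 - 2**-x)
    I_hom(x) = 0.25 * N_het * ((x - 1) - (1 - 2**-(x-1)))      for x >= 1

A Monte-Carlo gene-dropping simulator implementing the same per-mutation
transmission probabilities is provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SelfingModelParams",
    "AccumulationResult",
    "new_het_per_generation",
    "accumulate",
    "expected_indels",
    "fold_enrichment",
    "display_fold",
    "gene_dropping",
    "DEFAULT_SNV_RATE",
    "DEFAULT_INDEL_RATES",
]

#: per-site per-generation substitution rate (A. thaliana MA-line estimate)
DEFAULT_SNV_RATE = 6.53e-9
#: (1-3 bp indel rate, >3 bp indel rate), same units
DEFAULT_INDEL_RATES = (0.45e-9, 0.5e-9)


@dataclass(frozen=True)
class SelfingModelParams:
    """Parameters of the selfing accumulation model.

    Parameters
    ----------
    diploid_bp:
        Diploid site count (2 x haploid callable or assembly size), bp.
    mu:
        Mutation rate per site per generation.
    generations:
        Number of selfing generations T (>= 0); generation 0 is the founder
        and contributes no inherited mutations.
    """

    diploid_bp: float
    mu: float
    generations: int

    def __post_init__(self) -> None:
        if self.diploid_bp <= 0:
            raise ValueError(f"diploid_bp must be > 0, got {self.diploid_bp}")
        if not 0 <= self.mu < 1:
            raise ValueError(f"mu must be in [0, 1), got {self.mu}")
        if self.generations < 0 or int(self.generations) != self.generations:
            raise ValueError(f"generations must be a non-negative integer, got {self.generations}")


@dataclass(frozen=True)
class AccumulationResult:
    """Per-generation expected mutation counts from :func:`accumulate`."""

    n_het_per_gen: float
    i_het_by_gen: tuple[float, ...]
    i_hom_by_gen: tuple[float, ...]

    @property
    def total_het(self) -> float:
        return self.i_het_by_gen[-1]

    @property
    def total_hom(self) -> float:
        return self.i_hom_by_gen[-1]

    @property
    def total(self) -> float:
        return self.total_het + self.total_hom


def new_het_per_generation(params: SelfingModelParams) -> float:
    """Expected new heterozygous mutations per generation, N_het = diploid_bp * mu."""
    return params.diploid_bp * params.mu


def accumulate(params: SelfingModelParams) -> AccumulationResult:
    """Run the accumulation recursion for generations 0..T.

    Returns expected inherited-heterozygous and inherited-homozygous counts
    for every generation; ``result.total`` is the expected spontaneous
    mutation load of a generation-T individual.
    """
    n_het = new_het_per_generation(params)
    t = int(params.generations)
    i_het = [0.0]
    i_hom = [0.0]
    for x in range(1, t + 1):
        if x == 1:
            i_het.append(0.5 * n_het)
        else:
            i_het.append(0.5 * n_het + 0.5 * i_het[x - 1])
        if x < 2:
            i_hom.append(0.0)
        else:
            i_hom.append(i_hom[x - 1] + 0.25 * i_het[x - 1])
    return AccumulationResult(n_het, tuple(i_het), tuple(i_hom))


def expected_indels(
    diploid_bp: float,
    generations: int = 7,
    rates: tuple[float, ...] = DEFAULT_INDEL_RATES,
) -> float:
    """Expected spontaneous indel count after ``generations`` of selfing.

    The supplied per-class rates (by default the 1-3 bp and >3 bp classes)
    are summed into a single per-site rate before running the recursion.
    """
    for r in rates:
        if r < 0:
            raise ValueError(f"indel rates must be non-negative, got {rates}")
    mu = float(sum(rates))
    return accumulate(SelfingModelParams(diploid_bp, mu, generations)).total


def fold_enrichment(observed_mean: float, expected: float) -> float:
    """Observed-over-expected ratio; full precision (see :func:`display_fold`)."""
    if expected <= 0:
        raise ValueError(f"expected count must be > 0, got {expected}")
    return observed_mean / expected


def display_fold(observed_mean: float, expected: float) -> int:
    """Fold enrichment truncated toward zero to an integer for reporting."""
    return math.trunc(fold_enrichment(observed_mean, expected))


def gene_dropping(
    params: SelfingModelParams,
    n_replicates: int,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Monte-Carlo gene-dropping estimate of the accumulated mutation count.

    Each replicate simulates one pedigree: every generation draws
    Poisson(N_het) new heterozygous mutations, and each mutation is then
    transmitted through the remaining selfing steps — first transmission
    heterozygous w.p. 0.5 / lost w.p. 0.5, subsequent transmissions
    heterozygous 0.5 / homozygous 0.25 / lost 0.25, homozygous permanent.
    Returns (mean surviving count at generation T, standard error of mean).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_het = new_het_per_generation(params)
    t = int(params.generations)
    totals = np.zeros(n_replicates, dtype=np.int64)
    for g in range(t):  # mutations arise in the generation-g individual
        het = rng.poisson(n_het, size=n_replicates)
        # first transmission: het -> het w.p. 0.5, else lost
        het = rng.binomial(het, 0.5)
        hom = np.zeros(n_replicates, dtype=np.int64)
        for _ in range(t - g - 1):
            new_hom = rng.binomial(het, 0.25)
            het = rng.binomial(het - new_hom, 0.5 / 0.75)
            hom += new_hom
        totals += het + hom
    mean = float(totals.mean())
    se = float(totals.std(ddof=1) / math.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    return mean, se
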