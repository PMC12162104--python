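"""Mutation-spectrum and sequence-context statistics.

Single-base substitutions are collapsed with their reverse complements into
six classes whose reference base is A or C (so G→A is reported as C→T*).
Sequence-context analysis compares the bases flanking mutations of one focal
change (e.g. C→T) against matched controls — positions with the same
reference base sampled near each mutation — using per-position relative
entropy (Kullback–Leibler divergence, the letter heights of a sequence logo)
and a per-position G-test of independence (deviance) with 3 degrees of
freedom.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import Variant

BASES = "ACGT"
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: the six reverse-complement-collapsed substitution classes
COLLAPSED_CLASSES = ("A>C", "A>G", "A>T", "C>A", "C>G", "C>T")
#: transitions on the collapsed scale
TRANSITION_CLASSES = frozenset({"A>G", "C>T"})


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def collapse_change(ref: str, alt: str) -> str | None:
    """Map a single-base change to its collapsed class, or None if non-ACGT."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES or ref == alt:
        return None
    if ref in "GT":
        ref, alt = ref.translate(COMPLEMENT), alt.translate(COMPLEMENT)
    return f"{ref}>{alt}"


@dataclass
class MutationSpectrum:
    """Counts over the six collapsed substitution classes."""

    counts: dict[str, int]
    skipped: int = 0  # records with non-ACGT alleles

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {c: (n / t if t else float("nan")) for c, n in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": list(COLLAPSED_CLASSES),
             "count": [self.counts[c] for c in COLLAPSED_CLASSES],
             "fraction": [self.fractions[c] for c in COLLAPSED_CLASSES]}
        )


def collapse_spectrum(snvs: list[Variant]) -> MutationSpectrum:
    counts = {c: 0 for c in COLLAPSED_CLASSES}
    skipped = 0
    for v in snvs:
        if not v.is_snv:
            skipped += 1
            continue
        cls = collapse_change(v.ref, v.alt)
        if cls is None:
            skipped += 1
        else:
            counts[cls] += 1
    return MutationSpectrum(counts, skipped)


def ts_tv(snvs: list[Variant]) -> float | None:
    """Transition/transversion ratio; None (undefined) with zero transversions."""
    spectrum = collapse_spectrum(snvs)
    ts = sum(spectrum.counts[c] for c in TRANSITION_CLASSES)
    tv = spectrum.total - ts
    return None if tv == 0 else ts / tv


@dataclass
class IndelLengthHistogram:
    counts: dict[int, int]  # signed length -> count; +/-(max_len+1) are overflow bins
    max_len: int

    @property
    def ins_1bp_fraction(self) -> float | None:
        ins = sum(n for l, n in self.counts.items() if l > 0)
        return None if ins == 0 else self.counts.get(1, 0) / ins

    @property
    def del_1bp_fraction(self) -> float | None:
        dels = sum(n for l, n in self.counts.items() if l < 0)
        return None if dels == 0 else self.counts.get(-1, 0) / dels

    def to_frame(self) -> pd.DataFrame:
        lengths = sorted(self.counts)
        return pd.DataFrame({"length": lengths, "count": [self.counts[l] for l in lengths]})


def indel_length_histogram(indels: list[Variant], max_len: int = 20) -> IndelLengthHistogram:
    """Signed-length histogram (insertions positive, deletions negative)."""
    counts: dict[int, int] = {}
    for v in indels:
        length = v.length
        if length == 0:
            raise ValueError(f"record at {v.chrom}:{v.pos} has zero length change")
        binned = max(min(length, max_len + 1), -(max_len + 1))
        counts[binned] = counts.get(binned, 0) + 1
    return IndelLengthHistogram(counts, max_len)


def sample_controls(
    snvs: list[Variant],
    genome: dict[str, str],
    window: int = 100,
    seed: int | np.random.Generator = 0,
) -> tuple[list[tuple[str, int] | None], int]:
    """Matched-base control positions, one per mutation.

    For each SNV, uniformly samples a position within +/- ``window`` bp whose
    reference base equals the mutation's reference base, excluding the focal
    position itself.  Returns a list parallel to ``snvs`` — ``None`` where no
    eligible position exists — and the count of such exclusions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    controls: list[tuple[str, int] | None] = []
    excluded = 0
    for v in snvs:
        seq = genome[v.chrom]
        focal0 = v.pos - 1
        lo = max(0, focal0 - window)
        hi = min(len(seq), focal0 + window + 1)
        base = v.ref.upper()
        eligible = [i for i in range(lo, hi) if i != focal0 and seq[i].upper() == base]
        if not eligible:
            excluded += 1
            controls.append(None)
            continue
        controls.append((v.chrom, int(eligible[rng.integers(len(eligible))]) + 1))
    return controls, excluded


def drop_unmatched(
    snvs: list[Variant], controls: list[tuple[str, int] | None]
) -> tuple[list[Variant], list[tuple[str, int]]]:
    """Drop mutation/control pairs where no control could be sampled."""
    pairs = [(v, c) for v, c in zip(snvs, controls) if c is not None]
    if not pairs:
        return [], []
    kept, ctl = zip(*pairs)
    return list(kept), list(ctl)


@dataclass
class ContextProfile:
    """Flanking-base composition of a focal change vs matched controls."""

    change: str  # e.g. "C>T"
    flank: int
    positions: list[int]  # e.g. [-2, -1, 1, 2]
    mut_counts: pd.DataFrame  # index positions, columns ACGT
    ctl_counts: pd.DataFrame
    re_terms: pd.DataFrame  # signed per-base RE contributions, bits
    re_by_position: pd.Series  # KL divergence per position, bits

    @property
    def n_mut(self) -> int:
        return int(self.mut_counts.iloc[0].sum())

    @property
    def n_ctl(self) -> int:
        return int(self.ctl_counts.iloc[0].sum())


def _flank_counts(
    sites: list[tuple[str, int]], genome: dict[str, str], positions: list[int]
) -> pd.DataFrame:
    counts = pd.DataFrame(0, index=positions, columns=list(BASES))
    for chrom, pos in sites:
        seq = genome[chrom]
        for off in positions:
            i = pos - 1 + off
            if 0 <= i < len(seq):
                b = seq[i].upper()
                if b in BASES:
                    counts.loc[off, b] += 1
    return counts


def context_profile(
    snvs: list[Variant],
    genome: dict[str, str],
    controls: list[tuple[str, int]],
    flank: int = 2,
    pseudocount: float = 0.0,
) -> ContextProfile:
    """Per-position relative entropy of mutation flanks vs control flanks.

    All SNVs must share the same forward-strand focal change.  RE terms use
    p_m(b) * log2(p_m(b) / p_c(b)), zero where p_m(b)=0; each term carries
    the sign of (p_m - p_c) so logo rendering can invert underrepresented
    bases, while ``re_by_position`` sums the unsigned (KL) terms.
    """
    changes = {(v.ref.upper(), v.alt.upper()) for v in snvs}
    if len(changes) != 1:
        raise ValueError(f"expected one focal change, got {sorted(changes)}")
    if len(controls) != len(snvs) or any(c is None for c in controls):
        raise ValueError(
            f"{len(snvs)} mutations but {len(controls)} controls; "
            "pair with drop_unmatched() after sample_controls()"
        )
    ref, alt = changes.pop()
    positions = [p for p in range(-flank, flank + 1) if p != 0]
    mut_counts = _flank_counts([(v.chrom, v.pos) for v in snvs], genome, positions)
    ctl_counts = _flank_counts(controls, genome, positions)

    m = mut_counts.to_numpy(dtype=float) + pseudocount
    c = ctl_counts.to_numpy(dtype=float) + pseudocount
    p_m = m / m.sum(axis=1, keepdims=True)
    p_c = c / c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.divide(p_m, p_c, out=np.ones_like(p_m), where=p_c > 0)
        kl = np.where(p_m > 0, p_m * np.log2(ratio), 0.0)
        kl = np.where((p_m > 0) & (p_c == 0), np.inf, kl)
    signed = kl * np.sign(p_m - p_c)
    re_terms = pd.DataFrame(signed, index=positions, columns=list(BASES))
    re_by_position = pd.Series(kl.sum(axis=1), index=positions, name="RE")
    return ContextProfile(
        f"{ref}>{alt}", flank, positions, mut_counts, ctl_counts, re_terms, re_by_position
    )


def position_deviance(profile: ContextProfile) -> pd.DataFrame:
    """Per-flanking-position G-test of mutation-vs-control base composition.

    For each position the 2x4 (set x base) table is tested for independence:
    G = 2 * sum O * ln(O/E), df = 3, p from the chi-squared upper tail.
    Cells with O = 0 contribute nothing.
    """
    rows = []
    for pos in profile.positions:
        obs = np.array(
            [profile.mut_counts.loc[pos].to_numpy(), profile.ctl_counts.loc[pos].to_numpy()],
            dtype=float,
        )
        if obs.sum(axis=1).min() == 0:
            rows.append({"position": pos, "G": np.nan, "df": 3, "p": np.nan})
            continue
        expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(obs > 0, obs * np.log(obs / expected), 0.0)
        g = 2.0 * terms.sum()
        rows.append({"position": pos, "G": g, "df": 3, "p": float(stats.chi2.sf(g, 3))})
    return pd.DataFrame(rows)


@dataclass
class KmerComposition:
    k: int
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {kmer: n / t for kmer, n in self.counts.items()} if t else {}

    def to_frame(self) -> pd.DataFrame:
        kmers = sorted(self.counts)
        return pd.DataFrame(
            {"kmer": kmers,
             "count": [self.counts[k] for k in kmers],
             "fraction": [self.fractions[k] for k in kmers]}
        )


def count_kmers(sequences: dict[str, str] | str, k: int) -> KmerComposition:
    """Overlapping forward-strand k-mer counts; windows containing non-ACGT
    characters are excluded from both numerator and denominator."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    counts: Counter[str] = Counter()
    for seq in sequences.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if all(b in BASES for b in window):
                counts[window] += 1
    return KmerComposition(k, dict(counts))
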