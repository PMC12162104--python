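"""Synthetic genomes, masks, gene models and multi-sample variant sets.

The generator emulates the statistical structure of a chemically mutagenized
selfing-barley experiment at toy scale: a reference genome with callable /
uncallable region masks, a parent line carrying homozygous differences from
the reference (variety heterogeneity), mutagenized lines whose private
induced SNVs are dominated by C→T* changes preferentially placed where the
cytosine is followed by another cytosine, induced small indels dominated by
1-bp events, spontaneous mutations accumulated under the selfing expectation
model, and an untreated landrace cohort whose standing variation follows a
neutral 1/i site-frequency spectrum with a transition-rich, CpG-placed
substitution profile.  Every emitted variant is recorded in a ground-truth
table so filter sensitivity and parameter recovery can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import expectation
from .filters import build_callable_mask
from .io import write_bed, write_fasta, write_gff3, write_vcf
from .models import GeneModel, Genotype, RegionMask, SampleCall, Variant
from .spectrum import COLLAPSED_CLASSES, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")

#: collapsed-class probabilities of the induced (mutagen) spectrum; the
#: C→T* mass is the observed induced fraction, the remainder uniform
INDUCED_SPECTRUM = (0.0418, 0.0418, 0.0418, 0.0418, 0.0418, 0.791)

def _landrace_spectrum(ts_tv: float = 1.74) -> tuple[float, ...]:
    """Collapsed-class probabilities with E[Ts/Tv] = ``ts_tv``; C→T* gets
    two thirds of the transition mass (CpG-driven excess), A→G* one third."""
    ts = ts_tv / (1.0 + ts_tv)
    tv = (1.0 - ts) / 4.0
    return (tv, ts / 3.0, tv, tv, tv, 2.0 * ts / 3.0)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated experiment
    at toy scale (a few Mb instead of 4.2 Gb, hundreds instead of thousands
    of induced variants per line)."""

    seed: int = 0
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    gc_fraction: float = 0.44  # barley-like GC
    mask_fraction: float = 0.15
    n_genes: int = 20
    n_mut_lines: int = 11
    mean_induced_snv: float = 200.0
    mean_induced_indel: float = 45.0
    spectrum_probs: tuple[float, ...] = INDUCED_SPECTRUM
    cc_context_enrichment: float = 8.0  # odds multiplier, free parameter
    indel_1bp_fraction_ins: float = 0.283
    indel_1bp_fraction_del: float = 0.364
    indel_insertion_fraction: float = 0.417  # deletions dominate induced indels
    induced_het_fraction: float = 0.0  # M5 single-seed descent: essentially fixed
    generations: int = 7
    snv_rate: float = expectation.DEFAULT_SNV_RATE
    indel_rates: tuple[float, float] = expectation.DEFAULT_INDEL_RATES
    n_landraces: int = 13
    n_landrace_segsites: int = 5000
    landrace_spectrum_probs: tuple[float, ...] = field(default_factory=_landrace_spectrum)
    cpg_enrichment: float = 10.0
    n_parent_diffs: int = 500
    n_panel_positions: int = 100
    contaminate_masks: bool = False  # place some induced variants in masked regions

    def __post_init__(self) -> None:
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        for name in ("gc_fraction", "mask_fraction", "indel_1bp_fraction_ins",
                     "indel_1bp_fraction_del", "indel_insertion_fraction",
                     "induced_het_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for probs in (self.spectrum_probs, self.landrace_spectrum_probs):
            if len(probs) != 6 or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("spectrum probabilities must be 6 values summing to 1")
        for name in ("n_chromosomes", "n_mut_lines", "n_landraces", "n_landrace_segsites",
                     "n_parent_diffs", "n_genes", "n_panel_positions"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulatedDataset:
    """Everything one synthetic study run produces, plus the ground truth."""

    config: SimulationConfig
    genome: dict[str, str]
    contigs: dict[str, int]
    masks: list[RegionMask]
    callable_mask: RegionMask
    genes: list[GeneModel]
    parent: list[Variant]
    lines: dict[str, list[Variant]]
    landraces: list[Variant]
    panel: set[tuple[str, int]]
    truth: pd.DataFrame

    @property
    def parent_sample(self) -> str:
        return "Morex_parent"


# ---------------------------------------------------------------------------
# reference genome, masks, genes


def generate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], dict[str, int], list[RegionMask]]:
    """Random genome (as uint8 arrays) plus uncallable-region masks.

    Uncallable intervals (labels repeat / N_stretch / high_copy) total the
    configured mask fraction of each chromosome; an additional small
    low-complexity mask is emitted separately.  N-stretch intervals are
    written as N in the sequence.
    """
    rng = rng or np.random.default_rng(config.seed)
    per_chrom = config.genome_length // config.n_chromosomes
    contigs = {f"chr{i + 1}": per_chrom for i in range(config.n_chromosomes)}
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    arrays = {
        chrom: _BASES[rng.choice(4, size=length, p=probs)]
        for chrom, length in contigs.items()
    }

    labels = ("repeat", "N_stretch", "high_copy")
    masks = {label: RegionMask(label) for label in labels + ("low_complexity",)}
    for chrom, length in contigs.items():
        target = int(config.mask_fraction * length)
        if target > 0 and length < 3000:
            raise ValueError(f"{chrom} too short ({length} bp) to host masked regions")
        placed: list[tuple[int, int]] = []
        total = 0
        attempts = 0
        i = 0
        while total < target:
            attempts += 1
            if attempts > 100_000:
                raise ValueError("cannot place requested masked fraction")
            span = int(min(rng.integers(300, 2000), target - total))
            if span < 1:
                break
            start = int(rng.integers(0, length - span))
            if any(start < e and start + span > s for s, e in placed):
                continue
            placed.append((start, start + span))
            masks[labels[i % 3]].add(chrom, start, start + span)
            if labels[i % 3] == "N_stretch":
                arrays[chrom][start : start + span] = _N
            total += span
            i += 1
        # a sprinkling of low-complexity sequence, outside the 'uncallable' budget
        for _ in range(max(1, length // 500_000)):
            span = int(rng.integers(200, 800))
            start = int(rng.integers(0, length - span))
            if not any(start < e and start + span > s for s, e in placed):
                masks["low_complexity"].add(chrom, start, start + span)
    for m in masks.values():
        m.normalize()
    return arrays, contigs, list(masks.values())


_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


def generate_gene_models(
    config: SimulationConfig,
    arrays: dict[str, np.ndarray],
    callable_mask: RegionMask,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Place non-overlapping intron-containing genes on both strands.

    Each gene's coding sequence (ATG + internal-stop-free codons + stop) and
    canonical GT..AG introns are written into the genome arrays, so
    downstream consequence calls can be validated by translation.
    """
    genes: list[GeneModel] = []
    occupied: list[tuple[str, int, int]] = []
    for g in range(config.n_genes):
        n_exons = int(rng.integers(1, 4))
        exon_codons = [int(rng.integers(30, 90)) for _ in range(n_exons)]
        intron_lens = [int(rng.integers(60, 200)) for _ in range(n_exons - 1)]
        n_codons = sum(exon_codons)
        codons = ["ATG"] + [_CODONS[i] for i in rng.integers(len(_CODONS), size=n_codons - 2)]
        codons.append(("TAA", "TAG", "TGA")[rng.integers(3)])
        cds_seq = "".join(codons)
        total_len = 3 * n_codons + sum(intron_lens)
        strand = "+" if rng.random() < 0.5 else "-"

        placedg = False
        for _ in range(500):
            chrom = list(arrays)[int(rng.integers(len(arrays)))]
            if len(arrays[chrom]) <= total_len + 2:
                continue
            start0 = int(rng.integers(0, len(arrays[chrom]) - total_len))
            tree = callable_mask.trees.get(chrom)
            inside = tree is not None and any(
                iv.begin <= start0 and iv.end >= start0 + total_len for iv in tree.overlap(start0, start0 + total_len)
            )
            if not inside:
                continue
            if any(c == chrom and start0 < e and start0 + total_len > s for c, s, e in occupied):
                continue
            # assemble exon/intron structure in transcript orientation
            parts, cds_local, cursor, cds_cursor = [], [], 0, 0
            for ei, ncod in enumerate(exon_codons):
                seg = cds_seq[cds_cursor : cds_cursor + 3 * ncod]
                parts.append(seg)
                cds_local.append((cursor, cursor + len(seg)))
                cursor += len(seg)
                cds_cursor += len(seg)
                if ei < n_exons - 1:
                    ilen = intron_lens[ei]
                    interior = "".join(
                        "ACGT"[i] for i in rng.integers(4, size=ilen - 4)
                    )
                    parts.append("GT" + interior + "AG")
                    cursor += ilen
            gene_seq = "".join(parts)
            if strand == "-":
                gene_seq = revcomp(gene_seq)
                cds_genomic = [
                    (start0 + total_len - e + 1, start0 + total_len - s)
                    for s, e in cds_local
                ]
            else:
                cds_genomic = [(start0 + s + 1, start0 + e) for s, e in cds_local]
            arrays[chrom][start0 : start0 + total_len] = np.frombuffer(
                gene_seq.encode(), dtype=np.uint8
            )
            genes.append(
                GeneModel(
                    gene_id=f"gene{g + 1:03d}",
                    chrom=chrom,
                    start=start0 + 1,
                    end=start0 + total_len,
                    strand=strand,
                    cds=sorted(cds_genomic),
                )
            )
            occupied.append((chrom, start0, start0 + total_len))
            placedg = True
            break
        if not placedg:
            raise ValueError(f"could not place gene {g + 1} of {config.n_genes}")
    return genes


# ---------------------------------------------------------------------------
# variant placement machinery


class _SiteIndex:
    """Callable-site pools by reference base and dinucleotide context."""

    def __init__(
        self,
        arrays: dict[str, np.ndarray],
        callable_mask: RegionMask,
        contaminate: bool = False,
    ) -> None:
        self.chroms = list(arrays)
        self.pools: dict[str, list[tuple[int, np.ndarray]]] = {}
        self.callable_ok: dict[str, np.ndarray] = {}
        pool_names = (
            "A", "C", "G", "T",
            "C_cc", "C_noncc", "G_gg", "G_nongg",
            "C_cpg", "C_noncpg", "G_gpc", "G_nongpc",
        )
        per_chrom: dict[str, list[np.ndarray]] = {n: [] for n in pool_names}
        for ci, (chrom, arr) in enumerate(arrays.items()):
            ok = np.ones(len(arr), dtype=bool)
            if not contaminate:
                ok[:] = False
                tree = callable_mask.trees.get(chrom)
                for iv in (tree or []):
                    ok[iv.begin : iv.end] = True
            self.callable_ok[chrom] = ok
            nxt = np.empty_like(arr)
            nxt[:-1] = arr[1:]
            nxt[-1] = 0
            prv = np.empty_like(arr)
            prv[1:] = arr[:-1]
            prv[0] = 0
            is_c = arr == ord("C")
            is_g = arr == ord("G")
            sel = {
                "A": ok & (arr == ord("A")),
                "C": ok & is_c,
                "G": ok & is_g,
                "T": ok & (arr == ord("T")),
                "C_cc": ok & is_c & (nxt == ord("C")),
                "C_noncc": ok & is_c & (nxt != ord("C")),
                "G_gg": ok & is_g & (prv == ord("G")),
                "G_nongg": ok & is_g & (prv != ord("G")),
                "C_cpg": ok & is_c & (nxt == ord("G")),
                "C_noncpg": ok & is_c & (nxt != ord("G")),
                "G_gpc": ok & is_g & (prv == ord("C")),
                "G_nongpc": ok & is_g & (prv != ord("C")),
            }
            for name, m in sel.items():
                per_chrom[name].append(np.flatnonzero(m))
        for name in pool_names:
            self.pools[name] = [
                (ci, positions) for ci, positions in enumerate(per_chrom[name])
            ]
        self.used: set[tuple[str, int]] = set()

    def _draw(self, pool: str, rng: np.random.Generator) -> tuple[str, int]:
        """One unused 0-based position from a pool (uniform over all sites)."""
        sizes = np.array([len(p) for _, p in self.pools[pool]], dtype=float)
        total = sizes.sum()
        if total == 0:
            raise ValueError(f"no eligible sites in pool {pool!r}")
        for _ in range(10_000):
            ci = int(rng.choice(len(sizes), p=sizes / total))
            positions = self.pools[pool][ci][1]
            pos0 = int(positions[rng.integers(len(positions))])
            chrom = self.chroms[ci]
            if (chrom, pos0) not in self.used:
                return chrom, pos0
        raise ValueError(f"pool {pool!r} exhausted ({int(total)} sites, {len(self.used)} used)")

    def pool_size(self, pool: str) -> int:
        return sum(len(p) for _, p in self.pools[pool])

    def draw_for_base(self, base: str, rng: np.random.Generator) -> tuple[str, int]:
        return self._draw(base, rng)

    def draw_with_context(
        self, base: str, ctx: str, enrichment: float, rng: np.random.Generator
    ) -> tuple[str, int]:
        """Draw a C or G site with its context pool (cc/cpg and mirror)
        chosen with odds multiplied by ``enrichment``."""
        if base == "C":
            inpool, outpool = ("C_cc", "C_noncc") if ctx == "cc" else ("C_cpg", "C_noncpg")
        else:
            inpool, outpool = ("G_gg", "G_nongg") if ctx == "cc" else ("G_gpc", "G_nongpc")
        n_in, n_out = self.pool_size(inpool), self.pool_size(outpool)
        if n_in + n_out == 0:
            raise ValueError(f"no eligible {base} sites for context {ctx!r}")
        p_in = enrichment * n_in / (enrichment * n_in + n_out) if n_in else 0.0
        return self._draw(inpool if rng.random() < p_in else outpool, rng)

    def mark_used(self, chrom: str, start0: int, end0: int) -> None:
        for p in range(start0, end0):
            self.used.add((chrom, p))

    def span_free(self, chrom: str, start0: int, end0: int) -> bool:
        return all((chrom, p) not in self.used for p in range(start0, end0))

    def span_callable(self, chrom: str, start0: int, end0: int) -> bool:
        return bool(self.callable_ok[chrom][start0:end0].all())


_CLASS_ALT = {  # collapsed class -> alt base for the A/C-oriented representation
    "A>C": "C", "A>G": "G", "A>T": "T", "C>A": "A", "C>G": "G", "C>T": "T",
}


def _oriented_change(cls: str, forward: bool) -> tuple[str, str]:
    ref, alt = cls.split(">")
    if forward:
        return ref, alt
    return revcomp(ref), revcomp(alt)


def _good_call(gt: Genotype, rng: np.random.Generator) -> SampleCall:
    ab = None
    if gt is Genotype.HET:
        ab = float(np.clip(rng.normal(0.5, 0.03), 0.35, 0.65))
    return SampleCall(
        gt=gt,
        dp=int(rng.integers(15, 45)),
        gq=int(rng.integers(60, 100)),
        allele_balance=ab,
    )


def _base_at(arrays: dict[str, np.ndarray], chrom: str, pos0: int) -> str:
    return chr(arrays[chrom][pos0])


# ---------------------------------------------------------------------------
# variant generators


def generate_parent_diffs(
    config: SimulationConfig,
    arrays: dict[str, np.ndarray],
    index: _SiteIndex,
    rng: np.random.Generator,
    sample: str = "Morex_parent",
) -> tuple[list[Variant], list[dict]]:
    """Homozygous parent-vs-reference differences (variety heterogeneity):
    85% SNVs, 15% 1-bp indels, placed at distinct callable positions."""
    variants, truth_rows = [], []
    for _ in range(config.n_parent_diffs):
        if rng.random() < 0.85:
            base = "ACGT"[int(rng.integers(4))]
            chrom, pos0 = index.draw_for_base(base, rng)
            alt = rng.choice([b for b in "ACGT" if b != base])
            v = Variant(chrom, pos0 + 1, base, str(alt), qual=float(rng.integers(100, 1000)))
            index.mark_used(chrom, pos0, pos0 + 1)
        else:
            base = "ACGT"[int(rng.integers(4))]
            chrom, pos0 = index.draw_for_base(base, rng)
            ref0 = _base_at(arrays, chrom, pos0)
            if rng.random() < 0.5 or pos0 + 2 >= len(arrays[chrom]):
                ins = "ACGT"[int(rng.integers(4))]
                v = Variant(chrom, pos0 + 1, ref0, ref0 + ins, qual=float(rng.integers(100, 1000)))
                index.mark_used(chrom, pos0, pos0 + 1)
            else:
                if not index.span_free(chrom, pos0, pos0 + 2) or not index.span_callable(
                    chrom, pos0, pos0 + 2
                ):
                    continue
                ref = ref0 + _base_at(arrays, chrom, pos0 + 1)
                v = Variant(chrom, pos0 + 1, ref, ref0, qual=float(rng.integers(100, 1000)))
                index.mark_used(chrom, pos0, pos0 + 2)
        v.calls[sample] = _good_call(Genotype.HOM_ALT, rng)
        variants.append(v)
        truth_rows.append(_truth_row(sample, v, origin="heterogeneity", context="other"))
    return variants, truth_rows


def _truth_row(sample: str, v: Variant, origin: str, context: str) -> dict:
    from .spectrum import collapse_change

    vclass = collapse_change(v.ref, v.alt) if v.is_snv else f"indel{v.length:+d}"
    return {
        "sample": sample, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
        "vtype": v.vtype, "vclass": vclass, "context": context, "origin": origin,
    }


def _draw_indel_length(config: SimulationConfig, insertion: bool, rng: np.random.Generator) -> int:
    frac1 = config.indel_1bp_fraction_ins if insertion else config.indel_1bp_fraction_del
    if rng.random() < frac1:
        return 1
    # geometric tail over 2..20, matching the rapid decay of observed lengths
    length = 2 + int(rng.geometric(0.35)) - 1
    return min(length, 20)


def generate_mutagenized_lines(
    config: SimulationConfig,
    arrays: dict[str, np.ndarray],
    index: _SiteIndex,
    parent_diffs: list[Variant],
    rng: np.random.Generator,
) -> tuple[dict[str, list[Variant]], list[dict]]:
    """Per-line private induced SNVs/indels plus spontaneous mutations.

    Induced SNV classes follow ``spectrum_probs`` with a 50/50 choice of
    forward or reverse-complement orientation; C→T (and mirror G→A) draws
    are placed in the CC (GG) dinucleotide context with odds multiplied by
    ``cc_context_enrichment``.  Spontaneous counts per line are Poisson with
    means from the selfing accumulation model applied to the toy genome.
    Lines inherit every parent difference.
    """
    genome_bp = sum(len(a) for a in arrays.values())
    spont_snv_mean = expectation.accumulate(
        expectation.SelfingModelParams(2 * genome_bp, config.snv_rate, config.generations)
    ).total
    spont_indel_mean = expectation.expected_indels(
        2 * genome_bp, config.generations, config.indel_rates
    )

    classes = list(COLLAPSED_CLASSES)
    probs = np.asarray(config.spectrum_probs, dtype=float)
    lines: dict[str, list[Variant]] = {}
    truth_rows: list[dict] = []
    for li in range(config.n_mut_lines):
        sample = f"M{li + 1:02d}"
        records: list[Variant] = []
        # inherited heterogeneity
        for pv in parent_diffs:
            v = Variant(pv.chrom, pv.pos, pv.ref, pv.alt, qual=float(rng.integers(100, 1000)))
            v.calls[sample] = _good_call(Genotype.HOM_ALT, rng)
            records.append(v)
            truth_rows.append(_truth_row(sample, v, origin="heterogeneity", context="other"))
        # induced SNVs
        for _ in range(rng.poisson(config.mean_induced_snv)):
            cls = classes[int(rng.choice(6, p=probs))]
            forward = rng.random() < 0.5
            ref, alt = _oriented_change(cls, forward)
            if cls == "C>T":
                chrom, pos0 = index.draw_with_context(
                    ref, "cc", config.cc_context_enrichment, rng
                )
            else:
                chrom, pos0 = index.draw_for_base(ref, rng)
            v = Variant(chrom, pos0 + 1, ref, alt, qual=float(rng.integers(100, 1000)))
            gt = (
                Genotype.HET
                if rng.random() < config.induced_het_fraction
                else Genotype.HOM_ALT
            )
            v.calls[sample] = _good_call(gt, rng)
            index.mark_used(chrom, pos0, pos0 + 1)
            records.append(v)
            truth_rows.append(
                _truth_row(sample, v, origin="induced", context=_context_of(arrays, v))
            )
        # induced indels
        for _ in range(rng.poisson(config.mean_induced_indel)):
            insertion = rng.random() < config.indel_insertion_fraction
            length = _draw_indel_length(config, insertion, rng)
            v = _place_indel(arrays, index, length, insertion, rng)
            if v is None:
                continue
            v.calls[f"M{li + 1:02d}"] = _good_call(Genotype.HOM_ALT, rng)
            records.append(v)
            truth_rows.append(_truth_row(sample, v, origin="induced", context="other"))
        # spontaneous mutations under the accumulation model
        for _ in range(rng.poisson(spont_snv_mean)):
            base = "ACGT"[int(rng.integers(4))]
            chrom, pos0 = index.draw_for_base(base, rng)
            alt = str(rng.choice([b for b in "ACGT" if b != base]))
            v = Variant(chrom, pos0 + 1, base, alt, qual=float(rng.integers(100, 1000)))
            v.calls[sample] = _good_call(Genotype.HOM_ALT, rng)
            index.mark_used(chrom, pos0, pos0 + 1)
            records.append(v)
            truth_rows.append(_truth_row(sample, v, origin="spontaneous", context="other"))
        for _ in range(rng.poisson(spont_indel_mean)):
            insertion = rng.random() < 0.5
            v = _place_indel(arrays, index, 1, insertion, rng)
            if v is None:
                continue
            v.calls[sample] = _good_call(Genotype.HOM_ALT, rng)
            records.append(v)
            truth_rows.append(_truth_row(sample, v, origin="spontaneous", context="other"))
        lines[sample] = records
    return lines, truth_rows


def _context_of(arrays: dict[str, np.ndarray], v: Variant) -> str:
    arr = arrays[v.chrom]
    i = v.pos - 1
    if v.ref == "C" and i + 1 < len(arr):
        nxt = chr(arr[i + 1])
        if nxt == "C":
            return "CC"
        if nxt == "G":
            return "CpG"
    if v.ref == "G" and i >= 1:
        prv = chr(arr[i - 1])
        if prv == "G":
            return "CC"
        if prv == "C":
            return "CpG"
    return "other"


def _place_indel(
    arrays: dict[str, np.ndarray],
    index: _SiteIndex,
    length: int,
    insertion: bool,
    rng: np.random.Generator,
) -> Variant | None:
    """Left-anchored indel at a free callable anchor; None if placement fails."""
    for _ in range(50):
        base = "ACGT"[int(rng.integers(4))]
        chrom, pos0 = index.draw_for_base(base, rng)
        anchor = _base_at(arrays, chrom, pos0)
        if insertion:
            ins = "".join("ACGT"[i] for i in rng.integers(4, size=length))
            index.mark_used(chrom, pos0, pos0 + 1)
            return Variant(chrom, pos0 + 1, anchor, anchor + ins, qual=float(rng.integers(100, 1000)))
        if pos0 + 1 + length >= len(arrays[chrom]):
            continue
        if not index.span_free(chrom, pos0, pos0 + 1 + length):
            continue
        if not index.span_callable(chrom, pos0, pos0 + 1 + length):
            continue
        deleted = "".join(
            _base_at(arrays, chrom, p) for p in range(pos0, pos0 + 1 + length)
        )
        if "N" in deleted:
            continue
        index.mark_used(chrom, pos0, pos0 + 1 + length)
        return Variant(chrom, pos0 + 1, deleted, anchor, qual=float(rng.integers(100, 1000)))
    return None


def generate_landraces(
    config: SimulationConfig,
    arrays: dict[str, np.ndarray],
    index: _SiteIndex,
    rng: np.random.Generator,
) -> tuple[list[Variant], list[dict]]:
    """Standing variation in an untreated cohort.

    Each segregating site draws its non-reference allele count i from the
    neutral 1/i site-frequency spectrum over 1..2n-1 haplotypes, its
    substitution class from the transition-rich landrace spectrum, and —
    for C→T* draws — its position preferentially in a CpG context.
    """
    if config.n_landrace_segsites and config.n_landraces < 2:
        raise ValueError("need at least 2 landrace samples")
    samples = [f"L{i + 1:02d}" for i in range(config.n_landraces)]
    n_hap = 2 * config.n_landraces
    counts = np.arange(1, n_hap)
    sfs = (1.0 / counts) / (1.0 / counts).sum()
    classes = list(COLLAPSED_CLASSES)
    probs = np.asarray(config.landrace_spectrum_probs, dtype=float)
    variants, truth_rows = [], []
    for _ in range(config.n_landrace_segsites):
        cls = classes[int(rng.choice(6, p=probs))]
        forward = rng.random() < 0.5
        ref, alt = _oriented_change(cls, forward)
        if cls == "C>T":
            chrom, pos0 = index.draw_with_context(ref, "cpg", config.cpg_enrichment, rng)
        else:
            chrom, pos0 = index.draw_for_base(ref, rng)
        index.mark_used(chrom, pos0, pos0 + 1)
        ac = int(rng.choice(counts, p=sfs))
        haplotypes = np.zeros(n_hap, dtype=int)
        haplotypes[rng.choice(n_hap, size=ac, replace=False)] = 1
        v = Variant(chrom, pos0 + 1, ref, alt, qual=float(rng.integers(100, 1000)))
        for si, sample in enumerate(samples):
            dosage = int(haplotypes[2 * si] + haplotypes[2 * si + 1])
            gt = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[dosage]
            v.calls[sample] = _good_call(gt, rng)
        variants.append(v)
        truth_rows.append(
            _truth_row("landraces", v, origin="standing", context=_context_of(arrays, v))
            | {"alt_allele_count": ac}
        )
    return variants, truth_rows


# ---------------------------------------------------------------------------
# top-level driver


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: reference, masks, genes, parent, lines,
    landraces, genotyping panel, ground-truth table.  Deterministic for a
    fixed config (including its seed)."""
    rng = np.random.default_rng(config.seed)
    arrays, contigs, masks = generate_reference(config, rng)
    callable_mask = build_callable_mask(masks, contigs)
    genes = generate_gene_models(config, arrays, callable_mask, rng) if config.n_genes else []
    index = _SiteIndex(arrays, callable_mask, contaminate=config.contaminate_masks)
    parent, truth_parent = generate_parent_diffs(config, arrays, index, rng)
    lines, truth_lines = generate_mutagenized_lines(config, arrays, index, parent, rng)
    landraces, truth_land = generate_landraces(config, arrays, index, rng)

    panel: set[tuple[str, int]] = set()
    if landraces and config.n_panel_positions:
        n = min(config.n_panel_positions, len(landraces))
        chosen = rng.choice(len(landraces), size=n, replace=False)
        panel = {(landraces[i].chrom, landraces[i].pos) for i in chosen}

    truth_columns = [
        "sample", "chrom", "pos", "ref", "alt", "vtype", "vclass", "context",
        "origin", "alt_allele_count",
    ]
    truth = pd.DataFrame(truth_parent + truth_lines + truth_land, columns=truth_columns)
    genome = {chrom: arr.tobytes().decode() for chrom, arr in arrays.items()}
    return SimulatedDataset(
        config=config,
        genome=genome,
        contigs=contigs,
        masks=masks,
        callable_mask=callable_mask,
        genes=genes,
        parent=parent,
        lines=lines,
        landraces=landraces,
        panel=panel,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> None:
    """Write a simulated dataset as FASTA + BED + VCF + GFF3 + TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "reference.fa", ds.genome)
    for mask in ds.masks:
        write_bed(outdir / f"mask_{mask.label}.bed", mask)
    write_bed(outdir / "callable.bed", ds.callable_mask)
    if ds.genes:
        write_gff3(outdir / "genes.gff3", ds.genes)
    write_vcf(outdir / "parent.vcf", ds.parent, [ds.parent_sample], ds.contigs)
    for line, vs in ds.lines.items():
        write_vcf(outdir / f"line_{line}.vcf", vs, [line], ds.contigs)
    if ds.landraces:
        samples = sorted({s for v in ds.landraces for s in v.calls})
        write_vcf(outdir / "landraces.vcf", ds.landraces, samples, ds.contigs)
    with open(outdir / "panel.tsv", "w") as fh:
        for chrom, pos in sorted(ds.panel):
            fh.write(f"{chrom}\t{pos}\n")
    ds.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
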