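"""Variant consequence classification, deleteriousness labelling, and load summaries.

Consequences are assigned against single-transcript gene models by
precedence: splice-site > start/stop disruption > missense/synonymous >
intron > upstream/downstream flank > intergenic.  Deleteriousness is never
computed here — a phylogenetic-constraint test's per-variant p-values are
consumed and thresholded with a Bonferroni correction over the number of
tested codons, together with auxiliary evidence criteria (minimum alignment
depth, allele unseen in other species).  "Nonsynonymous" throughout means
missense + start-lost + stop-gained + stop-lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .models import GeneModel, RegionMask, Variant
from .spectrum import revcomp

CONSEQUENCES = (
    "splice_donor",
    "splice_acceptor",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "missense",
    "synonymous",
    "frameshift",
    "inframe_indel",
    "intron",
    "upstream",
    "downstream",
    "intergenic",
)

NONSYNONYMOUS = frozenset({"missense", "start_lost", "stop_gained", "stop_lost"})


@dataclass
class EffectAnnotation:
    variant: Variant
    consequence: str
    gene_id: str | None = None
    ref_codon: str | None = None
    alt_codon: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    cc_motif: bool | None = None

    @property
    def aa_change(self) -> str | None:
        if self.ref_aa is None or self.alt_aa is None:
            return None
        return f"{self.ref_aa}/{self.alt_aa}"

    @property
    def is_nonsynonymous(self) -> bool:
        return self.consequence in NONSYNONYMOUS


def _cds_sequence(gene: GeneModel, genome: dict[str, str]) -> str:
    seq = "".join(genome[gene.chrom][s - 1 : e] for s, e in gene.cds)
    return revcomp(seq) if gene.strand == "-" else seq


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of genomic position ``pos`` within the spliced CDS,
    reading in translation order; None if not in CDS."""
    acc = 0
    for s, e in gene.cds:
        if s <= pos <= e:
            off = acc + (pos - s)
            if gene.strand == "-":
                return gene.cds_length - 1 - off
            return off
        acc += e - s + 1
    return None


def _splice_consequence(gene: GeneModel, start0: int, end0: int) -> str | None:
    """Splice-site hit if the variant span touches the first or last two
    intronic bases (the GT/AG dinucleotides), strand-aware."""
    for intron_start, intron_end in gene.introns():
        if intron_end - intron_start + 1 < 4:
            continue
        left = (intron_start - 1, intron_start + 1)  # 0-based half-open, 2 bp
        right = (intron_end - 2, intron_end)
        hit_left = start0 < left[1] and end0 > left[0]
        hit_right = start0 < right[1] and end0 > right[0]
        if hit_left or hit_right:
            if gene.strand == "+":
                return "splice_donor" if hit_left else "splice_acceptor"
            return "splice_acceptor" if hit_left else "splice_donor"
    return None


def classify_effect(
    variant: Variant,
    genes: Sequence[GeneModel],
    genome: dict[str, str],
    flank_bp: int = 5000,
) -> EffectAnnotation:
    """Assign the single top-priority consequence of a variant."""
    start0, end0 = variant.span()
    pos = variant.pos
    best: EffectAnnotation | None = None
    rank = {c: i for i, c in enumerate(CONSEQUENCES)}

    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        ann = None
        if gene.start <= pos <= gene.end:
            splice = _splice_consequence(gene, start0, end0)
            if splice is not None:
                ann = EffectAnnotation(variant, splice, gene.gene_id)
            else:
                offset = _cds_offset(gene, pos) if variant.is_snv else None
                if variant.is_snv and offset is not None:
                    ann = _classify_cds_snv(variant, gene, genome, offset)
                elif not variant.is_snv and any(
                    start0 < e and end0 > s - 1 for s, e in gene.cds
                ):
                    kind = "frameshift" if variant.length % 3 != 0 else "inframe_indel"
                    ann = EffectAnnotation(variant, kind, gene.gene_id)
                else:
                    ann = EffectAnnotation(variant, "intron", gene.gene_id)
        elif gene.start - flank_bp <= pos < gene.start:
            side = "upstream" if gene.strand == "+" else "downstream"
            ann = EffectAnnotation(variant, side, gene.gene_id)
        elif gene.end < pos <= gene.end + flank_bp:
            side = "downstream" if gene.strand == "+" else "upstream"
            ann = EffectAnnotation(variant, side, gene.gene_id)
        if ann is not None and (best is None or rank[ann.consequence] < rank[best.consequence]):
            best = ann
    return best if best is not None else EffectAnnotation(variant, "intergenic")


def _classify_cds_snv(
    variant: Variant, gene: GeneModel, genome: dict[str, str], offset: int
) -> EffectAnnotation:
    if gene.cds_length % 3 != 0:
        raise ValueError(f"gene {gene.gene_id}: CDS length {gene.cds_length} not divisible by 3")
    cds = _cds_sequence(gene, genome)
    ref_base, alt_base = variant.ref.upper(), variant.alt.upper()
    if gene.strand == "-":
        ref_base, alt_base = revcomp(ref_base), revcomp(alt_base)
    if cds[offset] != ref_base:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos} in {gene.gene_id}: "
            f"CDS has {cds[offset]}, variant ref is {ref_base}"
        )
    codon_idx, within = divmod(offset, 3)
    ref_codon = cds[codon_idx * 3 : codon_idx * 3 + 3]
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        consequence = "start_lost"
    elif ref_aa != "*" and alt_aa == "*":
        consequence = "stop_gained"
    elif ref_aa == "*" and alt_aa != "*":
        consequence = "stop_lost"
    elif ref_aa != alt_aa:
        consequence = "missense"
    else:
        consequence = "synonymous"
    cc = cc_motif_flag(variant, genome)
    return EffectAnnotation(
        variant, consequence, gene.gene_id, ref_codon, alt_codon, ref_aa, alt_aa, cc
    )


def cc_motif_flag(variant: Variant, genome: dict[str, str]) -> bool:
    """True when the mutated base sits in the mutagen-associated CC motif on
    the reference forward strand (ref base + its 3' neighbor are CC) or its
    reverse complement GG (ref base + its 5' neighbor are GG)."""
    seq = genome[variant.chrom]
    i = variant.pos - 1
    ref = variant.ref.upper()
    if ref == "C":
        if i + 1 >= len(seq):
            return False
        return seq[i + 1].upper() == "C"
    if ref == "G":
        if i - 1 < 0:
            return False
        return seq[i - 1].upper() == "G"
    return False


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Bonferroni-corrected p-value cutoff.

    Returns (exact, displayed) where the displayed value truncates the exact
    threshold toward zero at two significant digits (0.05/611 = 8.18e-5 is
    reported as 8.1e-5).
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    exact = alpha / n_tests
    exponent = math.floor(math.log10(exact))
    mantissa = exact / 10**exponent
    displayed = math.floor(mantissa * 10) / 10 * 10**exponent
    return exact, displayed


def label_constraint(
    calls: pd.DataFrame,
    n_tests: int,
    alpha: float = 0.05,
    min_sequences: int = 10,
) -> pd.DataFrame:
    """Label constraint-test output deleterious or tolerated.

    ``calls`` needs columns ``p`` (constraint-test p-value), ``n_seqs``
    (species aligned at the codon) and ``allele_unseen`` (neither allele
    observed in other species).  Deleterious requires p strictly below the
    exact Bonferroni threshold AND both auxiliary criteria; rows with
    missing p are dropped and counted in the ``skipped`` attribute.
    """
    exact, _ = bonferroni_threshold(n_tests, alpha)
    out = calls.copy()
    skipped = int(out["p"].isna().sum())
    out = out.dropna(subset=["p"]).copy()
    out["label"] = np.where(
        (out["p"] < exact) & (out["n_seqs"] >= min_sequences) & out["allele_unseen"],
        "deleterious",
        "tolerated",
    )
    out.attrs["skipped"] = skipped
    out.attrs["threshold"] = exact
    return out


def amino_acid_change_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Ranked amino-acid-change counts within each (stratum, label) group.

    ``annotated`` needs columns ``aa_change``, ``label`` (deleterious /
    tolerated) and ``stratum`` (e.g. mutated / rare / common).  Percentages
    are of the group total, reported to two decimals.
    """
    rows = []
    for (stratum, label), grp in annotated.groupby(["stratum", "label"], sort=False):
        total = len(grp)
        counts = grp["aa_change"].value_counts()
        for change, n in counts.items():
            rows.append(
                {"stratum": stratum, "label": label, "aa_change": change,
                 "count": int(n), "percent": round(n / total * 100, 2)}
            )
    return pd.DataFrame(rows, columns=["stratum", "label", "aa_change", "count", "percent"])


def load_windows(
    annotations: Sequence[EffectAnnotation],
    labels: dict[tuple[str, int, str, str], str],
    genes: Sequence[GeneModel],
    contigs: dict[str, int],
    window_bp: int = 10_000_000,
    callable_mask: RegionMask | None = None,
) -> pd.DataFrame:
    """Deleterious and tolerated nonsynonymous variants per covered codon in
    tumbling windows.  Covered codons are (callable) CDS bp in the window
    divided by 3; windows with no covered codons are flagged undefined."""
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    rows = []
    for chrom, length in contigs.items():
        n_windows = (length + window_bp - 1) // window_bp
        cds_bp = np.zeros(n_windows)
        for gene in genes:
            if gene.chrom != chrom:
                continue
            for s, e in gene.cds:
                for pos0 in range(s - 1, e):
                    if callable_mask is not None and not callable_mask.contains(chrom, pos0):
                        continue
                    cds_bp[pos0 // window_bp] += 1
        del_counts = np.zeros(n_windows)
        tol_counts = np.zeros(n_windows)
        for ann in annotations:
            if ann.variant.chrom != chrom or not ann.is_nonsynonymous:
                continue
            label = labels.get(ann.variant.key)
            if label is None:
                continue
            w = (ann.variant.pos - 1) // window_bp
            if label == "deleterious":
                del_counts[w] += 1
            else:
                tol_counts[w] += 1
        for w in range(n_windows):
            codons = cds_bp[w] / 3
            rows.append(
                {"chrom": chrom, "window_start": w * window_bp,
                 "window_end": min((w + 1) * window_bp, length),
                 "covered_codons": codons,
                 "deleterious": int(del_counts[w]), "tolerated": int(tol_counts[w]),
                 "deleterious_per_codon": del_counts[w] / codons if codons else np.nan,
                 "tolerated_per_codon": tol_counts[w] / codons if codons else np.nan}
            )
    return pd.DataFrame(rows)


def correlate_load_phenotype(
    load: Sequence[float], phenotype: Sequence[float], method: str = "rank"
) -> tuple[float, float]:
    """Correlation between per-line mutational load and a phenotype.

    ``method`` is ``rank`` (Spearman) or ``linear`` (Pearson); returns
    (coefficient, two-sided p).  Raises on constant input, where the
    coefficient is undefined.
    """
    load = np.asarray(load, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if len(load) != len(phenotype) or len(load) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(load) == 0 or np.ptp(phenotype) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "rank":
        r, p = stats.spearmanr(load, phenotype)
    elif method == "linear":
        r, p = stats.pearsonr(load, phenotype)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def load_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-sample nonsynonymous/synonymous/deleterious/tolerated counts and
    the nSNV:sSNV ratio.  ``annotated`` needs columns ``sample``,
    ``consequence`` and (for nonsynonymous rows) ``label``."""
    rows = []
    for sample, grp in annotated.groupby("sample", sort=False):
        nonsyn = int(grp["consequence"].isin(NONSYNONYMOUS).sum())
        syn = int((grp["consequence"] == "synonymous").sum())
        delet = int((grp.get("label") == "deleterious").sum())
        rows.append(
            {"sample": sample, "nonsynonymous": nonsyn, "synonymous": syn,
             "deleterious": delet, "tolerated": nonsyn - delet,
             "nsnv_ssnv_ratio": nonsyn / syn if syn else np.nan}
        )
    return pd.DataFrame(rows)
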