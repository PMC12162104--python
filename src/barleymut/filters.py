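"""Two-part isolation of de novo (mutagen-induced) variants.

Part 1 characterizes the parent line against the reference assembly:
callable-region masking, hard genotype/site filters, and a 100-bp
diversity-window filter produce a set of "differences from reference"
regions where residual heterogeneity in the parent variety lives and where
de novo calls must not be trusted.

Part 2 filters each mutagenized line: callable masking, hard filters,
subtraction of the parent difference regions, exclusion of genotyping-panel
marker positions, and a privacy filter keeping only alleles seen in exactly
one line.  Landrace (standing-variation) cohorts are stratified into rare
(non-reference allele count <= 2) and common (>= 3) classes for comparison.

Every filter is a pure subset operation on its input and is idempotent; a
FilterReport accounts for each record removed at each step.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

from .models import Genotype, RegionMask, SampleCall, Variant

UNCALLABLE_LABELS = ("repeat", "N_stretch", "high_copy")


@dataclass
class HardFilterThresholds:
    """Site- and genotype-level hard-filter thresholds.

    Defaults follow the short-read profile: QUAL >= 30, GQ >= 9, per-sample
    DP in [5, 158], heterozygote allele-balance deviation from 0.5 of at
    most 0.1, per-site heterozygous-genotype proportion <= 0.1 and missing
    proportion <= 0.30.  A linked-read profile (DP in [5, 78], balance
    deviation 0.2) is available via :meth:`linked_read_profile`.
    """

    min_qual: float = 30.0
    min_gq: int = 9
    min_dp: int = 5
    max_dp: int = 158
    max_allele_balance_dev: float = 0.1
    max_het_proportion: float = 0.1
    max_missing_proportion: float = 0.30

    @classmethod
    def linked_read_profile(cls) -> "HardFilterThresholds":
        return cls(min_dp=5, max_dp=78, max_allele_balance_dev=0.2)


@dataclass
class FilterReport:
    """Ordered per-filter accounting: input, removed, surviving counts."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)  # (name, n_in, n_removed)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"filter {name!r} produced more records than it received")
        self.steps.append((name, n_in, n_in - n_out))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"filter": name, "input": n_in, "removed": removed, "surviving": n_in - removed}
            for name, n_in, removed in self.steps
        ]
        return pd.DataFrame(rows, columns=["filter", "input", "removed", "surviving"])


def build_callable_mask(
    masks: list[RegionMask],
    contigs: dict[str, int],
    exclude_low_complexity: bool = False,
) -> RegionMask:
    """Complement of the union of uncallable masks over each chromosome.

    ``masks`` carry labels among repeat / N_stretch / high_copy /
    low_complexity; low-complexity regions are only subtracted when
    ``exclude_low_complexity`` is set (the stricter callable set used for
    SV evaluation).
    """
    labels = set(UNCALLABLE_LABELS) | ({"low_complexity"} if exclude_low_complexity else set())
    union = RegionMask("uncallable")
    for mask in masks:
        if mask.label not in labels:
            continue
        for chrom, start, end in mask.intervals():
            if chrom not in contigs:
                raise ValueError(f"mask interval on unknown chromosome {chrom!r}")
            if end > contigs[chrom]:
                raise ValueError(
                    f"interval [{start},{end}) exceeds {chrom} length {contigs[chrom]}"
                )
            union.add(chrom, start, end)
    union.normalize()
    callable_mask = RegionMask("callable")
    for chrom, length in contigs.items():
        cursor = 0
        tree = union.trees.get(chrom)
        for iv in sorted(tree) if tree else []:
            if iv.begin > cursor:
                callable_mask.add(chrom, cursor, iv.begin)
            cursor = max(cursor, iv.end)
        if cursor < length:
            callable_mask.add(chrom, cursor, length)
    return callable_mask


def mask_filter(
    variants: list[Variant], callable_mask: RegionMask, report: FilterReport | None = None
) -> list[Variant]:
    """Keep variants whose full reference span lies inside callable regions."""
    kept = []
    for v in variants:
        start, end = v.span()
        tree = callable_mask.trees.get(v.chrom)
        covered = False
        if tree is not None:
            covering = tree.overlap(start, end)
            covered = any(iv.begin <= start and iv.end >= end for iv in covering)
        if covered:
            kept.append(v)
    if report is not None:
        report.record("callable_mask", len(variants), len(kept))
    return kept


def hard_filter_snps(
    variants: list[Variant],
    thresholds: HardFilterThresholds | None = None,
    report: FilterReport | None = None,
) -> list[Variant]:
    """Apply genotype-level then site-level hard filters.

    Per-sample failures (DP out of range, low GQ, het allele-balance
    deviation) invalidate the genotype rather than the site; site-level
    missingness and heterozygote-proportion rules are then evaluated on the
    updated genotypes, and QUAL is a site-level cut.
    """
    th = thresholds or HardFilterThresholds()
    kept = []
    for v in variants:
        if v.qual is not None and v.qual < th.min_qual:
            continue
        new_calls = {}
        for sample, call in v.calls.items():
            gt = call.gt
            if gt is not Genotype.MISSING:
                if call.dp is not None and not th.min_dp <= call.dp <= th.max_dp:
                    gt = Genotype.MISSING
                elif call.gq is not None and call.gq < th.min_gq:
                    gt = Genotype.MISSING
                elif (
                    gt is Genotype.HET
                    and call.allele_balance is not None
                    and abs(call.allele_balance - 0.5) > th.max_allele_balance_dev
                ):
                    gt = Genotype.MISSING
            new_calls[sample] = replace(call, gt=gt)
        n = len(new_calls)
        if n:
            n_missing = sum(1 for c in new_calls.values() if c.gt is Genotype.MISSING)
            if n_missing / n > th.max_missing_proportion:
                continue
            n_het = sum(1 for c in new_calls.values() if c.gt is Genotype.HET)
            if n_het / n > th.max_het_proportion:
                continue
        kept.append(replace(v, calls=new_calls))
    if report is not None:
        report.record("hard_filters", len(variants), len(kept))
    return kept


def diversity_window_filter(
    variants: list[Variant],
    window_bp: int = 100,
    max_variants: int = 2,
    report: FilterReport | None = None,
) -> list[Variant]:
    """Drop all SNVs in any tumbling ``window_bp`` window holding more than
    ``max_variants`` SNVs (>2 per 100 bp = >2% diversity); non-SNV records
    pass through untouched."""
    window_of = lambda v: (v.chrom, (v.pos - 1) // window_bp)
    snv_per_window = Counter(window_of(v) for v in variants if v.is_snv)
    kept = [
        v for v in variants if not v.is_snv or snv_per_window[window_of(v)] <= max_variants
    ]
    if report is not None:
        report.record("diversity_window", len(variants), len(kept))
    return kept


def build_difference_regions(parent_variants: list[Variant]) -> RegionMask:
    """Reference-difference regions: the reference spans of the (filtered)
    parent-vs-reference variant set."""
    mask = RegionMask("reference_difference")
    for v in parent_variants:
        start, end = v.span()
        mask.add(v.chrom, start, end)
    mask.normalize()
    return mask


def subtract_reference_differences(
    line_variants: list[Variant],
    diff_regions: RegionMask,
    report: FilterReport | None = None,
) -> list[Variant]:
    """Remove line variants whose reference span intersects a parent
    difference region (half-open interval intersection)."""
    kept = [v for v in line_variants if not diff_regions.overlaps(v.chrom, *v.span())]
    if report is not None:
        report.record("subtract_parent_differences", len(line_variants), len(kept))
    return kept


def privacy_filter(
    cohort: dict[str, list[Variant]],
    reports: dict[str, FilterReport] | None = None,
) -> dict[str, list[Variant]]:
    """Keep only variants whose (chrom, pos, ref, alt) occurs in exactly one
    line of the cohort — the operational definition of a de novo candidate."""
    if len(cohort) < 2:
        warnings.warn("privacy filter on a cohort of <2 lines is vacuous; keeping all variants")
        return {line: list(vs) for line, vs in cohort.items()}
    occurrences = Counter(v.key for vs in cohort.values() for v in vs)
    out = {}
    for line, vs in cohort.items():
        kept = [v for v in vs if occurrences[v.key] == 1]
        if reports is not None:
            reports[line].record("privacy", len(vs), len(kept))
        out[line] = kept
    return out


def panel_exclusion(
    variants: list[Variant],
    panel_positions: set[tuple[str, int]],
    report: FilterReport | None = None,
) -> list[Variant]:
    """Remove SNVs whose anchored position matches a genotyping-panel marker."""
    kept = [
        v for v in variants if not (v.is_snv and (v.chrom, v.pos) in panel_positions)
    ]
    if report is not None:
        report.record("panel_exclusion", len(variants), len(kept))
    return kept


def sv_support_filter(
    svs: list[Variant],
    min_support: int = 5,
    callable_mask: RegionMask | None = None,
    report: FilterReport | None = None,
) -> list[Variant]:
    """Keep SVs with >= ``min_support`` supporting reads that also lie fully
    within callable regions (when a callable mask is supplied)."""
    kept = []
    for v in svs:
        if v.support_reads is not None and v.support_reads < min_support:
            continue
        if callable_mask is not None:
            passing = mask_filter([v], callable_mask)
            if not passing:
                continue
        kept.append(v)
    if report is not None:
        report.record("sv_support", len(svs), len(kept))
    return kept


def classify_rare_common(variants: list[Variant]) -> pd.DataFrame:
    """Label multi-sample sites rare (alt allele count <= 2), common (>= 3)
    or invariant (count 0), counting het=1 / hom-alt=2 and skipping missing."""
    rows = []
    for v in variants:
        count = sum(
            c.gt.alt_dosage for c in v.calls.values() if c.gt is not Genotype.MISSING
        )
        label = "invariant" if count == 0 else ("rare" if count <= 2 else "common")
        rows.append(
            {"chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
             "alt_allele_count": count, "label": label}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_allele_count", "label"])


@dataclass
class IsolationResult:
    per_line: dict[str, list[Variant]]
    parent_filtered: list[Variant]
    difference_regions: RegionMask
    landrace_labels: pd.DataFrame | None
    parent_report: FilterReport
    line_reports: dict[str, FilterReport]


def run_isolation_pipeline(
    line_variants: dict[str, list[Variant]],
    parent_variants: list[Variant],
    masks: list[RegionMask],
    contigs: dict[str, int],
    panel_positions: set[tuple[str, int]] | None = None,
    landrace_variants: list[Variant] | None = None,
    thresholds: HardFilterThresholds | None = None,
    exclude_low_complexity: bool = False,
) -> IsolationResult:
    """Full two-part isolation: Part 1 on the parent, Part 2 on each line.

    Order of operations: callable masking -> hard filters -> diversity
    windows (parent only) -> build difference regions -> subtract from lines
    -> panel exclusion -> privacy filter; the landrace cohort, when given,
    is labelled rare/common at the end.
    """
    callable_mask = build_callable_mask(masks, contigs, exclude_low_complexity)

    parent_report = FilterReport()
    parent = mask_filter(parent_variants, callable_mask, parent_report)
    parent = hard_filter_snps(parent, thresholds, parent_report)
    parent = diversity_window_filter(parent, report=parent_report)
    diff_regions = build_difference_regions(parent)

    line_reports = {line: FilterReport() for line in line_variants}
    staged = {}
    for line, vs in line_variants.items():
        rep = line_reports[line]
        out = mask_filter(vs, callable_mask, rep)
        out = hard_filter_snps(out, thresholds, rep)
        out = subtract_reference_differences(out, diff_regions, rep)
        out = panel_exclusion(out, panel_positions or set(), rep)
        staged[line] = out
    per_line = privacy_filter(staged, line_reports)

    landrace_labels = None
    if landrace_variants is not None:
        landrace_labels = classify_rare_common(landrace_variants)

    return IsolationResult(
        per_line=per_line,
        parent_filtered=parent,
        difference_regions=diff_regions,
        landrace_labels=landrace_labels,
        parent_report=parent_report,
        line_reports=line_reports,
    )
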