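"""Consequence classification, constraint labelling, load summaries."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from barleymut.effects import (
    EffectAnnotation,
    amino_acid_change_table,
    bonferroni_threshold,
    cc_motif_flag,
    classify_effect,
    correlate_load_phenotype,
    label_constraint,
    load_summary,
    load_windows,
)
from barleymut.models import GeneModel, Variant
from barleymut.spectrum import revcomp


@pytest.fixture()
def toy_gene():
    """Plus-strand gene: ATG GGA CAA TGC TAA with a 60-bp intron after codon 2.

    Layout on a 400-bp chromosome starting at 1-based position 101.
    """
    cds1 = "ATGGGA"  # M G
    intron = "GT" + "A" * 56 + "AG"
    cds2 = "CAATGCTAA"  # Q C *
    gene_seq = cds1 + intron + cds2
    pre = "T" * 100
    post = "A" * (400 - 100 - len(gene_seq))
    genome = {"chr1": pre + gene_seq + post}
    gene = GeneModel(
        "g1", "chr1", 101, 100 + len(gene_seq), "+",
        cds=[(101, 106), (167, 175)],
    )
    return gene, genome


class TestClassifyEffect:
    def test_missense_gga_to_gaa(self, toy_gene):
        gene, genome = toy_gene
        # codon 2 GGA at 104-106; middle base G->A gives GAA (G/E)
        v = Variant("chr1", 105, "G", "A")
        ann = classify_effect(v, [gene], genome)
        assert ann.consequence == "missense"
        assert ann.ref_codon == "GGA" and ann.alt_codon == "GAA"
        assert ann.aa_change == "G/E"

    def test_stop_gained(self, toy_gene):
        gene, genome = toy_gene
        # codon 3 CAA at 167-169; C->T gives TAA
        v = Variant("chr1", 167, "C", "T")
        ann = classify_effect(v, [gene], genome)
        assert ann.consequence == "stop_gained"
        assert ann.aa_change == "Q/*"

    def test_synonymous(self, toy_gene):
        gene, genome = toy_gene
        # codon 2 GGA -> GGG, both glycine
        v = Variant("chr1", 106, "A", "G")
        ann = classify_effect(v, [gene], genome)
        assert ann.consequence == "synonymous"

    def test_start_lost(self, toy_gene):
        gene, genome = toy_gene
        v = Variant("chr1", 101, "A", "G")
        assert classify_effect(v, [gene], genome).consequence == "start_lost"

    def test_stop_lost(self, toy_gene):
        gene, genome = toy_gene
        # stop codon TAA at 173-175 -> CAA
        v = Variant("chr1", 173, "T", "C")
        assert classify_effect(v, [gene], genome).consequence == "stop_lost"

    def test_intron_and_splice(self, toy_gene):
        gene, genome = toy_gene
        assert classify_effect(Variant("chr1", 107, "G", "A"), [gene], genome).consequence == "splice_donor"
        assert classify_effect(Variant("chr1", 166, "G", "A"), [gene], genome).consequence == "splice_acceptor"
        assert classify_effect(Variant("chr1", 130, "A", "C"), [gene], genome).consequence == "intron"

    def test_frameshift_and_inframe(self, toy_gene):
        gene, genome = toy_gene
        two_bp_del = Variant("chr1", 103, "GGG", "G")
        assert classify_effect(two_bp_del, [gene], genome).consequence == "frameshift"
        three_bp_del = Variant("chr1", 102, "TGGG", "T")
        assert classify_effect(three_bp_del, [gene], genome).consequence == "inframe_indel"

    def test_flanks_and_intergenic(self, toy_gene):
        gene, genome = toy_gene
        assert classify_effect(Variant("chr1", 50, "T", "A"), [gene], genome).consequence == "upstream"
        assert classify_effect(Variant("chr1", 300, "A", "T"), [gene], genome).consequence == "downstream"
        lonely = Variant("chr2", 50, "A", "T")
        assert classify_effect(lonely, [gene], genome).consequence == "intergenic"

    def test_minus_strand_mirror_construction(self, toy_gene):
        """A gene and its reverse-complement mirror yield identical
        consequence and amino-acid calls for mirrored variants."""
        gene, genome = toy_gene
        seq = genome["chr1"]
        length = len(seq)
        mirror_genome = {"chr1": revcomp(seq)}
        mirror_gene = GeneModel(
            "g1m", "chr1", length - gene.end + 1, length - gene.start + 1, "-",
            cds=[(length - e + 1, length - s + 1) for s, e in gene.cds],
        )
        for pos, ref, alt in [(105, "G", "A"), (167, "C", "T"), (106, "A", "G"), (101, "A", "G")]:
            fwd = classify_effect(Variant("chr1", pos, ref, alt), [gene], genome)
            mpos = length - pos + 1
            mv = Variant("chr1", mpos, revcomp(ref), revcomp(alt))
            mirror = classify_effect(mv, [mirror_gene], mirror_genome)
            assert mirror.consequence == fwd.consequence
            assert mirror.aa_change == fwd.aa_change

    def test_consequence_partition(self, dataset):
        """Every variant gets exactly one consequence; class counts sum to
        the input size."""
        from collections import Counter

        variants = [v for vs in dataset.lines.values() for v in vs][:2000]
        counts = Counter(
            classify_effect(v, dataset.genes, dataset.genome).consequence
            for v in variants
        )
        assert sum(counts.values()) == len(variants)


class TestCcMotif:
    def test_c_to_t_at_first_c_of_cc(self):
        genome = {"chr1": "AACCAA"}
        assert cc_motif_flag(Variant("chr1", 3, "C", "T"), genome) is True

    def test_g_to_a_at_second_g_of_gg(self):
        genome = {"chr1": "AAGGAA"}
        assert cc_motif_flag(Variant("chr1", 4, "G", "A"), genome) is True

    def test_c_followed_by_a_is_false(self):
        genome = {"chr1": "AACAAA"}
        assert cc_motif_flag(Variant("chr1", 3, "C", "T"), genome) is False

    def test_sequence_edge_false(self):
        genome = {"chr1": "CCC"}
        assert cc_motif_flag(Variant("chr1", 3, "C", "T"), genome) is False
        assert cc_motif_flag(Variant("chr1", 1, "G", "A"), genome) is False


class TestBonferroni:
    @pytest.mark.parametrize(
        "n,displayed",
        [(611, 8.1e-5), (9716, 5.1e-6), (14537, 3.4e-6), (1, 5.0e-2)],
    )
    def test_published_thresholds_reproduced_by_truncation(self, n, displayed):
        exact, shown = bonferroni_threshold(n)
        assert shown == pytest.approx(displayed, rel=1e-9)
        assert exact == pytest.approx(0.05 / n, rel=1e-12)

    def test_truncation_not_rounding(self):
        # 0.05/611 = 8.18e-5 would round to 8.2e-5; truncation gives 8.1e-5
        _, shown = bonferroni_threshold(611)
        assert shown < 0.05 / 611

    def test_strictly_decreasing_in_n(self):
        values = [bonferroni_threshold(n)[0] for n in (1, 10, 100, 1000)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestLabelConstraint:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["p", "n_seqs", "allele_unseen"])

    def test_boundary_p_equal_threshold_tolerated(self):
        exact, _ = bonferroni_threshold(611)
        out = label_constraint(self._calls([(exact, 20, True)]), n_tests=611)
        assert out.loc[0, "label"] == "tolerated"

    def test_failing_auxiliary_flags_tolerated(self):
        out = label_constraint(self._calls([(1e-30, 5, True), (1e-30, 20, False)]), n_tests=611)
        assert (out["label"] == "tolerated").all()

    def test_deleterious_fraction_recovered_exactly(self):
        """A planted 17.9% deleterious fraction among nonsynonymous calls is
        recovered exactly from the labelling rule."""
        rng = np.random.default_rng(0)
        n = 1000
        n_del = 179
        exact, _ = bonferroni_threshold(611)
        p = np.concatenate([
            rng.uniform(0, exact * 0.99, n_del),
            rng.uniform(exact * 1.01, 1.0, n - n_del),
        ])
        calls = pd.DataFrame({"p": p, "n_seqs": 30, "allele_unseen": True})
        out = label_constraint(calls, n_tests=611)
        assert (out["label"] == "deleterious").mean() == pytest.approx(0.179)

    def test_missing_p_skipped_and_counted(self):
        calls = self._calls([(np.nan, 20, True), (1e-10, 20, True)])
        out = label_constraint(calls, n_tests=611)
        assert out.attrs["skipped"] == 1
        assert len(out) == 1


class TestAminoAcidTable:
    def test_published_stratum_percentages(self):
        """Percentage column reproduces count/stratum-total to 2 decimals
        (22 of 155 deleterious changes = 14.19%)."""
        rows = (
            [("G/D",)] * 22 + [("P/S",)] * 20 + [("A/T",)] * 19 + [("A/V",)] * 10
            + [(f"X/{i}",) for i in range(84)]
        )
        frame = pd.DataFrame(rows, columns=["aa_change"])
        frame["label"] = "deleterious"
        frame["stratum"] = "mutated"
        table = amino_acid_change_table(frame)
        top = table.set_index("aa_change")
        assert top.loc["G/D", "count"] == 22
        assert top.loc["G/D", "percent"] == 14.19
        assert top.loc["P/S", "percent"] == 12.90
        assert top.loc["A/T", "percent"] == 12.26  # 19/155, exact two-decimal rounding

    def test_single_change_is_100_percent(self):
        frame = pd.DataFrame(
            [{"aa_change": "A/V", "label": "tolerated", "stratum": "rare"}]
        )
        assert amino_acid_change_table(frame).loc[0, "percent"] == 100.0

    def test_percentages_sum_to_100_per_stratum(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({
            "aa_change": rng.choice(["A/V", "G/D", "P/S", "R/C"], 500),
            "label": rng.choice(["deleterious", "tolerated"], 500),
            "stratum": rng.choice(["mutated", "rare"], 500),
        })
        table = amino_acid_change_table(frame)
        for _, grp in table.groupby(["stratum", "label"]):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=0.05)


class TestLoadWindows:
    def _gene(self):
        return GeneModel("g1", "chr1", 1001, 4000, "+", cds=[(1001, 4000)])

    def test_rate_per_covered_codon(self):
        gene = self._gene()  # 3000 bp CDS = 1000 codons in window 0
        anns = [
            EffectAnnotation(Variant("chr1", 1500, "G", "A"), "missense", "g1"),
            EffectAnnotation(Variant("chr1", 2500, "G", "A"), "missense", "g1"),
        ]
        labels = {a.variant.key: "deleterious" for a in anns}
        frame = load_windows(anns, labels, [gene], {"chr1": 20_000_000}, window_bp=10_000_000)
        assert frame.loc[0, "covered_codons"] == 1000
        assert frame.loc[0, "deleterious_per_codon"] == pytest.approx(0.002)

    def test_empty_annotations_all_zero(self):
        frame = load_windows([], {}, [self._gene()], {"chr1": 10_000_000})
        assert (frame["deleterious"] == 0).all()

    def test_window_without_codons_flagged(self):
        frame = load_windows([], {}, [self._gene()], {"chr1": 20_000_000})
        assert np.isnan(frame.loc[1, "deleterious_per_codon"])

    def test_totals_conserved_under_anchor_shift(self):
        gene = self._gene()
        anns = [
            EffectAnnotation(Variant("chr1", p, "G", "A"), "missense", "g1")
            for p in (1500, 2500, 3500)
        ]
        labels = {a.variant.key: "deleterious" for a in anns}
        small = load_windows(anns, labels, [gene], {"chr1": 4000}, window_bp=1000)
        assert small["deleterious"].sum() == 3
        assert small["covered_codons"].sum() == 1000


class TestCorrelation:
    def test_perfect_anti_order(self):
        r, _ = correlate_load_phenotype([1, 2, 3, 4], [8, 6, 4, 2], method="rank")
        assert r == -1.0

    def test_identical_vectors(self):
        r, _ = correlate_load_phenotype([1, 2, 3], [1, 2, 3], method="rank")
        assert r == 1.0

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate_load_phenotype([1, 1, 1], [1, 2, 3])

    def test_planted_monotone_association_recovered(self):
        rng = np.random.default_rng(2)
        n = 200
        load = rng.normal(size=n)
        phen = -0.4 * load + rng.normal(scale=1.0, size=n)
        r, p = correlate_load_phenotype(load, phen, method="rank")
        assert -0.6 < r < -0.15
        assert p < 0.05


class TestLoadSummary:
    def test_counts_and_ratio(self):
        frame = pd.DataFrame({
            "sample": ["M1"] * 5,
            "consequence": ["missense", "missense", "stop_gained", "synonymous", "intron"],
            "label": ["deleterious", "tolerated", "tolerated", None, None],
        })
        out = load_summary(frame).set_index("sample")
        assert out.loc["M1", "nonsynonymous"] == 3
        assert out.loc["M1", "synonymous"] == 1
        assert out.loc["M1", "deleterious"] == 1
        assert out.loc["M1", "tolerated"] == 2
        assert out.loc["M1", "nsnv_ssnv_ratio"] == 3.0
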