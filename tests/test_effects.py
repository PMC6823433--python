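"""Consequence classification: codon fixtures, positional rules, summaries."""

import numpy as np
import pytest

from conftest import V, matrix_of

from snp2mab.effects import (
    CONSEQUENCES,
    IMPACT_OF,
    SEVERITY_RANK,
    ConsequenceCall,
    classify_consequence,
    impact_summary,
    tabulate_categories,
)
from snp2mab.model import GeneModel

_COMP = str.maketrans("ACGT", "TGCA")


def build_reference():
    seq = list("C" * 12000)
    seq[10:19] = "ATGTACTAA"          # CDS of the forward gene, positions 11-19
    seq[2027:2030] = "GAT"            # codon at 2028-2030 (exon-junction fixture)
    seq[3009:3012] = "ATC"            # 5' UTR positions 3010-3012
    return {"c": "".join(seq)}


REF = build_reference()

GENE_FW = GeneModel("gfw", "c", 5, 40, "+", exons=[(5, 40)], cds=[(11, 19, 0)])
GENE_POS = GeneModel("gpos", "c", 6000, 6400, "+", exons=[(6000, 6400)],
                     cds=[(6000, 6398, 0)])
GENE_POS_REV = GeneModel("gposr", "c", 6000, 6400, "-", exons=[(6000, 6400)],
                         cds=[(6002, 6400, 0)])
GENE_SPLICE = GeneModel("gspl", "c", 1001, 1060, "+",
                        exons=[(1001, 1020), (1041, 1060)])
GENE_SPLICE_REV = GeneModel("gsplr", "c", 1001, 1060, "-",
                            exons=[(1001, 1020), (1041, 1060)])
GENE_JUNCTION = GeneModel("gjun", "c", 2001, 2080, "+",
                          exons=[(2001, 2030), (2051, 2080)],
                          cds=[(2001, 2030, 0), (2051, 2080, 0)])
GENE_UTR = GeneModel("gutr", "c", 3001, 3100, "+", exons=[(3001, 3100)],
                     cds=[(3031, 3099, 0)])


def one_call(pos, ref, alt, gene, **kw):
    v = V("c", pos, ref, (alt,) if isinstance(alt, str) else tuple(alt), [(ref, ref)])
    calls = classify_consequence(v, [gene], REF, **kw)
    assert len(calls) == 1
    return calls[0]


class TestCodonRules:
    @pytest.mark.parametrize(
        "pos, ref, alt, expected, impact",
        [
            (16, "C", "T", "synonymous_variant", "LOW"),    # TAC -> TAT (Tyr)
            (15, "A", "T", "missense_variant", "MODERATE"),  # TAC -> TTC (Phe)
            (16, "C", "A", "stop_gained", "HIGH"),           # TAC -> TAA
            (11, "A", "G", "start_lost", "HIGH"),            # ATG -> GTG
            (18, "A", "C", "stop_lost", "HIGH"),             # TAA -> TCA (Ser)
        ],
    )
    def test_forward_strand_codon_calls(self, pos, ref, alt, expected, impact):
        call = one_call(pos, ref, alt, GENE_FW)
        assert call.consequence == expected
        assert call.impact == impact

    def test_multiallelic_keeps_most_severe(self):
        # C->A is stop_gained, C->T synonymous: stop_gained must win
        call = one_call(16, "C", ("A", "T"), GENE_FW)
        assert call.consequence == "stop_gained"

    def test_reference_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            one_call(16, "G", "A", GENE_FW)

    def test_frame_broken_cds_warns_and_skips(self, caplog):
        gene = GeneModel("gbad", "c", 5, 40, "+", exons=[(5, 40)], cds=[(11, 20, 0)])
        v = V("c", 16, "C", ("T",), [("C", "C")])
        with caplog.at_level("WARNING", logger="snp2mab"):
            classify_consequence(v, [gene], REF)
        assert "not divisible by 3" in caplog.text


class TestPositionalRules:
    def test_upstream_gene_variant_400bp(self):
        call = one_call(5600, "C", "T", GENE_POS)
        assert call.consequence == "upstream_gene_variant"
        assert call.impact == "MODIFIER"

    def test_same_side_is_downstream_for_reverse_gene(self):
        call = one_call(5600, "C", "T", GENE_POS_REV)
        assert call.consequence == "downstream_gene_variant"

    def test_intergenic_beyond_upstream_window(self):
        call = one_call(11500, "C", "T", GENE_POS)
        assert call.consequence == "intergenic_variant"
        assert call.gene_id is None

    def test_upstream_window_is_configurable(self):
        call = one_call(5600, "C", "T", GENE_POS, upstream_bp=300)
        assert call.consequence == "intergenic_variant"

    @pytest.mark.parametrize(
        "pos, gene, expected",
        [
            (1021, GENE_SPLICE, "splice_donor_variant"),
            (1022, GENE_SPLICE, "splice_donor_variant"),
            (1039, GENE_SPLICE, "splice_acceptor_variant"),
            (1040, GENE_SPLICE, "splice_acceptor_variant"),
            (1021, GENE_SPLICE_REV, "splice_acceptor_variant"),
            (1040, GENE_SPLICE_REV, "splice_donor_variant"),
            (1025, GENE_SPLICE, "splice_region_variant"),
            (1030, GENE_SPLICE, "intron_variant"),
        ],
    )
    def test_intron_and_splice_sites(self, pos, gene, expected):
        assert one_call(pos, "C", "T", gene).consequence == expected

    def test_exonic_junction_missense_outranks_splice_region(self):
        call = one_call(2030, "T", "G", GENE_JUNCTION)  # GAT -> GAG, Asp->Glu
        assert call.consequence == "missense_variant"

    def test_exonic_junction_synonymous_yields_splice_region(self):
        call = one_call(2030, "T", "C", GENE_JUNCTION)  # GAT -> GAC, both Asp
        assert call.consequence == "splice_region_variant"


class TestUtrRules:
    def test_premature_start_codon_gain(self):
        call = one_call(3012, "C", "G", GENE_UTR)  # ATC -> ATG in the 5' UTR
        assert call.consequence == "five_prime_UTR_premature_start_codon_gain_variant"
        assert call.impact == "LOW"

    def test_plain_five_prime_utr(self):
        call = one_call(3020, "C", "T", GENE_UTR)
        assert call.consequence == "five_prime_UTR_variant"

    def test_three_prime_utr(self):
        call = one_call(3100, "C", "T", GENE_UTR)
        assert call.consequence == "three_prime_UTR_variant"


class TestStrandSymmetry:
    def mirror(self, seq, pos, ref, alt, gene):
        L = len(seq)
        seq2 = seq.translate(_COMP)[::-1]
        exons2 = sorted((L - e + 1, L - s + 1) for s, e in gene.exons)
        cds2 = sorted((L - e + 1, L - s + 1, 0) for s, e, _ in gene.cds)
        gene2 = GeneModel(
            gene.gene_id + "_m", gene.chrom, L - gene.end + 1, L - gene.start + 1,
            "-" if gene.strand == "+" else "+", exons=exons2, cds=cds2,
        )
        return seq2, L - pos + 1, ref.translate(_COMP), alt.translate(_COMP), gene2

    def test_reverse_complement_preserves_coding_calls(self, rng):
        # CDS segments with in-frame lengths so mirrored phases stay zero
        for trial in range(10):
            codes = rng.integers(0, 4, size=400)
            seq = "".join("ACGT"[c] for c in codes)
            gene = GeneModel("g", "c", 101, 240, "+",
                             exons=[(101, 160), (181, 240)],
                             cds=[(101, 160, 0), (181, 240, 0)])
            pos = int(rng.choice(list(range(101, 161)) + list(range(181, 241))))
            ref = seq[pos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
            fwd = classify_consequence(
                V("c", pos, ref, (alt,), [(ref, ref)]), [gene], {"c": seq}
            )[0]
            seq2, pos2, ref2, alt2, gene2 = self.mirror(seq, pos, ref, alt, gene)
            rev = classify_consequence(
                V("c", pos2, ref2, (alt2,), [(ref2, ref2)]), [gene2], {"c": seq2}
            )[0]
            assert fwd.consequence == rev.consequence


def test_impact_mapping_total_over_enum():
    assert set(IMPACT_OF) == CONSEQUENCES
    assert set(IMPACT_OF.values()) <= {"HIGH", "MODERATE", "LOW", "MODIFIER"}
    assert set(SEVERITY_RANK) == CONSEQUENCES


class TestImpactSummary:
    def test_three_modifier_one_low(self):
        calls = [
            ConsequenceCall("c", i, "A", "G", None, "intergenic_variant", "MODIFIER")
            for i in range(3)
        ] + [ConsequenceCall("c", 9, "A", "G", "g", "synonymous_variant", "LOW")]
        summ = impact_summary(calls)
        assert summ["impact"]["MODIFIER"] == 75.0
        assert summ["impact"]["LOW"] == 25.0
        assert abs(sum(summ["impact"].values()) - 100.0) < 0.05
        assert abs(sum(summ["consequence"].values()) - 100.0) < 0.1

    def test_empty_input_all_zero(self):
        summ = impact_summary([])
        assert all(v == 0.0 for v in summ["impact"].values())


class TestCategoryTable:
    def test_alt_carriers_counted_per_accession(self):
        gene = GeneModel("gmyb", "c", 90, 120, "+", exons=[(90, 120)], category="MYB")
        v = V("c", 100, "A", ("G",),
              [("G", "G"), ("G", "G"), ("A", "A"), ("A", "A"), None])
        m = matrix_of([v], 5, {"c": 1000})
        table = tabulate_categories(m, [gene])
        assert list(table.counts["MYB"]) == [1, 1, 0, 0, 0]
        assert table.category_pct == {"MYB": 100.0}

    def test_callable_mode_counts_any_called_accession(self):
        gene = GeneModel("gmyb", "c", 90, 120, "+", exons=[(90, 120)], category="MYB")
        v = V("c", 100, "A", ("G",), [("G", "G"), ("A", "A"), None])
        m = matrix_of([v], 3, {"c": 1000})
        table = tabulate_categories(m, [gene], mode="callable")
        assert list(table.counts["MYB"]) == [1, 1, 0]

    def test_percentages_sum_to_100_across_categories(self):
        g1 = GeneModel("g1", "c", 90, 120, "+", exons=[(90, 120)], category="MYB")
        g2 = GeneModel("g2", "c", 490, 520, "+", exons=[(490, 520)], category="bHLH")
        vs = [
            V("c", 100, "A", ("G",), [("G", "G")]),
            V("c", 500, "A", ("G",), [("G", "G")]),
            V("c", 510, "A", ("G",), [("A", "A")]),
        ]
        m = matrix_of(vs, 1, {"c": 1000})
        table = tabulate_categories(m, [g1, g2])
        assert table.category_pct == {"MYB": 33.33, "bHLH": 66.67}

    def test_no_tags_warns_and_returns_empty(self, caplog):
        v = V("c", 100, "A", ("G",), [("G", "G")])
        m = matrix_of([v], 1, {"c": 1000})
        gene = GeneModel("g", "c", 90, 120, "+", exons=[(90, 120)])
        with caplog.at_level("WARNING", logger="snp2mab"):
            table = tabulate_categories(m, [gene])
        assert table.counts.empty or table.counts.shape[1] == 0
        assert "no category tags" in caplog.text
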