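"""Coarse variant-consequence classification and SNP-to-gene-category tables.

The classifier assigns each SNP one consequence per overlapping/nearby gene
(most severe wins) using the conventional region/codon rules:

* outside every gene but within ``upstream_bp`` -> upstream/downstream gene
  variant (strand-aware); beyond that -> intergenic;
* intronic: the first/last two intron bases are splice donor/acceptor sites,
  bases 3-8 into the intron and the last ``splice_region_bp`` exonic bases at
  an internal junction form the splice region;
* exonic non-CDS -> 5'/3' UTR (a substitution creating a new ATG in the
  5' UTR is the premature-start-codon-gain case);
* CDS: strand-aware codon translation under the standard code ->
  synonymous / missense / stop gained / stop lost / start lost.

Impact (HIGH/MODERATE/LOW/MODIFIER) is a fixed, total function of the
consequence, following the standard SnpEff assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio.Seq import Seq

from .model import GeneModel, GenotypeMatrix, VariantRecord, round_half_away

logger = logging.getLogger("snp2mab")

__all__ = [
    "CONSEQUENCES",
    "IMPACT_OF",
    "SEVERITY_RANK",
    "ConsequenceCall",
    "classify_consequence",
    "classify_matrix",
    "impact_summary",
    "CategoryTable",
    "tabulate_categories",
]

# most severe first; per-gene tie-breaking follows this order
SEVERITY_ORDER = (
    "stop_gained",
    "stop_lost",
    "start_lost",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "missense_variant",
    "five_prime_UTR_premature_start_codon_gain_variant",
    "splice_region_variant",
    "synonymous_variant",
    "five_prime_UTR_variant",
    "three_prime_UTR_variant",
    "intron_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "intergenic_variant",
)
CONSEQUENCES = frozenset(SEVERITY_ORDER)
SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

IMPACT_OF: dict[str, str] = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "missense_variant": "MODERATE",
    "five_prime_UTR_premature_start_codon_gain_variant": "LOW",
    "splice_region_variant": "LOW",
    "synonymous_variant": "LOW",
    "five_prime_UTR_variant": "MODIFIER",
    "three_prime_UTR_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "upstream_gene_variant": "MODIFIER",
    "downstream_gene_variant": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}
assert set(IMPACT_OF) == CONSEQUENCES

IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ConsequenceCall:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: Optional[str]
    consequence: str
    impact: str


def _most_severe(candidates: Sequence[str]) -> str:
    return min(candidates, key=lambda c: SEVERITY_RANK[c])


def _coding_consequence(
    gene: GeneModel, reference: Mapping[str, str], pos: int, ref: str, alt: str
) -> Optional[str]:
    """Codon-level consequence for a SNP inside the CDS, or None when the CDS
    is frame-broken (warned) or the variant sits in phase-skipped bases."""
    seq = reference[gene.chrom]
    segs = [(s, e) for s, e, _p in gene.cds]
    concat = "".join(seq[s - 1 : e].upper() for s, e in segs)
    # offset of pos within the genomic-order concatenation
    off_g = 0
    for s, e in segs:
        if s <= pos <= e:
            off_g += pos - s
            break
        off_g += e - s + 1
    if gene.strand == "+":
        cds_seq = concat
        offset = off_g
        phase = gene.cds[0][2]
        ref_c, alt_c = ref.upper(), alt.upper()
    else:
        cds_seq = _revcomp(concat)
        offset = len(concat) - 1 - off_g
        phase = gene.cds[-1][2]
        ref_c, alt_c = _revcomp(ref.upper()), _revcomp(alt.upper())
    cds_seq = cds_seq[phase:]
    offset -= phase
    if offset < 0:
        return None
    if len(cds_seq) % 3 != 0:
        logger.warning(
            "gene %s: CDS length %d not divisible by 3, skipped for coding calls",
            gene.gene_id,
            len(cds_seq),
        )
        return None
    codon_idx, within = divmod(offset, 3)
    ref_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    if ref_codon[within] != ref_c:
        raise ValueError(
            f"{gene.chrom}:{pos}: reference mismatch in gene {gene.gene_id} "
            f"(codon has {ref_codon[within]}, variant ref is {ref_c})"
        )
    alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1 :]
    if codon_idx == 0 and ref_codon == "ATG" and alt_codon != "ATG":
        return "start_lost"
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous_variant"
    if alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*":
        return "stop_lost"
    return "missense_variant"


def _utr_side(gene: GeneModel, pos: int) -> Optional[str]:
    """'five' or 'three' for an exonic position outside the CDS span."""
    span = gene.cds_span
    if span is None:
        return None
    lo, hi = span
    if pos < lo:
        return "five" if gene.strand == "+" else "three"
    if pos > hi:
        return "three" if gene.strand == "+" else "five"
    return None


def _five_utr_gain(
    gene: GeneModel, reference: Mapping[str, str], pos: int, ref: str, alt: str
) -> bool:
    """Does the substitution create a new ATG in the 5' UTR (coding strand)?"""
    span = gene.cds_span
    if span is None:
        return False
    lo, hi = span
    seq = reference[gene.chrom]
    if gene.strand == "+":
        parts = [(s, min(e, lo - 1)) for s, e in gene.exons if s < lo]
    else:
        parts = [(max(s, hi + 1), e) for s, e in gene.exons if e > hi]
    parts = [(s, e) for s, e in parts if s <= e]
    utr_g = "".join(seq[s - 1 : e].upper() for s, e in parts)
    idx = 0
    found = False
    for s, e in parts:
        if s <= pos <= e:
            idx += pos - s
            found = True
            break
        idx += e - s + 1
    if not found:
        return False
    if gene.strand == "+":
        utr, i = utr_g, idx
        ref_b, alt_b = ref.upper(), alt.upper()
    else:
        utr = _revcomp(utr_g)
        i = len(utr_g) - 1 - idx
        ref_b, alt_b = _revcomp(ref.upper()), _revcomp(alt.upper())
    utr_alt = utr[:i] + alt_b + utr[i + 1 :]
    for w in (i - 2, i - 1, i):
        if 0 <= w and w + 3 <= len(utr):
            if utr_alt[w : w + 3] == "ATG" and utr[w : w + 3] != "ATG":
                return True
    return False


def _genic_candidates(
    gene: GeneModel,
    reference: Mapping[str, str],
    pos: int,
    ref: str,
    alt: str,
    splice_region_bp: int,
) -> list[str]:
    cands: list[str] = []
    exon_idx = None
    for i, (s, e) in enumerate(gene.exons):
        if s <= pos <= e:
            exon_idx = i
            break
    if exon_idx is None:
        # intronic: locate flanking exons
        left_end = max(e for _s, e in gene.exons if e < pos)
        right_start = min(s for s, _e in gene.exons if s > pos)
        d_left = pos - left_end  # 1 = first intron base after the left exon
        d_right = right_start - pos
        donor_left = gene.strand == "+"
        if d_left <= 2:
            cands.append("splice_donor_variant" if donor_left else "splice_acceptor_variant")
        elif d_right <= 2:
            cands.append("splice_acceptor_variant" if donor_left else "splice_donor_variant")
        elif min(d_left, d_right) <= 8:
            cands.append("splice_region_variant")
        else:
            cands.append("intron_variant")
        return cands
    s, e = gene.exons[exon_idx]
    # exonic splice region: last splice_region_bp bases against an internal junction
    if exon_idx + 1 < len(gene.exons) and e - pos < splice_region_bp:
        cands.append("splice_region_variant")
    if exon_idx > 0 and pos - s < splice_region_bp:
        cands.append("splice_region_variant")
    in_cds = any(cs <= pos <= ce for cs, ce, _p in gene.cds)
    if in_cds:
        coding = _coding_consequence(gene, reference, pos, ref, alt)
        if coding is not None:
            cands.append(coding)
    else:
        side = _utr_side(gene, pos)
        if side == "five":
            if _five_utr_gain(gene, reference, pos, ref, alt):
                cands.append("five_prime_UTR_premature_start_codon_gain_variant")
            else:
                cands.append("five_prime_UTR_variant")
        elif side == "three":
            cands.append("three_prime_UTR_variant")
        elif not cands:
            # gene without CDS annotation: coarse gene-body call
            cands.append("intron_variant")
    return cands


def classify_consequence(
    variant: VariantRecord,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
    upstream_bp: int = 5000,
    splice_region_bp: int = 3,
) -> list[ConsequenceCall]:
    """One ConsequenceCall per (variant, nearby gene); intergenic when no gene
    lies within ``upstream_bp``.  Multiallelic variants are classified per alt
    and the most severe consequence is kept."""
    seq = reference.get(variant.chrom)
    if seq is not None and seq[variant.pos - 1].upper() != variant.ref.upper():
        raise ValueError(
            f"{variant.chrom}:{variant.pos}: reference base "
            f"{seq[variant.pos - 1].upper()} does not match variant ref {variant.ref}"
        )
    calls: list[ConsequenceCall] = []
    for gene in gene_models:
        if gene.chrom != variant.chrom:
            continue
        pos = variant.pos
        if gene.start <= pos <= gene.end:
            per_alt = []
            for alt in variant.alts:
                cands = _genic_candidates(gene, reference, pos, variant.ref, alt, splice_region_bp)
                if cands:
                    per_alt.append((_most_severe(cands), alt))
            if not per_alt:
                continue
            cons, alt = min(per_alt, key=lambda t: SEVERITY_RANK[t[0]])
        elif 0 < gene.start - pos <= upstream_bp:
            cons = "upstream_gene_variant" if gene.strand == "+" else "downstream_gene_variant"
            alt = variant.alts[0]
        elif 0 < pos - gene.end <= upstream_bp:
            cons = "downstream_gene_variant" if gene.strand == "+" else "upstream_gene_variant"
            alt = variant.alts[0]
        else:
            continue
        calls.append(
            ConsequenceCall(
                variant.chrom, variant.pos, variant.ref, alt, gene.gene_id, cons, IMPACT_OF[cons]
            )
        )
    if not calls:
        calls.append(
            ConsequenceCall(
                variant.chrom,
                variant.pos,
                variant.ref,
                variant.alts[0],
                None,
                "intergenic_variant",
                IMPACT_OF["intergenic_variant"],
            )
        )
    return calls


def classify_matrix(
    matrix: GenotypeMatrix,
    gene_models: Sequence[GeneModel],
    reference: Mapping[str, str],
    upstream_bp: int = 5000,
    splice_region_bp: int = 3,
) -> list[ConsequenceCall]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: list[ConsequenceCall] = []
    for v in matrix.variants:
        out.extend(
            classify_consequence(
                v, by_chrom.get(v.chrom, ()), reference, upstream_bp, splice_region_bp
            )
        )
    return out


def impact_summary(calls: Sequence[ConsequenceCall]) -> dict[str, dict[str, float]]:
    """Percentage (2 dp) of calls per impact class and per consequence."""
    n = len(calls)
    by_impact = {imp: 0 for imp in IMPACT_ORDER}
    by_cons = {c: 0 for c in SEVERITY_ORDER}
    for call in calls:
        by_impact[call.impact] += 1
        by_cons[call.consequence] += 1
    if n == 0:
        return {
            "impact": {imp: 0.0 for imp in IMPACT_ORDER},
            "consequence": {c: 0.0 for c in SEVERITY_ORDER},
        }
    return {
        "impact": {imp: round_half_away(100.0 * k / n, 2) for imp, k in by_impact.items()},
        "consequence": {c: round_half_away(100.0 * k / n, 2) for c, k in by_cons.items()},
    }


@dataclass
class CategoryTable:
    """Accession x functional-category counts of SNP-bearing genes."""

    counts: pd.DataFrame  # index: accessions, columns: categories
    category_pct: dict[str, float]  # shares of SNP-category assignments, 2 dp


def tabulate_categories(
    matrix: GenotypeMatrix,
    gene_models: Sequence[GeneModel],
    mode: str = "carrier",
) -> CategoryTable:
    """Count, per accession and gene category, SNPs in tagged genes.

    ``carrier`` (default) counts a SNP for an accession when that accession
    carries the non-reference allele; ``callable`` counts any non-missing
    call (SNP callability rather than alt carriage).
    """
    if mode not in ("carrier", "callable"):
        raise ValueError(f"unknown mode {mode!r}")
    tagged = [g for g in gene_models if g.category]
    categories = sorted({g.category for g in tagged})
    if not categories:
        logger.warning("tabulate_categories: no category tags on any gene")
        return CategoryTable(
            pd.DataFrame(index=list(matrix.accessions), dtype=int), {}
        )
    counts = pd.DataFrame(
        0, index=list(matrix.accessions), columns=categories, dtype=int
    )
    totals = {c: 0 for c in categories}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in tagged:
        by_chrom.setdefault(g.chrom, []).append(g)
    for v in matrix.variants:
        hit_cats = {
            g.category for g in by_chrom.get(v.chrom, ()) if g.start <= v.pos <= g.end
        }
        for cat in hit_cats:
            totals[cat] += 1
            for acc, call in zip(matrix.accessions, v.calls):
                if call is None:
                    continue
                if mode == "callable" or any(a != v.ref for a in call):
                    counts.loc[acc, cat] += 1
    grand = sum(totals.values())
    pct = {
        c: (round_half_away(100.0 * t / grand, 2) if grand else 0.0)
        for c, t in totals.items()
    }
    return CategoryTable(counts, pct)
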