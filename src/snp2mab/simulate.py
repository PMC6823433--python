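"""Seeded generator of synthetic inbred-line panels and KASP call matrices.

The generator emulates the statistical structure the downstream analysis
assumes — a nine-chromosome crop genome, a few dozen highly homozygous
inbred accessions with residual heterozygosity, biallelic SNPs with variable
allele splits and missingness, and position clustering that stresses the
60 bp flank-pruning rule — without claiming biological realism (reference
bases are i.i.d. uniform, genes are placed uniformly without overlap, there
is no linkage disequilibrium).

Every SNP's intended pass/fail for each cascade stage is recorded in a truth
table so filter outputs can be checked against ground truth.  All randomness
flows from a single ``numpy`` generator: the same seed yields byte-identical
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotyping import AlleleCallMatrix
from .model import FilterParams, GeneModel, GenotypeMatrix, VariantRecord

__all__ = [
    "RADISH_CHROM_SIZES_MB",
    "DEFAULT_CATEGORIES",
    "SimulationConfig",
    "simulate_genotype_matrix",
    "simulate_genes",
    "simulate_panel",
    "simulate_kasp_calls",
]

#: per-chromosome assembly sizes (Mb) of the nine-chromosome radish genome
RADISH_CHROM_SIZES_MB = (25.86, 41.50, 28.95, 46.08, 45.34, 53.29, 26.68, 29.11, 37.64)

#: functional-category labels used to tag genes (flowering TF families and
#: flowering-pathway memberships)
DEFAULT_CATEGORIES = (
    "MYB",
    "MADS",
    "AP2/EREB",
    "bHLH",
    "photoperiod",
    "vernalization",
    "autonomous",
    "gibberellin",
    "age",
    "floral_repressor",
    "floral_integrator",
)

_BASES = "ACGT"


@dataclass
class SimulationConfig:
    """Conditions of the synthetic panel.

    The stage-composition knobs (``het_snp_frac``, ``multiallelic_frac``,
    ``monomorphic_frac``, ``high_missing_frac``/``high_missing_rate``) exist
    so that every cascade stage removes a non-trivial share of SNPs, echoing
    the removal profile seen on real transcriptome panels.
    """

    seed: int = 0
    n_chrom: int = 9
    chrom_sizes_mb: tuple[float, ...] = RADISH_CHROM_SIZES_MB
    n_accessions: int = 33
    n_snps: int = 5000
    maf_dist: tuple[float, float] = (0.5, 0.5)  # Beta parameters for allele split
    missing_rate: float = 0.1
    het_rate_range: tuple[float, float] = (0.04, 0.44)
    cluster_frac: float = 0.1
    n_genes: int = 200
    category_labels: tuple[str, ...] = DEFAULT_CATEGORIES
    category_frac: float = 0.7
    het_snp_frac: float = 0.15
    multiallelic_frac: float = 0.04
    monomorphic_frac: float = 0.03
    high_missing_frac: float = 0.08
    high_missing_rate: float = 0.7
    flank_window: int = 60

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.het_rate_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("het_rate_range must lie within [0, 1)")
        if not (0.0 <= self.cluster_frac <= 1.0):
            raise ValueError("cluster_frac must be in [0, 1]")
        if len(self.chrom_sizes_mb) != self.n_chrom:
            raise ValueError("chrom_sizes_mb length must equal n_chrom")

    @property
    def chrom_names(self) -> list[str]:
        return [f"Chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def chrom_sizes_bp(self) -> dict[str, int]:
        return {
            name: int(round(mb * 1_000_000))
            for name, mb in zip(self.chrom_names, self.chrom_sizes_mb)
        }


def _apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment, deterministic."""
    w = np.asarray(weights, dtype=float)
    exact = total * w / w.sum()
    out = np.floor(exact).astype(int)
    order = np.argsort(-(exact - out), kind="stable")
    for i in order[: total - out.sum()]:
        out[i] += 1
    return out.tolist()


def _spaced_positions(
    rng: np.random.Generator, low: int, high: int, n: int, min_gap: int
) -> np.ndarray:
    """n sorted positions in [low, high] with pairwise gaps > min_gap."""
    if n == 0:
        return np.array([], dtype=np.int64)
    span = (high - low) - (n - 1) * (min_gap + 1)
    if span + 1 < n:
        raise ValueError(
            f"cannot place {n} positions with gap {min_gap} in [{low}, {high}]"
        )
    picks: set[int] = set()
    while len(picks) < n:
        for x in rng.integers(0, span + 1, size=n - len(picks)).tolist():
            if len(picks) < n:
                picks.add(int(x))
    u = np.sort(np.fromiter(picks, dtype=np.int64, count=n))
    return low + u + np.arange(n, dtype=np.int64) * (min_gap + 1)


# ---------------------------------------------------------------------------
# Genotype matrix + truth table
# ---------------------------------------------------------------------------


def simulate_genotype_matrix(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Generate the variants-x-accessions call matrix and its truth table.

    Truth columns record each SNP's pass/fail for the per-record stage
    criteria (at the default :class:`FilterParams`) and, for SNPs passing the
    first three, the flank-pruning outcome on the surviving set.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    params = FilterParams(flank_window=config.flank_window)
    sizes = config.chrom_sizes_bp
    names = config.chrom_names
    n_acc = config.n_accessions
    w = config.flank_window

    n_clustered = int(round(config.cluster_frac * config.n_snps))
    n_anchor = config.n_snps - n_clustered
    per_chrom = _apportion(n_anchor, [sizes[c] for c in names])

    anchors: list[tuple[str, int]] = []
    for chrom, n_c in zip(names, per_chrom):
        L = sizes[chrom]
        pos = _spaced_positions(rng, w + 1, L - w, n_c, 2 * w)
        anchors.extend((chrom, int(p)) for p in pos)

    taken: dict[str, set[int]] = {c: set() for c in names}
    for chrom, p in anchors:
        taken[chrom].add(p)
    positions = list(anchors)
    for _ in range(n_clustered):
        for _attempt in range(50):
            chrom, ap = anchors[int(rng.integers(0, len(anchors)))]
            delta = int(rng.integers(1, w + 1)) * (1 if rng.random() < 0.5 else -1)
            p = ap + delta
            if w + 1 <= p <= sizes[chrom] - w and p not in taken[chrom]:
                taken[chrom].add(p)
                positions.append((chrom, p))
                break
        else:
            raise ValueError("could not place clustered SNP; reduce n_snps or cluster_frac")
    positions.sort()

    het_rates = rng.uniform(*config.het_rate_range, size=n_acc)
    accessions = [f"K{i + 1:02d}" for i in range(n_acc)]

    variants: list[VariantRecord] = []
    rows = []
    t_het = config.het_snp_frac
    t_multi = t_het + config.multiallelic_frac
    t_mono = t_multi + config.monomorphic_frac
    for chrom, pos in positions:
        u = rng.random()
        ref_i = int(rng.integers(0, 4))
        alt_i = int((ref_i + rng.integers(1, 4)) % 4)
        ref, alt = _BASES[ref_i], _BASES[alt_i]
        if u < t_het:  # residual heterozygosity breaks the homozygous screen
            p = rng.beta(*config.maf_dist)
            is_alt = rng.random(n_acc) < p
            het = rng.random(n_acc) < het_rates
            if not het.any():
                het[int(rng.integers(0, n_acc))] = True
            calls = [
                (ref, alt) if h else ((alt, alt) if a else (ref, ref))
                for a, h in zip(is_alt, het)
            ]
            alts = (alt,)
        elif u < t_multi:  # third allele breaks the diallelic screen
            alt2 = _BASES[[i for i in range(4) if i not in (ref_i, alt_i)][int(rng.integers(0, 2))]]
            probs = rng.dirichlet((2.0, 1.5, 1.0))
            draw = rng.choice(3, size=n_acc, p=probs)
            allele_of = (ref, alt, alt2)
            calls = [(allele_of[d], allele_of[d]) for d in draw]
            alts = tuple(sorted({alt, alt2}))
        elif u < t_mono:  # no segregation at all
            calls = [(ref, ref)] * n_acc
            alts = (alt,)
        else:  # clean biallelic homozygous SNP, split drawn from the Beta
            p = rng.beta(*config.maf_dist)
            is_alt = rng.random(n_acc) < p
            calls = [((alt, alt) if a else (ref, ref)) for a in is_alt]
            alts = (alt,)
        rate = (
            config.high_missing_rate
            if rng.random() < config.high_missing_frac
            else config.missing_rate
        )
        miss = rng.random(n_acc) < rate
        calls = [None if m else c for c, m in zip(calls, miss)]
        variants.append(VariantRecord(chrom, pos, ref, alts, tuple(calls)))
        rows.append({"snp_id": f"{chrom}_{pos}", "chrom": chrom, "pos": pos})

    matrix = GenotypeMatrix(variants, accessions, dict(sizes))

    # truth: per-record stage criteria evaluated directly on the calls
    truth = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    s1, s2, s3 = [], [], []
    for v in matrix.variants:
        nm = v.non_missing()
        hom = all(a == b for a, b in nm)
        alleles = {a for c in nm for a in c}
        counts: dict[tuple[str, str], int] = {}
        for c in nm:
            counts[c] = counts.get(c, 0) + 1
        s1.append(hom and len(alleles) == 2)
        s2.append(len(nm) >= params.min_distinguishable)
        lo, hi = params.seg_ratio_bounds
        ok3 = False
        if len(counts) >= 2 and nm:
            minor = sorted(counts.values())[0] / len(nm)
            ok3 = lo <= minor <= hi
        s3.append(ok3)
    truth["pass_hom_diallelic"] = s1
    truth["pass_distinguishability"] = s2
    truth["pass_segregation"] = s3
    survivors = truth.pass_hom_diallelic & truth.pass_distinguishability & truth.pass_segregation
    s4 = []
    surv_pos = {
        c: sorted(truth.pos[(truth.chrom == c) & survivors]) for c in names
    }
    for i in range(len(truth)):
        if not survivors.iloc[i]:
            s4.append(False)
            continue
        c, p = truth.chrom.iloc[i], truth.pos.iloc[i]
        close = any(0 < abs(q - p) <= w for q in surv_pos[c])
        s4.append(not close)
    truth["pass_flanking"] = s4
    return matrix, truth


# ---------------------------------------------------------------------------
# Reference + genes
# ---------------------------------------------------------------------------


def simulate_genes(
    config: SimulationConfig, rng: np.random.Generator
) -> list[GeneModel]:
    """Place non-overlapping 1-3-exon genes with in-frame CDS and UTRs."""
    sizes = config.chrom_sizes_bp
    per_chrom = _apportion(config.n_genes, [sizes[c] for c in config.chrom_names])
    genes: list[GeneModel] = []
    gi = 0
    for chrom, n_g in zip(config.chrom_names, per_chrom):
        L = sizes[chrom]
        max_len = 3000
        starts = _spaced_positions(rng, 200, L - max_len - 200, n_g, max_len + 200)
        for gs in starts:
            gi += 1
            n_ex = int(rng.integers(1, 4))
            exon_len = int(rng.integers(250, 500))
            intron_len = int(rng.integers(80, 200))
            exons = []
            cur = int(gs)
            for _ in range(n_ex):
                exons.append((cur, cur + exon_len - 1))
                cur += exon_len + intron_len
            ge = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            total = n_ex * exon_len
            u5 = int(rng.integers(30, 90))
            u3 = int(rng.integers(30, 90))
            cds_len = total - u5 - u3
            u3 += cds_len % 3
            cds_len -= cds_len % 3
            # transcript CDS occupies [u5+1, u5+cds_len]; map back to genome
            tx_exons = exons if strand == "+" else exons[::-1]
            cds: list[tuple[int, int, int]] = []
            consumed = 0
            placed = 0
            for s, e in tx_exons:
                ex_len = e - s + 1
                lo_t = max(u5 + 1, consumed + 1)
                hi_t = min(u5 + cds_len, consumed + ex_len)
                if lo_t <= hi_t:
                    off_lo, off_hi = lo_t - consumed - 1, hi_t - consumed - 1
                    if strand == "+":
                        seg = (s + off_lo, s + off_hi)
                    else:
                        seg = (e - off_hi, e - off_lo)
                    phase = (3 - placed % 3) % 3
                    cds.append((seg[0], seg[1], phase))
                    placed += hi_t - lo_t + 1
                consumed += ex_len
            category = (
                str(rng.choice(list(config.category_labels)))
                if config.category_labels and rng.random() < config.category_frac
                else ""
            )
            genes.append(
                GeneModel(
                    gene_id=f"GENE{gi:05d}",
                    chrom=chrom,
                    start=int(gs),
                    end=int(ge),
                    strand=strand,
                    exons=exons,
                    cds=sorted(cds),
                    category=category,
                )
            )
    return genes


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _impose_codons(seq: bytearray, gene: GeneModel) -> None:
    """Write an ATG start and TAA stop into the reference for this gene."""
    pos_list = [p for s, e, _ in gene.cds for p in range(s, e + 1)]
    if len(pos_list) < 6:
        return
    tx = pos_list if gene.strand == "+" else pos_list[::-1]
    for p, base in zip(tx[:3], "ATG"):
        b = base if gene.strand == "+" else base.translate(_COMPLEMENT)
        seq[p - 1] = ord(b)
    for p, base in zip(tx[-3:], "TAA"):
        b = base if gene.strand == "+" else base.translate(_COMPLEMENT)
        seq[p - 1] = ord(b)


def simulate_panel(config: SimulationConfig, outdir: str):
    """Write ref.fa, genes.gff3, panel.vcf and truth.tsv under ``outdir``.

    Returns ``(matrix, genes, reference, truth, paths)``; deterministic
    (byte-identical files) under a fixed seed.
    """
    import os

    from .io import write_fasta, write_gff, write_vcf

    rng = np.random.default_rng(config.seed)
    matrix, truth = simulate_genotype_matrix(config, rng)
    genes = simulate_genes(config, rng)

    reference: dict[str, str] = {}
    for chrom, L in config.chrom_sizes_bp.items():
        codes = rng.integers(0, 4, size=L)
        seq = bytearray(np.frombuffer(b"ACGT", dtype="S1")[codes].tobytes())
        for g in genes:
            if g.chrom == chrom:
                _impose_codons(seq, g)
        for v in matrix.variants:
            if v.chrom == chrom:
                seq[v.pos - 1] = ord(v.ref)
        reference[chrom] = seq.decode()

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "ref.fa"),
        "gff": os.path.join(outdir, "genes.gff3"),
        "vcf": os.path.join(outdir, "panel.vcf"),
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    write_fasta(reference, paths["fasta"])
    write_gff(genes, paths["gff"])
    write_vcf(matrix, paths["vcf"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return matrix, genes, reference, truth, paths


# ---------------------------------------------------------------------------
# KASP call matrices
# ---------------------------------------------------------------------------


def simulate_kasp_calls(
    n_lines: int = 102,
    n_markers: int = 50,
    n_clusters: int = 3,
    het_range: tuple[float, float] = (0.04, 0.44),
    seed: int = 0,
    flip_rate: float = 0.02,
    missing_rate: float = 0.02,
) -> tuple[AlleleCallMatrix, pd.DataFrame]:
    """Clustered KASP call matrix plus truth (cluster label, het rate per line).

    Lines within a cluster share an AA/BB allele profile up to ``flip_rate``;
    each line's heterozygous-call fraction is drawn from ``het_range``, so
    expected per-line homozygosity is ``100 * (1 - het_rate)``.
    """
    if n_clusters > n_lines:
        raise ValueError("n_clusters cannot exceed n_lines")
    rng = np.random.default_rng(seed)
    prototypes = rng.integers(0, 2, size=(n_clusters, n_markers), dtype=np.int8)
    labels = np.arange(n_lines) % n_clusters
    calls = prototypes[labels].copy()
    flips = rng.random(calls.shape) < flip_rate
    calls[flips] = 1 - calls[flips]
    het_rates = rng.uniform(*het_range, size=n_lines)
    het = rng.random(calls.shape) < het_rates[:, None]
    calls[het] = 2
    miss = rng.random(calls.shape) < missing_rate
    calls[miss] = -1
    lines = [f"L{i + 1:03d}" for i in range(n_lines)]
    markers = [f"M{j + 1:02d}" for j in range(n_markers)]
    truth = pd.DataFrame(
        {"line": lines, "cluster": labels, "het_rate": het_rates}
    )
    return AlleleCallMatrix(lines, markers, calls), truth
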