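"""Five-stage SNP filter cascade with per-stage removal accounting.

Stage order is fixed:

1. ``homozygous_diallelic`` — every non-missing call homozygous, exactly two
   alleles observed across the panel, each carried by at least one accession.
2. ``distinguishability`` — the SNP can tell at least k accessions apart
   (two modes, see :class:`~snp2mab.model.FilterParams`).
3. ``segregation_ratio`` — the minor-genotype frequency among non-missing
   calls lies inside an inclusive window (default 0.3–0.7).
4. ``flanking_prune`` — SNPs with another surviving SNP within the flank
   window (default 60 bp, same chromosome) are removed so that KASP probe
   flanks are clean; removal is symmetric by default.
5. ``mab_select`` — even-spacing panel selection (delegated to
   :func:`snp2mab.panel.select_mab_panel`).

The report mirrors the conventional three-column accounting (retained,
removed, percentage removed at one decimal).
"""

from __future__ import annotations

import hashlib
import logging
from typing import Optional

from scipy.stats import chisquare

from .model import (
    STEP_ORDER,
    FilterParams,
    FilterReport,
    FilterStepResult,
    GenotypeMatrix,
    VariantRecord,
)

logger = logging.getLogger("snp2mab")

__all__ = [
    "filter_homozygous_diallelic",
    "filter_distinguishable",
    "filter_segregation_ratio",
    "prune_flanking",
    "run_cascade",
    "report_to_table",
]


# ---------------------------------------------------------------------------
# Stage predicates
# ---------------------------------------------------------------------------


def is_homozygous_diallelic(v: VariantRecord) -> bool:
    alleles: set[str] = set()
    n_by_allele: dict[str, int] = {}
    for c in v.calls:
        if c is None:
            continue
        if c[0] != c[1]:
            return False
        alleles.add(c[0])
        n_by_allele[c[0]] = n_by_allele.get(c[0], 0) + 1
    return len(alleles) == 2 and all(n >= 1 for n in n_by_allele.values())


def filter_homozygous_diallelic(
    matrix: GenotypeMatrix,
) -> tuple[GenotypeMatrix, FilterStepResult]:
    keep = [v for v in matrix.variants if is_homozygous_diallelic(v)]
    step = FilterStepResult(
        "homozygous_diallelic", len(matrix), len(keep), len(matrix) - len(keep)
    )
    return matrix.subset(keep), step


def _distinguishable(v: VariantRecord, params: FilterParams) -> bool:
    if params.distinguish_mode == "callable":
        return v.n_called() >= params.min_distinguishable
    counts = sorted(v.genotype_class_counts().values())
    if len(counts) < 2:
        return False
    return counts[0] >= params.min_distinguishable


def filter_distinguishable(
    matrix: GenotypeMatrix, params: FilterParams
) -> tuple[GenotypeMatrix, FilterStepResult]:
    if len(matrix) and params.min_distinguishable > len(matrix.accessions):
        raise ValueError(
            f"min_distinguishable={params.min_distinguishable} exceeds "
            f"{len(matrix.accessions)} accessions"
        )
    keep = [v for v in matrix.variants if _distinguishable(v, params)]
    step = FilterStepResult(
        "distinguishability", len(matrix), len(keep), len(matrix) - len(keep)
    )
    return matrix.subset(keep), step


def _seg_ratio_ok(v: VariantRecord, params: FilterParams) -> bool:
    counts = sorted(v.genotype_class_counts().values())
    n = sum(counts)
    if n == 0:
        logger.info("segregation_ratio: %s:%d has no calls, removed", v.chrom, v.pos)
        return False
    if len(counts) < 2:
        return False
    if params.seg_ratio_mode == "chi2":
        # alternative reading: keep SNPs not deviating from 1:1 at alpha
        stat, p = chisquare(counts[-2:])
        return p >= params.seg_ratio_alpha
    lo, hi = params.seg_ratio_bounds
    minor = counts[0] / n
    return lo <= minor <= hi


def filter_segregation_ratio(
    matrix: GenotypeMatrix, params: FilterParams
) -> tuple[GenotypeMatrix, FilterStepResult]:
    keep = [v for v in matrix.variants if _seg_ratio_ok(v, params)]
    step = FilterStepResult(
        "segregation_ratio", len(matrix), len(keep), len(matrix) - len(keep)
    )
    return matrix.subset(keep), step


def prune_flanking(
    matrix: GenotypeMatrix, params: FilterParams
) -> tuple[GenotypeMatrix, FilterStepResult]:
    """Remove SNPs with a same-chromosome neighbour within ``flank_window`` bp.

    Default mode removes *both* members of a close pair (neither has a clean
    probe flank); ``keep_first`` greedily keeps the lower-coordinate member.
    """
    w = params.flank_window
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in matrix.variants:  # matrix is sorted
        by_chrom.setdefault(v.chrom, []).append(v)
    keep: list[VariantRecord] = []
    for chrom_variants in by_chrom.values():
        n = len(chrom_variants)
        if params.prune_mode == "keep_first":
            last_kept: Optional[int] = None
            for v in chrom_variants:
                if last_kept is None or v.pos - last_kept > w:
                    keep.append(v)
                    last_kept = v.pos
            continue
        for i, v in enumerate(chrom_variants):
            close = (i > 0 and v.pos - chrom_variants[i - 1].pos <= w) or (
                i + 1 < n and chrom_variants[i + 1].pos - v.pos <= w
            )
            if not close:
                keep.append(v)
    out = matrix.subset(keep)
    # post-condition asserted on every run: surviving SNPs are well spaced
    prev: dict[str, int] = {}
    for v in out.variants:
        if v.chrom in prev and v.pos - prev[v.chrom] <= w and params.prune_mode == "symmetric":
            raise AssertionError(
                f"flanking prune left {v.chrom}:{prev[v.chrom]} and {v.pos} within {w} bp"
            )
        prev[v.chrom] = v.pos
    step = FilterStepResult(
        "flanking_prune", len(matrix), len(out), len(matrix) - len(out)
    )
    return out, step


# ---------------------------------------------------------------------------
# Cascade driver
# ---------------------------------------------------------------------------


def _digest(matrix: GenotypeMatrix) -> str:
    h = hashlib.sha256()
    h.update(",".join(matrix.accessions).encode())
    for v in matrix.variants:
        h.update(f"{v.chrom}:{v.pos}:{v.ref}:{','.join(v.alts)}".encode())
    return h.hexdigest()[:16]


def run_cascade(matrix: GenotypeMatrix, params: Optional[FilterParams] = None):
    """Apply the five stages in order; return (MarkerPanel, FilterReport).

    Stage 5 selects the evenly spaced MAB panel from the pruned candidates
    using per-chromosome quotas (``params.quotas``, or quotas proportional to
    candidate counts summing to ``params.panel_total``).
    """
    from .panel import default_quotas, select_mab_panel  # avoid import cycle

    params = params or FilterParams()
    digest = _digest(matrix)
    steps: list[FilterStepResult] = []
    m1, s1 = filter_homozygous_diallelic(matrix)
    steps.append(s1)
    m2, s2 = filter_distinguishable(m1, params)
    steps.append(s2)
    m3, s3 = filter_segregation_ratio(m2, params)
    steps.append(s3)
    m4, s4 = prune_flanking(m3, params)
    steps.append(s4)

    if len(m4) == 0:
        from .model import MarkerPanel

        panel = MarkerPanel([])
    else:
        quotas = params.quotas
        if quotas is None:
            counts = {c: sum(1 for v in m4.variants if v.chrom == c) for c in m4.chrom_sizes}
            counts = {c: n for c, n in counts.items() if n > 0}
            quotas = default_quotas(counts, min(params.panel_total, len(m4)))
        panel = select_mab_panel(m4, m4.chrom_sizes, quotas)
    steps.append(
        FilterStepResult("mab_select", len(m4), len(panel), len(m4) - len(panel))
    )
    report = FilterReport(steps, params=params, input_digest=digest)
    assert [s.step_name for s in report.steps] == list(STEP_ORDER)
    return panel, report


def report_to_table(report: FilterReport) -> list[tuple[str, int, int, float]]:
    """Rows of (step, n_retained, n_removed, pct_removed) in cascade order."""
    return [
        (s.step_name, s.n_retained, s.n_removed, s.pct_removed) for s in report.steps
    ]


def report_to_tsv(report: FilterReport, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("step\tn_retained\tn_removed\tpct_removed\n")
        for step, kept, removed, pct in report_to_table(report):
            fh.write(f"{step}\t{kept}\t{removed}\t{pct}\n")
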