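"""Core data model: variants, genotype matrices, filter parameters and reports.

Conventions used throughout the package:

* All genomic coordinates are 1-based inclusive.  BED exports are the only
  0-based half-open surface.
* A genotype call is an *unordered* pair of allele strings (phase is ignored)
  or ``None`` for a missing call.  Missing calls are excluded from every
  denominator unless a function says otherwise.
* Percentages printed in reports are rounded half-away-from-zero, never
  banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "MISSING",
    "round_half_away",
    "VariantRecord",
    "GenotypeMatrix",
    "FilterParams",
    "GeneModel",
    "FilterStepResult",
    "FilterReport",
    "Marker",
    "MarkerPanel",
    "ChromosomeStat",
]

#: Sentinel for a missing genotype call ("./." in VCF).
MISSING = None


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (0.05 -> 0.1, not 0.0)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


Call = Optional[tuple[str, str]]


def normalize_call(call: Call) -> Call:
    """Canonicalise a call as a sorted allele pair; ``None`` stays missing."""
    if call is None:
        return None
    a, b = call
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with per-accession genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    calls: tuple[Call, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} on {self.chrom}")
        if self.ref in self.alts:
            raise ValueError(f"{self.chrom}:{self.pos}: ref allele {self.ref} repeated in alts")
        allowed = {self.ref, *self.alts}
        norm = []
        for c in self.calls:
            c = normalize_call(c)
            if c is not None and not (c[0] in allowed and c[1] in allowed):
                raise ValueError(
                    f"{self.chrom}:{self.pos}: call {c} uses alleles outside {sorted(allowed)}"
                )
            norm.append(c)
        object.__setattr__(self, "calls", tuple(norm))

    # -- call-level summaries used by the filter cascade -------------------

    def non_missing(self) -> list[tuple[str, str]]:
        return [c for c in self.calls if c is not None]

    def n_called(self) -> int:
        return sum(1 for c in self.calls if c is not None)

    def observed_alleles(self) -> set[str]:
        out: set[str] = set()
        for c in self.calls:
            if c is not None:
                out.update(c)
        return out

    def genotype_class_counts(self) -> dict[tuple[str, str], int]:
        counts: dict[tuple[str, str], int] = {}
        for c in self.calls:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        return counts


@dataclass
class GenotypeMatrix:
    """Variants x accessions genotype calls, sorted by (chrom, pos)."""

    variants: list[VariantRecord]
    accessions: list[str]
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variants = sorted(self.variants, key=lambda v: (v.chrom, v.pos))
        seen: set[tuple[str, int]] = set()
        n_acc = len(self.accessions)
        for v in self.variants:
            key = (v.chrom, v.pos)
            if key in seen:
                raise ValueError(f"duplicate variant position {v.chrom}:{v.pos}")
            seen.add(key)
            if len(v.calls) != n_acc:
                raise ValueError(
                    f"{v.chrom}:{v.pos}: {len(v.calls)} calls for {n_acc} accessions"
                )
            size = self.chrom_sizes.get(v.chrom)
            if size is not None and v.pos > size:
                raise ValueError(
                    f"{v.chrom}:{v.pos} beyond chromosome size {size}"
                )

    def __len__(self) -> int:
        return len(self.variants)

    def subset(self, keep: Iterable[VariantRecord]) -> "GenotypeMatrix":
        keep = list(keep)
        return GenotypeMatrix(keep, list(self.accessions), dict(self.chrom_sizes))


@dataclass
class FilterParams:
    """Tunable thresholds of the five-stage filter cascade.

    ``distinguish_mode`` selects between the two defensible readings of the
    "distinguish at least k accessions" criterion: ``callable`` keeps a SNP
    when at least ``min_distinguishable`` accessions have a non-missing call;
    ``minor_class`` requires the smaller genotype class itself to reach k.
    """

    min_distinguishable: int = 15
    distinguish_mode: str = "callable"  # or "minor_class"
    seg_ratio_bounds: tuple[float, float] = (0.3, 0.7)
    flank_window: int = 60
    quotas: Optional[dict[str, int]] = None
    panel_total: int = 298
    prune_mode: str = "symmetric"  # or "keep_first"
    seg_ratio_mode: str = "window"  # or "chi2"
    seg_ratio_alpha: float = 0.05

    def __post_init__(self) -> None:
        lo, hi = self.seg_ratio_bounds
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"seg_ratio_bounds must satisfy 0 < lo < hi < 1, got {lo}, {hi}")
        if self.flank_window < 0:
            raise ValueError("flank_window must be >= 0")
        if self.distinguish_mode not in ("callable", "minor_class"):
            raise ValueError(f"unknown distinguish_mode {self.distinguish_mode!r}")
        if self.prune_mode not in ("symmetric", "keep_first"):
            raise ValueError(f"unknown prune_mode {self.prune_mode!r}")
        if self.quotas is not None and any(q <= 0 for q in self.quotas.values()):
            raise ValueError("quotas must be positive")


@dataclass
class GeneModel:
    """Gene with exon/CDS structure and an optional functional-category tag."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)
    category: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        self.exons = sorted(self.exons)
        prev_end = 0
        for s, e in self.exons:
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted at {s}-{e}")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} outside gene span")
            prev_end = e
        self.cds = sorted(self.cds)
        for s, e, _phase in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValueError(
                    f"gene {self.gene_id}: CDS interval {s}-{e} not contained in any exon"
                )

    @property
    def cds_span(self) -> Optional[tuple[int, int]]:
        if not self.cds:
            return None
        return (self.cds[0][0], self.cds[-1][1])


# ---------------------------------------------------------------------------
# Filter-report accounting
# ---------------------------------------------------------------------------

STEP_ORDER = (
    "homozygous_diallelic",
    "distinguishability",
    "segregation_ratio",
    "flanking_prune",
    "mab_select",
)


@dataclass(frozen=True)
class FilterStepResult:
    """Per-stage accounting row: input = retained + removed."""

    step_name: str
    n_input: int
    n_retained: int
    n_removed: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_retained + self.n_removed:
            raise ValueError(
                f"{self.step_name}: {self.n_input} != {self.n_retained} + {self.n_removed}"
            )

    @property
    def pct_removed(self) -> float:
        if self.n_input == 0:
            return 0.0
        return round_half_away(100.0 * self.n_removed / self.n_input, 1)


@dataclass
class FilterReport:
    """Ordered cascade accounting; stage i+1 input equals stage i retained."""

    steps: list[FilterStepResult]
    params: Optional[FilterParams] = None
    input_digest: str = ""

    def __post_init__(self) -> None:
        for prev, cur in zip(self.steps, self.steps[1:]):
            if cur.n_input != prev.n_retained:
                raise ValueError(
                    f"step {cur.step_name} input {cur.n_input} != "
                    f"previous retained {prev.n_retained}"
                )


# ---------------------------------------------------------------------------
# Marker panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    flank_seq: str = ""  # "...60bp[REF/ALT]60bp..." once extracted
    kasp_selected: bool = False


@dataclass
class MarkerPanel:
    """Ordered, uniquely-identified markers selected for MAB genotyping."""

    markers: list[Marker]

    def __post_init__(self) -> None:
        self.markers = sorted(self.markers, key=lambda m: (m.chrom, m.pos))
        ids = [m.marker_id for m in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker_ids in panel")

    def __len__(self) -> int:
        return len(self.markers)

    def on_chrom(self, chrom: str) -> list[Marker]:
        return [m for m in self.markers if m.chrom == chrom]

    def kasp_markers(self) -> list[Marker]:
        return [m for m in self.markers if m.kasp_selected]


@dataclass(frozen=True)
class ChromosomeStat:
    """Per-chromosome marker count and density (markers per Mb, 2 dp)."""

    chrom: str
    n_markers: int
    size_mb: float
    n_kasp: int = 0

    @property
    def density(self) -> float:
        if self.size_mb <= 0:
            raise ValueError(f"{self.chrom}: size must be positive")
        return round_half_away(self.n_markers / self.size_mb, 2)
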