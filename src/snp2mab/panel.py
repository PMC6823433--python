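"""Even-spacing MAB panel selection, density accounting, KASP flanks, map export.

"Evenly distributed" is made precise as follows: each chromosome of length L
with quota q is split into q equal bins; each bin must receive exactly one
marker, and the assignment of candidate SNPs to bins minimises the total
distance to the bin midpoints (candidates are never reused; a bin with no
local candidate is served by the nearest unused candidate anywhere on the
chromosome).  Ties prefer the lower coordinate, so selection is fully
deterministic.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import (
    ChromosomeStat,
    GenotypeMatrix,
    Marker,
    MarkerPanel,
    round_half_away,
)

__all__ = [
    "default_quotas",
    "select_mab_panel",
    "chromosome_density",
    "extract_flanks",
    "attach_flanks",
    "export_physical_map",
    "select_kasp_subset",
]


def default_quotas(candidate_counts: Mapping[str, int], total: int) -> dict[str, int]:
    """Quotas proportional to per-chromosome candidate counts (largest
    remainder), capped by availability; every chromosome with candidates gets
    at least one marker when the total allows."""
    chroms = sorted(c for c, n in candidate_counts.items() if n > 0)
    if not chroms:
        return {}
    total = min(total, sum(candidate_counts[c] for c in chroms))
    n_all = sum(candidate_counts[c] for c in chroms)
    exact = {c: total * candidate_counts[c] / n_all for c in chroms}
    quotas = {c: min(int(exact[c]), candidate_counts[c]) for c in chroms}
    if total >= len(chroms):
        for c in chroms:
            if quotas[c] == 0:
                quotas[c] = 1
    # distribute the remainder by largest fractional part, then name
    while sum(quotas.values()) < total:
        room = [c for c in chroms if quotas[c] < candidate_counts[c]]
        if not room:
            break
        room.sort(key=lambda c: (-(exact[c] - quotas[c]), c))
        quotas[room[0]] += 1
    while sum(quotas.values()) > total:
        over = sorted(chroms, key=lambda c: (exact[c] - quotas[c], c))
        quotas[over[0]] -= 1
    return {c: q for c, q in quotas.items() if q > 0}


def _marker_alleles(ref: str, alts: Sequence[str], observed: set[str]) -> tuple[str, str]:
    # marker REF is always the genome reference base; ALT is the observed
    # non-reference allele (first declared alt as fallback)
    non_ref = sorted(a for a in observed if a != ref)
    return ref, (non_ref[0] if non_ref else alts[0])


def select_mab_panel(
    candidates: GenotypeMatrix,
    chrom_sizes: Mapping[str, int],
    quotas: Mapping[str, int],
) -> MarkerPanel:
    """Pick ``quotas[c]`` evenly spaced markers per chromosome (see module
    docstring for the optimality criterion).  Raises if a quota exceeds the
    candidates available on that chromosome."""
    by_chrom: dict[str, list] = {}
    for v in candidates.variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    markers: list[Marker] = []
    for chrom in sorted(quotas):
        q = quotas[chrom]
        cands = by_chrom.get(chrom, [])
        if q > len(cands):
            raise ValueError(
                f"quota {q} exceeds {len(cands)} candidates on chromosome {chrom}"
            )
        length = chrom_sizes[chrom]
        positions = np.array([v.pos for v in cands], dtype=np.int64)
        # bin i midpoint = (i + 1/2) * L / q; scale by 2q to stay integral:
        # |2q*pos - (2i+1)*L|, tie-broken toward the lower coordinate.
        base = np.abs(
            2 * q * positions[None, :] - (2 * np.arange(q, dtype=np.int64)[:, None] + 1) * length
        )
        cost = base * (len(cands) + 1) + np.arange(len(cands), dtype=np.int64)[None, :]
        _rows, cols = linear_sum_assignment(cost)
        for j in sorted(cols):
            v = cands[j]
            ref, alt = _marker_alleles(v.ref, v.alts, v.observed_alleles())
            markers.append(
                Marker(f"{chrom}_{v.pos}", chrom, v.pos, ref, alt)
            )
    return MarkerPanel(markers)


def chromosome_density(
    panel: MarkerPanel, chrom_sizes_mb: Mapping[str, float]
) -> list[ChromosomeStat]:
    """Markers-per-Mb per chromosome plus a Total row (density of the sums)."""
    for m in panel.markers:
        if m.chrom not in chrom_sizes_mb:
            raise ValueError(f"marker {m.marker_id} on unknown chromosome {m.chrom}")
    stats = []
    for chrom in sorted(chrom_sizes_mb):
        on_c = panel.on_chrom(chrom)
        stats.append(
            ChromosomeStat(
                chrom,
                len(on_c),
                chrom_sizes_mb[chrom],
                n_kasp=sum(1 for m in on_c if m.kasp_selected),
            )
        )
    stats.append(
        ChromosomeStat(
            "Total",
            len(panel),
            round(sum(chrom_sizes_mb.values()), 6),
            n_kasp=len(panel.kasp_markers()),
        )
    )
    return stats


def extract_flanks(
    reference: Mapping[str, str],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    flank: int = 60,
) -> str:
    """KASP flank string: ``flank`` bases either side with ``[REF/ALT]`` at the
    variant (string index ``flank``).  Coordinates 1-based."""
    seq = reference[chrom]
    if pos - flank < 1 or pos + flank > len(seq):
        raise ValueError(
            f"{chrom}:{pos}: too close to chromosome end for a {flank} bp flank"
        )
    genome_base = seq[pos - 1].upper()
    if genome_base != ref.upper():
        raise ValueError(
            f"{chrom}:{pos}: reference mismatch, expected {ref} but observed {genome_base}"
        )
    up = seq[pos - 1 - flank : pos - 1].upper()
    down = seq[pos : pos + flank].upper()
    return f"{up}[{ref.upper()}/{alt.upper()}]{down}"


def attach_flanks(
    panel: MarkerPanel, reference: Mapping[str, str], flank: int = 60
) -> MarkerPanel:
    markers = [
        Marker(
            m.marker_id,
            m.chrom,
            m.pos,
            m.ref,
            m.alt,
            flank_seq=extract_flanks(reference, m.chrom, m.pos, m.ref, m.alt, flank),
            kasp_selected=m.kasp_selected,
        )
        for m in panel.markers
    ]
    return MarkerPanel(markers)


def export_physical_map(
    panel: MarkerPanel,
    chrom_sizes: Mapping[str, int],
    bed_path: str,
    map_path: str,
) -> None:
    """BED (0-based half-open) plus a MapChart-style per-chromosome position
    table; KASP-selected markers are flagged in both."""
    from .io import write_bed

    write_bed(panel, bed_path)
    with open(map_path, "w") as fh:
        fh.write("chrom\tmarker_id\tposition\tkasp_selected\n")
        for chrom in sorted(chrom_sizes):
            for m in panel.on_chrom(chrom):
                fh.write(
                    f"{chrom}\t{m.marker_id}\t{m.pos}\t{1 if m.kasp_selected else 0}\n"
                )


def select_kasp_subset(
    panel: MarkerPanel,
    n_total: int = 50,
    per_chrom_range: tuple[int, int] = (4, 7),
    seed: int = 0,
) -> MarkerPanel:
    """Seeded random draw of KASP validation markers: per-chromosome counts
    inside ``per_chrom_range`` summing to ``n_total``."""
    lo, hi = per_chrom_range
    chroms = sorted({m.chrom for m in panel.markers})
    avail = {c: len(panel.on_chrom(c)) for c in chroms}
    max_total = sum(min(hi, avail[c]) for c in chroms)
    if not (len(chroms) * lo <= n_total <= max_total) or any(avail[c] < lo for c in chroms):
        raise ValueError(
            f"cannot draw {n_total} markers with {lo}-{hi} per chromosome from "
            f"{len(chroms)} chromosomes (availability {avail})"
        )
    rng = np.random.default_rng(seed)
    counts = {c: lo for c in chroms}
    while sum(counts.values()) < n_total:
        room = [c for c in chroms if counts[c] < min(hi, avail[c])]
        counts[rng.choice(room)] += 1
    selected: set[str] = set()
    for c in chroms:
        ids = [m.marker_id for m in panel.on_chrom(c)]
        selected.update(rng.choice(ids, size=counts[c], replace=False))
    markers = [
        Marker(
            m.marker_id,
            m.chrom,
            m.pos,
            m.ref,
            m.alt,
            flank_seq=m.flank_seq,
            kasp_selected=m.marker_id in selected,
        )
        for m in panel.markers
    ]
    return MarkerPanel(markers)
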