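"""Readers and writers: VCF, FASTA, GFF3, marker/call tables, BED, JSON report.

VCF is the canonical variant input (upstream read processing and variant
calling are out of scope).  Reading goes through cyvcf2/htslib; writing emits
plain VCF v4.2 text so that identical inputs produce byte-identical files,
which the determinism guarantees rely on.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Mapping, Optional, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .model import (
    GeneModel,
    GenotypeMatrix,
    MarkerPanel,
    VariantRecord,
)

logger = logging.getLogger("snp2mab")

__all__ = [
    "VcfParseError",
    "read_vcf",
    "write_vcf",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "write_marker_table",
    "write_bed",
    "write_report_json",
]


class VcfParseError(ValueError):
    pass


def read_vcf(path: str, chrom_sizes: Optional[Mapping[str, int]] = None) -> GenotypeMatrix:
    """Load GT calls for all samples from a (plain or bgzipped) VCF.

    Only single-nucleotide records are kept; skipped non-SNV records are
    counted and logged.  ``./.`` becomes the missing call.  Multiallelic SNVs
    are preserved as-is (the diallelic filter removes them later, so the
    cascade accounting sees them).
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # htslib raises plain Exceptions
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF has no samples")
    variants: list[VariantRecord] = []
    n_skipped = 0
    try:
        for i, rec in enumerate(vcf):
            alts = tuple(rec.ALT)
            if len(rec.REF) != 1 or not alts or any(len(a) != 1 or not a.isalpha() for a in alts):
                n_skipped += 1
                continue
            calls = []
            for g in rec.genotypes:
                a1, a2 = g[0], g[1]
                if a1 < 0 or a2 < 0:
                    calls.append(None)
                else:
                    alleles = (rec.REF,) + alts
                    calls.append((alleles[a1], alleles[a2]))
            variants.append(
                VariantRecord(rec.CHROM, rec.POS, rec.REF, alts, tuple(calls))
            )
    except Exception as exc:
        raise VcfParseError(
            f"{path}: malformed VCF near record {len(variants) + n_skipped + 1}: {exc}"
        ) from exc
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-SNV record(s)", path, n_skipped)
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    return GenotypeMatrix(variants, samples, sizes)


def write_vcf(matrix: GenotypeMatrix, path: str) -> None:
    """Write a minimal, deterministic VCF v4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in sorted(matrix.chrom_sizes):
            fh.write(f"##contig=<ID={chrom},length={matrix.chrom_sizes[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(matrix.accessions) + "\n")
        for v in matrix.variants:
            alleles = (v.ref,) + v.alts
            idx = {a: i for i, a in enumerate(alleles)}
            gts = []
            for c in v.calls:
                if c is None:
                    gts.append("./.")
                else:
                    i, j = sorted((idx[c[0]], idx[c[1]]))
                    gts.append(f"{i}/{j}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{','.join(v.alts)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_fasta(path: str) -> dict[str, str]:
    """Load a reference FASTA as {chrom: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff(path: str, category_key: str = "note") -> list[GeneModel]:
    """Parse gene models (gene/mRNA/exon/CDS) from GFF3.

    The functional-category tag is read from ``category_key`` on the gene
    feature (case-insensitive lookup; absent -> empty string).  A CDS interval
    that falls outside every exon raises, naming the gene.
    """
    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        category = ""
        for key in (category_key, category_key.capitalize(), category_key.lower()):
            if key in g.attributes:
                category = g.attributes[key][0]
                break
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int, int]] = []
        for child in db.children(g, order_by="start"):
            if child.featuretype == "exon":
                exons.append((child.start, child.end))
            elif child.featuretype == "CDS":
                phase = int(child.frame) if child.frame not in (None, ".") else 0
                cds.append((child.start, child.end, phase))
        if not exons:
            exons = [(g.start, g.end)]
        try:
            genes.append(
                GeneModel(
                    gene_id=g.id,
                    chrom=g.seqid,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    exons=sorted(set(exons)),
                    cds=sorted(set(cds)),
                    category=category,
                )
            )
        except ValueError as exc:
            raise ValueError(str(exc)) from exc
    return genes


def write_gff(genes: Sequence[GeneModel], path: str, category_key: str = "note") -> None:
    """Emit gene/mRNA/exon/CDS features as GFF3 (deterministic order)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            attrs = f"ID={g.gene_id}"
            if g.category:
                attrs += f";{category_key}={g.category}"
            fh.write(
                f"{g.chrom}\tsnp2mab\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsnp2mab\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsnp2mab\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e, phase) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tsnp2mab\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Marker tables, BED, report JSON
# ---------------------------------------------------------------------------

MARKER_TABLE_COLUMNS = ("marker_id", "chrom", "pos", "ref", "alt", "flank_with_brackets")


def write_marker_table(panel: MarkerPanel, path: str) -> None:
    """TSV of panel markers with the bracketed KASP flank string."""
    if not len(panel):
        raise ValueError("cannot write an empty marker panel")
    with open(path, "w") as fh:
        fh.write("\t".join(MARKER_TABLE_COLUMNS) + "\n")
        for m in panel.markers:
            fh.write(
                f"{m.marker_id}\t{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t{m.flank_seq}\n"
            )


def write_bed(panel: MarkerPanel, path: str) -> None:
    """One 0-based half-open interval per marker; score 1 flags KASP markers."""
    with open(path, "w") as fh:
        for m in panel.markers:
            fh.write(
                f"{m.chrom}\t{m.pos - 1}\t{m.pos}\t{m.marker_id}\t"
                f"{1 if m.kasp_selected else 0}\n"
            )


def write_report_json(report, path: str) -> None:
    from .filters import report_to_table  # local import to avoid a cycle

    rows = report_to_table(report)
    payload = {
        "steps": [
            {
                "step": r[0],
                "n_retained": r[1],
                "n_removed": r[2],
                "pct_removed": r[3],
            }
            for r in rows
        ],
        "input_digest": report.input_digest,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
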