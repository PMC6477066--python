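"""Readers and writers for the standard formats the pipeline speaks.

FASTA goes through Bio.SeqIO, GFF3 reading through gffutils and VCF reading
through pysam; writing is plain-text serialisation in the matching
conventions (1-based inclusive coordinates, VCF-anchored indels, CDS
phase computed cumulatively). Pooled allele depths live in a standard
per-sample ``AD`` FORMAT field; the simulation truth labels variants with an
``ORIGIN`` INFO tag.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, Variant
from .rnaseq import CountMatrix
from .snpindex import PooledAlleleCount, SnpIndexRecord

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(reference: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(reference.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Serialise gene models as gene/mRNA/exon/CDS features."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            base = f"{g.chrom}\tcausalmap\t"
            fh.write(
                f"{base}gene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{base}mRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(f"{base}exon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n")
            phase = 0
            cds_tx = g.cds if g.strand == "+" else tuple(reversed(g.cds))
            for s, e in cds_tx:
                fh.write(f"{base}CDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\tParent={mrna}\n")
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def read_gff3(path) -> List[GeneModel]:
    """Load gene models (one mRNA per gene assumed) via gffutils."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    genes = []
    for gene in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            break
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(sorted(exons)),
                cds=tuple(sorted(cds)),
            )
        )
    return sorted(genes, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _vcf_header(reference: Optional[Mapping[str, str]], sample: Optional[str]) -> str:
    lines = ["##fileformat=VCFv4.2", "##source=causalmap"]
    for chrom, seq in sorted((reference or {}).items()):
        lines.append(f"##contig=<ID={chrom},length={len(seq)}>")
    lines.append('##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Simulated variant origin">')
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency (intra-cultivar)">')
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">'
        )
        cols += f"\tFORMAT\t{sample}"
    return "\n".join(lines) + "\n" + cols + "\n"


def _info(v: Variant) -> str:
    parts = [f"ORIGIN={v.origin}"]
    if v.pop_freq is not None:
        parts.append(f"AF={v.pop_freq:.4f}")
    return ";".join(parts)


def write_vcf(variants: Sequence[Variant], path, reference=None) -> None:
    """Write a truth-set VCF with ORIGIN labels and no samples."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(reference, sample=None))
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_info(v)}\n")


def write_pooled_vcf(
    counts: Sequence[PooledAlleleCount], path, reference=None, sample: str = "bulk"
) -> None:
    """Write bulk variant calls with per-allele read depths (AD)."""
    with open(path, "w") as fh:
        fh.write(_vcf_header(reference, sample=sample))
        for c in sorted(counts, key=lambda c: (c.variant.chrom, c.variant.pos)):
            v = c.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t{_info(v)}\t"
                f"GT:AD\t./.:{c.ref_reads},{c.alt_reads}\n"
            )


def read_vcf(path) -> List[Variant]:
    """Read variants (first ALT allele) with their ORIGIN labels if present."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            origin = rec.info.get("ORIGIN", "unknown")
            af = rec.info.get("AF")
            if isinstance(af, tuple):  # Number=A fields come back per-allele
                af = af[0]
            out.append(
                Variant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    origin=origin,
                    pop_freq=float(af) if af is not None else None,
                )
            )
    return out


def read_pooled_vcf(path, sample: Optional[str] = None) -> List[PooledAlleleCount]:
    """Read per-variant allele depths from a VCF with an AD FORMAT field."""
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        if sample is None:
            sample = list(vcf.header.samples)[0]
        for rec in vcf:
            ad = rec.samples[sample]["AD"]
            origin = rec.info.get("ORIGIN", "unknown")
            out.append(
                PooledAlleleCount(
                    variant=Variant(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=rec.alts[0], origin=origin
                    ),
                    ref_reads=int(ad[0]),
                    alt_reads=int(ad[1]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def write_genotype_table(table, calls_path, panel_path) -> None:
    frame = table.calls.copy()
    frame.insert(0, "phenotype", table.phenotype)
    frame.to_csv(calls_path, sep="\t", index_label="individual")
    table.panel.to_csv(panel_path, sep="\t", index_label="marker_id")


def read_genotype_table(calls_path, panel_path, chrom_lengths=None):
    from .simulate import GenotypeTable  # local import to avoid a cycle

    frame = pd.read_csv(calls_path, sep="\t", index_col="individual", dtype=object)
    phenotype = frame.pop("phenotype")
    panel = pd.read_csv(panel_path, sep="\t", index_col="marker_id")
    return GenotypeTable(
        calls=frame, phenotype=phenotype, panel=panel, chrom_lengths=chrom_lengths
    )


def write_snp_index_records(records: Sequence[SnpIndexRecord], path) -> None:
    rows = [
        {
            "chrom": r.variant.chrom,
            "pos": r.variant.pos,
            "ref": r.variant.ref,
            "alt": r.variant.alt,
            "origin": r.variant.origin,
            "alt_reads": round(r.index * r.depth) if r.defined else 0,
            "depth": r.depth,
            "snp_index": r.index,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_count_matrix(cm: CountMatrix, counts_path, lengths_path, groups_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.lengths.to_csv(lengths_path, sep="\t", index_label="gene_id", header=["length_bp"])
    cm.groups.to_csv(groups_path, sep="\t", index_label="sample", header=["group"])


def read_count_matrix(counts_path, lengths_path, groups_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id")["length_bp"]
    groups = pd.read_csv(groups_path, sep="\t", index_col="sample")["group"]
    return CountMatrix(counts=counts, lengths=lengths, groups=groups)
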