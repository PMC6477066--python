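"""Mapping-by-sequencing on a phenotype-selected bulk.

The SNP/Indel index of a variant is the proportion of sequenced reads in
the pooled bulk that carry the mutant allele. At a locus homozygous in every
pooled plant the index is ~1; at loci unlinked to the selected phenotype it
drifts around 0.5 in an F2 bulk. Candidate lesions are variants with a high
index, reliable depth (>= 10 reads by default), positions inside the mapped
candidate interval, and membership in a coding region — after known
intra-cultivar polymorphisms have been subtracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .models import GeneModel, Variant

__all__ = [
    "PooledAlleleCount",
    "SnpIndexRecord",
    "FilterLog",
    "CandidateGene",
    "compute_snp_index",
    "subtract_intracultivar",
    "filter_candidates",
    "variants_to_genes",
]


@dataclass(frozen=True)
class PooledAlleleCount:
    """Read support for one variant in a pooled bulk."""

    variant: Variant
    alt_reads: int  # reads carrying the mutant allele
    ref_reads: int  # reads carrying the WT allele

    def __post_init__(self) -> None:
        if self.alt_reads < 0 or self.ref_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.alt_reads + self.ref_reads


@dataclass(frozen=True)
class SnpIndexRecord:
    """A variant with its SNP/Indel index and filter flags."""

    variant: Variant
    index: float  # NaN when depth is zero
    depth: int
    passes_depth: Optional[bool] = None
    passes_index: Optional[bool] = None
    in_interval: Optional[bool] = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.index)


def compute_snp_index(counts: PooledAlleleCount) -> SnpIndexRecord:
    """index = mutant reads / total reads; zero-depth records are flagged NaN."""
    depth = counts.depth
    index = counts.alt_reads / depth if depth > 0 else float("nan")
    return SnpIndexRecord(variant=counts.variant, index=index, depth=depth)


def subtract_intracultivar(
    records: Sequence[SnpIndexRecord],
    background: Iterable[Variant],
) -> Tuple[List[SnpIndexRecord], List[str]]:
    """Remove records whose variant exactly matches a background polymorphism.

    Matching is on (chromosome, position, ref, alt) after the caller's
    left-normalisation; a record sharing only the position with a background
    variant is retained and reported in the warning list, so distinct
    overlapping alleles are never silently discarded. Idempotent.
    """
    keys = set()
    positions = set()
    for v in background:
        keys.add(v.key)
        positions.add((v.chrom, v.pos))
    kept, warnings = [], []
    for rec in records:
        v = rec.variant
        if v.key in keys:
            continue
        if (v.chrom, v.pos) in positions:
            warnings.append(
                f"{v.chrom}:{v.pos} {v.ref}>{v.alt} shares a position with a "
                "background variant but differs in allele; retained"
            )
        kept.append(rec)
    return kept, warnings


@dataclass
class FilterLog:
    """Per-criterion counts for one pass of :func:`filter_candidates`."""

    n_input: int = 0
    n_fail_depth: int = 0
    n_fail_index: int = 0
    n_outside_interval: int = 0
    n_passed: int = 0


def filter_candidates(
    records: Sequence[SnpIndexRecord],
    min_depth: int = 10,
    min_index: float = 0.9,
    interval=None,
) -> Tuple[List[SnpIndexRecord], FilterLog]:
    """Keep records with depth >= min_depth, index >= min_index, in interval.

    The three criteria are evaluated independently so the log reports how
    many records fail each one; a record must satisfy all of them (and have
    a defined index) to survive. ``interval`` is any object with ``chrom``,
    ``left`` and ``right`` attributes, or None for genome-wide mode.
    """
    if min_depth < 0 or not 0.0 <= min_index <= 1.0:
        raise ValueError("thresholds out of range")
    log = FilterLog(n_input=len(records))
    survivors = []
    for rec in records:
        ok_depth = rec.depth >= min_depth
        ok_index = rec.defined and rec.index >= min_index
        if interval is None:
            ok_pos = True
        else:
            v = rec.variant
            ok_pos = v.chrom == interval.chrom and interval.left <= v.pos <= interval.right
        log.n_fail_depth += not ok_depth
        log.n_fail_index += not ok_index
        log.n_outside_interval += not ok_pos
        rec = replace(rec, passes_depth=ok_depth, passes_index=ok_index, in_interval=ok_pos)
        if ok_depth and ok_index and ok_pos:
            survivors.append(rec)
    log.n_passed = len(survivors)
    return survivors, log


@dataclass
class CandidateGene:
    """A gene carrying one or more candidate variants in its CDS."""

    gene: GeneModel
    records: List[SnpIndexRecord] = field(default_factory=list)

    @property
    def gene_id(self) -> str:
        return self.gene.gene_id


def _touches_cds(variant: Variant, gene: GeneModel) -> bool:
    s, e = variant.affected_span()
    for cs, ce in gene.cds:
        if variant.kind == "insertion":
            if cs <= variant.pos < ce:
                return True
        elif s <= ce and cs <= e:
            return True
    return False


def variants_to_genes(
    records: Sequence[SnpIndexRecord],
    genes: Sequence[GeneModel],
) -> List[CandidateGene]:
    """Assign each variant to the genes whose CDS it touches.

    A variant is attached to a gene iff its affected bases overlap a CDS
    interval of that gene (the coding-region rule: intronic and intergenic
    variants are assigned to no gene). Genes are de-duplicated; several
    variants may attach to one gene. Output order follows genomic position.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    hits: Dict[str, CandidateGene] = {}
    for rec in records:
        for g in by_chrom.get(rec.variant.chrom, []):
            if _touches_cds(rec.variant, g):
                hits.setdefault(g.gene_id, CandidateGene(gene=g)).records.append(rec)
    return sorted(hits.values(), key=lambda c: (c.gene.chrom, c.gene.start))
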