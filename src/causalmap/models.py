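"""Core genomic value types shared across the toolkit.

Coordinate conventions (used everywhere in this package):

* positions are 1-based and intervals are inclusive on both ends, following
  GFF3 and VCF;
* indels are anchored on one shared leading reference base, VCF style, so a
  2 bp deletion has a 3 bp reference allele and a 1 bp alternate allele;
* a :class:`GeneModel`'s CDS excludes the stop codon, so a CDS of 2871 bp
  encodes exactly 957 amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class ModelError(ValueError):
    """A gene model violates a structural invariant."""


class PlacementError(ValueError):
    """A requested variant cannot be placed where asked."""


Interval = Tuple[int, int]


def _check_intervals(ivs: Sequence[Interval], what: str) -> None:
    prev_end = 0
    for s, e in ivs:
        if s < 1 or e < s:
            raise ModelError(f"{what} interval ({s}, {e}) is malformed")
        if s <= prev_end:
            raise ModelError(f"{what} intervals overlap or are unsorted at ({s}, {e})")
        prev_end = e


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand, exon and CDS intervals on one chromosome.

    Exon and CDS intervals are stored in ascending genomic order regardless
    of strand; strand is applied when the CDS is extracted and translated.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Interval, ...]
    cds: Tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        object.__setattr__(self, "exons", tuple(tuple(iv) for iv in self.exons))
        object.__setattr__(self, "cds", tuple(tuple(iv) for iv in self.cds))
        _check_intervals(self.exons, "exon")
        _check_intervals(self.cds, "CDS")
        for cs, ce in self.cds:
            if not any(es <= cs and ce <= ee for es, ee in self.exons):
                raise ModelError(
                    f"{self.gene_id}: CDS interval ({cs}, {ce}) not contained in any exon"
                )
        if self.cds and self.cds_length % 3 != 0:
            raise ModelError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    def contains(self, pos: int) -> bool:
        """True if *pos* falls within the gene span (first to last exon)."""
        return self.start <= pos <= self.end

    def overlaps(self, left: int, right: int) -> bool:
        """Closed-interval overlap of the gene span with [left, right]."""
        return self.start <= right and left <= self.end


@dataclass(frozen=True)
class Variant:
    """A SNP or indel in VCF-anchored representation.

    ``origin`` labels where the allele comes from in a simulation: the
    planted causal lesion, a mutagen-induced background change homozygous in
    the mutant parent, or a pre-existing intra-cultivar polymorphism
    (``pop_freq`` gives its allele frequency among cultivar individuals).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    origin: str = "unknown"
    pop_freq: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.pos < 1:
            raise ValueError(f"position {self.pos} is not 1-based")
        if len(self.ref) != len(self.alt) and self.ref[0] != self.alt[0]:
            raise ValueError(
                f"indel at {self.chrom}:{self.pos} must share its anchor base "
                f"({self.ref!r} vs {self.alt!r})"
            )

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt):
            return "snp" if len(self.ref) == 1 else "mnp"
        return "deletion" if len(self.ref) > len(self.alt) else "insertion"

    @property
    def net_length(self) -> int:
        """Length change introduced downstream (alt minus ref length)."""
        return len(self.alt) - len(self.ref)

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference position covered by the reference allele."""
        return self.pos + len(self.ref) - 1

    def affected_span(self) -> Interval:
        """Genomic bases whose content changes.

        SNP/MNP: the substituted bases. Deletion: the deleted bases (the
        anchor itself is untouched). Insertion: degenerate span at the anchor;
        callers should treat the insertion point as lying between ``pos`` and
        ``pos + 1``.
        """
        if self.kind in ("snp", "mnp"):
            return (self.pos, self.end)
        if self.kind == "deletion":
            return (self.pos + 1, self.end)
        return (self.pos, self.pos)


def left_normalize(variant: Variant, chrom_seq: str) -> Variant:
    """Left-align and trim an indel against its chromosome sequence.

    SNPs are returned unchanged. The standard parsimony/left-shift algorithm:
    trim shared trailing bases, trim shared leading bases (keeping one
    anchor), then shift left while the trailing base matches the base before
    the current anchor.
    """
    if variant.kind == "snp":
        return variant
    pos, ref, alt = variant.pos, variant.ref, variant.alt
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        pos += 1
        ref, alt = ref[1:], alt[1:]
    while pos > 1 and ref[-1] == alt[-1]:
        prev = chrom_seq[pos - 2]
        pos -= 1
        ref = prev + ref[:-1]
        alt = prev + alt[:-1]
    if variant.ref == ref and variant.alt == alt and variant.pos == pos:
        return variant
    return replace(variant, pos=pos, ref=ref, alt=alt)
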