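"""Variant effect classification and truncation prediction.

Variants are classified against UTR-aware gene models by codon comparison
(SNPs) or frame arithmetic (indels). For frameshifts the mutated CDS is
re-translated from the start codon — continuing past the annotated CDS end
into downstream transcript/genomic sequence when the native stop is lost —
to locate the first stop codon of the shifted frame. The stop position is
reported as a 1-based codon index in the mutated frame, so a premature stop
at codon 494 leaves a truncated protein of 493 residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from Bio.Seq import Seq

from .models import GeneModel, Variant, revcomp

__all__ = [
    "EffectCall",
    "CoordinateShift",
    "ReferenceMismatchError",
    "translate_cds",
    "apply_variant",
    "classify_effect",
]

#: ranking weight used to prioritise candidate lesions
SEVERITY = {
    "frameshift": 4,
    "nonsense": 4,
    "stop_lost_extension": 3,
    "missense": 2,
    "in_frame_indel": 1,
    "synonymous": 0,
    "intronic": 0,
    "intergenic": 0,
}


class ReferenceMismatchError(ValueError):
    """The variant's reference allele disagrees with the genome sequence."""


@dataclass(frozen=True)
class CoordinateShift:
    """Coordinate lift from reference to mutated sequence for one variant.

    Positions up to the anchor are unchanged; positions beyond the
    reference allele shift by (alt length - ref length); positions inside a
    deleted span collapse onto the anchor.
    """

    pos: int
    ref_len: int
    alt_len: int

    @property
    def delta(self) -> int:
        return self.alt_len - self.ref_len

    def lift(self, p: int) -> int:
        if p <= self.pos:
            return p
        last_ref = self.pos + self.ref_len - 1
        if p <= last_ref:  # inside a deleted/replaced span
            return self.pos
        return p + self.delta

    def lift_interval(self, start: int, end: int) -> Optional[Tuple[int, int]]:
        """Lift an inclusive interval; None if it vanishes entirely."""
        last_ref = self.pos + self.ref_len - 1
        ns = self.pos + self.alt_len if self.pos < start <= last_ref else self.lift(start)
        ne = self.pos + self.alt_len - 1 if self.pos < end <= last_ref else self.lift(end)
        if ne < ns:
            return None
        return ns, ne


@dataclass(frozen=True)
class EffectCall:
    """Predicted consequence of one variant on one gene."""

    variant: Variant
    gene_id: str
    effect: str
    wt_protein_length: int
    codon_index: Optional[int] = None          # codon containing the variant
    stop_codon_position: Optional[int] = None  # 1-based, mutated frame
    truncated_protein_length: Optional[int] = None
    wt_aa: Optional[str] = None
    mut_aa: Optional[str] = None
    domains_lost: Tuple[str, ...] = ()
    domains_truncated: Tuple[str, ...] = ()
    scanned_codons: Optional[int] = None       # for stop-lost extensions

    @property
    def severity(self) -> int:
        return SEVERITY.get(self.effect, 0)


def _extract(chrom_seq: str, intervals: Sequence[Tuple[int, int]], strand: str) -> str:
    seq = "".join(chrom_seq[s - 1 : e] for s, e in intervals)
    return revcomp(seq) if strand == "-" else seq


def translate_cds(gene: GeneModel, reference: Mapping[str, str]) -> str:
    """Translate a gene's CDS from the reference (standard code, no stop).

    Minus-strand genes are reverse-complemented before translation. The
    protein length equals CDS length / 3 since the CDS convention here
    excludes the stop codon; an internal stop in a supposed WT model raises
    a validation warning but is still returned.
    """
    cds_seq = _extract(reference[gene.chrom], gene.cds, gene.strand)
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {len(cds_seq)} not divisible by 3")
    protein = str(Seq(cds_seq).translate())
    if "*" in protein:
        warnings.warn(
            f"{gene.gene_id}: internal stop codon at position {protein.index('*') + 1} "
            "in a supposed WT model",
            stacklevel=2,
        )
    return protein


def apply_variant(chrom_seq: str, variant: Variant) -> Tuple[str, CoordinateShift]:
    """Apply a variant to a chromosome sequence.

    Returns the mutated sequence and the coordinate shift map used to lift
    gene-model coordinates. Raises :class:`ReferenceMismatchError` when the
    reference allele does not match the sequence (wrong genome build).
    """
    observed = chrom_seq[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if observed != variant.ref:
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} expected {variant.ref!r}, sequence has {observed!r}"
        )
    mutated = (
        chrom_seq[: variant.pos - 1] + variant.alt + chrom_seq[variant.pos - 1 + len(variant.ref) :]
    )
    return mutated, CoordinateShift(variant.pos, len(variant.ref), len(variant.alt))


def _cds_coordinate(gene: GeneModel, pos: int) -> Optional[int]:
    """1-based position within the CDS, in transcription order."""
    offset = 0
    if gene.strand == "+":
        for s, e in gene.cds:
            if s <= pos <= e:
                return offset + pos - s + 1
            offset += e - s + 1
    else:
        for s, e in reversed(gene.cds):
            if s <= pos <= e:
                return offset + e - pos + 1
            offset += e - s + 1
    return None


def _cds_overlap_len(gene: GeneModel, variant: Variant) -> int:
    """Number of CDS bases created/removed by the variant."""
    if variant.kind == "insertion":
        return len(variant.alt) - 1 if any(s <= variant.pos < e for s, e in gene.cds) else 0
    s, e = variant.affected_span()
    return sum(max(0, min(e, ce) - max(s, cs) + 1) for cs, ce in gene.cds)


def _mutant_translation(
    gene: GeneModel,
    reference: Mapping[str, str],
    variant: Variant,
    max_extension: int = 30_000,
) -> Tuple[str, int]:
    """Translate the mutated CDS, scanning downstream until a stop.

    Returns (protein up to but excluding the stop, scanned codon count).
    An empty stop hit is signalled by the protein length equalling the
    scanned codon count (no '*' found within the scan window).
    """
    mut_chrom, shift = apply_variant(reference[gene.chrom], variant)
    lifted = [iv for iv in (shift.lift_interval(s, e) for s, e in gene.cds) if iv]
    cds_seq = _extract(mut_chrom, lifted, gene.strand)
    if gene.strand == "+":
        tail_start = lifted[-1][1]  # 0-based slice start == position after CDS end
        tail = mut_chrom[tail_start : tail_start + max_extension]
    else:
        head_end = lifted[0][0] - 1
        tail = revcomp(mut_chrom[max(0, head_end - max_extension) : head_end])
    scan = cds_seq + tail
    scan = scan[: len(scan) - len(scan) % 3]
    protein = str(Seq(scan).translate())
    stop = protein.find("*")
    if stop == -1:
        return protein, len(protein)
    return protein[:stop], len(protein)


def _domain_losses(
    domains: Optional[Sequence[Tuple[str, int, int]]],
    truncated_length: int,
) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    lost, truncated = [], []
    for name, start, end in domains or ():
        if truncated_length < start:
            lost.append(name)
        elif truncated_length < end:
            truncated.append(name)
    return tuple(lost), tuple(truncated)


def classify_effect(
    variant: Variant,
    gene: GeneModel,
    reference: Mapping[str, str],
    domains: Optional[Sequence[Tuple[str, int, int]]] = None,
    max_extension: int = 30_000,
) -> EffectCall:
    """Classify one variant against one gene model.

    SNPs inside the CDS are called synonymous/missense/nonsense by codon
    comparison; CDS indels are in-frame when their net CDS length change is
    a multiple of three and frameshifts otherwise. Frameshift and nonsense
    calls carry the first-stop codon position of the mutated frame and the
    resulting truncated protein length; if no stop appears within
    ``max_extension`` bp past the CDS the effect is ``stop_lost_extension``.
    ``domains`` are optional user-supplied protein intervals
    (name, start_aa, end_aa) reported as lost or truncated.
    """
    if variant.chrom != gene.chrom:
        return EffectCall(variant, gene.gene_id, "intergenic", gene.n_codons)
    wt_len = gene.n_codons

    if variant.kind == "mnp":
        raise ValueError("multi-nucleotide substitutions are not supported")

    if variant.kind == "snp":
        cds_pos = _cds_coordinate(gene, variant.pos)
        if cds_pos is None:
            effect = "intronic" if gene.contains(variant.pos) else "intergenic"
            return EffectCall(variant, gene.gene_id, effect, wt_len)
        chrom_seq = reference[gene.chrom]
        observed = chrom_seq[variant.pos - 1]
        if observed != variant.ref:
            raise ReferenceMismatchError(
                f"{variant.chrom}:{variant.pos} expected {variant.ref!r}, "
                f"sequence has {observed!r}"
            )
        codon_idx = (cds_pos - 1) // 3 + 1
        wt_cds = _extract(chrom_seq, gene.cds, gene.strand)
        base = variant.alt if gene.strand == "+" else revcomp(variant.alt)
        mut_codon_seq = list(wt_cds[(codon_idx - 1) * 3 : codon_idx * 3])
        mut_codon_seq[(cds_pos - 1) % 3] = base
        wt_aa = str(Seq(wt_cds[(codon_idx - 1) * 3 : codon_idx * 3]).translate())
        mut_aa = str(Seq("".join(mut_codon_seq)).translate())
        if mut_aa == wt_aa:
            effect = "synonymous"
        elif mut_aa == "*":
            effect = "nonsense"
        else:
            effect = "missense"
        call = EffectCall(
            variant,
            gene.gene_id,
            effect,
            wt_len,
            codon_index=codon_idx,
            wt_aa=wt_aa,
            mut_aa=mut_aa,
        )
        if effect == "nonsense":
            trunc = codon_idx - 1
            lost, cut = _domain_losses(domains, trunc)
            call = EffectCall(
                variant,
                gene.gene_id,
                effect,
                wt_len,
                codon_index=codon_idx,
                stop_codon_position=codon_idx,
                truncated_protein_length=trunc,
                wt_aa=wt_aa,
                mut_aa=mut_aa,
                domains_lost=lost,
                domains_truncated=cut,
            )
        return call

    # indel
    overlap = _cds_overlap_len(gene, variant)
    if overlap == 0:
        span_s, span_e = variant.affected_span()
        inside = gene.start <= span_e and span_s <= gene.end
        return EffectCall(
            variant, gene.gene_id, "intronic" if inside else "intergenic", wt_len
        )
    # first CDS base (transcription order) whose content changes; on the
    # minus strand the bases after the genomic anchor come EARLIER in the
    # transcript, so the anchor itself is not a safe reference point
    affected_cds: List[int] = []
    if variant.kind == "deletion":
        for p in range(variant.pos + 1, variant.end + 1):
            c = _cds_coordinate(gene, p)
            if c is not None:
                affected_cds.append(c)
    else:  # insertion lands just after the anchor in transcription order
        anchor = variant.pos if gene.strand == "+" else variant.pos + 1
        c = _cds_coordinate(gene, anchor)
        if c is not None:
            affected_cds.append(c + 1)
    codon_idx = (min(affected_cds) - 1) // 3 + 1 if affected_cds else None
    net = overlap if variant.kind == "insertion" else -overlap
    if net % 3 == 0:
        return EffectCall(
            variant, gene.gene_id, "in_frame_indel", wt_len, codon_index=codon_idx
        )
    protein, scanned = _mutant_translation(gene, reference, variant, max_extension)
    if len(protein) == scanned:  # no stop within the scan window
        return EffectCall(
            variant,
            gene.gene_id,
            "stop_lost_extension",
            wt_len,
            codon_index=codon_idx,
            scanned_codons=scanned,
        )
    stop_pos = len(protein) + 1
    trunc = len(protein)
    lost, cut = _domain_losses(domains, trunc)
    return EffectCall(
        variant,
        gene.gene_id,
        "frameshift",
        wt_len,
        codon_index=codon_idx,
        stop_codon_position=stop_pos,
        truncated_protein_length=trunc,
        domains_lost=lost,
        domains_truncated=cut,
    )
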