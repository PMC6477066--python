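"""Brute-force variant-effect oracle, independent of the package internals.

Everything here is re-derived from first principles with plain string
operations and a hand-typed codon table: mutate the chromosome, recompute
the CDS intervals by explicit arithmetic, translate WT and mutant, and diff
the proteins. Used to cross-check the production classifier.

Restrictions (enforced by the test-case generators): indels must lie fully
inside a single CDS interval or entirely outside the CDS.
"""

_T = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _T[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_translate(seq):
    return "".join(_T[seq[i : i + 3]] for i in range(0, len(seq) - len(seq) % 3, 3))


def oracle_revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def _extract(chrom, intervals, strand):
    s = "".join(chrom[a - 1 : b] for a, b in intervals)
    return oracle_revcomp(s) if strand == "-" else s


def oracle_classify(reference, gene, variant, max_extension=30_000):
    """Return dict(effect, stop_codon_position, truncated_protein_length,
    wt_protein_length) by full re-translation."""
    chrom = reference[gene.chrom]
    wt_prot = oracle_translate(_extract(chrom, gene.cds, gene.strand))
    wt_len = len(wt_prot)
    ref, alt, pos = variant.ref, variant.alt, variant.pos
    out = {
        "effect": None,
        "stop_codon_position": None,
        "truncated_protein_length": None,
        "wt_protein_length": wt_len,
    }

    def _region(lo, hi):
        if any(a <= lo and hi <= b for a, b in gene.cds):
            return "cds"
        return "intronic" if gene.exons[0][0] <= hi and lo <= gene.exons[-1][1] else "intergenic"

    if len(ref) == len(alt) == 1:  # SNP
        region = _region(pos, pos)
        if region != "cds":
            out["effect"] = region
            return out
        mut_chrom = chrom[: pos - 1] + alt + chrom[pos:]
        mut_prot = oracle_translate(_extract(mut_chrom, gene.cds, gene.strand))
        if mut_prot == wt_prot:
            out["effect"] = "synonymous"
            return out
        idx = next(i for i in range(wt_len) if mut_prot[i] != wt_prot[i])
        if mut_prot[idx] == "*":
            out["effect"] = "nonsense"
            out["stop_codon_position"] = idx + 1
            out["truncated_protein_length"] = idx
        else:
            out["effect"] = "missense"
        return out

    # indel: generator guarantees it sits fully inside one CDS interval or
    # fully outside the CDS
    net = len(alt) - len(ref)
    if net < 0:
        lo, hi = pos + 1, pos + len(ref) - 1
        inside = any(a <= pos and hi <= b for a, b in gene.cds)
    else:
        lo = hi = pos
        inside = any(a <= pos < b for a, b in gene.cds)
    if not inside:
        out["effect"] = _region(lo, hi) if _region(lo, hi) != "cds" else "intronic"
        return out
    if net % 3 == 0:
        out["effect"] = "in_frame_indel"
        return out
    mut_chrom = chrom[: pos - 1] + alt + chrom[pos - 1 + len(ref) :]
    new_ivs = []
    for a, b in gene.cds:
        if b <= pos:
            new_ivs.append((a, b))
        elif a > pos + len(ref) - 1:
            new_ivs.append((a + net, b + net))
        else:  # the interval hosting the indel
            new_ivs.append((a, b + net))
    cds_seq = _extract(mut_chrom, new_ivs, gene.strand)
    if gene.strand == "+":
        tail = mut_chrom[new_ivs[-1][1] : new_ivs[-1][1] + max_extension]
    else:
        head = new_ivs[0][0] - 1
        tail = oracle_revcomp(mut_chrom[max(0, head - max_extension) : head])
    prot = oracle_translate(cds_seq + tail)
    stop = prot.find("*")
    if stop == -1:
        out["effect"] = "stop_lost_extension"
        return out
    out["effect"] = "frameshift"
    out["stop_codon_position"] = stop + 1
    out["truncated_protein_length"] = stop
    return out


def random_variant_cases(reference, genes, rng, n):
    """Yield (gene, variant) pairs covering SNPs, indels, both strands."""
    from causalmap.models import Variant

    genes = [g for g in genes if g.cds_length >= 120]
    cases = []
    while len(cases) < n:
        gene = genes[rng.integers(len(genes))]
        chrom = reference[gene.chrom]
        kind = rng.integers(3)
        if kind == 0:  # SNP anywhere in/around the gene
            pos = int(rng.integers(max(1, gene.start - 150), gene.end + 150))
            ref = chrom[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            cases.append((gene, Variant(gene.chrom, pos, ref, alt)))
            continue
        iv = gene.cds[rng.integers(len(gene.cds))]
        size = int(rng.integers(1, 4))
        if kind == 1:  # deletion fully inside one CDS interval
            if iv[1] - iv[0] < size + 2:
                continue
            pos = int(rng.integers(iv[0], iv[1] - size))
            ref = chrom[pos - 1 : pos + size]
            cases.append((gene, Variant(gene.chrom, pos, ref, ref[0])))
        else:  # insertion anchored inside one CDS interval
            pos = int(rng.integers(iv[0], iv[1]))
            anchor = chrom[pos - 1]
            alt = anchor + "".join("ACGT"[b] for b in rng.integers(0, 4, size=size))
            cases.append((gene, Variant(gene.chrom, pos, anchor, alt)))
    return cases
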