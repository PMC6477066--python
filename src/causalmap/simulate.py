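"""Seeded generators for every input the mapping pipeline consumes.

This module emulates the study design of a forward-genetics screen in
tomato: a reference genome with non-overlapping protein-coding genes, a
single planted causal lesion (by default a 2 bp exonic deletion, recessive),
mutagen-induced background variants homozygous in the mutant parent,
intra-cultivar polymorphisms segregating independently of the cross, F2
populations produced by Haldane-model meiosis, SNP-array genotyping of those
populations, pooled sequencing of a mutant-phenotype bulk, and
negative-binomial RNA-seq counts with planted fold changes.

All randomness flows through a single :class:`numpy.random.Generator`;
the same seed reproduces every output byte for byte.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .models import GeneModel, PlacementError, Variant, revcomp
from .rnaseq import CountMatrix
from .snpindex import PooledAlleleCount

MUTANT_PARENT = 0
WT_PARENT = 1

_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in _STOPS
]
# (61, 3) array of ASCII codes, indexed by codon id
_NONSTOP_BYTES = np.frombuffer("".join(_NONSTOP_CODONS).encode(), dtype=np.uint8).reshape(-1, 3)
_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[_a] = _b


class SizingError(ValueError):
    """The requested gene complement does not fit on the chromosomes."""


class CoordinateError(ValueError):
    """A position lies off the simulated chromosomes."""


# ---------------------------------------------------------------------------
# reference genome + gene models
# ---------------------------------------------------------------------------


def _split_counts(total: int, weights: Sequence[float]) -> List[int]:
    """Deterministic largest-remainder split of *total* by *weights*."""
    weights = np.asarray(weights, dtype=float)
    shares = total * weights / weights.sum()
    counts = np.floor(shares).astype(int)
    order = np.argsort(-(shares - counts), kind="stable")
    for i in order[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _gene_structure(config: SimulationConfig, rng: np.random.Generator) -> dict:
    n_codons = int(
        np.clip(
            rng.lognormal(np.log(config.mean_cds_codons), config.cds_codons_sigma),
            config.min_cds_codons,
            config.max_cds_codons,
        )
    )
    cds_len = 3 * n_codons
    k = int(rng.integers(1, config.max_exons + 1))
    if k > 1:
        extra = rng.multinomial(cds_len - 30 * k, np.full(k, 1.0 / k))
        exon_lens = (30 + extra).tolist()
        introns = rng.integers(config.intron_min_bp, config.intron_max_bp + 1, size=k - 1).tolist()
    else:
        exon_lens = [cds_len]
        introns = []
    strand = "+" if rng.integers(2) == 0 else "-"
    return {
        "n_codons": n_codons,
        "exon_lens": exon_lens,
        "introns": introns,
        "strand": strand,
        "span": cds_len + sum(introns),
    }


def build_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[Dict[str, str], List[GeneModel]]:
    """Generate a random reference genome with embedded gene models.

    Genes are non-overlapping, UTR-less (CDS intervals equal exon
    intervals), carry an ATG start and no internal stop codon in frame, and
    exclude the stop codon from the CDS; the genomic stop triplet is written
    immediately downstream of the CDS. Raises :class:`SizingError` when a
    fixed ``gene_count`` cannot be placed.
    """
    chroms = sorted(config.chromosome_lengths)
    lengths = [config.chromosome_lengths[c] for c in chroms]
    if config.gene_count is not None:
        per_chrom = _split_counts(config.gene_count, lengths)
    else:
        per_chrom = [
            int(rng.poisson(config.gene_density_per_mbp * length / 1e6)) for length in lengths
        ]

    margin, min_gap, stop_pad = 100, 20, 3
    reference: Dict[str, str] = {}
    genes: List[GeneModel] = []
    for chrom, length, n_genes in zip(chroms, lengths, per_chrom):
        seq = _BASE_BYTES[rng.integers(0, 4, size=length)]
        structures = [_gene_structure(config, rng) for _ in range(n_genes)]
        occupied = sum(s["span"] + 2 * stop_pad for s in structures)
        free = length - 2 * margin - occupied - min_gap * max(n_genes - 1, 0)
        if n_genes and free < 0:
            raise SizingError(
                f"{n_genes} genes need more than the {length} bp of {chrom}"
            )
        extras = (
            np.floor(rng.dirichlet(np.ones(n_genes + 1)) * free).astype(int)
            if n_genes
            else np.array([], dtype=int)
        )
        cursor = margin + 1 + (int(extras[0]) if n_genes else 0)
        for i, s in enumerate(structures):
            start = cursor + stop_pad
            exons = []
            pos = start
            for j, elen in enumerate(s["exon_lens"]):
                exons.append((pos, pos + elen - 1))
                pos += elen
                if j < len(s["introns"]):
                    pos += s["introns"][j]
            gene = GeneModel(
                gene_id=f"gene_{chrom}_{i + 1:04d}",
                chrom=chrom,
                strand=s["strand"],
                exons=tuple(exons),
                cds=tuple(exons),
            )
            # CDS content: ATG then codons drawn from the 61 non-stop codons
            codon_ids = rng.integers(0, 61, size=s["n_codons"])
            cds_bytes = _NONSTOP_BYTES[codon_ids].reshape(-1).copy()
            cds_bytes[0:3] = np.frombuffer(b"ATG", dtype=np.uint8)
            if gene.strand == "-":
                genomic = _COMP_TABLE[cds_bytes][::-1]
            else:
                genomic = cds_bytes
            offset = 0
            for es, ee in gene.exons:
                n = ee - es + 1
                seq[es - 1 : ee] = genomic[offset : offset + n]
                offset += n
            if gene.strand == "+":
                seq[gene.end : gene.end + 3] = np.frombuffer(b"TAA", dtype=np.uint8)
            else:
                seq[gene.start - 4 : gene.start - 1] = np.frombuffer(b"TTA", dtype=np.uint8)
            genes.append(gene)
            cursor = gene.end + stop_pad + min_gap + int(extras[i + 1])
        reference[chrom] = seq.tobytes().decode("ascii")
    return reference, genes


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


@dataclass
class VariantSet:
    """Truth set of planted variants plus the identity of the causal lesion."""

    variants: List[Variant]
    causal: Variant
    causal_gene_id: str

    def by_origin(self, origin: str) -> List[Variant]:
        return [v for v in self.variants if v.origin == origin]


def _pick_causal_gene(genes: Sequence[GeneModel], config: SimulationConfig) -> GeneModel:
    if config.causal_gene is not None:
        for g in genes:
            if g.gene_id == config.causal_gene:
                return g
        raise PlacementError(f"causal gene {config.causal_gene!r} not among gene models")
    chrom = config.causal_chrom or sorted(config.chromosome_lengths)[-1]
    candidates = [g for g in genes if g.chrom == chrom]
    if not candidates:
        raise PlacementError(f"no genes on {chrom} to host the causal variant")
    mid = config.chromosome_lengths[chrom] / 2
    return min(candidates, key=lambda g: abs((g.start + g.end) / 2 - mid))


def plant_variants(
    reference: Dict[str, str],
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> VariantSet:
    """Plant the causal deletion plus mutagen and intra-cultivar background.

    Exactly one causal variant is created (default: a 2 bp deletion in the
    transcription-order first exon of the causal gene, VCF-anchored so a
    2 bp deletion carries a 3 bp reference allele). Mutagen variants are
    homozygous in the mutant parent; intra-cultivar variants carry a
    population allele frequency and segregate independently of the cross.
    """
    causal_gene = _pick_causal_gene(genes, config)
    order = causal_gene.cds if causal_gene.strand == "+" else causal_gene.cds[::-1]
    try:
        es, ee = order[config.causal_exon_index]
    except IndexError:
        raise PlacementError(
            f"causal exon index {config.causal_exon_index} outside the "
            f"{len(order)} exons of {causal_gene.gene_id}"
        ) from None
    d = config.causal_deletion_bp
    anchor = es + max(3, (ee - es + 1) // 3)
    if anchor + d > ee - 3:
        anchor = es + 3
    if anchor + d > ee - 3:
        raise PlacementError(
            f"a {d} bp deletion does not fit inside exon ({es}, {ee}) of "
            f"{causal_gene.gene_id}"
        )
    chrom_seq = reference[causal_gene.chrom]
    causal = Variant(
        chrom=causal_gene.chrom,
        pos=anchor,
        ref=chrom_seq[anchor - 1 : anchor + d],
        alt=chrom_seq[anchor - 1],
        origin="causal",
    )

    chroms = sorted(config.chromosome_lengths)
    lengths = np.array([config.chromosome_lengths[c] for c in chroms], dtype=float)
    genome_len = lengths.sum()
    occupied = {(causal.chrom, p) for p in range(causal.pos, causal.end + 1)}

    variants: List[Variant] = [causal]

    def _draw_background(rate: float, origin: str, allow_indels: bool) -> None:
        n = int(rng.poisson(rate * genome_len))
        if n == 0:
            return
        chrom_idx = rng.choice(len(chroms), size=n, p=lengths / genome_len)
        for ci in chrom_idx:
            chrom = chroms[ci]
            seq = reference[chrom]
            pos = int(rng.integers(2, len(seq) - 2))
            is_indel = allow_indels and rng.random() < config.mutagen_indel_fraction
            if is_indel:
                size = int(rng.integers(1, 3))
                deletes = rng.integers(2) == 0
                span = range(pos, pos + size + 1) if deletes else (pos,)
                if any((chrom, p) in occupied for p in span):
                    continue
                if deletes:
                    ref, alt = seq[pos - 1 : pos + size], seq[pos - 1]
                else:
                    ref = seq[pos - 1]
                    alt = ref + "".join(
                        "ACGT"[b] for b in rng.integers(0, 4, size=size)
                    )
                occupied.update((chrom, p) for p in span)
            else:
                if (chrom, pos) in occupied:
                    continue
                ref = seq[pos - 1]
                alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
                occupied.add((chrom, pos))
            pop_freq = float(rng.uniform(0.1, 0.9)) if origin == "intra_cultivar" else None
            variants.append(
                Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, origin=origin, pop_freq=pop_freq)
            )

    _draw_background(config.mutagen_rate, "mutagen", allow_indels=True)
    _draw_background(config.intracultivar_rate, "intra_cultivar", allow_indels=False)
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return VariantSet(variants=variants, causal=causal, causal_gene_id=causal_gene.gene_id)


# ---------------------------------------------------------------------------
# meiosis and F2 individuals
# ---------------------------------------------------------------------------


@dataclass
class Haplotype:
    """One chromosome copy as parental-origin segments.

    ``ends`` are inclusive 1-based segment end positions (the last equals the
    chromosome length); segment *i* covers ``(ends[i-1], ends[i]]`` and has
    origin ``origins[i]`` (0 = mutant parent, 1 = WT parent).
    """

    ends: np.ndarray
    origins: np.ndarray

    def origin_at(self, pos: int) -> int:
        return int(self.origins[np.searchsorted(self.ends, pos)])

    def origins_at(self, positions: np.ndarray) -> np.ndarray:
        return self.origins[np.searchsorted(self.ends, positions)]

    def segments(self) -> List[Tuple[int, int, int]]:
        out, start = [], 1
        for end, origin in zip(self.ends.tolist(), self.origins.tolist()):
            out.append((start, end, int(origin)))
            start = end + 1
        return out


def simulate_gamete(length: int, morgans: float, rng: np.random.Generator) -> Haplotype:
    """One meiotic product under the Haldane model (no interference).

    Crossover count is Poisson with mean equal to the map length in Morgans;
    crossover positions are uniform; the starting parental origin is a fair
    coin flip.
    """
    n_x = int(rng.poisson(morgans))
    if n_x:
        breaks = np.unique(rng.integers(1, length, size=n_x))
    else:
        breaks = np.empty(0, dtype=np.int64)
    ends = np.append(breaks, length)
    first = int(rng.integers(0, 2))
    origins = ((first + np.arange(ends.size)) % 2).astype(np.int8)
    return Haplotype(ends=ends, origins=origins)


@dataclass
class F2Individual:
    """An F2 plant: two haplotypes per chromosome plus its phenotype."""

    haplotypes: Dict[str, Tuple[Haplotype, Haplotype]]
    phenotype: str

    def origins_at(self, chrom: str, positions: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        h1, h2 = self.haplotypes[chrom]
        return h1.origins_at(positions), h2.origins_at(positions)

    def is_mutant_at(self, chrom: str, pos: int) -> bool:
        h1, h2 = self.haplotypes[chrom]
        return h1.origin_at(pos) == MUTANT_PARENT and h2.origin_at(pos) == MUTANT_PARENT


CausalLocus = Union[Variant, Tuple[str, int], "VariantSet"]


def _causal_locus(causal: CausalLocus) -> Tuple[str, int]:
    if isinstance(causal, VariantSet):
        causal = causal.causal
    if isinstance(causal, Variant):
        return causal.chrom, causal.pos
    return causal


def simulate_f2(
    config: SimulationConfig,
    causal: CausalLocus,
    n: int,
    rng: np.random.Generator,
) -> List[F2Individual]:
    """Simulate *n* F2 individuals from a selfed F1 heterozygote.

    Each haplotype is an independent F1 gamete. Phenotype is assigned by the
    recessive rule: mutant iff both haplotypes carry mutant-parent origin at
    the causal position, giving an expected 3:1 WT:mutant segregation.
    """
    if n < 1:
        raise ConfigError("population size must be at least 1")
    chrom, pos = _causal_locus(causal)
    chroms = sorted(config.chromosome_lengths)
    morgans = {c: config.morgans(c) for c in chroms}
    out = []
    for _ in range(n):
        haps = {
            c: (
                simulate_gamete(config.chromosome_lengths[c], morgans[c], rng),
                simulate_gamete(config.chromosome_lengths[c], morgans[c], rng),
            )
            for c in chroms
        }
        h1, h2 = haps[chrom]
        mutant = (
            h1.origin_at(pos) == MUTANT_PARENT and h2.origin_at(pos) == MUTANT_PARENT
        )
        out.append(F2Individual(haplotypes=haps, phenotype="mutant" if mutant else "wt"))
    return out


def simulate_f2_until(
    config: SimulationConfig,
    causal: CausalLocus,
    n_mutant: int,
    n_wt: int,
    rng: np.random.Generator,
    batch: int = 64,
) -> Tuple[List[F2Individual], List[F2Individual]]:
    """Simulate F2 plants until at least *n_mutant* mutants and *n_wt* WT exist."""
    mutants: List[F2Individual] = []
    wts: List[F2Individual] = []
    while len(mutants) < n_mutant or len(wts) < n_wt:
        for ind in simulate_f2(config, causal, batch, rng):
            (mutants if ind.phenotype == "mutant" else wts).append(ind)
    return mutants[:n_mutant], wts[:n_wt]


# ---------------------------------------------------------------------------
# marker array
# ---------------------------------------------------------------------------


def simulate_marker_panel(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """A SolCAP-like array: marker positions plus parental genotype calls.

    Exactly ``informative_markers`` of the ``marker_array_size`` markers are
    informative (distinct homozygous parental calls, mutant parent coded
    ``AA``); the remainder are monomorphic, heterozygous in one parent, or
    missing, mimicking an array designed against other germplasm.
    """
    chroms = sorted(config.chromosome_lengths)
    lengths = [config.chromosome_lengths[c] for c in chroms]
    per_chrom = _split_counts(config.marker_array_size, lengths)
    rows = []
    for chrom, length, m in zip(chroms, lengths, per_chrom):
        pos = np.unique(rng.integers(1, length + 1, size=m))
        while pos.size < m:
            pos = np.unique(np.append(pos, rng.integers(1, length + 1, size=m - pos.size)))
        for p in np.sort(pos).tolist():
            rows.append((chrom, p))
    panel = pd.DataFrame(rows, columns=["chrom", "pos"])
    panel.index = [f"mk{i:06d}" for i in range(len(panel))]
    total = len(panel)
    informative = np.zeros(total, dtype=bool)
    informative[rng.choice(total, size=config.informative_markers, replace=False)] = True
    parent_mut = np.where(informative, "AA", "AA").astype(object)
    parent_wt = np.where(informative, "BB", "AA").astype(object)
    u = rng.random(total)
    for i in np.flatnonzero(~informative):
        if u[i] < 0.70:
            pass  # monomorphic, both AA
        elif u[i] < 0.85:
            parent_wt[i] = "AB"
        else:
            parent_wt[i] = np.nan
    panel["parent_mutant"] = parent_mut
    panel["parent_wt"] = parent_wt
    return panel


# ---------------------------------------------------------------------------
# array genotyping
# ---------------------------------------------------------------------------

_CALL_CODES = np.array(["AA", "AB", "BB"], dtype=object)


@dataclass
class GenotypeTable:
    """Individuals x markers genotype calls, plus phenotypes and the panel.

    Calls are coded against parental origin: ``AA`` homozygous mutant-parent,
    ``BB`` homozygous WT-parent, ``AB`` heterozygous, ``NaN`` missing.
    """

    calls: pd.DataFrame
    phenotype: pd.Series
    panel: pd.DataFrame
    chrom_lengths: Optional[Dict[str, int]] = None

    @property
    def mutant_ids(self) -> List[str]:
        return self.phenotype.index[self.phenotype == "mutant"].tolist()


def genotype_array(
    individuals: Sequence[F2Individual],
    panel: pd.DataFrame,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    chrom_lengths: Optional[Dict[str, int]] = None,
) -> GenotypeTable:
    """Genotype individuals at the panel's marker positions.

    The true call is determined by the parental origins of the two
    haplotypes at the marker position; genotyping errors (a uniformly chosen
    wrong call) and missingness are then applied independently per call.
    """
    if (error_rate or missing_rate) and rng is None:
        raise ValueError("error/missing rates require a random generator")
    if chrom_lengths is not None:
        for mid, row in panel.iterrows():
            length = chrom_lengths.get(row["chrom"])
            if length is None or not 1 <= row["pos"] <= length:
                raise CoordinateError(f"marker {mid} at {row['chrom']}:{row['pos']} is off-chromosome")
    panel = panel.sort_values(["chrom", "pos"], kind="stable")
    n_ind, n_mark = len(individuals), len(panel)
    geno = np.zeros((n_ind, n_mark), dtype=np.int8)
    for chrom in panel["chrom"].unique():
        col_idx = np.flatnonzero((panel["chrom"] == chrom).to_numpy())
        positions = panel["pos"].to_numpy()[col_idx]
        for i, ind in enumerate(individuals):
            o1, o2 = ind.origins_at(chrom, positions)
            geno[i, col_idx] = o1 + o2
    if error_rate > 0:
        err = rng.random((n_ind, n_mark)) < error_rate
        offsets = rng.integers(1, 3, size=(n_ind, n_mark))
        geno = (geno + offsets * err) % 3
    missing = (
        rng.random((n_ind, n_mark)) < missing_rate
        if missing_rate > 0
        else np.zeros((n_ind, n_mark), dtype=bool)
    )
    calls = _CALL_CODES[geno].astype(object)
    calls[missing] = np.nan
    ids = [f"F2_{i + 1:04d}" for i in range(n_ind)]
    frame = pd.DataFrame(calls, index=ids, columns=panel.index)
    phen = pd.Series([ind.phenotype for ind in individuals], index=ids, name="phenotype")
    return GenotypeTable(calls=frame, phenotype=phen, panel=panel, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------


def pool_and_sequence(
    bulk: Sequence[F2Individual],
    variants: Sequence[Variant],
    depth_mean: float,
    seq_error_rate: float,
    rng: np.random.Generator,
) -> List[PooledAlleleCount]:
    """Sequence a pooled bulk: per-variant read depths and allele counts.

    Every plant contributes equally. Depth is Poisson(``depth_mean``);
    mutant-allele reads are binomial with success probability equal to the
    bulk mutant-allele frequency, perturbed by a symmetric per-read allele
    flip at ``seq_error_rate``. Zero-depth variants yield (0, 0) records.
    """
    if not bulk:
        raise ValueError("bulk must contain at least one individual")
    n2 = 2 * len(bulk)
    # carrier counts for cross-borne alleles, vectorised per chromosome
    carriers = np.zeros(len(variants), dtype=np.int64)
    by_chrom: Dict[str, List[int]] = {}
    for i, v in enumerate(variants):
        if v.origin != "intra_cultivar":
            by_chrom.setdefault(v.chrom, []).append(i)
    for chrom, idxs in by_chrom.items():
        positions = np.array([variants[i].pos for i in idxs])
        tot = np.zeros(len(idxs), dtype=np.int64)
        for ind in bulk:
            o1, o2 = ind.origins_at(chrom, positions)
            tot += (o1 == MUTANT_PARENT).astype(np.int64)
            tot += (o2 == MUTANT_PARENT).astype(np.int64)
        carriers[idxs] = tot
    out = []
    for i, v in enumerate(variants):
        if v.origin == "intra_cultivar":
            k = int(rng.binomial(n2, v.pop_freq))
        else:
            k = int(carriers[i])
        p = k / n2
        depth = int(rng.poisson(depth_mean))
        p_eff = p * (1 - seq_error_rate) + (1 - p) * seq_error_rate
        alt = int(rng.binomial(depth, p_eff)) if depth > 0 else 0
        out.append(PooledAlleleCount(variant=v, alt_reads=alt, ref_reads=depth - alt))
    return out


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def simulate_rnaseq_counts(
    config: SimulationConfig,
    rng: np.random.Generator,
    genes: Optional[Sequence[GeneModel]] = None,
) -> CountMatrix:
    """Negative-binomial counts for two groups with planted fold changes.

    Baseline means are log-normal; ``rnaseq_n_up`` genes are up-regulated in
    the mutant group (the first at ``rnaseq_top_fold``, emulating the
    >10-fold GA-biosynthesis gene) and ``rnaseq_n_down`` are down-regulated.
    Planted genes are drawn among well-expressed genes so the planted truth
    is recoverable in principle.
    """
    if config.rnaseq_replicates < 2:
        raise ConfigError("at least two replicates per group are required")
    if genes:
        ids = [g.gene_id for g in genes]
        lengths = np.array([g.cds_length for g in genes])
    else:
        ids = [f"tg{i:05d}" for i in range(config.rnaseq_n_genes)]
        lengths = rng.integers(300, 3001, size=config.rnaseq_n_genes)
    G = len(ids)
    mu = rng.lognormal(config.rnaseq_log_mean, config.rnaseq_log_sigma, size=G)
    folds = np.ones(G)
    n_planted = config.rnaseq_n_up + config.rnaseq_n_down
    top_gene = None
    planted: Dict[str, dict] = {}
    if n_planted:
        eligible = np.flatnonzero(
            (mu >= config.rnaseq_planted_min_mean) & (mu <= config.rnaseq_planted_max_mean)
        )
        if eligible.size < n_planted:
            eligible = np.argsort(mu, kind="stable")[-n_planted:]
        chosen = rng.choice(eligible, size=n_planted, replace=False)
        ups, downs = chosen[: config.rnaseq_n_up], chosen[config.rnaseq_n_up :]
        folds[ups] = config.rnaseq_up_fold
        if ups.size:
            folds[ups[0]] = config.rnaseq_top_fold
            top_gene = ids[ups[0]]
        folds[downs] = config.rnaseq_down_fold
        for i in chosen.tolist():
            planted[ids[i]] = {"fold": float(folds[i]), "base_mean": float(mu[i])}
    r = 1.0 / config.rnaseq_dispersion
    reps = config.rnaseq_replicates
    blocks, samples, groups = [], [], []
    for group, lam in (("wt", mu), ("mutant", mu * folds)):
        p = r / (r + lam)
        blocks.append(rng.negative_binomial(r, p[:, None], size=(G, reps)))
        samples.extend(f"{group}_{j + 1}" for j in range(reps))
        groups.extend([group] * reps)
    counts = pd.DataFrame(np.hstack(blocks), index=ids, columns=samples)
    return CountMatrix(
        counts=counts,
        lengths=pd.Series(lengths, index=ids, name="length_bp"),
        groups=pd.Series(groups, index=samples, name="group"),
        planted=planted or None,
        top_gene=top_gene,
    )


# ---------------------------------------------------------------------------
# worked truncation example
# ---------------------------------------------------------------------------


@dataclass
class TruncationExample:
    """A two-exon gene with an engineered frameshifting 2 bp deletion."""

    reference: Dict[str, str]
    gene: GeneModel
    variant: Variant
    domains: Tuple[Tuple[str, int, int], ...]


def build_truncation_example(seed: int = 0) -> TruncationExample:
    """Construct the worked truncation example used throughout the docs.

    A plus-strand two-exon gene with a 2871 bp stop-free CDS (957 codons)
    carries a 2 bp deletion removing the last two bases of codon 100 in its
    first exon. The sequence is engineered so that the shifted reading frame
    is stop-free up to codon 493 and hits its first stop at codon 494,
    truncating the protein to 493 residues — upstream of a transmembrane
    domain annotated at residues 505-524, which the truncation removes.
    """
    rng = np.random.default_rng(seed)
    n_codons, L = 957, 2871
    bases = "ACGT"
    cds = [""] * L

    def _codon() -> str:
        while True:
            c = "".join(bases[b] for b in rng.integers(0, 4, size=3))
            if c not in _STOPS:
                return c

    cds[0:3] = "ATG"
    for k in range(1, 100):  # WT codons 2..100
        cds[3 * k : 3 * k + 3] = _codon()
    forced = {1481: "T", 1482: "A", 1483: "A"}  # mutant codon 494 = TAA
    p = 301
    while p <= L:
        idx = p - 1
        cds[idx] = forced.get(idx) or bases[rng.integers(0, 4)]
        ok = True
        if p % 3 == 0 and "".join(cds[p - 3 : p]) in _STOPS:
            ok = False  # would put a stop into the WT frame
        if ok and p >= 302 and (p - 2) % 3 == 0:
            m = (p - 2) // 3
            if 100 <= m <= 493:
                trip = (
                    cds[297] + cds[300] + cds[301] if m == 100 else "".join(cds[p - 3 : p])
                )
                if trip in _STOPS:
                    ok = False  # would stop the shifted frame too early
        if ok:
            p += 1
        elif idx in forced:  # unreachable by construction
            raise AssertionError("forced stop clashes with frame constraints")
    cds_seq = "".join(cds)

    def _random_seq(n: int) -> str:
        return "".join(bases[b] for b in rng.integers(0, 4, size=n))

    flank5, intron, flank3 = _random_seq(200), _random_seq(150), _random_seq(200)
    chrom_seq = flank5 + cds_seq[:1200] + intron + cds_seq[1200:] + "TAA" + flank3
    gene = GeneModel(
        gene_id="RLK_demo",
        chrom="chr4",
        strand="+",
        exons=((201, 1400), (1551, 3221)),
        cds=((201, 1400), (1551, 3221)),
    )
    anchor = 201 + 297  # genomic position of CDS base 298
    variant = Variant(
        chrom="chr4",
        pos=anchor,
        ref=chrom_seq[anchor - 1 : anchor + 2],
        alt=chrom_seq[anchor - 1],
        origin="causal",
    )
    return TruncationExample(
        reference={"chr4": chrom_seq},
        gene=gene,
        variant=variant,
        domains=(("transmembrane", 505, 524),),
    )
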