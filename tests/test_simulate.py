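"""Properties of the synthetic-data generators."""

import math

import numpy as np
import pytest

from causalmap import SimulationConfig, build_reference, plant_variants, simulate_f2
from causalmap.config import ConfigError
from causalmap.models import PlacementError, Variant
from causalmap.simulate import (
    MUTANT_PARENT,
    WT_PARENT,
    SizingError,
    genotype_array,
    pool_and_sequence,
    simulate_gamete,
    simulate_marker_panel,
    simulate_rnaseq_counts,
)
from causalmap import io as cm_io


# ---------------------------------------------------------------------------
# reference + gene models
# ---------------------------------------------------------------------------


def test_zero_genes_gives_bare_sequence_of_requested_length():
    cfg = SimulationConfig(chromosome_lengths={"chrA": 50_000}, gene_count=0)
    reference, genes = build_reference(cfg, np.random.default_rng(0))
    assert genes == []
    assert len(reference["chrA"]) == 50_000


def test_gene_count_at_reference_density():
    """A 2.6 Mbp region at the default density holds ~267 genes."""
    fixed = SimulationConfig(chromosome_lengths={"c": 2_600_000}, gene_count=267)
    _, genes = build_reference(fixed, np.random.default_rng(0))
    assert len(genes) == 267
    poisson = SimulationConfig(chromosome_lengths={"c": 2_600_000})
    counts = [
        len(build_reference(poisson, np.random.default_rng(seed))[1]) for seed in range(4)
    ]
    sigma = math.sqrt(267)
    for c in counts:
        assert abs(c - 267) < 4 * sigma


def test_genes_nonoverlapping_with_valid_cds(small_world):
    genes = small_world["genes"]
    by_chrom = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
        assert g.cds_length % 3 == 0
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.start)
        for a, b in zip(glist, glist[1:]):
            assert a.end < b.start


def test_oversized_gene_request_raises():
    cfg = SimulationConfig(chromosome_lengths={"c": 30_000}, gene_count=50)
    with pytest.raises(SizingError):
        build_reference(cfg, np.random.default_rng(0))


def test_reference_deterministic_bytes(tmp_path, small_config):
    paths = []
    for run in range(2):
        rng = np.random.default_rng(42)
        reference, genes = build_reference(small_config, rng)
        fa, gff = tmp_path / f"r{run}.fa", tmp_path / f"r{run}.gff3"
        cm_io.write_fasta(reference, fa)
        cm_io.write_gff3(genes, gff)
        paths.append((fa.read_bytes(), gff.read_bytes()))
    assert paths[0] == paths[1]


# ---------------------------------------------------------------------------
# planted variants
# ---------------------------------------------------------------------------


def test_zero_rates_leave_only_the_causal_variant(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, mutagen_rate=0.0, intracultivar_rate=0.0)
    rng = np.random.default_rng(3)
    reference, genes = build_reference(cfg, rng)
    vs = plant_variants(reference, genes, cfg, rng)
    assert len(vs.variants) == 1
    assert vs.variants[0].origin == "causal"


def test_causal_deletion_is_vcf_anchored(small_world):
    causal = small_world["variant_set"].causal
    assert len(causal.ref) == 3 and len(causal.alt) == 1
    assert causal.ref[0] == causal.alt
    assert causal.kind == "deletion"
    # the deletion sits inside a CDS interval of the causal gene
    gene = next(
        g for g in small_world["genes"] if g.gene_id == small_world["variant_set"].causal_gene_id
    )
    assert any(s <= causal.pos and causal.end <= e for s, e in gene.cds)


def test_mutagen_count_follows_poisson_rate():
    cfg = SimulationConfig(
        chromosome_lengths={"c": 2_000_000},
        gene_count=5,
        mutagen_rate=5e-5,
        intracultivar_rate=0.0,
    )
    lam = 5e-5 * 2_000_000
    counts = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        reference, genes = build_reference(cfg, rng)
        counts.append(len(plant_variants(reference, genes, cfg, rng).by_origin("mutagen")))
    for c in counts:
        assert abs(c - lam) < 4 * math.sqrt(lam)


def test_bad_causal_exon_index_raises(small_world):
    import dataclasses

    cfg = dataclasses.replace(small_world["config"], causal_exon_index=99)
    with pytest.raises(PlacementError):
        plant_variants(
            small_world["reference"], small_world["genes"], cfg, np.random.default_rng(0)
        )


# ---------------------------------------------------------------------------
# meiosis / F2
# ---------------------------------------------------------------------------


def test_zero_map_length_gives_single_segment_haplotypes():
    cfg = SimulationConfig(chromosome_lengths={"c": 1_000_000}, map_kb_per_cm=math.inf)
    inds = simulate_f2(cfg, ("c", 500_000), 30, np.random.default_rng(0))
    for ind in inds:
        for hap in ind.haplotypes["c"]:
            assert len(hap.segments()) == 1


def test_haplotype_segments_tile_chromosome(small_config, small_world):
    inds = simulate_f2(
        small_config, small_world["variant_set"].causal, 40, np.random.default_rng(5)
    )
    for ind in inds:
        for chrom, length in small_config.chromosome_lengths.items():
            for hap in ind.haplotypes[chrom]:
                segs = hap.segments()
                assert segs[0][0] == 1 and segs[-1][1] == length
                for (s1, e1, o1), (s2, e2, o2) in zip(segs, segs[1:]):
                    assert s2 == e1 + 1
                    assert o1 != o2


def test_mutant_fraction_converges_to_quarter():
    cfg = SimulationConfig(chromosome_lengths={"c": 1_000_000})
    n = 100_000
    inds = simulate_f2(cfg, ("c", 500_000), n, np.random.default_rng(11))
    frac = sum(i.phenotype == "mutant" for i in inds) / n
    sigma = math.sqrt(0.25 * 0.75 / n)
    assert abs(frac - 0.25) < 4 * sigma


def test_mean_mutant_count_in_186_plant_population():
    """Repeated 186-plant F2 populations average ~46.5 mutants (186/4)."""
    cfg = SimulationConfig(chromosome_lengths={"c": 2_000_000})
    rng = np.random.default_rng(21)
    reps = 150
    counts = [
        sum(i.phenotype == "mutant" for i in simulate_f2(cfg, ("c", 1_000_000), 186, rng))
        for _ in range(reps)
    ]
    se = math.sqrt(186 * 0.25 * 0.75 / reps)
    assert abs(np.mean(counts) - 46.5) < 4 * se


def test_phenotype_matches_recessive_rule(small_config, small_world):
    causal = small_world["variant_set"].causal
    for ind in simulate_f2(small_config, causal, 50, np.random.default_rng(9)):
        homozygous = ind.is_mutant_at(causal.chrom, causal.pos)
        assert (ind.phenotype == "mutant") == homozygous


# ---------------------------------------------------------------------------
# array genotyping
# ---------------------------------------------------------------------------


def test_homozygous_mutant_genome_is_all_AA(small_config, small_world):
    import dataclasses

    cfg = dataclasses.replace(small_config, map_kb_per_cm=math.inf)
    causal = small_world["variant_set"].causal
    inds = simulate_f2(cfg, causal, 40, np.random.default_rng(2))
    mutants = [i for i in inds if i.phenotype == "mutant"]
    table = genotype_array(mutants, small_world["panel"])
    # without recombination a mutant is mutant-parent across the causal
    # chromosome; markers there must all read AA
    chrom_markers = table.panel.index[table.panel["chrom"] == causal.chrom]
    assert (table.calls[chrom_markers] == "AA").all().all()


def test_missing_rate_one_blanks_every_call(small_world):
    inds = simulate_f2(
        small_world["config"], small_world["variant_set"].causal, 5, np.random.default_rng(3)
    )
    table = genotype_array(
        inds, small_world["panel"], missing_rate=1.0, rng=np.random.default_rng(0)
    )
    assert table.calls.isna().all().all()


def test_marker_off_chromosome_raises(small_world):
    import pandas as pd

    panel = pd.DataFrame({"chrom": ["chrZ"], "pos": [1000]}, index=["bad"])
    inds = simulate_f2(
        small_world["config"], small_world["variant_set"].causal, 2, np.random.default_rng(0)
    )
    from causalmap.simulate import CoordinateError

    with pytest.raises(CoordinateError):
        genotype_array(inds, panel, chrom_lengths=small_world["config"].chromosome_lengths)


def test_informative_marker_selection_counts(small_world):
    raw, panel = small_world["raw_panel"], small_world["panel"]
    assert len(panel) == small_world["config"].informative_markers
    # enumeration oracle: recount informativeness directly
    expected = sum(
        a in ("AA", "BB") and b in ("AA", "BB") and a != b
        for a, b in zip(raw["parent_mutant"], raw["parent_wt"])
    )
    assert len(panel) == expected


# ---------------------------------------------------------------------------
# pooled sequencing
# ---------------------------------------------------------------------------


def test_causal_index_is_one_in_mutant_bulk_without_error(small_config, small_world):
    causal = small_world["variant_set"].causal
    rng = np.random.default_rng(17)
    bulk = []
    while len(bulk) < small_config.bulk_size:
        bulk.extend(
            i
            for i in simulate_f2(small_config, causal, 30, rng)
            if i.phenotype == "mutant"
        )
    counts = pool_and_sequence(bulk[: small_config.bulk_size], [causal], 30, 0.0, rng)
    assert counts[0].ref_reads == 0 and counts[0].alt_reads > 0


def test_unlinked_variant_index_near_half(small_config):
    causal = Variant("chr2", 750_000, "ATT", "A", origin="causal")
    unlinked = Variant("chr1", 750_000, "G", "T", origin="mutagen")
    rng = np.random.default_rng(23)
    means = []
    for _ in range(400):
        bulk = [
            i
            for i in simulate_f2(small_config, causal, 60, rng)
            if i.phenotype == "mutant"
        ][:10]
        c = pool_and_sequence(bulk, [unlinked], 40, 0.0, rng)[0]
        if c.depth:
            means.append(c.alt_reads / c.depth)
    mean = np.mean(means)
    se = np.std(means, ddof=1) / math.sqrt(len(means))
    assert abs(mean - 0.5) < 4 * se


def test_zero_depth_mean_yields_flagged_records(small_config, small_world):
    causal = small_world["variant_set"].causal
    rng = np.random.default_rng(5)
    bulk = simulate_f2(small_config, causal, 4, rng)
    counts = pool_and_sequence(bulk, [causal], depth_mean=0.0, seq_error_rate=0.0, rng=rng)
    from causalmap import compute_snp_index

    rec = compute_snp_index(counts[0])
    assert rec.depth == 0 and not rec.defined


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


def test_unit_fold_changes_give_equal_group_means():
    cfg = SimulationConfig(rnaseq_n_up=0, rnaseq_n_down=0, rnaseq_n_genes=3000)
    cm = simulate_rnaseq_counts(cfg, np.random.default_rng(4))
    wt = cm.counts.loc[:, cm.groups == "wt"].to_numpy().mean()
    mut = cm.counts.loc[:, cm.groups == "mutant"].to_numpy().mean()
    assert abs(mut - wt) / wt < 0.05
    assert cm.planted is None


def test_planted_sixteen_fold_gene_measures_log2_near_four():
    cfg = SimulationConfig(
        rnaseq_n_up=1,
        rnaseq_n_down=0,
        rnaseq_top_fold=16.0,
        rnaseq_planted_min_mean=150.0,
        rnaseq_planted_max_mean=400.0,
        rnaseq_n_genes=500,
    )
    for seed in range(5):
        cm = simulate_rnaseq_counts(cfg, np.random.default_rng(seed))
        g = cm.top_gene
        wt = cm.counts.loc[g, cm.groups == "wt"].mean()
        mut = cm.counts.loc[g, cm.groups == "mutant"].mean()
        assert abs(np.log2(mut / wt) - 4.0) < 1.0


def test_rnaseq_counts_deterministic():
    cfg = SimulationConfig(rnaseq_n_genes=200)
    a = simulate_rnaseq_counts(cfg, np.random.default_rng(8))
    b = simulate_rnaseq_counts(cfg, np.random.default_rng(8))
    assert a.counts.equals(b.counts)
    assert a.planted == b.planted


def test_nonpositive_dispersion_rejected():
    with pytest.raises(ConfigError):
        SimulationConfig(rnaseq_dispersion=0.0)
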