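"""End-to-end orchestration: simulate, test segregation, map, sequence the
bulk, annotate candidates, confirm linkage, and run the expression stage.

The chain mirrors how a recessive causal lesion is pinned down in a
forward-genetics screen: a 3:1 segregation check on two F2 crosses; SNP-array
cosegregation mapping of mutant-phenotype plants to a candidate interval;
pooled sequencing of a 20-plant mutant bulk with SNP/Indel-index filtering
(depth >= 10, index >= 0.9, inside the interval) after subtracting known
intra-cultivar polymorphisms; effect annotation of surviving coding variants;
an independent cosegregation confirmation on 83 mutant + 80 WT plants; and
ranking by predicted severity. The report states whether the planted causal
gene came out on top.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import io as cm_io
from .config import SimulationConfig
from .effects import EffectCall, classify_effect
from .intervals import genes_in_interval, interval_length_mbp, map_cosegregating_interval, select_informative_markers
from .models import Variant
from .rnaseq import compute_rpkm, differential_test, filter_expressed
from .segregation import SegregationCounts, chi_square_segregation
from .simulate import (
    MUTANT_PARENT,
    F2Individual,
    build_reference,
    genotype_array,
    plant_variants,
    pool_and_sequence,
    simulate_f2,
    simulate_f2_until,
    simulate_marker_panel,
    simulate_rnaseq_counts,
)
from .snpindex import compute_snp_index, filter_candidates, subtract_intracultivar, variants_to_genes

logger = logging.getLogger(__name__)

__all__ = ["RunReport", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and any finished intermediates."""

    def __init__(self, stage: str, original: BaseException, intermediates: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.intermediates = intermediates


@dataclass
class RunReport:
    """Structured result of one pipeline run; serialises to JSON."""

    seed: int
    config: dict
    segregation: dict
    interval: dict
    snp_index: dict
    candidates: List[dict]
    ranking: List[str]
    recovered: bool
    truth: dict
    rnaseq: dict
    stage_counts: List[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config,
            "segregation": self.segregation,
            "interval": self.interval,
            "snp_index": self.snp_index,
            "candidates": self.candidates,
            "ranking": self.ranking,
            "recovered": self.recovered,
            "truth": self.truth,
            "rnaseq": self.rnaseq,
            "stage_counts": self.stage_counts,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def summary(self) -> str:
        lines = [f"pipeline run, seed {self.seed}"]
        for name, seg in self.segregation.items():
            lines.append(
                f"  segregation [{name}]: {seg['n_wt']} WT : {seg['n_mutant']} mutant, "
                f"chi2(3:1) = {seg['statistic']:.2f} "
                f"({'significant' if seg['significant'] else 'ns'})"
            )
        iv = self.interval
        lines.append(
            f"  interval: {iv['chrom']}:{iv['left']}-{iv['right']} "
            f"({iv['length_mbp']} Mbp, {iv['n_genes']} genes, "
            f"{iv['n_mutants_used']} mutants used)"
        )
        si = self.snp_index
        lines.append(
            f"  snp-index: {si['n_variants_sequenced']} variants sequenced, "
            f"{si['n_after_subtraction']} after background subtraction, "
            f"{si['n_candidate_variants']} pass filters in "
            f"{si['n_candidate_genes']} genes"
        )
        for rank, gid in enumerate(self.ranking, 1):
            cand = next(c for c in self.candidates if c["gene_id"] == gid)
            effects = ",".join(sorted({v["effect"] for v in cand["variants"]}))
            lines.append(
                f"    #{rank} {gid} [{effects}] "
                f"coseg={'yes' if cand['perfect_coseg'] else 'no'}"
            )
        lines.append(
            f"  causal gene {self.truth['causal_gene']} "
            f"{'RECOVERED as top candidate' if self.recovered else 'NOT top-ranked'}"
        )
        rn = self.rnaseq
        lines.append(
            f"  rna-seq: {rn['n_up']} up / {rn['n_down']} down of "
            f"{rn['n_expressed']} expressed genes; top planted gene "
            f"{rn['top_gene']} ratio {rn['top_gene_ratio']:.1f} "
            f"({'called up' if rn['top_gene_called_up'] else 'missed'})"
        )
        return "\n".join(lines)


def _variant_genotype(
    variant: Variant, ind: F2Individual, rng: np.random.Generator
) -> int:
    """Mutant-allele dosage (0/1/2) of a variant in one F2 plant."""
    if variant.origin == "intra_cultivar":
        return int(rng.binomial(2, variant.pop_freq))
    h1, h2 = ind.haplotypes[variant.chrom]
    return int(h1.origin_at(variant.pos) == MUTANT_PARENT) + int(
        h2.origin_at(variant.pos) == MUTANT_PARENT
    )


def _perfect_cosegregation(
    variant: Variant,
    mutants: Sequence[F2Individual],
    wts: Sequence[F2Individual],
    rng: np.random.Generator,
) -> bool:
    """All mutants homozygous for the allele, no WT plant homozygous."""
    for ind in mutants:
        if _variant_genotype(variant, ind, rng) != 2:
            return False
    for ind in wts:
        if _variant_genotype(variant, ind, rng) == 2:
            return False
    return True


def _seg_dict(n_wt: int, n_mutant: int) -> dict:
    res = chi_square_segregation(SegregationCounts(n_wt=n_wt, n_mutant=n_mutant))
    return {
        "n_total": n_wt + n_mutant,
        "n_wt": n_wt,
        "n_mutant": n_mutant,
        "statistic": round(res.statistic, 2),
        "df": res.df,
        "p_value": res.p_value,
        "significant": res.significant,
    }


def run_pipeline(
    config: Optional[SimulationConfig] = None,
    seed: int = 0,
    outdir: Optional[Path] = None,
) -> RunReport:
    """Execute the full simulated screen and report causal-gene recovery.

    All randomness derives from *seed*; the same seed yields a byte-identical
    report. When *outdir* is given, every stage's inputs/outputs are written
    there in standard formats so stages can be re-run in isolation.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    intermediates: dict = {}
    counts_log: List[dict] = []
    stage = "setup"

    def _tick(name: str, **counts) -> None:
        counts_log.append({"stage": name, **counts})
        logger.info("stage %-18s %s", name, counts)

    try:
        stage = "reference"
        t0 = time.perf_counter()
        reference, genes = build_reference(config, rng)
        intermediates["reference"], intermediates["genes"] = reference, genes
        _tick(stage, n_chromosomes=len(reference), n_genes=len(genes))

        stage = "variants"
        vs = plant_variants(reference, genes, config, rng)
        intermediates["variants"] = vs
        _tick(
            stage,
            n_total=len(vs.variants),
            n_mutagen=len(vs.by_origin("mutagen")),
            n_intracultivar=len(vs.by_origin("intra_cultivar")),
        )

        stage = "marker_panel"
        raw_panel = simulate_marker_panel(config, rng)
        panel = select_informative_markers(
            raw_panel["parent_mutant"], raw_panel["parent_wt"], raw_panel
        )
        _tick(stage, n_array=len(raw_panel), n_informative=len(panel))

        stage = "f2_populations"
        f2_mapping = simulate_f2(config, vs.causal, config.f2_size_mapping, rng)
        f2_bulk_pop = simulate_f2(config, vs.causal, config.f2_size_bulk, rng)
        segregation = {
            "mapping_cross": _seg_dict(
                sum(i.phenotype == "wt" for i in f2_mapping),
                sum(i.phenotype == "mutant" for i in f2_mapping),
            ),
            "bulk_cross": _seg_dict(
                sum(i.phenotype == "wt" for i in f2_bulk_pop),
                sum(i.phenotype == "mutant" for i in f2_bulk_pop),
            ),
        }
        _tick(stage, n_mapping=len(f2_mapping), n_bulk_population=len(f2_bulk_pop))

        stage = "interval_mapping"
        mutants_mapping = [i for i in f2_mapping if i.phenotype == "mutant"]
        table = genotype_array(
            mutants_mapping,
            panel,
            error_rate=config.genotype_error_rate,
            missing_rate=config.genotype_missing_rate,
            rng=rng,
            chrom_lengths=config.chromosome_lengths,
        )
        mapping = map_cosegregating_interval(table)
        if mapping.interval is None:
            raise RuntimeError("no cosegregating marker run found")
        interval = mapping.interval
        interval_genes = genes_in_interval(interval, genes)
        interval_dict = {
            "chrom": interval.chrom,
            "left": interval.left,
            "right": interval.right,
            "left_marker": interval.left_marker,
            "right_marker": interval.right_marker,
            "length_mbp": interval_length_mbp(interval),
            "n_genes": len(interval_genes),
            "n_markers_in_run": len(mapping.run_markers),
            "n_mutants_used": mapping.n_mutants_used,
        }
        intermediates["interval"] = interval
        _tick(stage, n_mutants=len(mutants_mapping), n_genes_in_interval=len(interval_genes))

        stage = "pooled_sequencing"
        bulk_mutants = [i for i in f2_bulk_pop if i.phenotype == "mutant"]
        while len(bulk_mutants) < config.bulk_size:
            extra = simulate_f2(config, vs.causal, 50, rng)
            bulk_mutants.extend(i for i in extra if i.phenotype == "mutant")
        bulk = bulk_mutants[: config.bulk_size]
        pooled = pool_and_sequence(
            bulk, vs.variants, config.depth_mean, config.seq_error_rate, rng
        )
        records = [compute_snp_index(c) for c in pooled]
        background = vs.by_origin("intra_cultivar")
        after_subtraction, warnings_list = subtract_intracultivar(records, background)
        survivors, flog = filter_candidates(
            after_subtraction, config.min_depth, config.min_index, interval
        )
        candidate_genes = variants_to_genes(survivors, interval_genes)
        snp_index_dict = {
            "n_variants_sequenced": len(records),
            "n_after_subtraction": len(after_subtraction),
            "n_subtraction_warnings": len(warnings_list),
            "filter": {
                "n_fail_depth": flog.n_fail_depth,
                "n_fail_index": flog.n_fail_index,
                "n_outside_interval": flog.n_outside_interval,
            },
            "n_candidate_variants": flog.n_passed,
            "n_candidate_genes": len(candidate_genes),
        }
        intermediates["records"] = records
        _tick(
            stage,
            n_sequenced=len(records),
            n_after_subtraction=len(after_subtraction),
            n_pass_filters=flog.n_passed,
            n_candidate_genes=len(candidate_genes),
        )

        stage = "effect_annotation"
        effect_calls: Dict[str, List[EffectCall]] = {}
        for cand in candidate_genes:
            effect_calls[cand.gene_id] = [
                classify_effect(rec.variant, cand.gene, reference) for rec in cand.records
            ]
        _tick(stage, n_genes=len(effect_calls))

        stage = "linkage_confirmation"
        link_mutants, link_wts = simulate_f2_until(
            config, vs.causal, config.linkage_n_mutant, config.linkage_n_wt, rng
        )
        coseg: Dict[str, bool] = {}
        for cand in candidate_genes:
            coseg[cand.gene_id] = any(
                _perfect_cosegregation(rec.variant, link_mutants, link_wts, rng)
                for rec in cand.records
            )
        _tick(stage, n_mutant_plants=len(link_mutants), n_wt_plants=len(link_wts))

        stage = "ranking"
        candidates = []
        for cand in candidate_genes:
            calls = effect_calls[cand.gene_id]
            severity = max((c.severity for c in calls), default=0)
            best_index = max(r.index for r in cand.records)
            candidates.append(
                {
                    "gene_id": cand.gene_id,
                    "chrom": cand.gene.chrom,
                    "start": cand.gene.start,
                    "end": cand.gene.end,
                    "severity": severity,
                    "max_index": best_index,
                    "perfect_coseg": coseg[cand.gene_id],
                    "variants": [
                        {
                            "pos": rec.variant.pos,
                            "ref": rec.variant.ref,
                            "alt": rec.variant.alt,
                            "origin": rec.variant.origin,
                            "index": rec.index,
                            "depth": rec.depth,
                            "effect": call.effect,
                            "stop_codon_position": call.stop_codon_position,
                            "truncated_protein_length": call.truncated_protein_length,
                        }
                        for rec, call in zip(cand.records, calls)
                    ],
                }
            )
        ranked = sorted(
            candidates,
            key=lambda c: (
                not c["perfect_coseg"],
                -c["severity"],
                -c["max_index"],
                c["chrom"],
                c["start"],
            ),
        )
        ranking = [c["gene_id"] for c in ranked]
        recovered = bool(ranking) and ranking[0] == vs.causal_gene_id
        _tick(stage, n_candidates=len(ranking), recovered=recovered)

        stage = "rnaseq"
        cm = simulate_rnaseq_counts(config, rng, genes=genes)
        rpkm = compute_rpkm(cm)
        expressed = filter_expressed(rpkm, cm.groups)
        de = differential_test(rpkm, cm.groups, expressed)
        top = cm.top_gene
        ratio = float(
            (de.at[top, "mean_alt"] + 1e-9) / (de.at[top, "mean_ref"] + 1e-9)
        ) if top else float("nan")
        rnaseq_dict = {
            "n_genes": len(cm.counts),
            "n_expressed": int(len(expressed)),
            "n_up": int((de["call"] == "up").sum()),
            "n_down": int((de["call"] == "down").sum()),
            "top_gene": top,
            "top_gene_ratio": ratio,
            "top_gene_called_up": bool(top and de.at[top, "call"] == "up"),
        }
        _tick(stage, n_expressed=rnaseq_dict["n_expressed"], n_up=rnaseq_dict["n_up"], n_down=rnaseq_dict["n_down"])
        logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(stage, exc, intermediates) from exc

    report = RunReport(
        seed=seed,
        config=config.to_dict(),
        segregation=segregation,
        interval=interval_dict,
        snp_index=snp_index_dict,
        candidates=sorted(candidates, key=lambda c: (c["chrom"], c["start"])),
        ranking=ranking,
        recovered=recovered,
        truth={
            "causal_gene": vs.causal_gene_id,
            "causal_variant": {
                "chrom": vs.causal.chrom,
                "pos": vs.causal.pos,
                "ref": vs.causal.ref,
                "alt": vs.causal.alt,
            },
            "n_mutagen": len(vs.by_origin("mutagen")),
            "n_intracultivar": len(vs.by_origin("intra_cultivar")),
        },
        rnaseq=rnaseq_dict,
        stage_counts=counts_log,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cm_io.write_fasta(reference, outdir / "reference.fa")
        cm_io.write_gff3(genes, outdir / "genes.gff3")
        cm_io.write_vcf(vs.variants, outdir / "truth.vcf", reference=reference)
        cm_io.write_pooled_vcf(pooled, outdir / "bulk.vcf", reference=reference)
        cm_io.write_genotype_table(table, outdir / "genotypes.tsv", outdir / "panel.tsv")
        cm_io.write_snp_index_records(records, outdir / "snp_index.tsv")
        cm_io.write_count_matrix(cm, outdir / "counts.tsv", outdir / "gene_lengths.tsv", outdir / "groups.tsv")
        de.to_csv(outdir / "de_results.tsv", sep="\t")
        (outdir / "report.json").write_text(report.to_json() + "\n")
        (outdir / "report.txt").write_text(report.summary() + "\n")
    return report
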