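"""Simulation configuration.

The defaults encode the study conditions the simulator emulates: a
monogenic recessive 2 bp deletion segregating 3:1 in F2 crosses of 109 and
186 plants, a 20-plant mutant-phenotype sequencing bulk at ~30x depth, a
SolCAP-like array of 7600 markers of which 1956 are informative between the
two parental cultivars, gamma-ray mutagen background plus intra-cultivar
polymorphism, and three-replicate ovary RNA-seq with 13 planted up- and 12
planted down-regulated genes, one of them >10-fold up.

The genome itself is a desk-scale stand-in (two 12 Mbp chromosomes at a
tomato-euchromatin-like gene density of ~103 genes/Mbp); see the methods
note for what this does and does not emulate.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml


class ConfigError(ValueError):
    """A configuration value violates its constraints."""


def _default_chromosomes() -> Dict[str, int]:
    return {"chr1": 12_000_000, "chr2": 12_000_000}


@dataclass
class SimulationConfig:
    # genome / annotation
    chromosome_lengths: Dict[str, int] = field(default_factory=_default_chromosomes)
    gene_count: Optional[int] = None          # None => Poisson at gene_density_per_mbp
    gene_density_per_mbp: float = 102.7       # ~267 genes / 2.6 Mbp
    mean_cds_codons: int = 400
    cds_codons_sigma: float = 0.5             # log-normal spread of CDS length
    min_cds_codons: int = 60
    max_cds_codons: int = 1500
    max_exons: int = 3
    intron_min_bp: int = 60
    intron_max_bp: int = 400

    # marker array
    marker_array_size: int = 7600
    informative_markers: int = 1956

    # causal lesion
    causal_gene: Optional[str] = None         # None => auto-pick near causal_chrom midpoint
    causal_chrom: Optional[str] = None        # None => last chromosome (sorted name)
    causal_deletion_bp: int = 2
    causal_exon_index: int = 0                # transcription-order exon carrying the deletion

    # background variation
    mutagen_rate: float = 2e-5                # per bp, homozygous in the mutant parent
    mutagen_indel_fraction: float = 0.1
    intracultivar_rate: float = 3e-5          # per bp, segregating among cultivar plants

    # cross design
    f2_size_mapping: int = 186                # inter-cultivar cross used for array mapping
    f2_size_bulk: int = 109                   # intra-cultivar cross feeding the bulk
    bulk_size: int = 20
    map_kb_per_cm: float = 750.0              # uniform genetic map; math.inf => no recombination
    linkage_n_mutant: int = 83
    linkage_n_wt: int = 80

    # genotyping / sequencing noise
    genotype_error_rate: float = 0.0
    genotype_missing_rate: float = 0.0
    depth_mean: float = 30.0
    seq_error_rate: float = 0.005

    # SNP/Indel-index filters
    min_depth: int = 10
    min_index: float = 0.9

    # RNA-seq stage
    rnaseq_replicates: int = 3
    rnaseq_dispersion: float = 0.002          # replicates pool many ovaries => low dispersion
    rnaseq_n_up: int = 13
    rnaseq_n_down: int = 12
    rnaseq_up_fold: float = 4.0
    rnaseq_down_fold: float = 0.25
    rnaseq_top_fold: float = 12.0             # the >10-fold GA20ox1-like gene
    rnaseq_planted_min_mean: float = 300.0
    rnaseq_planted_max_mean: float = 3000.0   # keeps one planted gene from dominating the library
    rnaseq_log_mean: float = 4.5
    rnaseq_log_sigma: float = 1.6
    rnaseq_n_genes: int = 2000                # used only when no gene models are supplied

    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.chromosome_lengths:
            raise ConfigError("at least one chromosome is required")
        for name, length in self.chromosome_lengths.items():
            if length < 1:
                raise ConfigError(f"chromosome {name!r} has non-positive length")
        for rate_name in (
            "mutagen_rate",
            "intracultivar_rate",
            "mutagen_indel_fraction",
            "genotype_error_rate",
            "genotype_missing_rate",
            "seq_error_rate",
            "min_index",
        ):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"{rate_name} must lie in [0, 1], got {rate}")
        for count_name in (
            "marker_array_size",
            "informative_markers",
            "f2_size_mapping",
            "f2_size_bulk",
            "bulk_size",
            "linkage_n_mutant",
            "linkage_n_wt",
            "min_depth",
            "rnaseq_replicates",
            "rnaseq_n_up",
            "rnaseq_n_down",
            "rnaseq_n_genes",
        ):
            if getattr(self, count_name) < 0:
                raise ConfigError(f"{count_name} must be non-negative")
        if self.gene_count is not None and self.gene_count < 0:
            raise ConfigError("gene_count must be non-negative")
        if self.informative_markers > self.marker_array_size:
            raise ConfigError("informative_markers cannot exceed marker_array_size")
        if self.causal_deletion_bp < 1:
            raise ConfigError("causal_deletion_bp must be at least 1")
        if self.rnaseq_dispersion <= 0:
            raise ConfigError("rnaseq_dispersion must be positive")
        if self.depth_mean < 0:
            raise ConfigError("depth_mean must be non-negative")
        if not (self.map_kb_per_cm > 0 or math.isinf(self.map_kb_per_cm)):
            raise ConfigError("map_kb_per_cm must be positive (math.inf disables recombination)")
        for fold_name in ("rnaseq_up_fold", "rnaseq_down_fold", "rnaseq_top_fold"):
            if getattr(self, fold_name) <= 0:
                raise ConfigError(f"{fold_name} must be positive")

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def morgans(self, chrom: str) -> float:
        """Genetic length of a chromosome in Morgans under the uniform map."""
        if math.isinf(self.map_kb_per_cm):
            return 0.0
        length = self.chromosome_lengths[chrom]
        return length / (self.map_kb_per_cm * 1000.0) / 100.0
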