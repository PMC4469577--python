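"""Pipeline configuration with literature-sourced defaults.

Every stage threshold lives here so a single YAML file drives the whole CLI.
``PipelineConfig.to_yaml`` / ``from_yaml`` round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class SimProfile:
    """Scale of the synthetic cross (kept small so tests run in seconds)."""

    n_chromosomes: int = 2
    chromosome_length_bp: int = 1_000_000
    chromosome_length_cm: float = 150.0
    scaffolds_per_chromosome: int = 5
    n_individuals: int = 59
    depth_mean: float = 5.3
    parent_depth_mean: float = 30.0
    snp_density: float = 1.0 / 500.0  # SNPs per bp
    hemi_fraction: float = 0.1
    n_chimeras: int = 0
    centromere_hits_per_chrom: int = 200
    centromere_spread_bp: int = 50_000
    centromere_background_rate: float = 0.0


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their default values.

    Coordinates are 0-based half-open internally; ``bed_output`` controls
    whether interval files are emitted as BED (0-based half-open) or
    1-based inclusive TSV.
    """

    genome_size_gb: float = 2.5
    seed: int = 1
    bed_output: bool = True

    # parental SNP calling
    parent_min_depth: int = 10
    parent_min_allele_reads: int = 3
    parent_min_allele_fraction: float = 0.20

    # initial F2 genotype calls
    initial_min_depth: int = 4
    initial_min_allele_reads: int = 1

    # block building + sliding-window genotyper
    block_similarity_threshold: float = 0.7
    window_min_depth: int = 40
    error_rate_parent1: float = 0.058
    error_rate_parent2: float = 0.02
    prior_p1p1: float = 0.25
    prior_p2p2: float = 0.25
    prior_p1p2: float = 0.50
    # minimum winning posterior for a windowed call to count as unambiguous
    # (only unambiguous sites enter bin formation)
    posterior_min: float = 0.99

    # linkage
    group_r_max: float = 0.4
    group_lod_min: float = 6.0
    em_tol: float = 1e-8
    em_max_iter: int = 200

    # anchoring / mis-assembly detection
    segment_length: int = 201
    min_segment_run: int = 10
    intra_break_cm_jump: float = 20.0
    anchor_min_scaffold_bp: int = 500_000
    agp_gap_bp: int = 100

    # landscape
    suppression_rate_cm_per_mb: float = 1.0
    density_window_bp: int = 50_000
    snp_poor_min_run: int = 20
    snp_poor_fraction_of_median: float = 0.10
    hit_min_identity: float = 80.0
    hit_max_evalue: float = 1e-20
    centromere_min_hits: int = 5

    # comparative
    synteny_min_anchors: int = 10
    synteny_max_gap: int = 3

    # SSR-anchor concordance
    anchor_flank_bp: int = 10_000

    simulate: SimProfile = field(default_factory=SimProfile)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulate", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"simulate"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(simulate=SimProfile(**sim), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
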