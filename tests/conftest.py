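from __future__ import annotations

import numpy as np
import pytest

from polybinmap.config import PipelineConfig, SimProfile
from polybinmap.pipeline import (
    DiscoveryResult,
    GenotypingResult,
    MapResult,
    discover_snps,
    genotype_population,
    map_population,
)
from polybinmap.simulate import SimulatedCross, simulate_cross


def simple_site_indices(cross: SimulatedCross, discovery: DiscoveryResult) -> np.ndarray:
    """Indices (into the cross's site order) of discovered simple SNPs."""
    key_to_idx = {
        (s, p): i
        for i, (s, p) in enumerate(zip(cross.snps.scaffold, cross.snps.scaffold_pos))
    }
    return np.array([key_to_idx[(r.scaffold, r.position)] for r in discovery.simple])


def run_through_genotyping(
    cross: SimulatedCross, config: PipelineConfig | None = None
) -> tuple[np.ndarray, GenotypingResult]:
    config = config or PipelineConfig()
    disc = discover_snps(
        cross.snps.scaffold,
        cross.snps.scaffold_pos,
        cross.parent1_counts,
        cross.parent2_counts,
        config,
    )
    idx = simple_site_indices(cross, disc)
    result = genotype_population(
        cross.snps.scaffold[idx],
        cross.snps.scaffold_pos[idx],
        cross.f2_c1[idx],
        cross.f2_c2[idx],
        config,
    )
    return idx, result


def run_anchor_pipeline(seed: int, n_chimeras: int, length_cm: float = 50.0):
    """Full simulate -> genotype -> map -> segment pipeline for anchoring tests.

    Returns (cross, map_result, segments, breakpoints).
    """
    from polybinmap.assembly_anchor import (
        assign_segment_positions,
        detect_misassemblies,
        extract_segments,
    )
    from polybinmap.pipeline import apply_group_labels, label_groups_by_majority

    config = PipelineConfig()
    profile = SimProfile(
        n_chromosomes=2,
        chromosome_length_bp=1_000_000,
        chromosome_length_cm=length_cm,
        n_chimeras=n_chimeras,
    )
    cross = simulate_cross(profile, seed)
    idx, geno = run_through_genotyping(cross, config)
    m = map_population(geno.unambiguous, geno.scaffolds, geno.positions0, config)
    mapping = label_groups_by_majority(m.gmap, cross.snps.chrom[idx], m.assignment)
    apply_group_labels(m.gmap, mapping)
    m.bin_positions = {
        bid: (grp.name, float(cm))
        for grp in m.gmap.groups
        for bid, cm in zip(grp.bin_ids, grp.cum_cm)
    }
    lengths = {s.name: s.length for s in cross.scaffolds}
    segments, _ = extract_segments(geno.positions0, geno.scaffolds, lengths)
    segments = assign_segment_positions(segments, m.assignment, m.bin_positions)
    breakpoints = detect_misassemblies(
        segments,
        config.min_segment_run,
        config.intra_break_cm_jump,
        bin_vectors={b.bin_id: b.genotype for b in m.bins},
    )
    return cross, m, segments, breakpoints


@pytest.fixture(scope="session")
def small_profile() -> SimProfile:
    return SimProfile(n_chromosomes=2, chromosome_length_bp=1_000_000)


@pytest.fixture(scope="session")
def small_cross(small_profile) -> SimulatedCross:
    return simulate_cross(small_profile, seed=1)


@pytest.fixture(scope="session")
def small_genotyped(small_cross) -> tuple[np.ndarray, GenotypingResult]:
    return run_through_genotyping(small_cross)


@pytest.fixture(scope="session")
def small_mapped(small_genotyped) -> MapResult:
    idx, geno = small_genotyped
    return map_population(geno.unambiguous, geno.scaffolds, geno.positions0)
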