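"""In-memory stage orchestration shared by the CLI and the test suite.

Each function consumes plain arrays / domain objects and returns a result
dataclass; the CLI wraps these with on-disk formats from
:mod:`polybinmap.iotables`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polybinmap.config import PipelineConfig
from polybinmap.genotypes import MISSING
from polybinmap.genotyping import (
    ErrorModel,
    build_blocks,
    call_initial_matrix,
    slide_windows,
)
from polybinmap.linkage import (
    GeneticMap,
    RecombinationBin,
    build_bins,
    build_genetic_map,
    pairwise_rf_matrix,
)
from polybinmap.snp_discovery import (
    CallThresholds,
    ClassSummary,
    SnpRecord,
    call_parental_site,
    derive_interspecific_snps,
    filter_for_mapping,
)

_ACGT = ("A", "C", "G", "T")


@dataclass
class DiscoveryResult:
    records: list[SnpRecord]
    simple: list[SnpRecord]
    summary: ClassSummary


def discover_snps(
    scaffolds: np.ndarray,
    positions0: np.ndarray,
    parent1_counts: np.ndarray,
    parent2_counts: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> DiscoveryResult:
    """Call both parents at every site and derive classified SNP records."""
    thresholds = CallThresholds(
        config.parent_min_depth,
        config.parent_min_allele_reads,
        config.parent_min_allele_fraction,
    )
    calls = []
    for counts in (parent1_counts, parent2_counts):
        calls.append(
            [
                call_parental_site(
                    dict(zip(_ACGT, counts[i])),
                    thresholds,
                    scaffold=str(scaffolds[i]),
                    position=int(positions0[i]),
                )
                for i in range(len(positions0))
            ]
        )
    records = derive_interspecific_snps(calls[0], calls[1])
    simple, summary = filter_for_mapping(records)
    return DiscoveryResult(records=records, simple=simple, summary=summary)


@dataclass
class GenotypingResult:
    scaffolds: np.ndarray
    positions0: np.ndarray
    initial: np.ndarray  # (sites x individuals)
    blocks: np.ndarray  # globally unique block ids, contiguous per scaffold
    imputed: np.ndarray
    confidence: np.ndarray  # winning posterior per imputed call
    unambiguous: np.ndarray  # imputed with low-confidence entries masked


def genotype_population(
    scaffolds: np.ndarray,
    positions0: np.ndarray,
    c1: np.ndarray,
    c2: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
) -> GenotypingResult:
    """Two-step genotyping of sites ordered by (scaffold, position)."""
    scaffolds = np.asarray(scaffolds)
    positions0 = np.asarray(positions0)
    order = np.lexsort((positions0, scaffolds))
    if not np.array_equal(order, np.arange(len(order))):
        raise ValueError("sites must be ordered by (scaffold, position)")
    error_model = ErrorModel(config.error_rate_parent1, config.error_rate_parent2)
    priors = (config.prior_p1p1, config.prior_p2p2, config.prior_p1p2)
    initial = call_initial_matrix(
        c1, c2, config.initial_min_depth, config.initial_min_allele_reads
    )
    blocks = np.zeros(len(positions0), dtype=np.int64)
    offset = 0
    for scaf in np.unique(scaffolds):
        sel = np.flatnonzero(scaffolds == scaf)
        local = build_blocks(initial[sel], config.block_similarity_threshold)
        blocks[sel] = local + offset
        offset += local.max() + 1 if len(local) else 0
    imputed, confidence = slide_windows(
        c1,
        c2,
        positions0,
        blocks,
        config.window_min_depth,
        error_model,
        priors,
        return_confidence=True,
    )
    # ambiguous calls (boundary-zone windows) are masked before bin formation
    unambiguous = imputed.copy()
    unambiguous[confidence < config.posterior_min] = MISSING
    return GenotypingResult(
        scaffolds, positions0, initial, blocks, imputed, confidence, unambiguous
    )


@dataclass
class MapResult:
    bins: list[RecombinationBin]
    assignment: np.ndarray  # per-site bin id (-1: excluded)
    r: np.ndarray
    lod: np.ndarray
    gmap: GeneticMap
    bin_positions: dict[int, tuple[str, float]] = field(default_factory=dict)

    def group_of_bin(self) -> dict[int, str]:
        return {b: grp for b, (grp, _) in self.bin_positions.items()}


def map_population(
    imputed: np.ndarray,
    scaffolds: np.ndarray,
    positions0: np.ndarray,
    config: PipelineConfig = PipelineConfig(),
    group_labels: dict[int, str] | None = None,
) -> MapResult:
    """Bins -> pairwise (r, LOD) -> grouped/ordered Kosambi map."""
    bins, assignment = build_bins(imputed, scaffolds, positions0)
    geno = np.stack([b.genotype for b in bins])
    r, lod = pairwise_rf_matrix(geno, config.em_tol, config.em_max_iter)
    gmap = build_genetic_map(
        bins, r, lod, config.group_r_max, config.group_lod_min, group_labels
    )
    bin_positions = {}
    for group in gmap.groups:
        for bid, cm in zip(group.bin_ids, group.cum_cm):
            bin_positions[bid] = (group.name, float(cm))
    return MapResult(bins, assignment, r, lod, gmap, bin_positions)


def label_groups_by_majority(
    gmap: GeneticMap, site_labels: np.ndarray, assignment: np.ndarray
) -> dict[str, str]:
    """Relabel linkage groups by the majority site label of their members.

    ``site_labels`` give a framework name per site (e.g. from anchors with
    known chromosome assignments); returns old-name -> new-name.
    """
    site_labels = np.asarray(site_labels)
    mapping = {}
    for group in gmap.groups:
        votes: dict[str, int] = {}
        for bid in group.bin_ids:
            for si in gmap.bins[bid].site_indices:
                lab = str(site_labels[si])
                votes[lab] = votes.get(lab, 0) + 1
        if votes:
            mapping[group.name] = max(sorted(votes), key=lambda k: votes[k])
    return mapping


def apply_group_labels(gmap: GeneticMap, mapping: dict[str, str]) -> None:
    for group in gmap.groups:
        if group.name in mapping:
            group.name = mapping[group.name]


def bin_physical_positions(
    bins: list[RecombinationBin], site_positions: np.ndarray
) -> dict[int, float]:
    """Median physical position of each bin's member sites."""
    site_positions = np.asarray(site_positions)
    return {
        b.bin_id: float(np.median(site_positions[b.site_indices])) for b in bins
    }
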