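"""Scaffold mis-assembly detection and anchoring into pseudomolecules.

Every mapped SNP yields a 201-bp segment centred on it.  Segments that map
uniquely at full length carry their bin's genetic position (linkage group +
cM).  Within a scaffold, maximal runs of consecutive segments sharing a
genetic position are computed; runs of at least ``min_run`` (default 10)
segments are *stable*.  A breakpoint is emitted between adjacent stable runs
whose genetic positions disagree — different groups, or a cM jump beyond the
adjacency tolerance — and classified as homoeologous (A/D partner groups),
interchromosomal or intrachromosomal.  Chimeric scaffolds are split at
breakpoint midpoints; pieces are ordered within their group by median cM,
oriented by the sign of the cM-vs-coordinate rank correlation, and laid out
as AGP rows with fixed-size gaps.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

HOMOEOLOGOUS = "homoeologous"
INTERCHROMOSOMAL = "interchromosomal"
INTRACHROMOSOMAL = "intrachromosomal"


@dataclass
class SnpSegment:
    """A 201-bp scaffold segment centred on a mapped SNP (0-based half-open)."""

    scaffold: str
    start: int
    end: int
    snp_index: int
    bin_id: int = -1
    group: str = ""
    cm: float = float("nan")
    unique: bool = True

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class Breakpoint:
    scaffold: str
    left_end: int  # end of the last segment of the left stable run
    right_start: int  # start of the first segment of the right stable run
    left_position: tuple[str, float]  # (group, cM)
    right_position: tuple[str, float]
    classification: str

    @property
    def midpoint(self) -> int:
        return (self.left_end + self.right_start) // 2


@dataclass
class PlacedPiece:
    name: str
    scaffold: str
    start: int  # within-scaffold, 0-based half-open
    end: int
    group: str
    median_cm: float
    orientation: str  # "+", "-", or "?"


@dataclass
class PseudomoleculeLayout:
    placed: dict[str, list[PlacedPiece]]  # group -> ordered pieces
    unplaced: list[PlacedPiece] = field(default_factory=list)

    def agp_rows(self, gap_bp: int = 100) -> list[tuple]:
        """AGP v2.1 rows (1-based inclusive object coordinates)."""
        rows = []
        for group in sorted(self.placed):
            pos = 0
            part = 0
            for i, piece in enumerate(self.placed[group]):
                if i > 0:
                    part += 1
                    rows.append(
                        (group, pos + 1, pos + gap_bp, part, "N", gap_bp, "scaffold", "yes", "map")
                    )
                    pos += gap_bp
                part += 1
                length = piece.end - piece.start
                orient = piece.orientation if piece.orientation in "+-" else "?"
                rows.append(
                    (
                        group,
                        pos + 1,
                        pos + length,
                        part,
                        "W",
                        piece.scaffold,
                        piece.start + 1,
                        piece.end,
                        orient,
                    )
                )
                pos += length
        return rows


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------


def extract_segments(
    snp_positions: np.ndarray,
    snp_scaffolds: np.ndarray,
    scaffold_lengths: dict[str, int],
    segment_length: int = 201,
) -> tuple[list[SnpSegment], int]:
    """One centred segment per mapped SNP; edge SNPs are skipped and counted.

    Positions are 0-based.  Returns (segments, n_skipped_at_edges).
    """
    half = segment_length // 2
    segments = []
    skipped = 0
    for i, (pos, scaf) in enumerate(zip(snp_positions, snp_scaffolds)):
        pos = int(pos)
        length = scaffold_lengths[str(scaf)]
        start, end = pos - half, pos + half + 1
        if start < 0 or end > length:
            skipped += 1
            continue
        segments.append(SnpSegment(str(scaf), start, end, i))
    return segments, skipped


def count_exact_occurrences(queries: list[str], genome: dict[str, str]) -> list[int]:
    """Occurrence count of each query (either strand) across genome sequences.

    Single linear scan of every sequence with a membership set, so cost is
    O(genome size x query length) independent of the number of queries.
    """
    if not queries:
        return []
    k = len(queries[0])
    if any(len(q) != k for q in queries):
        raise ValueError("all queries must have equal length")
    comp = str.maketrans("ACGT", "TGCA")
    fwd = {}
    for i, q in enumerate(queries):
        fwd.setdefault(q, []).append(i)
        fwd.setdefault(q.translate(comp)[::-1], []).append(i)
    counts = [0] * len(queries)
    for seq in genome.values():
        for j in range(len(seq) - k + 1):
            hits = fwd.get(seq[j : j + k])
            if hits:
                for i in hits:
                    counts[i] += 1
    return counts


def assign_segment_positions(
    segments: list[SnpSegment],
    site_bin: np.ndarray,
    bin_positions: dict[int, tuple[str, float]],
    unique_flags: dict[int, bool] | None = None,
    full_length: int = 201,
) -> list[SnpSegment]:
    """Attach (group, cM) to segments; drop unusable ones.

    Dropped: segments whose SNP is not in a mapped bin, segments flagged
    multi-mapping, and segments shorter than ``full_length`` (partial
    matches).  ``unique_flags`` maps snp_index -> uniquely-mapped, default
    all unique (for real data the flag column comes from the upstream
    aligner; on synthetic genomes use :func:`count_exact_occurrences`).
    """
    out = []
    for seg in segments:
        if seg.length < full_length:
            continue
        if unique_flags is not None and not unique_flags.get(seg.snp_index, False):
            continue
        bid = int(site_bin[seg.snp_index])
        if bid < 0 or bid not in bin_positions:
            continue
        group, cm = bin_positions[bid]
        out.append(
            SnpSegment(seg.scaffold, seg.start, seg.end, seg.snp_index, bid, group, cm, True)
        )
    return out


# ---------------------------------------------------------------------------
# mis-assembly detection
# ---------------------------------------------------------------------------

_GROUP_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def classify_breakpoint(
    left_group: str, right_group: str, pairing: dict[str, str] | None = None
) -> str:
    """Homoeologous when the groups are subgenome partners (A05/D05), else
    inter- or intrachromosomal.  ``pairing`` overrides the index-pairing
    convention for other polyploids."""
    if left_group == right_group:
        return INTRACHROMOSOMAL
    if pairing is not None:
        if pairing.get(left_group) == right_group or pairing.get(right_group) == left_group:
            return HOMOEOLOGOUS
        return INTERCHROMOSOMAL
    m1, m2 = _GROUP_RE.match(left_group), _GROUP_RE.match(right_group)
    if m1 and m2 and m1.group(2) == m2.group(2) and m1.group(1) != m2.group(1):
        return HOMOEOLOGOUS
    return INTERCHROMOSOMAL


def _stable_runs(
    segments: list[SnpSegment], min_run: int
) -> list[tuple[int, int, str, float, int]]:
    """Maximal runs of consecutive segments in the same bin.

    Returns (first_idx, last_idx, group, cM, bin_id) for runs of >= min_run
    segments.
    """
    runs = []
    i = 0
    while i < len(segments):
        j = i
        while j + 1 < len(segments) and segments[j + 1].bin_id == segments[i].bin_id:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i, j, segments[i].group, segments[i].cm, segments[i].bin_id))
        i = j + 1
    return runs


def detect_misassemblies(
    segments: list[SnpSegment],
    min_run: int = 10,
    cm_jump: float = 20.0,
    pairing: dict[str, str] | None = None,
    bin_vectors: dict[int, "np.ndarray"] | None = None,
) -> list[Breakpoint]:
    """Breakpoints between adjacent stable runs with conflicting positions.

    ``segments`` may cover several scaffolds; they are ordered by scaffold
    coordinate within each scaffold.  Runs shorter than ``min_run`` are
    ignored.  Adjacent stable runs conflict when their groups differ or,
    within a group, when their genetic positions jump by more than
    ``cm_jump``.  When ``bin_vectors`` supplies the bins' genotype vectors
    the within-group jump is measured as the Kosambi distance of the two
    bins' directly estimated recombination fraction — robust to local
    bin-ordering noise in the map — otherwise as the map-position
    difference, explained away when intervening (unstable) same-group
    segments form a cM staircase with no step over ``cm_jump``.
    """
    from polybinmap.linkage import estimate_rf_f2, kosambi

    by_scaffold: dict[str, list[SnpSegment]] = {}
    for seg in segments:
        by_scaffold.setdefault(seg.scaffold, []).append(seg)
    breakpoints = []
    for scaf in sorted(by_scaffold):
        segs = sorted(by_scaffold[scaf], key=lambda s: s.start)
        runs = _stable_runs(segs, min_run)
        for (_, l_end, l_grp, l_cm, l_bid), (r_start, _, r_grp, r_cm, r_bid) in zip(
            runs, runs[1:]
        ):
            if l_grp == r_grp:
                if bin_vectors is not None:
                    r_hat = estimate_rf_f2(bin_vectors[l_bid], bin_vectors[r_bid]).r
                    if kosambi(min(r_hat, 0.4999)) <= cm_jump:
                        continue
                else:
                    if abs(l_cm - r_cm) <= cm_jump:
                        continue
                    # a cM staircase through intervening (unstable) same-group
                    # segments explains the jump without a real discontinuity
                    ladder = [l_cm]
                    ladder += [
                        s.cm for s in segs[l_end + 1 : r_start] if s.group == l_grp
                    ]
                    ladder.append(r_cm)
                    if max(abs(b - a) for a, b in zip(ladder, ladder[1:])) <= cm_jump:
                        continue
            breakpoints.append(
                Breakpoint(
                    scaffold=scaf,
                    left_end=segs[l_end].end,
                    right_start=segs[r_start].start,
                    left_position=(l_grp, l_cm),
                    right_position=(r_grp, r_cm),
                    classification=classify_breakpoint(l_grp, r_grp, pairing),
                )
            )
    return breakpoints


# ---------------------------------------------------------------------------
# splitting and anchoring
# ---------------------------------------------------------------------------


def split_and_anchor(
    scaffold_lengths: dict[str, int],
    segments: list[SnpSegment],
    breakpoints: list[Breakpoint],
    min_scaffold_bp: int = 500_000,
    orient_min_abs_rho: float = 0.5,
) -> PseudomoleculeLayout:
    """Split chimeras at breakpoint midpoints and anchor pieces by cM.

    Each piece takes the group of its stable segments, is ordered within the
    group by median cM of its segments, and oriented by the sign of the
    Spearman correlation between scaffold coordinate and cM (|rho| below
    ``orient_min_abs_rho`` leaves the piece unoriented).  Pieces shorter than
    ``min_scaffold_bp`` or without mapped segments are reported unplaced.
    """
    cuts: dict[str, list[int]] = {}
    for bp in breakpoints:
        cuts.setdefault(bp.scaffold, []).append(bp.midpoint)
    seg_by_scaffold: dict[str, list[SnpSegment]] = {}
    for seg in segments:
        seg_by_scaffold.setdefault(seg.scaffold, []).append(seg)

    placed: dict[str, list[PlacedPiece]] = {}
    unplaced: list[PlacedPiece] = []
    for scaf in sorted(scaffold_lengths):
        length = scaffold_lengths[scaf]
        edges = [0] + sorted(cuts.get(scaf, [])) + [length]
        multi = len(edges) > 2
        for pi, (lo, hi) in enumerate(zip(edges, edges[1:])):
            name = f"{scaf}:part{pi + 1}" if multi else scaf
            segs = [s for s in seg_by_scaffold.get(scaf, []) if lo <= s.center < hi]
            if not segs:
                unplaced.append(PlacedPiece(name, scaf, lo, hi, "", float("nan"), "?"))
                continue
            groups = {s.group for s in segs}
            if multi and len(groups) > 1:
                raise ValueError(f"piece {name} spans groups {sorted(groups)} after splitting")
            group = max(groups, key=lambda g: sum(s.group == g for s in segs))
            gsegs = [s for s in segs if s.group == group]
            med = float(np.median([s.cm for s in gsegs]))
            if len({s.cm for s in gsegs}) > 1 and len({s.center for s in gsegs}) > 1:
                rho = spearmanr([s.center for s in gsegs], [s.cm for s in gsegs]).statistic
            else:
                rho = 0.0
            if np.isnan(rho) or abs(rho) < orient_min_abs_rho:
                orient = "?"
            else:
                orient = "+" if rho > 0 else "-"
            piece = PlacedPiece(name, scaf, lo, hi, group, med, orient)
            if hi - lo >= min_scaffold_bp:
                placed.setdefault(group, []).append(piece)
            else:
                unplaced.append(piece)
    for group in placed:
        placed[group].sort(key=lambda p: (p.median_cm, p.name))
    return PseudomoleculeLayout(placed=placed, unplaced=unplaced)
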