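"""Genetic-map versus reference-genome comparison.

Anchors (map position -> reference chromosome/bp, best hit only) are chained
into synteny blocks: maximal runs collinear in reference coordinate with a
consistent orientation, tolerating up to ``max_gap`` inconsistent anchors
and discarding runs shorter than ``min_anchors``.  Block patterns are then
interpreted against each linkage group's configured "home" reference
chromosome:

* reciprocal translocation — two groups each carry a block on the other's
  home chromosome (exchange pattern);
* simple translocation — an isolated foreign-chromosome block inside an
  otherwise homogeneous group;
* inversion — an orientation-reversed block inside a same-chromosome
  context.
"""

from __future__ import annotations

from dataclasses import dataclass, field

RECIPROCAL = "reciprocal_translocation"
SIMPLE_TRANSLOCATION = "simple_translocation"
INVERSION = "inversion"


@dataclass
class SyntenyAnchor:
    group: str
    map_cm: float
    ref_chrom: str
    ref_bp: int
    orientation: str = "+"


@dataclass
class SyntenyBlock:
    group: str
    ref_chrom: str
    orientation: str  # "+" or "-"
    anchors: list[SyntenyAnchor] = field(default_factory=list)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def cm_range(self) -> tuple[float, float]:
        cms = [a.map_cm for a in self.anchors]
        return min(cms), max(cms)

    @property
    def ref_range(self) -> tuple[int, int]:
        bps = [a.ref_bp for a in self.anchors]
        return min(bps), max(bps)


@dataclass
class RearrangementSegment:
    group: str
    cm_lo: float
    cm_hi: float
    ref_chrom: str
    ref_start: int
    ref_end: int
    size_mb: float
    fraction_pct: float | None = None


@dataclass
class RearrangementCall:
    rtype: str
    segments: list[RearrangementSegment]


def interval_length_mb(start_bp: int, end_bp: int) -> float:
    """(end - start) / 1e6, two decimals; end must be >= start."""
    if end_bp < start_bp:
        raise ValueError("end before start")
    return round((end_bp - start_bp) / 1e6, 2)


def fraction_of_chromosome(interval_mb: float, chrom_length_mb: float) -> float:
    """Interval as a percent of its chromosome, two decimals."""
    if chrom_length_mb <= 0:
        raise ValueError("chromosome length must be positive")
    if interval_mb > chrom_length_mb:
        raise ValueError("interval longer than chromosome")
    return round(100.0 * interval_mb / chrom_length_mb, 2)


# ---------------------------------------------------------------------------
# block chaining
# ---------------------------------------------------------------------------


def build_synteny_blocks(
    anchors: list[SyntenyAnchor], min_anchors: int = 10, max_gap: int = 3
) -> list[SyntenyBlock]:
    """Chain map-ordered anchors into collinear blocks.

    An anchor extends the current block when it shares the block's reference
    chromosome and keeps its reference coordinate strictly monotone in the
    block's direction (fixed by the first two members).  Up to ``max_gap``
    consecutive inconsistent anchors are skipped; a longer inconsistent
    stretch closes the block and chaining restarts at the first skipped
    anchor.  Runs shorter than ``min_anchors`` are discarded.
    """
    ordered = sorted(anchors, key=lambda a: (a.map_cm, a.ref_chrom, a.ref_bp))
    blocks: list[SyntenyBlock] = []
    i = 0
    n = len(ordered)
    while i < n:
        member = [ordered[i]]
        direction = 0
        skipped_at: int | None = None
        gap = 0
        j = i + 1
        while j < n:
            a = ordered[j]
            prev = member[-1]
            ok = a.ref_chrom == prev.ref_chrom
            if ok and direction == 0 and a.ref_bp != prev.ref_bp:
                direction_candidate = 1 if a.ref_bp > prev.ref_bp else -1
            else:
                direction_candidate = direction
            if ok and direction_candidate != 0:
                step = a.ref_bp - prev.ref_bp
                ok = step * direction_candidate > 0
            if ok:
                member.append(a)
                direction = direction_candidate
                gap = 0
                skipped_at = None
            else:
                if skipped_at is None:
                    skipped_at = j
                gap += 1
                if gap > max_gap:
                    break
            j += 1
        if len(member) >= min_anchors:
            orient = "-" if direction < 0 else "+"
            blocks.append(
                SyntenyBlock(member[0].group, member[0].ref_chrom, orient, member)
            )
        i = skipped_at if skipped_at is not None else j
    return blocks


# ---------------------------------------------------------------------------
# rearrangement calls
# ---------------------------------------------------------------------------


def _segment(block: SyntenyBlock, ref_lengths_mb: dict[str, float] | None) -> RearrangementSegment:
    lo_cm, hi_cm = block.cm_range
    lo_bp, hi_bp = block.ref_range
    size = interval_length_mb(lo_bp, hi_bp)
    frac = None
    if ref_lengths_mb and block.ref_chrom in ref_lengths_mb:
        frac = fraction_of_chromosome(size, ref_lengths_mb[block.ref_chrom])
    return RearrangementSegment(
        block.group, lo_cm, hi_cm, block.ref_chrom, lo_bp, hi_bp, size, frac
    )


def detect_rearrangements(
    blocks: list[SyntenyBlock],
    home_chrom: dict[str, str],
    ref_lengths_mb: dict[str, float] | None = None,
) -> list[RearrangementCall]:
    """Classify synteny blocks into rearrangement calls.

    ``home_chrom`` maps each linkage group to its expected reference
    chromosome.  Groups without blocks are skipped.
    """
    by_group: dict[str, list[SyntenyBlock]] = {}
    for b in blocks:
        by_group.setdefault(b.group, []).append(b)

    calls: list[RearrangementCall] = []
    used_in_reciprocal: set[id] = set()

    groups = sorted(by_group)
    for gi, g1 in enumerate(groups):
        for g2 in groups[gi + 1 :]:
            h1, h2 = home_chrom.get(g1), home_chrom.get(g2)
            if h1 is None or h2 is None or h1 == h2:
                continue
            b12 = [b for b in by_group[g1] if b.ref_chrom == h2]
            b21 = [b for b in by_group[g2] if b.ref_chrom == h1]
            if b12 and b21:
                big12 = max(b12, key=lambda b: b.n_anchors)
                big21 = max(b21, key=lambda b: b.n_anchors)
                used_in_reciprocal.update({id(big12), id(big21)})
                segs = sorted(
                    [_segment(big12, ref_lengths_mb), _segment(big21, ref_lengths_mb)],
                    key=lambda s: s.group,
                )
                calls.append(RearrangementCall(RECIPROCAL, segs))

    for group in groups:
        home = home_chrom.get(group)
        gblocks = by_group[group]
        home_blocks = [b for b in gblocks if b.ref_chrom == home]
        for b in gblocks:
            if id(b) in used_in_reciprocal:
                continue
            if b.ref_chrom != home:
                calls.append(
                    RearrangementCall(SIMPLE_TRANSLOCATION, [_segment(b, ref_lengths_mb)])
                )
        if home_blocks:
            # dominant orientation among home-chromosome blocks, by anchor mass
            plus = sum(b.n_anchors for b in home_blocks if b.orientation == "+")
            minus = sum(b.n_anchors for b in home_blocks if b.orientation == "-")
            dominant = "+" if plus >= minus else "-"
            for b in home_blocks:
                if b.orientation != dominant and len(home_blocks) > 1:
                    calls.append(RearrangementCall(INVERSION, [_segment(b, ref_lengths_mb)]))
    return calls
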