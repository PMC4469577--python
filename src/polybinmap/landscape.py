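"""Recombination landscapes, SNP-density scans and centromere localization.

Recombination rate per adjacent-bin interval is delta-cM / delta-Mb;
intervals below 1.0 cM/Mb are *suppression* regions, the rest *hotspots*.
SNP density is counted in 50-kb windows; runs of >= 20 consecutive
low-density windows become SNP-poor regions.  Centromeric regions come from
repeat-homology hits filtered at >= 80 % identity and e-value <= 1e-20: the
region is the distribution-free 95 % confidence interval of the median hit
position (order-statistic ranks from Binomial(n, 1/2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

SUPPRESSION = "suppression"
HOTSPOT = "hotspot"


@dataclass
class RateSegment:
    chromosome: str
    start: int  # bp, 0-based half-open
    end: int
    cm_span: float
    rate: float  # cM/Mb
    klass: str


@dataclass
class HomologyHit:
    """One tabular (outfmt-6 style) alignment of a repeat query to the genome."""

    query: str
    subject: str
    identity: float
    length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int  # 1-based inclusive, normalized so sstart <= send
    send: int
    evalue: float
    bitscore: float
    strand: str = "+"

    @property
    def midpoint(self) -> int:
        return (self.sstart + self.send) // 2


@dataclass
class CentromereInterval:
    chromosome: str
    median: float
    ci_low: float
    ci_high: float
    n_hits: int


# ---------------------------------------------------------------------------
# recombination profile
# ---------------------------------------------------------------------------


def recombination_profile(
    chromosome: str,
    bin_bp: np.ndarray,
    bin_cm: np.ndarray,
    suppression_threshold: float = 1.0,
) -> list[RateSegment]:
    """Per adjacent-bin-interval cM/Mb rate with suppression/hotspot classes.

    ``bin_bp`` are anchored physical midpoints and ``bin_cm`` cumulative map
    positions, in map order.  Intervals with zero physical span are skipped.
    """
    bin_bp = np.asarray(bin_bp, dtype=float)
    bin_cm = np.asarray(bin_cm, dtype=float)
    if bin_bp.shape != bin_cm.shape:
        raise ValueError("bp and cM arrays must align")
    segments = []
    for i in range(len(bin_bp) - 1):
        lo, hi = sorted((bin_bp[i], bin_bp[i + 1]))
        span_mb = (hi - lo) / 1e6
        if span_mb == 0:
            continue
        cm = abs(bin_cm[i + 1] - bin_cm[i])
        rate = cm / span_mb
        klass = SUPPRESSION if rate < suppression_threshold else HOTSPOT
        segments.append(RateSegment(chromosome, int(lo), int(hi), cm, rate, klass))
    return segments


def mean_rate(segments: list[RateSegment]) -> float:
    """Physical-length-weighted mean rate == total cM / total Mb."""
    total_cm = sum(s.cm_span for s in segments)
    total_mb = sum((s.end - s.start) / 1e6 for s in segments)
    return total_cm / total_mb if total_mb else float("nan")


# ---------------------------------------------------------------------------
# SNP density
# ---------------------------------------------------------------------------


def snp_density_scan(
    positions: np.ndarray, chrom_length: int, window_bp: int = 50_000
) -> tuple[np.ndarray, np.ndarray]:
    """SNP counts per half-open window; the final partial window is kept.

    Returns (counts, window_widths).
    """
    positions = np.asarray(positions)
    if positions.size and (positions.min() < 0 or positions.max() >= chrom_length):
        raise ValueError("SNP position outside chromosome bounds")
    n_win = max(1, -(-chrom_length // window_bp))
    counts = np.bincount(positions // window_bp, minlength=n_win).astype(np.int64)
    widths = np.full(n_win, window_bp, dtype=np.int64)
    widths[-1] = chrom_length - (n_win - 1) * window_bp
    return counts, widths


def detect_snp_poor(
    counts: np.ndarray,
    window_bp: int = 50_000,
    min_run: int = 20,
    low_threshold: float | None = None,
    genome_median: float | None = None,
    median_fraction: float = 0.10,
) -> list[tuple[int, int]]:
    """Intervals of >= ``min_run`` consecutive windows below the low threshold.

    Default threshold: ``median_fraction`` of the genome-wide median window
    count (pass ``genome_median`` when scanning one chromosome of many).
    Returns bp intervals (0-based half-open).
    """
    counts = np.asarray(counts)
    if low_threshold is None:
        med = genome_median if genome_median is not None else float(np.median(counts))
        low_threshold = median_fraction * med
    low = counts < low_threshold
    intervals = []
    i = 0
    n = len(low)
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                intervals.append((i * window_bp, (j + 1) * window_bp))
            i = j + 1
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# centromeres
# ---------------------------------------------------------------------------


def filter_hits(
    hits: list[HomologyHit], min_identity: float = 80.0, max_evalue: float = 1e-20
) -> list[HomologyHit]:
    """Keep hits with identity >= ``min_identity`` and e-value <= ``max_evalue``."""
    return [h for h in hits if h.identity >= min_identity and h.evalue <= max_evalue]


def median_ci_ranks(n: int, confidence: float = 0.95) -> tuple[int, int]:
    """1-based order-statistic ranks bounding the median's CI.

    Lower rank l is the Binomial(n, 1/2) quantile at alpha/2; upper is
    n + 1 - l (e.g. n=25 -> ranks (8, 18))."""
    if n < 1:
        raise ValueError("need n >= 1")
    alpha = 1.0 - confidence
    low = int(stats.binom.ppf(alpha / 2.0, n, 0.5))
    low = max(low, 1)
    high = n + 1 - low
    return low, high


def centromere_interval(
    chromosome: str,
    hits: list[HomologyHit],
    min_hits: int = 5,
    confidence: float = 0.95,
) -> CentromereInterval | None:
    """Median hit midpoint and its order-statistic CI; None below min_hits.

    Callers choosing the pooled recipe merge hits from all query repeats
    before calling; the per-query recipe calls once per query and combines.
    """
    if len(hits) < min_hits:
        return None
    mids = np.sort(np.array([h.midpoint for h in hits], dtype=float))
    n = len(mids)
    low, high = median_ci_ranks(n, confidence)
    return CentromereInterval(
        chromosome=chromosome,
        median=float(np.median(mids)),
        ci_low=float(mids[low - 1]),
        ci_high=float(mids[high - 1]),
        n_hits=n,
    )


def subgenome_hit_summary(
    hits: list[HomologyHit],
    chrom_to_subgenome: dict[str, str],
) -> dict:
    """Per-chromosome and per-subgenome hit counts with a Welch t-test.

    The t-test compares per-chromosome counts between the two subgenomes and
    is skipped (statistic None) when either side has fewer than two
    chromosomes.
    """
    per_chrom: dict[str, int] = {c: 0 for c in chrom_to_subgenome}
    for h in hits:
        if h.subject in per_chrom:
            per_chrom[h.subject] += 1
    subgenomes = sorted(set(chrom_to_subgenome.values()))
    by_sub = {
        s: [per_chrom[c] for c in sorted(per_chrom) if chrom_to_subgenome[c] == s]
        for s in subgenomes
    }
    result = {
        "per_chromosome": per_chrom,
        "subgenome_totals": {s: int(np.sum(v)) for s, v in by_sub.items()},
        "subgenome_means": {s: float(np.mean(v)) if v else float("nan") for s, v in by_sub.items()},
        "t_statistic": None,
        "p_value": None,
    }
    if len(subgenomes) == 2 and all(len(v) >= 2 for v in by_sub.values()):
        a, b = by_sub[subgenomes[0]], by_sub[subgenomes[1]]
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            result["t_statistic"], result["p_value"] = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            result["t_statistic"] = float(t)
            result["p_value"] = float(p)
    return result
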