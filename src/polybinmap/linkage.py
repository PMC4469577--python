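"""Recombination-bin construction and genetic-map building.

Sites with complete (no-missing) imputed genotype vectors are collapsed into
*recombination bins* by exact vector equality; bins are grouped into linkage
groups by single-linkage closure over pairs with recombination fraction
r < 0.4 and LOD >= 6, ordered within groups (greedy nearest-neighbour
chaining plus 2-opt), and spaced by the Kosambi mapping function
``d = 25 ln((1+2r)/(1-2r))`` cM.

The recombination fraction between two codominant F2 loci is the maximum
likelihood estimate obtained by EM over the nine genotype-pair classes, the
double-heterozygote class being a phase mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from polybinmap.genotypes import A, B, H, MISSING
from polybinmap.genotyping import similarity_score


def kosambi(r) -> np.ndarray | float:
    """Kosambi map distance in centimorgans; defined on 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("kosambi requires 0 <= r < 0.5")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


@dataclass
class RecombinationBin:
    """A class of SNP sites with identical complete genotype vectors."""

    bin_id: int
    site_indices: np.ndarray  # indices into the source genotype matrix
    genotype: np.ndarray  # representative vector over individuals
    scaffolds: list[str] = field(default_factory=list)
    first_position: int = 0

    @property
    def n_snps(self) -> int:
        return len(self.site_indices)


@dataclass
class RecombinationEstimate:
    r: float
    lod: float
    n: int
    low_confidence: bool = False


@dataclass
class LinkageGroup:
    name: str
    bin_ids: list[int]  # ordered
    cum_cm: np.ndarray  # cumulative cM per bin, starts at 0

    @property
    def length_cm(self) -> float:
        return float(self.cum_cm[-1]) if len(self.cum_cm) else 0.0


@dataclass
class GeneticMap:
    bins: list[RecombinationBin]
    groups: list[LinkageGroup]

    @property
    def total_length_cm(self) -> float:
        return sum(g.length_cm for g in self.groups)

    @property
    def total_bins(self) -> int:
        return sum(len(g.bin_ids) for g in self.groups)


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------


def build_bins(
    genotypes: np.ndarray,
    site_scaffolds: np.ndarray | None = None,
    site_positions: np.ndarray | None = None,
) -> tuple[list[RecombinationBin], np.ndarray]:
    """Partition complete-genotype sites into bins by exact vector equality.

    Sites with any missing entry are excluded from bin formation (their
    assignment is -1 in the returned per-site array).  Bin ids are assigned
    by the position of each bin's first member site.
    """
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.size == 0:
        raise ValueError("empty genotype matrix")
    n_sites = genotypes.shape[0]
    if site_scaffolds is None:
        site_scaffolds = np.array([""] * n_sites)
    if site_positions is None:
        site_positions = np.arange(n_sites)
    complete = ~(genotypes == MISSING).any(axis=1)
    assignment = np.full(n_sites, -1, dtype=np.int64)
    groups: dict[bytes, list[int]] = {}
    for i in np.flatnonzero(complete):
        groups.setdefault(genotypes[i].tobytes(), []).append(i)
    members = sorted(groups.values(), key=lambda idx: idx[0])
    bins = []
    for bid, idx in enumerate(members):
        idx_arr = np.array(idx)
        assignment[idx_arr] = bid
        bins.append(
            RecombinationBin(
                bin_id=bid,
                site_indices=idx_arr,
                genotype=genotypes[idx[0]].copy(),
                scaffolds=sorted(set(site_scaffolds[idx_arr].tolist())),
                first_position=int(site_positions[idx[0]]),
            )
        )
    return bins, assignment


# ---------------------------------------------------------------------------
# recombination fraction (F2, codominant) by EM
# ---------------------------------------------------------------------------


def _pair_counts(g1: np.ndarray, g2: np.ndarray) -> dict[str, int]:
    ok = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[ok], g2[ok]
    keys = {}
    for x, xs in ((A, "A"), (H, "H"), (B, "B")):
        for y, ys in ((A, "A"), (H, "H"), (B, "B")):
            keys[xs + ys] = int(((a == x) & (b == y)).sum())
    return keys


def _em_r(
    n_fixed_rec: np.ndarray,
    n_hh: np.ndarray,
    n_total: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """EM for r given fixed recombinant-gamete counts and the HH mixture.

    ``n_fixed_rec`` counts recombinant gametes from unambiguous classes
    (single-het pairs contribute 1, opposite-homozygote pairs 2); each
    double-het individual contributes 0 or 2 with posterior weight
    r^2 / ((1-r)^2 + r^2) for the recombinant phase.
    """
    r = np.full(np.shape(n_total), 0.25, dtype=float)
    two_n = 2.0 * np.maximum(n_total, 1)
    for _ in range(max_iter):
        w = r**2 / ((1.0 - r) ** 2 + r**2)
        r_new = (n_fixed_rec + 2.0 * n_hh * w) / two_n
        r_new = np.clip(r_new, 1e-12, 0.5)
        if np.all(np.abs(r_new - r) < tol):
            r = r_new
            break
        r = r_new
    return np.asarray(r, dtype=float)


def _log10_likelihood(counts: dict[str, np.ndarray], r: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = {
            "hom_same": np.log10((1.0 - r) ** 2 / 4.0),
            "hom_diff": np.log10(r**2 / 4.0),
            "single_het": np.log10(r * (1.0 - r) / 2.0),
            "hh": np.log10(((1.0 - r) ** 2 + r**2) / 2.0),
        }
    total = np.zeros(np.shape(r))
    for key, n in counts.items():
        term = np.where(n > 0, n * lp[key], 0.0)
        total = total + term
    return total


def estimate_rf_f2(
    g1: np.ndarray,
    g2: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    min_joint: int = 10,
) -> RecombinationEstimate:
    """ML recombination fraction and LOD between two codominant F2 loci."""
    c = _pair_counts(np.asarray(g1), np.asarray(g2))
    n = sum(c.values())
    hom_same = c["AA"] + c["BB"]
    hom_diff = c["AB"] + c["BA"]
    single_het = c["AH"] + c["HA"] + c["BH"] + c["HB"]
    n_fixed = single_het + 2 * hom_diff
    r = _em_r(np.array(float(n_fixed)), np.array(float(c["HH"])), np.array(float(n)), tol, max_iter)
    counts = {
        "hom_same": np.array(float(hom_same)),
        "hom_diff": np.array(float(hom_diff)),
        "single_het": np.array(float(single_het)),
        "hh": np.array(float(c["HH"])),
    }
    lod = _log10_likelihood(counts, r) - _log10_likelihood(counts, np.array(0.5))
    return RecombinationEstimate(
        r=float(np.clip(r, 0.0, 0.5)),
        lod=float(max(lod, 0.0)),
        n=n,
        low_confidence=n < min_joint,
    )


def pairwise_rf_matrix(
    bin_genotypes: np.ndarray, tol: float = 1e-8, max_iter: int = 200
) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (r, LOD) between bins, vectorized over the 9 class counts.

    ``bin_genotypes`` is (bins x individuals) and must be missing-free (the
    bin definition guarantees it).
    """
    g = np.asarray(bin_genotypes, dtype=np.int8)
    if (g == MISSING).any():
        raise ValueError("bin genotype vectors must be complete")
    ind = {x: (g == x).astype(np.float64) for x in (A, H, B)}
    n_pair = {}
    for x in (A, H, B):
        for y in (A, H, B):
            n_pair[(x, y)] = ind[x] @ ind[y].T
    n_total = np.full(n_pair[(A, A)].shape, float(g.shape[1]))
    hom_same = n_pair[(A, A)] + n_pair[(B, B)]
    hom_diff = n_pair[(A, B)] + n_pair[(B, A)]
    single_het = n_pair[(A, H)] + n_pair[(H, A)] + n_pair[(B, H)] + n_pair[(H, B)]
    hh = n_pair[(H, H)]
    n_fixed = single_het + 2.0 * hom_diff
    r = _em_r(n_fixed, hh, n_total, tol, max_iter)
    counts = {"hom_same": hom_same, "hom_diff": hom_diff, "single_het": single_het, "hh": hh}
    lod = _log10_likelihood(counts, r) - _log10_likelihood(counts, np.full_like(r, 0.5))
    lod = np.maximum(lod, 0.0)
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(lod, np.inf)
    return r, lod


# ---------------------------------------------------------------------------
# grouping and ordering
# ---------------------------------------------------------------------------


def group_bins(
    r: np.ndarray, lod: np.ndarray, r_max: float = 0.4, lod_min: float = 6.0
) -> list[list[int]]:
    """Single-linkage transitive closure over qualifying edges.

    Returns lists of bin indices, largest group first; singletons (bins with
    no qualifying edge) come last.
    """
    k = r.shape[0]
    adj = (r < r_max) & (lod >= lod_min)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
    groups.sort(key=lambda m: (-len(m), m[0]))
    return groups


def _path_length(order: np.ndarray, d: np.ndarray) -> float:
    return float(d[order[:-1], order[1:]].sum())


def _two_opt(order: np.ndarray, d: np.ndarray, max_sweeps: int = 60) -> np.ndarray:
    """2-opt improvement of an open path minimizing sum of adjacent distances."""
    order = order.copy()
    k = len(order)
    for _ in range(max_sweeps):
        improved = False
        for i in range(k - 1):
            a = order[i - 1] if i > 0 else -1
            js = np.arange(i + 1, k)
            b = order[i]
            ends = order[js]
            after = np.where(js + 1 < k, order[np.minimum(js + 1, k - 1)], -1)
            # current edge cost: d[a,b] + d[end, after]; reversed: d[a,end] + d[b, after]
            cur = (d[a, b] if a >= 0 else 0.0) + np.where(after >= 0, d[ends, after], 0.0)
            new = (d[a, ends] if a >= 0 else np.zeros(len(js))) + np.where(
                after >= 0, d[b, after], 0.0
            )
            delta = new - cur
            jbest = int(np.argmin(delta))
            if delta[jbest] < -1e-12:
                j = js[jbest]
                order[i : j + 1] = order[i : j + 1][::-1]
                improved = True
        if not improved:
            break
    return order


def order_bins(
    member_ids: list[int], r: np.ndarray
) -> tuple[list[int], np.ndarray]:
    """Order a linkage group's bins and return cumulative Kosambi cM.

    Greedy nearest-neighbour chaining (started from the most peripheral bin)
    followed by 2-opt on the sum of adjacent r.  Raises when the estimates
    leave the group disconnected at r = 0.5 everywhere.
    """
    ids = np.asarray(member_ids)
    k = len(ids)
    if k == 1:
        return list(ids), np.zeros(1)
    d = r[np.ix_(ids, ids)].astype(float)
    if k > 2 and np.all(d[~np.eye(k, dtype=bool)] >= 0.5 - 1e-12):
        raise ValueError("group is internally disconnected: all pairwise r at 0.5")
    # seed with the first principal coordinate of the Kosambi-scaled distance
    # matrix (classical MDS): immune to the end-folds greedy chaining makes
    dk = kosambi(np.clip(d, 0.0, 0.4999))
    sq = dk**2
    j_center = np.eye(k) - np.ones((k, k)) / k
    b_mat = -0.5 * j_center @ sq @ j_center
    vals, vecs = np.linalg.eigh(b_mat)
    axis = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    order = np.argsort(axis, kind="stable")
    order = _two_opt(order, d)
    if order[0] > order[-1]:  # canonical orientation for determinism
        order = order[::-1]
    adj_r = np.clip(d[order[:-1], order[1:]], 0.0, 0.4999999)
    cum = np.concatenate([[0.0], np.cumsum(kosambi(adj_r))])
    return [int(ids[i]) for i in order], cum


def build_genetic_map(
    bins: list[RecombinationBin],
    r: np.ndarray,
    lod: np.ndarray,
    r_max: float = 0.4,
    lod_min: float = 6.0,
    group_labels: dict[int, str] | None = None,
) -> GeneticMap:
    """Group, order and space bins into a GeneticMap.

    ``group_labels`` optionally maps a member bin index to a framework group
    name (e.g. from SSR anchors); a group takes the label of any labeled
    member, else LG1, LG2, ... by size.
    """
    groups = []
    for gi, member in enumerate(group_bins(r, lod, r_max, lod_min)):
        if len(member) >= 2:
            ordered, cum = order_bins(member, r)
        else:
            ordered, cum = list(member), np.zeros(len(member))
        name = f"LG{gi + 1}"
        if group_labels:
            labels = {group_labels[b] for b in member if b in group_labels}
            if len(labels) == 1:
                name = labels.pop()
        groups.append(LinkageGroup(name=name, bin_ids=ordered, cum_cm=cum))
    return GeneticMap(bins=bins, groups=groups)


# ---------------------------------------------------------------------------
# map quality matrix (BIT/REC-style halves)
# ---------------------------------------------------------------------------


def quality_matrix(ordered_genotypes: np.ndarray, r: np.ndarray | None = None) -> np.ndarray:
    """Pairwise linkage-score matrix for an ordered bin list.

    Upper triangle (and diagonal): pairwise similarity score of the genotype
    vectors.  Lower triangle: 1 - 2*r clipped to [0, 1].  For a correct
    order, high scores concentrate near the diagonal.
    """
    g = np.asarray(ordered_genotypes, dtype=np.int8)
    k = g.shape[0]
    if r is None:
        r, _ = pairwise_rf_matrix(g)
    out = np.zeros((k, k))
    for i in range(k):
        out[i, i] = 1.0
        for j in range(i + 1, k):
            out[i, j], _ = similarity_score(g[i], g[j])
            out[j, i] = np.clip(1.0 - 2.0 * r[i, j], 0.0, 1.0)
    return out
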