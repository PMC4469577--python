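"""Two-step genotyping of a low-coverage F2 population.

Step 1 makes a per-site call for every individual (depth >= 4, each observed
parental allele counted from >= 1 read).  Sites within a scaffold are then
partitioned into *blocks*: a site joins the current block when its similarity
score against the block's running consensus genotype is at least 0.7.

Step 2 slides a depth-adaptive window over consecutive same-block sites; the
reads of all sites in the window are pooled (minimum 40) and a Bayesian call
is made from binomial likelihoods with asymmetric per-parent error rates
``E1`` (default 0.058) and ``E2`` (default 0.02) and F2 priors
P1P1 : P2P2 : P1P2 = 0.25 : 0.25 : 0.5.

Likelihoods for observing ``n1`` parent-1 reads out of ``n``::

    P(n1 | P1P1) = C(n, n1) (1 - E1)^n1 * E2^(n - n1)
    P(n1 | P2P2) = C(n, n1) E1^n1 * (1 - E2)^(n - n1)
    P(n1 | P1P2) = C(n, n1) ((1 - E1 + E2)/2)^n1 * ((1 + E1 - E2)/2)^(n - n1)

The heterozygote terms carry the 1/2-per-read normalization so that all three
per-read weight pairs behave as probabilities.  Everything is computed in log
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from polybinmap.genotypes import A, B, H, MISSING


@dataclass(frozen=True)
class ErrorModel:
    """Per-parent read error rates; both must lie in [0, 0.5)."""

    e1: float = 0.058
    e2: float = 0.02

    def __post_init__(self) -> None:
        for e in (self.e1, self.e2):
            if not 0.0 <= e < 0.5:
                raise ValueError(f"error rate {e} outside [0, 0.5)")

    @property
    def het_p1(self) -> float:
        """Per-read probability of a parent-1 allele under a heterozygote."""
        return (1.0 - self.e1 + self.e2) / 2.0


F2_PRIORS = (0.25, 0.25, 0.5)  # P1P1 : P2P2 : P1P2


@dataclass
class PosteriorTriple:
    p_p1p1: float
    p_p2p2: float
    p_p1p2: float

    def as_array(self) -> np.ndarray:
        return np.array([self.p_p1p1, self.p_p2p2, self.p_p1p2])


# ---------------------------------------------------------------------------
# step 1: initial calls
# ---------------------------------------------------------------------------


def call_initial_genotype(
    n_p1: int, n_p2: int, min_depth: int = 4, min_allele_reads: int = 1
) -> int:
    """Initial per-site call from parental-allele read counts.

    Reads carrying neither parental allele are not counted here; the caller
    tracks them separately.
    """
    depth = n_p1 + n_p2
    if depth < min_depth:
        return MISSING
    has1 = n_p1 >= min_allele_reads
    has2 = n_p2 >= min_allele_reads
    if has1 and has2:
        return H
    if has1:
        return A
    if has2:
        return B
    return MISSING


def call_initial_matrix(
    c1: np.ndarray, c2: np.ndarray, min_depth: int = 4, min_allele_reads: int = 1
) -> np.ndarray:
    """Vectorized :func:`call_initial_genotype` over a sites x individuals grid."""
    depth = c1 + c2
    has1 = c1 >= min_allele_reads
    has2 = c2 >= min_allele_reads
    out = np.full(c1.shape, MISSING, dtype=np.int8)
    out[has1 & ~has2] = A
    out[~has1 & has2] = B
    out[has1 & has2] = H
    out[depth < min_depth] = MISSING
    return out


# ---------------------------------------------------------------------------
# similarity scores and blocks
# ---------------------------------------------------------------------------


def similarity_score(gz: np.ndarray, gj: np.ndarray) -> tuple[float, int]:
    """Mean pairwise genotype agreement between two sites.

    Per individual: s=1 for identical genotypes, s=0.5 when they differ and
    one is H, s=0 when they differ and neither is H.  Individuals missing at
    either site are excluded.  Returns ``(score, n)``; score is NaN when no
    individual is jointly scored.
    """
    gz = np.asarray(gz)
    gj = np.asarray(gj)
    if gz.shape != gj.shape:
        raise ValueError("genotype vectors must have the same length")
    ok = (gz != MISSING) & (gj != MISSING)
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    a, b = gz[ok], gj[ok]
    s = np.where(a == b, 1.0, np.where((a == H) | (b == H), 0.5, 0.0))
    return float(s.mean()), n


class _RunningConsensus:
    """Missing-aware per-individual majority genotype of a growing block."""

    def __init__(self, n_ind: int) -> None:
        self.votes = np.zeros((3, n_ind), dtype=np.int32)  # rows: A, H, B

    def add(self, g: np.ndarray) -> None:
        for code in (A, H, B):
            self.votes[code] += g == code

    def genotype(self) -> np.ndarray:
        best = self.votes.max(axis=0)
        argbest = self.votes.argmax(axis=0)
        ties = (self.votes == best).sum(axis=0) > 1
        out = argbest.astype(np.int8)
        out[(best == 0) | ties] = MISSING
        return out


def build_blocks(genotypes: np.ndarray, threshold: float = 0.7) -> np.ndarray:
    """Partition position-ordered sites of one scaffold into blocks.

    Greedy left-to-right agglomeration: a site joins the current block when
    its similarity against the block's running consensus is >= ``threshold``
    (undefined scores never join).  Returns a block id per site; ids are
    contiguous and increasing along the scaffold.
    """
    n_sites, n_ind = genotypes.shape
    blocks = np.zeros(n_sites, dtype=np.int32)
    if n_sites == 0:
        return blocks
    consensus = _RunningConsensus(n_ind)
    consensus.add(genotypes[0])
    current = 0
    for i in range(1, n_sites):
        score, n = similarity_score(genotypes[i], consensus.genotype())
        if n == 0 or score < threshold:
            current += 1
            consensus = _RunningConsensus(n_ind)
        blocks[i] = current
        consensus.add(genotypes[i])
    return blocks


# ---------------------------------------------------------------------------
# step 2: windowed Bayesian calls
# ---------------------------------------------------------------------------


def window_likelihoods(n1, n, error_model: ErrorModel = ErrorModel()) -> np.ndarray:
    """Log-likelihoods (P1P1, P2P2, P1P2) of n1 parent-1 reads out of n.

    Accepts scalars or broadcastable arrays; returns shape (..., 3).
    """
    n1 = np.asarray(n1, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise ValueError("window depth n must be positive")
    if np.any((n1 < 0) | (n1 > n)):
        raise ValueError("need 0 <= n1 <= n")
    e1, e2 = error_model.e1, error_model.e2
    n2 = n - n1
    logc = gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n2 + 1)
    het1 = (1.0 - e1 + e2) / 2.0
    ll = np.stack(
        [
            logc + xlogy(n1, 1.0 - e1) + xlogy(n2, e2),
            logc + xlogy(n1, e1) + xlogy(n2, 1.0 - e2),
            logc + xlogy(n1, het1) + xlogy(n2, 1.0 - het1),
        ],
        axis=-1,
    )
    return ll


def posterior_genotype(
    n1: int,
    n: int,
    error_model: ErrorModel = ErrorModel(),
    priors: tuple[float, float, float] = F2_PRIORS,
) -> tuple[int, PosteriorTriple]:
    """Posterior genotype call for a pooled window; exact ties -> missing."""
    ll = window_likelihoods(n1, n, error_model)
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(np.asarray(priors, dtype=float))
    assert np.all(np.isfinite(logpost) | (logpost == -np.inf))
    m = logpost.max()
    post = np.exp(logpost - m)
    post /= post.sum()
    winners = np.flatnonzero(logpost == logpost.max())
    call = (A, B, H)[winners[0]] if winners.size == 1 else MISSING
    return call, PosteriorTriple(*post)


def _posterior_matrix(
    n1: np.ndarray,
    n: np.ndarray,
    error_model: ErrorModel,
    priors: tuple[float, float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized argmax-posterior call; entries with n == 0 are missing.

    Also returns the winning posterior probability (0 where missing)."""
    out = np.full(n1.shape, MISSING, dtype=np.int8)
    conf = np.zeros(n1.shape, dtype=np.float64)
    valid = n > 0
    if not valid.any():
        return out, conf
    ll = window_likelihoods(n1[valid], n[valid], error_model)
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(np.asarray(priors, dtype=float))
    order = np.argsort(logpost, axis=-1)
    top = np.take_along_axis(logpost, order[..., -1:], axis=-1)[..., 0]
    second = np.take_along_axis(logpost, order[..., -2:-1], axis=-1)[..., 0]
    call = np.array([A, B, H], dtype=np.int8)[order[..., -1]]
    call[top == second] = MISSING  # exact posterior tie
    out[valid] = call
    with np.errstate(over="ignore"):
        norm = np.exp(logpost - top[..., None]).sum(axis=-1)
    conf[valid] = 1.0 / norm
    return out, conf


def slide_windows(
    c1: np.ndarray,
    c2: np.ndarray,
    positions: np.ndarray,
    blocks: np.ndarray,
    window_min_depth: int = 40,
    error_model: ErrorModel = ErrorModel(),
    priors: tuple[float, float, float] = F2_PRIORS,
    return_confidence: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Windowed Bayesian genotype per site per individual.

    For each focal site the window grows symmetrically (nearer flanking site
    first, left on distance ties) over consecutive sites of the same block
    until the pooled read depth reaches ``window_min_depth``; if the block is
    exhausted first the call is missing.  With ``return_confidence`` the
    winning posterior probability per call is returned alongside (0 where
    missing), so callers can keep only unambiguous calls for mapping.

    Parameters
    ----------
    c1, c2
        (sites x individuals) read counts for the parent-1 / parent-2 allele.
    positions
        bp position per site (sites ordered by position within scaffold).
    blocks
        block id per site; windows never cross block boundaries.
    """
    n_sites, n_ind = c1.shape
    pooled1 = np.zeros((n_sites, n_ind), dtype=np.int64)
    pooledn = np.zeros((n_sites, n_ind), dtype=np.int64)
    depth = (c1 + c2).astype(np.int64)
    starts = np.flatnonzero(np.diff(blocks, prepend=blocks[0] - 1 if n_sites else 0))
    bounds = list(starts) + [n_sites]
    for bi in range(len(bounds) - 1):
        lo, hi = bounds[bi], bounds[bi + 1]
        d = depth[lo:hi]
        b1 = c1[lo:hi]
        pos = positions[lo:hi]
        m = hi - lo
        block_total = d.sum(axis=0)
        for ind in range(n_ind):
            if block_total[ind] < window_min_depth:
                continue  # whole block below the floor: stays missing
            dv = d[:, ind]
            n1v = b1[:, ind]
            for i in range(m):
                tot = dv[i]
                t1 = n1v[i]
                left, right = i - 1, i + 1
                while tot < window_min_depth:
                    if left >= 0 and (
                        right >= m or pos[i] - pos[left] <= pos[right] - pos[i]
                    ):
                        tot += dv[left]
                        t1 += n1v[left]
                        left -= 1
                    else:
                        tot += dv[right]
                        t1 += n1v[right]
                        right += 1
                pooledn[lo + i, ind] = tot
                pooled1[lo + i, ind] = t1
    calls, conf = _posterior_matrix(pooled1, pooledn, error_model, priors)
    return (calls, conf) if return_confidence else calls


# ---------------------------------------------------------------------------
# concordance against anchor genotypes
# ---------------------------------------------------------------------------


@dataclass
class ConcordanceReport:
    accuracy: float
    missing_rate: float
    a_h_miscall_rate: float
    b_h_miscall_rate: float
    n_compared: int
    n_missing: int


def evaluate_concordance(
    genotypes: np.ndarray,
    site_scaffolds: np.ndarray,
    site_positions: np.ndarray,
    anchors: list[tuple[str, int, np.ndarray]],
    flank_bp: int = 10_000,
) -> ConcordanceReport:
    """Compare called genotypes to anchor truth in flanking windows.

    Each anchor supplies (scaffold, position, genotype vector); every called
    site within ``flank_bp`` of an anchor position on the same scaffold is
    assumed to share the anchor's genotype.  A↔H / B↔H miscall rates are
    fractions of all compared (non-missing) entries.
    """
    site_scaffolds = np.asarray(site_scaffolds)
    site_positions = np.asarray(site_positions)
    called = []
    truth = []
    total = 0
    for scaf, pos, gvec in anchors:
        sel = (site_scaffolds == scaf) & (np.abs(site_positions - pos) <= flank_bp)
        if not sel.any():
            continue
        g = genotypes[sel]
        total += g.size
        t = np.broadcast_to(np.asarray(gvec, dtype=np.int8), g.shape)
        called.append(g.ravel())
        truth.append(t.ravel())
    if total == 0:
        raise ValueError("no called site falls inside any anchor flank window")
    called_all = np.concatenate(called)
    truth_all = np.concatenate(truth)
    miss = called_all == MISSING
    n_missing = int(miss.sum())
    cmp_called = called_all[~miss]
    cmp_truth = truth_all[~miss]
    n_compared = cmp_called.size
    if n_compared == 0:
        raise ValueError("all comparable genotypes are missing")
    acc = float((cmp_called == cmp_truth).mean())
    ah = ((cmp_truth == A) & (cmp_called == H)) | ((cmp_truth == H) & (cmp_called == A))
    bh = ((cmp_truth == B) & (cmp_called == H)) | ((cmp_truth == H) & (cmp_called == B))
    return ConcordanceReport(
        accuracy=acc,
        missing_rate=n_missing / total,
        a_h_miscall_rate=float(ah.mean()),
        b_h_miscall_rate=float(bh.mean()),
        n_compared=n_compared,
        n_missing=n_missing,
    )
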