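"""Synthetic allopolyploid F2 cross generator.

Produces, deterministically from a master seed:

* two homozygous parental genomes with Poisson-spaced biallelic SNPs (a
  configurable fraction of sites carries a constant 50 % homoeologous
  contamination stream in one parent — "hemi" sites);
* true F2 genotypes via simulated meiosis (Poisson crossovers, no
  interference, uniform positions);
* low-coverage per-site allele counts with the asymmetric per-parent error
  structure used by the genotyper (E1 penalizing the parent-1 read stream,
  E2 the parent-2 stream);
* optional chimeric scaffolds (two genomic locations concatenated, junction
  recorded) and centromere-clustered repeat-homology hits.

Per-stage child RNGs are derived from the master seed by fixed offsets so
each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from polybinmap.config import SimProfile
from polybinmap.genotypes import A, B, H
from polybinmap.genotyping import ErrorModel
from polybinmap.landscape import HomologyHit

_ALLELES = np.array(["A", "C", "G", "T"])

# fixed per-stage seed offsets
_SEED_PARENTS = 1
_SEED_MEIOSIS = 2
_SEED_READS = 3
_SEED_CHIMERA = 4
_SEED_HITS = 5
_SEED_SEQ = 6


@dataclass
class SimChromosome:
    name: str
    length_bp: int
    length_cm: float
    centromere_bp: int
    scaffold_breakpoints: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        bp = self.scaffold_breakpoints
        if any(not 0 < b < self.length_bp for b in bp) or sorted(set(bp)) != list(bp):
            raise ValueError("breakpoints must be strictly increasing inside (0, length)")
        if not 0 <= self.centromere_bp < self.length_bp:
            raise ValueError("centromere outside chromosome")


@dataclass
class Gamete:
    """Crossover positions plus the parental phase at position 0."""

    crossovers: np.ndarray
    start_phase: int  # 0 = parent 1, 1 = parent 2

    def phase_at(self, positions: np.ndarray) -> np.ndarray:
        k = np.searchsorted(self.crossovers, positions, side="right")
        return (self.start_phase + k) % 2


@dataclass
class Scaffold:
    """A scaffold as a list of source-genome pieces (chrom, start, end)."""

    name: str
    pieces: list[tuple[str, int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.pieces)

    @property
    def is_chimeric(self) -> bool:
        return len({p[0] for p in self.pieces}) > 1 or len(self.pieces) > 1


@dataclass
class SnpTable:
    chrom: np.ndarray
    chrom_pos: np.ndarray
    scaffold: np.ndarray
    scaffold_pos: np.ndarray
    p1_allele: np.ndarray
    p2_allele: np.ndarray
    hemi: np.ndarray
    hemi_parent: np.ndarray
    hemi_allele: np.ndarray

    def __len__(self) -> int:
        return len(self.chrom_pos)

    def take(self, order: np.ndarray) -> "SnpTable":
        return SnpTable(**{k: getattr(self, k)[order] for k in self.__dataclass_fields__})


@dataclass
class ChimeraJunction:
    scaffold: str
    offset_bp: int  # junction position within the chimeric scaffold
    left_chrom: str
    right_chrom: str
    classification: str


@dataclass
class TruthSet:
    chromosomes: list[SimChromosome]
    gametes: list[dict[str, tuple[Gamete, Gamete]]]  # per individual
    genotypes: np.ndarray  # (n_sites, n_individuals) in {A,H,B}
    junctions: list[ChimeraJunction] = field(default_factory=list)
    centromeres: dict[str, int] = field(default_factory=dict)


@dataclass
class SimulatedCross:
    profile: SimProfile
    seed: int
    chromosomes: list[SimChromosome]
    scaffolds: list[Scaffold]
    snps: SnpTable
    truth: TruthSet
    parent1_counts: np.ndarray  # (n_sites, 4) ACGT
    parent2_counts: np.ndarray
    f2_c1: np.ndarray  # (n_sites, n_ind) reads carrying the parent-1 allele
    f2_c2: np.ndarray
    f2_contam: np.ndarray  # homoeolog-contamination reads at hemi sites

    @property
    def n_individuals(self) -> int:
        return self.f2_c1.shape[1]


# ---------------------------------------------------------------------------
# chromosomes and parents
# ---------------------------------------------------------------------------


def make_chromosomes(profile: SimProfile) -> list[SimChromosome]:
    """A/D-paired chromosomes (A01, D01, A02, ...) of equal size."""
    chroms = []
    per = profile.scaffolds_per_chromosome
    length = profile.chromosome_length_bp
    breakpoints = [length * k // per for k in range(1, per)]
    for i in range(profile.n_chromosomes):
        sub = "AD"[i % 2]
        idx = i // 2 + 1
        chroms.append(
            SimChromosome(
                name=f"{sub}{idx:02d}",
                length_bp=length,
                length_cm=profile.chromosome_length_cm,
                centromere_bp=length // 2,
                scaffold_breakpoints=list(breakpoints),
            )
        )
    return chroms


def paper_scale_lite_profile() -> SimProfile:
    """26 chromosomes x 5 Mb: the acceptance-scale profile."""
    return SimProfile(n_chromosomes=26, chromosome_length_bp=5_000_000)


def simulate_parents(
    chromosomes: list[SimChromosome],
    snp_density: float,
    hemi_fraction: float,
    rng: np.random.Generator,
) -> SnpTable:
    """Biallelic SNPs at Poisson-spaced positions, parents homozygous/distinct.

    A ``hemi_fraction`` of sites is flagged hemi: one parent's reads carry a
    constant 50 % stream of a third (homoeologous) allele.
    """
    cols: dict[str, list] = {k: [] for k in SnpTable.__dataclass_fields__}
    for chrom in chromosomes:
        expect = snp_density * chrom.length_bp
        if expect < 10:
            raise ValueError(
                f"{chrom.name}: expected SNP count {expect:.1f} < 10 is degenerate"
            )
        n = rng.poisson(expect)
        pos = np.sort(rng.choice(chrom.length_bp, size=n, replace=False))
        a1 = rng.integers(0, 4, size=n)
        a2 = (a1 + rng.integers(1, 4, size=n)) % 4
        hemi = rng.random(n) < hemi_fraction
        hemi_parent = np.where(hemi, rng.integers(1, 3, size=n), 0).astype(np.int8)
        own = np.where(hemi_parent == 1, a1, a2)
        contam = (own + rng.integers(1, 4, size=n)) % 4
        # scaffold assignment from breakpoints
        edges = np.array([0] + chrom.scaffold_breakpoints + [chrom.length_bp])
        scaf_idx = np.searchsorted(edges, pos, side="right") - 1
        cols["chrom"].append(np.full(n, chrom.name))
        cols["chrom_pos"].append(pos)
        cols["scaffold"].append(
            np.array([f"scf_{chrom.name}_{k}" for k in scaf_idx])
        )
        cols["scaffold_pos"].append(pos - edges[scaf_idx])
        cols["p1_allele"].append(_ALLELES[a1])
        cols["p2_allele"].append(_ALLELES[a2])
        cols["hemi"].append(hemi)
        cols["hemi_parent"].append(hemi_parent)
        cols["hemi_allele"].append(np.where(hemi, _ALLELES[contam], ""))
    return SnpTable(**{k: np.concatenate(v) for k, v in cols.items()})


def make_scaffolds(chromosomes: list[SimChromosome]) -> list[Scaffold]:
    scaffolds = []
    for chrom in chromosomes:
        edges = [0] + chrom.scaffold_breakpoints + [chrom.length_bp]
        for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
            scaffolds.append(Scaffold(f"scf_{chrom.name}_{k}", [(chrom.name, lo, hi)]))
    return scaffolds


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


def simulate_meiosis(
    chromosome: SimChromosome,
    rng: np.random.Generator,
    suppression_radius_bp: int = 0,
    suppression_keep_prob: float = 0.1,
) -> Gamete:
    """One gamete: Poisson(length_cM/100) crossovers, i.i.d. uniform positions.

    With a nonzero ``suppression_radius_bp``, crossovers falling within that
    radius of the centromere are kept only with ``suppression_keep_prob``
    (models pericentromeric recombination suppression).
    """
    n = rng.poisson(chromosome.length_cm / 100.0)
    pos = rng.uniform(0, chromosome.length_bp, size=n)
    if suppression_radius_bp > 0 and n > 0:
        near = np.abs(pos - chromosome.centromere_bp) <= suppression_radius_bp
        keep = ~near | (rng.random(n) < suppression_keep_prob)
        pos = pos[keep]
    return Gamete(np.sort(pos), int(rng.integers(0, 2)))


def simulate_f2_genotypes(
    chromosomes: list[SimChromosome],
    snps: SnpTable,
    n_individuals: int,
    rng: np.random.Generator,
    suppression_radius_bp: int = 0,
) -> TruthSet:
    """True genotypes for every individual at every SNP via paired gametes."""
    n_sites = len(snps)
    genotypes = np.empty((n_sites, n_individuals), dtype=np.int8)
    gametes = []
    site_sel = {c.name: np.flatnonzero(snps.chrom == c.name) for c in chromosomes}
    for ind in range(n_individuals):
        per_chrom = {}
        for chrom in chromosomes:
            g1 = simulate_meiosis(chrom, rng, suppression_radius_bp)
            g2 = simulate_meiosis(chrom, rng, suppression_radius_bp)
            per_chrom[chrom.name] = (g1, g2)
            sel = site_sel[chrom.name]
            pos = snps.chrom_pos[sel]
            dose = g1.phase_at(pos) + g2.phase_at(pos)  # copies of parent-2
            genotypes[sel, ind] = np.where(dose == 0, A, np.where(dose == 1, H, B))
        gametes.append(per_chrom)
    return TruthSet(
        chromosomes=chromosomes,
        gametes=gametes,
        genotypes=genotypes,
        centromeres={c.name: c.centromere_bp for c in chromosomes},
    )


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


def simulate_read_counts(
    truth_genotypes: np.ndarray,
    hemi: np.ndarray,
    depth_mean: float,
    error_model: ErrorModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site, per-individual allele counts (c1, c2, contamination).

    Depth ~ Poisson(depth_mean); each read carries the parent-1 allele with
    probability 1-E1 (genotype A), E1 (B) or (1-E1+E2)/2 (H).  Hemi sites
    receive an extra Poisson(depth_mean) stream of contaminating reads.
    """
    if depth_mean <= 0:
        raise ValueError("depth_mean must be positive")
    shape = truth_genotypes.shape
    depth = rng.poisson(depth_mean, size=shape)
    p1 = np.empty(shape)
    p1[truth_genotypes == A] = 1.0 - error_model.e1
    p1[truth_genotypes == B] = error_model.e1
    p1[truth_genotypes == H] = error_model.het_p1
    c1 = rng.binomial(depth, p1)
    c2 = depth - c1
    contam = np.zeros(shape, dtype=np.int64)
    hemi_rows = np.flatnonzero(hemi)
    if hemi_rows.size:
        contam[hemi_rows] = rng.poisson(depth_mean, size=(hemi_rows.size, shape[1]))
    return c1, c2, contam


def simulate_parent_counts(
    snps: SnpTable, parent: int, depth_mean: float, rng: np.random.Generator
) -> np.ndarray:
    """(n_sites, 4) ACGT read counts for one parent.

    Parents are homozygous; at a hemi site the affected parent's reads are an
    even mixture of its own allele and the contaminating homoeolog allele.
    """
    n = len(snps)
    own = snps.p1_allele if parent == 1 else snps.p2_allele
    own_idx = np.searchsorted(_ALLELES, own)
    counts = np.zeros((n, 4), dtype=np.int64)
    depth = rng.poisson(depth_mean, size=n)
    affected = snps.hemi & (snps.hemi_parent == parent)
    contam_idx = np.where(affected, np.searchsorted(_ALLELES, snps.hemi_allele), 0)
    n_contam = np.where(affected, rng.binomial(depth, 0.5), 0)
    np.add.at(counts, (np.arange(n), own_idx), depth - n_contam)
    np.add.at(counts, (np.arange(n), contam_idx), n_contam)
    return counts


# ---------------------------------------------------------------------------
# chimeras
# ---------------------------------------------------------------------------


def inject_misassemblies(
    scaffolds: list[Scaffold],
    snps: SnpTable,
    n_chimeras: int,
    rng: np.random.Generator,
) -> tuple[list[Scaffold], SnpTable, list[ChimeraJunction]]:
    """Concatenate pairs of scaffolds from different chromosomes into chimeras.

    Each chimera replaces its two source scaffolds; SNP scaffold coordinates
    are rewritten and junction truth recorded.  Raises when there are not
    enough cross-chromosome pairs.
    """
    from polybinmap.assembly_anchor import classify_breakpoint

    if n_chimeras == 0:
        return scaffolds, snps, []
    if 2 * n_chimeras > len(scaffolds):
        raise ValueError("n_chimeras exceeds available scaffolds")
    by_chrom: dict[str, list[Scaffold]] = {}
    for s in scaffolds:
        by_chrom.setdefault(s.pieces[0][0], []).append(s)
    if len(by_chrom) < 2:
        raise ValueError("need scaffolds from >= 2 chromosomes")
    order = rng.permutation(len(scaffolds))
    used: set[str] = set()
    pairs = []
    for i in order:
        if len(pairs) == n_chimeras:
            break
        s1 = scaffolds[i]
        if s1.name in used:
            continue
        mates = [
            s
            for s in scaffolds
            if s.name not in used and s.name != s1.name and s.pieces[0][0] != s1.pieces[0][0]
        ]
        if not mates:
            continue
        s2 = mates[int(rng.integers(0, len(mates)))]
        used.update({s1.name, s2.name})
        pairs.append((s1, s2))
    if len(pairs) < n_chimeras:
        raise ValueError("could not form enough cross-chromosome pairs")

    new_scaffolds = [s for s in scaffolds if s.name not in used]
    snps = SnpTable(**{k: getattr(snps, k).copy() for k in SnpTable.__dataclass_fields__})
    junctions = []
    for k, (s1, s2) in enumerate(pairs):
        name = f"chimera_{k}"
        chim = Scaffold(name, s1.pieces + s2.pieces)
        new_scaffolds.append(chim)
        offset = s1.length
        left_chrom = s1.pieces[-1][0]
        right_chrom = s2.pieces[0][0]
        junctions.append(
            ChimeraJunction(
                scaffold=name,
                offset_bp=offset,
                left_chrom=left_chrom,
                right_chrom=right_chrom,
                classification=classify_breakpoint(left_chrom, right_chrom),
            )
        )
        in1 = snps.scaffold == s1.name
        in2 = snps.scaffold == s2.name
        snps.scaffold[in1] = name
        snps.scaffold[in2] = name
        snps.scaffold_pos[in2] += offset
    order = np.lexsort((snps.scaffold_pos, snps.scaffold))
    return new_scaffolds, snps.take(order), junctions


# ---------------------------------------------------------------------------
# centromere hits
# ---------------------------------------------------------------------------


def simulate_centromere_hits(
    chromosomes: list[SimChromosome],
    n_hits_per_chrom: int | dict[str, int],
    spread_bp: float,
    background_rate: float,
    rng: np.random.Generator,
    n_queries: int = 4,
) -> list[HomologyHit]:
    """Centromere-clustered homology hits plus uniform background.

    True hits ~ Normal(centromere, spread) truncated to the chromosome, with
    identity >= 80 and e-value <= 1e-20; background hits are uniform with
    mixed identity/e-value.  ``background_rate`` is the expected number of
    background hits per chromosome.
    """
    if spread_bp <= 0:
        raise ValueError("spread_bp must be positive")
    hits = []
    for chrom in chromosomes:
        n_true = (
            n_hits_per_chrom[chrom.name]
            if isinstance(n_hits_per_chrom, dict)
            else n_hits_per_chrom
        )
        pos = rng.normal(chrom.centromere_bp, spread_bp, size=n_true)
        pos = np.clip(pos, 0, chrom.length_bp - 1).astype(np.int64)
        ident = rng.uniform(80.0, 100.0, size=n_true)
        lode = rng.uniform(21.0, 100.0, size=n_true)
        n_bg = rng.poisson(background_rate)
        bg_pos = rng.integers(0, chrom.length_bp, size=n_bg)
        bg_ident = rng.uniform(60.0, 100.0, size=n_bg)
        bg_lode = rng.uniform(0.0, 40.0, size=n_bg)
        for p, idy, le in zip(
            np.concatenate([pos, bg_pos]),
            np.concatenate([ident, bg_ident]),
            np.concatenate([lode, bg_lode]),
        ):
            length = int(rng.integers(100, 500))
            q = int(rng.integers(1, n_queries + 1))
            sstart = int(max(0, p - length // 2)) + 1
            hits.append(
                HomologyHit(
                    query=f"LTR{q}",
                    subject=chrom.name,
                    identity=round(float(idy), 2),
                    length=length,
                    mismatches=int(length * (100 - idy) / 100),
                    gap_opens=0,
                    qstart=1,
                    qend=length,
                    sstart=sstart,
                    send=sstart + length - 1,
                    evalue=10.0 ** (-float(le)),
                    bitscore=round(2.0 * length * idy / 100, 1),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# genome sequences (for exact-match segment mapping)
# ---------------------------------------------------------------------------


def simulate_genome_sequences(
    chromosomes: list[SimChromosome], snps: SnpTable, rng: np.random.Generator
) -> dict[str, str]:
    """Random parent-1 chromosome sequences carrying the parent-1 alleles."""
    seqs = {}
    for chrom in chromosomes:
        arr = rng.integers(0, 4, size=chrom.length_bp)
        sel = snps.chrom == chrom.name
        arr[snps.chrom_pos[sel]] = np.searchsorted(_ALLELES, snps.p1_allele[sel])
        seqs[chrom.name] = "".join(_ALLELES[arr])
    return seqs


def scaffold_sequences(scaffolds: list[Scaffold], genome: dict[str, str]) -> dict[str, str]:
    return {
        s.name: "".join(genome[c][lo:hi] for c, lo, hi in s.pieces) for s in scaffolds
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def simulate_cross(
    profile: SimProfile,
    seed: int,
    chromosomes: list[SimChromosome] | None = None,
    suppression_radius_bp: int = 0,
) -> SimulatedCross:
    """Run the full generator; identical (profile, seed) gives identical output."""
    if chromosomes is None:
        chromosomes = make_chromosomes(profile)
    rng_parents = np.random.default_rng(seed + _SEED_PARENTS)
    rng_meiosis = np.random.default_rng(seed + _SEED_MEIOSIS)
    rng_reads = np.random.default_rng(seed + _SEED_READS)
    rng_chimera = np.random.default_rng(seed + _SEED_CHIMERA)

    snps = simulate_parents(chromosomes, profile.snp_density, profile.hemi_fraction, rng_parents)
    scaffolds = make_scaffolds(chromosomes)
    scaffolds, snps, junctions = inject_misassemblies(
        scaffolds, snps, profile.n_chimeras, rng_chimera
    )
    order = np.lexsort((snps.scaffold_pos, snps.scaffold))
    snps = snps.take(order)
    truth = simulate_f2_genotypes(
        chromosomes, snps, profile.n_individuals, rng_meiosis, suppression_radius_bp
    )
    truth.junctions = junctions
    error_model = ErrorModel()
    c1, c2, contam = simulate_read_counts(
        truth.genotypes, snps.hemi, profile.depth_mean, error_model, rng_reads
    )
    p1_counts = simulate_parent_counts(snps, 1, profile.parent_depth_mean, rng_reads)
    p2_counts = simulate_parent_counts(snps, 2, profile.parent_depth_mean, rng_reads)
    return SimulatedCross(
        profile=profile,
        seed=seed,
        chromosomes=chromosomes,
        scaffolds=scaffolds,
        snps=snps,
        truth=truth,
        parent1_counts=p1_counts,
        parent2_counts=p2_counts,
        f2_c1=c1,
        f2_c2=c2,
        f2_contam=contam,
    )
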