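"""Parental variant calling and interspecific SNP classification.

Each parent is called independently from its allele counts; a site yields an
interspecific SNP record when the two parental allele sets differ.  Records
are classified by allele-set arithmetic:

* **simple** — both parents show a single allele and the alleles differ;
* **hemi**   — exactly one parent shows two alleles (a homoeolog-mixed site);
* **complex** — both parents show two alleles and the sets differ.

Only simple SNPs feed the downstream genotyper and map.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

ALLELES = ("A", "C", "G", "T")

SIMPLE = "simple"
HEMI = "hemi"
COMPLEX = "complex"


@dataclass(frozen=True)
class CallThresholds:
    """Per-parent site-calling thresholds."""

    min_depth: int = 10
    min_allele_reads: int = 3
    min_allele_fraction: float = 0.20


@dataclass
class ParentalCall:
    scaffold: str
    position: int
    counts: dict[str, int]
    alleles: frozenset[str]
    passed: bool


@dataclass
class SnpRecord:
    scaffold: str
    position: int  # 0-based internally
    p1_alleles: frozenset[str]
    p2_alleles: frozenset[str]
    snp_class: str

    def __post_init__(self) -> None:
        if self.snp_class == SIMPLE:
            if len(self.p1_alleles) != 1 or len(self.p2_alleles) != 1:
                raise ValueError("simple SNP must have one allele per parent")
            if self.p1_alleles == self.p2_alleles:
                raise ValueError("simple SNP alleles must differ")

    @property
    def p1_allele(self) -> str:
        (a,) = self.p1_alleles
        return a

    @property
    def p2_allele(self) -> str:
        (a,) = self.p2_alleles
        return a


def call_parental_site(
    counts: Mapping[str, int],
    thresholds: CallThresholds = CallThresholds(),
    scaffold: str = "",
    position: int = 0,
) -> ParentalCall:
    """Call the allele set at one parental site.

    A site passes only if total depth >= ``min_depth``; each reported allele
    must have >= ``min_allele_reads`` supporting reads and make up at least
    ``min_allele_fraction`` of all observed reads.
    """
    clean = {a: int(c) for a, c in counts.items() if c > 0}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative allele count")
    depth = sum(clean.values())
    if depth < thresholds.min_depth:
        return ParentalCall(scaffold, position, clean, frozenset(), False)
    alleles = frozenset(
        a
        for a, c in clean.items()
        if c >= thresholds.min_allele_reads and c / depth >= thresholds.min_allele_fraction
    )
    return ParentalCall(scaffold, position, clean, alleles, bool(alleles))


def classify_snp(p1_alleles: frozenset[str], p2_alleles: frozenset[str]) -> str | None:
    """Classify a pair of differing parental allele sets; None if identical.

    Raises on empty sets or sets with more than two alleles (the upstream
    caller must have filtered those).
    """
    for s in (p1_alleles, p2_alleles):
        if not 1 <= len(s) <= 2:
            raise ValueError(f"allele set must have 1 or 2 members, got {set(s)}")
    if p1_alleles == p2_alleles:
        return None
    n1, n2 = len(p1_alleles), len(p2_alleles)
    if n1 == 1 and n2 == 1:
        return SIMPLE
    if (n1 == 2) != (n2 == 2):
        return HEMI
    return COMPLEX


def derive_interspecific_snps(
    p1_calls: Iterable[ParentalCall],
    p2_calls: Iterable[ParentalCall],
) -> list[SnpRecord]:
    """Join the two parental call lists and emit classified SNP records.

    Sites missing or failing in either parent are dropped.  Calls are joined
    on (scaffold, position); scaffold name sets must be consistent.
    """
    p1 = {(c.scaffold, c.position): c for c in p1_calls if c.passed}
    p2 = {(c.scaffold, c.position): c for c in p2_calls if c.passed}
    s1 = {k[0] for k in p1}
    s2 = {k[0] for k in p2}
    if s1 and s2 and not (s1 & s2):
        raise ValueError(
            f"no shared scaffold names between parents ({sorted(s1)[:3]} vs {sorted(s2)[:3]})"
        )
    records = []
    for key in sorted(p1.keys() & p2.keys()):
        a1, a2 = p1[key].alleles, p2[key].alleles
        if len(a1) > 2 or len(a2) > 2:
            continue  # upstream filter: classes defined on <=2 alleles
        cls = classify_snp(a1, a2)
        if cls is None:
            continue
        records.append(SnpRecord(key[0], key[1], a1, a2, cls))
    return records


@dataclass
class ClassSummary:
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def simple_fraction(self) -> float:
        return self.counts[SIMPLE] / self.total if self.total else float("nan")


def filter_for_mapping(records: list[SnpRecord]) -> tuple[list[SnpRecord], ClassSummary]:
    """Retain only simple SNPs (hemi/complex are homoeolog mixtures)."""
    summary = ClassSummary(Counter(r.snp_class for r in records))
    simple = [r for r in records if r.snp_class == SIMPLE]
    return simple, summary
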