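"""Readers and writers for the pipeline's on-disk formats.

All tabular outputs are 1-based inclusive except BED (0-based half-open);
every file starts with a ``#`` comment stating its coordinate dialect.
Internal coordinates are 0-based half-open; conversion happens here only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from polybinmap.genotypes import from_chars, to_chars
from polybinmap.landscape import HomologyHit
from polybinmap.linkage import GeneticMap, LinkageGroup, RecombinationBin
from polybinmap.snp_discovery import SnpRecord, classify_snp

_ALLELE_ORDER = ("A", "C", "G", "T")


class ParseError(ValueError):
    """Malformed input; the message names the offending line."""


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------


@dataclass
class AlleleCountTable:
    """Per-site read counts by allele for one sample (positions 1-based)."""

    sample_id: str
    records: list[tuple[str, int, dict[str, int]]] = field(default_factory=list)

    def validate(self) -> None:
        last: dict[str, int] = {}
        for scaffold, pos, counts in self.records:
            if pos <= last.get(scaffold, 0):
                raise ValueError(
                    f"positions not strictly increasing on {scaffold} at {pos}"
                )
            last[scaffold] = pos
            for allele, c in counts.items():
                if allele not in _ALLELE_ORDER:
                    raise ValueError(f"unknown allele symbol {allele!r}")
                if c < 0:
                    raise ValueError(f"negative count at {scaffold}:{pos}")


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    path = Path(path)
    sample_id = path.stem
    records = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# sample:"):
                    sample_id = line.split(":", 1)[1].strip()
                continue
            fields = line.split("\t")
            if not header_seen:
                if fields != ["scaffold", "pos", "nA", "nC", "nG", "nT"]:
                    raise ParseError(f"line {lineno}: bad header {fields}")
                header_seen = True
                continue
            if len(fields) != 6:
                raise ParseError(f"line {lineno}: expected 6 columns, got {len(fields)}")
            try:
                pos = int(fields[1])
                counts = {a: int(v) for a, v in zip(_ALLELE_ORDER, fields[2:])}
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            if any(v < 0 for v in counts.values()):
                raise ParseError(f"line {lineno}: negative count")
            records.append((fields[0], pos, counts))
    table = AlleleCountTable(sample_id, records)
    table.validate()
    return table


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    table.validate()
    with open(path, "w") as fh:
        fh.write("# coords: 1-based inclusive\n")
        fh.write(f"# sample: {table.sample_id}\n")
        fh.write("scaffold\tpos\tnA\tnC\tnG\tnT\n")
        for scaffold, pos, counts in table.records:
            row = "\t".join(str(counts.get(a, 0)) for a in _ALLELE_ORDER)
            fh.write(f"{scaffold}\t{pos}\t{row}\n")


def allele_count_table(
    sample_id: str,
    scaffolds: np.ndarray,
    positions0: np.ndarray,
    counts_acgt: np.ndarray,
) -> AlleleCountTable:
    """Build a table from arrays (0-based positions, (n, 4) ACGT counts)."""
    order = np.lexsort((positions0, scaffolds))
    records = [
        (
            str(scaffolds[i]),
            int(positions0[i]) + 1,
            {a: int(c) for a, c in zip(_ALLELE_ORDER, counts_acgt[i])},
        )
        for i in order
    ]
    return AlleleCountTable(sample_id, records)


# ---------------------------------------------------------------------------
# homology hit tables (12-column tabular dialect)
# ---------------------------------------------------------------------------


def read_hit_table(path: str | Path) -> list[HomologyHit]:
    """Read a 12-column tabular alignment file; strand from sstart > send."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                sstart, send = int(fields[8]), int(fields[9])
                strand = "-" if sstart > send else "+"
                if strand == "-":
                    sstart, send = send, sstart
                hits.append(
                    HomologyHit(
                        query=fields[0],
                        subject=fields[1],
                        identity=float(fields[2]),
                        length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=sstart,
                        send=send,
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        strand=strand,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
    return hits


def write_hit_table(hits: list[HomologyHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = (h.send, h.sstart) if h.strand == "-" else (h.sstart, h.send)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query,
                        h.subject,
                        h.identity,
                        h.length,
                        h.mismatches,
                        h.gap_opens,
                        h.qstart,
                        h.qend,
                        sstart,
                        send,
                        f"{h.evalue:.2e}",
                        h.bitscore,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SNP table (VCF-like with a CLASS column)
# ---------------------------------------------------------------------------


def write_snp_table(records: list[SnpRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coords: 1-based inclusive\n")
        fh.write("CHROM\tPOS\tPARENT1\tPARENT2\tCLASS\n")
        for r in records:
            fh.write(
                f"{r.scaffold}\t{r.position + 1}\t"
                f"{'/'.join(sorted(r.p1_alleles))}\t{'/'.join(sorted(r.p2_alleles))}\t"
                f"{r.snp_class}\n"
            )


def read_snp_table(path: str | Path) -> list[SnpRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("CHROM"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5 columns")
            p1 = frozenset(fields[2].split("/"))
            p2 = frozenset(fields[3].split("/"))
            cls = classify_snp(p1, p2)
            if cls != fields[4]:
                raise ParseError(
                    f"line {lineno}: stated class {fields[4]} != derived {cls}"
                )
            records.append(SnpRecord(fields[0], int(fields[1]) - 1, p1, p2, fields[4]))
    return records


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------


def write_genotype_matrix(
    genotypes: np.ndarray,
    scaffolds: np.ndarray,
    positions0: np.ndarray,
    sample_ids: list[str],
    path: str | Path,
) -> None:
    chars = to_chars(genotypes)
    with open(path, "w") as fh:
        fh.write("# coords: 1-based inclusive; codes A/B/H/-\n")
        fh.write("scaffold\tpos\t" + "\t".join(sample_ids) + "\n")
        for i in range(genotypes.shape[0]):
            fh.write(
                f"{scaffolds[i]}\t{int(positions0[i]) + 1}\t" + "\t".join(chars[i]) + "\n"
            )


def read_genotype_matrix(
    path: str | Path,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Returns (genotypes, scaffolds, positions0, sample_ids)."""
    scaffolds, positions, rows = [], [], []
    sample_ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not sample_ids:
                sample_ids = fields[2:]
                continue
            scaffolds.append(fields[0])
            positions.append(int(fields[1]) - 1)
            rows.append(fields[2:])
    genotypes = from_chars(np.array(rows)) if rows else np.empty((0, 0), dtype=np.int8)
    return genotypes, np.array(scaffolds), np.array(positions), sample_ids


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------


def write_genetic_map(gmap: GeneticMap, path_map: str | Path, path_summary: str | Path) -> None:
    """Per-bin map text plus a per-group summary TSV with a totals row."""
    for group in gmap.groups:
        if np.any(np.diff(group.cum_cm) < 0):
            raise ValueError(f"group {group.name}: cumulative cM not non-decreasing")
    bin_by_id = {b.bin_id: b for b in gmap.bins}
    with open(path_map, "w") as fh:
        fh.write("# coords: 1-based inclusive; cumulative cM per bin\n")
        fh.write("group\tbin_id\tcum_cm\tn_snps\tscaffolds\n")
        for group in gmap.groups:
            for bid, cm in zip(group.bin_ids, group.cum_cm):
                b = bin_by_id[bid]
                fh.write(
                    f"{group.name}\t{bid}\t{cm:.6f}\t{b.n_snps}\t{','.join(b.scaffolds)}\n"
                )
    with open(path_summary, "w") as fh:
        fh.write("group\tn_bins\tlength_cm\tn_snps\n")
        tot_bins = tot_snps = 0
        tot_cm = 0.0
        for group in gmap.groups:
            n_snps = sum(bin_by_id[b].n_snps for b in group.bin_ids)
            fh.write(
                f"{group.name}\t{len(group.bin_ids)}\t{group.length_cm:.2f}\t{n_snps}\n"
            )
            tot_bins += len(group.bin_ids)
            tot_cm += group.length_cm
            tot_snps += n_snps
        fh.write(f"Total\t{tot_bins}\t{tot_cm:.2f}\t{tot_snps}\n")


def read_genetic_map(path_map: str | Path) -> GeneticMap:
    """Rebuild a map skeleton (groups, bin ids, cM, SNP counts) from disk."""
    groups: dict[str, tuple[list[int], list[float]]] = {}
    bins: dict[int, RecombinationBin] = {}
    with open(path_map) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("group\t"):
                continue
            name, bid, cm, n_snps, scafs = line.split("\t")
            bid = int(bid)
            ids, cms = groups.setdefault(name, ([], []))
            ids.append(bid)
            cms.append(float(cm))
            bins[bid] = RecombinationBin(
                bin_id=bid,
                site_indices=np.arange(int(n_snps)),
                genotype=np.empty(0, dtype=np.int8),
                scaffolds=scafs.split(",") if scafs else [],
            )
    return GeneticMap(
        bins=[bins[b] for b in sorted(bins)],
        groups=[
            LinkageGroup(name=n, bin_ids=ids, cum_cm=np.array(cms))
            for n, (ids, cms) in groups.items()
        ],
    )


# ---------------------------------------------------------------------------
# intervals, AGP, FASTA
# ---------------------------------------------------------------------------


def write_intervals_bed(
    intervals: list[tuple[str, int, int, str]], path: str | Path
) -> None:
    """BED: 0-based half-open (chrom, start, end, label); overlaps preserved."""
    for chrom, start, end, _ in intervals:
        if end <= start:
            raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
    with open(path, "w") as fh:
        fh.write("# coords: 0-based half-open (BED)\n")
        for chrom, start, end, label in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, start, end, label = line.split("\t")[:4]
            out.append((chrom, int(start), int(end), label))
    return out


def write_agp(rows: list[tuple], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ParseError("sequence before header")
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}
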