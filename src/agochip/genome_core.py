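"""Genomic coordinate model, gene-model I/O, genome feature partitioning,
and strand-aware TSS distance arithmetic.

All internal coordinates are 0-based, half-open (BED convention). GTF input
(1-based, inclusive) is converted on read. Every other module builds on the
types defined here.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FEATURE_LABELS",
    "ChromSizes",
    "Interval",
    "GeneModel",
    "FeatureMap",
    "read_chrom_sizes",
    "read_gene_models",
    "write_gene_models",
    "read_bed_intervals",
    "write_bed_intervals",
    "partition_genome",
    "locate_interval",
    "signed_tss_distance",
]

#: Feature classes in decreasing precedence. When a base is claimed by more
#: than one class (e.g. one gene's promoter inside another gene's intron) the
#: highest-precedence label wins; promoter outranks everything.
FEATURE_LABELS = (
    "promoter",
    "5utr",
    "coding_exon",
    "intron",
    "3utr",
    "3flank",
    "intergenic",
)

_LABEL_CODE = {label: i for i, label in enumerate(FEATURE_LABELS)}
_INTERGENIC = _LABEL_CODE["intergenic"]


class ChromSizes(collections.OrderedDict):
    """Ordered mapping of chromosome name to length in bp.

    Names must be unique (enforced by the mapping) and lengths positive.
    """

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        super().__setitem__(name, length)

    @property
    def total(self) -> int:
        """Total genome length in bp."""
        return sum(self.values())


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column (name, length) tab-separated chromosome sizes file."""
    sizes = ChromSizes()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            name = fields[0]
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = int(fields[1])
    return sizes


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A single gene model: transcript bounds, optional CDS, exon structure.

    The TSS is the strand-oriented 5' end: ``tx_start`` on the + strand and
    ``tx_end - 1`` (the last base) on the - strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.gene_id}: invalid transcript bounds")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: gene has no exons")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if not self.tx_start <= s < e <= self.tx_end:
                raise ValueError(
                    f"gene {self.gene_id}: exon {s}-{e} outside transcript "
                    f"{self.tx_start}-{self.tx_end}"
                )
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.gene_id}: cds bounds must be both set or both absent")
        if self.cds_start is not None:
            if not self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end:
                raise ValueError(f"gene {self.gene_id}: CDS outside transcript bounds")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None and self.cds_start < self.cds_end


def _parse_bed12(line: str, lineno: int, path: str) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"{path}:{lineno}: BED12 record needs 12 columns, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed BED12 record: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"{path}:{lineno}: block count mismatch")
    exons = [(start + off, start + off + sz) for off, sz in zip(starts, sizes)]
    cds_start = cds_end = None
    if thick_end > thick_start:
        cds_start, cds_end = thick_start, thick_end
    return GeneModel(
        gene_id=name, chrom=chrom, strand=strand, tx_start=start, tx_end=end,
        exons=exons, cds_start=cds_start, cds_end=cds_end,
    )


def _parse_gtf(path: str | Path) -> list[GeneModel]:
    # Group exon/CDS features per transcript; convert 1-based inclusive
    # GTF coordinates to 0-based half-open.
    exons: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    cds: dict[str, list[tuple[int, int]]] = collections.defaultdict(list)
    meta: dict[str, tuple[str, str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"{path}:{lineno}: GTF record needs 9 columns, got {len(f)}")
            chrom, _, feature, start, end, _, strand, _, attrs = f
            if feature not in ("exon", "CDS"):
                continue
            try:
                iv = (int(start) - 1, int(end))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
            attr_map = {}
            for item in attrs.rstrip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attr_map[key] = val.strip().strip('"')
            tid = attr_map.get("transcript_id") or attr_map.get("gene_id")
            if tid is None:
                raise ValueError(f"{path}:{lineno}: record lacks transcript_id/gene_id")
            if tid not in meta:
                meta[tid] = (chrom, strand, attr_map.get("gene_id", tid))
                order.append(tid)
            if feature == "exon":
                exons[tid].append(iv)
            else:
                cds[tid].append(iv)
    genes = []
    for tid in order:
        chrom, strand, gid = meta[tid]
        ex = sorted(exons[tid])
        if not ex:
            raise ValueError(f"{path}: transcript {tid} has no exon records")
        cds_start = cds_end = None
        if cds[tid]:
            cds_start = min(s for s, _ in cds[tid])
            cds_end = max(e for _, e in cds[tid])
        genes.append(GeneModel(
            gene_id=gid, chrom=chrom, strand=strand,
            tx_start=ex[0][0], tx_end=ex[-1][1],
            exons=ex, cds_start=cds_start, cds_end=cds_end,
        ))
    return genes


def read_gene_models(path: str | Path, dialect: str | None = None) -> list[GeneModel]:
    """Read gene models from a BED12 or GTF file.

    Parameters
    ----------
    path:
        Input file. The dialect is taken from the extension (``.bed`` -> BED12,
        ``.gtf``/``.gff`` -> GTF) unless given explicitly.
    dialect:
        ``"bed12"`` or ``"gtf"``; overrides extension sniffing.
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = "gtf" if suffix in (".gtf", ".gff") else "bed12"
    if dialect == "gtf":
        return _parse_gtf(path)
    if dialect != "bed12":
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            genes.append(_parse_bed12(line, lineno, str(path)))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (exact round-trip with :func:`read_gene_models`)."""
    with open(path, "w") as fh:
        for g in genes:
            thick = (g.cds_start, g.cds_end) if g.has_cds else (g.tx_start, g.tx_start)
            sizes = ",".join(str(e - s) for s, e in g.exons)
            starts = ",".join(str(s - g.tx_start) for s, _ in g.exons)
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{thick[0]}\t{thick[1]}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read BED3/BED6 intervals; column 4 (name) and 6 (strand) kept if present."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 3 columns")
            name = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(Interval(f[0], int(f[1]), int(f[2]), strand=strand, name=name))
    return out


def write_bed_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


@dataclass
class FeatureMap:
    """Exhaustive per-base feature labelling of a genome.

    Each base carries exactly one label from :data:`FEATURE_LABELS`; the
    per-label bp totals therefore sum to the genome length.
    """

    labels: dict[str, np.ndarray]
    flank_width: int
    sizes: ChromSizes = field(repr=False, default=None)

    @property
    def genome_composition(self) -> dict[str, int]:
        """Total bp per feature label across all chromosomes."""
        totals = {label: 0 for label in FEATURE_LABELS}
        for arr in self.labels.values():
            counts = np.bincount(arr, minlength=len(FEATURE_LABELS))
            for label, code in _LABEL_CODE.items():
                totals[label] += int(counts[code])
        return totals

    @property
    def genome_fractions(self) -> dict[str, float]:
        comp = self.genome_composition
        total = sum(comp.values())
        return {label: bp / total for label, bp in comp.items()}

    def label_at(self, chrom: str, pos: int) -> str:
        if chrom not in self.labels:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return FEATURE_LABELS[self.labels[chrom][pos]]


def _gene_class_intervals(gene: GeneModel, flank: int, chrom_len: int):
    """Yield (label_code, start, end) regions for one gene, clipped to the chromosome."""
    fwd = gene.strand == "+"
    if fwd:
        promoter = (gene.tx_start - flank, gene.tx_start)
        flank3 = (gene.tx_end, gene.tx_end + flank)
    else:
        promoter = (gene.tx_end, gene.tx_end + flank)
        flank3 = (gene.tx_start - flank, gene.tx_start)
    regions = [
        (_LABEL_CODE["promoter"], *promoter),
        (_LABEL_CODE["3flank"], *flank3),
    ]
    # introns are the gaps between consecutive exons
    for (_, prev_end), (next_start, _) in zip(gene.exons, gene.exons[1:]):
        if prev_end < next_start:
            regions.append((_LABEL_CODE["intron"], prev_end, next_start))
    # Exonic bases: split into UTRs and coding exon around the CDS when
    # annotated; genes without CDS contribute all exon bases as coding_exon.
    for s, e in gene.exons:
        if not gene.has_cds:
            regions.append((_LABEL_CODE["coding_exon"], s, e))
            continue
        cs, ce = gene.cds_start, gene.cds_end
        left = (s, min(e, cs))     # exon bases 5' (genomic) of the CDS
        mid = (max(s, cs), min(e, ce))
        right = (max(s, ce), e)    # exon bases 3' (genomic) of the CDS
        left_label = "5utr" if fwd else "3utr"
        right_label = "3utr" if fwd else "5utr"
        for (rs, re_), lab in ((left, left_label), (mid, "coding_exon"), (right, right_label)):
            if rs < re_:
                regions.append((_LABEL_CODE[lab], rs, re_))
    for code, s, e in regions:
        s, e = max(0, s), min(chrom_len, e)
        if s < e:
            yield code, s, e


def partition_genome(
    genes: Sequence[GeneModel], sizes: ChromSizes, flank_width: int = 5000
) -> FeatureMap:
    """Label every genomic base with one of the feature classes.

    The promoter is ``flank_width`` bp upstream of the TSS (strand-aware) and
    the 3' flank is ``flank_width`` bp downstream of the gene end. Bases
    claimed by several classes take the highest-precedence label
    (promoter > 5'UTR > coding exon > intron > 3'UTR > 3' flank).
    """
    if flank_width <= 0:
        raise ValueError("flank_width must be positive")
    labels = {
        chrom: np.full(length, _INTERGENIC, dtype=np.uint8)
        for chrom, length in sizes.items()
    }
    for g in genes:
        if g.chrom not in labels:
            raise KeyError(f"gene {g.gene_id} on unknown chromosome {g.chrom!r}")
        if g.tx_end > sizes[g.chrom]:
            raise ValueError(f"gene {g.gene_id} extends past end of {g.chrom}")
    # Paint lowest precedence first so higher-precedence classes overwrite;
    # each class is painted across all genes before the next, so precedence
    # holds between overlapping genes too.
    per_class: dict[int, list[tuple[str, int, int]]] = collections.defaultdict(list)
    for g in genes:
        for code, s, e in _gene_class_intervals(g, flank_width, sizes[g.chrom]):
            per_class[code].append((g.chrom, s, e))
    for code in sorted(per_class, reverse=True):
        for chrom, s, e in per_class[code]:
            labels[chrom][s:e] = code
    return FeatureMap(labels=labels, flank_width=flank_width, sizes=sizes)


def locate_interval(fm: FeatureMap, iv: Interval, mode: str = "midpoint"):
    """Assign an interval to feature classes.

    ``midpoint`` mode returns the single label at the interval midpoint;
    ``bp_composition`` returns a label -> fraction mapping over the interval
    (fractions sum to 1).
    """
    if iv.chrom not in fm.labels:
        raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")
    arr = fm.labels[iv.chrom]
    if iv.end > len(arr):
        raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} extends past chromosome end")
    if mode == "midpoint":
        return FEATURE_LABELS[arr[iv.midpoint]]
    if mode == "bp_composition":
        counts = np.bincount(arr[iv.start:iv.end], minlength=len(FEATURE_LABELS))
        n = len(iv)
        return {label: counts[code] / n for label, code in _LABEL_CODE.items()}
    raise ValueError(f"unknown mode {mode!r}")


def signed_tss_distance(gene: GeneModel, position: int) -> int:
    """Signed distance from the TSS to ``position`` in gene orientation.

    Zero at the TSS base; positive downstream (into the gene body), negative
    upstream of the TSS.
    """
    if gene.strand == "+":
        return position - gene.tss
    return gene.tss - position
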