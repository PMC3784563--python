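"""Integration of promoter binding with knockdown expression changes.

Bound genes (AbGs) are those with a peak midpoint within a stated window of
their TSS; responsive genes (ArGs) pass fold-change and p-value thresholds in
the knockdown differential-expression table. Their overlap is tested against
a hypergeometric null over the gene universe (genes present in both the
annotation and the expression table). The positional scan repeats the
enrichment test at every 1-bp offset in a +/- 5 kb window around TSSs, where
a gene counts as bound *at* offset d if some peak interval covers TSS + d in
gene orientation (interval cover, deliberately distinct from the
midpoint-window rule used for AbG sets).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome_core import GeneModel
from .peak_processing import Peak

__all__ = [
    "ExpressionRecord",
    "GeneSetOverlap",
    "PositionalScanResult",
    "read_expression_table",
    "define_abgs",
    "define_args",
    "overlap_test",
    "positional_scan",
]


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's knockdown-vs-control expression change.

    ``fold_change`` is a linear ratio (> 0); log2 input dialects are converted
    on read.
    """

    gene_id: str
    fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.gene_id}: linear fold change must be > 0")
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"{self.gene_id}: p-value outside [0, 1]")


@dataclass
class GeneSetOverlap:
    """Observed vs expected overlap of two gene sets in a universe."""

    universe_size: int
    n_a: int
    n_b: int
    observed: int
    expected: float
    p_value: float


@dataclass
class PositionalScanResult:
    """Per-offset enrichment p-values for up/down responsive genes."""

    offsets: np.ndarray       # -W .. +W inclusive, step 1
    p_up: np.ndarray
    p_down: np.ndarray
    bound_counts: np.ndarray  # genes bound at each offset
    argmin_up: int
    argmin_down: int
    min_p_up: float
    min_p_down: float


def read_expression_table(
    path: str | Path, collapse_duplicates: bool = False
) -> list[ExpressionRecord]:
    """Read a TSV of (gene_id, fold_change | log2_fold_change, p_value).

    The header declares the fold-change dialect; it is never guessed. With
    ``collapse_duplicates`` the record with the largest |log2 fold change| is
    kept per gene; otherwise duplicate gene ids raise.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "gene_id" not in header or "p_value" not in header:
            raise ValueError(f"{path}: header must name gene_id and p_value columns")
        if "fold_change" in header:
            fc_col, log2 = header.index("fold_change"), False
        elif "log2_fold_change" in header:
            fc_col, log2 = header.index("log2_fold_change"), True
        else:
            raise ValueError(f"{path}: header must declare fold_change or log2_fold_change")
        gid_col, p_col = header.index("gene_id"), header.index("p_value")
        records: dict[str, ExpressionRecord] = {}
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gid = f[gid_col]
            fc = float(f[fc_col])
            if log2:
                fc = 2.0 ** fc
            rec = ExpressionRecord(gid, fc, float(f[p_col]))
            if gid in records:
                if not collapse_duplicates:
                    raise ValueError(f"{path}:{lineno}: duplicate gene id {gid!r}")
                if abs(np.log2(rec.fold_change)) > abs(np.log2(records[gid].fold_change)):
                    records[gid] = rec
            else:
                records[gid] = rec
    return list(records.values())


def define_abgs(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    windows: Sequence[int] = (5000, 1000, 500),
) -> dict[int, set[str]]:
    """Bound-gene sets: gene in set(W) iff some peak midpoint lies within W bp
    of the gene's TSS. Sets are nested by construction."""
    if any(w <= 0 for w in windows):
        raise ValueError("windows must be positive")
    mids: dict[str, np.ndarray] = {}
    for p in peaks:
        mids.setdefault(p.chrom, []).append(p.midpoint)
    mids = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in mids.items()}
    out: dict[int, set[str]] = {w: set() for w in windows}
    for g in genes:
        arr = mids.get(g.chrom)
        if arr is None or not len(arr):
            continue
        for w in windows:
            lo = np.searchsorted(arr, g.tss - w, side="left")
            hi = np.searchsorted(arr, g.tss + w, side="right")
            if hi > lo:
                out[w].add(g.gene_id)
    return out


def define_args(
    records: Iterable[ExpressionRecord],
    fc_threshold: float = 1.2,
    p_threshold: float = 0.05,
) -> tuple[set[str], set[str]]:
    """Responsive gene sets: up = fold change strictly > threshold, down =
    strictly < 1/threshold, both requiring p strictly < p_threshold."""
    if fc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    up, down, seen = set(), set(), set()
    for r in records:
        if r.gene_id in seen:
            raise ValueError(f"duplicate gene id {r.gene_id!r} in expression records")
        seen.add(r.gene_id)
        if r.p_value < p_threshold:
            if r.fold_change > fc_threshold:
                up.add(r.gene_id)
            elif r.fold_change < 1.0 / fc_threshold:
                down.add(r.gene_id)
    return up, down


def overlap_test(set_a: set, set_b: set, universe: set) -> GeneSetOverlap:
    """Hypergeometric upper-tail test of the overlap between two gene sets.

    p = P(overlap >= observed) drawing |B| genes from a universe of N with
    |A| marked. Expected overlap is |A| * |B| / N.
    """
    if not universe:
        raise ValueError("empty universe")
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both sets must be subsets of the universe")
    n = len(universe)
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))
    return GeneSetOverlap(
        universe_size=n, n_a=len(set_a), n_b=len(set_b),
        observed=k, expected=len(set_a) * len(set_b) / n, p_value=min(p, 1.0),
    )


def _cover_matrix(
    peaks: Sequence[Peak], genes: Sequence[GeneModel], window: int
) -> np.ndarray:
    """Boolean (genes x offsets) matrix: gene bound at TSS + d (gene-oriented)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    n_off = 2 * window + 1
    cover = np.zeros((len(genes), n_off), dtype=bool)
    for gi, g in enumerate(genes):
        for s, e in by_chrom.get(g.chrom, []):
            if g.strand == "+":
                lo, hi = s - g.tss, e - g.tss  # half-open offset range
            else:
                lo, hi = g.tss - e + 1, g.tss - s + 1
            lo = max(lo, -window)
            hi = min(hi, window + 1)
            if lo < hi:
                cover[gi, lo + window:hi + window] = True
    return cover


def positional_scan(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    up_set: set[str],
    down_set: set[str],
    universe: set[str],
    window: int = 5000,
) -> PositionalScanResult:
    """Hypergeometric enrichment of responsive genes among genes bound at each
    1-bp offset in [-window, +window] around the TSS.

    Offsets where no gene is bound get p = 1 by convention. The argmin per
    direction is the first offset attaining the minimal p.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not universe:
        raise ValueError("empty universe")
    gene_list = [g for g in genes if g.gene_id in universe]
    cover = _cover_matrix(peaks, gene_list, window)
    n = len(universe)
    ids = np.array([g.gene_id for g in gene_list])
    bound_counts = cover.sum(axis=0)
    offsets = np.arange(-window, window + 1)
    result_p = {}
    for name, gene_set in (("up", up_set & universe), ("down", down_set & universe)):
        in_set = np.isin(ids, sorted(gene_set))
        k = cover[in_set].sum(axis=0)
        p = np.ones(len(offsets))
        nz = bound_counts > 0
        p[nz] = stats.hypergeom.sf(k[nz] - 1, n, len(gene_set), bound_counts[nz])
        result_p[name] = np.minimum(p, 1.0)
    i_up = int(np.argmin(result_p["up"]))
    i_down = int(np.argmin(result_p["down"]))
    return PositionalScanResult(
        offsets=offsets, p_up=result_p["up"], p_down=result_p["down"],
        bound_counts=bound_counts,
        argmin_up=int(offsets[i_up]), argmin_down=int(offsets[i_down]),
        min_p_up=float(result_p["up"][i_up]), min_p_down=float(result_p["down"][i_down]),
    )
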