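"""Peak distribution relative to transcription start sites and co-occurrence
with H3K4me3 marks.

A peak's position is its midpoint; its TSS distance is the signed,
gene-strand-oriented distance to the *nearest* TSS (ties in absolute distance
broken toward the downstream, positive side).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_core import GeneModel
from .peak_processing import Peak

__all__ = [
    "TSSHistogram",
    "CostratResult",
    "nearest_tss_distances",
    "tss_distance_histogram",
    "h3k4me3_costratification",
]


@dataclass
class TSSHistogram:
    """Binned counts of peak-to-nearest-TSS signed distances."""

    window: int
    bin_width: int
    counts: dict[int, int]  # bin start offset -> count; bins are [lo, lo + bin_width)
    n_peaks_in_window: int


@dataclass
class CostratResult:
    """Fraction of TSS-proximal peaks from one set overlapping another set."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float | None:
        return self.numerator / self.denominator if self.denominator else None


def _tss_index(genes: Sequence[GeneModel]):
    """Per-chromosome sorted TSS positions with strand signs (+1 / -1)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append((g.tss, 1 if g.strand == "+" else -1))
    index = {}
    for chrom, items in by_chrom.items():
        items.sort()
        index[chrom] = (
            np.array([t for t, _ in items], dtype=np.int64),
            np.array([s for _, s in items], dtype=np.int64),
        )
    return index


def nearest_tss_distances(peaks: Sequence[Peak], genes: Sequence[GeneModel]) -> np.ndarray:
    """Signed gene-oriented distance from each peak midpoint to its nearest TSS.

    Peaks on chromosomes without genes get NaN. Among genes tied in absolute
    distance the downstream (positive) signed distance is reported.
    """
    if not genes:
        raise ValueError("need at least one gene model")
    index = _tss_index(genes)
    out = np.full(len(peaks), np.nan)
    for i, p in enumerate(peaks):
        if p.chrom not in index:
            continue
        tss, sign = index[p.chrom]
        mid = p.midpoint
        d = (mid - tss) * sign
        absd = np.abs(d)
        best = absd.min()
        candidates = d[absd == best]
        out[i] = candidates.max()  # ties break toward the positive side
    return out


def tss_distance_histogram(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = 5000,
    bin_width: int = 100,
) -> TSSHistogram:
    """Histogram of signed nearest-TSS distances within +/- ``window`` bp.

    Bins are half-open ``[lo, lo + bin_width)`` covering [-window, +window);
    a peak exactly at +window falls in the last bin. Peaks farther than the
    window (or on gene-free chromosomes) are excluded.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if (2 * window) % bin_width != 0:
        raise ValueError("bin_width must divide 2 * window")
    n_bins = 2 * window // bin_width
    counts = {(-window + i * bin_width): 0 for i in range(n_bins)}
    d = nearest_tss_distances(peaks, genes)
    kept = d[~np.isnan(d)]
    kept = kept[np.abs(kept) <= window]
    for dist in kept:
        idx = min(int((dist + window) // bin_width), n_bins - 1)
        counts[-window + idx * bin_width] += 1
    return TSSHistogram(
        window=window, bin_width=bin_width, counts=counts,
        n_peaks_in_window=int(len(kept)),
    )


def h3k4me3_costratification(
    peaks_a: Sequence[Peak],
    peaks_k4: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = 1000,
) -> CostratResult:
    """Of the A-peaks within +/- ``window`` of a TSS, the fraction that share
    at least 1 bp with any K4 peak."""
    d = nearest_tss_distances(peaks_a, genes)
    proximal = [p for p, dist in zip(peaks_a, d) if not np.isnan(dist) and abs(dist) <= window]
    k4_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for k in peaks_k4:
        k4_by_chrom.setdefault(k.chrom, []).append((k.start, k.end))
    for v in k4_by_chrom.values():
        v.sort()
    n_hit = 0
    for p in proximal:
        for s, e in k4_by_chrom.get(p.chrom, []):
            if s >= p.end:
                break
            if e > p.start:
                n_hit += 1
                break
    return CostratResult(numerator=n_hit, denominator=len(proximal))
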