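"""Peak I/O, validation-driven FDR cutoff selection, filtering, and
descriptive peak statistics.

Peaks arrive as BED6+1 (column 7 = per-peak FDR from the caller). The FDR
cutoff is chosen from an independent ChIP-qPCR validation table: scanning
validation bins in increasing FDR order, the cutoff is the upper FDR bound of
the last bin in the maximal prefix whose validation rates all meet a minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_core import ChromSizes, Interval

__all__ = [
    "Peak",
    "ValidationBin",
    "PeakSummary",
    "NO_CUTOFF",
    "read_peaks",
    "write_peaks",
    "read_validation_table",
    "select_fdr_cutoff",
    "filter_peaks",
    "summarize_peaks",
]

#: Sentinel returned by :func:`select_fdr_cutoff` when no validation bin
#: meets the minimum rate.
NO_CUTOFF = None


@dataclass(frozen=True)
class Peak:
    """A scored peak interval with a caller-assigned FDR."""

    interval: Interval
    score: float = 0.0
    fdr: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"peak FDR {self.fdr} outside [0, 1]")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class ValidationBin:
    """One FDR range from an independent ChIP validation experiment."""

    fdr_lo: float
    fdr_hi: float
    n_tested: int
    n_validated: int

    def __post_init__(self) -> None:
        if not 0 <= self.fdr_lo < self.fdr_hi <= 1:
            raise ValueError("validation bin bounds must satisfy 0 <= lo < hi <= 1")
        if not 0 <= self.n_validated <= self.n_tested:
            raise ValueError("need 0 <= n_validated <= n_tested")

    @property
    def rate(self) -> float:
        return self.n_validated / self.n_tested


@dataclass
class PeakSummary:
    """Descriptive statistics for a peak set."""

    n_peaks: int
    size_quantiles: dict[float, float]       # bp at 0.25 / 0.5 / 0.75
    density_per_chrom: dict[str, float]      # peaks per `window` bp
    mean_spacing_kb: float | None            # genome kb per peak; None if no peaks
    window: int


def read_peaks(path: str | Path, fdr_column: int = 6) -> list[Peak]:
    """Read BED6+1 peaks (0-based half-open; ``fdr_column`` 0-based index)."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) <= fdr_column:
                raise ValueError(f"{path}:{lineno}: record has no FDR column {fdr_column + 1}")
            try:
                iv = Interval(f[0], int(f[1]), int(f[2]),
                              strand=f[5] if len(f) > 5 and f[5] in "+-" else ".",
                              name=f[3] if len(f) > 3 else ".")
                score = float(f[4]) if len(f) > 4 else 0.0
                fdr = float(f[fdr_column])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed peak record: {exc}") from exc
            if not 0.0 <= fdr <= 1.0:
                raise ValueError(f"{path}:{lineno}: FDR {fdr} outside [0, 1]")
            peaks.append(Peak(interval=iv, score=score, fdr=fdr))
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            # %.17g keeps write/read round-trips exact
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.interval.name}\t{p.score:.17g}\t"
                f"{p.interval.strand}\t{p.fdr:.17g}\n"
            )


def read_validation_table(path: str | Path) -> list[ValidationBin]:
    """Read a TSV with columns fdr_lo, fdr_hi, n_tested, n_validated (header optional)."""
    bins = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[0] == "fdr_lo":
                continue
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            bins.append(ValidationBin(float(f[0]), float(f[1]), int(f[2]), int(f[3])))
    return bins


def select_fdr_cutoff(bins: Sequence[ValidationBin], min_rate: float):
    """Choose an FDR cutoff from validation bins.

    Scanning bins in increasing FDR order, find the maximal prefix whose
    validation rates are all >= ``min_rate``; the cutoff is the ``fdr_hi`` of
    the last bin in that prefix. Returns :data:`NO_CUTOFF` (``None``) if the
    first bin already fails.
    """
    if not bins:
        raise ValueError("need at least one validation bin")
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    ordered = list(bins)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.fdr_lo < prev.fdr_hi:
            raise ValueError("validation bins must be sorted and non-overlapping")
    cutoff = NO_CUTOFF
    for b in ordered:
        if b.rate >= min_rate:
            cutoff = b.fdr_hi
        else:
            break
    return cutoff


def filter_peaks(peaks: Sequence[Peak], cutoff: float) -> list[Peak]:
    """Keep peaks with FDR <= cutoff (inclusive), preserving order."""
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    return [p for p in peaks if p.fdr <= cutoff]


def summarize_peaks(
    peaks: Sequence[Peak], sizes: ChromSizes, window: int = 100_000
) -> PeakSummary:
    """Peak count, size quantiles, per-chromosome density, and mean spacing.

    Density is peaks per ``window`` bp (default 100 kb). Mean spacing is total
    genome length divided by peak count ("one peak every X kb"), reported in
    kb; ``None`` when there are no peaks.
    """
    for p in peaks:
        if p.chrom not in sizes:
            raise KeyError(f"peak on unknown chromosome {p.chrom!r}")
    n = len(peaks)
    widths = np.array([len(p) for p in peaks], dtype=float)
    quantiles = (
        {q: float(np.quantile(widths, q)) for q in (0.25, 0.5, 0.75)}
        if n else {q: float("nan") for q in (0.25, 0.5, 0.75)}
    )
    counts = {chrom: 0 for chrom in sizes}
    for p in peaks:
        counts[p.chrom] += 1
    density = {chrom: counts[chrom] / sizes[chrom] * window for chrom in sizes}
    spacing = (sizes.total / n / 1000.0) if n else None
    return PeakSummary(
        n_peaks=n, size_quantiles=quantiles, density_per_chrom=density,
        mean_spacing_kb=spacing, window=window,
    )
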