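"""Peak composition over feature classes, repeat classes and chromosomes,
with enrichment statistics and density regressions.

Enrichment of a class compares the fraction of peaks (or peak bp) falling in
the class with the fraction of the genome the class occupies; significance is
a two-sided exact binomial test with the genome fraction as the null
probability. Reported raw p-values are clamped at the smallest positive
double, and ``log10_p`` is always finite; extreme printed values such as
5e-324 are double-precision underflow artifacts, so ``log10_p`` is the
authoritative quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome_core import ChromSizes, FeatureMap, FEATURE_LABELS, GeneModel, Interval, locate_interval
from .peak_processing import Peak

__all__ = [
    "REPEAT_CLASSES",
    "EnrichmentResult",
    "RegressionResult",
    "feature_composition",
    "repeat_composition",
    "genome_repeat_fractions",
    "build_density_table",
    "regress_peak_density",
    "overlap_fraction",
]

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "low_complexity", "simple_repeat", "other")

_P_FLOOR = 5e-324  # smallest positive (subnormal) double


@dataclass
class EnrichmentResult:
    """Observed vs genome-expected occupancy of one feature class."""

    label: str
    observed_count: int
    observed_fraction: float
    genome_fraction: float
    ratio: float
    p_value: float
    log10_p: float


@dataclass
class RegressionResult:
    """Simple and multiple OLS regressions of one response on covariates."""

    response: str
    covariates: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    simple_r2: dict[str, float]
    multiple_r2: float
    collinear: bool = False


def _binom_enrichment(k: int, n: int, p0: float, label: str) -> EnrichmentResult:
    obs_frac = k / n if n else 0.0
    if p0 <= 0:
        if k > 0:
            warnings.warn(f"class {label!r} absent from genome but observed in peaks")
            ratio: float = math.inf
        else:
            ratio = 0.0
        return EnrichmentResult(label, k, obs_frac, p0, ratio, 1.0, 0.0)
    ratio = obs_frac / p0
    p = stats.binomtest(k, n, p0, alternative="two-sided").pvalue if n else 1.0
    p = max(float(p), _P_FLOOR)
    return EnrichmentResult(label, k, obs_frac, p0, ratio, p, math.log10(p))


def feature_composition(
    peaks: Sequence[Peak], fm: FeatureMap, mode: str = "midpoint"
) -> tuple[dict[str, int], list[EnrichmentResult]]:
    """Peak occupancy per feature class with enrichment vs the genome.

    ``midpoint`` mode counts each peak once, for the class at its midpoint;
    ``bp_composition`` totals peak bp per class. Enrichment ratio is the
    observed fraction over the genome fraction of the class.
    """
    counts = {label: 0 for label in FEATURE_LABELS}
    if mode == "midpoint":
        for p in peaks:
            counts[locate_interval(fm, p.interval, "midpoint")] += 1
    elif mode == "bp_composition":
        for p in peaks:
            fractions = locate_interval(fm, p.interval, "bp_composition")
            for label, frac in fractions.items():
                counts[label] += round(frac * len(p))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = sum(counts.values())
    genome_fracs = fm.genome_fractions
    results = [
        _binom_enrichment(counts[label], n, genome_fracs[label], label)
        for label in FEATURE_LABELS
    ]
    return counts, results


def _class_coverage(length: int, intervals: Sequence[tuple[int, int, int]]) -> np.ndarray:
    """Per-base class index over [0, length); -1 where uncovered.

    ``intervals`` are (start, end, class_index) in input order; earlier
    entries win where annotations overlap.
    """
    cov = np.full(length, -1, dtype=np.int16)
    for s, e, ci in intervals:
        s, e = max(0, s), min(length, e)
        if s >= e:
            continue
        seg = cov[s:e]
        unset = seg == -1
        if not unset.all():
            warnings.warn("overlapping repeat annotations; keeping first-listed class")
        seg[unset] = ci
    return cov


def _normalize_repeat_class(name: str) -> str:
    key = name.strip().replace(" ", "_")
    lowered = key.lower()
    aliases = {"line": "LINE", "sine": "SINE", "ltr": "LTR",
               "low_complexity": "low_complexity", "simple_repeat": "simple_repeat"}
    return aliases.get(lowered, key if key in REPEAT_CLASSES else "other")


def genome_repeat_fractions(
    repeats: Sequence[Interval], sizes: ChromSizes
) -> dict[str, float]:
    """Fraction of the genome covered by each repeat class (plus non_repetitive).

    Repeat class is taken from the interval name; overlapping annotations are
    resolved in favour of the first listed.
    """
    class_index = {c: i for i, c in enumerate(REPEAT_CLASSES)}
    per_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in sizes}
    for r in repeats:
        if r.chrom not in per_chrom:
            raise KeyError(f"repeat on unknown chromosome {r.chrom!r}")
        per_chrom[r.chrom].append((r.start, r.end, class_index[_normalize_repeat_class(r.name)]))
    totals = np.zeros(len(REPEAT_CLASSES), dtype=np.int64)
    uncovered = 0
    for chrom, length in sizes.items():
        cov = _class_coverage(length, per_chrom[chrom])
        counts = np.bincount(cov[cov >= 0], minlength=len(REPEAT_CLASSES))
        totals += counts
        uncovered += int((cov == -1).sum())
    genome = sizes.total
    fractions = {c: totals[i] / genome for i, c in enumerate(REPEAT_CLASSES)}
    fractions["non_repetitive"] = uncovered / genome
    return fractions


def repeat_composition(
    peaks: Sequence[Peak],
    repeats: Sequence[Interval],
    genome_fractions: Mapping[str, float],
) -> tuple[dict[str, float], list[EnrichmentResult]]:
    """bp-overlap composition of peak sequence over repeat classes.

    Returns per-class fractions of total peak bp (summing to 1 with the
    ``non_repetitive`` remainder) and enrichment of each class against its
    genome abundance.
    """
    class_index = {c: i for i, c in enumerate(REPEAT_CLASSES)}
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(
            (r.start, r.end, class_index[_normalize_repeat_class(r.name)])
        )
    bp = np.zeros(len(REPEAT_CLASSES), dtype=np.int64)
    total = 0
    for p in peaks:
        total += len(p)
        cand = [
            (max(s, p.start) - p.start, min(e, p.end) - p.start, ci)
            for s, e, ci in by_chrom.get(p.chrom, [])
            if s < p.end and e > p.start
        ]
        if not cand:
            continue
        cov = _class_coverage(len(p), cand)
        bp += np.bincount(cov[cov >= 0], minlength=len(REPEAT_CLASSES))
    if total == 0:
        raise ValueError("no peak bp to compose")
    fractions = {c: bp[i] / total for i, c in enumerate(REPEAT_CLASSES)}
    fractions["non_repetitive"] = 1.0 - bp.sum() / total
    results = []
    for c in (*REPEAT_CLASSES, "non_repetitive"):
        k = int(round(fractions[c] * total))
        results.append(_binom_enrichment(k, total, genome_fractions.get(c, 0.0), c))
    return fractions, results


def build_density_table(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    sizes: ChromSizes,
    gc_percent: Mapping[str, float] | None = None,
    repeat_percent: Mapping[str, float] | None = None,
    fasta: str | None = None,
    repeats: Sequence[Interval] | None = None,
    window: int = 100_000,
) -> pd.DataFrame:
    """One row per chromosome: peak density, gene density (per ``window`` bp),
    GC% and repeat%.

    GC% may be supplied directly or computed from a genome FASTA; repeat% may
    be supplied or computed from a repeat interval list.
    """
    if gc_percent is None:
        if fasta is None:
            raise ValueError("need gc_percent mapping or a genome FASTA")
        from pyfaidx import Fasta

        fa = Fasta(fasta)
        gc_percent = {}
        for chrom in sizes:
            if chrom not in fa:
                raise KeyError(f"chromosome {chrom!r} missing from FASTA")
            seq = str(fa[chrom][:]).upper()
            acgt = sum(seq.count(b) for b in "ACGT")
            gc_percent[chrom] = 100.0 * sum(seq.count(b) for b in "GC") / acgt if acgt else 0.0
    if repeat_percent is None:
        if repeats is None:
            raise ValueError("need repeat_percent mapping or a repeat interval list")
        repeat_percent = {}
        for chrom, length in sizes.items():
            cov = np.zeros(length, dtype=bool)
            for r in repeats:
                if r.chrom == chrom:
                    cov[max(0, r.start):min(length, r.end)] = True
            repeat_percent[chrom] = 100.0 * cov.sum() / length
    missing = [c for c in sizes if c not in gc_percent or c not in repeat_percent]
    if missing:
        raise KeyError(f"missing covariates for chromosomes: {missing}")
    peak_counts = {c: 0 for c in sizes}
    for p in peaks:
        peak_counts[p.chrom] += 1
    gene_counts = {c: 0 for c in sizes}
    for g in genes:
        gene_counts[g.chrom] += 1
    rows = {
        chrom: {
            "peak_density": peak_counts[chrom] / length * window,
            "gene_density": gene_counts[chrom] / length * window,
            "gc_percent": float(gc_percent[chrom]),
            "repeat_percent": float(repeat_percent[chrom]),
        }
        for chrom, length in sizes.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def regress_peak_density(
    table: pd.DataFrame,
    response: str = "peak_density",
    covariates: Sequence[str] = ("gene_density", "gc_percent", "repeat_percent"),
) -> RegressionResult:
    """OLS of peak density on chromosome covariates.

    Reports the simple-regression R-squared of each covariate alone plus a
    multiple regression with per-coefficient t-test p-values. Collinear
    designs are flagged and affected p-values reported as NaN.
    """
    covariates = list(covariates)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for simple regression")
    if len(table) < len(covariates) + 2:
        raise ValueError("too few rows for multiple regression")
    y = table[response].to_numpy(dtype=float)
    simple_r2 = {}
    for cov in covariates:
        x = sm.add_constant(table[cov].to_numpy(dtype=float))
        simple_r2[cov] = float(sm.OLS(y, x).fit().rsquared)
    X = sm.add_constant(table[covariates].to_numpy(dtype=float))
    collinear = np.linalg.matrix_rank(X) < X.shape[1]
    fit = sm.OLS(y, X).fit()
    names = ["const", *covariates]
    coefs = dict(zip(names, map(float, fit.params)))
    ses = dict(zip(names, map(float, fit.bse)))
    pvals = dict(zip(names, map(float, fit.pvalues)))
    if collinear:
        pvals = {k: math.nan for k in pvals}
    return RegressionResult(
        response=response, covariates=covariates, coefficients=coefs,
        std_errors=ses, p_values=pvals, simple_r2=simple_r2,
        multiple_r2=float(fit.rsquared), collinear=collinear,
    )


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _covered_bp(ivs: dict[str, list[tuple[int, int]]]) -> int:
    return sum(e - s for chrom in ivs for s, e in _merge(ivs[chrom]))


def overlap_fraction(
    peaks: Sequence[Peak], regions: Sequence[Interval]
) -> tuple[float, float]:
    """Fraction of peaks overlapping (>= 1 bp) any region, plus bp Jaccard.

    Jaccard is intersection bp over union bp of the two merged interval sets.
    """
    reg_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        reg_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    reg_merged = {c: _merge(v) for c, v in reg_by_chrom.items()}
    n_hit = 0
    for p in peaks:
        for s, e in reg_merged.get(p.chrom, []):
            if s < p.end and e > p.start:
                n_hit += 1
                break
    fraction = n_hit / len(peaks) if peaks else 0.0
    peaks_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    peaks_merged = {c: _merge(v) for c, v in peaks_by_chrom.items()}
    inter = 0
    for chrom in set(peaks_merged) & set(reg_merged):
        a, b = peaks_merged[chrom], reg_merged[chrom]
        i = j = 0
        while i < len(a) and j < len(b):
            s = max(a[i][0], b[j][0])
            e = min(a[i][1], b[j][1])
            if s < e:
                inter += e - s
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
    union = _covered_bp(peaks_merged) + _covered_bp(reg_merged) - inter
    jaccard = inter / union if union else 0.0
    return fraction, jaccard
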