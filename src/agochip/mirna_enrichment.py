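"""miRNA seed-match target-site prediction in peak sequences, matched-control
sampling, per-miRNA enrichment calls, and consensus-motif analysis.

Target prediction is seed complementarity: the DNA match motif is the reverse
complement of the miRNA seed (default 7mer-m8, miRNA positions 2-8), scanned
on both strands with overlapping occurrences all counted. Enrichment per
miRNA compares total site counts in peak sequences against length-matched
random control sequences via a two-sided exact binomial test on the
allocation of sites between the two equal-length sets, with
Benjamini-Hochberg correction across miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome_core import ChromSizes, Interval
from .peak_processing import Peak

__all__ = [
    "SEED_RULES",
    "MiRNA",
    "SiteHits",
    "MiRNAEnrichment",
    "MotifResult",
    "read_mirna_fasta",
    "seed_match_motif",
    "sample_matched_controls",
    "extract_sequences",
    "predict_target_sites",
    "mirna_enrichment_table",
    "discover_motif",
    "motif_homology",
]

#: Seed rules as (first, last) 1-based miRNA positions plus whether an 'A'
#: anchor is appended at the target 3' end (8mer rule).
SEED_RULES = {
    "6mer": (2, 7, False),
    "7mer-m8": (2, 8, False),
    "8mer": (2, 8, True),
}

_RNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "U": "A"}
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_IUPAC_PAIR = {
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AU"): "W",
    frozenset("CG"): "S", frozenset("CU"): "Y", frozenset("GU"): "K",
}
_IUPAC_EXPAND = {v: sorted(k) for k, v in _IUPAC_PAIR.items()}


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA sequence (RNA alphabet, 5'->3') with its seed rule."""

    mirna_id: str
    sequence: str
    seed_rule: str = "7mer-m8"

    def __post_init__(self) -> None:
        if len(self.sequence) < 8:
            raise ValueError(f"{self.mirna_id}: miRNA shorter than 8 nt")
        if set(self.sequence) - set("ACGU"):
            raise ValueError(f"{self.mirna_id}: sequence must use the RNA alphabet ACGU")
        if self.seed_rule not in SEED_RULES:
            raise ValueError(f"{self.mirna_id}: unknown seed rule {self.seed_rule!r}")

    @property
    def seed(self) -> str:
        first, last, _ = SEED_RULES[self.seed_rule]
        return self.sequence[first - 1:last]


@dataclass
class SiteHits:
    """Seed-match occurrences of one miRNA in one DNA sequence."""

    count: int
    forward_positions: list[int]
    reverse_positions: list[int]


@dataclass
class MiRNAEnrichment:
    """Per-miRNA target-site counts in peaks vs matched controls."""

    mirna_id: str
    sites_peaks: int
    sites_controls: int
    ratio: float  # inf sentinel when sites_controls == 0 and sites_peaks > 0
    p_value: float
    adjusted_p: float
    call: str  # enriched | depleted | neutral


@dataclass
class MotifResult:
    """The most widely shared (possibly single-position-degenerate) k-mer."""

    consensus: str
    n_mirnas_containing: int
    n_mirnas_with_two: int
    total_occurrences: int


def read_mirna_fasta(path: str | Path, seed_rule: str = "7mer-m8") -> list[MiRNA]:
    """Read miRNA sequences from FASTA; T is auto-converted to U with a warning."""
    from Bio import SeqIO

    mirnas = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "T" in seq:
            warnings.warn(f"{rec.id}: DNA alphabet in miRNA FASTA; converting T -> U")
            seq = seq.replace("T", "U")
        mirnas.append(MiRNA(rec.id, seq, seed_rule))
    return mirnas


def seed_match_motif(mirna: MiRNA) -> str:
    """DNA motif (5'->3') whose occurrence constitutes a predicted target site:
    the reverse complement of the miRNA seed, plus a 3' 'A' anchor for 8mer."""
    _, _, anchor = SEED_RULES[mirna.seed_rule]
    rc = "".join(_RNA_COMPLEMENT[b] for b in reversed(mirna.seed))
    return rc + ("A" if anchor else "")


def _revcomp_dna(seq: str) -> str:
    return "".join(_DNA_COMPLEMENT[b] for b in reversed(seq))


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence start positions."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def predict_target_sites(dna_sequence: str, mirna: MiRNA) -> SiteHits:
    """Count seed-match sites on both strands of a DNA sequence.

    'N' bases never match; overlapping occurrences are all counted. Reverse
    positions index into the given (forward) sequence coordinate system.
    """
    seq = dna_sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence must use the DNA alphabet ACGTN")
    motif = seed_match_motif(mirna)
    fwd = _find_all(seq, motif)
    rev_motif = _revcomp_dna(motif)
    rev = _find_all(seq, rev_motif)
    return SiteHits(count=len(fwd) + len(rev), forward_positions=fwd, reverse_positions=rev)


def count_sites(sequences: Sequence[str], mirna: MiRNA) -> int:
    """Total seed-match sites of one miRNA across a set of DNA sequences."""
    return sum(predict_target_sites(s, mirna).count for s in sequences)


def sample_matched_controls(
    peaks: Sequence[Peak],
    sizes: ChromSizes,
    seed: int,
    excluded: Sequence[Interval] | None = None,
    gc_match: float | None = None,
    genome: Mapping[str, str] | None = None,
    max_attempts: int = 1000,
) -> list[Interval]:
    """Draw one random control interval per peak: same chromosome, identical
    length, uniform position, avoiding all excluded intervals (default: the
    peaks themselves). Fully determined by ``seed``.

    With ``gc_match`` set, controls are additionally rejection-sampled until
    their GC fraction is within the tolerance of the peak's (requires
    ``genome``, a chrom -> sequence mapping).
    """
    if gc_match is not None and genome is None:
        raise ValueError("gc_match requires genome sequences")
    if excluded is None:
        excluded = [p.interval for p in peaks]
    excl_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in excluded:
        excl_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for v in excl_by_chrom.values():
        v.sort()

    def _gc(seq: str) -> float:
        seq = seq.upper()
        n = len(seq)
        return (seq.count("G") + seq.count("C")) / n if n else 0.0

    rng = np.random.default_rng(seed)
    controls = []
    for p in peaks:
        length = len(p)
        chrom_len = sizes[p.chrom]
        if chrom_len < length:
            raise ValueError(f"chromosome {p.chrom} shorter than peak {p.interval.name}")
        target_gc = _gc(genome[p.chrom][p.start:p.end]) if gc_match is not None else None
        placed = None
        for _ in range(max_attempts):
            start = int(rng.integers(0, chrom_len - length + 1))
            end = start + length
            if any(s < end and e > start for s, e in excl_by_chrom.get(p.chrom, [])):
                continue
            if target_gc is not None:
                if abs(_gc(genome[p.chrom][start:end]) - target_gc) > gc_match:
                    continue
            placed = Interval(p.chrom, start, end, name=f"ctrl_{p.interval.name}")
            break
        if placed is None:
            raise RuntimeError(
                f"failed to place a matched control for peak {p.interval.name} "
                f"after {max_attempts} attempts"
            )
        controls.append(placed)
    return controls


def extract_sequences(
    intervals: Sequence[Interval | Peak], genome: Mapping[str, str]
) -> list[str]:
    """Pull DNA sequences for intervals from a chrom -> sequence mapping
    (a dict, or a pyfaidx.Fasta opened over the genome FASTA)."""
    out = []
    for iv in intervals:
        chrom, start, end = iv.chrom, iv.start, iv.end
        out.append(str(genome[chrom][start:end]).upper())
    return out


def mirna_enrichment_table(
    peak_seqs: Sequence[str],
    control_seqs: Sequence[str],
    mirnas: Sequence[MiRNA],
    fold_cutoff: float = 1.5,
    alpha: float = 0.05,
) -> list[MiRNAEnrichment]:
    """Per-miRNA enrichment of predicted sites in peaks vs matched controls.

    Under the null that sites fall equally into the two length-matched sets,
    the peak-set count is Binomial(total, 1/2); a two-sided exact test is
    applied per miRNA and Benjamini-Hochberg across miRNAs. A miRNA is called
    enriched when ratio >= fold_cutoff and adjusted p < alpha (depleted
    symmetrically at ratio <= 1/fold_cutoff).
    """
    if fold_cutoff <= 1:
        raise ValueError("fold_cutoff must exceed 1")
    raw = []
    for m in mirnas:
        sp = count_sites(peak_seqs, m)
        sc = count_sites(control_seqs, m)
        total = sp + sc
        p = stats.binomtest(sp, total, 0.5, alternative="two-sided").pvalue if total else 1.0
        raw.append((m.mirna_id, sp, sc, float(p)))
    adj = multipletests([r[3] for r in raw], method="fdr_bh")[1] if raw else []
    results = []
    for (mid, sp, sc, p), ap in zip(raw, adj):
        if sc == 0:
            ratio = float("inf") if sp > 0 else float("nan")
        else:
            ratio = sp / sc
        call = "neutral"
        if ap < alpha:
            if ratio >= fold_cutoff:
                call = "enriched"
            elif ratio <= 1.0 / fold_cutoff:
                call = "depleted"
        results.append(MiRNAEnrichment(mid, sp, sc, ratio, p, float(ap), call))
    return results


def _expand_consensus(consensus: str) -> list[str]:
    """Concrete k-mers matching a (single-position) IUPAC consensus."""
    kmers = [""]
    for ch in consensus:
        options = _IUPAC_EXPAND.get(ch, [ch])
        kmers = [k + o for k in kmers for o in options]
    return kmers


def discover_motif(
    mirna_sequences: Sequence[str], k: int = 6, max_degenerate_positions: int = 1
) -> MotifResult:
    """Find the k-mer consensus shared by the most sequences.

    All exact k-mers are candidates, plus every merge of two observed k-mers
    differing at exactly one position (IUPAC two-letter code at that
    position), when ``max_degenerate_positions`` >= 1. The winner maximizes
    the number of sequences containing it, then total occurrences, then is
    lexicographically smallest. Occurrence counts include overlaps.
    """
    if not mirna_sequences:
        raise ValueError("no sequences supplied")
    if k < 4:
        raise ValueError("k must be >= 4")
    seqs = [s.upper() for s in mirna_sequences]
    for s in seqs:
        if set(s) - set("ACGU"):
            raise ValueError("motif discovery expects RNA-alphabet sequences")
    # per-sequence k-mer occurrence counts
    per_seq: list[dict[str, int]] = []
    for s in seqs:
        counts: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        per_seq.append(counts)
    all_kmers = sorted(set().union(*per_seq)) if per_seq else []
    candidates: set[str] = set(all_kmers)
    if max_degenerate_positions >= 1:
        # bucket k-mers by each single-position wildcard mask; pairs within a
        # bucket differ at exactly that position
        for pos in range(k):
            buckets: dict[str, list[str]] = {}
            for kmer in all_kmers:
                buckets.setdefault(kmer[:pos] + "." + kmer[pos + 1:], []).append(kmer)
            for group in buckets.values():
                for i in range(len(group)):
                    for j in range(i + 1, len(group)):
                        a, b = group[i][pos], group[j][pos]
                        code = _IUPAC_PAIR.get(frozenset((a, b)))
                        if code:
                            candidates.add(group[i][:pos] + code + group[i][pos + 1:])
    best = None
    for cand in sorted(candidates):
        concrete = _expand_consensus(cand)
        occ = [sum(c.get(kmer, 0) for kmer in concrete) for c in per_seq]
        n_containing = sum(1 for o in occ if o > 0)
        n_two = sum(1 for o in occ if o >= 2)
        total = sum(occ)
        key = (-n_containing, -total, cand)
        if best is None or key < best[0]:
            best = (key, MotifResult(cand, n_containing, n_two, total))
    return best[1]


def motif_homology(variants: Sequence[str], reference: str) -> float:
    """Maximum ungapped percent identity of any variant against the reference."""
    if not variants:
        raise ValueError("no variants supplied")
    best = 0.0
    for v in variants:
        if len(v) != len(reference):
            raise ValueError("variant and reference lengths differ")
        matches = sum(1 for a, b in zip(v, reference) if a == b)
        best = max(best, 100.0 * matches / len(reference))
    return best
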