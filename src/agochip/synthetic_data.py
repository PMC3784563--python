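"""Seeded generator for a complete toy ChIP-seq + expression dataset.

The generator emits every input the pipeline consumes — a multi-chromosome
genome FASTA, BED12 gene models with UTR/exon structure, scored peaks with
caller FDRs, H3K4me3 marks at active TSSs, repeat and HOT-region intervals,
a knockdown expression table, miRNA sequences, and a ChIP-qPCR-style
validation table — together with a ground-truth record, so every downstream
stage is testable without external data.

Statistical structure baked in:

* a configurable fraction of genes is "active"; TSS-proximal peaks are placed
  around active TSSs with Normal(mean, sd) offsets, the rest uniformly;
* H3K4me3 intervals co-occur with active TSSs at a configurable probability;
* genes whose TSS-proximal peak covers TSS + ``effect_center_offset`` receive
  a downregulation shift ``binding_effect_log2fc`` on top of Normal baseline
  noise, so promoter-bound genes are enriched among downregulated genes at
  that offset;
* miRNA seed-match sites are implanted into peak sequences at a configurable
  per-sequence rate, creating the signal the target-site enrichment detects.

Every output is fully determined by the master seed; each file type draws
from its own pseudo-random stream derived from that seed, so adding an output
never perturbs the others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_core import (
    ChromSizes, GeneModel, Interval, write_bed_intervals, write_gene_models,
)
from .mirna_enrichment import MiRNA, seed_match_motif
from .peak_processing import Peak, ValidationBin, write_peaks

__all__ = ["SimulationConfig", "SyntheticTruth", "SyntheticDataset",
           "simulate_dataset", "implant_seed_sites"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# stable sub-stream ids (one per output) derived from the master seed
_STREAMS = {
    "genome": 0, "genes": 1, "peaks": 2, "k4": 3, "repeats": 4,
    "hot": 5, "expression": 6, "mirnas": 7, "implant": 8,
}

_REPEAT_WEIGHTS = {
    "SINE": 0.40, "LINE": 0.30, "LTR": 0.15,
    "low_complexity": 0.08, "simple_repeat": 0.05, "other": 0.02,
}


@dataclass
class SimulationConfig:
    """All knobs of the generator. The defaults are the study conditions the
    rest of the package is exercised under; see docs/methods.md."""

    seed: int
    n_chromosomes: int = 6
    chromosome_length: int = 500_000
    chromosome_lengths: tuple[int, ...] | None = None
    n_genes: int = 150
    # relative gene density per chromosome (gene-dense vs gene-poor
    # chromosomes, so peak density co-varies with gene density); None = even
    gene_density_weights: tuple[float, ...] | None = None
    gene_length_range: tuple[int, int] = (2000, 4000)
    fraction_active: float = 0.5
    n_tss_peaks: int = 60
    n_background_peaks: int = 60
    max_peaks_per_gene: int = 1
    tss_offset_mean: float = 0.0
    tss_offset_sd: float = 400.0
    peak_length: int = 1000
    k4_length: int = 1500
    k4_coplacement_prob: float = 0.9
    background_pass_fraction: float = 0.5  # background peaks with sub-cutoff FDR
    repeat_fraction: float = 0.15
    n_hot_regions: int = 10
    hot_length: int = 5000
    baseline_log2fc_sd: float = 0.25
    binding_effect_log2fc: float = -0.6   # delta < 0: knockdown downregulation
    effect_center_offset: int = 100
    n_mirnas: int = 30
    mirna_length: int = 22
    implant_rate: float = 0.9
    n_target_mirnas: int = 5  # implants drawn from the first n miRNAs only
    seed_rule: str = "7mer-m8"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.chromosome_lengths is None:
            self.chromosome_lengths = (self.chromosome_length,) * self.n_chromosomes
        self.chromosome_lengths = tuple(int(x) for x in self.chromosome_lengths)
        if len(self.chromosome_lengths) != self.n_chromosomes:
            raise ValueError("chromosome_lengths must match n_chromosomes")
        if self.gene_density_weights is None:
            self.gene_density_weights = tuple(
                float(x) for x in np.linspace(0.5, 2.0, self.n_chromosomes))
        self.gene_density_weights = tuple(float(x) for x in self.gene_density_weights)
        if len(self.gene_density_weights) != self.n_chromosomes:
            raise ValueError("gene_density_weights must match n_chromosomes")
        if any(w < 0 for w in self.gene_density_weights) or \
                sum(self.gene_density_weights) == 0:
            raise ValueError("gene_density_weights must be non-negative, not all zero")
        if any(x <= 0 for x in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")
        for name in ("fraction_active", "k4_coplacement_prob",
                     "background_pass_fraction", "repeat_fraction", "implant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.binding_effect_log2fc >= 0:
            raise ValueError("binding_effect_log2fc models knockdown downregulation; must be < 0")
        if not 0 <= self.n_target_mirnas <= self.n_mirnas:
            raise ValueError("n_target_mirnas must be in [0, n_mirnas]")
        n_active = int(round(self.fraction_active * self.n_genes))
        if n_active > 0 and self.n_tss_peaks > n_active * self.max_peaks_per_gene:
            raise ValueError(
                f"n_tss_peaks={self.n_tss_peaks} exceeds active genes ({n_active}) "
                f"x max_peaks_per_gene ({self.max_peaks_per_gene})"
            )

    @property
    def sizes(self) -> ChromSizes:
        s = ChromSizes()
        for i, length in enumerate(self.chromosome_lengths, 1):
            s[f"chr{i}"] = length
        return s


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    genes: dict[str, dict]          # gene_id -> {active, bound, responsive_direction}
    peaks: dict[str, dict]          # peak name -> {origin, gene_id, offset}
    mirna_implants: dict[str, int]  # mirna_id -> implanted site count in peaks
    n_implant_skipped: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    """In-memory simulated bundle; ``write`` persists it as plain-text files."""

    config: SimulationConfig
    sizes: ChromSizes
    genome: dict[str, str]
    genes: list[GeneModel]
    peaks: list[Peak]
    k4_peaks: list[Peak]
    repeats: list[Interval]
    hot_regions: list[Interval]
    expression: "object"  # pandas.DataFrame: gene_id, fold_change, p_value
    mirnas: list[MiRNA]
    validation_bins: list[ValidationBin]
    truth: SyntheticTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        fa = out / "genome.fa"
        with open(fa, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        paths["genome"] = fa
        sizes_path = out / "chrom.sizes"
        with open(sizes_path, "w") as fh:
            for chrom, length in self.sizes.items():
                fh.write(f"{chrom}\t{length}\n")
        paths["sizes"] = sizes_path
        write_gene_models(self.genes, out / "genes.bed")
        paths["genes"] = out / "genes.bed"
        write_peaks(self.peaks, out / "peaks.bed")
        paths["peaks"] = out / "peaks.bed"
        write_peaks(self.k4_peaks, out / "h3k4me3.bed")
        paths["k4"] = out / "h3k4me3.bed"
        write_bed_intervals(self.repeats, out / "repeats.bed")
        paths["repeats"] = out / "repeats.bed"
        write_bed_intervals(self.hot_regions, out / "hot_regions.bed")
        paths["hot"] = out / "hot_regions.bed"
        expr_path = out / "expression.tsv"
        self.expression.to_csv(expr_path, sep="\t", index=False, float_format="%.6g")
        paths["expression"] = expr_path
        mirna_path = out / "mirnas.fa"
        with open(mirna_path, "w") as fh:
            for m in self.mirnas:
                fh.write(f">{m.mirna_id}\n{m.sequence}\n")
        paths["mirnas"] = mirna_path
        val_path = out / "validation.tsv"
        with open(val_path, "w") as fh:
            fh.write("fdr_lo\tfdr_hi\tn_tested\tn_validated\n")
            for b in self.validation_bins:
                fh.write(f"{b.fdr_lo:g}\t{b.fdr_hi:g}\t{b.n_tested}\t{b.n_validated}\n")
        paths["validation"] = val_path
        truth_path = out / "truth.json"
        truth_path.write_text(self.truth.to_json())
        paths["truth"] = truth_path
        return paths


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STREAMS[stream]])


def _make_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    sizes = config.sizes
    chroms = list(sizes)
    # apportion genes by density weight (largest remainder)
    w = np.array(config.gene_density_weights, dtype=float)
    ideal = config.n_genes * w / w.sum()
    per_chrom = np.floor(ideal).astype(int)
    remainder = config.n_genes - per_chrom.sum()
    for i in np.argsort(ideal - per_chrom)[::-1][:remainder]:
        per_chrom[i] += 1
    per_chrom = per_chrom.tolist()
    genes = []
    gid = 0
    lo, hi = config.gene_length_range
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        slot = sizes[chrom] // n_here
        if slot < hi + 1000:
            raise ValueError(
                f"{chrom}: too many genes for chromosome length (slot {slot} bp "
                f"cannot hold a {hi} bp gene with margins)"
            )
        for j in range(n_here):
            gene_len = int(rng.integers(lo, hi + 1))
            margin = slot - gene_len
            start = j * slot + int(rng.integers(margin // 4, margin - margin // 4))
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(2, 6))
            min_needed = n_exons * 150 + (n_exons - 1) * 100
            extra = gene_len - min_needed
            shares = rng.multinomial(extra, np.full(2 * n_exons - 1, 1.0 / (2 * n_exons - 1)))
            exons, pos = [], start
            for seg in range(2 * n_exons - 1):
                if seg % 2 == 0:  # exon
                    size = 150 + int(shares[seg])
                    exons.append((pos, pos + size))
                    pos += size
                else:             # intron
                    pos += 100 + int(shares[seg])
            gid += 1
            first_s, first_e = exons[0]
            last_s, last_e = exons[-1]
            cds_start = first_s + int(0.3 * (first_e - first_s))
            cds_end = last_e - int(0.3 * (last_e - last_s))
            genes.append(GeneModel(
                gene_id=f"g{gid:04d}", chrom=chrom, strand=strand,
                tx_start=start, tx_end=pos, exons=exons,
                cds_start=cds_start, cds_end=cds_end,
            ))
    return genes


def _place_peak(center: int, length: int, chrom_len: int) -> tuple[int, int]:
    start = center - length // 2
    start = min(max(start, 0), chrom_len - length)
    return start, start + length


def _overlaps_any(chrom: str, start: int, end: int,
                  existing: dict[str, list[tuple[int, int]]]) -> bool:
    return any(s < end and e > start for s, e in existing.get(chrom, []))


def implant_seed_sites(
    sequences: Sequence[str],
    mirnas: Sequence[MiRNA],
    implant_rate: float,
    seed: int,
) -> tuple[list[str], dict[str, int], int]:
    """Write miRNA seed-match sites into a fraction of DNA sequences.

    Each sequence is independently selected with probability ``implant_rate``;
    a uniformly chosen miRNA's DNA match motif (reverse complement of its
    seed) is written at a uniform position. Sequences shorter than the motif
    are skipped (counted). Returns the modified sequences, exact per-miRNA
    implant counts, and the number of skipped sequences.
    """
    if not 0.0 <= implant_rate <= 1.0:
        raise ValueError("implant_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    counts = {m.mirna_id: 0 for m in mirnas}
    out, skipped = [], 0
    for seq in sequences:
        if not mirnas or rng.random() >= implant_rate:
            out.append(seq)
            continue
        m = mirnas[int(rng.integers(0, len(mirnas)))]
        motif = seed_match_motif(m)
        if len(seq) < len(motif):
            skipped += 1
            warnings.warn("sequence shorter than implant site; skipped")
            out.append(seq)
            continue
        pos = int(rng.integers(0, len(seq) - len(motif) + 1))
        out.append(seq[:pos] + motif + seq[pos + len(motif):])
        counts[m.mirna_id] += 1
    return out, counts, skipped


def simulate_dataset(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate the full synthetic bundle; optionally write it to ``out_dir``.

    With ``fraction_active`` = 0 no TSS-proximal peaks are emitted regardless
    of ``n_tss_peaks``; otherwise requesting more TSS-proximal peaks than
    active genes x ``max_peaks_per_gene`` is a configuration error (raised at
    construction).
    """
    import pandas as pd
    from scipy import stats as sps

    sizes = config.sizes
    chrom_names = list(sizes)

    # --- genome ---
    g_rng = _rng(config, "genome")
    genome_codes = {
        chrom: g_rng.integers(0, 4, size=sizes[chrom]).astype(np.uint8)
        for chrom in chrom_names
    }

    # --- genes & activity ---
    genes = _make_genes(config, _rng(config, "genes"))
    gene_by_id = {g.gene_id: g for g in genes}
    p_rng = _rng(config, "peaks")
    n_active = int(round(config.fraction_active * len(genes)))
    active_ids = sorted(
        p_rng.choice([g.gene_id for g in genes], size=n_active, replace=False)
    ) if n_active else []
    active_set = set(active_ids)

    # --- peaks ---
    peaks: list[Peak] = []
    truth_peaks: dict[str, dict] = {}
    occupied: dict[str, list[tuple[int, int]]] = {}
    bound_genes: set[str] = set()
    effect_genes: set[str] = set()
    n_tss = config.n_tss_peaks if n_active else 0
    if n_tss:
        pool = [gid for gid in active_ids for _ in range(config.max_peaks_per_gene)]
        chosen = p_rng.choice(pool, size=n_tss, replace=False)
    else:
        chosen = []
    idx = 0
    for gid in chosen:
        g = gene_by_id[gid]
        offset = int(round(p_rng.normal(config.tss_offset_mean, config.tss_offset_sd)))
        center = g.tss + offset if g.strand == "+" else g.tss - offset
        start, end = _place_peak(center, config.peak_length, sizes[g.chrom])
        idx += 1
        name = f"peak_{idx:05d}"
        fdr = float(p_rng.uniform(0.0, 0.05))
        peaks.append(Peak(Interval(g.chrom, start, end, name=name),
                          score=float(p_rng.uniform(10, 100)), fdr=fdr))
        occupied.setdefault(g.chrom, []).append((start, end))
        # gene-oriented offsets covered by this peak
        if g.strand == "+":
            cov_lo, cov_hi = start - g.tss, end - g.tss
        else:
            cov_lo, cov_hi = g.tss - end + 1, g.tss - start + 1
        actual_offset = (start + end) // 2 - g.tss if g.strand == "+" \
            else g.tss - (start + end) // 2
        truth_peaks[name] = {"origin": "tss", "gene_id": gid, "offset": actual_offset}
        bound_genes.add(gid)
        if cov_lo <= config.effect_center_offset < cov_hi:
            effect_genes.add(gid)
    for _ in range(config.n_background_peaks):
        idx += 1
        name = f"peak_{idx:05d}"
        for _attempt in range(1000):
            chrom = chrom_names[int(p_rng.integers(0, len(chrom_names)))]
            start = int(p_rng.integers(0, sizes[chrom] - config.peak_length + 1))
            end = start + config.peak_length
            if not _overlaps_any(chrom, start, end, occupied):
                break
        else:
            raise RuntimeError("could not place a background peak without overlap")
        if p_rng.random() < config.background_pass_fraction:
            fdr = float(p_rng.uniform(0.0, 0.05))
        else:
            fdr = float(p_rng.uniform(0.06, 0.9))
        peaks.append(Peak(Interval(chrom, start, end, name=name),
                          score=float(p_rng.uniform(5, 60)), fdr=fdr))
        occupied.setdefault(chrom, []).append((start, end))
        truth_peaks[name] = {"origin": "background", "gene_id": None, "offset": None}

    # --- H3K4me3 marks at active TSSs ---
    k4_rng = _rng(config, "k4")
    k4_peaks = []
    for i, gid in enumerate(active_ids, 1):
        if k4_rng.random() >= config.k4_coplacement_prob:
            continue
        g = gene_by_id[gid]
        start, end = _place_peak(g.tss, config.k4_length, sizes[g.chrom])
        k4_peaks.append(Peak(Interval(g.chrom, start, end, name=f"k4_{i:05d}"),
                             score=float(k4_rng.uniform(10, 100)),
                             fdr=float(k4_rng.uniform(0.0, 0.05))))

    # --- repeats ---
    r_rng = _rng(config, "repeats")
    classes = list(_REPEAT_WEIGHTS)
    weights = np.array(list(_REPEAT_WEIGHTS.values()))
    weights = weights / weights.sum()
    repeats: list[Interval] = []
    rid = 0
    for chrom in chrom_names:
        target = int(config.repeat_fraction * sizes[chrom])
        covered = 0
        placed: list[tuple[int, int]] = []
        attempts = 0
        while covered < target and attempts < 20000:
            attempts += 1
            length = int(r_rng.integers(150, 1501))
            start = int(r_rng.integers(0, sizes[chrom] - length + 1))
            end = start + length
            if any(s < end and e > start for s, e in placed):
                continue
            cls = classes[int(r_rng.choice(len(classes), p=weights))]
            rid += 1
            repeats.append(Interval(chrom, start, end, name=cls))
            placed.append((start, end))
            covered += length

    # --- HOT regions ---
    h_rng = _rng(config, "hot")
    hot = []
    for i in range(config.n_hot_regions):
        chrom = chrom_names[int(h_rng.integers(0, len(chrom_names)))]
        start = int(h_rng.integers(0, sizes[chrom] - config.hot_length + 1))
        hot.append(Interval(chrom, start, start + config.hot_length, name=f"hot_{i + 1:03d}"))

    # --- expression table ---
    e_rng = _rng(config, "expression")
    sd0 = config.baseline_log2fc_sd
    rows = []
    truth_genes = {}
    for g in genes:
        log2fc = float(e_rng.normal(0.0, sd0))
        shifted = g.gene_id in effect_genes
        if shifted:
            log2fc += config.binding_effect_log2fc
        p = float(2.0 * sps.norm.sf(abs(log2fc) / sd0))
        rows.append({"gene_id": g.gene_id, "fold_change": 2.0 ** log2fc,
                     "p_value": min(p, 1.0)})
        truth_genes[g.gene_id] = {
            "active": g.gene_id in active_set,
            "bound": g.gene_id in bound_genes,
            "responsive_direction": "down" if shifted else None,
        }
    expression = pd.DataFrame(rows)

    # --- miRNAs and site implantation into peak sequences ---
    m_rng = _rng(config, "mirnas")
    mirnas = [
        MiRNA(f"mir{i + 1:03d}",
              "".join("ACGU"[b] for b in m_rng.integers(0, 4, config.mirna_length)),
              config.seed_rule)
        for i in range(config.n_mirnas)
    ]
    peak_seqs = [
        genome_codes[p.chrom][p.start:p.end].tobytes().translate(
            bytes.maketrans(bytes(range(4)), b"ACGT")).decode()
        for p in peaks
    ]
    implant_seed_val = int(np.random.default_rng(
        [int(config.seed), _STREAMS["implant"]]).integers(0, 2**31))
    targets = mirnas[: config.n_target_mirnas]
    new_seqs, target_counts, skipped = implant_seed_sites(
        peak_seqs, targets, config.implant_rate, implant_seed_val)
    implant_counts = {m.mirna_id: target_counts.get(m.mirna_id, 0) for m in mirnas}
    decode_table = np.zeros(256, dtype=np.uint8)
    for code, base in enumerate(b"ACGT"):
        decode_table[base] = code
    for p, seq in zip(peaks, new_seqs):
        ascii_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        genome_codes[p.chrom][p.start:p.end] = decode_table[ascii_codes]
    genome = {
        chrom: codes.tobytes().translate(
            bytes.maketrans(bytes(range(4)), b"ACGT")).decode()
        for chrom, codes in genome_codes.items()
    }

    validation_bins = [
        ValidationBin(0.0, 0.05, 20, 19),
        ValidationBin(0.05, 0.2, 12, 7),
        ValidationBin(0.2, 1.0, 12, 2),
    ]

    truth = SyntheticTruth(
        genes=truth_genes, peaks=truth_peaks,
        mirna_implants=implant_counts, n_implant_skipped=skipped,
    )
    ds = SyntheticDataset(
        config=config, sizes=sizes, genome=genome, genes=genes, peaks=peaks,
        k4_peaks=k4_peaks, repeats=repeats, hot_regions=hot,
        expression=expression, mirnas=mirnas, validation_bins=validation_bins,
        truth=truth,
    )
    if out_dir is not None:
        ds.write(out_dir)
    return ds
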