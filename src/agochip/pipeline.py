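"""Pipeline configuration, orchestration and report assembly.

``run_pipeline`` executes the stages in order — filter, enrich, tss,
integrate, mirna — each writing per-stage TSVs plus a JSON fragment into the
output directory, then assembles ``summary.json`` from the fragments and a
plain-text log recording the config hash and seed. Stages are idempotent:
re-running a stage only depends on the persisted output of earlier stages
(the filtered peak set), so any suffix of the pipeline can be re-run.

All thresholds are explicit in the config after loading; nothing is guessed
downstream, including the fold-change dialect of the expression table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding_expression as bx
from . import feature_enrichment as fe
from . import genome_core as gc
from . import mirna_enrichment as mi
from . import peak_processing as pp
from . import tss_analysis as ta

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("filter", "enrich", "tss", "integrate", "mirna")

#: Hexamer reported to act as a nucleic-acid nuclear localization signal on
#: miR-29b; the discovered consensus is compared against it.
MIR29B_NLS = "AGUGUU"


@dataclass
class PipelineConfig:
    """Every input path and threshold of the pipeline, defaults materialized."""

    out_dir: str
    peaks: str
    genes: str
    sizes: str
    genome_fasta: str | None = None
    repeats: str | None = None
    hot_regions: str | None = None
    k4_peaks: str | None = None
    expression: str | None = None
    mirnas: str | None = None
    validation_table: str | None = None
    gene_dialect: str | None = None       # bed12 | gtf; None = by extension
    fdr_cutoff: float | None = None       # explicit cutoff, or use validation table
    min_validation_rate: float = 0.8
    flank_width: int = 5000
    composition_mode: str = "midpoint"
    tss_window: int = 5000
    tss_bin_width: int = 100
    costrat_window: int = 1000
    abg_windows: tuple[int, ...] = (5000, 1000, 500)
    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    scan_window: int = 5000
    fold_cutoff: float = 1.5
    alpha: float = 0.05
    seed_rule: str = "7mer-m8"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "abg_windows" in raw:
            raw["abg_windows"] = tuple(raw["abg_windows"])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_fragment(out: Path, stage: str, data: dict) -> None:
    (out / f"{stage}.json").write_text(json.dumps(data, indent=1, sort_keys=True))


def _load_filtered(cfg: PipelineConfig, out: Path) -> list[pp.Peak]:
    path = out / "peaks_filtered.bed"
    if not path.exists():
        raise FileNotFoundError(
            "filtered peak set not found; run the 'filter' stage first"
        )
    return pp.read_peaks(path)


def _stage_filter(cfg: PipelineConfig, out: Path) -> dict:
    peaks = pp.read_peaks(cfg.peaks)
    sizes = gc.read_chrom_sizes(cfg.sizes)
    if cfg.fdr_cutoff is not None:
        cutoff = cfg.fdr_cutoff
    else:
        if cfg.validation_table is None:
            raise ValueError("config must give fdr_cutoff or a validation_table")
        bins = pp.read_validation_table(cfg.validation_table)
        cutoff = pp.select_fdr_cutoff(bins, cfg.min_validation_rate)
        if cutoff is pp.NO_CUTOFF:
            raise ValueError("no validation bin meets min_validation_rate; no FDR cutoff")
    kept = pp.filter_peaks(peaks, cutoff)
    pp.write_peaks(kept, out / "peaks_filtered.bed")
    summary = pp.summarize_peaks(kept, sizes)
    frag = {
        "fdr_cutoff": cutoff,
        "n_peaks_raw": len(peaks),
        "n_peaks_filtered": len(kept),
        "mean_spacing_kb": summary.mean_spacing_kb,
        "median_peak_size_bp": summary.size_quantiles[0.5],
    }
    _write_fragment(out, "filter", frag)
    return frag


def _stage_enrich(cfg: PipelineConfig, out: Path) -> dict:
    peaks = _load_filtered(cfg, out)
    sizes = gc.read_chrom_sizes(cfg.sizes)
    genes = gc.read_gene_models(cfg.genes, cfg.gene_dialect)
    fm = gc.partition_genome(genes, sizes, cfg.flank_width)
    counts, results = fe.feature_composition(peaks, fm, cfg.composition_mode)
    pd.DataFrame([dataclasses.asdict(r) for r in results]).to_csv(
        out / "feature_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    frag: dict = {
        "feature_ratios": {r.label: r.ratio for r in results},
        "feature_log10_p": {r.label: r.log10_p for r in results},
    }
    if cfg.repeats:
        repeats = gc.read_bed_intervals(cfg.repeats)
        genome_fracs = fe.genome_repeat_fractions(repeats, sizes)
        fractions, rep_results = fe.repeat_composition(peaks, repeats, genome_fracs)
        pd.DataFrame([dataclasses.asdict(r) for r in rep_results]).to_csv(
            out / "repeat_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
        frag["repeat_fractions"] = fractions
        frag["repetitive_fraction"] = 1.0 - fractions["non_repetitive"]
        frag["genome_repetitive_fraction"] = 1.0 - genome_fracs["non_repetitive"]
    if cfg.hot_regions:
        hot = gc.read_bed_intervals(cfg.hot_regions)
        frac, jaccard = fe.overlap_fraction(peaks, hot)
        frag["hot_overlap_fraction"] = frac
        frag["hot_jaccard"] = jaccard
    if cfg.genome_fasta and cfg.repeats:
        table = fe.build_density_table(
            peaks, genes, sizes, fasta=cfg.genome_fasta,
            repeats=gc.read_bed_intervals(cfg.repeats))
        table.to_csv(out / "density_table.tsv", sep="\t", float_format="%.6g")
        if len(table) >= len(table.columns) + 1:
            reg = fe.regress_peak_density(table)
            frag["simple_r2"] = reg.simple_r2
            frag["multiple_r2"] = reg.multiple_r2
            frag["gene_density_slope"] = reg.coefficients.get("gene_density")
    _write_fragment(out, "enrich", frag)
    return frag


def _stage_tss(cfg: PipelineConfig, out: Path) -> dict:
    peaks = _load_filtered(cfg, out)
    genes = gc.read_gene_models(cfg.genes, cfg.gene_dialect)
    hist = ta.tss_distance_histogram(peaks, genes, cfg.tss_window, cfg.tss_bin_width)
    with open(out / "tss_histogram.tsv", "w") as fh:
        fh.write("offset_bin_start\tcount\n")
        for lo in sorted(hist.counts):
            fh.write(f"{lo}\t{hist.counts[lo]}\n")
    within_1kb = sum(
        c for lo, c in hist.counts.items()
        if lo >= -1000 and lo + hist.bin_width <= 1000
    )
    frag: dict = {
        "n_peaks_in_window": hist.n_peaks_in_window,
        "fraction_within_1kb_of_window": (
            within_1kb / hist.n_peaks_in_window if hist.n_peaks_in_window else None
        ),
    }
    if cfg.k4_peaks:
        k4 = pp.read_peaks(cfg.k4_peaks)
        co = ta.h3k4me3_costratification(peaks, k4, genes, cfg.costrat_window)
        frag["k4_costratification"] = {
            "numerator": co.numerator, "denominator": co.denominator,
            "fraction": co.fraction,
        }
    _write_fragment(out, "tss", frag)
    return frag


def _stage_integrate(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.expression is None:
        raise ValueError("integrate stage requested but no expression table configured")
    peaks = _load_filtered(cfg, out)
    genes = gc.read_gene_models(cfg.genes, cfg.gene_dialect)
    records = bx.read_expression_table(cfg.expression)
    expr_ids = {r.gene_id for r in records}
    universe = {g.gene_id for g in genes} & expr_ids
    abgs = bx.define_abgs(peaks, genes, cfg.abg_windows)
    up, down = bx.define_args(records, cfg.fc_threshold, cfg.p_threshold)
    up &= universe
    down &= universe
    frag: dict = {"universe_size": len(universe),
                  "n_up": len(up), "n_down": len(down)}
    for w, gene_set in abgs.items():
        gene_set &= universe
        (out / f"abg_{w}.txt").write_text("\n".join(sorted(gene_set)) + "\n")
        frag[f"n_abg_{w}"] = len(gene_set)
    (out / "arg_up.txt").write_text("\n".join(sorted(up)) + "\n")
    (out / "arg_down.txt").write_text("\n".join(sorted(down)) + "\n")
    abg_main = abgs[cfg.abg_windows[0]] & universe
    for name, gene_set in (("all", up | down), ("up", up), ("down", down)):
        ov = bx.overlap_test(abg_main, gene_set, universe)
        frag[f"overlap_{name}"] = {
            "observed": ov.observed, "expected": ov.expected, "p_value": ov.p_value,
        }
        if gene_set:
            frag[f"bound_fraction_{name}"] = (
                len(gene_set & abg_main) / len(gene_set)
            )
    scan = bx.positional_scan(peaks, genes, up, down, universe, cfg.scan_window)
    pd.DataFrame({
        "offset": scan.offsets, "p_up": scan.p_up, "p_down": scan.p_down,
        "n_bound": scan.bound_counts,
    }).to_csv(out / "positional_scan.tsv", sep="\t", index=False, float_format="%.6g")
    frag["scan"] = {
        "argmin_up": scan.argmin_up, "min_p_up": scan.min_p_up,
        "argmin_down": scan.argmin_down, "min_p_down": scan.min_p_down,
    }
    _write_fragment(out, "integrate", frag)
    return frag


def _stage_mirna(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.mirnas is None or cfg.genome_fasta is None:
        raise ValueError("mirna stage needs mirnas FASTA and genome_fasta")
    from pyfaidx import Fasta

    peaks = _load_filtered(cfg, out)
    sizes = gc.read_chrom_sizes(cfg.sizes)
    mirnas = mi.read_mirna_fasta(cfg.mirnas, cfg.seed_rule)
    genome = Fasta(cfg.genome_fasta)
    controls = mi.sample_matched_controls(peaks, sizes, seed=cfg.rng_seed)
    peak_seqs = mi.extract_sequences(peaks, genome)
    control_seqs = mi.extract_sequences(controls, genome)
    table = mi.mirna_enrichment_table(
        peak_seqs, control_seqs, mirnas, cfg.fold_cutoff, cfg.alpha)
    pd.DataFrame([dataclasses.asdict(r) for r in table]).to_csv(
        out / "mirna_enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    enriched = [r.mirna_id for r in table if r.call == "enriched"]
    frag: dict = {
        "n_mirnas": len(mirnas),
        "n_enriched": len(enriched),
        "n_depleted": sum(1 for r in table if r.call == "depleted"),
        "enriched_mirnas": sorted(enriched),
    }
    if enriched:
        by_id = {m.mirna_id: m.sequence for m in mirnas}
        motif = mi.discover_motif([by_id[i] for i in enriched])
        frag["motif"] = {
            "consensus": motif.consensus,
            "n_containing": motif.n_mirnas_containing,
            "n_with_two": motif.n_mirnas_with_two,
            "total_occurrences": motif.total_occurrences,
        }
        if len(motif.consensus) == len(MIR29B_NLS):
            variants = mi._expand_consensus(motif.consensus)
            frag["motif"]["nls_homology_percent"] = mi.motif_homology(variants, MIR29B_NLS)
    _write_fragment(out, "mirna", frag)
    return frag


_STAGE_FUNCS = {
    "filter": _stage_filter,
    "enrich": _stage_enrich,
    "tss": _stage_tss,
    "integrate": _stage_integrate,
    "mirna": _stage_mirna,
}


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Run the requested stages (default: all) and assemble summary.json.

    Identical config + inputs produce a byte-identical summary. A stage
    failure aborts with the stage name; fragments from earlier successful
    stages remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    todo = STAGES if stages is None else tuple(stages)
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    log_lines = [f"config_hash\t{cfg.digest()}", f"rng_seed\t{cfg.rng_seed}"]
    for stage in STAGES:
        if stage not in todo:
            continue
        try:
            _STAGE_FUNCS[stage](cfg, out)
        except Exception as exc:
            log_lines.append(f"stage\t{stage}\tFAILED\t{exc}")
            (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        log_lines.append(f"stage\t{stage}\tok")
    summary: dict = {"config_hash": cfg.digest(), "rng_seed": cfg.rng_seed}
    for stage in STAGES:
        frag_path = out / f"{stage}.json"
        if frag_path.exists():
            summary[stage] = json.loads(frag_path.read_text())
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return summary
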