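"""Seed-match site prediction, matched controls, enrichment calls, motifs."""

import math

import numpy as np
import pytest

from agochip.genome_core import ChromSizes, Interval
from agochip.mirna_enrichment import (
    MiRNA,
    discover_motif,
    mirna_enrichment_table,
    motif_homology,
    predict_target_sites,
    sample_matched_controls,
    seed_match_motif,
)
from agochip.peak_processing import Peak

LET7_LIKE = MiRNA("m1", "UAGCUUAUCAGACUGAUGUUGA")  # seed 2-8 = AGCUUAU


def mkpeak(chrom, start, end, name="p"):
    return Peak(Interval(chrom, start, end, name=name), fdr=0.0)


def revcomp(s):
    return s[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


class TestPredictTargetSites:
    def test_seed_reverse_complement_motif(self):
        assert seed_match_motif(LET7_LIKE) == "ATAAGCT"

    def test_forward_hit(self):
        hits = predict_target_sites("GGATAAGCTGG", LET7_LIKE)
        assert hits.count == 1 and hits.forward_positions == [2]

    def test_one_site_per_strand(self):
        seq = "GG" + "ATAAGCT" + "CCCCC" + revcomp("ATAAGCT") + "GG"
        assert predict_target_sites(seq, LET7_LIKE).count == 2

    def test_empty_and_all_n(self):
        assert predict_target_sites("", LET7_LIKE).count == 0
        assert predict_target_sites("N" * 50, LET7_LIKE).count == 0

    def test_overlapping_occurrences_counted(self):
        poly_u = MiRNA("pu", "GUUUUUUUUG" + "ACGUACGUACGU")  # seed 2-8 = UUUUUUU
        assert seed_match_motif(poly_u) == "AAAAAAA"
        hits = predict_target_sites("G" + "A" * 8 + "G", poly_u)
        assert len(hits.forward_positions) == 2

    def test_strand_symmetry(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), 300))
            assert (predict_target_sites(seq, LET7_LIKE).count
                    == predict_target_sites(revcomp(seq), LET7_LIKE).count)

    def test_8mer_rule_appends_a_anchor(self):
        m8 = MiRNA("m8", LET7_LIKE.sequence, seed_rule="8mer")
        assert seed_match_motif(m8) == "ATAAGCTA"


class TestMatchedControls:
    def test_lengths_chromosomes_and_determinism(self, sim):
        controls = sample_matched_controls(sim.peaks, sim.sizes, seed=5)
        assert [len(c) for c in controls] == [len(p) for p in sim.peaks]
        assert [c.chrom for c in controls] == [p.chrom for p in sim.peaks]
        again = sample_matched_controls(sim.peaks, sim.sizes, seed=5)
        assert controls == again
        other = sample_matched_controls(sim.peaks, sim.sizes, seed=6)
        assert controls != other

    def test_controls_avoid_peaks_quadratic_scan(self, sim):
        controls = sample_matched_controls(sim.peaks, sim.sizes, seed=5)
        for c in controls:
            assert not any(c.overlaps(p.interval) for p in sim.peaks)

    def test_gc_matching_within_tolerance(self, sim):
        controls = sample_matched_controls(
            sim.peaks[:20], sim.sizes, seed=5, gc_match=0.03, genome=sim.genome)

        def gc(s):
            return (s.count("G") + s.count("C")) / len(s)

        for p, c in zip(sim.peaks[:20], controls):
            assert abs(gc(sim.genome[p.chrom][p.start:p.end])
                       - gc(sim.genome[c.chrom][c.start:c.end])) <= 0.03

    def test_impossible_placement_raises(self):
        sizes = ChromSizes()
        sizes["chr1"] = 1000
        peak = mkpeak("chr1", 0, 900)  # excludes nearly the whole chromosome
        with pytest.raises(RuntimeError, match="failed to place"):
            sample_matched_controls([peak], sizes, seed=1, max_attempts=50)


def binom_two_sided_oracle(k, n):
    pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
    ref = pmf[k] * (1 + 1e-9)
    return sum(p for p in pmf if p <= ref)


class TestEnrichmentTable:
    def test_identical_sets_all_neutral(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("ACGT"), 500)) for _ in range(20)]
        mirnas = [MiRNA(f"m{i}", "".join(rng.choice(list("ACGU"), 22))) for i in range(10)]
        table = mirna_enrichment_table(seqs, list(seqs), mirnas)
        for row in table:
            assert row.call == "neutral"
            if row.sites_controls:
                assert row.ratio == pytest.approx(1.0)

    def test_implanted_subset_called_enriched(self):
        rng = np.random.default_rng(8)
        mirnas = [MiRNA(f"m{i:02d}", "".join(rng.choice(list("ACGU"), 22)))
                  for i in range(50)]
        controls = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(60)]
        peaks = ["".join(rng.choice(list("ACGT"), 400)) for _ in range(60)]
        # implant sites for the first 5 miRNAs at ~3x the background rate
        for m in mirnas[:5]:
            motif = seed_match_motif(m)
            for idx in rng.choice(len(peaks), size=20, replace=False):
                pos = int(rng.integers(0, 400 - len(motif)))
                s = peaks[idx]
                peaks[idx] = s[:pos] + motif + s[pos + len(motif):]
        table = {r.mirna_id: r for r in mirna_enrichment_table(peaks, controls, mirnas)}
        for m in mirnas[:5]:
            assert table[m.mirna_id].call == "enriched", m.mirna_id

    def test_binomial_p_matches_enumeration(self):
        # small constructed counts: sites only from implants
        m = LET7_LIKE
        motif = seed_match_motif(m)
        peaks = ["G" * 30 + motif + "G" * 30 for _ in range(9)]
        controls = ["G" * 30 + motif + "G" * 30 for _ in range(3)] + ["G" * 60] * 6
        (row,) = mirna_enrichment_table(peaks, controls, [m])
        assert (row.sites_peaks, row.sites_controls) == (9, 3)
        assert row.p_value == pytest.approx(binom_two_sided_oracle(9, 12), rel=1e-12)

    def test_zero_sites_neutral_p_one(self):
        (row,) = mirna_enrichment_table(["G" * 50], ["G" * 50], [LET7_LIKE])
        assert row.call == "neutral" and row.p_value == 1.0


def exhaustive_motif_oracle(seqs, k):
    """Independent recount: every exact k-mer and every one-position merge,
    scored by (n sequences containing, total occurrences, lexicographic)."""
    iupac = {frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AU"): "W",
             frozenset("CG"): "S", frozenset("CU"): "Y", frozenset("GU"): "K"}
    kmers = {s[i:i + k] for s in seqs for i in range(len(s) - k + 1)}
    cands = set(kmers)
    for a in kmers:
        for b in kmers:
            diff = [i for i in range(k) if a[i] != b[i]]
            if len(diff) == 1:
                code = iupac.get(frozenset((a[diff[0]], b[diff[0]])))
                if code:
                    cands.add(a[:diff[0]] + code + a[diff[0] + 1:])
    expand = {v: "".join(sorted(s)) for s, v in iupac.items()}

    def matches(window, cand):
        return all(w == c or (c in expand and w in expand[c])
                   for w, c in zip(window, cand))

    best = None
    for cand in sorted(cands):
        occ = [sum(matches(s[i:i + k], cand) for i in range(len(s) - k + 1))
               for s in seqs]
        key = (-sum(1 for o in occ if o), -sum(occ), cand)
        if best is None or key < best[0]:
            best = (key, cand, sum(1 for o in occ if o),
                    sum(1 for o in occ if o >= 2), sum(occ))
    return best[1:]


class TestDiscoverMotif:
    def test_spec_like_mixed_variant_case(self):
        # unique random pads so no background k-mer is shared across sequences
        rng = np.random.default_rng(0)

        def pad(n=10):
            return "".join(rng.choice(list("ACGU"), n))

        seqs = [pad() + "AGUGCA" + pad() for _ in range(3)]
        seqs += [pad() + "AGUGCU" + pad()]
        seqs += [pad() + "AGUGCU" + pad() + "AGUGCU" + pad()]  # two hits
        res = discover_motif(seqs, k=6)
        assert res.consensus == "AGUGCW"
        assert res.n_mirnas_containing == 5
        assert res.n_mirnas_with_two == 1
        assert res.total_occurrences == 6

    def test_single_sequence(self):
        res = discover_motif(["AGUGCA"], k=6)
        assert res.consensus == "AGUGCA"
        assert (res.n_mirnas_containing, res.n_mirnas_with_two,
                res.total_occurrences) == (1, 0, 1)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGU"), 30)) for _ in range(12)]
        res = discover_motif(seqs, k=6)
        consensus, n_cont, n_two, total = exhaustive_motif_oracle(seqs, 6)
        assert (res.consensus, res.n_mirnas_containing,
                res.n_mirnas_with_two, res.total_occurrences) \
            == (consensus, n_cont, n_two, total)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            discover_motif([])


class TestMotifHomology:
    def test_consensus_variants_vs_nls(self):
        assert motif_homology(["AGUGCU", "AGUGCA"], "AGUGUU") == pytest.approx(500 / 6)

    def test_identity_and_disjoint(self):
        assert motif_homology(["AGUGUU"], "AGUGUU") == 100.0
        assert motif_homology(["AAAAAA"], "UUUUUU") == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            motif_homology(["AGU"], "AGUGUU")
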