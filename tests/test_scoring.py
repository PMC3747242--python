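"""The signed Poisson dimorphism score and the combined gene calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import poisson_difference_oracle
from dimorphseq.core import CoverageTrack, GenomicInterval, GeneModel, Peak
from dimorphseq.scoring import (
    DimorphismCall,
    GeneScore,
    ScoreConfig,
    call_dimorphic_genes,
    poisson_difference_pvalue,
    poisson_difference_pvalues,
    score_genes_pol2,
    score_peaks,
    signed_score,
    signed_scores,
    stratify,
    summit_window,
)


def mkpeak(name, chrom, summit, width=400, height=1.0):
    return Peak(GenomicInterval(chrom, summit - width // 2, summit + width // 2),
                name, summit, height)


class TestSummitWindow:
    def test_centered_300bp(self):
        win = summit_window(mkpeak("p", "chr1", 1000), 300)
        assert (win.start, win.end) == (850, 1150)

    def test_clipped_at_zero(self):
        win = summit_window(mkpeak("p", "chr1", 100, width=200), 300)
        assert (win.start, win.end) == (0, 250)

    def test_minimal_window(self):
        win = summit_window(mkpeak("p", "chr1", 1000), 2)
        assert (win.start, win.end) == (999, 1001)

    def test_odd_window_rejected(self):
        with pytest.raises(ValueError):
            summit_window(mkpeak("p", "chr1", 1000), 301)


class TestPoissonDifferencePvalue:
    @pytest.mark.parametrize("method", ["poisson_tail", "conditional_binomial"])
    def test_equal_counts_not_significant(self, method):
        p = poisson_difference_pvalue(50, 50, method=method)
        assert p >= 0.5

    def test_poisson_tail_matches_term_by_term_summation(self):
        # 25 vs 5 with equal norms: upper tail of Poisson(5) at 25
        p = poisson_difference_pvalue(25, 5, method="poisson_tail")
        lam = 5.0
        term = math.exp(-lam)
        tail = 0.0
        for i in range(0, 300):
            if i >= 25:
                tail += term
            term *= lam / (i + 1)
        assert p == pytest.approx(tail, rel=1e-10)
        assert signed_score(p, "a_stronger") > 6

    def test_zero_zero_gives_p_one(self):
        for method in ("poisson_tail", "conditional_binomial"):
            assert poisson_difference_pvalue(0, 0, method=method) == 1.0

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            poisson_difference_pvalues([1.5], [2])

    def test_k_zero_pair_is_finite(self):
        p = poisson_difference_pvalue(40, 0, method="poisson_tail")
        assert 0 < p < 1  # lambda floored at 1 keeps this finite

    @pytest.mark.parametrize("method", ["poisson_tail", "conditional_binomial"])
    def test_monotone_in_excess_count(self, method):
        ks = np.arange(10, 120)
        p = poisson_difference_pvalues(ks, np.full_like(ks, 10), method=method)
        assert np.all(np.diff(p) <= 1e-15)
        s = signed_scores(p, np.ones_like(ks))
        assert np.all(np.diff(s) >= -1e-12)

    @pytest.mark.parametrize("method", ["poisson_tail", "conditional_binomial"])
    def test_oracle_equivalence_on_sampled_grid(self, method):
        rng = np.random.default_rng(11)
        for _ in range(200):
            ka, kb = int(rng.integers(0, 201)), int(rng.integers(0, 201))
            na, nb = float(rng.uniform(0.5, 2)), float(rng.uniform(0.5, 2))
            got = poisson_difference_pvalue(ka, kb, na, nb, method=method)
            want = poisson_difference_oracle(ka, kb, na, nb, method=method)
            assert got == pytest.approx(want, rel=1e-12)

    def test_library_size_normalization_shifts_direction(self):
        # 100 vs 60 is an excess of a only if a's library is not larger
        p_eq = poisson_difference_pvalue(100, 60)
        p_norm = poisson_difference_pvalue(100, 60, norm_a=2.0, norm_b=1.0)
        assert p_eq < 0.01
        assert p_norm > 0.05  # normalized rates 50 vs 60: no male excess


class TestSignedScore:
    def test_significance_boundary_is_six(self):
        assert signed_score(10 ** -6.4, "a_stronger") == pytest.approx(6.0, abs=1e-9)

    def test_medium_boundary_is_three(self):
        assert signed_score(10 ** -0.8, "b_stronger") == pytest.approx(-3.0, abs=1e-9)

    def test_p_one_clamps_to_zero(self):
        assert signed_score(1.0, "a_stronger") == 0.0

    def test_direction_none_clamps_to_zero(self):
        assert signed_score(1e-10, "none") == 0.0

    def test_invalid_p_rejected(self):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                signed_score(bad, "a_stronger")

    @settings(derandomize=True, max_examples=300)
    @given(st.floats(min_value=1e-300, max_value=1.0, exclude_max=False))
    def test_threshold_equivalence_property(self, p):
        s = signed_score(p, "a_stronger")
        assert (s > 6) == (p < 10 ** -6.4)
        assert (s >= 3) == (p <= 10 ** -0.8)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(5)
        ps = 10 ** rng.uniform(-12, 0, 100)
        vec = signed_scores(ps, np.ones(100))
        for p, v in zip(ps, vec):
            assert v == pytest.approx(signed_score(float(p), "a_stronger"), abs=1e-12)


class TestStratify:
    @pytest.mark.parametrize(
        "score,expected",
        [(6.5, "High"), (-4, "Medium"), (3, "Medium"), (6, "Medium"),
         (-6.01, "High"), (2.99, "Low"), (0, "Low"), (-2, "Low")],
    )
    def test_boundaries(self, score, expected):
        assert stratify(score) == expected


def _track_from_counts(chrom_counts, library_size=1.0):
    """chrom -> {pos: count} point-read track."""
    runs = []
    for chrom, per_pos in chrom_counts.items():
        for pos, c in sorted(per_pos.items()):
            runs.append((chrom, pos, pos + 1, float(c)))
    return CoverageTrack.from_runs(runs, library_size)


class TestScorePeaks:
    def test_planted_difference_recovers_high_stratum(self):
        rng = np.random.default_rng(2)
        peak = mkpeak("p", "chr1", 1000)
        km, kf = rng.poisson(200), rng.poisson(50)
        tm = _track_from_counts({"chr1": {1000: km}})
        tf = _track_from_counts({"chr1": {1000: kf}})
        (sp,) = score_peaks([peak], tm, tf)
        assert sp.count_m == km and sp.count_f == kf
        assert sp.score > 6 and sp.stratum == "High"

    def test_identical_tracks_score_zero(self):
        track = _track_from_counts({"chr1": {990: 30, 1010: 25}})
        (sp,) = score_peaks([mkpeak("p", "chr1", 1000)], track, track)
        assert sp.score == 0.0

    def test_swapped_tracks_negate_scores(self):
        tm = _track_from_counts({"chr1": {1000: 80}})
        tf = _track_from_counts({"chr1": {1000: 30}})
        peaks = [mkpeak("p", "chr1", 1000)]
        (fwd,) = score_peaks(peaks, tm, tf)
        (rev,) = score_peaks(peaks, tf, tm)
        assert rev.score == -fwd.score

    def test_missing_chromosome_counts_zero(self, caplog):
        tm = _track_from_counts({"chr1": {1000: 10}})
        tf = _track_from_counts({"chr2": {1000: 10}})
        (sp,) = score_peaks([mkpeak("p", "chr1", 1000)], tm, tf)
        assert sp.count_f == 0


class TestScoreGenesPol2:
    @staticmethod
    def _gene(gid="g", strand="+"):
        start, end = 10_000, 14_000
        iv = (GenomicInterval("chr1", start, end, strand),)
        if strand == "+":
            return GeneModel(gid, "chr1", strand, start, end - 1, iv)
        return GeneModel(gid, "chr1", strand, end - 1, start, iv)

    def test_equal_counts_score_zero(self):
        reads = {f"chr1": {11_000: 100}}
        tm = _track_from_counts(reads)
        tf = _track_from_counts(reads)
        (gs,) = score_genes_pol2([self._gene()], tm, tf)
        assert gs.count_m == gs.count_f == 100 and gs.score == 0.0

    def test_planted_difference_scores_high(self):
        rng = np.random.default_rng(4)
        km, kf = rng.poisson(300), rng.poisson(60)
        (gs,) = score_genes_pol2(
            [self._gene()],
            _track_from_counts({"chr1": {11_000: km}}),
            _track_from_counts({"chr1": {11_000: kf}}),
        )
        assert gs.score > 6

    def test_minus_strand_counts_same_genomic_span(self):
        tm = _track_from_counts({"chr1": {10_000: 5, 13_999: 7}})
        tf = _track_from_counts({"chr1": {11_000: 12}})
        (plus,) = score_genes_pol2([self._gene(strand="+")], tm, tf)
        (minus,) = score_genes_pol2([self._gene(strand="-")], tm, tf)
        assert (plus.count_m, plus.count_f) == (minus.count_m, minus.count_f) == (12, 12)

    def test_zero_coverage_gene_degenerate(self):
        empty = CoverageTrack.from_runs([("chr2", 0, 1, 0.0)], library_size=1)
        (gs,) = score_genes_pol2([self._gene()], empty, empty)
        assert gs.p_value == 1.0 and gs.score == 0.0


class TestCallDimorphicGenes:
    CFG = ScoreConfig()

    @staticmethod
    def _scored(name, score):
        p = mkpeak(name, "chr1", 1000)
        from dimorphseq.scoring import ScoredPeak

        return ScoredPeak(p, 0, 0, 1.0, 1.0, 0.5, score, stratify(score))

    def test_requires_both_peak_and_pol2(self):
        peaks = [self._scored("p1", 7.1), self._scored("p2", -2.0)]
        mapping = {"p1": {"g"}, "p2": {"g"}}
        calls = call_dimorphic_genes(peaks, mapping, [GeneScore("g", 0, 0, 0.5, 6.5)])
        (c,) = calls
        assert c.call == "male_dominant"
        assert c.supporting_peaks == ("p1",)

    def test_conjunction_fails_on_weak_pol2(self):
        peaks = [self._scored("p1", 7.1)]
        calls = call_dimorphic_genes(peaks, {"p1": {"g"}},
                                     [GeneScore("g", 0, 0, 0.5, 2.0)])
        assert calls[0].call == "none"

    def test_female_dominant_is_mirrored(self):
        peaks = [self._scored("p1", -8.0)]
        calls = call_dimorphic_genes(peaks, {"p1": {"g"}},
                                     [GeneScore("g", 0, 0, 0.5, -9.0)])
        assert calls[0].call == "female_dominant"

    def test_missing_pol2_score_yields_none(self, caplog):
        peaks = [self._scored("p1", 8.0)]
        calls = call_dimorphic_genes(peaks, {"p1": {"g"}}, [])
        assert calls[0].call == "none"

    def test_gene_without_peaks_is_none(self):
        calls = call_dimorphic_genes([], {}, [GeneScore("g", 0, 0, 0.5, 9.0)])
        assert calls[0].call == "none"
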