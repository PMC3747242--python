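"""The synthetic landscape generator: determinism, planted structure, round-trips."""

import json

import numpy as np
import pandas as pd
import pytest

from dimorphseq import io as gio
from dimorphseq.intervals import classify_overlap
from dimorphseq.synthetic import (
    SimulationConfig,
    generate_annotation,
    generate_peak_landscape,
    simulate_bundle,
    simulate_expression,
    simulate_tracks,
    write_fixture_bundle,
)


class TestGenerateAnnotation:
    def test_count_and_non_overlap(self, sim_config):
        genes = generate_annotation(sim_config)
        assert len(genes) == sim_config.n_genes
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs.sort(key=lambda g: g.span_start)
            for a, b in zip(gs, gs[1:]):
                assert a.span_end <= b.span_start

    def test_deterministic_given_seed(self, sim_config):
        assert generate_annotation(sim_config) == generate_annotation(sim_config)

    def test_infeasible_packing_raises(self):
        cfg = SimulationConfig(n_genes=2000, chromosome_length=100_000)
        with pytest.raises(ValueError, match="packing"):
            generate_annotation(cfg)

    def test_exon_structure(self, bundle):
        for g in bundle.genes[:50]:
            assert 2 <= len(g.exons) <= 5
            assert g.exons[0].start == g.span_start
            assert g.exons[-1].end == g.span_end


class TestGeneratePeakLandscape:
    def test_dominant_gene_counts_follow_fractions(self, bundle, sim_config):
        classes = bundle.truth.genes["true_class"].value_counts()
        assert classes["male_dominant"] == round(
            sim_config.fraction_male_dominant * sim_config.n_genes
        )
        assert classes["female_dominant"] == round(
            sim_config.fraction_female_dominant * sim_config.n_genes
        )

    def test_fully_shared_landscape_has_no_unique_peaks(self):
        cfg = SimulationConfig(seed=3, fraction_shared_peaks=1.0, n_peaks=300)
        genes = generate_annotation(cfg)
        pm, pf, _ = generate_peak_landscape(cfg, genes)
        res = classify_overlap(pm, pf)
        assert not res.unique_a and not res.unique_b
        assert [(p.chrom, p.start, p.end) for p in pm] == \
               [(p.chrom, p.start, p.end) for p in pf]

    def test_fully_unique_landscape_has_no_common_peaks(self):
        cfg = SimulationConfig(seed=3, fraction_shared_peaks=0.0, n_peaks=300)
        genes = generate_annotation(cfg)
        pm, pf, _ = generate_peak_landscape(cfg, genes)
        res = classify_overlap(pm, pf)
        assert not res.common_a and not res.common_b

    def test_dominant_genes_have_near_tss_peak(self, bundle):
        genes = {g.gene_id: g for g in bundle.genes}
        planted = bundle.truth.genes.query("true_class != 'none'")
        peak_df = bundle.truth.peaks.set_index("name")
        for row in planted.itertuples():
            names = row.peak_names.split(",")
            assert names
            for name in names:
                summit = peak_df.loc[name, "summit"]
                assert abs(summit - genes[row.gene_id].tss) <= 10_000

    def test_planted_rate_pairs_oriented_by_class(self, bundle, sim_config):
        lam = sim_config.baseline_rate
        mult = sim_config.effect_multiplier
        pk = bundle.truth.peaks
        male = pk[pk.true_class == "male_dominant"]
        female = pk[pk.true_class == "female_dominant"]
        assert (male.rate_m == lam * mult).all() and (male.rate_f == lam).all()
        assert (female.rate_f == lam * mult).all() and (female.rate_m == lam).all()
        nulls = pk[pk.true_class == "none"]
        assert (nulls.rate_m == lam).all() and (nulls.rate_f == lam).all()


class TestSimulateTracks:
    def test_null_window_counts_average_near_baseline(self, bundle, sim_config):
        # law of large numbers: mean over ~1600 null windows within [47, 53]
        pk = bundle.truth.peaks
        nulls = pk[pk.true_class == "none"]
        win = 150
        counts = [
            bundle.tracks.rxr_m.window_sum(r.chrom, r.summit - win, r.summit + win)
            for r in nulls.itertuples()
        ]
        assert 47 <= np.mean(counts) <= 53

    def test_zero_background_leaves_gaps_empty(self):
        cfg = SimulationConfig(seed=5, background_rate_per_bp=0.0, n_peaks=100,
                               n_genes=20)
        genes = generate_annotation(cfg)
        _, _, truth = generate_peak_landscape(cfg, genes)
        tracks = simulate_tracks(cfg, genes, truth)
        # a region far from any peak or gene body: between first two peaks
        pk = truth.peaks.sort_values(["chrom", "summit"])
        first, second = pk.iloc[0], pk.iloc[1]
        gap_lo, gap_hi = first.summit + 200, second.summit - 200
        in_gene = any(
            g.chrom == first.chrom and g.span_start < gap_hi and g.span_end > gap_lo
            for g in genes
        )
        if not in_gene and gap_hi > gap_lo:
            assert tracks.rxr_m.window_sum(first.chrom, gap_lo, gap_hi) == 0

    def test_deterministic_given_seed(self, sim_config):
        genes = generate_annotation(sim_config)
        _, _, truth = generate_peak_landscape(sim_config, genes)
        t1 = simulate_tracks(sim_config, genes, truth)
        t2 = simulate_tracks(sim_config, genes, truth)
        assert list(t1.rxr_m.iter_runs()) == list(t2.rxr_m.iter_runs())
        assert list(t1.pol2_f.iter_runs()) == list(t2.pol2_f.iter_runs())


class TestSimulateExpression:
    def test_noise_free_limit_reproduces_planted_fc(self):
        cfg = SimulationConfig(seed=7, expression_sd=0.0)
        genes = generate_annotation(cfg)
        _, _, truth = generate_peak_landscape(cfg, genes)
        matrix = simulate_expression(cfg, truth)
        mcols = [c for c in matrix.columns if c.startswith("M")]
        fcols = [c for c in matrix.columns if c.startswith("F")]
        fc = matrix[mcols].mean(axis=1) / matrix[fcols].mean(axis=1)
        for row in truth.genes.itertuples():
            expected = {
                "male_dominant": cfg.effect_multiplier,
                "female_dominant": 1 / cfg.effect_multiplier,
                "none": 1.0,
            }[row.true_class]
            assert fc[row.gene_id] == pytest.approx(expected, rel=1e-9)

    def test_dominant_genes_pass_expression_screen(self, bundle):
        from dimorphseq.expression import differential_expression

        records = {r.gene_id: r for r in differential_expression(bundle.expression)}
        planted = bundle.truth.genes.query("true_class != 'none'")
        n_pass = sum(records[g].passes for g in planted.gene_id)
        assert n_pass >= 0.9 * len(planted)


class TestWriteFixtureBundle:
    def test_file_count_and_manifest(self, sim_config, fixture_dir):
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        assert len(manifest["files"]) == 10
        for entry in manifest["files"].values():
            assert (fixture_dir / entry["path"]).exists()

    def test_rerun_reproduces_checksums(self, sim_config, fixture_dir, tmp_path):
        manifest2 = write_fixture_bundle(sim_config, tmp_path)
        manifest1 = json.loads((fixture_dir / "manifest.json").read_text())
        for key in manifest1["files"]:
            assert manifest1["files"][key]["sha256"] == manifest2["files"][key]["sha256"]

    def test_round_trip_through_readers(self, bundle, fixture_dir):
        peaks_m = gio.read_peaks(fixture_dir / "peaks_m.narrowPeak")
        assert peaks_m == bundle.peaks_m
        genes = gio.read_gene_models(fixture_dir / "genes.refflat")
        assert genes == bundle.genes
        track = gio.read_coverage(fixture_dir / "rxr_m.bedgraph", "bedGraph",
                                  library_size=bundle.tracks.rxr_m.library_size)
        for (c1, s1, e1, v1), (c2, s2, e2, v2) in zip(
            track.iter_runs(), bundle.tracks.rxr_m.iter_runs()
        ):
            assert (c1, s1, e1, v1) == (c2, s2, e2, v2)
        matrix = pd.read_csv(fixture_dir / "expression.tsv", sep="\t", index_col=0)
        assert np.allclose(matrix.to_numpy(), bundle.expression.to_numpy())
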