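"""Pipeline orchestration: load inputs, score, classify, integrate, report.

Each stage is a plain function over a :class:`PipelineConfig`; the CLI in
:mod:`dimorphseq.cli` is a thin wrapper. Stages write TSV tables and a
JSON run report into the configured output directory and are idempotent:
re-running with unchanged inputs rewrites identical content.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as gio
from .core import CoverageTrack, GeneModel, Peak
from .expression import (
    ExpressionRecord,
    IntegratedCall,
    best_peak_score_per_gene,
    differential_expression,
    integrate_three_way,
    read_expression,
    score_expression_correlation,
)
from .intervals import assign_genes, classify_overlap
from .scoring import (
    DimorphismCall,
    GeneScore,
    ScoreConfig,
    ScoredPeak,
    call_dimorphic_genes,
    score_genes_pol2,
    score_peaks,
)
from .synthetic import FIXTURE_FILES, SimulationConfig, write_fixture_bundle

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File locations and thresholds for one pipeline run."""

    peaks_m: str
    peaks_f: str
    rxr_track_m: str
    rxr_track_f: str
    pol2_track_m: str
    pol2_track_f: str
    gene_models: str
    out_dir: str
    expression: str | None = None
    peak_dialect: str = "narrowPeak"
    track_format: str = "bedGraph"
    score: ScoreConfig = field(default_factory=ScoreConfig)
    fc_cutoff: float = 1.5
    p_cutoff: float = 0.1
    assign_mode: str = "tss_window"
    assign_up: int = 10_000
    assign_down: int = 10_000
    swap_conditions: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.score, dict):
            self.score = ScoreConfig(**self.score)
        if self.fc_cutoff <= 0 or self.p_cutoff <= 0:
            raise ValueError("cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_fixture_dir(
        cls, fixture_dir: str | Path, out_dir: str | Path, **overrides
    ) -> "PipelineConfig":
        d = Path(fixture_dir)
        return cls(
            peaks_m=str(d / FIXTURE_FILES["peaks_m"]),
            peaks_f=str(d / FIXTURE_FILES["peaks_f"]),
            rxr_track_m=str(d / FIXTURE_FILES["rxr_m"]),
            rxr_track_f=str(d / FIXTURE_FILES["rxr_f"]),
            pol2_track_m=str(d / FIXTURE_FILES["pol2_m"]),
            pol2_track_f=str(d / FIXTURE_FILES["pol2_f"]),
            gene_models=str(d / FIXTURE_FILES["genes"]),
            expression=str(d / FIXTURE_FILES["expression"]),
            out_dir=str(out_dir),
            **overrides,
        )


@dataclass
class PipelineInputs:
    peaks_m: list[Peak]
    peaks_f: list[Peak]
    peaks_union: list[Peak]
    genes: list[GeneModel]
    rxr_m: CoverageTrack
    rxr_f: CoverageTrack
    pol2_m: CoverageTrack
    pol2_f: CoverageTrack


@dataclass
class ScoreResult:
    scored_peaks: list[ScoredPeak]
    gene_scores: list[GeneScore]
    peak_to_gene: dict[str, set[str]]


def load_inputs(cfg: PipelineConfig) -> PipelineInputs:
    peaks_m = gio.read_peaks(cfg.peaks_m, cfg.peak_dialect)
    peaks_f = gio.read_peaks(cfg.peaks_f, cfg.peak_dialect)
    # shared peaks appear under the same name in both condition files;
    # the union is scored once per distinct name
    union: dict[str, Peak] = {}
    for p in peaks_m + peaks_f:
        union.setdefault(p.name, p)
    peaks_union = sorted(union.values(), key=lambda p: (p.chrom, p.start, p.name))
    genes = gio.read_gene_models(cfg.gene_models)
    tracks = [
        gio.read_coverage(path, cfg.track_format)
        for path in (cfg.rxr_track_m, cfg.rxr_track_f,
                     cfg.pol2_track_m, cfg.pol2_track_f)
    ]
    if cfg.swap_conditions:
        peaks_m, peaks_f = peaks_f, peaks_m
        tracks = [tracks[1], tracks[0], tracks[3], tracks[2]]
    return PipelineInputs(peaks_m, peaks_f, peaks_union, genes, *tracks)


def compute_scores(cfg: PipelineConfig, inputs: PipelineInputs) -> ScoreResult:
    scored = score_peaks(inputs.peaks_union, inputs.rxr_m, inputs.rxr_f, cfg.score)
    gene_scores = score_genes_pol2(inputs.genes, inputs.pol2_m, inputs.pol2_f, cfg.score)
    peak_to_gene = assign_genes(
        inputs.peaks_union, inputs.genes, cfg.assign_mode,
        cfg.assign_up, cfg.assign_down,
    )
    return ScoreResult(scored, gene_scores, peak_to_gene)


def _strata_counts(scored: Sequence[ScoredPeak]) -> dict[str, dict[str, int]]:
    """Per-direction strata tallies mirroring the High/Medium/Low tables."""
    out = {"male": {"High": 0, "Medium": 0, "Low": 0},
           "female": {"High": 0, "Medium": 0, "Low": 0}}
    for sp in scored:
        side = "male" if sp.score >= 0 else "female"
        out[side][sp.stratum] += 1
    return out


def scored_peaks_frame(scored: Sequence[ScoredPeak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(chrom=sp.peak.chrom, start=sp.peak.start, end=sp.peak.end,
                 name=sp.name, summit=sp.peak.summit, count_m=sp.count_m,
                 count_f=sp.count_f, p_value=sp.p_value, score=sp.score,
                 stratum=sp.stratum)
            for sp in scored
        ]
    )


def gene_scores_frame(gene_scores: Sequence[GeneScore]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene_id=gs.gene_id, count_m=gs.count_m, count_f=gs.count_f,
                 p_value=gs.p_value, pol2_score=gs.score)
            for gs in gene_scores
        ]
    )


def calls_frame(calls: Sequence[DimorphismCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(gene_id=c.gene_id, call=c.call,
                 n_supporting_peaks=len(c.supporting_peaks),
                 best_peak_score=c.best_peak_score, pol2_score=c.pol2_score)
            for c in calls
        ]
    )


def integrated_frame(calls: Sequence[IntegratedCall]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in calls])


def run_simulate(sim_config: SimulationConfig, out_dir: str | Path) -> dict:
    """Generate and write a fixture bundle; returns the file manifest."""
    return write_fixture_bundle(sim_config, out_dir)


def run_score(cfg: PipelineConfig) -> tuple[ScoreResult, dict]:
    """Score peaks and genes, write the per-peak/per-gene tables and a
    Venn + strata summary; returns the scores and the report fragment."""
    t0 = time.monotonic()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(cfg)
    result = compute_scores(cfg, inputs)
    venn = classify_overlap(inputs.peaks_m, inputs.peaks_f).summary()
    scored_peaks_frame(result.scored_peaks).to_csv(
        out / "peaks_scored.tsv", sep="\t", index=False
    )
    gene_scores_frame(result.gene_scores).to_csv(
        out / "genes_pol2.tsv", sep="\t", index=False
    )
    strata = _strata_counts(result.scored_peaks)
    report = {
        "peaks_m": len(inputs.peaks_m),
        "peaks_f": len(inputs.peaks_f),
        "peaks_scored": len(result.scored_peaks),
        "genes_scored": len(result.gene_scores),
        "venn": venn,
        "strata": strata,
        "wall_seconds": round(time.monotonic() - t0, 3),
    }
    with open(out / "venn.json", "w") as fh:
        json.dump(venn, fh, indent=2)
    return result, report


def run_classify(cfg: PipelineConfig) -> tuple[list[DimorphismCall], dict]:
    """Score then combine binding-site and Pol2 evidence into per-gene
    dominance calls; writes calls.tsv."""
    t0 = time.monotonic()
    result, score_report = run_score(cfg)
    calls = call_dimorphic_genes(
        result.scored_peaks, result.peak_to_gene, result.gene_scores, cfg.score
    )
    out = Path(cfg.out_dir)
    calls_frame(calls).to_csv(out / "calls.tsv", sep="\t", index=False)
    by_call = {"male_dominant": 0, "female_dominant": 0, "none": 0}
    for c in calls:
        by_call[c.call] += 1
    report = dict(score_report)
    report["calls"] = by_call
    report["wall_seconds"] = round(time.monotonic() - t0, 3)
    return calls, report


def run_integrate(cfg: PipelineConfig) -> tuple[list[IntegratedCall], dict]:
    """Full pipeline: classify, screen the expression matrix, integrate
    the three lines of evidence, and write the run report."""
    t0 = time.monotonic()
    calls, report = run_classify(cfg)
    out = Path(cfg.out_dir)
    integrated: list[IntegratedCall] = []
    if cfg.expression is None or not Path(cfg.expression).exists():
        logger.warning("no expression matrix; integration skipped")
        report["integration"] = "skipped"
    else:
        matrix = read_expression(cfg.expression)
        if cfg.swap_conditions:
            def _swap(col: str) -> str:
                pre, _, rest = col.partition("_")
                pre = {"M": "F", "F": "M"}.get(pre, pre)
                return f"{pre}_{rest}" if rest else pre

            matrix = matrix.rename(columns=_swap)
        records = differential_expression(
            matrix, fc_cutoff=cfg.fc_cutoff, p_cutoff=cfg.p_cutoff
        )
        integrated = integrate_three_way(calls, records)
        integrated_frame(integrated).to_csv(
            out / "integrated.tsv", sep="\t", index=False
        )
        pol2_scores = {
            row.gene_id: row.pol2_score
            for row in pd.read_csv(out / "genes_pol2.tsv", sep="\t").itertuples()
        }
        _, pearson, spearman = score_expression_correlation(pol2_scores, records)
        n_final = {"male": 0, "female": 0, "none": 0}
        for c in integrated:
            n_final[c.final] += 1
        report["expression_genes"] = len(records)
        report["expression_pass"] = sum(r.passes for r in records)
        report["integrated"] = n_final
        report["pol2_expression_pearson"] = pearson
        report["pol2_expression_spearman"] = spearman
    report["wall_seconds"] = round(time.monotonic() - t0, 3)
    report["parameters"] = {
        "score": asdict(cfg.score),
        "fc_cutoff": cfg.fc_cutoff,
        "p_cutoff": cfg.p_cutoff,
        "assign_mode": cfg.assign_mode,
        "assign_up": cfg.assign_up,
        "assign_down": cfg.assign_down,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return integrated, report
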