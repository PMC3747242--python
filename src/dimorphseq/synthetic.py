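"""Synthetic two-condition ChIP-seq landscapes with planted dimorphism.

Generates a small genome of gene models, a peak landscape with shared and
condition-unique peaks, point-read coverage tracks whose window counts are
exact Poisson draws, and an expression matrix with planted fold changes —
plus a machine-readable truth table, so the whole pipeline can be
exercised end-to-end with known ground truth.

Planted structure: a configurable fraction of genes is male-dominant
(resp. female-dominant). Each dominant gene carries one binding site near
its TSS whose window read rates are (baseline * effect_multiplier,
baseline) oriented by class, a matching gene-body Pol2 rate asymmetry,
and an expression fold change equal to the effect multiplier. All other
peaks and genes are null (equal rates in both conditions).

A single global seed drives every stage through derived per-stage
substreams, so stages are independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .core import CoverageTrack, GenomicInterval, GeneModel, Peak
from . import io as gio

_STAGE_ANNOTATION = 1
_STAGE_PEAKS = 2
_STAGE_TRACKS = 3
_STAGE_EXPRESSION = 4


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    baseline_rate is the expected read count per 300-bp summit window of a
    null binding site in either condition; effect_multiplier the rate
    ratio planted for the dominant direction; pol2_baseline the expected
    Pol2 gene-body read count of a null gene; expression_sd the log2
    replicate noise of the array emulation.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 5_000_000
    n_genes: int = 200
    n_peaks: int = 2_000
    fraction_shared_peaks: float = 0.8
    fraction_male_dominant: float = 0.1
    fraction_female_dominant: float = 0.1
    baseline_rate: float = 50.0
    effect_multiplier: float = 4.0
    pol2_baseline: float = 60.0
    background_rate_per_bp: float = 0.001
    expression_sd: float = 0.2
    expression_base_mean: float = 8.0
    expression_base_sd: float = 1.0
    n_replicates: int = 3
    library_size_m: float = 1_000_000.0
    library_size_f: float = 1_000_000.0
    peak_width: int = 400
    gene_length_min: int = 4_000
    gene_length_max: int = 10_000

    def __post_init__(self) -> None:
        for name in ("fraction_shared_peaks", "fraction_male_dominant",
                     "fraction_female_dominant"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fraction_male_dominant + self.fraction_female_dominant > 1:
            raise ValueError("dominant fractions must sum to <= 1")
        if self.baseline_rate <= 0 or self.pol2_baseline <= 0:
            raise ValueError("rates must be positive")
        if self.effect_multiplier <= 1:
            raise ValueError("effect_multiplier must exceed 1")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")
        if self.library_size_m <= 0 or self.library_size_f <= 0:
            raise ValueError("library sizes must be positive")
        if self.peak_width % 2 or self.peak_width <= 0:
            raise ValueError("peak_width must be even and positive")

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([stage, self.seed])

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthTable:
    """Planted ground truth: per-gene classes and per-peak rate pairs."""

    genes: pd.DataFrame  # gene_id, true_class, peak_names, rate_m, rate_f, expression_fc
    peaks: pd.DataFrame  # name, chrom, summit, rate_m, rate_f, in_m, in_f, gene_id, true_class

    def gene_classes(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["true_class"]))


class TrackBundle(NamedTuple):
    rxr_m: CoverageTrack
    rxr_f: CoverageTrack
    pol2_m: CoverageTrack
    pol2_f: CoverageTrack


class FixtureBundle(NamedTuple):
    config: SimulationConfig
    genes: list[GeneModel]
    peaks_m: list[Peak]
    peaks_f: list[Peak]
    truth: TruthTable
    tracks: TrackBundle
    expression: pd.DataFrame


# gap kept around each gene so that TSS assignment windows (+/-10 kb) of
# neighbouring genes never collide with a planted near-TSS peak
_GENE_MARGIN = 24_000


def generate_annotation(config: SimulationConfig) -> list[GeneModel]:
    """Non-overlapping gene models on a regular grid, alternating strands,
    2-5 exons each; deterministic given the config seed."""
    rng = config.rng(_STAGE_ANNOTATION)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    idx = 0
    for chrom, n_here in zip(config.chrom_names, per_chrom):
        if n_here == 0:
            continue
        stride = config.chromosome_length // (n_here + 1)
        if stride < config.gene_length_max + _GENE_MARGIN:
            raise ValueError(
                f"infeasible gene packing: {n_here} genes of up to "
                f"{config.gene_length_max} bp (+{_GENE_MARGIN} bp margin) do "
                f"not fit on a {config.chromosome_length} bp chromosome"
            )
        for k in range(n_here):
            start = (k + 1) * stride
            length = int(rng.integers(config.gene_length_min,
                                      config.gene_length_max + 1))
            strand = "+" if idx % 2 == 0 else "-"
            n_ex = int(rng.integers(2, 6))
            interior = np.sort(
                rng.choice(np.arange(1, length), size=2 * n_ex - 2, replace=False)
            )
            bounds = np.concatenate(([0], interior, [length])) + start
            exons = tuple(
                GenomicInterval(chrom, int(bounds[i]), int(bounds[i + 1]), strand)
                for i in range(0, 2 * n_ex - 1, 2)
            )
            tx_start, tx_end = start, start + length
            if strand == "+":
                tss, tes = tx_start, tx_end - 1
            else:
                tss, tes = tx_end - 1, tx_start
            genes.append(
                GeneModel(f"gene{idx:04d}", chrom, strand, tss, tes, exons)
            )
            idx += 1
    return genes


def generate_peak_landscape(
    config: SimulationConfig, genes: list[GeneModel]
) -> tuple[list[Peak], list[Peak], TruthTable]:
    """Plant one strong binding site near each dominant gene's TSS and
    scatter the remaining (null) peaks on a genome-wide grid; split all
    peaks into shared and condition-unique per the configured fraction."""
    rng = config.rng(_STAGE_PEAKS)
    half = config.peak_width // 2
    lam0 = config.baseline_rate
    mult = config.effect_multiplier

    n_md = round(config.fraction_male_dominant * config.n_genes)
    n_fd = round(config.fraction_female_dominant * config.n_genes)
    order = rng.permutation(len(genes))
    md_genes = [genes[i] for i in order[:n_md]]
    fd_genes = [genes[i] for i in order[n_md:n_md + n_fd]]
    gene_class = {g.gene_id: "none" for g in genes}
    gene_class.update({g.gene_id: "male_dominant" for g in md_genes})
    gene_class.update({g.gene_id: "female_dominant" for g in fd_genes})

    # (chrom, summit, rate_m, rate_f, gene_id, class)
    planted: list[tuple[str, int, float, float, str, str]] = []
    for g, cls in [(g, "male_dominant") for g in md_genes] + [
        (g, "female_dominant") for g in fd_genes
    ]:
        offset = int(rng.integers(-2000, 2001))
        summit = max(half, g.tss + offset)
        rm, rf = (lam0 * mult, lam0) if cls == "male_dominant" else (lam0, lam0 * mult)
        planted.append((g.chrom, summit, rm, rf, g.gene_id, cls))

    n_null = config.n_peaks - len(planted)
    if n_null < 0:
        raise ValueError("n_peaks smaller than the number of dominant genes")
    per_chrom = [n_null // config.n_chromosomes] * config.n_chromosomes
    for i in range(n_null % config.n_chromosomes):
        per_chrom[i] += 1
    planted_summits: dict[str, list[int]] = {}
    for chrom, summit, *_ in planted:
        planted_summits.setdefault(chrom, []).append(summit)
    nulls: list[tuple[str, int, float, float, str, str]] = []
    for chrom, n_here in zip(config.chrom_names, per_chrom):
        if n_here == 0:
            continue
        stride = config.chromosome_length // (n_here + 1)
        for j in range(n_here):
            summit = (j + 1) * stride
            # keep null peaks clear of planted intervals so shared/unique
            # bookkeeping is exact even with fraction_shared_peaks = 0
            while any(abs(summit - s) < config.peak_width
                      for s in planted_summits.get(chrom, ())):
                summit += 2 * config.peak_width
            nulls.append((chrom, summit, lam0, lam0, "", "none"))

    records = sorted(planted + nulls, key=lambda r: (r[0], r[1]))
    n_total = len(records)
    n_shared = round(config.fraction_shared_peaks * n_total)
    shared_mask = np.zeros(n_total, dtype=bool)
    shared_mask[rng.permutation(n_total)[:n_shared]] = True
    unique_to_m = rng.random(n_total) < 0.5  # used only for unique null peaks

    peaks_m: list[Peak] = []
    peaks_f: list[Peak] = []
    peak_rows = []
    gene_peaks: dict[str, list[str]] = {}
    for i, (chrom, summit, rm, rf, gid, cls) in enumerate(records):
        name = f"peak{i:05d}"
        iv = GenomicInterval(chrom, summit - half, summit + half)
        if shared_mask[i]:
            in_m = in_f = True
        elif cls == "male_dominant":
            in_m, in_f = True, False
        elif cls == "female_dominant":
            in_m, in_f = False, True
        else:
            in_m, in_f = bool(unique_to_m[i]), not bool(unique_to_m[i])
        if in_m:
            peaks_m.append(Peak(iv, name, summit, rm))
        if in_f:
            peaks_f.append(Peak(iv, name, summit, rf))
        peak_rows.append(
            dict(name=name, chrom=chrom, summit=summit, rate_m=rm, rate_f=rf,
                 in_m=in_m, in_f=in_f, gene_id=gid, true_class=cls)
        )
        if gid:
            gene_peaks.setdefault(gid, []).append(name)

    gene_rows = []
    for g in genes:
        cls = gene_class[g.gene_id]
        names = gene_peaks.get(g.gene_id, [])
        if cls == "male_dominant":
            rm, rf, fc = lam0 * mult, lam0, mult
        elif cls == "female_dominant":
            rm, rf, fc = lam0, lam0 * mult, mult
        else:
            rm = rf = np.nan
            fc = 1.0
        gene_rows.append(
            dict(gene_id=g.gene_id, true_class=cls, peak_names=",".join(names),
                 rate_m=rm, rate_f=rf, expression_fc=fc)
        )
    truth = TruthTable(pd.DataFrame(gene_rows), pd.DataFrame(peak_rows))
    return peaks_m, peaks_f, truth


def _positions_to_track(
    pos_by_chrom: dict[str, np.ndarray], library_size: float
) -> CoverageTrack:
    runs = {}
    for chrom, pos in pos_by_chrom.items():
        if len(pos) == 0:
            continue
        uniq, counts = np.unique(pos, return_counts=True)
        runs[chrom] = (uniq, uniq + 1, counts.astype(float))
    return CoverageTrack(runs, library_size)


def simulate_tracks(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: TruthTable,
    window: int = 300,
) -> TrackBundle:
    """Point-read coverage tracks for both factors and both conditions.

    Each binding site emits Poisson(rate) reads uniformly inside its
    ``window``-bp summit window per condition (rates from the truth
    table, regardless of which condition's peak set it was called in);
    each gene body emits Poisson Pol2 reads over its TSS-TES span with
    the class multiplier applied to the dominant condition; a uniform
    low-rate background is added everywhere.
    """
    rng = config.rng(_STAGE_TRACKS)
    halfw = window // 2
    mult = config.effect_multiplier

    def empty() -> dict[str, list[np.ndarray]]:
        return {c: [] for c in config.chrom_names}

    rxr = {"m": empty(), "f": empty()}
    for row in truth.peaks.itertuples(index=False):
        lo = max(0, row.summit - halfw)
        hi = row.summit + halfw
        for cond, rate in (("m", row.rate_m), ("f", row.rate_f)):
            k = int(rng.poisson(rate))
            if k:
                rxr[cond][row.chrom].append(rng.integers(lo, hi, size=k))

    pol2 = {"m": empty(), "f": empty()}
    cls_by_gene = truth.gene_classes()
    for g in genes:
        cls = cls_by_gene.get(g.gene_id, "none")
        rate_m = config.pol2_baseline * (mult if cls == "male_dominant" else 1.0)
        rate_f = config.pol2_baseline * (mult if cls == "female_dominant" else 1.0)
        for cond, rate in (("m", rate_m), ("f", rate_f)):
            k = int(rng.poisson(rate))
            if k:
                pol2[cond][g.chrom].append(
                    rng.integers(g.span_start, g.span_end, size=k)
                )

    for pools in (rxr, pol2):
        for cond in ("m", "f"):
            for chrom in config.chrom_names:
                n_bg = int(rng.poisson(
                    config.background_rate_per_bp * config.chromosome_length
                ))
                if n_bg:
                    pools[cond][chrom].append(
                        rng.integers(0, config.chromosome_length, size=n_bg)
                    )

    def build(pools: dict[str, list[np.ndarray]], lib: float) -> CoverageTrack:
        merged = {
            chrom: np.concatenate(parts) if parts else np.array([], dtype=np.int64)
            for chrom, parts in pools.items()
        }
        return _positions_to_track(merged, lib)

    return TrackBundle(
        rxr_m=build(rxr["m"], config.library_size_m),
        rxr_f=build(rxr["f"], config.library_size_f),
        pol2_m=build(pol2["m"], config.library_size_m),
        pol2_f=build(pol2["f"], config.library_size_f),
    )


def simulate_expression(config: SimulationConfig, truth: TruthTable) -> pd.DataFrame:
    """Linear-scale expression matrix (genes x replicates per condition).

    Dominant genes get a planted log2 fold change of
    log2(effect_multiplier) in the matching direction; replicates carry
    N(0, expression_sd^2) noise on the log2 scale.
    """
    rng = config.rng(_STAGE_EXPRESSION)
    n = len(truth.genes)
    base = rng.normal(config.expression_base_mean, config.expression_base_sd, n)
    delta = np.zeros(n)
    cls = truth.genes["true_class"].to_numpy()
    half_lfc = np.log2(config.effect_multiplier) / 2.0
    delta[cls == "male_dominant"] = half_lfc
    delta[cls == "female_dominant"] = -half_lfc
    reps = config.n_replicates
    log_m = base[:, None] + delta[:, None] + rng.normal(0, config.expression_sd, (n, reps))
    log_f = base[:, None] - delta[:, None] + rng.normal(0, config.expression_sd, (n, reps))
    cols = [f"M_{i + 1}" for i in range(reps)] + [f"F_{i + 1}" for i in range(reps)]
    data = np.exp2(np.hstack([log_m, log_f]))
    return pd.DataFrame(data, index=pd.Index(truth.genes["gene_id"], name="gene_id"),
                        columns=cols)


def simulate_bundle(config: SimulationConfig) -> FixtureBundle:
    """Run every generator stage and return the in-memory objects."""
    genes = generate_annotation(config)
    peaks_m, peaks_f, truth = generate_peak_landscape(config, genes)
    tracks = simulate_tracks(config, genes, truth)
    expression = simulate_expression(config, truth)
    return FixtureBundle(config, genes, peaks_m, peaks_f, truth, tracks, expression)


FIXTURE_FILES = {
    "peaks_m": "peaks_m.narrowPeak",
    "peaks_f": "peaks_f.narrowPeak",
    "rxr_m": "rxr_m.bedgraph",
    "rxr_f": "rxr_f.bedgraph",
    "pol2_m": "pol2_m.bedgraph",
    "pol2_f": "pol2_f.bedgraph",
    "genes": "genes.refflat",
    "expression": "expression.tsv",
    "truth": "truth.tsv",
    "config": "config.yaml",
}


def write_fixture_bundle(
    config: SimulationConfig,
    output_dir: str | Path,
    bundle: FixtureBundle | None = None,
) -> dict:
    """Write the full fixture bundle (10 files) plus a checksum manifest.

    Returns the manifest mapping logical names to paths and sha256
    checksums; re-running with the same seed reproduces identical files.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if bundle is None:
        bundle = simulate_bundle(config)

    gio.write_peaks(bundle.peaks_m, out / FIXTURE_FILES["peaks_m"])
    gio.write_peaks(bundle.peaks_f, out / FIXTURE_FILES["peaks_f"])
    gio.write_coverage(bundle.tracks.rxr_m, out / FIXTURE_FILES["rxr_m"])
    gio.write_coverage(bundle.tracks.rxr_f, out / FIXTURE_FILES["rxr_f"])
    gio.write_coverage(bundle.tracks.pol2_m, out / FIXTURE_FILES["pol2_m"])
    gio.write_coverage(bundle.tracks.pol2_f, out / FIXTURE_FILES["pol2_f"])
    gio.write_gene_models(bundle.genes, out / FIXTURE_FILES["genes"])
    bundle.expression.to_csv(out / FIXTURE_FILES["expression"], sep="\t")
    bundle.truth.genes.to_csv(out / FIXTURE_FILES["truth"], sep="\t", index=False)
    with open(out / FIXTURE_FILES["config"], "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    manifest = {"seed": config.seed, "files": {}}
    for key, fname in FIXTURE_FILES.items():
        path = out / fname
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][key] = {"path": fname, "sha256": digest}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig(**yaml.safe_load(fh))
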