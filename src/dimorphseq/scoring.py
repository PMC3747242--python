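"""The signed Poisson dimorphism score.

For each binding site, reads from the two conditions (male and female
liver in the motivating study) are counted in a fixed window centered on
the peak summit and compared under a Poisson model. The resulting p-value
is transformed to a signed, log-scaled score

    score = +log2(-10 * log10 p)   when condition M is stronger,
            -log2(-10 * log10 p)   when condition F is stronger,

so that |score| > 6 corresponds to p < 10^-6.4 and |score| >= 3 to
p <= 10^-0.8. Scores are stratified as High (|score| > 6),
Medium (3 <= |score| <= 6) or Low (|score| < 3).

The same machinery applied to Pol2 reads summed over a gene's TSS-to-TES
span yields a per-gene transcription score; a gene is called
male-dominant when it carries at least one binding-site score above the
High threshold AND its Pol2 score is above the threshold (female-dominant
is the mirror image with both below the negated threshold).

Two variants of the two-sample Poisson comparison are provided:

* ``conditional_binomial`` (default) — the exact conditional test: given
  the total n = k_a + k_b, k_a is Binomial(n, norm_a/(norm_a+norm_b))
  under the null of equal rates, and the one-sided tail in the direction
  of the observed excess is reported. This variant is well calibrated:
  under a null of equal rates the chance of |score| > 6 is ~2e-7.
* ``poisson_tail`` — the larger count is tested as an upper tail of a
  Poisson whose rate is the smaller count rescaled to the larger side's
  library size (floored at ``lambda_min`` so a (k, 0) pair stays finite).
  Conditioning on the smaller observed count as if it were the true rate
  makes this variant anticonservative (opposite-direction fluctuations
  are double-counted), so it is exposed as an interpretation of the
  historical procedure rather than used as the default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import CoverageTrack, GenomicInterval, GeneModel, Peak

logger = logging.getLogger(__name__)

STRATA = ("High", "Medium", "Low")
TEST_METHODS = ("poisson_tail", "conditional_binomial")


@dataclass
class ScoreConfig:
    """Parameters of the dimorphism score.

    window: width (bp) of the summit-centered counting window.
    high_threshold / medium_threshold: |score| boundaries of the High and
        Medium strata.
    test_method: which two-sample Poisson comparison to use.
    p_floor: smallest representable p-value (caps |score| at
        log2(3000) ~ 11.55 for the default 1e-300).
    lambda_min: rate floor for poisson_tail when the smaller count is 0.
    """

    window: int = 300
    high_threshold: float = 6.0
    medium_threshold: float = 3.0
    test_method: str = "conditional_binomial"
    p_floor: float = 1e-300
    lambda_min: float = 1.0

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2:
            raise ValueError("window must be even and positive")
        if not (0 < self.medium_threshold < self.high_threshold):
            raise ValueError("need 0 < medium_threshold < high_threshold")
        if self.test_method not in TEST_METHODS:
            raise ValueError(f"unknown test method {self.test_method!r}")
        if not (0 < self.p_floor < 1):
            raise ValueError("p_floor must be in (0, 1)")


@dataclass(frozen=True)
class ScoredPeak:
    peak: Peak
    count_m: int
    count_f: int
    norm_m: float
    norm_f: float
    p_value: float
    score: float
    stratum: str

    @property
    def name(self) -> str:
        return self.peak.name


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    count_m: int
    count_f: int
    p_value: float
    score: float


@dataclass(frozen=True)
class DimorphismCall:
    gene_id: str
    call: str  # "male_dominant" | "female_dominant" | "none"
    supporting_peaks: tuple[str, ...]
    best_peak_score: float
    pol2_score: float


def summit_window(peak: Peak, window: int = 300) -> GenomicInterval:
    """The window-bp interval centered on the peak summit, clipped at 0."""
    if window % 2:
        raise ValueError("window must be even")
    half = window // 2
    start = max(0, peak.summit - half)
    return GenomicInterval(peak.chrom, start, peak.summit + half)


def _direction(k_a, k_b, norm_a, norm_b):
    """+1 if a's normalized rate exceeds b's, -1 if smaller, 0 on tie."""
    ra = np.asarray(k_a, dtype=float) / norm_a
    rb = np.asarray(k_b, dtype=float) / norm_b
    return np.sign(ra - rb)


def poisson_difference_pvalues(
    k_a,
    k_b,
    norm_a: float = 1.0,
    norm_b: float = 1.0,
    method: str = "conditional_binomial",
    p_floor: float = 1e-300,
    lambda_min: float = 1.0,
) -> np.ndarray:
    """Vectorized two-sample Poisson difference p-values (see module doc)."""
    k_a = np.asarray(k_a)
    k_b = np.asarray(k_b)
    if not (
        np.issubdtype(k_a.dtype, np.integer)
        or np.all(np.equal(np.mod(k_a, 1), 0))
    ) or not (
        np.issubdtype(k_b.dtype, np.integer)
        or np.all(np.equal(np.mod(k_b, 1), 0))
    ):
        raise ValueError("counts must be integers")
    if np.any(k_a < 0) or np.any(k_b < 0):
        raise ValueError("counts must be non-negative")
    if norm_a <= 0 or norm_b <= 0:
        raise ValueError("normalizers must be positive")
    ka = k_a.astype(np.int64)
    kb = k_b.astype(np.int64)
    sign = _direction(ka, kb, norm_a, norm_b)

    if method == "poisson_tail":
        a_is_max = sign >= 0
        k_max = np.where(a_is_max, ka, kb)
        k_min = np.where(a_is_max, kb, ka)
        # rescale the smaller-rate count into the larger side's library
        ratio = np.where(a_is_max, norm_a / norm_b, norm_b / norm_a)
        lam = np.maximum(k_min * ratio, lambda_min)
        p = stats.poisson.sf(k_max - 1, lam)
        p = np.where((ka == 0) & (kb == 0), 1.0, p)
    elif method == "conditional_binomial":
        n = ka + kb
        pa = norm_a / (norm_a + norm_b)
        upper = stats.binom.sf(ka - 1, n, pa)
        lower = stats.binom.cdf(ka, n, pa)
        p = np.where(sign >= 0, upper, lower)
        p = np.where(n == 0, 1.0, p)
    else:
        raise ValueError(f"unknown test method {method!r}")
    return np.clip(p, p_floor, 1.0)


def poisson_difference_pvalue(
    k_a: int,
    k_b: int,
    norm_a: float = 1.0,
    norm_b: float = 1.0,
    method: str = "conditional_binomial",
    p_floor: float = 1e-300,
    lambda_min: float = 1.0,
) -> float:
    """Scalar convenience wrapper around :func:`poisson_difference_pvalues`."""
    return float(
        poisson_difference_pvalues(
            [k_a], [k_b], norm_a, norm_b, method, p_floor, lambda_min
        )[0]
    )


def signed_score(p: float, direction: str) -> float:
    """Signed log-scaled p-value: +/- log2(-10*log10 p).

    direction is "a_stronger", "b_stronger" or "none". The score is
    clamped to 0 when -10*log10(p) <= 1 (p >= 10^-0.1) or when there is
    no direction, keeping log2 defined.
    """
    if not (0 < p <= 1):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if direction not in {"a_stronger", "b_stronger", "none"}:
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "none":
        return 0.0
    q = -10.0 * math.log10(p)
    if q <= 1.0:
        return 0.0
    mag = math.log2(q)
    return mag if direction == "a_stronger" else -mag


def signed_scores(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Vectorized :func:`signed_score`; *sign* in {-1, 0, +1}."""
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        q = -10.0 * np.log10(p)
    mag = np.where(q > 1.0, np.log2(np.maximum(q, 1.0)), 0.0)
    return mag * np.asarray(sign, dtype=float)


def stratify(score: float, config: ScoreConfig | None = None) -> str:
    """High (|s| > 6), Medium (3 <= |s| <= 6) or Low (|s| < 3); both
    boundaries belong to Medium."""
    cfg = config or ScoreConfig()
    s = abs(score)
    if s > cfg.high_threshold:
        return "High"
    if s >= cfg.medium_threshold:
        return "Medium"
    return "Low"


def _score_counts(
    counts_m: np.ndarray,
    counts_f: np.ndarray,
    norm_m: float,
    norm_f: float,
    config: ScoreConfig,
) -> tuple[np.ndarray, np.ndarray]:
    p = poisson_difference_pvalues(
        counts_m,
        counts_f,
        norm_m,
        norm_f,
        method=config.test_method,
        p_floor=config.p_floor,
        lambda_min=config.lambda_min,
    )
    sign = _direction(counts_m, counts_f, norm_m, norm_f)
    return p, signed_scores(p, sign)


def score_peaks(
    peaks: Sequence[Peak],
    track_m: CoverageTrack,
    track_f: CoverageTrack,
    config: ScoreConfig | None = None,
    norm_m: float | None = None,
    norm_f: float | None = None,
) -> list[ScoredPeak]:
    """Score every peak: window counts in both conditions, Poisson p,
    signed score (positive = condition M stronger) and stratum.

    Normalizers default to the tracks' library sizes. A peak on a
    chromosome absent from a track counts 0 there (warned once per
    chromosome).
    """
    cfg = config or ScoreConfig()
    nm = track_m.library_size if norm_m is None else norm_m
    nf = track_f.library_size if norm_f is None else norm_f
    warned: set[str] = set()
    counts_m = np.zeros(len(peaks), dtype=np.int64)
    counts_f = np.zeros(len(peaks), dtype=np.int64)
    for i, p in enumerate(peaks):
        win = summit_window(p, cfg.window)
        for track, counts in ((track_m, counts_m), (track_f, counts_f)):
            if p.chrom not in track.chroms and p.chrom not in warned:
                logger.warning("peak chromosome %s absent from track", p.chrom)
                warned.add(p.chrom)
            counts[i] = int(round(track.window_sum(win.chrom, win.start, win.end)))
    pvals, scores = _score_counts(counts_m, counts_f, nm, nf, cfg)
    return [
        ScoredPeak(
            peak=p,
            count_m=int(cm),
            count_f=int(cf),
            norm_m=nm,
            norm_f=nf,
            p_value=float(pv),
            score=float(sc),
            stratum=stratify(float(sc), cfg),
        )
        for p, cm, cf, pv, sc in zip(peaks, counts_m, counts_f, pvals, scores)
    ]


def score_genes_pol2(
    genes: Sequence[GeneModel],
    track_m: CoverageTrack,
    track_f: CoverageTrack,
    config: ScoreConfig | None = None,
    norm_m: float | None = None,
    norm_f: float | None = None,
) -> list[GeneScore]:
    """Per-gene Pol2 score: reads counted over the genomic span between
    TSS and TES (strand-agnostic), compared with the same Poisson score
    machinery as the binding sites."""
    cfg = config or ScoreConfig()
    nm = track_m.library_size if norm_m is None else norm_m
    nf = track_f.library_size if norm_f is None else norm_f
    counts_m = np.zeros(len(genes), dtype=np.int64)
    counts_f = np.zeros(len(genes), dtype=np.int64)
    for i, g in enumerate(genes):
        counts_m[i] = int(round(track_m.window_sum(g.chrom, g.span_start, g.span_end)))
        counts_f[i] = int(round(track_f.window_sum(g.chrom, g.span_start, g.span_end)))
    pvals, scores = _score_counts(counts_m, counts_f, nm, nf, cfg)
    return [
        GeneScore(g.gene_id, int(cm), int(cf), float(pv), float(sc))
        for g, cm, cf, pv, sc in zip(genes, counts_m, counts_f, pvals, scores)
    ]


def call_dimorphic_genes(
    scored_peaks: Sequence[ScoredPeak],
    peak_to_gene: Mapping[str, Iterable[str]],
    gene_scores: Sequence[GeneScore],
    config: ScoreConfig | None = None,
) -> list[DimorphismCall]:
    """Combine binding-site and Pol2 scores into per-gene dominance calls.

    male_dominant: at least one assigned peak with score > high_threshold
    AND gene Pol2 score > high_threshold. female_dominant is the mirrored
    rule with both below -high_threshold. Everything else is "none".
    A gene referenced by peaks but missing a Pol2 score is "none" (logged).
    """
    cfg = config or ScoreConfig()
    thr = cfg.high_threshold
    pol2 = {gs.gene_id: gs.score for gs in gene_scores}
    gene_peaks: dict[str, list[ScoredPeak]] = {}
    for sp in scored_peaks:
        for gid in peak_to_gene.get(sp.name, ()):
            gene_peaks.setdefault(gid, []).append(sp)
    calls = []
    for gid in sorted(set(gene_peaks) | set(pol2)):
        peaks_here = gene_peaks.get(gid, [])
        if gid not in pol2:
            if peaks_here:
                logger.warning("gene %s has peaks but no Pol2 score", gid)
            calls.append(DimorphismCall(gid, "none", (), _best(peaks_here), math.nan))
            continue
        p2 = pol2[gid]
        male_support = tuple(sp.name for sp in peaks_here if sp.score > thr)
        female_support = tuple(sp.name for sp in peaks_here if sp.score < -thr)
        if male_support and p2 > thr:
            call, support = "male_dominant", male_support
        elif female_support and p2 < -thr:
            call, support = "female_dominant", female_support
        else:
            call, support = "none", ()
        calls.append(DimorphismCall(gid, call, support, _best(peaks_here), p2))
    return calls


def _best(peaks: Sequence[ScoredPeak]) -> float:
    """The score of largest magnitude among the gene's peaks (0 if none)."""
    if not peaks:
        return 0.0
    return max((sp.score for sp in peaks), key=abs)
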