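"""Interval comparisons and peak annotation.

Implements the common/unique peak classification (two condition peak sets,
common = sharing at least ``min_overlap`` bases with a peak of the other
set), summit-based feature-class annotation with precedence
TSS > TES > exon > intron > intergenic, peak-to-gene assignment (nearest
TSS or a strand-oriented window around the TSS), observed-vs-expected
category tests, and peak-height stratification.
"""

from __future__ import annotations

import bisect
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval, Peak

FEATURE_CLASSES = ("TSS", "TES", "exon", "intron", "intergenic")


@dataclass
class OverlapClassification:
    """Partition of two peak sets into common and unique peaks."""

    common_a: list[Peak]
    unique_a: list[Peak]
    common_b: list[Peak]
    unique_b: list[Peak]

    def summary(self) -> dict[str, int]:
        return {
            "common_a": len(self.common_a),
            "unique_a": len(self.unique_a),
            "common_b": len(self.common_b),
            "unique_b": len(self.unique_b),
        }


@dataclass(frozen=True)
class FeatureAnnotation:
    peak_name: str
    feature_class: str
    gene_id: str | None


@dataclass(frozen=True)
class DistributionTest:
    category: str
    observed: int
    expected: float
    p_value: float
    direction: str  # "enriched" | "depleted"


def _peak_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.chrom].addi(p.start, p.end, p)
    return trees


def _is_common(peak: Peak, trees: Mapping[str, IntervalTree], min_overlap: int) -> bool:
    tree = trees.get(peak.chrom)
    if tree is None:
        return False
    for hit in tree.overlap(peak.start, peak.end):
        if min(hit.end, peak.end) - max(hit.begin, peak.start) >= min_overlap:
            return True
    return False


def classify_overlap(
    peaks_a: Sequence[Peak], peaks_b: Sequence[Peak], min_overlap: int = 1
) -> OverlapClassification:
    """Classify each peak as common (overlapping >= min_overlap bases with
    any peak of the other set) or unique. Intervals are half-open, so
    bookended peaks ([100,200) vs [200,300)) share zero bases."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees_a = _peak_trees(peaks_a)
    trees_b = _peak_trees(peaks_b)
    common_a, unique_a, common_b, unique_b = [], [], [], []
    for p in peaks_a:
        (common_a if _is_common(p, trees_b, min_overlap) else unique_a).append(p)
    for p in peaks_b:
        (common_b if _is_common(p, trees_a, min_overlap) else unique_b).append(p)
    return OverlapClassification(common_a, unique_a, common_b, unique_b)


class GeneIndex:
    """Per-chromosome lookup structures over a set of gene models."""

    def __init__(self, genes: Sequence[GeneModel]) -> None:
        self.genes = list(genes)
        self.span_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.exon_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._tss: dict[str, list[tuple[int, str]]] = defaultdict(list)
        self._by_id: dict[str, GeneModel] = {}
        for g in genes:
            self.span_trees[g.chrom].addi(g.span_start, g.span_end, g)
            for ex in g.exons:
                self.exon_trees[g.chrom].addi(ex.start, ex.end, g)
            self._tss[g.chrom].append((g.tss, g.gene_id))
            self._by_id[g.gene_id] = g
        for chrom in self._tss:
            self._tss[chrom].sort()

    def __len__(self) -> int:
        return len(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def genes_near_tss(self, chrom: str, lo: int, hi: int) -> list[GeneModel]:
        """Genes whose TSS lies in [lo, hi] on *chrom*."""
        entries = self._tss.get(chrom, [])
        i = bisect.bisect_left(entries, (lo, ""))
        j = bisect.bisect_right(entries, (hi, "\U0010ffff"))
        return [self._by_id[gid] for _, gid in entries[i:j]]

    def nearest_tss(self, chrom: str, pos: int) -> GeneModel | None:
        """Gene with minimum |pos - tss|; ties to the smaller gene_id."""
        entries = self._tss.get(chrom)
        if not entries:
            return None
        i = bisect.bisect_left(entries, (pos, ""))
        best: tuple[int, str] | None = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(entries):
                tss, gid = entries[j]
                cand = (abs(pos - tss), gid)
                if best is None or cand < best:
                    best = cand
        # neighbors at equal tss need a full local scan for the id tie-break
        if best is not None:
            dist = best[0]
            lo = bisect.bisect_left(entries, (pos - dist, ""))
            hi = bisect.bisect_right(entries, (pos + dist, "\U0010ffff"))
            for tss, gid in entries[lo:hi]:
                cand = (abs(pos - tss), gid)
                if cand < best:
                    best = cand
            return self._by_id[best[1]]
        return None


def annotate_feature(
    peak: Peak,
    genes: Sequence[GeneModel] | GeneIndex,
    tss_window: int = 500,
    tes_window: int = 500,
) -> FeatureAnnotation:
    """Assign the peak's summit a single feature class.

    Precedence TSS > TES > exon > intron > intergenic; TSS means the
    summit lies within ``tss_window`` bp of a gene's TSS (TES analogous),
    exon/intron from the gene model containing the summit.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    s = peak.summit
    hits_tss: list[str] = []
    hits_tes: list[str] = []
    hits_exon: list[str] = []
    hits_intron: list[str] = []
    for hit in index.span_trees.get(peak.chrom, IntervalTree()).overlap(
        s - max(tss_window, tes_window), s + max(tss_window, tes_window) + 1
    ):
        g: GeneModel = hit.data
        if abs(s - g.tss) <= tss_window:
            hits_tss.append(g.gene_id)
        if abs(s - g.tes) <= tes_window:
            hits_tes.append(g.gene_id)
        if g.span_start <= s < g.span_end:
            if any(ex.start <= s < ex.end for ex in g.exons):
                hits_exon.append(g.gene_id)
            else:
                hits_intron.append(g.gene_id)
    for cls, hits in (
        ("TSS", hits_tss),
        ("TES", hits_tes),
        ("exon", hits_exon),
        ("intron", hits_intron),
    ):
        if hits:
            return FeatureAnnotation(peak.name, cls, min(hits))
    return FeatureAnnotation(peak.name, "intergenic", None)


def annotate_features(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | GeneIndex,
    tss_window: int = 500,
    tes_window: int = 500,
) -> list[FeatureAnnotation]:
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    return [annotate_feature(p, index, tss_window, tes_window) for p in peaks]


def assign_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel] | GeneIndex,
    mode: str = "tss_window",
    up: int = 10000,
    down: int = 10000,
) -> dict[str, set[str]]:
    """Map each peak name to the set of genes it is assigned to.

    mode="nearest_tss": the single gene with minimum |summit - TSS|
    (ties broken by gene_id). mode="tss_window": every gene whose TSS
    lies within ``up`` bp upstream to ``down`` bp downstream of the
    summit in the gene's strand orientation, boundaries inclusive.
    """
    if mode not in {"nearest_tss", "tss_window"}:
        raise ValueError(f"unknown assignment mode {mode!r}")
    if up < 0 or down < 0:
        raise ValueError("up/down must be >= 0")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    if len(index) == 0:
        raise ValueError("empty gene list")
    out: dict[str, set[str]] = {}
    if mode == "nearest_tss":
        for p in peaks:
            g = index.nearest_tss(p.chrom, p.summit)
            out[p.name] = {g.gene_id} if g is not None else set()
        return out
    reach = max(up, down)
    for p in peaks:
        assigned: set[str] = set()
        for g in index.genes_near_tss(p.chrom, p.summit - reach, p.summit + reach):
            if g.strand == "+":
                lo, hi = g.tss - up, g.tss + down
            else:
                lo, hi = g.tss - down, g.tss + up
            if lo <= p.summit <= hi:
                assigned.add(g.gene_id)
        out[p.name] = assigned
    return out


def distribution_test(
    observed: Sequence[Peak] | Mapping[str, int],
    categories: Mapping[str, float],
    genome_length: float,
) -> list[DistributionTest]:
    """Observed vs expected peak counts per category (chromosome or
    feature class) under a uniform-placement null.

    expected_c = N * length_c / genome_length; exact two-sided binomial p.
    If *observed* is a peak list, peaks are tallied by chromosome.
    """
    if isinstance(observed, Mapping):
        counts: Mapping[str, int] = dict(observed)
    else:
        tally: dict[str, int] = defaultdict(int)
        for p in observed:
            tally[p.chrom] += 1
        counts = tally
    total = sum(counts.get(c, 0) for c in categories)
    if total <= 0:
        raise ValueError("no peaks to test")
    if sum(categories.values()) > genome_length * (1 + 1e-9):
        raise ValueError("category lengths exceed genome length")
    out = []
    for cat, length in categories.items():
        if length <= 0:
            raise ValueError(f"zero-length category {cat!r}")
        frac = length / genome_length
        obs = counts.get(cat, 0)
        expected = total * frac
        p = stats.binomtest(obs, total, frac, alternative="two-sided").pvalue
        direction = "enriched" if obs >= expected else "depleted"
        out.append(DistributionTest(cat, obs, expected, float(p), direction))
    return out


def stratify_peak_heights(
    peaks: Sequence[Peak], bin_edges: Sequence[float]
) -> list[int]:
    """Count peaks per height bin: right-open bins below each edge plus an
    overflow bin at/above the last edge. len(result) == len(bin_edges)+1."""
    edges = list(bin_edges)
    if any(b >= a for b, a in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing")
    counts = [0] * (len(edges) + 1)
    for p in peaks:
        counts[bisect.bisect_right(edges, p.height)] += 1
    return counts
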