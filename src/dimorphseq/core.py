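"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout ([start, end)), the BED
convention. Formats that use other conventions (UCSC wiggle is 1-based)
are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        """Number of shared bases with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called binding site: interval plus summit and height.

    ``summit`` is an absolute 0-based position inside the interval;
    ``height`` is the read count at the summit (or the caller's signal
    value standing in for it).
    """

    interval: GenomicInterval
    name: str
    summit: int
    height: float

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end}) for {self.name}"
            )
        if self.height < 0:
            raise ValueError(f"height must be >= 0, got {self.height}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass(frozen=True)
class ReadPosition:
    """The 5' position of a single aligned read."""

    chrom: str
    pos: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene model with strand-aware TSS/TES.

    ``tss`` is always the biological transcription start: for minus-strand
    genes it is the larger genomic coordinate (``txEnd - 1`` in refFlat
    terms) and ``tes`` the smaller.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss <= tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss >= tes")
        prev_end = -1
        for ex in self.exons:
            if ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def span_start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def span_end(self) -> int:
        """Half-open end of the genomic span covered by the gene."""
        return max(self.tss, self.tes) + 1

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.span_start, self.span_end, self.strand)


class CoverageTrack:
    """Per-base read coverage for one condition, queryable by window.

    Internally a sorted, non-overlapping set of (start, end, value)
    runs per chromosome. Two construction modes:

    * point-read tracks (:meth:`from_reads`): each read contributes 1 at
      its 5' position, so a window sum is an exact read count;
    * run-length coverage (:meth:`from_runs`): arbitrary non-negative
      per-base values, as parsed from wiggle/bedGraph.

    ``library_size`` is the total mapped-read normalizer used when two
    conditions are compared.
    """

    def __init__(
        self,
        runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        library_size: float,
    ) -> None:
        if library_size <= 0:
            raise ValueError("library_size must be positive")
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, vals) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            vals = np.asarray(vals, dtype=np.float64)
            if np.any(vals < 0):
                raise ValueError(f"negative coverage value on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, vals = starts[order], ends[order], vals[order]
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping coverage runs on {chrom}")
            self._runs[chrom] = (starts, ends, vals)
        self.library_size = float(library_size)

    @classmethod
    def from_runs(
        cls,
        runs: Iterable[tuple[str, int, int, float]],
        library_size: float | None = None,
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) runs, 0-based half-open."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        total = 0.0
        for chrom, start, end, value in runs:
            per_chrom.setdefault(chrom, []).append((start, end, value))
            total += value * (end - start)
        packed = {
            chrom: (
                np.array([r[0] for r in rs]),
                np.array([r[1] for r in rs]),
                np.array([r[2] for r in rs]),
            )
            for chrom, rs in per_chrom.items()
        }
        if library_size is None:
            library_size = total if total > 0 else 1.0
        return cls(packed, library_size)

    @classmethod
    def from_reads(
        cls,
        reads: Iterable[ReadPosition],
        library_size: float | None = None,
    ) -> "CoverageTrack":
        """Point-read track: value at a base = number of read 5' ends there."""
        counts: dict[str, dict[int, int]] = {}
        n = 0
        for read in reads:
            counts.setdefault(read.chrom, {}).setdefault(read.pos, 0)
            counts[read.chrom][read.pos] += 1
            n += 1
        runs = [
            (chrom, pos, pos + 1, float(c))
            for chrom, per_pos in counts.items()
            for pos, c in sorted(per_pos.items())
        ]
        if library_size is None:
            library_size = float(n) if n else 1.0
        return cls.from_runs(runs, library_size)

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(self._runs)

    def point(self, chrom: str, pos: int) -> float:
        """Coverage value at a single base (0 outside covered regions)."""
        return self.window_sum(chrom, pos, pos + 1)

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if chrom not in self._runs or end <= start:
            return 0.0
        starts, ends, vals = self._runs[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        return float(np.dot(vals[lo:hi], ov))

    def window_sums(self, intervals: Sequence[GenomicInterval]) -> np.ndarray:
        return np.array(
            [self.window_sum(iv.chrom, iv.start, iv.end) for iv in intervals]
        )

    def total(self) -> float:
        return float(
            sum(np.dot(v, e - s) for s, e, v in self._runs.values())
        )

    def iter_runs(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in sorted(self._runs):
            starts, ends, vals = self._runs[chrom]
            for s, e, v in zip(starts, ends, vals):
                yield chrom, int(s), int(e), float(v)
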