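"""Readers and writers for the text formats the pipeline touches.

Supported: ENCODE narrowPeak (BED6+4) and BED6-with-summit peak files,
refFlat gene tables, UCSC wiggle (fixedStep/variableStep) and bedGraph
coverage, plus the PCR-duplicate read filter. All readers accept plain or
gzip-compressed files and return objects in 0-based half-open coordinates.
"""

from __future__ import annotations

import gzip
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .core import CoverageTrack, GenomicInterval, GeneModel, Peak, ReadPosition


class FormatError(ValueError):
    """A malformed record in an input file."""


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _unique_names(names: Sequence[str]) -> list[str]:
    """Disambiguate duplicate names by suffixing .2, .3, ... in input order."""
    seen: Counter[str] = Counter()
    out = []
    for name in names:
        seen[name] += 1
        out.append(name if seen[name] == 1 else f"{name}.{seen[name]}")
    return out


# ---------------------------------------------------------------------------
# Peaks


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> list[Peak]:
    """Read peak calls.

    dialect="narrowPeak": 10 columns; height from the signalValue column,
    summit from the summit-offset column (-1 means interval midpoint).
    dialect="bed_summit": BED6; the score column is the height and the
    summit is the interval midpoint.

    Peaks are returned sorted by (chrom, start); duplicate names are made
    unique by suffixing.
    """
    if dialect not in {"narrowPeak", "bed_summit"}:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    records: list[tuple[str, int, int, str, int, float]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                if dialect == "narrowPeak":
                    if len(fields) < 10:
                        raise FormatError("expected 10 narrowPeak columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3]
                    height = float(fields[6])
                    offset = int(fields[9])
                    if offset == -1:
                        summit = (start + end) // 2
                    else:
                        summit = start + offset
                else:
                    if len(fields) < 6:
                        raise FormatError("expected 6 BED columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3]
                    height = float(fields[4])
                    summit = (start + end) // 2
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: malformed line {lineno}: {exc}") from exc
            if not (start <= summit < end):
                raise FormatError(
                    f"{path}: line {lineno}: summit {summit} outside "
                    f"[{start}, {end})"
                )
            records.append((chrom, start, end, name, summit, height))
    records.sort(key=lambda r: (r[0], r[1]))
    names = _unique_names([r[3] for r in records])
    return [
        Peak(GenomicInterval(chrom, start, end), name, summit, height)
        for (chrom, start, end, _, summit, height), name in zip(records, names)
    ]


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as narrowPeak; round-trips coordinates, summits, heights."""
    with _open_text(path, "wt") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        "0",
                        ".",
                        repr(float(p.height)),
                        "-1",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat-style gene table.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds. The biological TSS is txStart
    for + strand genes and txEnd-1 for - strand genes.
    """
    genes: list[GeneModel] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"{path}: line {lineno}: expected 11 refFlat columns"
                )
            gene_id, _name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            tx_start, tx_end = int(fields[4]), int(fields[5])
            exon_count = int(fields[8])
            exon_starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
            exon_ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            if len(exon_starts) != exon_count or len(exon_ends) != exon_count:
                raise FormatError(
                    f"{path}: line {lineno}: exonCount {exon_count} does not "
                    f"match exon lists ({len(exon_starts)}/{len(exon_ends)})"
                )
            exons = tuple(
                GenomicInterval(chrom, s, e, strand)
                for s, e in zip(exon_starts, exon_ends)
            )
            if strand == "+":
                tss, tes = tx_start, tx_end - 1
            else:
                tss, tes = tx_end - 1, tx_start
            genes.append(GeneModel(gene_id, chrom, strand, tss, tes, exons))
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            tx_start, tx_end = g.span_start, g.span_end
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.gene_id,
                        g.chrom,
                        g.strand,
                        str(tx_start),
                        str(tx_end),
                        str(tx_start),
                        str(tx_end),
                        str(len(g.exons)),
                        ",".join(str(e.start) for e in g.exons) + ",",
                        ",".join(str(e.end) for e in g.exons) + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Coverage


def _parse_wiggle(fh) -> Iterator[tuple[str, int, int, float]]:
    """Yield 0-based half-open runs from a UCSC wiggle stream.

    Wiggle declarations use 1-based start coordinates; runs are converted
    to the internal 0-based half-open convention here.
    """
    mode = None
    chrom = None
    start = step = span = 1
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        if line.startswith("fixedStep"):
            params = dict(kv.split("=") for kv in line.split()[1:])
            mode = "fixed"
            chrom = params["chrom"]
            start = int(params["start"]) - 1
            step = int(params.get("step", 1))
            span = int(params.get("span", 1))
            continue
        if line.startswith("variableStep"):
            params = dict(kv.split("=") for kv in line.split()[1:])
            mode = "variable"
            chrom = params["chrom"]
            span = int(params.get("span", 1))
            continue
        if mode is None:
            raise FormatError(f"line {lineno}: data before track declaration")
        if mode == "fixed":
            value = float(line)
            if value < 0:
                raise FormatError(f"line {lineno}: negative coverage value")
            yield chrom, start, start + span, value
            start += step
        else:
            pos_s, val_s = line.split()
            pos = int(pos_s) - 1
            value = float(val_s)
            if value < 0:
                raise FormatError(f"line {lineno}: negative coverage value")
            yield chrom, pos, pos + span, value


def _parse_bedgraph(fh) -> Iterator[tuple[str, int, int, float]]:
    for lineno, line in enumerate(fh, start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) != 4:
            raise FormatError(f"line {lineno}: expected 4 bedGraph columns")
        value = float(fields[3])
        if value < 0:
            raise FormatError(f"line {lineno}: negative coverage value")
        yield fields[0], int(fields[1]), int(fields[2]), value


def read_coverage(
    path: str | Path,
    format: str = "bedGraph",
    library_size: float | None = None,
) -> CoverageTrack:
    """Read a coverage track (wiggle or bedGraph) into a CoverageTrack.

    If library_size is None it defaults to the track's total signal.
    """
    if format not in {"wiggle", "bedGraph"}:
        raise ValueError(f"unknown coverage format {format!r}")
    parser = _parse_wiggle if format == "wiggle" else _parse_bedgraph
    with _open_text(path) as fh:
        try:
            runs = list(parser(fh))
        except FormatError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return CoverageTrack.from_runs(runs, library_size)


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph (zero runs omitted)."""
    with _open_text(path, "wt") as fh:
        for chrom, start, end, value in track.iter_runs():
            if value != 0:
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def count_in_window(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Sum of per-base coverage over the interval.

    On a point-read track (reads collapsed to their 5' base) this is
    exactly the number of reads whose 5' end falls in the window; on a
    run-length coverage track it is the raw coverage sum.
    """
    return track.window_sum(interval.chrom, interval.start, interval.end)


# ---------------------------------------------------------------------------
# Reads


def read_positions(path: str | Path) -> list[ReadPosition]:
    """Read 5' read positions from a BED6-style file (start used as 5' pos)."""
    reads = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected BED6")
            chrom, start, strand = fields[0], int(fields[1]), fields[5]
            end = int(fields[2])
            pos = start if strand == "+" else end - 1
            reads.append(ReadPosition(chrom, pos, strand))
    return reads


def deduplicate_reads(
    reads: Iterable[ReadPosition], max_per_position: int = 2
) -> list[ReadPosition]:
    """Drop PCR duplicates: keep at most *max_per_position* reads per
    (chrom, 5' position, strand) key, preserving input order.

    The default of 2 discards reads appearing more than twice at the same
    position on the same strand.
    """
    if max_per_position < 1:
        raise ValueError("max_per_position must be >= 1")
    seen: Counter[tuple[str, int, str]] = Counter()
    kept = []
    for read in reads:
        key = (read.chrom, read.pos, read.strand)
        seen[key] += 1
        if seen[key] <= max_per_position:
            kept.append(read)
    return kept
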