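"""Genomic data types and readers/writers for BED, narrowPeak and minimal GTF.

All coordinates are 0-based half-open internally (the BED convention).
GTF input (1-based closed) is converted at the parser boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

__all__ = [
    "FormatError",
    "GenomicInterval",
    "Peak",
    "GeneModel",
    "read_bed",
    "read_narrowpeak",
    "write_bed",
    "read_genes",
    "peak_center",
]

Strand = Literal["+", "-", "."]

_HEADER_PREFIXES = ("track", "browser", "#")


class FormatError(ValueError):
    """A malformed record in a genomic text file; the message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A called ChIP-seq peak: an interval plus optional score and summit.

    ``summit_offset`` is the bp offset of the summit from ``start``
    (narrowPeak column 10); ``None`` when absent (-1 in the file).
    """

    interval: GenomicInterval
    name: str = ""
    score: float | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} out of range for "
                f"{len(self.interval)} bp peak {self.name!r}"
            )

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
class GeneModel:
    """A gene with strand-aware TSS/TES and exon/UTR substructure.

    ``cds_start``/``cds_end`` are half-open coding bounds; both ``None``
    for non-coding genes. Exons must be sorted, non-overlapping, and lie
    within the gene interval.
    """

    gene_id: str
    name: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.gene_id}: exon outside gene bounds")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"gene {self.gene_id}: cds bounds must come in pairs")
        if self.cds_start is not None:
            if not (
                self.interval.start <= self.cds_start < self.cds_end <= self.interval.end
            ):
                raise ValueError(f"gene {self.gene_id}: cds bounds outside gene interval")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        """Transcription start site (base coordinate, strand-aware)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site (base coordinate, strand-aware)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_HEADER_PREFIXES):
                continue
            yield lineno, line.split("\t")


def _parse_coords(fields: list[str], lineno: int) -> tuple[str, int, int]:
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer coordinate") from exc
    if not (0 <= start < end):
        raise FormatError(f"line {lineno}: require 0 <= start < end, got {start}..{end}")
    return chrom, start, end


def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3+ file into Peaks, skipping track/browser/# header lines.

    Input order is preserved. Raises :class:`FormatError` naming the line
    number on a malformed record.
    """
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"line {lineno}: fewer than 3 tab-separated fields")
        chrom, start, end = _parse_coords(fields, lineno)
        name = fields[3] if len(fields) > 3 else ""
        score: float | None = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric score") from exc
        strand: Strand = "."
        if len(fields) > 5 and fields[5] in ("+", "-"):
            strand = fields[5]  # type: ignore[assignment]
        peaks.append(
            Peak(GenomicInterval(chrom, start, end, strand), name=name, score=score)
        )
    return peaks


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (10-column) file into Peaks.

    Column 10 is the summit offset from start; the file sentinel -1 maps
    to ``summit_offset=None``.
    """
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 10:
            raise FormatError(
                f"line {lineno}: narrowPeak requires 10 columns, got {len(fields)}"
            )
        chrom, start, end = _parse_coords(fields, lineno)
        name = fields[3]
        score = float(fields[4]) if fields[4] not in (".", "") else None
        strand: Strand = fields[5] if fields[5] in ("+", "-") else "."  # type: ignore[assignment]
        try:
            summit = int(fields[9])
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer summit offset") from exc
        summit_offset = None if summit == -1 else summit
        if summit_offset is not None and not (0 <= summit_offset < end - start):
            raise FormatError(
                f"line {lineno}: summit offset {summit_offset} outside "
                f"{end - start} bp peak"
            )
        peaks.append(
            Peak(
                GenomicInterval(chrom, start, end, strand),
                name=name,
                score=score,
                summit_offset=summit_offset,
            )
        )
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as BED, preserving order.

    Round-trip contract: ``read_bed`` on the output reproduces
    (chrom, start, end, name) for every peak.
    """
    with open(path, "w") as fh:
        for p in peaks:
            cols = [p.chrom, str(p.start), str(p.end)]
            if p.name or p.score is not None or p.interval.strand != ".":
                cols.append(p.name if p.name else ".")
            if p.score is not None or p.interval.strand != ".":
                cols.append(str(p.score) if p.score is not None else ".")
            if p.interval.strand != ".":
                cols.append(p.interval.strand)
            fh.write("\t".join(cols) + "\n")


def peak_center(peak: Peak, mode: str = "midpoint") -> int:
    """Return the peak's center base.

    midpoint mode: floor((start + end - 1) / 2), the middle base of the
    closed base span. summit mode: start + summit_offset when a summit is
    recorded, falling back to the midpoint otherwise.
    """
    if mode == "summit" and peak.summit_offset is not None:
        return peak.start + peak.summit_offset
    if mode not in ("midpoint", "summit"):
        raise ValueError(f"unknown center mode {mode!r}")
    return (peak.start + peak.end - 1) // 2


# ---------------------------------------------------------------------------
# gene models: BED12 and minimal GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, f in _data_lines(path):
        if len(f) < 12:
            raise FormatError(f"line {lineno}: BED12 requires 12 columns")
        chrom, start, end = _parse_coords(f, lineno)
        gene_id = f[3]
        if f[5] not in ("+", "-"):
            raise FormatError(f"line {lineno}: gene {gene_id}: strand required")
        strand: Strand = f[5]  # type: ignore[assignment]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise FormatError(f"line {lineno}: blockCount does not match block lists")
        exons = tuple(
            GenomicInterval(chrom, start + off, start + off + size, strand)
            for off, size in zip(offsets, sizes)
        )
        cds_start = cds_end = None
        if thick_end > thick_start:
            cds_start, cds_end = thick_start, thick_end
        try:
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    name=gene_id,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return genes


def _read_genes_gtf(path: str | Path) -> list[GeneModel]:
    # accumulate gene / exon / CDS features per gene_id, then assemble
    span: dict[str, tuple[str, int, int, str]] = {}
    has_gene_line: set[str] = set()
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    names: dict[str, str] = {}
    order: list[str] = []

    for lineno, f in _data_lines(path):
        if len(f) < 9:
            raise FormatError(f"line {lineno}: GTF requires 9 columns")
        chrom, feature, start1, end1, strand = f[0], f[2], f[3], f[4], f[6]
        if feature not in ("gene", "exon", "CDS"):
            continue
        try:
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> half-open
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-integer coordinate") from exc
        attrs = dict(_GTF_ATTR.findall(f[8]))
        gid = attrs.get("gene_id")
        if not gid:
            raise FormatError(f"line {lineno}: missing gene_id attribute")
        if strand not in ("+", "-"):
            raise FormatError(f"line {lineno}: gene {gid}: strand required")
        if gid not in order:
            order.append(gid)
        names.setdefault(gid, attrs.get("gene_name", gid))
        if feature == "gene":
            span[gid] = (chrom, start, end, strand)
            has_gene_line.add(gid)
        elif feature == "exon":
            exons.setdefault(gid, []).append((start, end))
            span.setdefault(gid, (chrom, start, end, strand))
        else:
            cds.setdefault(gid, []).append((start, end))

    genes: list[GeneModel] = []
    for gid in order:
        chrom, gstart, gend, strand = span[gid]
        ex = sorted(exons.get(gid, [(gstart, gend)]))
        # with no explicit gene feature the span is the exon envelope
        if gid not in has_gene_line:
            gstart = min(gstart, ex[0][0])
            gend = max(gend, ex[-1][1])
        cds_start = cds_end = None
        if gid in cds:
            cds_start = min(s for s, _ in cds[gid])
            cds_end = max(e for _, e in cds[gid])
        try:
            genes.append(
                GeneModel(
                    gene_id=gid,
                    name=names[gid],
                    interval=GenomicInterval(chrom, gstart, gend, strand),  # type: ignore[arg-type]
                    exons=tuple(
                        GenomicInterval(chrom, s, e, strand) for s, e in ex  # type: ignore[arg-type]
                    ),
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
        except ValueError as exc:
            raise FormatError(f"gene {gid}: {exc}") from exc
    return genes


def read_genes(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GTF dialect.

    The GTF dialect uses feature types gene/exon/CDS and a quoted
    ``gene_id`` attribute; exons are assembled and sorted per gene_id.
    """
    if format == "bed12":
        return _read_genes_bed12(path)
    if format in ("gtf", "gtf-minimal"):
        return _read_genes_gtf(path)
    raise ValueError(f"unknown gene format {format!r}")
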