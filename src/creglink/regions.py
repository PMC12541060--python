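"""Genomic interval primitives and readers/writers for the pipeline's file formats.

Coordinates are BED-style throughout: 0-based, half-open ``[start, end)``.
Peak identifiers use the ``chrom-start-end`` rendering of those coordinates,
e.g. ``chr8-133320109-133321082``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Inconsistent dimensions or otherwise malformed input files."""


class BedParseError(ValueError):
    """A malformed BED/fragment line; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A half-open genomic interval.

    ``start`` is 0-based inclusive, ``end`` exclusive; ``end > start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")

    @property
    def id(self) -> str:
        return f"{self.chrom}-{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @classmethod
    def from_id(cls, region_id: str) -> "GenomicRegion":
        parts = region_id.rsplit("-", 2)
        if len(parts) != 3:
            raise ValueError(f"not a chrom-start-end id: {region_id!r}")
        chrom, start, end = parts
        return cls(chrom, int(start), int(end))

    def overlap_length(self, other: "GenomicRegion") -> int:
        if self.chrom != other.chrom:
            return 0
        return min(self.end, other.end) - max(self.start, other.start)


@dataclass(frozen=True)
class FragmentRecord:
    """One sequencing fragment: a region, the cell barcode and a duplicate count."""

    region: GenomicRegion
    barcode: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("fragment count must be >= 1")


def _check_matrix(counts: sp.spmatrix, n_rows: int, n_cols: int, what: str) -> sp.csr_matrix:
    counts = sp.csr_matrix(counts)
    if counts.shape != (n_rows, n_cols):
        raise FormatError(
            f"{what}: matrix shape {counts.shape} does not match "
            f"{n_rows} features x {n_cols} cells"
        )
    if counts.nnz and counts.data.min() < 0:
        raise FormatError(f"{what}: negative counts")
    return counts


@dataclass
class AccessibilityMatrix:
    """Sparse peak x cell ATAC count matrix with region coordinates and cell metadata."""

    counts: sp.csr_matrix
    peaks: list[GenomicRegion]
    cells: list[str]
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    peak_gc: np.ndarray | None = None  # optional per-peak GC fraction

    def __post_init__(self):
        self.counts = _check_matrix(self.counts, len(self.peaks), len(self.cells), "ATAC")
        ids = [p.id for p in self.peaks]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate peak ids")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes")
        if len(self.cell_meta):
            self.cell_meta = self.cell_meta.reindex(self.cells)

    @property
    def peak_ids(self) -> list[str]:
        return [p.id for p in self.peaks]

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "AccessibilityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cells = [self.cells[i] for i in keep]
        meta = self.cell_meta.iloc[keep] if len(self.cell_meta) else self.cell_meta
        return AccessibilityMatrix(self.counts[:, keep], list(self.peaks), cells, meta, self.peak_gc)

    def subset_peaks(self, keep: Sequence[int] | np.ndarray) -> "AccessibilityMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        gc = self.peak_gc[keep] if self.peak_gc is not None else None
        return AccessibilityMatrix(
            self.counts[keep], [self.peaks[i] for i in keep], list(self.cells), self.cell_meta, gc
        )


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell RNA count matrix.

    ``genes`` is a DataFrame indexed by gene symbol with columns
    ``chrom``, ``tss`` (0-based position) and ``strand`` ('+'/'-'): exactly one
    TSS record per gene.
    """

    counts: sp.csr_matrix
    genes: pd.DataFrame
    cells: list[str]
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.counts = _check_matrix(self.counts, len(self.genes), len(self.cells), "RNA")
        if self.genes.index.duplicated().any():
            raise FormatError("duplicate gene symbols")
        for col in ("chrom", "tss"):
            if col not in self.genes.columns:
                raise FormatError(f"gene table missing column {col!r}")
        if (np.asarray(self.genes["tss"]) < 0).any():
            raise FormatError("negative TSS coordinate")
        if len(set(self.cells)) != len(self.cells):
            raise FormatError("duplicate cell barcodes")
        if len(self.cell_meta):
            self.cell_meta = self.cell_meta.reindex(self.cells)

    def tss_region(self, gene: str) -> GenomicRegion:
        row = self.genes.loc[gene]
        return GenomicRegion(row["chrom"], int(row["tss"]), int(row["tss"]) + 1)

    def subset_cells(self, keep: Sequence[int] | np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        cells = [self.cells[i] for i in keep]
        meta = self.cell_meta.iloc[keep] if len(self.cell_meta) else self.cell_meta
        return ExpressionMatrix(self.counts[:, keep], self.genes, cells, meta)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bed_regions(path: str | os.PathLike) -> tuple[list[GenomicRegion], np.ndarray | None]:
    """Parse a BED3+ file into regions; an optional 5th numeric column is read as GC."""
    regions: list[GenomicRegion] = []
    gc: list[float] = []
    have_gc = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise BedParseError("fewer than 3 fields", lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"non-integer coordinates: {exc}", lineno) from None
            try:
                regions.append(GenomicRegion(parts[0], start, end))
            except ValueError as exc:
                raise BedParseError(str(exc), lineno) from None
            if len(parts) >= 5:
                try:
                    gc.append(float(parts[4]))
                except ValueError:
                    have_gc = False
            else:
                have_gc = False
    return regions, (np.array(gc) if have_gc and gc else None)


def _read_lines(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def read_peak_matrix(
    mtx_path: str | os.PathLike,
    peaks_bed_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
) -> AccessibilityMatrix:
    """Read a MatrixMarket peak x cell matrix with BED peaks and barcode/metadata TSVs."""
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    peaks, gc = read_bed_regions(peaks_bed_path)
    barcodes = _read_lines(barcodes_path)
    if counts.shape != (len(peaks), len(barcodes)):
        raise FormatError(
            f"matrix is {counts.shape} but peaks BED has {len(peaks)} rows and "
            f"barcodes file {len(barcodes)} rows"
        )
    meta = pd.DataFrame(index=barcodes)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return AccessibilityMatrix(counts, peaks, barcodes, meta, gc)


def read_expression_matrix(
    mtx_path: str | os.PathLike,
    genes_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    meta_path: str | os.PathLike | None = None,
) -> ExpressionMatrix:
    """Read a MatrixMarket gene x cell matrix; ``genes_path`` is a TSV with columns
    gene, chrom, tss, strand."""
    counts = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    genes = pd.read_csv(genes_path, sep="\t", index_col=0)
    barcodes = _read_lines(barcodes_path)
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {counts.shape} but gene table has {len(genes)} rows and "
            f"barcodes file {len(barcodes)} rows"
        )
    meta = pd.DataFrame(index=barcodes)
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(counts, genes, barcodes, meta)


def read_fragments(path: str | os.PathLike) -> Iterator[FragmentRecord]:
    """Stream fragment records from a 10x-style tab-separated fragments file.

    Columns: chrom, start, end, barcode, count; '#'-prefixed lines are skipped.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise BedParseError("fewer than 5 fields", lineno)
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError as exc:
                raise BedParseError(f"non-integer field: {exc}", lineno) from None
            try:
                yield FragmentRecord(GenomicRegion(parts[0], start, end), parts[3], count)
            except ValueError as exc:
                raise BedParseError(str(exc), lineno) from None


def fragments_to_frame(records: Iterable[FragmentRecord]) -> pd.DataFrame:
    """Materialize a fragment stream into the columnar frame used internally."""
    rows = [(r.region.chrom, r.region.start, r.region.end, r.barcode, r.count) for r in records]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "barcode", "count"])


def write_fragments(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval overlap
# ---------------------------------------------------------------------------

def overlap_regions(
    a: Sequence[GenomicRegion],
    b: Sequence[GenomicRegion],
    min_bp: int = 1,
) -> list[tuple[int, int]]:
    """All index pairs ``(i, j)`` with ``a[i]`` overlapping ``b[j]`` by >= ``min_bp``.

    Half-open convention: abutting intervals do not overlap. Implemented as a
    per-chromosome sorted sweep.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    by_chrom_a: dict[str, list[int]] = {}
    by_chrom_b: dict[str, list[int]] = {}
    for i, r in enumerate(a):
        by_chrom_a.setdefault(r.chrom, []).append(i)
    for j, r in enumerate(b):
        by_chrom_b.setdefault(r.chrom, []).append(j)
    pairs: list[tuple[int, int]] = []
    for chrom, ia in by_chrom_a.items():
        ib = by_chrom_b.get(chrom)
        if not ib:
            continue
        ia = sorted(ia, key=lambda i: a[i].start)
        ib = sorted(ib, key=lambda j: b[j].start)
        starts_b = [b[j].start for j in ib]
        import bisect

        for i in ia:
            ri = a[i]
            # b intervals with start < ri.end could overlap; scan back is avoided by
            # checking all with start in [0, ri.end) and filtering on their ends.
            hi = bisect.bisect_left(starts_b, ri.end)
            for j in ib[:hi]:
                if min(ri.end, b[j].end) - max(ri.start, b[j].start) >= min_bp:
                    pairs.append((i, j))
    pairs.sort()
    return pairs


def overlaps_any(a: Sequence[GenomicRegion], b: Sequence[GenomicRegion], min_bp: int = 1) -> np.ndarray:
    """Boolean mask over ``a``: region has >= min_bp overlap with some region of ``b``."""
    mask = np.zeros(len(a), dtype=bool)
    for i, _ in overlap_regions(a, b, min_bp):
        mask[i] = True
    return mask


# ---------------------------------------------------------------------------
# link network I/O
# ---------------------------------------------------------------------------

LINK_COLUMNS = [
    "peak_chrom", "peak_start", "peak_end",
    "tss_chrom", "tss_start", "tss_end",
    "gene", "r", "z", "p", "fdr", "coaccess", "reliable",
]


def write_link_network(links: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write peak-gene links as a BEDPE-style TSV (floats at 8 significant digits)."""
    out = links.loc[:, LINK_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_link_network(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LINK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"link network missing columns: {missing}")
    df["reliable"] = df["reliable"].astype(bool)
    return df
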