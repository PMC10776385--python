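"""Readers and writers for the on-disk formats the tool touches.

Supported formats: MatrixMarket coordinate matrices with barcode/peak TSV
sidecars (the GEO deposit layout), 10x-style ``fragments.tsv[.gz]``, BED3+
peak files, metadata TSV, and TSV embeddings. Fragment coordinates are
treated as 0-based half-open (10x dialect; any Tn5 +4/-5 shift is assumed to
have been applied upstream).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import CellTable, CountKind, CountMatrix, PeakSet

logger = logging.getLogger(__name__)

__all__ = [
    "read_mtx_dataset", "write_mtx_dataset", "read_fragments",
    "FragmentStats", "read_peaks_bed", "read_cell_metadata",
    "write_embedding", "read_embedding",
]


class FormatError(ValueError):
    """A file does not satisfy the expected on-disk contract."""


def _read_lines(path: str | Path) -> list[str]:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [ln.rstrip("\n") for ln in fh if ln.strip()]


def _read_peaks_sidecar(path: str | Path) -> PeakSet:
    lines = _read_lines(path)
    first = lines[0].split("\t")
    if len(first) >= 3 and first[1].isdigit() and first[2].isdigit():
        chrom = [ln.split("\t")[0] for ln in lines]
        start = [int(ln.split("\t")[1]) for ln in lines]
        end = [int(ln.split("\t")[2]) for ln in lines]
        return PeakSet(np.array(chrom, dtype=object), np.array(start), np.array(end))
    return PeakSet.from_strings([ln.split("\t")[0] for ln in lines])


def read_mtx_dataset(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    peaks_path: str | Path,
    kind: CountKind | str,
    orientation: str = "auto",
) -> CountMatrix:
    """Load an MTX matrix plus sidecars into a cells x peaks CountMatrix.

    Public deposits store either orientation; with ``orientation="auto"`` the
    sidecar lengths decide, and a square matrix with equally long sidecars
    must be disambiguated explicitly (``"cells_by_peaks"`` or
    ``"peaks_by_cells"``).
    """
    mat = sp.csr_matrix(scipy.io.mmread(str(matrix_path)))
    barcodes = [ln.split("\t")[0] for ln in _read_lines(barcodes_path)]
    peaks = _read_peaks_sidecar(peaks_path)
    n_bc, n_pk = len(barcodes), len(peaks)

    r, c = mat.shape
    if orientation == "auto":
        if (r, c) == (n_bc, n_pk) and (r, c) == (n_pk, n_bc):
            raise FormatError(
                "square matrix with equal sidecar lengths: pass orientation="
                "'cells_by_peaks' or 'peaks_by_cells'"
            )
        if (r, c) == (n_bc, n_pk):
            orientation = "cells_by_peaks"
        elif (r, c) == (n_pk, n_bc):
            orientation = "peaks_by_cells"
        else:
            which = "barcodes" if n_bc not in (r, c) else "peaks"
            raise FormatError(
                f"matrix shape {mat.shape} matches neither sidecar "
                f"orientation ({n_bc} barcodes x {n_pk} peaks); "
                f"check the {which} sidecar"
            )
    if orientation == "peaks_by_cells":
        mat = sp.csr_matrix(mat.T)
    if mat.shape != (n_bc, n_pk):
        which = "barcodes" if mat.shape[0] != n_bc else "peaks"
        raise FormatError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({n_bc} barcodes, {n_pk} peaks); check the {which} sidecar"
        )
    cells = CellTable(np.array(barcodes, dtype=object),
                      np.array(["batch0"] * n_bc, dtype=object))
    return CountMatrix(mat, CountKind(kind), cells, peaks).with_totals()


def write_mtx_dataset(matrix: CountMatrix, out_dir: str | Path,
                      prefix: str = "matrix") -> dict[str, Path]:
    """Write matrix.mtx + barcodes.tsv + peaks.tsv; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / f"{prefix}.mtx",
        "barcodes": out / f"{prefix}.barcodes.tsv",
        "peaks": out / f"{prefix}.peaks.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), matrix.values.astype(np.int64).tocoo(),
                     field="integer")
    paths["barcodes"].write_text("\n".join(matrix.cells.barcode) + "\n")
    paths["peaks"].write_text("\n".join(matrix.peaks.peak_ids) + "\n")
    return paths


@dataclass
class FragmentStats:
    """Bookkeeping for one pass over a fragment file."""

    total: int = 0
    yielded: int = 0
    filtered: int = 0   # barcode not in whitelist
    malformed: int = 0  # start >= end, skipped

    def as_dict(self) -> dict[str, int]:
        return {"total": self.total, "yielded": self.yielded,
                "filtered": self.filtered, "malformed": self.malformed}


def read_fragments(
    fragments_path: str | Path,
    barcode_whitelist: Iterable[str] | None = None,
    stats: FragmentStats | None = None,
) -> Iterator[tuple[str, int, int, str]]:
    """Stream (chrom, start, end, barcode) records from a fragment file.

    Single-pass and order-preserving. Records with start >= end are skipped
    with a warning and counted in ``stats.malformed``; records whose barcode
    is not in the whitelist are counted in ``stats.filtered``.
    """
    whitelist = None if barcode_whitelist is None else set(barcode_whitelist)
    opener = gzip.open if str(fragments_path).endswith(".gz") else open
    with opener(fragments_path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"fragment record with <4 columns: {line!r}")
            chrom, start, end, barcode = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if stats is not None:
                stats.total += 1
            if start >= end:
                logger.warning("skipping malformed fragment %s:%d-%d", chrom, start, end)
                if stats is not None:
                    stats.malformed += 1
                continue
            if whitelist is not None and barcode not in whitelist:
                if stats is not None:
                    stats.filtered += 1
                continue
            if stats is not None:
                stats.yielded += 1
            yield chrom, start, end, barcode


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read a BED3+ peak file (extra columns ignored)."""
    chrom, start, end = [], [], []
    for i, ln in enumerate(_read_lines(path)):
        if ln.startswith(("#", "track", "browser")):
            continue
        f = ln.split("\t")
        if len(f) < 3:
            raise FormatError(f"line {i + 1}: BED record with <3 columns")
        chrom.append(f[0]); start.append(int(f[1])); end.append(int(f[2]))
    return PeakSet(np.array(chrom, dtype=object), np.array(start), np.array(end))


def read_cell_metadata(path: str | Path, barcode_col: str = "barcode",
                       batch_col: str = "batch",
                       cell_type_col: str = "cell_type") -> CellTable:
    """Read a metadata TSV into a CellTable (cell_type column optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (barcode_col, batch_col):
        if col not in df.columns:
            raise FormatError(f"metadata file lacks required column {col!r}")
    ct = df[cell_type_col].to_numpy(object) if cell_type_col in df.columns else None
    return CellTable(df[barcode_col].to_numpy(object),
                     df[batch_col].to_numpy(object), ct)


def write_embedding(embedding: np.ndarray, cell_table: CellTable,
                    path: str | Path) -> None:
    """Write a cells x d embedding as TSV with a leading barcode column."""
    embedding = np.asarray(embedding, dtype=float)
    if embedding.ndim != 2 or embedding.shape[0] != len(cell_table):
        raise ValueError(
            f"embedding rows ({embedding.shape[0] if embedding.ndim == 2 else '?'}) "
            f"do not match cell table length ({len(cell_table)})"
        )
    cols = [f"dim{i}" for i in range(embedding.shape[1])]
    df = pd.DataFrame(embedding, columns=cols)
    df.insert(0, "barcode", cell_table.barcode)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_embedding(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an embedding TSV; returns (matrix, barcodes)."""
    df = pd.read_csv(path, sep="\t")
    barcodes = df["barcode"].astype(str).tolist()
    return df.drop(columns=["barcode"]).to_numpy(dtype=float), barcodes
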