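"""Core in-memory containers for cell-by-peak accessibility data.

The central object is :class:`CountMatrix`, a sparse cells x peaks integer
matrix tagged with what its entries count: ``reads`` (deduplicated fragment
ends, the CellRanger ATAC convention), ``fragments`` (Tn5 fragments, the
quantity that is approximately Poisson across cells), or ``binary``
(accessibility indicators). Keeping the kind explicit lets downstream code
refuse statistically inappropriate inputs, e.g. fitting a Poisson model to
read counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountKind", "PeakSet", "CellTable", "CountMatrix"]


class CountKind(str, Enum):
    """What the entries of a count matrix represent."""

    reads = "reads"
    fragments = "fragments"
    binary = "binary"


_PEAK_RE = re.compile(r"^(?P<chrom>[^:_]+)[:_](?P<start>\d+)[-_](?P<end>\d+)$")


@dataclass
class PeakSet:
    """An ordered set of genomic peak intervals (0-based, half-open)."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.chrom) == len(self.start) == len(self.end)):
            raise ValueError("chrom/start/end length mismatch")
        if np.any(self.start >= self.end):
            bad = int(np.argmax(self.start >= self.end))
            raise ValueError(f"peak {bad}: start >= end")
        ids = self.peak_ids
        if len(set(ids)) != len(ids):
            raise ValueError("peak ids are not unique")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def peak_ids(self) -> list[str]:
        return [f"{c}:{s}-{e}" for c, s, e in zip(self.chrom, self.start, self.end)]

    @classmethod
    def from_strings(cls, strings: list[str]) -> "PeakSet":
        """Parse peak identifiers like ``chr1:100-500`` or ``chr1_100_500``.

        Both dialects occur in public deposits; they are normalized to the
        colon-dash form internally.
        """
        chrom, start, end = [], [], []
        for i, s in enumerate(strings):
            s = s.strip()
            m = _PEAK_RE.match(s)
            if m is None:
                parts = s.split("_")
                # GEO dialect chr1_100_500 with underscores in chrom is not
                # supported; fall back to right-most two fields as coords.
                if len(parts) >= 3 and parts[-1].isdigit() and parts[-2].isdigit():
                    chrom.append("_".join(parts[:-2]))
                    start.append(int(parts[-2]))
                    end.append(int(parts[-1]))
                    continue
                raise ValueError(f"line {i + 1}: unparseable peak string {s!r}")
            chrom.append(m["chrom"])
            start.append(int(m["start"]))
            end.append(int(m["end"]))
        return cls(np.array(chrom, dtype=object), np.array(start), np.array(end))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PeakSet":
        return cls(
            df.iloc[:, 0].to_numpy(dtype=object),
            df.iloc[:, 1].to_numpy(),
            df.iloc[:, 2].to_numpy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end,
             "peak_id": self.peak_ids}
        )

    def subset(self, index: np.ndarray) -> "PeakSet":
        return PeakSet(self.chrom[index], self.start[index], self.end[index])


@dataclass
class CellTable:
    """Per-cell metadata: barcode, batch label, optional cell type, depth.

    ``batch`` is the covariate s_c handed to the decoder; ``total_fragments``
    is Sigma_p x_cp, the per-cell sequencing depth whose log is the Poisson
    model's offset l_c.
    """

    barcode: np.ndarray
    batch: np.ndarray
    cell_type: np.ndarray | None = None
    total_fragments: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.barcode = np.asarray(self.barcode, dtype=object)
        self.batch = np.asarray(self.batch, dtype=object)
        if len(set(self.barcode)) != len(self.barcode):
            raise ValueError("barcodes are not unique")
        if len(self.batch) != len(self.barcode):
            raise ValueError("batch length mismatch")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if len(self.cell_type) != len(self.barcode):
                raise ValueError("cell_type length mismatch")
        if self.total_fragments is not None:
            self.total_fragments = np.asarray(self.total_fragments, dtype=np.int64)
            if np.any(self.total_fragments < 0):
                raise ValueError("total_fragments must be non-negative")

    def __len__(self) -> int:
        return len(self.barcode)

    @property
    def batch_categories(self) -> list:
        return sorted(set(self.batch))

    @property
    def batch_codes(self) -> np.ndarray:
        cats = {b: i for i, b in enumerate(self.batch_categories)}
        return np.array([cats[b] for b in self.batch], dtype=np.int64)

    def subset(self, index: np.ndarray) -> "CellTable":
        return CellTable(
            self.barcode[index],
            self.batch[index],
            None if self.cell_type is None else self.cell_type[index],
            None if self.total_fragments is None else self.total_fragments[index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        d = {"barcode": self.barcode, "batch": self.batch}
        if self.cell_type is not None:
            d["cell_type"] = self.cell_type
        if self.total_fragments is not None:
            d["total_fragments"] = self.total_fragments
        return pd.DataFrame(d)


@dataclass
class CountMatrix:
    """Sparse cells x peaks non-negative integer matrix with metadata."""

    values: sp.csr_matrix
    kind: CountKind
    cells: CellTable
    peaks: PeakSet
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.kind = CountKind(self.kind)
        n, p = self.values.shape
        if n != len(self.cells):
            raise ValueError(f"matrix has {n} rows but CellTable has {len(self.cells)}")
        if p != len(self.peaks):
            raise ValueError(f"matrix has {p} cols but PeakSet has {len(self.peaks)}")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")
        if self.kind is CountKind.binary and self.values.nnz and self.values.data.max() > 1:
            raise ValueError("binary matrix has entries > 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.values.shape[1]

    def row_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def binarize(self) -> "CountMatrix":
        """Threshold at >= 1 count: the standard binarization y_cp."""
        b = self.values.copy()
        b.data = np.ones_like(b.data)
        return CountMatrix(b, CountKind.binary, self.cells, self.peaks)

    def with_totals(self) -> "CountMatrix":
        """Return a copy whose CellTable carries the observed row sums."""
        cells = CellTable(
            self.cells.barcode, self.cells.batch, self.cells.cell_type,
            self.row_totals().astype(np.int64),
        )
        return CountMatrix(self.values, self.kind, cells, self.peaks)

    def subset_cells(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[index], self.kind,
                           self.cells.subset(index), self.peaks)

    def subset_peaks(self, index: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.values[:, index], self.kind,
                           self.cells, self.peaks.subset(index))
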