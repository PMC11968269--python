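"""Binned symmetric contact matrices and their on-disk interchange format.

Matrices are stored dense in memory (loci of interest span at most a few
thousand bins) and written to disk as Matrix Market coordinate triplets of
the upper triangle plus a BED bin table, both plain text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = ["ContactMatrix"]


@dataclass
class ContactMatrix:
    """Square symmetric binned contact counts for one chromosomal region.

    matrix
        (n, n) float array, symmetric, non-negative.
    bin_size
        Bin width in bp.
    chrom, start
        Genomic location of bin 0 (0-based).
    weights
        Optional per-bin balancing weights (NaN where masked).
    """

    matrix: np.ndarray
    bin_size: int
    chrom: str = "chrS"
    start: int = 0
    weights: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if np.any(self.matrix < 0):
            raise ValueError("contact counts must be non-negative")
        if not np.allclose(self.matrix, self.matrix.T, rtol=0, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    @property
    def end(self) -> int:
        return self.start + self.n_bins * self.bin_size

    def bin_starts(self) -> np.ndarray:
        return self.start + np.arange(self.n_bins) * self.bin_size

    def bin_index(self, position: int) -> int:
        """Bin containing a genomic position; errors if outside the matrix."""
        if not (self.start <= position < self.end):
            raise ValueError(
                f"position {position} outside matrix span [{self.start}, {self.end})"
            )
        return int((position - self.start) // self.bin_size)

    def cis_total(self) -> float:
        return float(self.matrix.sum())

    def copy(self) -> "ContactMatrix":
        return ContactMatrix(
            matrix=self.matrix.copy(),
            bin_size=self.bin_size,
            chrom=self.chrom,
            start=self.start,
            weights=None if self.weights is None else self.weights.copy(),
        )

    # ---- I/O -------------------------------------------------------------

    def write(self, prefix) -> None:
        """Write ``<prefix>.mtx`` (upper-triangle triplets) and ``<prefix>.bins.bed``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        lower = scipy.sparse.coo_matrix(np.tril(self.matrix))
        scipy.io.mmwrite(str(prefix) + ".mtx", lower, symmetry="symmetric")
        starts = self.bin_starts()
        bins = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": starts,
                "end": starts + self.bin_size,
                "name": np.arange(self.n_bins),
            }
        )
        bins.to_csv(str(prefix) + ".bins.bed", sep="\t", header=False, index=False)
        if self.weights is not None:
            pd.DataFrame({"bin": np.arange(self.n_bins), "weight": self.weights}).to_csv(
                str(prefix) + ".weights.tsv", sep="\t", index=False
            )

    @classmethod
    def read(cls, prefix) -> "ContactMatrix":
        prefix = str(prefix)
        sparse = scipy.io.mmread(prefix + ".mtx")
        dense = np.asarray(sparse.todense(), dtype=float)
        # mmread with symmetric storage already mirrors the lower triangle
        bins = pd.read_csv(
            prefix + ".bins.bed",
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "name"],
        )
        bin_size = int(bins.iloc[0]["end"] - bins.iloc[0]["start"])
        weights = None
        wpath = Path(prefix + ".weights.tsv")
        if wpath.exists():
            weights = pd.read_csv(wpath, sep="\t")["weight"].to_numpy()
        return cls(
            matrix=dense,
            bin_size=bin_size,
            chrom=str(bins.iloc[0]["chrom"]),
            start=int(bins.iloc[0]["start"]),
            weights=weights,
        )

    @classmethod
    def from_dense_tsv(cls, path, bin_size: int, chrom: str = "chrS", start: int = 0):
        dense = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        return cls(matrix=dense, bin_size=bin_size, chrom=chrom, start=start)
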