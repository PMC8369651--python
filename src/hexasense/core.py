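"""Core containers shared across the pipeline.

Coordinates are 0-based, half-open everywhere. A genome binning tiles each
chromosome with fixed-width bins; bin ``i`` covers ``[i*res, (i+1)*res)`` and
the last bin may be short. Missing values are NaN throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeBinning",
    "BinTrack",
    "ContactMatrix",
    "QuantTable",
    "FRAPTrace",
]


@dataclass(frozen=True)
class GenomeBinning:
    """Fixed-resolution tiling of one or more chromosomes."""

    chrom_sizes: dict
    resolution: int

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be a positive integer")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.resolution

    def bin_start(self, i: int) -> int:
        return i * self.resolution

    def bin_end(self, chrom: str, i: int) -> int:
        return min((i + 1) * self.resolution, self.chrom_sizes[chrom])


@dataclass
class BinTrack:
    """Per-bin scalar signal on a fixed binning (PC1, insulation, density...)."""

    chrom: str
    binning: GenomeBinning
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.binning.n_bins(self.chrom)
        if self.values.shape != (n,):
            raise ValueError(
                f"track has {self.values.shape} values but {self.chrom} has {n} bins"
            )

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins(self.chrom)


@dataclass
class ContactMatrix:
    """One chromosome's symmetric binned contact map, upper triangle stored.

    ``bin1 <= bin2`` for every stored pixel; counts are raw (unbalanced).
    """

    chrom: str
    binning: GenomeBinning
    bin1: np.ndarray
    bin2: np.ndarray
    count: np.ndarray

    def __post_init__(self):
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=float)
        if not (self.bin1.shape == self.bin2.shape == self.count.shape):
            raise ValueError("pixel arrays must have identical shape")
        n = self.n_bins
        if self.bin1.size:
            if self.bin1.min() < 0 or self.bin2.max() >= n:
                raise ValueError("bin index out of range")
            if np.any(self.count < 0):
                raise ValueError("negative contact count")
            if np.any(self.bin1 > self.bin2):
                raise ValueError("pixels must satisfy bin1 <= bin2")

    @property
    def n_bins(self) -> int:
        return self.binning.n_bins(self.chrom)

    @property
    def n_pixels(self) -> int:
        return int(self.bin1.size)

    def to_dense(self) -> np.ndarray:
        """Full symmetric dense matrix of raw counts."""
        n = self.n_bins
        m = np.zeros((n, n))
        np.add.at(m, (self.bin1, self.bin2), self.count)
        off = self.bin1 != self.bin2
        np.add.at(m, (self.bin2[off], self.bin1[off]), self.count[off])
        return m

    @classmethod
    def from_dense(cls, chrom, binning, dense) -> "ContactMatrix":
        dense = np.asarray(dense, dtype=float)
        iu = np.triu_indices(dense.shape[0])
        nz = dense[iu] != 0
        return cls(chrom, binning, iu[0][nz], iu[1][nz], dense[iu][nz])


QUANT_KINDS = ("iBAQ", "FOT", "FOT_normalized")
CONDITIONS = ("control", "treated", "undigested")


@dataclass
class QuantTable:
    """Proteins x samples label-free abundance matrix with sample metadata.

    ``data`` is indexed by protein id with one column per sample; ``condition``
    and ``batch`` are indexed by sample id. ``kind`` advances only along
    iBAQ -> FOT -> FOT_normalized.
    """

    data: pd.DataFrame
    condition: pd.Series
    batch: pd.Series
    kind: str = "iBAQ"

    def __post_init__(self):
        if self.kind not in QUANT_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate protein identifiers")
        for meta in (self.condition, self.batch):
            missing = self.data.columns.difference(meta.index)
            if len(missing):
                raise ValueError(f"samples lack metadata: {list(missing)}")
        bad = set(self.condition[self.data.columns]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("abundance values must be non-negative")

    @property
    def protein_ids(self):
        return list(self.data.index)

    @property
    def sample_ids(self):
        return list(self.data.columns)

    def samples_of(self, condition: str):
        cond = self.condition[self.data.columns]
        return list(cond.index[cond == condition])

    def replace_values(self, values: pd.DataFrame, kind: str) -> "QuantTable":
        if QUANT_KINDS.index(kind) < QUANT_KINDS.index(self.kind):
            raise ValueError(f"kind may not regress from {self.kind} to {kind}")
        return QuantTable(values, self.condition.copy(), self.batch.copy(), kind)


@dataclass
class FRAPTrace:
    """Photobleaching recovery time series for one bleach spot.

    ``times`` are seconds; the first ``n_prebleach`` frames precede the bleach.
    ``normalized`` is filled by :func:`hexasense.frap.normalize_trace` and is a
    proportion of pre-bleach intensity (pre-bleach mean = 1).
    """

    times: np.ndarray
    bleached: np.ndarray
    control: np.ndarray
    background: np.ndarray
    n_prebleach: int = 3
    normalized: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.bleached = np.asarray(self.bleached, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        n = self.times.size
        if not (self.bleached.size == self.control.size == self.background.size == n):
            raise ValueError("trace series must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.n_prebleach < 1:
            raise ValueError("need at least one pre-bleach frame")

    @property
    def post_times(self) -> np.ndarray:
        """Times measured from the first post-bleach frame."""
        t = self.times[self.n_prebleach:]
        return t - t[0]
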