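"""Shared in-memory containers used across the analysis modules.

The containers are thin wrappers around numpy arrays and pandas DataFrames:
a :class:`ClusterPopulation` is the canonical per-cell cluster table, an
:class:`ImageStack` is a 3D fluorescence volume with physical voxel sizes,
a :class:`Movie` is a 2D time series (single-molecule blink data), and a
:class:`SparkletTrace` is a uniformly sampled fluorescence trace from one
sparklet site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Required columns of a 3D cluster table.
CLUSTER_COLUMNS_3D = ["id", "volume_um3", "x", "y", "z", "on_membrane"]
#: Required columns of a 2D (super-resolution footprint) cluster table.
CLUSTER_COLUMNS_2D = ["id", "area_nm2", "x", "y", "on_membrane"]


@dataclass
class ClusterPopulation:
    """Per-cell collection of segmented (or synthesized) clusters.

    ``table`` holds one row per cluster.  3D populations carry
    ``volume_um3`` and centroid columns ``x, y, z`` in micrometres; 2D
    populations carry ``area_nm2`` and centroids ``x, y`` in nanometres.
    ``meta`` carries cell-level metadata (cell id, sex, genotype,
    membrane area, ...); it is free-form but serialized with the table.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "volume_um3" in self.table.columns:
            vals = self.table["volume_um3"].to_numpy(dtype=float)
            if len(vals) and np.any(vals <= 0):
                raise ValueError("cluster volumes must be positive")
        if "area_nm2" in self.table.columns:
            vals = self.table["area_nm2"].to_numpy(dtype=float)
            if len(vals) and np.any(vals <= 0):
                raise ValueError("cluster areas must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def is_3d(self) -> bool:
        return "volume_um3" in self.table.columns

    @property
    def volumes(self) -> np.ndarray:
        """Cluster volumes in μm³ (3D populations only)."""
        return self.table["volume_um3"].to_numpy(dtype=float)

    @property
    def areas(self) -> np.ndarray:
        """Cluster areas in nm² (2D populations only)."""
        return self.table["area_nm2"].to_numpy(dtype=float)

    def membrane_subset(self) -> "ClusterPopulation":
        """Clusters flagged as overlapping the surface membrane."""
        mask = self.table["on_membrane"].astype(bool)
        return ClusterPopulation(self.table[mask].reset_index(drop=True), dict(self.meta))


@dataclass
class ImageStack:
    """A 3D fluorescence volume, axis order ``(z, y, x)``.

    ``voxel_size`` is ``(x, y, z)`` in micrometres; the axial step defaults
    to 0.13 μm per optical plane in the synthetic renderer.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("all voxel dimensions must be positive")

    @property
    def voxel_volume_um3(self) -> float:
        vx, vy, vz = self.voxel_size
        return vx * vy * vz


@dataclass
class Movie:
    """A 2D time series, axis order ``(frame, y, x)``, pixels in nm."""

    frames: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("Movie frames must be 3D (t, y, x)")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel size must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class SparkletTrace:
    """Fluorescence versus frame for one sparklet site (uniform sampling)."""

    samples: np.ndarray
    sampling_rate: float = 100.0
    site_id: str = ""
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("trace must be a non-empty 1D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class SizeDistribution:
    """Histogram of cluster sizes with normalized relative frequencies.

    ``sizes`` are either integer lattice-site counts (assembly simulations)
    or bin centers of a physical-size histogram.  ``exp_fit`` optionally
    stores ``(amplitude, decay_constant)`` of a single-exponential fit.
    """

    sizes: np.ndarray
    counts: np.ndarray
    exp_fit: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.sizes.shape != self.counts.shape:
            raise ValueError("sizes and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_sizes(cls, sizes: np.ndarray) -> "SizeDistribution":
        """Tabulate a list of raw (integer) sizes into a distribution."""
        sizes = np.asarray(sizes, dtype=int)
        if sizes.size == 0:
            return cls(np.array([]), np.array([]))
        uniq, counts = np.unique(sizes, return_counts=True)
        return cls(uniq.astype(float), counts.astype(float))

    @property
    def relative_frequency(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / total

    @property
    def total(self) -> float:
        return float(self.counts.sum())
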