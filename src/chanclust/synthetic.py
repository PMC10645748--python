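"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
cluster populations with exponentially distributed volumes on a membrane
shell, rendered 3D fluorescence stacks, coupled-gating sparklet traces,
and single-molecule blink movies.  Each generator takes a frozen spec
carrying one seed; identical specs produce bit-identical outputs.

These generators emulate the statistics of the real data (exponential
size distributions, punctate Gaussian spots, quantized gating), not the
morphology of myocytes or the photophysics of the fluorophores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ClusterPopulation, ImageStack, Movie, SparkletTrace
from .sparklets import (
    DEFAULT_MEAN_OPEN_FRAMES,
    IdealizedRecord,
    coupled_initial_distribution,
    coupled_transition_matrix,
)

#: Intensity units rendered per μm³ of cluster volume (before noise).
INTENSITY_PER_UM3 = 1.0e4


@dataclass(frozen=True)
class SyntheticClusterSpec:
    """Population of clusters with i.i.d. exponential volumes.

    ``mean_volume`` (μm³) is the exponential mean; centroids are placed
    uniformly on an axis-aligned box shell of the given thickness, a
    simple stand-in for the surface membrane.
    """

    n_clusters: int
    mean_volume: float
    spatial_domain: tuple[float, float, float] = (20.0, 20.0, 4.0)
    membrane_shell_thickness: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")
        if self.mean_volume <= 0:
            raise ValueError(f"mean_volume must be positive, got {self.mean_volume}")
        if any(d <= 0 for d in self.spatial_domain):
            raise ValueError("spatial_domain extents must be positive")


@dataclass(frozen=True)
class ImageRenderSpec:
    """Rendering parameters for a synthetic confocal-like stack.

    The axial voxel step defaults to 0.13 μm per optical plane.  Noise is
    Poisson shot noise on the rendered intensity plus additive Gaussian
    read noise; either can be switched off.
    """

    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.13)
    psf_sigma: float = 0.12
    background_level: float = 10.0
    poisson_noise: bool = True
    gaussian_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("all voxel dimensions must be positive")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be positive")


@dataclass(frozen=True)
class SparkletSimSpec:
    """Coupled N-channel gating trace with known κ and quantal amplitude."""

    n_channels: int = 3
    kappa_true: float = 0.0
    open_prob: float = 0.1
    quantal_amplitude: float = 1.0
    noise_sd: float = 0.0
    sampling_rate: float = 100.0
    duration: float = 20.0
    mean_open_frames: float = DEFAULT_MEAN_OPEN_FRAMES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.kappa_true <= 1:
            raise ValueError("kappa_true must lie in [0, 1]")
        if not 0 < self.open_prob < 1:
            raise ValueError("open_prob must lie strictly between 0 and 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.quantal_amplitude <= 0:
            raise ValueError("quantal_amplitude must be positive")
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise ValueError("duration and sampling_rate must be positive")


@dataclass(frozen=True)
class BlinkMovieSpec:
    """Single-molecule blink movie for localization/rendering tests.

    Each frame activates a random subset of emitters; apparent positions
    are jittered by ``localization_noise_sd`` to mimic finite localization
    precision.  The 35,000-frame default matches a typical single-cell
    ground-state-depletion acquisition.
    """

    emitter_positions: tuple[tuple[float, float], ...]  # (x, y) in nm
    frames: int = 35_000
    blink_prob: float = 0.01
    localization_noise_sd: float = 20.0
    psf_sigma_nm: float = 150.0
    pixel_size_nm: float = 100.0
    image_shape: tuple[int, int] = (64, 64)
    photons_per_blink: float = 1000.0
    background_level: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frames <= 0:
            raise ValueError("frames must be positive")
        if not 0 <= self.blink_prob <= 1:
            raise ValueError("blink_prob must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Cluster populations


def _sample_shell_points(rng: np.random.Generator, n: int, domain, thickness: float):
    """Uniform points on the shell of an axis-aligned box.

    A face is chosen with probability proportional to its area, a point
    drawn uniformly on it, then offset inward uniformly within the shell
    thickness.  Corner overlaps are ignored; only the statistics matter.
    """
    dx, dy, dz = domain
    areas = np.array([dy * dz, dy * dz, dx * dz, dx * dz, dx * dy, dx * dy])
    faces = rng.choice(6, size=n, p=areas / areas.sum())
    u = rng.uniform(size=(n, 2))
    depth = rng.uniform(0.0, min(thickness, min(domain) / 2), size=n)
    pts = np.empty((n, 3))
    for i, f in enumerate(faces):
        a, b = u[i]
        d = depth[i]
        if f == 0:
            pts[i] = (d, a * dy, b * dz)
        elif f == 1:
            pts[i] = (dx - d, a * dy, b * dz)
        elif f == 2:
            pts[i] = (a * dx, d, b * dz)
        elif f == 3:
            pts[i] = (a * dx, dy - d, b * dz)
        elif f == 4:
            pts[i] = (a * dx, b * dy, d)
        else:
            pts[i] = (a * dx, b * dy, dz - d)
    return pts


def gen_cluster_population(spec: SyntheticClusterSpec) -> ClusterPopulation:
    """Draw a cluster population with exponential volumes on the shell."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_clusters
    if n == 0:
        table = pd.DataFrame(
            {"id": pd.Series(dtype=int), "volume_um3": pd.Series(dtype=float),
             "x": pd.Series(dtype=float), "y": pd.Series(dtype=float),
             "z": pd.Series(dtype=float), "on_membrane": pd.Series(dtype=bool)}
        )
        return ClusterPopulation(table, {"spec": spec})
    volumes = rng.exponential(spec.mean_volume, size=n)
    pts = _sample_shell_points(rng, n, spec.spatial_domain, spec.membrane_shell_thickness)
    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "volume_um3": volumes,
            "x": pts[:, 0],
            "y": pts[:, 1],
            "z": pts[:, 2],
            "on_membrane": np.ones(n, dtype=bool),
        }
    )
    return ClusterPopulation(table, {"spec": spec})


def grid_cluster_population(
    n_clusters: int,
    volume_um3: float,
    spacing_um: float,
    domain: tuple[float, float, float],
    z_um: float | None = None,
) -> ClusterPopulation:
    """Deterministic population of identical clusters on a planar grid.

    Centroids are laid out on a square lattice with the given spacing,
    guaranteeing well-separated blobs for segmentation recovery tests.
    """
    dx, dy, dz = domain
    per_row = max(1, int((dx - spacing_um) // spacing_um))
    xs, ys = [], []
    for i in range(n_clusters):
        r, c = divmod(i, per_row)
        xs.append(spacing_um * (c + 1))
        ys.append(spacing_um * (r + 1))
    if max(ys, default=0) > dy - spacing_um / 2:
        raise ValueError("domain too small for requested cluster count and spacing")
    z = dz / 2 if z_um is None else z_um
    table = pd.DataFrame(
        {
            "id": np.arange(n_clusters),
            "volume_um3": np.full(n_clusters, float(volume_um3)),
            "x": xs,
            "y": ys,
            "z": np.full(n_clusters, z),
            "on_membrane": np.ones(n_clusters, dtype=bool),
        }
    )
    return ClusterPopulation(table, {"generator": "grid"})


# ---------------------------------------------------------------------------
# Image rendering


def render_image_stack(pop: ClusterPopulation, spec: ImageRenderSpec,
                       domain: tuple[float, float, float] | None = None) -> ImageStack:
    """Render clusters as 3D Gaussian blobs on a voxel grid.

    Each cluster contributes a Gaussian of width ``psf_sigma`` whose
    integrated intensity equals ``INTENSITY_PER_UM3 × volume``; the blob
    is normalized over its evaluation window so the proportionality is
    exact up to domain clipping.  Clusters outside the domain are clipped
    with a warning.
    """
    vx, vy, vz = spec.voxel_size
    if domain is None:
        if len(pop) and "spec" in pop.meta and hasattr(pop.meta["spec"], "spatial_domain"):
            domain = pop.meta["spec"].spatial_domain
        else:
            domain = (20.0, 20.0, 4.0)
    dx, dy, dz = domain
    shape = (int(np.ceil(dz / vz)), int(np.ceil(dy / vy)), int(np.ceil(dx / vx)))
    img = np.zeros(shape, dtype=float)

    sig = np.array([spec.psf_sigma / vz, spec.psf_sigma / vy, spec.psf_sigma / vx])
    half = np.ceil(4 * sig).astype(int)
    # local Gaussian template offsets, shared across clusters
    zz, yy, xx = np.meshgrid(
        np.arange(-half[0], half[0] + 1),
        np.arange(-half[1], half[1] + 1),
        np.arange(-half[2], half[2] + 1),
        indexing="ij",
    )

    clipped = 0
    for _, row in pop.table.iterrows():
        if not (0 <= row["x"] <= dx and 0 <= row["y"] <= dy and 0 <= row["z"] <= dz):
            clipped += 1
        cz, cy, cx = row["z"] / vz, row["y"] / vy, row["x"] / vx
        iz, iy, ix = int(round(cz)), int(round(cy)), int(round(cx))
        blob = np.exp(
            -((zz + iz - cz) ** 2) / (2 * sig[0] ** 2)
            - ((yy + iy - cy) ** 2) / (2 * sig[1] ** 2)
            - ((xx + ix - cx) ** 2) / (2 * sig[2] ** 2)
        )
        blob *= INTENSITY_PER_UM3 * row["volume_um3"] / blob.sum()
        z0, y0, x0 = iz - half[0], iy - half[1], ix - half[2]
        z1, y1, x1 = z0 + blob.shape[0], y0 + blob.shape[1], x0 + blob.shape[2]
        sz0, sy0, sx0 = max(0, -z0), max(0, -y0), max(0, -x0)
        tz0, ty0, tx0 = max(0, z0), max(0, y0), max(0, x0)
        tz1, ty1, tx1 = min(shape[0], z1), min(shape[1], y1), min(shape[2], x1)
        if tz1 <= tz0 or ty1 <= ty0 or tx1 <= tx0:
            continue
        img[tz0:tz1, ty0:ty1, tx0:tx1] += blob[
            sz0 : sz0 + (tz1 - tz0), sy0 : sy0 + (ty1 - ty0), sx0 : sx0 + (tx1 - tx0)
        ]
    if clipped:
        warnings.warn(f"{clipped} cluster(s) fell outside the rendering domain and were clipped")

    img += spec.background_level
    rng = np.random.default_rng(spec.seed)
    if spec.poisson_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.gaussian_noise_sd > 0:
        img += rng.normal(0.0, spec.gaussian_noise_sd, size=img.shape)
    return ImageStack(img, spec.voxel_size)


# ---------------------------------------------------------------------------
# Sparklet traces


def gen_sparklet_trace(spec: SparkletSimSpec) -> tuple[SparkletTrace, IdealizedRecord]:
    """Simulate a coupled-gating sparklet trace and its ground-truth levels.

    The latent level sequence is drawn from the aggregate coupled Markov
    chain (mixture of an independent and a synchronized kernel); the
    observed trace is ``level × quantal_amplitude`` plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.sampling_rate))
    N = spec.n_channels
    P = coupled_transition_matrix(N, spec.open_prob, spec.kappa_true, spec.mean_open_frames)
    pi0 = coupled_initial_distribution(N, spec.open_prob, spec.kappa_true)
    cum = np.cumsum(P, axis=1)

    levels = np.empty(n_frames, dtype=int)
    levels[0] = rng.choice(N + 1, p=pi0)
    u = rng.uniform(size=n_frames)
    for t in range(1, n_frames):
        levels[t] = np.searchsorted(cum[levels[t - 1]], u[t])

    signal = levels * spec.quantal_amplitude
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=n_frames)
    trace = SparkletTrace(signal, sampling_rate=spec.sampling_rate)
    record = IdealizedRecord.from_levels(levels)
    return trace, record


# ---------------------------------------------------------------------------
# Blink movies


def gen_blink_movie(spec: BlinkMovieSpec) -> Movie:
    """Simulate a blink movie: random emitter subsets per frame, jittered."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    px = spec.pixel_size_nm
    sig_px = spec.psf_sigma_nm / px
    half = int(np.ceil(4 * sig_px))
    yy, xx = np.meshgrid(np.arange(-half, half + 1), np.arange(-half, half + 1), indexing="ij")

    frames = np.full((spec.frames, h, w), float(spec.background_level))
    positions = np.asarray(spec.emitter_positions, dtype=float)
    for t in range(spec.frames):
        on = rng.uniform(size=len(positions)) < spec.blink_prob
        for ex, ey in positions[on]:
            jx = ex + rng.normal(0.0, spec.localization_noise_sd)
            jy = ey + rng.normal(0.0, spec.localization_noise_sd)
            cx, cy = jx / px, jy / px
            ix, iy = int(round(cx)), int(round(cy))
            blob = np.exp(
                -((yy + iy - cy) ** 2 + (xx + ix - cx) ** 2) / (2 * sig_px**2)
            )
            blob *= spec.photons_per_blink / (2 * np.pi * sig_px**2)
            y0, x0 = iy - half, ix - half
            y1, x1 = y0 + blob.shape[0], x0 + blob.shape[1]
            sy0, sx0 = max(0, -y0), max(0, -x0)
            ty0, tx0 = max(0, y0), max(0, x0)
            ty1, tx1 = min(h, y1), min(w, x1)
            if ty1 <= ty0 or tx1 <= tx0:
                continue
            frames[t, ty0:ty1, tx0:tx1] += blob[
                sy0 : sy0 + (ty1 - ty0), sx0 : sx0 + (tx1 - tx0)
            ]
    return Movie(frames, pixel_size_nm=px)
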