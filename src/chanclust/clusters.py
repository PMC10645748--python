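"""Cluster segmentation and size-distribution analysis.

Segments channel clusters from 3D confocal stacks (fixed threshold,
26-connected components, physical-size minima) and from 2D localization
maps, computes per-cell metrics including the percent of surface membrane
occupied, fits single-exponential size distributions, classifies macro
versus micro clusters with the mean-minus-2-SD threshold, and quantifies
proximity-ligation puncta.

Macro/micro convention: the macro-cluster limit is the wild-type mean
cluster volume minus two standard deviations (0.06 μm³ for a mean of
0.12 μm³ and SD of 0.03 μm³); a cluster strictly larger than the
threshold is a macro-cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage import measure

from .core import ClusterPopulation, ImageStack, Movie, SizeDistribution

#: Default histogram bin widths for exponential fits.
DEFAULT_VOLUME_BIN_UM3 = 0.02
DEFAULT_AREA_BIN_NM2 = 500.0


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and minimum-size rules for 3D spot segmentation.

    ``min_voxels`` defaults to 3: a bright signal must occupy strictly
    more than two voxels to count as a cluster.  ``min_lateral_extent``
    and ``min_axial_extent`` (nm) are minimum physical bounding-box
    extents in x/y and z.
    """

    intensity_threshold: float
    min_voxels: int = 3
    min_lateral_extent_nm: float = 100.0
    min_axial_extent_nm: float = 150.0
    membrane_restrict: bool = False

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ValueError("min_voxels must be >= 1")
        if self.min_lateral_extent_nm <= 0 or self.min_axial_extent_nm <= 0:
            raise ValueError("extent minima must be positive")


@dataclass
class CellMetrics:
    """Per-cell cluster statistics."""

    clusters_per_cell: int
    total_cluster_volume: float
    mean_cluster_volume: float
    membrane_occupancy_pct: float
    cluster_density_per_um2: float
    mean_defined: bool = True


@dataclass
class MacroMicroThreshold:
    """Macro-cluster lower volume limit: mean − 2·SD."""

    mean_volume: float
    sd_volume: float
    threshold: float
    equivalent_diameter_nm: float


@dataclass
class PlaResult:
    """Proximity-ligation puncta summary for one cell."""

    puncta_count: int
    puncta_density_per_um2: float
    total_puncta_area_um2: float


@dataclass
class LocalizationMap:
    """Localization centroids (nm) and their rendered pixel grid."""

    points: np.ndarray  # (n, 2) of (x, y) in nm
    rendered: np.ndarray  # (rows, cols) intensity grid
    pixel_size_nm: float = 20.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size must be positive")
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.rendered = np.asarray(self.rendered, dtype=float)


# ---------------------------------------------------------------------------
# 3D segmentation


def segment_stack(
    stack: ImageStack,
    config: SegmentationConfig,
    membrane_mask: np.ndarray | None = None,
) -> ClusterPopulation:
    """Threshold and label a 3D stack into a cluster population.

    Voxels above the fixed intensity threshold are grouped into
    26-connected components; components smaller than ``min_voxels`` or
    with bounding-box extents below the lateral/axial minima are dropped.
    Volumes are voxel counts times the voxel volume; centroids are in μm.
    With ``membrane_restrict`` set and a mask given, only components
    overlapping the mask are kept (others are flagged off-membrane).
    """
    if stack.voxel_size is None or any(v is None for v in stack.voxel_size):
        raise ValueError("stack must carry voxel-size metadata")
    vx, vy, vz = stack.voxel_size
    binary = stack.data > config.intensity_threshold
    labels = measure.label(binary, connectivity=3)  # 26-connectivity in 3D
    props = measure.regionprops(labels)

    rows = []
    for i, p in enumerate(props):
        n_vox = int(p.area)
        if n_vox < config.min_voxels:
            continue
        z0, y0, x0, z1, y1, x1 = p.bbox
        extent_x_nm = (x1 - x0) * vx * 1e3
        extent_y_nm = (y1 - y0) * vy * 1e3
        extent_z_nm = (z1 - z0) * vz * 1e3
        if (
            extent_x_nm < config.min_lateral_extent_nm
            or extent_y_nm < config.min_lateral_extent_nm
            or extent_z_nm < config.min_axial_extent_nm
        ):
            continue
        cz, cy, cx = p.centroid
        on_mem = True
        if membrane_mask is not None:
            on_mem = bool(np.any(membrane_mask[labels == p.label]))
        if config.membrane_restrict and membrane_mask is not None and not on_mem:
            continue
        rows.append(
            {
                "id": len(rows),
                "volume_um3": n_vox * vx * vy * vz,
                "x": cx * vx,
                "y": cy * vy,
                "z": cz * vz,
                "on_membrane": on_mem,
                "n_voxels": n_vox,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["id", "volume_um3", "x", "y", "z", "on_membrane", "n_voxels"],
    )
    if len(rows) == 0:
        table = table.astype(
            {"id": int, "volume_um3": float, "x": float, "y": float, "z": float,
             "on_membrane": bool, "n_voxels": int}
        )
    return ClusterPopulation(table, {"voxel_size": stack.voxel_size})


# ---------------------------------------------------------------------------
# Per-cell metrics


def sphere_equivalent_cross_section_um2(volumes_um3: np.ndarray) -> np.ndarray:
    """Cross-sectional area π·r² of the volume-equivalent sphere."""
    volumes_um3 = np.asarray(volumes_um3, dtype=float)
    r = (3.0 * volumes_um3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return np.pi * r**2


def cell_metrics(pop: ClusterPopulation, membrane_area_um2: float) -> CellMetrics:
    """Counts, volume totals, and percent membrane occupancy for one cell.

    Occupancy uses the sphere-equivalent cross-sectional footprint of each
    membrane cluster over the membrane area (the raw data report occupancy
    without a formula; this is the simplest geometry-consistent choice and
    is documented as this package's definition).
    """
    if membrane_area_um2 <= 0:
        raise ValueError("membrane_area must be positive")
    n = len(pop)
    if n == 0:
        return CellMetrics(0, 0.0, float("nan"), 0.0, 0.0, mean_defined=False)
    vols = pop.volumes
    mem = pop.table["on_membrane"].astype(bool).to_numpy()
    footprint = float(sphere_equivalent_cross_section_um2(vols[mem]).sum())
    occupancy = min(100.0, 100.0 * footprint / membrane_area_um2)
    return CellMetrics(
        clusters_per_cell=n,
        total_cluster_volume=float(vols.sum()),
        mean_cluster_volume=float(vols.mean()),
        membrane_occupancy_pct=occupancy,
        cluster_density_per_um2=n / membrane_area_um2,
    )


# ---------------------------------------------------------------------------
# Exponential size-distribution fits


def histogram_distribution(
    values: np.ndarray, bin_width: float, start: float = 0.0
) -> SizeDistribution:
    """Fixed-width histogram of sizes; bin centers become the sizes."""
    values = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if values.size == 0:
        return SizeDistribution(np.array([]), np.array([]))
    n_bins = int(np.ceil((values.max() - start) / bin_width)) + 1
    edges = start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return SizeDistribution(centers, counts.astype(float))


def fit_exponential(dist: SizeDistribution) -> tuple[float, float, float]:
    """Least-squares fit of ``count = A·exp(−size/τ)`` on bin centers.

    Returns ``(A, tau, r_squared)``.  Requires at least three non-empty
    bins; an exponential is the expected steady-state shape of a
    stochastically self-assembled cluster population.
    """
    mask = dist.counts > 0
    if int(mask.sum()) < 3:
        raise ValueError("need at least 3 non-empty bins to fit an exponential")
    x = dist.sizes[mask]
    y = dist.counts[mask]
    # log-linear start values, then nonlinear least squares on the counts
    slope, intercept = np.polyfit(x, np.log(y), 1)
    tau0 = -1.0 / slope if slope < 0 else x.mean()
    a0 = float(np.exp(intercept))

    def model(s, a, tau):
        return a * np.exp(-s / tau)

    popt, _ = optimize.curve_fit(
        model, x, y, p0=[a0, abs(tau0)], maxfev=10_000,
        bounds=([0, 1e-12], [np.inf, np.inf]),
    )
    a, tau = float(popt[0]), float(popt[1])
    pred = model(x, a, tau)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, tau, r2


# ---------------------------------------------------------------------------
# Macro / micro classification


def macro_threshold(mean_volume: float, sd_volume: float) -> MacroMicroThreshold:
    """Macro-cluster lower limit: mean volume minus two standard deviations.

    The equivalent diameter is that of the sphere with the threshold
    volume, ``d = (6·V/π)^(1/3)``.  A non-positive threshold (very broad
    distributions) is returned with a warning rather than raised.
    """
    if sd_volume < 0:
        raise ValueError("sd_volume must be non-negative")
    thr = mean_volume - 2.0 * sd_volume
    if thr <= 0:
        warnings.warn(
            f"macro threshold {thr:.4g} μm³ is non-positive; "
            "the volume distribution is too broad for a mean−2SD limit"
        )
        d_nm = 0.0
    else:
        d_nm = (6.0 * thr / np.pi) ** (1.0 / 3.0) * 1e3
    return MacroMicroThreshold(
        mean_volume=mean_volume,
        sd_volume=sd_volume,
        threshold=thr,
        equivalent_diameter_nm=d_nm,
    )


def classify_macro_micro(
    pop: ClusterPopulation, threshold_um3: float
) -> tuple[int, int, float]:
    """Split a population at the macro threshold (strictly larger = macro).

    Returns ``(macro_count, micro_count, macro_fraction)``; the fraction
    is NaN for an empty population.
    """
    if threshold_um3 <= 0:
        raise ValueError("threshold must be positive")
    if len(pop) == 0:
        return 0, 0, float("nan")
    vols = pop.volumes
    macro = int(np.sum(vols > threshold_um3))
    micro = len(vols) - macro
    return macro, micro, macro / len(vols)


# ---------------------------------------------------------------------------
# Localization microscopy


def _fit_gaussian_2d(patch: np.ndarray) -> tuple[float, float, float, float] | None:
    """Fit an isotropic 2D Gaussian plus offset to a small patch.

    Returns ``(row, col, photons, sigma)`` in patch coordinates, or None
    if the fit fails.
    """
    h, w = patch.shape
    yy, xx = np.mgrid[0:h, 0:w]
    offset0 = float(patch.min())
    amp0 = float(patch.max() - offset0)
    if amp0 <= 0:
        return None
    cy0, cx0 = np.unravel_index(np.argmax(patch), patch.shape)

    def model(coords, amp, cy, cx, sigma, offset):
        y, x = coords
        return (amp * np.exp(-((y - cy) ** 2 + (x - cx) ** 2) / (2 * sigma**2)) + offset).ravel()

    try:
        popt, _ = optimize.curve_fit(
            model,
            (yy, xx),
            patch.ravel(),
            p0=[amp0, cy0, cx0, max(1.0, h / 6), offset0],
            maxfev=2000,
        )
    except RuntimeError:
        return None
    amp, cy, cx, sigma, _ = popt
    if not (0 <= cy < h and 0 <= cx < w) or sigma <= 0:
        return None
    photons = float(2 * np.pi * amp * sigma**2)
    return float(cy), float(cx), photons, float(sigma)


def localize_and_render(
    movie: Movie,
    photon_threshold: float,
    pixel_size_nm: float = 20.0,
    detect_sigma_px: float = 1.5,
    patch_half: int = 5,
    render_shape: tuple[int, int] | None = None,
) -> LocalizationMap:
    """Per-frame 2D Gaussian localization accumulated into a rendered map.

    Each frame is smoothed, local maxima above the frame background are
    fit with a 2D Gaussian in a small window, fits below the photon
    threshold are discarded, and accepted centroids (nm) are histogrammed
    onto a ``pixel_size_nm`` grid with zero-based, half-open pixel bins.
    """
    if len(movie) == 0:
        raise ValueError("movie must contain at least one frame")
    from skimage.feature import peak_local_max

    cam_px = movie.pixel_size_nm
    points = []
    for frame in movie.frames:
        smoothed = ndimage.gaussian_filter(frame, detect_sigma_px)
        bg = np.median(frame)
        noise = max(1e-9, float(np.std(frame)))
        peaks = peak_local_max(
            smoothed, min_distance=patch_half, threshold_abs=bg + 2 * noise
        )
        for py, px_ in peaks:
            y0, x0 = py - patch_half, px_ - patch_half
            y1, x1 = py + patch_half + 1, px_ + patch_half + 1
            if y0 < 0 or x0 < 0 or y1 > frame.shape[0] or x1 > frame.shape[1]:
                continue
            fit = _fit_gaussian_2d(frame[y0:y1, x0:x1])
            if fit is None:
                continue
            cy, cx, photons, _ = fit
            if photons < photon_threshold:
                continue
            points.append(((x0 + cx) * cam_px, (y0 + cy) * cam_px))
    points_arr = np.asarray(points, dtype=float).reshape(-1, 2)
    if render_shape is None:
        extent_nm = (movie.frames.shape[1] * cam_px, movie.frames.shape[2] * cam_px)
        render_shape = (
            int(np.ceil(extent_nm[0] / pixel_size_nm)),
            int(np.ceil(extent_nm[1] / pixel_size_nm)),
        )
    rendered = render_points(points_arr, pixel_size_nm, render_shape)
    return LocalizationMap(points_arr, rendered, pixel_size_nm)


def render_points(
    points_nm: np.ndarray, pixel_size_nm: float, shape: tuple[int, int]
) -> np.ndarray:
    """Histogram (x, y) centroids onto a pixel grid (zero-based, half-open)."""
    points_nm = np.asarray(points_nm, dtype=float).reshape(-1, 2)
    rendered = np.zeros(shape)
    if len(points_nm) == 0:
        return rendered
    cols = np.floor(points_nm[:, 0] / pixel_size_nm).astype(int)
    rows = np.floor(points_nm[:, 1] / pixel_size_nm).astype(int)
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    np.add.at(rendered, (rows[ok], cols[ok]), 1.0)
    return rendered


def gaussian_blur_gsd(loc_map: LocalizationMap, radius_nm: float = 200.0) -> LocalizationMap:
    """Blur a rendered localization map down to confocal-like resolution.

    Each pixel is replaced by a Gaussian-weighted average of its
    neighbours within ``radius_nm``; the Gaussian sigma is radius/2 so the
    kernel support (±2σ) matches the stated radius.  Periodic boundary
    handling conserves the integrated intensity exactly; radius → 0
    returns the input unchanged.
    """
    if radius_nm < 0:
        raise ValueError("radius must be non-negative")
    if radius_nm == 0:
        return LocalizationMap(loc_map.points.copy(), loc_map.rendered.copy(),
                               loc_map.pixel_size_nm)
    sigma_px = (radius_nm / 2.0) / loc_map.pixel_size_nm
    blurred = ndimage.gaussian_filter(loc_map.rendered, sigma_px, mode="wrap")
    return LocalizationMap(loc_map.points.copy(), blurred, loc_map.pixel_size_nm)


# ---------------------------------------------------------------------------
# Proximity ligation puncta


def pla_quantify(puncta: ClusterPopulation, cell_area_um2: float) -> PlaResult:
    """Puncta density (per μm²) and total puncta area for one cell."""
    if cell_area_um2 <= 0:
        raise ValueError("cell_area must be positive")
    n = len(puncta)
    total_area_um2 = float(puncta.areas.sum() * 1e-6) if n else 0.0  # nm² → μm²
    return PlaResult(
        puncta_count=n,
        puncta_density_per_um2=n / cell_area_um2,
        total_puncta_area_um2=total_area_um2,
    )
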