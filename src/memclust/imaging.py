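"""Quantification of receptor clusters in time-lapse fluorescence frames.

The pipeline follows the standard workflow for ligand-induced receptor
clustering at the plasma membrane: frames are converted to grayscale, a
local background is estimated with an anisotropic Gaussian filter, pixels
whose intensity exceeds a fixed ratio of their background are kept as
cluster pixels, connected clusters are labeled with the Hoshen-Kopelman
algorithm, and cluster areas are summarized by a logarithmically binned
size distribution ``P(A)`` together with its power-law decay exponent
``alpha`` (``P(A) ~ A^-alpha``).  Per-frame occupied area scaled by the
cell perimeter gives a surface-density time course, which is segmented
into the three canonical regimes: transient, exponential growth, and
fluctuating steady state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters as _skfilters
from skimage import measure as _skmeasure

from ._steady import NoSteadyStateError, steady_window_stats
from .labeling import ClusterLabeling, label_clusters

__all__ = [
    "FrameStack",
    "BackgroundField",
    "BinaryMask",
    "ClusterLabeling",
    "SizeDistribution",
    "PowerLawFit",
    "DensityTimeSeries",
    "RegimeSegmentation",
    "CellGeometry",
    "NoSteadyStateError",
    "to_grayscale",
    "estimate_background",
    "segment_clusters",
    "label_clusters",
    "size_distribution",
    "fit_power_law",
    "cell_geometry",
    "cell_mask_from_stack",
    "density_timeseries",
    "segment_regimes",
]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Default threshold ratio between a pixel and its local background.
DEFAULT_THRESHOLD_RATIO = 1.5
#: Default anisotropic smoothing widths (sigma_row, sigma_col), pixels.
DEFAULT_SMOOTHING_WIDTHS = (4.0, 2.0)
#: Default logarithmic binning resolution.
DEFAULT_BINS_PER_DECADE = 5
#: Fraction of the steady mean that ends the transient regime.
TRANSIENT_FRACTION = 0.05
#: Fraction of the steady mean that ends the growth regime (1 - 1/e).
GROWTH_FRACTION = 1.0 - 1.0 / np.e


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FrameStack:
    """Ordered grayscale frames with acquisition metadata.

    Attributes
    ----------
    frames:
        Array of shape (n_frames, height, width); finite, nonnegative.
    timestamps:
        Seconds from treatment start, strictly increasing.
    pixel_size:
        Micrometres per pixel.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        if frames.ndim != 3 or frames.shape[0] == 0:
            raise ValueError("frames must be a non-empty (n, h, w) array")
        if not np.all(np.isfinite(frames)) or np.any(frames < 0):
            raise ValueError("frame intensities must be finite and >= 0")
        if ts.shape != (frames.shape[0],):
            raise ValueError("one timestamp per frame is required")
        if np.any(np.diff(ts) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "timestamps", ts)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class BackgroundField:
    """Smoothed local-background estimate of a single frame."""

    values: np.ndarray
    smoothing_params: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) < 0):
            raise ValueError("background values must be >= 0")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean cluster-pixel occupancy of a single frame."""

    grid: np.ndarray
    threshold_ratio: float


@dataclass(frozen=True)
class SizeDistribution:
    """Logarithmically binned empirical density of cluster sizes.

    ``densities[k] = counts[k] / (total * width_k)`` so that
    ``sum(densities * widths) == 1``.
    """

    bin_edges: np.ndarray
    densities: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.densities, dtype=float)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(dens < 0):
            raise ValueError("densities must be >= 0")
        norm = float(np.sum(dens * np.diff(edges)))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"densities must integrate to 1 (got {norm!r})")

    @property
    def widths(self) -> np.ndarray:
        return np.diff(np.asarray(self.bin_edges, dtype=float))

    @property
    def centers(self) -> np.ndarray:
        """Geometric bin midpoints (natural abscissa on a log axis)."""
        edges = np.asarray(self.bin_edges, dtype=float)
        return np.sqrt(edges[:-1] * edges[1:])


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares estimate of the decay exponent of ``P(A) ~ A^-alpha``."""

    alpha: float
    fit_range: tuple[float, float]
    stderr: float


@dataclass(frozen=True)
class DensityTimeSeries:
    """Cluster-signal density per unit cell-periphery length over time."""

    timestamps: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if ts.shape != d.shape:
            raise ValueError("timestamps and density must have equal length")
        if np.any(d < 0):
            raise ValueError("density must be >= 0")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "density", d)


@dataclass(frozen=True)
class RegimeSegmentation:
    """Transient / exponential-growth / steady-state segmentation."""

    transient_end: float
    growth_end: float
    steady_mean: float
    steady_band: tuple[float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.transient_end <= self.growth_end:
            raise ValueError("regime boundaries must satisfy 0 <= transient <= growth")
        lo, hi = self.steady_band
        if not lo <= self.steady_mean <= hi:
            raise ValueError("steady_band must contain steady_mean")


@dataclass(frozen=True)
class CellGeometry:
    """Cell outline summary: area, perimeter, equal-area circle diameter."""

    cell_mask: np.ndarray
    area: float
    perimeter: float
    equivalent_diameter: float

    def __post_init__(self) -> None:
        if not self.perimeter > 0:
            raise ValueError("perimeter must be positive")
        expected = 2.0 * np.sqrt(self.area / np.pi)
        if abs(self.equivalent_diameter - expected) > 1e-9 * max(expected, 1.0):
            raise ValueError("equivalent_diameter must equal 2*sqrt(area/pi)")


# ---------------------------------------------------------------------------
# operations


def to_grayscale(raw_frame: np.ndarray) -> np.ndarray:
    """Convert a raw frame to a single 2D intensity field.

    Grayscale input is returned unchanged (as float); RGB(A) input is
    reduced with ITU-R BT.601 luminance weights (alpha is ignored).
    """
    frame = np.asarray(raw_frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty image")
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., :3] @ _LUMA_WEIGHTS
    raise ValueError(f"cannot interpret shape {frame.shape} as an image frame")


def estimate_background(
    frame: np.ndarray, widths: tuple[float, float] = DEFAULT_SMOOTHING_WIDTHS
) -> BackgroundField:
    """Estimate the local background with an anisotropic Gaussian filter.

    ``widths`` are the per-axis Gaussian sigmas in pixels.  Reflect padding
    is used at the borders so that a constant field is exactly conserved.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    sy, sx = widths
    if sy <= 0 or sx <= 0:
        raise ValueError("smoothing widths must be positive")
    smoothed = ndimage.gaussian_filter(frame, sigma=(sy, sx), mode="reflect")
    # tiny negative round-off from the separable filter is clipped
    np.clip(smoothed, 0.0, None, out=smoothed)
    return BackgroundField(values=smoothed, smoothing_params=(float(sy), float(sx)))


def segment_clusters(
    frame: np.ndarray,
    background: BackgroundField,
    threshold_ratio: float = DEFAULT_THRESHOLD_RATIO,
) -> BinaryMask:
    """Keep pixels whose intensity exceeds ``threshold_ratio`` x background.

    Pixels with exactly zero background are occupied iff their intensity is
    positive (the ratio criterion degenerates there).
    """
    frame = np.asarray(frame, dtype=float)
    bg = np.asarray(background.values, dtype=float)
    if frame.shape != bg.shape:
        raise ValueError("frame and background shapes differ")
    if not threshold_ratio > 1:
        raise ValueError("threshold_ratio must exceed 1")
    occupied = np.where(bg > 0, frame > threshold_ratio * bg, frame > 0)
    return BinaryMask(grid=occupied, threshold_ratio=float(threshold_ratio))


def size_distribution(
    sizes: np.ndarray, bins_per_decade: int = DEFAULT_BINS_PER_DECADE
) -> SizeDistribution:
    """Logarithmically binned probability density of cluster sizes.

    Bin edges are decade-aligned powers of ``10^(1/bins_per_decade)``
    covering ``[min(sizes), max(sizes)]``.
    """
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size == 0:
        raise ValueError("empty size list")
    if np.any(sizes < 1):
        raise ValueError("cluster sizes must be >= 1")
    if bins_per_decade < 1:
        raise ValueError("bins_per_decade must be >= 1")
    lo, hi = np.log10(sizes.min()), np.log10(sizes.max())
    e0 = int(np.floor(lo * bins_per_decade + 1e-9))
    e1 = int(np.ceil(hi * bins_per_decade - 1e-9))
    if e1 <= e0:
        e1 = e0 + 1
    edges = 10.0 ** (np.arange(e0, e1 + 1) / bins_per_decade)
    # guard against float round-off pushing the extremes out of range
    edges[0] = min(edges[0], sizes.min())
    edges[-1] = max(edges[-1], sizes.max())
    counts, _ = np.histogram(sizes, bins=edges)
    widths = np.diff(edges)
    densities = counts / (sizes.size * widths)
    return SizeDistribution(bin_edges=edges, densities=densities, counts=counts)


def fit_power_law(
    dist: SizeDistribution, fit_range: tuple[float, float] | None = None
) -> PowerLawFit:
    """Fit ``P(A) ~ A^-alpha`` by weighted least squares in log-log space.

    Non-empty bins whose geometric centers fall inside ``fit_range`` are
    used; weights are the raw per-bin counts, so well-populated bins
    dominate.  At least 3 usable bins are required.
    """
    centers = dist.centers
    if fit_range is None:
        fit_range = (float(centers.min()), float(centers.max()))
    a_min, a_max = fit_range
    if not a_min < a_max:
        raise ValueError("fit range must satisfy A_min < A_max")
    counts = np.asarray(dist.counts, dtype=float)
    dens = np.asarray(dist.densities, dtype=float)
    keep = (counts > 0) & (dens > 0) & (centers >= a_min) & (centers <= a_max)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 usable bins inside the fit range")
    x = np.log10(centers[keep])
    y = np.log10(dens[keep])
    w = counts[keep]

    # weighted least squares for y = b0 + b1 x
    wsum = w.sum()
    xm, ym = (w * x).sum() / wsum, (w * y).sum() / wsum
    sxx = (w * (x - xm) ** 2).sum()
    slope = (w * (x - xm) * (y - ym)).sum() / sxx
    resid = y - (ym + slope * (x - xm))
    dof = keep.sum() - 2
    s2 = (w * resid**2).sum() / dof if dof > 0 else 0.0
    stderr = float(np.sqrt(s2 / sxx))
    return PowerLawFit(alpha=float(-slope), fit_range=(float(a_min), float(a_max)), stderr=stderr)


def cell_geometry(cell_mask: np.ndarray, pixel_size: float) -> CellGeometry:
    """Summarize a cell outline mask.

    Area is the pixel count times ``pixel_size**2``; the equivalent
    diameter is that of a circle with the same area; the perimeter is a
    Crofton-formula contour length of the mask boundary.
    """
    mask = np.asarray(cell_mask).astype(bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("cell mask must be a 2D mask with at least one pixel")
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    area = float(mask.sum()) * pixel_size**2
    perimeter = float(_skmeasure.perimeter_crofton(mask, directions=4)) * pixel_size
    diameter = 2.0 * np.sqrt(area / np.pi)
    return CellGeometry(
        cell_mask=mask, area=area, perimeter=perimeter, equivalent_diameter=diameter
    )


def cell_mask_from_stack(stack: FrameStack) -> np.ndarray:
    """Fallback cell outline: Otsu threshold of the median time-projection.

    The median over time suppresses transient bright clusters and keeps
    the persistent diffuse cell signal, so the threshold separates cell
    from background rather than clusters from everything else.  Intended
    for stacks without a user-supplied cell mask; holes are filled.
    """
    projection = np.median(stack.frames, axis=0)
    mask = projection > _skfilters.threshold_otsu(projection)
    return ndimage.binary_fill_holes(mask)


def density_timeseries(
    stack: FrameStack,
    geometry: CellGeometry,
    threshold_ratio: float = DEFAULT_THRESHOLD_RATIO,
    widths: tuple[float, float] = DEFAULT_SMOOTHING_WIDTHS,
    measure: str = "pixels",
) -> DensityTimeSeries:
    """Per-frame above-threshold signal scaled by the cell periphery.

    Two signal measures are offered.  ``"pixels"`` counts the occupied
    pixels of the segmented frame — the simplest convention, but the
    measured area of a cluster carries a PSF-broadening fringe whose
    relative weight depends on cluster size, which makes the measure
    mildly nonlinear in the true clustered area.  ``"intensity"`` sums the
    background-subtracted intensity over the occupied pixels; total
    fluorescence is conserved under PSF blurring, so this measure tracks
    the underlying clustered signal linearly and is preferred for regime
    timing.  Both are divided by the cell perimeter (micrometres) to make
    cells of different sizes comparable.
    """
    if geometry.cell_mask.shape != stack.frame_shape:
        raise ValueError("cell geometry does not match the frame dimensions")
    if measure not in ("pixels", "intensity"):
        raise ValueError("measure must be 'pixels' or 'intensity'")
    values = np.empty(stack.n_frames)
    for k, frame in enumerate(stack.frames):
        bg = estimate_background(frame, widths)
        mask = segment_clusters(frame, bg, threshold_ratio)
        if measure == "pixels":
            values[k] = np.count_nonzero(mask.grid)
        else:
            excess = np.clip(frame - bg.values, 0.0, None)
            values[k] = float(excess[mask.grid].sum())
    return DensityTimeSeries(
        timestamps=stack.timestamps.copy(), density=values / geometry.perimeter
    )


def segment_regimes(series: DensityTimeSeries) -> RegimeSegmentation:
    """Split a density time course into transient, growth and steady regimes.

    The steady mean and fluctuation band (mean +/- 1 SD) come from the
    trailing quarter of the samples, which must pass a stationarity check.
    The growth regime ends when the density first reaches ``1 - 1/e`` of
    the steady mean (mirroring the saturation-time definition of the
    kinetic model); the transient regime ends when it first exceeds 5% of
    the steady mean.

    Raises
    ------
    NoSteadyStateError
        If the series never settles (trailing window still drifting) or
        never reaches the growth criterion.
    """
    t = series.timestamps
    d = series.density
    if t.size < 10:
        raise ValueError("need at least 10 samples spanning the three regimes")
    _, steady_mean, sd = steady_window_stats(d)
    band = (steady_mean - sd, steady_mean + sd)

    if steady_mean == 0:
        return RegimeSegmentation(
            transient_end=float(t[0]), growth_end=float(t[0]),
            steady_mean=0.0, steady_band=band,
        )

    above_growth = d >= GROWTH_FRACTION * steady_mean
    if not above_growth.any():
        raise NoSteadyStateError("no steady state detected: growth criterion never met")
    growth_end = float(t[int(np.argmax(above_growth))])
    above_transient = d >= TRANSIENT_FRACTION * steady_mean
    transient_end = float(t[int(np.argmax(above_transient))])
    return RegimeSegmentation(
        transient_end=transient_end,
        growth_end=growth_end,
        steady_mean=steady_mean,
        steady_band=band,
    )
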