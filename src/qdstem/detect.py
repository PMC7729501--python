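"""Two-size-class quantum-dot detection in dark-field STEM frames.

The pipeline mirrors the classical ImageJ-style particle analysis used for
QD-labelled membrane receptors:

1. Gaussian smoothing to suppress shot noise.
2. FFT bandpass to remove the slowly varying cellular background (and,
   at the other end, residual single-pixel noise).
3. Maximum-entropy (Kapur) histogram thresholding to binarize.
4. Connected-component labelling.
5. Size gating: components whose pixel area corresponds to the physical
   diameter window of the large QD class (default 11 +/- 2 nm) are called
   "large"; a second window, derived from the first by a diameter ratio,
   calls the "small" class; everything else is rejected.

All stages are pure functions of their inputs, so a (image, config) pair
always reproduces byte-identical particle lists.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .image import ImageGrid

__all__ = [
    "SizeGate",
    "DetectionConfig",
    "ParticleRecord",
    "Component",
    "DetectionResult",
    "DegenerateHistogramError",
    "gaussian_smooth",
    "fourier_background_filter",
    "kapur_threshold",
    "diameter_to_area_px",
    "area_px_to_diameter",
    "label_components",
    "gate_particles",
    "derive_small_gate",
    "run_pipeline",
]

LARGE = "large"
SMALL = "small"
REJECTED = "rejected"


class DegenerateHistogramError(ValueError):
    """Raised when a histogram has fewer than two occupied bins."""


def diameter_to_area_px(d_nm: float, pixel_size_nm: float) -> float:
    """Projected disk area, in pixels^2, of a particle of physical diameter ``d_nm``.

    ``area = pi * (d/2)^2 / pixel_size^2``; strictly increasing in ``d``.
    """
    if d_nm <= 0 or pixel_size_nm <= 0:
        raise ValueError("diameter and pixel size must both be positive")
    return math.pi * (d_nm / 2.0) ** 2 / pixel_size_nm**2


def area_px_to_diameter(area_px: float, pixel_size_nm: float) -> float:
    """Equivalent circular diameter, in nm, of a component of ``area_px`` pixels.

    Exact inverse of :func:`diameter_to_area_px`:
    ``d = 2 * pixel_size * sqrt(area / pi)``.
    """
    if area_px < 0 or pixel_size_nm <= 0:
        raise ValueError("area must be >= 0 and pixel size > 0")
    return 2.0 * pixel_size_nm * math.sqrt(area_px / math.pi)


@dataclass(frozen=True)
class SizeGate:
    """Closed physical-diameter acceptance window for one QD class.

    The gate is specified in nanometres and converted to a pixel-area
    interval ``[a_min_px, a_max_px]`` through :func:`diameter_to_area_px`
    once the pixel size is known.  Both interval ends are inclusive.
    """

    class_label: str
    d_min_nm: float
    d_max_nm: float

    def __post_init__(self) -> None:
        if self.class_label not in (LARGE, SMALL):
            raise ValueError(f"class_label must be 'large' or 'small', got {self.class_label!r}")
        if not (0 < self.d_min_nm < self.d_max_nm):
            raise ValueError(
                f"need 0 < d_min < d_max, got [{self.d_min_nm}, {self.d_max_nm}]"
            )

    def area_bounds_px(self, pixel_size_nm: float) -> tuple[float, float]:
        a_min = diameter_to_area_px(self.d_min_nm, pixel_size_nm)
        a_max = diameter_to_area_px(self.d_max_nm, pixel_size_nm)
        if a_min < 1.0:
            raise ValueError(
                f"gate [{self.d_min_nm}, {self.d_max_nm}] nm spans less than one "
                f"pixel at {pixel_size_nm} nm/px"
            )
        return a_min, a_max

    def contains_area(self, area_px: float, pixel_size_nm: float) -> bool:
        a_min, a_max = self.area_bounds_px(pixel_size_nm)
        return a_min <= area_px <= a_max


def derive_small_gate(large_gate: SizeGate, diameter_ratio: float = 7.0 / 11.0) -> SizeGate:
    """Scale the large-QD gate down to the small class by a diameter ratio.

    The user sets the large gate manually (11 +/- 2 nm for the larger QD
    conjugate); the small gate is adopted automatically by multiplying both
    diameter bounds by ``diameter_ratio`` (< 1).  If the scaled upper bound
    would overlap the large gate it is clipped just below ``large.d_min`` so
    the two windows stay disjoint.
    """
    if not (0 < diameter_ratio < 1):
        raise ValueError(f"diameter_ratio must be in (0, 1), got {diameter_ratio}")
    d_min = large_gate.d_min_nm * diameter_ratio
    d_max = large_gate.d_max_nm * diameter_ratio
    if d_max >= large_gate.d_min_nm:
        warnings.warn(
            "derived small gate overlaps the large gate; clipping its upper "
            "bound below the large gate's lower bound",
            stacklevel=2,
        )
        d_max = large_gate.d_min_nm - 1e-6
    return SizeGate(SMALL, d_min, d_max)


@dataclass
class DetectionConfig:
    """Parameters of the detection pipeline.

    Attributes
    ----------
    gaussian_sigma_px:
        Standard deviation of the denoising Gaussian (the classical
        "radius 1.5 px" filter, interpreted as sigma).
    bandpass_large_cutoff_px / bandpass_small_cutoff_px:
        Characteristic structure sizes: features larger than the large
        cutoff (cell background, including the DC level) are suppressed,
        features smaller than the small cutoff attenuated.  The large
        cutoff also sets how tightly the local mean is subtracted around
        each particle and thereby where the entropy-threshold contour
        falls on the blurred particle edge; the 20 px default keeps
        apparent blob areas close to the physical footprint while still
        passing QD-scale structure.
    histogram_bins:
        Bin count of the min-max rescaled histogram fed to the
        maximum-entropy threshold.
    large_gate / small_gate:
        Physical diameter windows of the two QD classes.  When
        ``small_gate`` is None it is derived from the large gate with
        ``small_large_diameter_ratio``.
    connectivity:
        4 or 8 pixel connectivity for component labelling.
    """

    gaussian_sigma_px: float = 1.5
    bandpass_large_cutoff_px: float = 20.0
    bandpass_small_cutoff_px: float = 2.0
    histogram_bins: int = 256
    large_gate: SizeGate = field(default_factory=lambda: SizeGate(LARGE, 9.0, 13.0))
    small_gate: SizeGate | None = None
    small_large_diameter_ratio: float = 7.0 / 11.0
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.gaussian_sigma_px <= 0:
            raise ValueError("gaussian_sigma_px must be > 0")
        if not (0 < self.bandpass_small_cutoff_px < self.bandpass_large_cutoff_px):
            raise ValueError("need 0 < small cutoff < large cutoff")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.small_gate is None:
            self.small_gate = derive_small_gate(
                self.large_gate, self.small_large_diameter_ratio
            )
        if self.small_gate.d_max_nm >= self.large_gate.d_min_nm:
            raise ValueError("size gates overlap: small.d_max must be < large.d_min")


@dataclass(frozen=True)
class ParticleRecord:
    """One detected spot: centroid, area and assigned QD class."""

    x_px: float
    y_px: float
    area_px: int
    equivalent_diameter_nm: float
    class_label: str
    on_edge: bool = False


@dataclass(frozen=True)
class Component:
    """A connected foreground component prior to size gating."""

    area_px: int
    x_px: float
    y_px: float
    on_edge: bool


@dataclass
class DetectionResult:
    """Output of :func:`run_pipeline`: the two class lists plus bookkeeping."""

    large: list[ParticleRecord]
    small: list[ParticleRecord]
    rejected: list[ParticleRecord]
    threshold_bin: int | None

    @property
    def n_components(self) -> int:
        return len(self.large) + len(self.small) + len(self.rejected)


def gaussian_smooth(image: ImageGrid, sigma_px: float) -> ImageGrid:
    """Convolve with a normalized isotropic Gaussian (reflective boundaries)."""
    if sigma_px <= 0:
        raise ValueError(f"sigma_px must be > 0, got {sigma_px}")
    smoothed = ndimage.gaussian_filter(
        image.values.astype(np.float64), sigma=sigma_px, mode="reflect"
    )
    return ImageGrid(smoothed, image.pixel_size_nm)


def _bandpass_transfer(shape: tuple[int, int], large_cutoff_px: float,
                       small_cutoff_px: float) -> np.ndarray:
    # Gaussian rolloff with half-power at structure size == cutoff:
    #   high-pass 1 - exp(-(f L)^2 ln2), low-pass exp(-(f S)^2 ln2),
    # f the radial frequency in cycles/px, so a sinusoid of period exactly
    # L (or S) px is attenuated to 50%.
    ny, nx = shape
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.rfftfreq(nx)[None, :]
    f2 = fx**2 + fy**2
    ln2 = math.log(2.0)
    high_pass = 1.0 - np.exp(-f2 * large_cutoff_px**2 * ln2)
    low_pass = np.exp(-f2 * small_cutoff_px**2 * ln2)
    return high_pass * low_pass


def fourier_background_filter(
    image: ImageGrid,
    large_cutoff_px: float,
    small_cutoff_px: float,
    *,
    offset_to_non_negative: bool = True,
) -> ImageGrid:
    """Frequency-domain bandpass removing background and single-pixel noise.

    Structures of characteristic size above ``large_cutoff_px`` — including
    the DC component, so the output is zero-mean before the offset — are
    suppressed; structures below ``small_cutoff_px`` are attenuated.  The
    rolloff is Gaussian in squared frequency with half-power exactly at each
    cutoff.  For downstream histogram thresholding the result is shifted by
    the negation of its minimum so intensities are non-negative.
    """
    ny, nx = image.shape
    if large_cutoff_px > max(ny, nx):
        raise ValueError(
            f"large cutoff {large_cutoff_px} px exceeds frame size {max(ny, nx)} px"
        )
    if not (0 < small_cutoff_px < large_cutoff_px):
        raise ValueError("need 0 < small cutoff < large cutoff")
    values = image.values.astype(np.float64)
    spectrum = np.fft.rfft2(values)
    spectrum *= _bandpass_transfer((ny, nx), large_cutoff_px, small_cutoff_px)
    filtered = np.fft.irfft2(spectrum, s=(ny, nx))
    if offset_to_non_negative:
        filtered -= filtered.min()
    return ImageGrid(filtered, image.pixel_size_nm)


def kapur_threshold(histogram: Sequence[int] | np.ndarray) -> int:
    """Maximum-entropy threshold of a gray-level histogram.

    Returns the bin index ``t`` maximizing ``H_background(t) +
    H_foreground(t)`` where background = bins ``<= t``, foreground = bins
    ``> t`` and ``H`` is the Shannon entropy of the class-normalized bin
    probabilities.  A class with zero mass contributes zero entropy.  Ties
    are broken towards the smallest ``t``.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two bins are occupied (no split can separate
        foreground from background).
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("histogram must be a 1-D array with at least two bins")
    if np.any(h < 0):
        raise ValueError("histogram counts must be non-negative")
    if int(np.count_nonzero(h)) < 2:
        raise DegenerateHistogramError("histogram has fewer than two occupied bins")

    p = h / h.sum()
    cum = np.cumsum(p)                       # P(t): background mass for split t
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    s = np.cumsum(plogp)                     # sum p ln p over bins <= t
    s_total = s[-1]

    back_mass = cum[:-1]
    fore_mass = 1.0 - back_mass
    tiny = np.finfo(np.float64).tiny
    h_back = np.where(
        back_mass > 0,
        np.log(np.maximum(back_mass, tiny)) - s[:-1] / np.maximum(back_mass, tiny),
        0.0,
    )
    h_fore = np.where(
        fore_mass > tiny,
        np.log(np.maximum(fore_mass, tiny))
        - (s_total - s[:-1]) / np.maximum(fore_mass, tiny),
        0.0,
    )
    total = h_back + h_fore
    # smallest-t tie break, tolerant of float round-off between exactly
    # tied splits (e.g. symmetric histograms)
    best = float(total.max())
    tol = 1e-10 * max(1.0, abs(best))
    return int(np.argmax(total >= best - tol))


_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCTURE_8 = np.ones((3, 3), dtype=bool)


def label_components(binary: np.ndarray, connectivity: int = 8) -> list[Component]:
    """Connected components of a boolean mask with area, centroid, edge flag.

    The centroid is the arithmetic mean of member pixel coordinates
    (x = column, y = row).  Components touching the frame boundary are kept
    but flagged ``on_edge``.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 2:
        raise ValueError("binary image must be 2-D")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    structure = _STRUCTURE_4 if connectivity == 4 else _STRUCTURE_8
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(binary, labels, idx).astype(int)
    # centroid: mean of (row, col) per label
    centroids = ndimage.center_of_mass(binary, labels, idx)
    edge_labels = np.unique(
        np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
    )
    edge_set = set(int(v) for v in edge_labels if v > 0)
    out = []
    for lab, area, (cy, cx) in zip(idx, areas, centroids):
        out.append(
            Component(
                area_px=int(area),
                x_px=float(cx),
                y_px=float(cy),
                on_edge=int(lab) in edge_set,
            )
        )
    return out


def gate_particles(
    components: Iterable[Component],
    large_gate: SizeGate,
    small_gate: SizeGate,
    pixel_size_nm: float,
) -> list[ParticleRecord]:
    """Assign each component to exactly one of {large, small, rejected}.

    Gates are closed intervals in pixel area; a component area exactly on a
    bound is included.  Counts are conserved: every input component appears
    once in the output.
    """
    la_min, la_max = large_gate.area_bounds_px(pixel_size_nm)
    sa_min, sa_max = small_gate.area_bounds_px(pixel_size_nm)
    if sa_max >= la_min:
        raise ValueError("size gates overlap in area")
    records = []
    for comp in components:
        a = comp.area_px
        if la_min <= a <= la_max:
            label = LARGE
        elif sa_min <= a <= sa_max:
            label = SMALL
        else:
            label = REJECTED
        records.append(
            ParticleRecord(
                x_px=comp.x_px,
                y_px=comp.y_px,
                area_px=a,
                equivalent_diameter_nm=area_px_to_diameter(a, pixel_size_nm),
                class_label=label,
                on_edge=comp.on_edge,
            )
        )
    return records


def run_pipeline(image: ImageGrid, config: DetectionConfig) -> DetectionResult:
    """Full detection chain: smooth, bandpass, threshold, label, gate.

    The bandpassed image is min-max rescaled into ``histogram_bins`` bins;
    the maximum-entropy split ``t`` defines foreground as pixels falling in
    bins ``> t``.  A flat (degenerate) histogram means nothing is detectable
    and yields empty lists.
    """
    smoothed = gaussian_smooth(image, config.gaussian_sigma_px)
    filtered = fourier_background_filter(
        smoothed, config.bandpass_large_cutoff_px, config.bandpass_small_cutoff_px
    )
    values = filtered.values
    vmin = float(values.min())
    vmax = float(values.max())
    nbins = config.histogram_bins
    if vmax <= vmin:
        return DetectionResult([], [], [], None)
    scaled = (values - vmin) / (vmax - vmin)
    bin_index = np.minimum((scaled * nbins).astype(np.int64), nbins - 1)
    histogram = np.bincount(bin_index.ravel(), minlength=nbins)
    try:
        t = kapur_threshold(histogram)
    except DegenerateHistogramError:
        return DetectionResult([], [], [], None)
    binary = bin_index > t
    components = label_components(binary, config.connectivity)
    assert config.small_gate is not None
    records = gate_particles(
        components, config.large_gate, config.small_gate, image.pixel_size_nm
    )
    large = [r for r in records if r.class_label == LARGE]
    small = [r for r in records if r.class_label == SMALL]
    rejected = [r for r in records if r.class_label == REJECTED]
    return DetectionResult(large, small, rejected, t)
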