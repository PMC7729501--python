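"""Synthetic annular dark-field STEM frames of QD-labelled cell membranes.

Real acquisitions of this kind are not publicly deposited, so every
downstream stage is exercised against simulated frames with exhaustive
ground truth.  A frame is built as

    background level
  + correlated Gaussian texture (membrane / cell material)
  + bright quasi-circular particles of two diameter classes
  + Poisson counting noise,

clipped to the 16-bit range.  Particle positions follow a homogeneous
Poisson process at the configured surface density inside each region mask;
an optional hard-core distance is enforced by sequential dart-throwing
(candidates violating the minimum separation are redrawn), which preserves
the expected count ``density x area`` at densities well below the jamming
limit, unlike post-hoc thinning.  Identical (config, seed) pairs produce
bit-identical images and truth tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import erfc

from .detect import LARGE, SMALL
from .image import ImageGrid
from .quantify import RegionAnnotation

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_field",
    "generate_region_layout",
    "write_truth",
    "read_truth",
]

_TRUTH_COLUMNS = ["x", "y", "class", "diameter_nm"]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dark-field STEM field of view.

    Geometry defaults follow the modelled acquisition (0.83 nm pixels;
    512 x 512 px test frames, 2048 x 2048 px full frames).  Rendered
    diameters are the electron-dense core scales of the two conjugates
    (large 10.0 +/- 0.7 nm, small 5.5 +/- 0.5 nm), calibrated so that the
    APPARENT particle sizes after the detection pipeline's blur and
    entropy-threshold contour (which dilates radii by ~0.5-1 px) fall at
    the centres of the 9-13 nm large gate and the derived small gate.
    Default densities correspond to the most frequently sampled membrane
    condition (clustered regions of bulk cells): ~270 small labels/um^2
    and ~6.6 large labels/um^2.  Amplitudes are intensity counts above
    local background; the large class defaults to 1.5x the small one
    (more scattering mass).
    """

    frame_size_px: tuple[int, int] = (512, 512)
    pixel_size_nm: float = 0.83
    large_diameter_nm: tuple[float, float] = (10.0, 0.7)   # mean, SD
    small_diameter_nm: tuple[float, float] = (5.5, 0.5)
    density_large_per_um2: float = 6.6
    density_small_per_um2: float = 270.0
    particle_amplitude_large: float = 9000.0
    particle_amplitude_small: float = 6000.0
    background_level: float = 3000.0
    texture_amplitude: float = 500.0
    texture_correlation_px: float = 50.0
    noise_gain: float = 0.05        # Poisson counts per intensity unit; 0 = noiseless
    min_separation_nm: float | None = None
    edge_sigma_px: float = 1.0      # Gaussian softness of the rendered disk edge
    seed: int = 0

    def __post_init__(self) -> None:
        ny, nx = self.frame_size_px
        if ny < 64 or nx < 64:
            raise ValueError(f"frame must be at least 64 px per side, got {ny}x{nx}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        for name in ("large_diameter_nm", "small_diameter_nm"):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and SD >= 0")
        if self.small_diameter_nm[0] >= self.large_diameter_nm[0]:
            raise ValueError("small mean diameter must be below the large mean diameter")
        if self.density_large_per_um2 < 0 or self.density_small_per_um2 < 0:
            raise ValueError("densities must be >= 0")
        if self.particle_amplitude_large <= 0 or self.particle_amplitude_small <= 0:
            raise ValueError("particle amplitudes must be > 0")
        if self.background_level < 0 or self.texture_amplitude < 0:
            raise ValueError("background and texture levels must be >= 0")
        if self.noise_gain < 0:
            raise ValueError("noise_gain must be >= 0")
        if self.min_separation_nm is not None and self.min_separation_nm <= 0:
            raise ValueError("min_separation_nm must be > 0 when set")

    @property
    def frame_area_um2(self) -> float:
        ny, nx = self.frame_size_px
        return ny * nx * (self.pixel_size_nm / 1000.0) ** 2

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=int(seed))


@dataclass
class GroundTruth:
    """Everything the simulator knows about one frame.

    ``particles`` holds one row per rendered QD (sub-pixel centre, class,
    sampled physical diameter); ``region_masks`` the annotations particles
    were placed in; ``true_density`` the realized count/area per
    (region label, class).
    """

    particles: pd.DataFrame
    region_masks: list[RegionAnnotation]
    true_density: dict[tuple[str, str], float]

    def count(self, class_label: str | None = None) -> int:
        if class_label is None:
            return len(self.particles)
        return int((self.particles["class"] == class_label).sum())


def generate_region_layout(
    frame_size_px: tuple[int, int],
    pixel_size_nm: float,
    layout_spec: Sequence[Mapping[str, object]],
) -> list[RegionAnnotation]:
    """Partition a frame into vertical-strip region masks by area fraction.

    ``layout_spec`` is a sequence of mappings with keys ``label`` (one of
    LMP / clustered / flat / background), ``fraction`` (target area
    fraction) and optionally ``subtype``, ``cell_id``, ``image_id``.  The
    strips are laid out left to right, never overlap, and cover at most the
    whole frame; each annotation's area is its pixel count times the pixel
    area.
    """
    ny, nx = frame_size_px
    if pixel_size_nm <= 0:
        raise ValueError("pixel_size_nm must be > 0")
    fractions = [float(spec["fraction"]) for spec in layout_spec]
    if any(f < 0 for f in fractions):
        raise ValueError("area fractions must be >= 0")
    if sum(fractions) > 1.0 + 1e-9:
        raise ValueError(f"area fractions sum to {sum(fractions):.3f} > 1")
    annotations = []
    left = 0
    cum = 0.0
    for spec in layout_spec:
        cum += float(spec["fraction"])
        right = int(round(cum * nx))
        mask = np.zeros((ny, nx), dtype=bool)
        mask[:, left:right] = True
        label = str(spec["label"])
        subtype = str(
            spec.get("subtype", "none" if label == "background" else "bulk")
        )
        area_um2 = int(mask.sum()) * (pixel_size_nm / 1000.0) ** 2
        if area_um2 <= 0:
            raise ValueError(f"region {label!r} received zero pixels")
        annotations.append(
            RegionAnnotation(
                region_label=label,
                subtype=subtype,
                cell_id=str(spec.get("cell_id", "cell0")),
                image_id=str(spec.get("image_id", "image0")),
                area_um2=area_um2,
                mask=mask,
            )
        )
        left = right
    return annotations


def _correlated_texture(
    rng: np.random.Generator,
    shape: tuple[int, int],
    amplitude: float,
    correlation_px: float,
) -> np.ndarray:
    """Zero-mean Gaussian random field with SD ``amplitude`` and the given
    correlation length (white noise smoothed and rescaled)."""
    white = rng.standard_normal(shape)
    if correlation_px > 0:
        smooth = ndimage.gaussian_filter(white, sigma=correlation_px, mode="wrap")
    else:
        smooth = white
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return amplitude * (smooth - smooth.mean()) / sd


def _render_particle(
    canvas: np.ndarray,
    x: float,
    y: float,
    radius_px: float,
    amplitude: float,
    edge_sigma_px: float,
) -> None:
    """Add a flat-top disk with a Gaussian-smoothed edge at sub-pixel (x, y)."""
    ny, nx = canvas.shape
    margin = radius_px + 4.0 * edge_sigma_px
    x0 = max(int(math.floor(x - margin)), 0)
    x1 = min(int(math.ceil(x + margin)) + 1, nx)
    y0 = max(int(math.floor(y - margin)), 0)
    y1 = min(int(math.ceil(y + margin)) + 1, ny)
    if x0 >= x1 or y0 >= y1:
        return
    # pixel index i samples the continuous field at coordinate i (pixel
    # centres on the integer grid), matching the centroid convention of the
    # detector's component labelling
    yy, xx = np.mgrid[y0:y1, x0:x1]
    rho = np.hypot(xx - x, yy - y)
    # 0.5*erfc is the radial profile of a hard disk edge blurred by a
    # Gaussian of SD edge_sigma_px: amplitude inside, 0 outside, half at rho=r.
    canvas[y0:y1, x0:x1] += amplitude * 0.5 * erfc(
        (rho - radius_px) / (edge_sigma_px * math.sqrt(2.0))
    )


def _sample_positions(
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    min_sep_px: float | None,
    accepted: list[tuple[float, float]],
    max_attempts: int = 200,
) -> list[tuple[float, float]]:
    """Uniform positions inside ``mask`` honouring a global hard-core distance."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        if n > 0:
            warnings.warn("empty region mask: requested particles dropped", stacklevel=2)
        return []
    placed: list[tuple[float, float]] = []
    dropped = 0
    for _ in range(n):
        ok = False
        for _attempt in range(max_attempts):
            k = int(rng.integers(rows.size))
            # uniform within the selected pixel's extent [i-0.5, i+0.5),
            # clipped so the centroid stays inside the frame
            ny_m, nx_m = mask.shape
            x = min(max(float(cols[k]) - 0.5 + float(rng.random()), 0.0), nx_m - 1.0)
            y = min(max(float(rows[k]) - 0.5 + float(rng.random()), 0.0), ny_m - 1.0)
            if min_sep_px is not None and (accepted or placed):
                # toroidal distance: keeps the hard-core process spatially
                # homogeneous up to the frame edge (a plain bounded-window
                # check leaves excess density near the boundary, depleting
                # the interior); wrap distance <= real distance, so the
                # real-space minimum separation is still guaranteed
                pts = np.asarray(accepted + placed)
                dx = np.abs(pts[:, 0] - x)
                dy = np.abs(pts[:, 1] - y)
                dx = np.minimum(dx, nx_m - dx)
                dy = np.minimum(dy, ny_m - dy)
                if float((dx**2 + dy**2).min()) < min_sep_px**2:
                    continue
            placed.append((x, y))
            ok = True
            break
        if not ok:
            dropped += 1
    if dropped:
        warnings.warn(
            f"hard-core constraint could not place {dropped} particle(s); "
            "requested density may be near the packing limit",
            stacklevel=2,
        )
    return placed


def simulate_field(
    config: SimulationConfig,
    regions: Sequence[RegionAnnotation] | None = None,
    region_densities: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[ImageGrid, GroundTruth]:
    """Render one simulated frame and its exhaustive ground truth.

    Parameters
    ----------
    config:
        Simulation parameters; ``config.seed`` fully determines the output.
    regions:
        Region annotations (with frame-shaped masks) to place particles in.
        Defaults to a single full-frame "clustered" region on a bulk cell.
    region_densities:
        Optional per-region-label override mapping ``label -> (large, small)``
        densities in QDs/um^2; labels not listed use the config densities.

    Returns
    -------
    (ImageGrid, GroundTruth)
        A 16-bit frame and the particle/region/density truth.
    """
    ny, nx = config.frame_size_px
    if regions is None:
        regions = generate_region_layout(
            (ny, nx),
            config.pixel_size_nm,
            [{"label": "clustered", "fraction": 1.0, "subtype": "bulk"}],
        )
    for ann in regions:
        if ann.mask is None or ann.mask.shape != (ny, nx):
            raise ValueError(
                "every simulation region needs a mask matching the frame shape"
            )

    def _densities(label: str) -> tuple[float, float]:
        if region_densities is not None and label in region_densities:
            return region_densities[label]
        return config.density_large_per_um2, config.density_small_per_um2

    expected = sum(
        sum(_densities(ann.region_label)) * ann.area_um2 for ann in regions
    )
    if expected > 0.25 * ny * nx:
        raise ValueError(
            f"density infeasible: expected {expected:.0f} particles exceeds a "
            f"quarter of the {ny * nx} frame pixels"
        )

    rng = np.random.default_rng(config.seed)
    canvas = np.full((ny, nx), float(config.background_level))

    if config.texture_amplitude > 0:
        texture = _correlated_texture(
            rng, (ny, nx), config.texture_amplitude, config.texture_correlation_px
        )
        cell_mask = np.zeros((ny, nx), dtype=bool)
        for ann in regions:
            if ann.region_label != "background":
                cell_mask |= ann.mask
        canvas[cell_mask] += texture[cell_mask]

    min_sep_px = (
        config.min_separation_nm / config.pixel_size_nm
        if config.min_separation_nm is not None
        else None
    )

    class_params = {
        LARGE: (config.large_diameter_nm, config.particle_amplitude_large),
        SMALL: (config.small_diameter_nm, config.particle_amplitude_small),
    }
    accepted: list[tuple[float, float]] = []
    rows: list[dict] = []
    counts: dict[tuple[str, str], int] = {}
    for ann in regions:
        dens = dict(zip((LARGE, SMALL), _densities(ann.region_label)))
        for cls in (LARGE, SMALL):
            lam = dens[cls] * ann.area_um2
            n = int(rng.poisson(lam)) if lam > 0 else 0
            positions = _sample_positions(rng, ann.mask, n, min_sep_px, accepted)
            (d_mean, d_sd), amplitude = class_params[cls]
            diameters = np.maximum(
                rng.normal(d_mean, d_sd, size=len(positions)), 0.1 * d_mean
            )
            for (x, y), d_nm in zip(positions, diameters):
                radius_px = d_nm / (2.0 * config.pixel_size_nm)
                _render_particle(
                    canvas, x, y, radius_px, amplitude, config.edge_sigma_px
                )
                rows.append(
                    {"x": x, "y": y, "class": cls, "diameter_nm": float(d_nm)}
                )
            accepted.extend(positions)
            counts[(ann.region_label, cls)] = counts.get(
                (ann.region_label, cls), 0
            ) + len(positions)

    if config.noise_gain > 0:
        counts_img = rng.poisson(np.clip(canvas, 0.0, None) * config.noise_gain)
        canvas = counts_img / config.noise_gain

    values = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    image = ImageGrid(values, config.pixel_size_nm)

    area_by_label: dict[str, float] = {}
    for ann in regions:
        area_by_label[ann.region_label] = (
            area_by_label.get(ann.region_label, 0.0) + ann.area_um2
        )
    true_density = {
        (label, cls): counts.get((label, cls), 0) / area_by_label[label]
        for label in area_by_label
        for cls in (LARGE, SMALL)
    }
    particles = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    truth = GroundTruth(
        particles=particles, region_masks=list(regions), true_density=true_density
    )
    return image, truth


def write_truth(truth: GroundTruth, path) -> None:
    """Write the particle truth table as CSV (columns x, y, class, diameter_nm)."""
    truth.particles.to_csv(path, index=False, columns=_TRUTH_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    """Read a truth CSV back into a DataFrame (lossless round-trip)."""
    frame = pd.read_csv(path)
    missing = set(_TRUTH_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"truth file missing columns: {sorted(missing)}")
    return frame[_TRUTH_COLUMNS]
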