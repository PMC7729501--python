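"""File formats and configuration loading.

Images travel as 16-bit single-channel grayscale TIFF (the export dialect
of the modelled acquisitions); particle lists, region tables and per-cell
intensities as comma-separated UTF-8 CSV with a header row; configuration
as YAML (JSON being a YAML subset, .json files load too).  The physical
pixel size always comes from configuration — TIFF metadata is never
trusted silently.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import DetectionConfig, ParticleRecord, SizeGate
from .image import ImageGrid
from .quantify import RegionAnnotation
from .simulate import SimulationConfig

__all__ = [
    "ImageFormatError",
    "read_image",
    "write_image",
    "write_particles",
    "read_particles",
    "write_regions",
    "read_regions",
    "load_config_file",
    "simulation_config_from_dict",
    "detection_config_from_dict",
]


class ImageFormatError(ValueError):
    """Raised when an image file cannot be read as 16-bit grayscale TIFF."""


def read_image(path, pixel_size_nm: float) -> ImageGrid:
    """Read a single-channel grayscale TIFF into an :class:`ImageGrid`.

    8-bit inputs are upcast to 16-bit with a warning; multi-channel images,
    truncated or otherwise unreadable files raise :class:`ImageFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # tifffile raises several exception types
        raise ImageFormatError(f"cannot read {path} as TIFF: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ImageFormatError(
            f"{path}: expected single-channel 2-D image, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        warnings.warn(f"{path}: 8-bit input upcast to 16-bit", stacklevel=2)
        arr = arr.astype(np.uint16) * 257  # maps 255 -> 65535
    elif arr.dtype != np.uint16:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ImageFormatError(
                f"{path}: unsupported dtype {arr.dtype}; expected 8/16-bit grayscale"
            )
        arr = arr.astype(np.uint16)
    return ImageGrid(arr, pixel_size_nm)


def write_image(image: ImageGrid, path) -> None:
    """Write an :class:`ImageGrid` as uncompressed 16-bit grayscale TIFF."""
    values = image.values
    if values.dtype != np.uint16:
        values = np.clip(np.rint(values), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, values, photometric="minisblack")


_PARTICLE_COLUMNS = ["x", "y", "area_px", "equivalent_diameter_nm", "class"]


def write_particles(records: Iterable[ParticleRecord], path) -> None:
    """Write a particle list (one detected class per file, mirroring the
    separate large/small coordinate lists)."""
    frame = pd.DataFrame(
        [
            {
                "x": r.x_px,
                "y": r.y_px,
                "area_px": r.area_px,
                "equivalent_diameter_nm": r.equivalent_diameter_nm,
                "class": r.class_label,
            }
            for r in records
        ],
        columns=_PARTICLE_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_particles(path) -> pd.DataFrame:
    """Read a particle CSV; requires at least x, y and class columns."""
    frame = pd.read_csv(path)
    missing = {"x", "y", "class"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: particle table missing columns {sorted(missing)}")
    return frame


_REGION_COLUMNS = ["image_id", "cell_id", "subtype", "region_label", "area_um2"]


def write_regions(annotations: Iterable[RegionAnnotation], path,
                  mask_path=None) -> None:
    """Write region annotations as CSV; masks optionally as an 8-bit label TIFF.

    When ``mask_path`` is given, regions of one frame are encoded as
    integer labels 1..n in file order and the CSV gains ``mask_path`` and
    ``mask_label`` columns.
    """
    annotations = list(annotations)
    rows = []
    label_image = None
    for i, ann in enumerate(annotations, start=1):
        row = {
            "image_id": ann.image_id,
            "cell_id": ann.cell_id,
            "subtype": ann.subtype,
            "region_label": ann.region_label,
            "area_um2": ann.area_um2,
        }
        if mask_path is not None:
            if ann.mask is None:
                raise ValueError("cannot write a label image: annotation has no mask")
            if label_image is None:
                label_image = np.zeros(ann.mask.shape, dtype=np.uint8)
            label_image[ann.mask] = i
            row["mask_path"] = str(mask_path)
            row["mask_label"] = i
        rows.append(row)
    columns = _REGION_COLUMNS + (["mask_path", "mask_label"] if mask_path else [])
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    if mask_path is not None and label_image is not None:
        tifffile.imwrite(mask_path, label_image, photometric="minisblack")


def read_regions(path) -> list[RegionAnnotation]:
    """Read region annotations; reload masks when the CSV references a label TIFF."""
    frame = pd.read_csv(path)
    missing = set(_REGION_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: region table missing columns {sorted(missing)}")
    has_masks = "mask_path" in frame.columns and "mask_label" in frame.columns
    label_images: dict[str, np.ndarray] = {}
    annotations = []
    base = Path(path).parent
    for _, row in frame.iterrows():
        mask = None
        if has_masks and not pd.isna(row["mask_path"]):
            mask_file = Path(str(row["mask_path"]))
            if not mask_file.is_absolute():
                mask_file = base / mask_file
            key = str(mask_file)
            if key not in label_images:
                label_images[key] = tifffile.imread(mask_file)
            mask = label_images[key] == int(row["mask_label"])
        annotations.append(
            RegionAnnotation(
                region_label=str(row["region_label"]),
                subtype=str(row["subtype"]),
                cell_id=str(row["cell_id"]),
                image_id=str(row["image_id"]),
                area_um2=float(row["area_um2"]),
                mask=mask,
            )
        )
    return annotations


def load_config_file(path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def _take(data: dict, fields: set[str], context: str) -> dict:
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return dict(data)


_SIM_FIELDS = {
    "frame_size_px", "pixel_size_nm", "large_diameter_nm", "small_diameter_nm",
    "density_large_per_um2", "density_small_per_um2", "particle_amplitude_large",
    "particle_amplitude_small", "background_level", "texture_amplitude",
    "texture_correlation_px", "noise_gain", "min_separation_nm",
    "edge_sigma_px", "seed",
}


def simulation_config_from_dict(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain mapping (e.g. YAML)."""
    kwargs = _take(data, _SIM_FIELDS, "simulation")
    for key in ("frame_size_px", "large_diameter_nm", "small_diameter_nm"):
        if key in kwargs and isinstance(kwargs[key], (list, tuple)):
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)


_DET_FIELDS = {
    "gaussian_sigma_px", "bandpass_large_cutoff_px", "bandpass_small_cutoff_px",
    "histogram_bins", "large_gate", "small_gate", "small_large_diameter_ratio",
    "connectivity",
}


def detection_config_from_dict(data: dict) -> DetectionConfig:
    """Build a :class:`DetectionConfig` from a plain mapping.

    Gates may be given as ``[d_min_nm, d_max_nm]`` pairs.
    """
    kwargs = _take(data, _DET_FIELDS, "detection")
    if "large_gate" in kwargs and isinstance(kwargs["large_gate"], (list, tuple)):
        lo, hi = kwargs["large_gate"]
        kwargs["large_gate"] = SizeGate("large", float(lo), float(hi))
    if "small_gate" in kwargs and isinstance(kwargs["small_gate"], (list, tuple)):
        lo, hi = kwargs["small_gate"]
        kwargs["small_gate"] = SizeGate("small", float(lo), float(hi))
    return DetectionConfig(**kwargs)
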