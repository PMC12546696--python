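"""Containers and file I/O for OCT/OCTA volume series and en face maps.

Axis convention (used project-wide)
-----------------------------------
Volume arrays are indexed ``(z, x, y)``:

* ``z`` — depth along an A-scan, with the vitreous at ``z = 0`` and the
  posterior retina at large ``z`` ("above the ILM" therefore means
  *smaller* ``z``);
* ``x`` — fast-scan position within a B-scan;
* ``y`` — slow-scan position, i.e. the B-scan index.

En face maps are indexed ``(x, y)``.  Spacings are physical voxel sizes
in micrometers, ordered to match the array axes.

OCTA intensities are treated as arbitrary linear units; no log/dB
conversion is applied anywhere.  The coefficient of variation is
invariant under a global intensity rescaling, so linear units are the
safe default.

Supported on-disk formats are multi-page TIFF (one B-scan per page, page
index = ``y``) and NIfTI-1.  NIfTI round-trips are lossless at floating
point precision.  TIFF intensity volumes are quantized to 16 bit with
the original range stored in the page description, masks are written as
8-bit ``{0, 255}``.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import tifffile
import yaml


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(ValueError):
    """File content is structurally inconsistent with the declared format."""


class Modality(str, enum.Enum):
    OCT = "OCT"
    OCTA = "OCTA"
    COV = "COV"
    MASK = "MASK"
    DEPTH_INDEX = "DEPTH_INDEX"


class MapKind(str, enum.Enum):
    OCTA = "OCTA"
    COV = "COV"
    VARIANCE = "VARIANCE"
    DEPTH_STD = "DEPTH_STD"
    PROBABILITY = "PROBABILITY"
    MASK = "MASK"


def _as_float(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.floating):
        return arr
    return arr.astype(np.float64)


@dataclass
class VolumeGrid:
    """A 3D scalar field indexed ``(z, x, y)`` with physical voxel spacing.

    Carrier type for OCT / OCTA intensity volumes and all derived
    volumetric fields (CoV, binary masks, depth indices).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = Modality.OCTA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 3 positive values, got {self.spacing}")
        self.spacing = spacing
        self.modality = Modality(self.modality)
        if self.modality in (Modality.OCT, Modality.OCTA, Modality.COV):
            self.data = _as_float(self.data)
        if self.modality is Modality.MASK:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("MASK volume may only contain values {0, 1}")
        elif self.modality is Modality.COV:
            if not np.isfinite(self.data).all():
                raise ValidationError("COV volume must be finite everywhere")
            if (self.data < 0).any():
                raise ValidationError("COV volume must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def nz(self) -> int:
        return self.data.shape[0]

    @property
    def nx(self) -> int:
        return self.data.shape[1]

    @property
    def ny(self) -> int:
        return self.data.shape[2]


@dataclass
class EnFaceMap:
    """A 2D transverse map indexed ``(x, y)`` with pixel spacing in μm."""

    data: np.ndarray
    spacing: tuple[float, float]
    kind: MapKind = MapKind.OCTA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValidationError(f"en face map must be 2D, got ndim={self.data.ndim}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 2 or any(s <= 0 for s in spacing):
            raise ValidationError(f"spacing must be 2 positive values, got {self.spacing}")
        self.spacing = spacing
        self.kind = MapKind(self.kind)
        if self.kind is MapKind.PROBABILITY:
            if (self.data < 0).any() or (self.data > 1).any():
                raise ValidationError("PROBABILITY map values must lie in [0, 1]")
        elif self.kind is MapKind.MASK:
            vals = np.unique(self.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValidationError("MASK map may only contain values {0, 1}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class LayerBoundaries:
    """Per-A-scan retinal layer boundary depth indices over ``(x, y)``.

    ``ilm`` is the inner limiting membrane (upper boundary of the
    retina), ``nfl_lower`` the lower boundary of the nerve fiber layer
    and ``opl_lower`` the lower boundary of the outer plexiform layer.
    Indices follow the project z convention (vitreous at small z), so
    ``ilm <= nfl_lower <= opl_lower`` everywhere.
    """

    ilm: np.ndarray
    nfl_lower: np.ndarray
    opl_lower: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm).astype(np.intp)
        self.nfl_lower = np.asarray(self.nfl_lower).astype(np.intp)
        self.opl_lower = np.asarray(self.opl_lower).astype(np.intp)
        if not (self.ilm.shape == self.nfl_lower.shape == self.opl_lower.shape):
            raise ValidationError("boundary maps must share one (x, y) shape")
        if (self.ilm < 0).any():
            raise ValidationError("ILM indices must be >= 0")
        if (self.ilm > self.nfl_lower).any() or (self.nfl_lower > self.opl_lower).any():
            raise ValidationError("boundary ordering ILM <= NFL-lower <= OPL-lower violated")

    def validate_depth(self, nz: int) -> None:
        if (self.opl_lower >= nz).any():
            raise ValidationError(f"OPL-lower indices must be < nz={nz}")

    def crop(self, margin: int) -> "LayerBoundaries":
        sl = slice(margin, -margin) if margin else slice(None)
        return LayerBoundaries(
            self.ilm[sl, sl], self.nfl_lower[sl, sl], self.opl_lower[sl, sl]
        )


@dataclass
class AcquisitionSeries:
    """N co-located OCT+OCTA volume pairs from one imaging session.

    All volumes must share shape and spacing (they either come
    co-registered or go through the registration pipeline first).
    The per-voxel coefficient of variation is undefined for a single
    repeat, hence N >= 2.
    """

    octa_volumes: list[VolumeGrid]
    oct_volumes: list[VolumeGrid]
    session_id: str = "session-0"

    def __post_init__(self) -> None:
        if len(self.octa_volumes) < 2:
            raise ValidationError(
                f"need at least 2 repeats for CoV, got {len(self.octa_volumes)}"
            )
        if len(self.oct_volumes) != len(self.octa_volumes):
            raise ValidationError(
                "OCT and OCTA volume lists must have the same length "
                f"({len(self.oct_volumes)} vs {len(self.octa_volumes)})"
            )
        ref = self.octa_volumes[0]
        for vol in [*self.octa_volumes, *self.oct_volumes]:
            if vol.shape != ref.shape:
                raise ValidationError(
                    f"all volumes must share shape {ref.shape}, got {vol.shape}"
                )
            if vol.spacing != ref.spacing:
                raise ValidationError(
                    f"all volumes must share spacing {ref.spacing}, got {vol.spacing}"
                )

    @property
    def n_volumes(self) -> int:
        return len(self.octa_volumes)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.octa_volumes[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.octa_volumes[0].spacing


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters with the defaults used throughout.

    ``noise_region_above_ilm`` is the (lower, upper) pixel offset of the
    background band anterior to the ILM used for noise-floor estimation;
    ``delta`` is the extra threshold offset (a number, or ``"auto"`` to
    calibrate against a reference vessel mask).
    """

    n_volumes: int = 10
    crop_margin_px: int = 20
    noise_region_above_ilm: tuple[int, int] = (10, 30)
    delta: float | str = "auto"
    vessel_prob_threshold: float = 0.5
    ring_distances_mm: tuple[float, float] = (0.5, 1.0)
    histogram_bins: int = 100
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_margin_px < 0:
            raise ValidationError("crop_margin_px must be >= 0")
        lo, hi = self.noise_region_above_ilm
        if not (0 < lo < hi):
            raise ValidationError("noise region bounds must satisfy 0 < lower < upper")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("noise_region_above_ilm", "ring_distances_mm"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "n_volumes": self.n_volumes,
            "crop_margin_px": self.crop_margin_px,
            "noise_region_above_ilm": list(self.noise_region_above_ilm),
            "delta": self.delta,
            "vessel_prob_threshold": self.vessel_prob_threshold,
            "ring_distances_mm": list(self.ring_distances_mm),
            "histogram_bins": self.histogram_bins,
            "random_seed": self.random_seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


# ---------------------------------------------------------------------------
# Volume file I/O


_TIFF_SUFFIXES = {".tif", ".tiff"}


def _is_nifti(path: Path) -> bool:
    return path.suffix == ".nii" or path.name.endswith(".nii.gz")


def read_volume(
    path: str | Path,
    modality: Modality | str,
    spacing: Sequence[float],
) -> VolumeGrid:
    """Read a volume from multi-page TIFF or NIfTI-1.

    TIFF pages are B-scans of shape ``(z, x)``; the page index maps to
    the slow-scan axis ``y``.  Intensity TIFFs written by
    :func:`write_volume` carry their quantization range in the page
    description and are rescaled back on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    modality = Modality(modality)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(str(path)) as tf:
            shapes = {p.shape for p in tf.pages}
            if len(shapes) != 1:
                raise FormatError(f"TIFF pages have inconsistent shapes: {sorted(shapes)}")
            pages = [p.asarray() for p in tf.pages]
            desc = tf.pages[0].description or ""
        data = np.stack(pages, axis=-1)
        if modality is Modality.MASK:
            data = (data > 0).astype(np.uint8)
        else:
            scale = _parse_scale(desc)
            if scale is not None:
                vmin, vmax = scale
                data = vmin + data.astype(np.float64) / 65535.0 * (vmax - vmin)
    else:
        raise FormatError(f"unsupported volume format: {path.suffix!r}")
    return VolumeGrid(data=data, spacing=tuple(spacing), modality=modality)


def _parse_scale(description: str) -> tuple[float, float] | None:
    try:
        meta = json.loads(description)
    except (json.JSONDecodeError, TypeError):
        return None
    if isinstance(meta, dict) and "vmin" in meta and "vmax" in meta:
        return float(meta["vmin"]), float(meta["vmax"])
    return None


def write_volume(volume: VolumeGrid, path: str | Path, format: str | None = None) -> None:
    """Write a volume as NIfTI-1 (lossless) or multi-page TIFF.

    TIFF quantization: masks become 8-bit ``{0, 255}``, depth indices
    16-bit integers, and intensity/CoV volumes are linearly scaled to
    the full 16-bit range with (vmin, vmax) recorded in the page
    description so :func:`read_volume` can undo the scaling.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    if format is None:
        format = "nifti" if _is_nifti(path) else (
            "tiff" if path.suffix.lower() in _TIFF_SUFFIXES else None
        )
    if format == "nifti":
        affine = np.diag([*volume.spacing, 1.0])
        nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))
    elif format == "tiff":
        pages = np.moveaxis(np.asarray(volume.data), -1, 0)  # (y, z, x)
        if volume.modality is Modality.MASK:
            tifffile.imwrite(str(path), (pages * 255).astype(np.uint8), photometric="minisblack")
        elif volume.modality is Modality.DEPTH_INDEX:
            tifffile.imwrite(str(path), pages.astype(np.uint16), photometric="minisblack")
        else:
            vmin, vmax = float(pages.min()), float(pages.max())
            span = (vmax - vmin) or 1.0
            quant = np.round((pages - vmin) / span * 65535.0).astype(np.uint16)
            desc = json.dumps({"vmin": vmin, "vmax": vmax})
            tifffile.imwrite(str(path), quant, description=desc, photometric="minisblack")
    else:
        raise ValueError(f"unsupported format {format!r} (use 'nifti' or 'tiff')")


def write_enface(emap: EnFaceMap, path: str | Path) -> None:
    """Write an en face map as a single-page TIFF (float32, lossless)."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    tifffile.imwrite(str(path), np.asarray(emap.data, dtype=np.float32))


def read_enface(path: str | Path, kind: MapKind | str, spacing: Sequence[float]) -> EnFaceMap:
    data = tifffile.imread(str(path))
    return EnFaceMap(data=data, spacing=tuple(spacing), kind=MapKind(kind))


# ---------------------------------------------------------------------------
# Series manifest


def load_series(manifest: str | Path) -> AcquisitionSeries:
    """Load an acquisition series described by a YAML manifest.

    Manifest layout::

        session_id: subject1-session1
        spacing: [dz, dx, dy]          # micrometers
        repeats:
          - oct: repeat00_oct.nii.gz
            octa: repeat00_octa.nii.gz
          - ...

    Paths are resolved relative to the manifest location.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "repeats" not in raw:
        raise ValidationError("manifest must be a mapping with a 'repeats' list")
    repeats = raw["repeats"]
    if not isinstance(repeats, list) or len(repeats) < 2:
        raise ValidationError(f"need at least 2 repeats, manifest lists {len(repeats or [])}")
    spacing = tuple(float(s) for s in raw.get("spacing", (1.0, 1.0, 1.0)))
    base = manifest.parent
    octs, octas = [], []
    for i, entry in enumerate(repeats):
        if not isinstance(entry, dict) or "oct" not in entry or "octa" not in entry:
            raise ValidationError(f"repeat {i} must list both 'oct' and 'octa' paths")
        octs.append(read_volume(base / entry["oct"], Modality.OCT, spacing))
        octas.append(read_volume(base / entry["octa"], Modality.OCTA, spacing))
    return AcquisitionSeries(
        octa_volumes=octas,
        oct_volumes=octs,
        session_id=str(raw.get("session_id", manifest.stem)),
    )


def save_series(
    series: AcquisitionSeries,
    out_dir: str | Path,
    format: str = "nifti",
) -> Path:
    """Write every repeat of a series plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if format == "nifti" else ".tiff"
    entries = []
    for k in range(series.n_volumes):
        oct_name = f"repeat{k:02d}_oct{ext}"
        octa_name = f"repeat{k:02d}_octa{ext}"
        write_volume(series.oct_volumes[k], out_dir / oct_name, format)
        write_volume(series.octa_volumes[k], out_dir / octa_name, format)
        entries.append({"oct": oct_name, "octa": octa_name})
    manifest = {
        "session_id": series.session_id,
        "spacing": list(series.spacing),
        "repeats": entries,
    }
    manifest_path = out_dir / "manifest.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest_path
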