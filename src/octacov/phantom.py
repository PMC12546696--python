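"""Synthetic OCT/OCTA phantom with known vasculature, noise and motion.

The phantom emulates a fovea-centered raster scan: smooth retinal layer
surfaces (ILM, NFL-lower, OPL-lower), two depth-separated vascular
plexuses (superficial and deep) built from tube primitives, a foveal
avascular zone (FAZ), and a ring of high-variability "shunt" vessels at
the FAZ margin.  Each vessel class carries a prescribed temporal
coefficient of variation: across the N repeats every vessel voxel is an
independent draw from a normal distribution with mean equal to the
class mean intensity and standard deviation CoV x mean, truncated at
zero.  The background is sub-threshold noise with a configurable mean
and standard deviation, also truncated at zero.

Because truncation at zero slightly shifts the mean and shrinks the
standard deviation of a normal distribution, the *realized* CoV of a
vessel class is not exactly the nominal parameter for large CoV values.
The ground-truth carrier therefore records the exact CoV of the
truncated sampling distribution (closed form via the truncated-normal
moments) — that is the quantity an unbiased estimator should recover.

Geometric realism (perfusion physics, speckle, shadowing, projection
artifacts) is deliberately out of scope; the phantom exists to give
every pipeline stage a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import truncnorm
from skimage.draw import circle_perimeter, line

from .volume_io import (
    AcquisitionSeries,
    EnFaceMap,
    LayerBoundaries,
    MapKind,
    Modality,
    ValidationError,
    VolumeGrid,
)

__all__ = [
    "VesselClass",
    "MotionSpec",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom_series",
    "emulate_device_enface",
    "perturb_motion",
    "truncated_normal_cov",
]


@dataclass
class VesselClass:
    """One vessel population: geometry, brightness and temporal variability.

    ``pattern`` picks the centerline layout: ``arcade`` (a few large
    vessels crossing the field), ``grid`` (axis-aligned capillary mesh),
    ``diag_grid`` (diagonal capillary mesh) or ``faz_ring`` (a ring
    hugging the FAZ margin, the shunt-vessel location).
    """

    radius_um: float
    mean_intensity: float
    cov: float  # fractional temporal CoV of the voxel intensity
    plexus: str  # "svp" or "dvp"
    pattern: str = "grid"

    def __post_init__(self) -> None:
        if self.cov < 0:
            raise ValidationError("vessel class CoV must be >= 0")
        if self.plexus not in ("svp", "dvp"):
            raise ValidationError(f"unknown plexus {self.plexus!r}")
        if self.pattern not in ("arcade", "grid", "diag_grid", "faz_ring"):
            raise ValidationError(f"unknown pattern {self.pattern!r}")


def default_vessel_classes() -> dict[str, VesselClass]:
    """Four populations spanning the CoV range reported for healthy retina:
    quiet large arterioles/venules, mid-variability capillaries in both
    plexuses, and high-variability shunt vessels at the FAZ margin."""
    return {
        "large_vessel": VesselClass(35.0, 200.0, 0.10, "svp", "arcade"),
        "capillary_svp": VesselClass(10.0, 120.0, 0.30, "svp", "grid"),
        "capillary_dvp": VesselClass(10.0, 120.0, 0.30, "dvp", "diag_grid"),
        "shunt_near_faz": VesselClass(12.0, 130.0, 0.50, "svp", "faz_ring"),
    }


@dataclass
class MotionSpec:
    """Per-repeat residual motion amplitudes (repeat 0 is never moved).

    Each non-template repeat draws a transverse shift uniformly in
    ``[-max_shift_px, max_shift_px]`` per axis, a rotation in
    ``[-max_rotation_deg, max_rotation_deg]``, a smooth sinusoidal
    deformation with the given amplitude, and a constant integer axial
    shift in ``[-max_axial_px, max_axial_px]``.
    """

    max_shift_px: float = 5.0
    max_rotation_deg: float = 0.5
    deformation_amplitude_px: float = 0.0
    max_axial_px: int = 0


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition session."""

    shape: tuple[int, int, int] = (64, 96, 96)  # (z, x, y)
    spacing: tuple[float, float, float] = (6.0, 23.4, 23.4)  # μm
    ilm_depth_px: int = 36
    nfl_offset_px: int = 8
    opl_offset_px: int = 24
    surface_wave_px: float = 1.5
    vessel_classes: dict[str, VesselClass] = field(default_factory=default_vessel_classes)
    faz_radius_mm: float = 0.25
    noise_mean: float = 10.0
    noise_std: float = 2.0
    motion: MotionSpec | None = None
    n_repeats: int = 10
    seed: int = 0

    def validate(self) -> None:
        nz, nx, ny = self.shape
        if self.n_repeats < 2:
            raise ValidationError("n_repeats must be >= 2")
        noise_floor = self.noise_mean + self.noise_std
        for name, cls in self.vessel_classes.items():
            if cls.mean_intensity <= noise_floor:
                raise ValidationError(
                    f"class {name!r} mean intensity must exceed noise mean + std"
                )
        faz_px = self.faz_radius_mm * 1000.0 / self.spacing[1]
        if faz_px >= min(nx, ny) / 2:
            raise ValidationError("FAZ radius must be smaller than half the field")
        if self.ilm_depth_px + self.opl_offset_px >= nz:
            raise ValidationError("layer stack does not fit in the depth range")

    @property
    def faz_radius_px(self) -> float:
        return self.faz_radius_mm * 1000.0 / self.spacing[1]


@dataclass
class PhantomTruth:
    """Ground truth accompanying a generated series (template frame)."""

    layers: LayerBoundaries
    class_masks: dict[str, np.ndarray]  # name -> 3D bool mask
    faz_mask: EnFaceMap
    true_cov: VolumeGrid  # exact per-voxel CoV of the sampling distribution
    true_class_cov: dict[str, float]
    vessel_probability: EnFaceMap
    transforms: list[dict]  # per-repeat applied motion parameters


def _sample_truncated(rng: np.random.Generator, mean: float, std: float, size) -> np.ndarray:
    """Draw from normal(mean, std) truncated to [0, inf) by rejection
    (exact; redraw until every sample is non-negative)."""
    x = rng.normal(mean, std, size)
    bad = x < 0
    while bad.any():
        x[bad] = rng.normal(mean, std, int(bad.sum()))
        bad = x < 0
    return x


def truncated_normal_cov(mean: float, std: float) -> float:
    """Exact CoV of a normal(mean, std) truncated to [0, inf)."""
    if std == 0:
        return 0.0
    a = (0.0 - mean) / std
    m, v = truncnorm.stats(a, np.inf, loc=mean, scale=std, moments="mv")
    return float(np.sqrt(v) / m)


# ---------------------------------------------------------------------------
# Geometry


def _layer_surfaces(spec: PhantomSpec) -> LayerBoundaries:
    nz, nx, ny = spec.shape
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    wave = spec.surface_wave_px * (
        np.sin(2 * np.pi * xx / max(nx, 1) * 1.3) * np.cos(2 * np.pi * yy / max(ny, 1))
    )
    ilm = np.clip(np.round(spec.ilm_depth_px + wave).astype(int), 31, nz - 1)
    nfl = np.clip(ilm + spec.nfl_offset_px, 0, nz - 1)
    opl = np.clip(ilm + spec.opl_offset_px, 0, nz - 1)
    return LayerBoundaries(ilm=ilm, nfl_lower=nfl, opl_lower=opl)


def _centerline_maps(spec: PhantomSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """2D boolean centerline maps per vessel class, FAZ kept avascular."""
    _, nx, ny = spec.shape
    cx, cy = nx // 2, ny // 2
    faz_px = spec.faz_radius_px
    maps = {name: np.zeros((nx, ny), dtype=bool) for name in spec.vessel_classes}

    def draw_line(mask, x0, y0, x1, y1):
        rr, cc = line(int(x0), int(y0), int(x1), int(y1))
        ok = (rr >= 0) & (rr < nx) & (cc >= 0) & (cc < ny)
        mask[rr[ok], cc[ok]] = True

    for name, cls in spec.vessel_classes.items():
        mask = maps[name]
        if cls.pattern == "arcade":
            off = int(faz_px + 6)
            draw_line(mask, 0, cy - off, nx - 1, cy - off)
            draw_line(mask, cx + off, 0, cx + off, ny - 1)
            draw_line(mask, 0, 0, nx - 1 - 2 * off, ny - 1)
        elif cls.pattern == "grid":
            for x0 in range(4, nx, 9):
                draw_line(mask, x0, 0, x0, ny - 1)
            for y0 in range(7, ny, 11):
                draw_line(mask, 0, y0, nx - 1, y0)
        elif cls.pattern == "diag_grid":
            for d in range(-nx, ny, 8):
                draw_line(
                    mask,
                    max(0, -d), max(0, d),
                    min(nx - 1, ny - 1 - d), min(ny - 1, nx - 1 + d),
                )
            for y0 in range(3, ny, 10):
                draw_line(mask, 0, y0, nx - 1, y0)
        elif cls.pattern == "faz_ring":
            rr, cc = circle_perimeter(cx, cy, int(faz_px + 2), shape=(nx, ny))
            mask[rr, cc] = True

    # keep the FAZ avascular except for the shunt ring hugging its margin
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    inside_faz = (xx - cx) ** 2 + (yy - cy) ** 2 <= faz_px**2
    for name in maps:
        if name != "shunt_near_faz":
            maps[name] &= ~inside_faz
    return maps


def _build_masks(
    spec: PhantomSpec, layers: LayerBoundaries, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Rasterize tube primitives into disjoint 3D class masks."""
    nz, nx, ny = spec.shape
    dz, dx, _ = spec.spacing
    centers = _centerline_maps(spec, rng)
    zz = np.arange(nz)[:, None, None]
    svp_center = layers.ilm + 4
    dvp_center = np.minimum(layers.ilm + spec.opl_offset_px - 4, nz - 1)

    claimed = np.zeros(spec.shape, dtype=bool)
    masks: dict[str, np.ndarray] = {}
    # priority: brighter/larger classes claim overlapping voxels first
    order = ["large_vessel", "shunt_near_faz", "capillary_svp", "capillary_dvp"]
    order = [n for n in order if n in spec.vessel_classes] + [
        n for n in spec.vessel_classes if n not in order
    ]
    for name in order:
        cls = spec.vessel_classes[name]
        radius_px = max(cls.radius_um / dx, 0.7)
        dist = ndimage.distance_transform_edt(~centers[name])
        mask2d = dist <= radius_px
        zc = svp_center if cls.plexus == "svp" else dvp_center
        half = max(1, int(round(cls.radius_um / dz)))
        # tube cross-section: stay at/below the ILM so the noise band is clean
        zlo = np.maximum(zc - half, layers.ilm)
        zhi = np.minimum(zc + half, nz - 1)
        mask3d = mask2d[None, :, :] & (zz >= zlo[None]) & (zz <= zhi[None])
        mask3d &= ~claimed
        claimed |= mask3d
        masks[name] = mask3d
    return masks, claimed


# ---------------------------------------------------------------------------
# Motion


def perturb_motion(
    volume: VolumeGrid,
    shift: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    deformation: np.ndarray | None = None,
    axial_shift: np.ndarray | float | None = None,
    fill: float = 0.0,
) -> VolumeGrid:
    """Apply transverse rigid motion, smooth deformation and axial shift.

    The transverse transform moves image content by ``shift`` pixels
    (rotation about the transverse center) identically on every z-slice;
    ``deformation`` is a forward displacement field ``u`` of shape
    ``(nx, ny, 2)`` so that ``out(p) = in(p - u(p))``; ``axial_shift``
    moves content deeper by ``s`` samples per A-scan
    (``out(z) = in(z - s)``).  Linear interpolation, constant ``fill``
    padding.
    """
    nz, nx, ny = volume.shape
    sx, sy = float(shift[0]), float(shift[1])
    if abs(sx) >= nx or abs(sy) >= ny:
        raise ValidationError("transverse shift exceeds the image extent")
    data = np.asarray(volume.data, dtype=np.float64)
    out = data

    if sx or sy or rotation_deg or deformation is not None:
        px, py = np.meshgrid(np.arange(nx, dtype=np.float64),
                             np.arange(ny, dtype=np.float64), indexing="ij")
        qx, qy = px, py
        if deformation is not None:
            if deformation.shape != (nx, ny, 2):
                raise ValidationError("deformation field must have shape (nx, ny, 2)")
            qx = px - deformation[..., 0]
            qy = py - deformation[..., 1]
        theta = math.radians(rotation_deg)
        c, s = math.cos(theta), math.sin(theta)
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        ux, uy = qx - sx - cx, qy - sy - cy
        src_x = c * ux + s * uy + cx
        src_y = -s * ux + c * uy + cy
        out = np.empty_like(data)
        for z in range(nz):
            out[z] = ndimage.map_coordinates(
                data[z], [src_x, src_y], order=1, mode="constant", cval=fill
            )

    if axial_shift is not None:
        s_map = np.broadcast_to(np.asarray(axial_shift, dtype=np.float64), (nx, ny))
        if np.abs(s_map).max() >= nz:
            raise ValidationError("axial shift exceeds the depth extent")
        zz = np.arange(nz, dtype=np.float64)[:, None, None]
        src_z = zz - s_map[None, :, :]
        xx = np.broadcast_to(np.arange(nx, dtype=np.float64)[None, :, None], (nz, nx, ny))
        yy = np.broadcast_to(np.arange(ny, dtype=np.float64)[None, None, :], (nz, nx, ny))
        out = ndimage.map_coordinates(
            out, [np.broadcast_to(src_z, (nz, nx, ny)), xx, yy],
            order=1, mode="constant", cval=fill,
        )
    return VolumeGrid(out, volume.spacing, volume.modality)


def _sinusoidal_field(nx: int, ny: int, amplitude: float, phase: float) -> np.ndarray:
    px, py = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    u = np.empty((nx, ny, 2))
    u[..., 0] = amplitude * np.sin(2 * np.pi * py / max(ny, 1) + phase)
    u[..., 1] = amplitude * np.cos(2 * np.pi * px / max(nx, 1) + phase)
    return u


# ---------------------------------------------------------------------------
# Generation


def generate_phantom_series(spec: PhantomSpec) -> tuple[AcquisitionSeries, PhantomTruth]:
    """Generate N OCT+OCTA repeats plus ground truth; deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, nx, ny = spec.shape
    layers = _layer_surfaces(spec)
    masks, any_vessel = _build_masks(spec, layers, rng)

    true_cov = np.zeros(spec.shape, dtype=np.float64)
    true_class_cov: dict[str, float] = {}
    for name, cls in spec.vessel_classes.items():
        cov_t = truncated_normal_cov(cls.mean_intensity, cls.cov * cls.mean_intensity)
        true_class_cov[name] = cov_t
        true_cov[masks[name]] = cov_t

    # structural OCT: layered bands with mild per-repeat noise
    zz = np.arange(nz)[:, None, None]
    oct_base = np.full(spec.shape, 15.0)
    oct_base[zz >= layers.ilm[None]] = 140.0
    oct_base[zz >= layers.nfl_lower[None]] = 70.0
    oct_base[zz >= layers.opl_lower[None]] = 100.0

    cx, cy = nx // 2, ny // 2
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    faz2d = (((xx - cx) ** 2 + (yy - cy) ** 2) <= spec.faz_radius_px**2).astype(np.uint8)

    octa_vols: list[VolumeGrid] = []
    oct_vols: list[VolumeGrid] = []
    transforms: list[dict] = []
    for k in range(spec.n_repeats):
        octa = _sample_truncated(rng, spec.noise_mean, spec.noise_std, spec.shape)
        for name, cls in spec.vessel_classes.items():
            m = masks[name]
            n = int(m.sum())
            if n == 0:
                continue
            std = cls.cov * cls.mean_intensity
            if std == 0:
                octa[m] = cls.mean_intensity
            else:
                octa[m] = _sample_truncated(rng, cls.mean_intensity, std, n)
        oct_vol = oct_base + rng.normal(0.0, 4.0, spec.shape)

        params = {"shift": (0.0, 0.0), "rotation_deg": 0.0,
                  "deformation_amplitude": 0.0, "axial_shift": 0}
        octa_v = VolumeGrid(octa, spec.spacing, Modality.OCTA)
        oct_v = VolumeGrid(oct_vol, spec.spacing, Modality.OCT)
        if spec.motion is not None and k > 0:
            mo = spec.motion
            sh = tuple(rng.uniform(-mo.max_shift_px, mo.max_shift_px, 2))
            rot = float(rng.uniform(-mo.max_rotation_deg, mo.max_rotation_deg))
            defo = None
            if mo.deformation_amplitude_px > 0:
                defo = _sinusoidal_field(
                    nx, ny, mo.deformation_amplitude_px, float(rng.uniform(0, 2 * np.pi))
                )
            ax = int(rng.integers(-mo.max_axial_px, mo.max_axial_px + 1)) if mo.max_axial_px else 0
            octa_v = perturb_motion(octa_v, sh, rot, defo, ax or None, fill=spec.noise_mean)
            oct_v = perturb_motion(oct_v, sh, rot, defo, ax or None, fill=15.0)
            params = {"shift": sh, "rotation_deg": rot,
                      "deformation_amplitude": mo.deformation_amplitude_px,
                      "axial_shift": ax}
        octa_vols.append(octa_v)
        oct_vols.append(oct_v)
        transforms.append(params)

    series = AcquisitionSeries(octa_vols, oct_vols, session_id=f"phantom-seed{spec.seed}")
    truth = PhantomTruth(
        layers=layers,
        class_masks=masks,
        faz_mask=EnFaceMap(faz2d, spec.spacing[1:], MapKind.MASK),
        true_cov=VolumeGrid(true_cov, spec.spacing, Modality.COV),
        true_class_cov=true_class_cov,
        vessel_probability=EnFaceMap(
            any_vessel.any(axis=0).astype(np.float64), spec.spacing[1:], MapKind.PROBABILITY
        ),
        transforms=transforms,
    )
    return series, truth


# ---------------------------------------------------------------------------
# Device-style en face emulation (Protocol A input surrogate)


def emulate_device_enface(
    octa: VolumeGrid,
    layers: LayerBoundaries,
    gamma: float = 0.6,
    stretch_percentiles: tuple[float, float] = (1.0, 99.0),
    enhance: bool = True,
) -> EnFaceMap:
    """Slab mean projection (ILM to OPL-lower) with monotone contrast refinement.

    Emulates the device's contrast-enhanced en face rendering: a gamma
    correction plus percentile histogram stretch applied after the plain
    slab projection.  The mapping is monotone, so pixel rank order is
    preserved, but the intensity *distribution* is reshaped — which is
    exactly why CoV computed on such images misrepresents the underlying
    temporal variability.
    """
    nz = octa.nz
    layers.validate_depth(nz)
    if (layers.ilm >= layers.opl_lower).any():
        raise ValidationError("degenerate slab: ILM >= OPL-lower somewhere")
    zz = np.arange(nz)[:, None, None]
    slab = (zz >= layers.ilm[None]) & (zz < layers.opl_lower[None])
    data = np.where(slab, octa.data, np.nan)
    proj = np.nanmean(data, axis=0)
    if not enhance:
        return EnFaceMap(proj, octa.spacing[1:], MapKind.OCTA)
    lo, hi = np.percentile(proj, stretch_percentiles)
    span = (hi - lo) or 1.0
    stretched = np.clip((proj - lo) / span, 0.0, 1.0)
    enhanced = np.power(stretched, gamma)
    return EnFaceMap(enhanced, octa.spacing[1:], MapKind.OCTA)
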