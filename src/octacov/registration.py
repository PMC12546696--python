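"""Multi-volume 3D registration: rigid + non-rigid transverse, axial matching.

Serially acquired OCTA volumes retain residual motion even with device
tracking enabled.  The pipeline aligns each repeat to an automatically
selected template in three stages:

1. transverse rigid — keypoints from two complementary detector/
   descriptor schemes (a binary corner-based one and a float
   gradient/blob-based one) are matched separately, the match pools are
   merged, and one similarity transform is estimated by RANSAC over the
   union;
2. transverse non-rigid — a diffeomorphic demons displacement field
   refines the rigidly aligned en face images;
3. axial — per-A-scan integer depth shifts from 1D cross-correlation of
   the structural OCT profiles (OCT delineates layers far better than
   OCTA), median-smoothed over the transverse plane.

One 2D transverse transform per repeat is applied identically to every
z-slice of both the OCT and OCTA volume (depth-invariant transverse
motion model).  After registration, a fixed margin is cropped from every
transverse side so all repeats share one field of view.

Coordinate convention: 2D operations act on ``(x, y)`` en face arrays;
transforms are 3x3 homogeneous matrices acting on ``(x, y)`` coordinate
column vectors.  A transform maps *template* coordinates to *target*
coordinates, so resampling the target at ``T(p)`` aligns it to the
template.  Deformation fields ``u`` follow the same convention:
``aligned(p) = target(p + u(p))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.feature import ORB, SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

from .volume_io import (
    AcquisitionSeries,
    EnFaceMap,
    LayerBoundaries,
    MapKind,
    ValidationError,
    VolumeGrid,
)

__all__ = [
    "RigidTransform2D",
    "DeformationField",
    "AxialShiftMap",
    "RegistrationResult",
    "RegistrationError",
    "ConvergenceError",
    "select_template",
    "register_rigid",
    "register_nonrigid",
    "apply_transverse",
    "warp_enface",
    "axial_match",
    "apply_axial",
    "crop_standard",
    "register_series",
    "enface_projection",
]


class RegistrationError(RuntimeError):
    """Feature matching produced too few inliers or an implausible transform."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConvergenceError(RuntimeError):
    """Iterative registration diverged."""


@dataclass
class RigidTransform2D:
    """Similarity transform (rotation, translation, near-unit scale)."""

    matrix: np.ndarray  # 3x3 homogeneous, acts on (x, y)
    inliers: int = 0
    residual_px: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape == (2, 3):
            self.matrix = np.vstack([self.matrix, [0.0, 0.0, 1.0]])
        if self.matrix.shape != (3, 3):
            raise ValidationError("rigid transform matrix must be 2x3 or 3x3")
        if abs(np.linalg.det(self.matrix[:2, :2])) < 1e-12:
            raise ValidationError("rigid transform matrix is singular")

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(np.eye(3))

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:2, 2].copy()

    @property
    def rotation_deg(self) -> float:
        return math.degrees(math.atan2(self.matrix[1, 0], self.matrix[0, 0]))

    @property
    def scale(self) -> float:
        return float(np.sqrt(abs(np.linalg.det(self.matrix[:2, :2]))))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]


@dataclass
class DeformationField:
    """Dense 2D displacement field ``u(x, y)`` in pixels."""

    u: np.ndarray  # (nx, ny, 2)
    smoothness: float = 0.0

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float64)
        if self.u.ndim != 3 or self.u.shape[2] != 2:
            raise ValidationError("deformation field must have shape (nx, ny, 2)")
        if not np.isfinite(self.u).all():
            raise ValidationError("deformation field must be finite everywhere")

    @classmethod
    def zero(cls, shape: tuple[int, int]) -> "DeformationField":
        return cls(np.zeros((*shape, 2)))

    @property
    def max_magnitude(self) -> float:
        return float(np.hypot(self.u[..., 0], self.u[..., 1]).max())


@dataclass
class AxialShiftMap:
    """Per-A-scan integer depth shift with a matching confidence."""

    shift: np.ndarray  # (nx, ny) int
    confidence: np.ndarray  # (nx, ny) in [0, 1]

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift).astype(np.intp)
        self.confidence = np.asarray(self.confidence, dtype=np.float64)
        if self.shift.shape != self.confidence.shape:
            raise ValidationError("shift and confidence maps must share a shape")


@dataclass
class RegistrationResult:
    template_index: int
    rigid: list[RigidTransform2D | None]  # None at the template slot
    deformation: list[DeformationField | None]
    axial: list[AxialShiftMap | None]
    post_crop_shape: tuple[int, int, int]


# ---------------------------------------------------------------------------
# Template selection


def enface_projection(volume: VolumeGrid, layers: LayerBoundaries | None = None) -> EnFaceMap:
    """Mean en face projection, over the ILM->OPL slab when layers are given."""
    if layers is None:
        proj = volume.data.mean(axis=0)
    else:
        zz = np.arange(volume.nz)[:, None, None]
        slab = (zz >= layers.ilm[None]) & (zz < layers.opl_lower[None])
        proj = np.nanmean(np.where(slab, volume.data, np.nan), axis=0)
    return EnFaceMap(proj, volume.spacing[1:], MapKind.OCTA)


def select_template(
    series: AcquisitionSeries,
    layers: LayerBoundaries | None = None,
    override: int | None = None,
) -> int:
    """Pick the repeat with the least motion artifact as the template.

    Quality score: mean gradient magnitude of the en face projection
    (sharpness; motion blurs vessels) minus the worst adjacent-B-scan
    discontinuity (a mid-scan saccade produces one large row-to-row
    jump).  Ties (and the all-identical case) resolve to the lowest
    index.
    """
    if override is not None:
        if not 0 <= override < series.n_volumes:
            raise ValidationError(f"template override {override} out of range")
        return int(override)
    scores = []
    for vol in series.octa_volumes:
        enface = enface_projection(vol, layers).data
        span = enface.max() - enface.min() or 1.0
        norm = (enface - enface.min()) / span
        gx, gy = np.gradient(norm)
        sharpness = float(np.hypot(gx, gy).mean())
        row_jump = np.abs(np.diff(norm, axis=1)).mean(axis=0)  # per y-boundary
        discontinuity = float(row_jump.max())
        scores.append(sharpness - discontinuity)
    return int(np.argmax(scores))


# ---------------------------------------------------------------------------
# Rigid (hybrid feature) registration


def _normalize(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    span = img.max() - img.min()
    return (img - img.min()) / span if span else np.zeros_like(img)


def _detect_and_match(template: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pool correspondences from a binary corner detector and a float
    gradient detector; returns (src, dst) coordinate arrays in (x, y)."""
    src_list, dst_list = [], []
    schemes = [(ORB, {"n_keypoints": 800}), (SIFT, {})]
    for scheme, kwargs in schemes:
        det_s, det_t = scheme(**kwargs), scheme(**kwargs)
        try:
            det_s.detect_and_extract(template)
            det_t.detect_and_extract(target)
        except RuntimeError:
            continue  # this scheme found no keypoints
        if len(det_s.keypoints) == 0 or len(det_t.keypoints) == 0:
            continue
        # match_descriptors picks Hamming for binary descriptors (ORB)
        # and Euclidean for float ones (SIFT)
        matches = match_descriptors(det_s.descriptors, det_t.descriptors, cross_check=True)
        if len(matches):
            src_list.append(det_s.keypoints[matches[:, 0]])
            dst_list.append(det_t.keypoints[matches[:, 1]])
    if not src_list:
        return np.empty((0, 2)), np.empty((0, 2))
    return np.vstack(src_list), np.vstack(dst_list)


def register_rigid(
    template_enface: EnFaceMap,
    target_enface: EnFaceMap,
    min_inliers: int = 6,
    residual_threshold: float = 2.0,
    scale_bounds: tuple[float, float] = (0.9, 1.1),
    seed: int = 0,
) -> RigidTransform2D:
    """Estimate the template->target similarity transform from pooled
    keypoint matches via RANSAC."""
    if template_enface.shape != target_enface.shape:
        raise ValidationError("en face maps must share a shape")
    tpl = _normalize(template_enface.data)
    tgt = _normalize(target_enface.data)
    src, dst = _detect_and_match(tpl, tgt)
    if len(src) < min_inliers:
        raise RegistrationError(
            f"only {len(src)} keypoint matches (need >= {min_inliers})",
            {"n_matches": len(src)},
        )
    model, inlier_mask = ransac(
        (src, dst),
        SimilarityTransform,
        min_samples=3,
        residual_threshold=residual_threshold,
        max_trials=2000,
        rng=seed,
    )
    if model is None or inlier_mask is None or inlier_mask.sum() < min_inliers:
        n_in = 0 if inlier_mask is None else int(inlier_mask.sum())
        raise RegistrationError(
            f"RANSAC found only {n_in} inliers (need >= {min_inliers})",
            {"n_matches": len(src), "n_inliers": n_in},
        )
    resid = float(np.sqrt(np.mean(model.residuals(src[inlier_mask], dst[inlier_mask]) ** 2)))
    transform = RigidTransform2D(model.params, inliers=int(inlier_mask.sum()),
                                 residual_px=resid)
    lo, hi = scale_bounds
    if not (lo <= transform.scale <= hi):
        raise RegistrationError(
            f"estimated scale {transform.scale:.3f} outside bounds {scale_bounds}",
            {"scale": transform.scale, "n_inliers": transform.inliers},
        )
    return transform


def _source_coords(
    shape: tuple[int, int],
    rigid: RigidTransform2D | None,
    deformation: DeformationField | None,
) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = shape
    px, py = np.meshgrid(np.arange(nx, dtype=np.float64),
                         np.arange(ny, dtype=np.float64), indexing="ij")
    if deformation is not None:
        px = px + deformation.u[..., 0]
        py = py + deformation.u[..., 1]
    if rigid is not None:
        m = rigid.matrix
        sx = m[0, 0] * px + m[0, 1] * py + m[0, 2]
        sy = m[1, 0] * px + m[1, 1] * py + m[1, 2]
        px, py = sx, sy
    return px, py


def warp_enface(
    emap: EnFaceMap,
    rigid: RigidTransform2D | None = None,
    deformation: DeformationField | None = None,
    fill: float = 0.0,
) -> EnFaceMap:
    """Resample a target en face map onto the template grid."""
    sx, sy = _source_coords(emap.shape, rigid, deformation)
    warped = ndimage.map_coordinates(
        np.asarray(emap.data, dtype=np.float64), [sx, sy],
        order=1, mode="constant", cval=fill,
    )
    return EnFaceMap(warped, emap.spacing, emap.kind)


# ---------------------------------------------------------------------------
# Non-rigid (diffeomorphic demons)


def register_nonrigid(
    template_enface: EnFaceMap,
    rigidly_aligned_target: EnFaceMap,
    iterations: int = 100,
    smoothing_sigma: float = 2.0,
    divergence_tolerance: float = 1.05,
) -> DeformationField:
    """Diffeomorphic demons displacement field on rigidly aligned en face maps.

    The returned field ``u`` samples the target at ``p + u(p)``; applying
    it must not increase the mean squared intensity difference (checked,
    divergence raises).
    """
    if template_enface.shape != rigidly_aligned_target.shape:
        raise ValidationError("en face maps must share a shape")
    fixed = sitk.GetImageFromArray(_normalize(template_enface.data).astype(np.float32))
    moving = sitk.GetImageFromArray(_normalize(rigidly_aligned_target.data).astype(np.float32))
    demons = sitk.DiffeomorphicDemonsRegistrationFilter()
    demons.SetNumberOfIterations(int(iterations))
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(float(smoothing_sigma))
    disp = demons.Execute(fixed, moving)
    arr = sitk.GetArrayFromImage(disp)  # (nx, ny, 2) with (col, row) components
    u = np.empty_like(arr)
    u[..., 0] = arr[..., 1]  # row (= x) displacement
    u[..., 1] = arr[..., 0]  # col (= y) displacement
    gx = np.gradient(u[..., 0])
    gy = np.gradient(u[..., 1])
    smoothness = float(np.mean(np.hypot(gx[0], gx[1]) + np.hypot(gy[0], gy[1])))
    field = DeformationField(u, smoothness=smoothness)

    tpl = _normalize(template_enface.data)
    tgt = _normalize(rigidly_aligned_target.data)
    sx, sy = _source_coords(tgt.shape, None, field)
    warped = ndimage.map_coordinates(tgt, [sx, sy], order=1, mode="nearest")
    before = float(np.mean((tpl - tgt) ** 2))
    after = float(np.mean((tpl - warped) ** 2))
    if after > before:
        if after > before * divergence_tolerance and field.max_magnitude > 1.0:
            raise ConvergenceError(f"demons diverged: MSD {before:.3e} -> {after:.3e}")
        # already at the noise floor: the identity field is the better
        # (non-worsening) estimate, keeping the improvement contract
        return DeformationField.zero(tpl.shape)
    return field


# ---------------------------------------------------------------------------
# Applying transforms to volumes


def apply_transverse(
    volume: VolumeGrid,
    rigid: RigidTransform2D | None = None,
    deformation: DeformationField | None = None,
    fill: float = 0.0,
) -> VolumeGrid:
    """Apply one 2D transverse transform identically to every z-slice.

    Intensities are only altered by linear interpolation — no
    normalization happens here.  The same call must be made with the
    same transforms for the OCT and OCTA volume of a repeat.
    """
    nz, nx, ny = volume.shape
    if deformation is not None and deformation.u.shape[:2] != (nx, ny):
        raise ValidationError("deformation field shape does not match the volume")
    if rigid is None and deformation is None:
        return VolumeGrid(volume.data.copy(), volume.spacing, volume.modality)
    sx, sy = _source_coords((nx, ny), rigid, deformation)
    data = np.asarray(volume.data, dtype=np.float64)
    out = np.empty((nz, nx, ny))
    for z in range(nz):
        out[z] = ndimage.map_coordinates(data[z], [sx, sy], order=1,
                                         mode="constant", cval=fill)
    return VolumeGrid(out, volume.spacing, volume.modality)


# ---------------------------------------------------------------------------
# Axial matching


def axial_match(
    template_oct: VolumeGrid,
    target_oct: VolumeGrid,
    search_range: int = 10,
    median_radius: int = 2,
    confidence_threshold: float = 0.3,
) -> AxialShiftMap:
    """Per-A-scan integer axial shift from 1D cross-correlation of OCT
    depth profiles, median-smoothed over (x, y).

    Flat or contentless A-scans get confidence 0 and are imputed from
    their neighborhood before smoothing.
    """
    if template_oct.shape != target_oct.shape:
        raise ValidationError("OCT volumes must share a shape")
    nz, nx, ny = template_oct.shape
    if search_range >= nz:
        raise ValidationError("search range must be smaller than the depth extent")
    tpl = np.asarray(template_oct.data, dtype=np.float64)
    tgt = np.asarray(target_oct.data, dtype=np.float64)
    tpl = tpl - tpl.mean(axis=0, keepdims=True)
    tgt = tgt - tgt.mean(axis=0, keepdims=True)
    tpl_norm = np.sqrt((tpl**2).sum(axis=0))
    tgt_norm = np.sqrt((tgt**2).sum(axis=0))

    lags = np.arange(-search_range, search_range + 1)
    corr = np.empty((len(lags), nx, ny))
    for i, lag in enumerate(lags):
        # correlate template(z) with target(z + lag)
        if lag >= 0:
            prod = tpl[: nz - lag] * tgt[lag:]
        else:
            prod = tpl[-lag:] * tgt[:lag]
        corr[i] = prod.sum(axis=0)
    best = corr.argmax(axis=0)
    shift = lags[best]
    denom = tpl_norm * tgt_norm
    peak = np.take_along_axis(corr, best[None], axis=0)[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        confidence = np.where(denom > 1e-9, np.clip(peak / np.maximum(denom, 1e-30), 0, 1), 0.0)

    # impute unreliable A-scans from confident neighbors, then smooth
    valid = confidence >= confidence_threshold
    if valid.any() and not valid.all():
        fill_value = int(np.median(shift[valid]))
        shift = np.where(valid, shift, fill_value)
    size = 2 * median_radius + 1
    shift = ndimage.median_filter(shift, size=size, mode="nearest")
    return AxialShiftMap(shift=shift, confidence=confidence)


def apply_axial(volume: VolumeGrid, shifts: AxialShiftMap, fill: float = 0.0) -> VolumeGrid:
    """Resample each A-scan at ``z + s(x, y)`` (integer shifts, no blur)."""
    nz, nx, ny = volume.shape
    if shifts.shift.shape != (nx, ny):
        raise ValidationError("shift map shape does not match the volume")
    zz = np.arange(nz)[:, None, None] + shifts.shift[None, :, :]
    valid = (zz >= 0) & (zz < nz)
    zz_c = np.clip(zz, 0, nz - 1)
    xx = np.broadcast_to(np.arange(nx)[None, :, None], (nz, nx, ny))
    yy = np.broadcast_to(np.arange(ny)[None, None, :], (nz, nx, ny))
    out = np.where(valid, np.asarray(volume.data)[zz_c, xx, yy], fill)
    return VolumeGrid(out, volume.spacing, volume.modality)


# ---------------------------------------------------------------------------
# Cropping and the full pipeline


def crop_standard(series: AcquisitionSeries, margin_px: int) -> AcquisitionSeries:
    """Remove a fixed margin from every transverse side; depth untouched."""
    if margin_px < 0:
        raise ValidationError("margin must be >= 0")
    if margin_px == 0:
        return series
    _, nx, ny = series.shape
    if 2 * margin_px >= nx or 2 * margin_px >= ny:
        raise ValidationError(
            f"margin {margin_px} px too large for transverse shape {(nx, ny)}"
        )
    sl = slice(margin_px, -margin_px)

    def crop(vol: VolumeGrid) -> VolumeGrid:
        return VolumeGrid(vol.data[:, sl, sl], vol.spacing, vol.modality)

    return AcquisitionSeries(
        [crop(v) for v in series.octa_volumes],
        [crop(v) for v in series.oct_volumes],
        session_id=series.session_id,
    )


def register_series(
    series: AcquisitionSeries,
    layers: LayerBoundaries | None = None,
    template: int | str = "auto",
    margin_px: int = 20,
    fill: float = 0.0,
    axial_search: int = 10,
    seed: int = 0,
) -> tuple[AcquisitionSeries, RegistrationResult]:
    """Full pipeline: template selection, rigid + demons + axial per
    repeat, then standardized cropping.  The template passes through
    unchanged (identity transforms)."""
    t_idx = select_template(series, layers) if template == "auto" else int(template)
    if not 0 <= t_idx < series.n_volumes:
        raise ValidationError(f"template index {t_idx} out of range")
    # Full-depth mean projections for the transverse stages: axial
    # mismatch is only corrected later, and a layer-bounded slab would
    # let it leak content changes into the feature images.
    tpl_enface = enface_projection(series.octa_volumes[t_idx])
    rigids: list[RigidTransform2D | None] = []
    fields: list[DeformationField | None] = []
    axials: list[AxialShiftMap | None] = []
    octa_out: list[VolumeGrid] = []
    oct_out: list[VolumeGrid] = []
    for k in range(series.n_volumes):
        if k == t_idx:
            rigids.append(None)
            fields.append(None)
            axials.append(None)
            octa_out.append(series.octa_volumes[k])
            oct_out.append(series.oct_volumes[k])
            continue
        tgt_enface = enface_projection(series.octa_volumes[k])
        rigid = register_rigid(tpl_enface, tgt_enface, seed=seed)
        aligned = warp_enface(tgt_enface, rigid, fill=fill)
        defo = register_nonrigid(tpl_enface, aligned)
        octa_k = apply_transverse(series.octa_volumes[k], rigid, defo, fill=fill)
        oct_k = apply_transverse(series.oct_volumes[k], rigid, defo, fill=fill)
        ax = axial_match(series.oct_volumes[t_idx], oct_k, search_range=axial_search)
        octa_k = apply_axial(octa_k, ax, fill=fill)
        oct_k = apply_axial(oct_k, ax, fill=fill)
        rigids.append(rigid)
        fields.append(defo)
        axials.append(ax)
        octa_out.append(octa_k)
        oct_out.append(oct_k)
    registered = AcquisitionSeries(octa_out, oct_out, session_id=series.session_id)
    cropped = crop_standard(registered, margin_px)
    result = RegistrationResult(
        template_index=t_idx,
        rigid=rigids,
        deformation=fields,
        axial=axials,
        post_crop_shape=cropped.shape,
    )
    return cropped, result
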