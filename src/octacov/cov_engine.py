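"""Per-voxel coefficient of variation across repeated OCTA volumes.

Three protocols quantify perfusion heterogeneity from N registered
repeats:

* **Protocol A** — per-pixel CoV of a stack of device-style,
  contrast-refined 2D en face images (the conventional approach; the
  nonlinear rendering reshapes the intensity distribution and biases
  the CoV);
* **Protocol B** — per-pixel CoV of per-repeat maximum intensity
  projections of the raw volume (MIP can select its maximum at a
  different depth in each repeat, mixing signals from different
  vessels);
* **Protocol C** — the volumetric method: CoV is computed per *voxel*,

      CoV(x,z;y) = σ(x,z;y) / Ī(x,z;y),

  with Ī the arithmetic mean over the N repeats and σ the sample
  standard deviation (N−1 denominator), then noise-masked per B-scan
  and projected to en face by a median over a layer slab.

Noise masking: for every B-scan y the noise floor is estimated in a
background band R(y) spanning 10–30 pixels *anterior* to the per-A-scan
ILM on the averaged volume; the threshold is

    T(y) = Ī_noise(y) + σ_noise(y) + δ,

and the binary mask keeps voxels with Ī strictly above T(y).  δ is
either supplied or calibrated as the largest offset that suppresses
background without eroding the vasculature (Dice overlap against a
reference vessel mask).

CoV is defined as 0 where Ī = 0 (such voxels are always sub-threshold
and masked; this avoids division errors).  Wherever σ = 0 the CoV is
exactly 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .volume_io import (
    AcquisitionSeries,
    EnFaceMap,
    LayerBoundaries,
    MapKind,
    Modality,
    ValidationError,
    VolumeGrid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseEstimate",
    "CoVResult",
    "DepthIndexMap",
    "cov_volumetric",
    "estimate_noise",
    "select_delta",
    "binary_mask",
    "filtered_cov",
    "protocol_a_cov",
    "protocol_b_cov",
    "depth_index_variability",
    "median_projection",
    "apply_vessel_mask",
    "slab_bounds",
    "protocol_c_enface",
]


@dataclass
class NoiseEstimate:
    """Per-B-scan noise floor statistics and binary threshold."""

    noise_mean: np.ndarray  # Ī_noise(y), shape (ny,)
    noise_std: np.ndarray  # σ_noise(y)
    delta: float
    region: tuple[int, int]  # (lower, upper) pixel offsets above the ILM

    def __post_init__(self) -> None:
        self.noise_mean = np.asarray(self.noise_mean, dtype=np.float64)
        self.noise_std = np.asarray(self.noise_std, dtype=np.float64)
        self.delta = float(self.delta)

    @property
    def threshold(self) -> np.ndarray:
        """T(y) = Ī_noise(y) + σ_noise(y) + δ."""
        return self.noise_mean + self.noise_std + self.delta


@dataclass
class CoVResult:
    """Raw and (optionally) noise-filtered volumetric CoV."""

    cov: VolumeGrid  # raw CoV(x,z;y)
    mean: VolumeGrid  # Ī
    std: VolumeGrid  # σ
    protocol: str = "C"
    mask: VolumeGrid | None = None  # M(x,z;y)
    filtered: VolumeGrid | None = None  # V = CoV ⊙ M


@dataclass
class DepthIndexMap:
    """Per-repeat argmax depth per A-scan and its STD across repeats."""

    indices: np.ndarray  # (N, nx, ny) int
    std: np.ndarray  # (nx, ny)


def _stack(series: AcquisitionSeries) -> np.ndarray:
    return np.stack([np.asarray(v.data, dtype=np.float64) for v in series.octa_volumes])


def _cov_of_stack(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=1)
    cov = np.zeros_like(mean)
    np.divide(std, mean, out=cov, where=mean > 0)
    cov[std == 0] = 0.0
    return cov, mean, std


def cov_volumetric(series: AcquisitionSeries) -> CoVResult:
    """Protocol C raw CoV: σ/Ī per voxel across the N repeats."""
    if series.n_volumes < 2:
        raise ValidationError("CoV needs at least 2 repeats")
    cov, mean, std = _cov_of_stack(_stack(series))
    spacing = series.spacing
    return CoVResult(
        cov=VolumeGrid(cov, spacing, Modality.COV),
        mean=VolumeGrid(mean, spacing, Modality.OCTA),
        std=VolumeGrid(std, spacing, Modality.OCTA),
        protocol="C",
    )


def estimate_noise(
    mean_volume: VolumeGrid,
    layers: LayerBoundaries | np.ndarray,
    delta: float = 0.0,
    region: tuple[int, int] = (10, 30),
) -> NoiseEstimate:
    """Noise floor per B-scan from the band ``z in [ILM-upper, ILM-lower]``.

    The band sits anterior to the retina (vitreous), so it samples pure
    background.  Statistics use all (x, z) samples of the band within
    the averaged volume: the mean with a 1/|R| denominator and the
    sample standard deviation with 1/(|R|-1).  Bands that would extend
    above z = 0 are clipped with a logged warning; an empty band for
    some y is an error.
    """
    ilm = layers.ilm if isinstance(layers, LayerBoundaries) else np.asarray(layers)
    nz, nx, ny = mean_volume.shape
    if ilm.shape != (nx, ny):
        raise ValidationError("ILM map shape does not match the volume")
    lower, upper = region
    if not (0 < lower < upper):
        raise ValidationError("noise region bounds must satisfy 0 < lower < upper")
    data = np.asarray(mean_volume.data, dtype=np.float64)
    offsets = np.arange(-upper, -lower + 1)  # inclusive band, |R| per A-scan
    clipped = bool((ilm.min() - upper) < 0)
    if clipped:
        logger.warning("noise band clipped at z = 0 for some A-scans")
    means = np.empty(ny)
    stds = np.empty(ny)
    xs = np.arange(nx)
    for y in range(ny):
        zidx = ilm[:, y][:, None] + offsets[None, :]  # (nx, |R|)
        valid = zidx >= 0
        if not valid.any():
            raise ValidationError(f"noise region empty after clipping at y={y}")
        xi = np.broadcast_to(xs[:, None], zidx.shape)[valid]
        vals = data[zidx[valid], xi, y]
        means[y] = vals.mean()
        stds[y] = vals.std(ddof=1) if vals.size > 1 else 0.0
    return NoiseEstimate(noise_mean=means, noise_std=stds, delta=delta,
                         region=(lower, upper))


def binary_mask(mean_volume: VolumeGrid, noise: NoiseEstimate) -> VolumeGrid:
    """M(x,z;y) = 1 where Ī(x,z;y) strictly exceeds T(y), else 0.

    A voxel exactly at the threshold is excluded (strict inequality)."""
    thr = noise.threshold
    if thr.shape[0] != mean_volume.ny:
        raise ValidationError("noise estimate does not cover every B-scan")
    m = (np.asarray(mean_volume.data) > thr[None, None, :]).astype(np.uint8)
    return VolumeGrid(m, mean_volume.spacing, Modality.MASK)


def filtered_cov(raw: CoVResult, mask: VolumeGrid) -> CoVResult:
    """V(x,z;y) = CoV(x,z;y) ⊙ M(x,z;y)."""
    if mask.shape != raw.cov.shape:
        raise ValidationError("mask shape does not match the CoV volume")
    v = np.asarray(raw.cov.data) * np.asarray(mask.data)
    return CoVResult(
        cov=raw.cov,
        mean=raw.mean,
        std=raw.std,
        protocol=raw.protocol,
        mask=mask,
        filtered=VolumeGrid(v, raw.cov.spacing, Modality.COV),
    )


def slab_bounds(
    layers: LayerBoundaries, slab: tuple[str, str] = ("ilm", "opl")
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a (upper, lower) boundary-name pair to per-A-scan indices.

    Boundary names: ``ilm``, ``nfl`` (NFL lower boundary), ``opl`` (OPL
    lower boundary).  Slabs are half-open: ``z in [upper, lower)``.
    """
    named = {"ilm": layers.ilm, "nfl": layers.nfl_lower, "opl": layers.opl_lower}
    try:
        upper, lower = named[slab[0]], named[slab[1]]
    except KeyError as exc:
        raise ValidationError(f"unknown slab boundary {exc}") from exc
    if (upper >= lower).any():
        raise ValidationError("degenerate slab: upper >= lower somewhere")
    return upper, lower


def select_delta(
    mean_volume: VolumeGrid,
    reference_vessel_mask: EnFaceMap,
    layers: LayerBoundaries,
    delta_grid: Sequence[float] | None = None,
    region: tuple[int, int] = (10, 30),
    slab: tuple[str, str] = ("ilm", "opl"),
    tolerance: float = 0.02,
) -> float:
    """Calibrate δ: the largest offset that suppresses noise without
    compromising vascular integrity.

    For each δ on the grid, the binary mask is built, projected through
    the slab, and scored by Dice overlap against the reference vessel
    mask; the selected δ is the largest one whose Dice stays within
    ``tolerance`` of the best value.
    """
    if delta_grid is None:
        span = float(np.percentile(mean_volume.data, 99.5))
        delta_grid = np.linspace(0.0, max(span, 1.0), 21)
    delta_grid = np.asarray(list(delta_grid), dtype=np.float64)
    if delta_grid.size == 0:
        raise ValueError("delta grid must be non-empty")
    ref = np.asarray(reference_vessel_mask.data) > 0
    base = estimate_noise(mean_volume, layers, delta=0.0, region=region)
    upper, lower = slab_bounds(layers, slab)
    zz = np.arange(mean_volume.nz)[:, None, None]
    in_slab = (zz >= upper[None]) & (zz < lower[None])
    dices = np.empty_like(delta_grid)
    for i, d in enumerate(delta_grid):
        noise = NoiseEstimate(base.noise_mean, base.noise_std, d, base.region)
        m = binary_mask(mean_volume, noise).data.astype(bool)
        proj = (m & in_slab).any(axis=0)
        inter = 2.0 * np.logical_and(proj, ref).sum()
        denom = proj.sum() + ref.sum()
        dices[i] = inter / denom if denom else 0.0
    best = dices.max()
    ok = np.flatnonzero(dices >= best - tolerance)
    return float(delta_grid[ok.max()])


# ---------------------------------------------------------------------------
# Baseline protocols and projections


def protocol_a_cov(enface_stack: Sequence[EnFaceMap]) -> EnFaceMap:
    """Per-pixel CoV of N registered 2D en face images (Protocol A)."""
    if len(enface_stack) < 2:
        raise ValidationError("CoV needs at least 2 images")
    shapes = {m.shape for m in enface_stack}
    if len(shapes) != 1:
        raise ValidationError(f"en face images must share a shape, got {shapes}")
    stack = np.stack([np.asarray(m.data, dtype=np.float64) for m in enface_stack])
    cov, _, _ = _cov_of_stack(stack)
    return EnFaceMap(cov, enface_stack[0].spacing, MapKind.COV)


def protocol_b_cov(
    series: AcquisitionSeries,
    layers: LayerBoundaries,
    slab: tuple[str, str] = ("ilm", "opl"),
) -> EnFaceMap:
    """Per-pixel CoV of per-repeat slab MIPs (Protocol B).

    The maximum is free to come from a different depth in every repeat;
    when two vessels share an A-scan, their temporal signals mix and the
    resulting CoV no longer describes either vessel.
    """
    if series.n_volumes < 2:
        raise ValidationError("CoV needs at least 2 repeats")
    upper, lower = slab_bounds(layers, slab)
    zz = np.arange(series.shape[0])[:, None, None]
    in_slab = (zz >= upper[None]) & (zz < lower[None])
    mips = []
    for vol in series.octa_volumes:
        data = np.where(in_slab, np.asarray(vol.data, dtype=np.float64), -np.inf)
        mips.append(data.max(axis=0))
    cov, _, _ = _cov_of_stack(np.stack(mips))
    return EnFaceMap(cov, series.spacing[1:], MapKind.COV)


def depth_index_variability(
    series: AcquisitionSeries,
    layers: LayerBoundaries,
    slab: tuple[str, str] = ("ilm", "opl"),
) -> DepthIndexMap:
    """Depth index of the per-repeat slab maximum and its STD across repeats.

    Argmax ties resolve to the smallest z (first maximum), so the map is
    deterministic on tied input.  A nonzero STD flags A-scans where MIP
    mixes signals from different depths (the Protocol B failure mode).
    """
    upper, lower = slab_bounds(layers, slab)
    zz = np.arange(series.shape[0])[:, None, None]
    in_slab = (zz >= upper[None]) & (zz < lower[None])
    idx = []
    for vol in series.octa_volumes:
        data = np.where(in_slab, np.asarray(vol.data, dtype=np.float64), -np.inf)
        idx.append(data.argmax(axis=0))
    indices = np.stack(idx)
    return DepthIndexMap(indices=indices, std=indices.std(axis=0, ddof=1))


def median_projection(
    filtered: VolumeGrid | CoVResult,
    upper: np.ndarray,
    lower: np.ndarray,
    nonzero_only: bool = False,
) -> EnFaceMap:
    """Median intensity projection of the filtered CoV volume over the
    half-open slab ``z in [upper, lower)`` per A-scan.

    An even sample count yields the mean of the central pair.  With
    ``nonzero_only`` the median runs over the mask-retained (positive)
    voxels of the slab only — a capillary a few voxels thick would
    otherwise be outvoted by the masked-out zeros around it — yielding
    0 where the A-scan holds no retained voxel.  The en face pipeline
    uses that variant; the default is the plain slab median.
    """
    vol = filtered.filtered if isinstance(filtered, CoVResult) else filtered
    if vol is None:
        raise ValidationError("CoVResult has no filtered volume; apply the mask first")
    nz = vol.nz
    upper = np.asarray(upper)
    lower = np.asarray(lower)
    if (upper >= lower).any() or (upper < 0).any() or (lower > nz).any():
        raise ValidationError("invalid slab bounds")
    zz = np.arange(nz)[:, None, None]
    in_slab = (zz >= upper[None]) & (zz < lower[None])
    data = np.asarray(vol.data, dtype=np.float64)
    keep = in_slab & (data > 0) if nonzero_only else in_slab
    data = np.where(keep, data, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        proj = np.nanmedian(data, axis=0)
    return EnFaceMap(np.nan_to_num(proj), vol.spacing[1:], MapKind.COV)


def apply_vessel_mask(
    cov_map: EnFaceMap, probability: EnFaceMap, threshold: float = 0.5
) -> EnFaceMap:
    """Zero the CoV map outside the binarized vessel-probability support.

    A probability of exactly 0.5 counts as vessel (>= rule): the
    threshold is the 50% confidence level for *identifying* a pixel as a
    blood vessel."""
    if cov_map.shape != probability.shape:
        raise ValidationError("map shapes do not match")
    p = np.asarray(probability.data)
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("probability values must lie in [0, 1]")
    out = np.asarray(cov_map.data) * (p >= threshold)
    return EnFaceMap(out, cov_map.spacing, cov_map.kind)


# ---------------------------------------------------------------------------
# Orchestration


def protocol_c_enface(
    series: AcquisitionSeries,
    layers: LayerBoundaries,
    delta: float | str = 0.0,
    reference_vessel_mask: EnFaceMap | None = None,
    vessel_probability: EnFaceMap | None = None,
    region: tuple[int, int] = (10, 30),
    slab: tuple[str, str] = ("ilm", "opl"),
) -> tuple[CoVResult, EnFaceMap]:
    """Full Protocol C: volumetric CoV, noise masking, median projection,
    optional vessel-probability masking.  ``delta="auto"`` calibrates δ
    against the reference vessel mask."""
    raw = cov_volumetric(series)
    if delta == "auto":
        if reference_vessel_mask is None:
            raise ValidationError("delta='auto' needs a reference vessel mask")
        delta = select_delta(raw.mean, reference_vessel_mask, layers, region=region, slab=slab)
    noise = estimate_noise(raw.mean, layers, delta=float(delta), region=region)
    mask = binary_mask(raw.mean, noise)
    result = filtered_cov(raw, mask)
    upper, lower = slab_bounds(layers, slab)
    enface = median_projection(result, upper, lower, nonzero_only=True)
    if vessel_probability is not None:
        enface = apply_vessel_mask(enface, vessel_probability)
    return result, enface
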