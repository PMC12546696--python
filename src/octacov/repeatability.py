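"""Intersession repeatability of CoV maps: pairwise variance and
FAZ-centered ring summaries.

A subject imaged in S sessions yields S en face CoV maps V₁…V_S.  After
mutual rigid alignment, the per-pixel sample variance of every session
pair (a − b)²/2 quantifies how stable the CoV estimate is over time
(S = 3 gives 3 pairs per subject; 8 subjects give 24 variance
estimates).  Because perfusion heterogeneity is spatially structured,
variances are summarized within concentric regions around the foveal
avascular zone: z0 is the FAZ itself, z1 the annulus reaching 0.5 mm
beyond the z0 boundary and z2 the annulus from 0.5 mm to 1 mm.
Distances are Euclidean distances to the z0 boundary in physical units.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import registration
from .volume_io import EnFaceMap, MapKind, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SessionSet",
    "RingRegions",
    "RingSummary",
    "register_session_maps",
    "pairwise_variance",
    "joint_variance",
    "define_rings",
    "summarize_rings",
    "all_pairwise_variances",
]


@dataclass
class SessionSet:
    """Mutually registered en face CoV maps from S >= 2 sessions."""

    maps: list[EnFaceMap]
    subject: str = "subject-0"

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValidationError("need at least 2 sessions")
        shapes = {m.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValidationError(f"session maps must share a shape, got {shapes}")

    @property
    def n_sessions(self) -> int:
        return len(self.maps)


@dataclass
class RingRegions:
    """z0 (FAZ) plus two annuli at physical distances from its boundary."""

    z0: EnFaceMap
    z1: EnFaceMap
    z2: EnFaceMap
    distances_mm: tuple[float, float]
    spacing: tuple[float, float]  # μm per pixel

    def masks(self) -> dict[str, np.ndarray]:
        return {
            "z0": np.asarray(self.z0.data).astype(bool),
            "z1": np.asarray(self.z1.data).astype(bool),
            "z2": np.asarray(self.z2.data).astype(bool),
        }


@dataclass
class RingSummary:
    """Per-ring mean and STD of the spatial-mean variance over session pairs."""

    subject: str
    per_pair_means: dict[str, np.ndarray]  # ring -> (n_pairs,)
    mean: dict[str, float]
    std: dict[str, float]
    protocol: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject, "ring": ring, "protocol": self.protocol,
             "mean_variance": self.mean[ring], "std_variance": self.std[ring]}
            for ring in self.mean
        ]
        return pd.DataFrame(rows)


def register_session_maps(
    maps: list[EnFaceMap], subject: str = "subject-0", seed: int = 0
) -> SessionSet:
    """Rigidly align all session maps to the first and crop to the
    common support (the first map is the template by convention)."""
    if len(maps) < 2:
        raise ValidationError("need at least 2 session maps")
    template = maps[0]
    aligned = [template]
    supports = [np.ones(template.shape, dtype=bool)]
    for k, target in enumerate(maps[1:], start=1):
        try:
            rigid = registration.register_rigid(template, target, seed=seed)
        except registration.RegistrationError as exc:
            raise registration.RegistrationError(
                f"session {k} failed to register to session 0: {exc}",
                exc.diagnostics,
            ) from exc
        aligned.append(registration.warp_enface(target, rigid))
        ones = EnFaceMap(np.ones(target.shape), target.spacing, MapKind.OCTA)
        support = registration.warp_enface(ones, rigid).data >= 0.999
        supports.append(support)
    common = np.logical_and.reduce(supports)
    if not common.any():
        raise ValidationError("registered sessions share no common support")
    rows = np.flatnonzero(common.any(axis=1))
    cols = np.flatnonzero(common.any(axis=0))
    sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    cropped = [EnFaceMap(m.data[sl], m.spacing, m.kind) for m in aligned]
    return SessionSet(maps=cropped, subject=subject)


def pairwise_variance(map_a: EnFaceMap, map_b: EnFaceMap) -> EnFaceMap:
    """Per-pixel sample variance of two sessions: (a − b)²/2.

    This is the n = 2 case of the N−1-denominator sample variance, the
    same convention used for the temporal standard deviation."""
    if map_a.shape != map_b.shape:
        raise ValidationError("maps must share a shape")
    var = (np.asarray(map_a.data, dtype=np.float64)
           - np.asarray(map_b.data, dtype=np.float64)) ** 2 / 2.0
    return EnFaceMap(var, map_a.spacing, MapKind.VARIANCE)


def joint_variance(session_set: SessionSet) -> EnFaceMap:
    """Per-pixel sample variance across all S sessions jointly."""
    stack = np.stack([np.asarray(m.data, dtype=np.float64) for m in session_set.maps])
    return EnFaceMap(stack.var(axis=0, ddof=1), session_set.maps[0].spacing,
                     MapKind.VARIANCE)


def all_pairwise_variances(session_set: SessionSet) -> list[EnFaceMap]:
    """Variance maps for every unordered session pair: S(S−1)/2 maps."""
    return [
        pairwise_variance(a, b)
        for a, b in itertools.combinations(session_set.maps, 2)
    ]


def define_rings(
    faz_mask: EnFaceMap,
    spacing: tuple[float, float] | None = None,
    distances_mm: tuple[float, float] = (0.5, 1.0),
) -> RingRegions:
    """Annular regions at physical distances from the FAZ boundary.

    ``z1`` holds pixels whose Euclidean distance to the z0 region is in
    (0, d₁] mm, ``z2`` those in (d₁, d₂] mm; distances use the pixel
    spacing, so the rings are genuinely metric, not pixel counts.
    """
    faz = np.asarray(faz_mask.data) > 0
    if not faz.any():
        raise ValidationError("FAZ mask is empty")
    if spacing is None:
        spacing = faz_mask.spacing
    d1, d2 = distances_mm
    if not (0 < d1 < d2):
        raise ValidationError("ring distances must satisfy 0 < d1 < d2")
    sampling_mm = (spacing[0] / 1000.0, spacing[1] / 1000.0)
    dist = ndimage.distance_transform_edt(~faz, sampling=sampling_mm)
    z1 = (dist > 0) & (dist <= d1)
    z2 = (dist > d1) & (dist <= d2)
    sp = tuple(spacing)
    return RingRegions(
        z0=EnFaceMap(faz.astype(np.uint8), sp, MapKind.MASK),
        z1=EnFaceMap(z1.astype(np.uint8), sp, MapKind.MASK),
        z2=EnFaceMap(z2.astype(np.uint8), sp, MapKind.MASK),
        distances_mm=(float(d1), float(d2)),
        spacing=sp,
    )


def summarize_rings(
    variance_maps: list[EnFaceMap],
    rings: RingRegions,
    exclude: np.ndarray | None = None,
    subject: str = "subject-0",
    protocol: str = "",
) -> RingSummary:
    """Spatial mean of each variance map within each ring, then mean and
    sample STD across the session pairs.

    ``exclude`` marks pixels to drop from the ring means (e.g. pixels
    with zero CoV in any session — background, not vasculature)."""
    masks = rings.masks()
    if exclude is not None:
        excluded = int(exclude.sum())
        if excluded:
            logger.info("excluding %d background pixels from ring means", excluded)
        masks = {name: m & ~exclude for name, m in masks.items()}
    per_pair: dict[str, np.ndarray] = {}
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for name, m in masks.items():
        if not m.any():
            logger.warning("ring %s has no usable pixels; summary undefined", name)
            per_pair[name] = np.full(len(variance_maps), np.nan)
            mean[name] = float("nan")
            std[name] = float("nan")
            continue
        vals = np.array([float(np.asarray(v.data)[m].mean()) for v in variance_maps])
        per_pair[name] = vals
        mean[name] = float(vals.mean())
        std[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return RingSummary(subject=subject, per_pair_means=per_pair,
                       mean=mean, std=std, protocol=protocol)
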