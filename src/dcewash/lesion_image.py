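"""Image-domain operations on lesion masks and multi-phase volumes.

The kinetic read-out of a lesion is defined by an exhaustive search: a
circular ROI of fixed diameter (default 3 mm) is placed at every voxel
center, in every slice of every orthogonal plane family, such that the
disc lies fully inside the lesion mask; the ROI with the highest
washout index is reported.  Lesion size is the longest in-plane Feret
diameter over the three reformatted plane families.  Shrinkage-pattern
classification is a computational proxy for the radiologists' visual
concentric-vs-dendritic call.

Conventions: 0-based voxel indexing; world coordinates are
``index * spacing`` (axis-aligned grids only); all in-plane distances
are voxel-center to voxel-center in millimetres.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import EmptyLesionError, GridMismatchError, NoPlacementError
from .kinetics import KineticResult, KineticSample, classify_curve

logger = logging.getLogger(__name__)

DEFAULT_ROI_DIAMETER_MM: float = 3.0

#: Erosion radius (mm) of the baseline envelope used by the uneven-
#: shrinkage test of :func:`classify_shrinkage`.
DEFAULT_SHRINKAGE_EROSION_MM: float = 2.0


class Phase(enum.Enum):
    PRE = "pre"
    EARLY = "early"
    DELAY = "delay"


class ShrinkagePattern(enum.Enum):
    CONCENTRIC = "concentric"
    DENDRITIC = "dendritic"


@dataclass(frozen=True)
class PhaseVolume:
    """One DCE phase: a 3-D scalar grid plus per-axis voxel size in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    phase: Phase

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")


@dataclass(frozen=True)
class LesionMask:
    """Binary lesion mask on the same grid as its companion volumes."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        object.__setattr__(self, "data", self.data.astype(bool))

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())


@dataclass(frozen=True)
class RoiPlacement:
    """A single disc ROI: plane held fixed, slice, in-plane center, voxels.

    ``member_voxels`` is a tuple of (i, j, k) voxel indices; ``center``
    is the in-plane position of the central voxel in mm, in the order
    of the two in-plane axes (ascending axis index).
    """

    plane_axis: int
    slice_index: int
    center: tuple[float, float]
    member_voxels: tuple[tuple[int, int, int], ...]


@dataclass(frozen=True)
class LesionKinetics:
    """Result of the max-WI ROI search over one lesion."""

    best_sample: KineticSample
    best_result: KineticResult
    best_placement: RoiPlacement
    n_placements: int


def _inplane_axes(plane_axis: int) -> tuple[int, int]:
    return tuple(a for a in range(3) if a != plane_axis)  # type: ignore[return-value]


def _disc_footprint(spacing_rc: tuple[float, float], diameter: float) -> np.ndarray:
    """2-D boolean footprint of voxel centers within diameter/2 (inclusive)."""
    radius = diameter / 2.0
    nr = int(np.floor(radius / spacing_rc[0]))
    nc = int(np.floor(radius / spacing_rc[1]))
    rr, cc = np.meshgrid(
        np.arange(-nr, nr + 1) * spacing_rc[0],
        np.arange(-nc, nc + 1) * spacing_rc[1],
        indexing="ij",
    )
    return rr**2 + cc**2 <= radius**2 + 1e-12


def _valid_centers(
    mask: np.ndarray, plane_axis: int, footprint2d: np.ndarray
) -> np.ndarray:
    """Boolean grid of centers whose disc lies fully inside the mask."""
    shape = [1, 1, 1]
    r_ax, c_ax = _inplane_axes(plane_axis)
    shape[r_ax], shape[c_ax] = footprint2d.shape
    structure = footprint2d.reshape(shape)
    return ndimage.binary_erosion(mask, structure=structure, border_value=0)


def enumerate_roi_placements(
    mask: LesionMask,
    diameter: float = DEFAULT_ROI_DIAMETER_MM,
    planes: str = "all",
    fallback: str | None = None,
) -> list[RoiPlacement]:
    """Enumerate every fully-contained disc ROI inside the lesion mask.

    One placement is generated per (plane family, slice, in-plane voxel
    center) for which every in-plane voxel whose center lies within
    ``diameter / 2`` of the candidate center belongs to the mask.
    Ordering is deterministic: plane axis, then slice, then row, then
    column.

    Parameters
    ----------
    planes:
        ``"all"`` (default) enumerates the three orthogonal plane
        families; ``"axial"`` restricts to slices perpendicular to
        axis 0.
    fallback:
        ``None`` (default) raises :class:`NoPlacementError` when no
        disc fits (mirrors the exclusion of lesions too small to
        measure); ``"voxel"`` degrades to single-voxel ROIs instead.
    """
    if mask.is_empty:
        raise EmptyLesionError("lesion mask is empty (no enhancing lesion)")
    plane_axes = (0,) if planes == "axial" else (0, 1, 2)

    placements: list[RoiPlacement] = []
    for plane_axis in plane_axes:
        r_ax, c_ax = _inplane_axes(plane_axis)
        sp_rc = (mask.spacing[r_ax], mask.spacing[c_ax])
        foot = _disc_footprint(sp_rc, diameter)
        offs = np.argwhere(foot) - np.array([foot.shape[0] // 2, foot.shape[1] // 2])
        valid = _valid_centers(mask.data, plane_axis, foot)
        # centers in (slice, row, column) order
        order = (plane_axis, r_ax, c_ax)
        centers = np.argwhere(np.transpose(valid, order))
        for s, r, c in centers:
            idx = np.empty((len(offs), 3), dtype=int)
            idx[:, plane_axis] = s
            idx[:, r_ax] = r + offs[:, 0]
            idx[:, c_ax] = c + offs[:, 1]
            placements.append(
                RoiPlacement(
                    plane_axis=plane_axis,
                    slice_index=int(s),
                    center=(float(r * sp_rc[0]), float(c * sp_rc[1])),
                    member_voxels=tuple(map(tuple, idx.tolist())),
                )
            )
    if placements:
        return placements
    if fallback == "voxel":
        voxels = np.argwhere(mask.data)
        return [
            RoiPlacement(
                plane_axis=0,
                slice_index=int(i),
                center=(float(j * mask.spacing[1]), float(k * mask.spacing[2])),
                member_voxels=((int(i), int(j), int(k)),),
            )
            for i, j, k in voxels
        ]
    raise NoPlacementError(
        f"no {diameter} mm disc fits inside the lesion mask "
        "(lesion too small for the ROI)"
    )


def roi_mean_signal(volume: PhaseVolume, placement: RoiPlacement) -> float:
    """Arithmetic mean signal intensity over the ROI member voxels."""
    idx = np.asarray(placement.member_voxels)
    if (idx < 0).any() or (idx >= np.array(volume.data.shape)).any():
        raise IndexError("ROI placement extends outside the volume grid")
    return float(volume.data[idx[:, 0], idx[:, 1], idx[:, 2]].mean())


def _center_voxel(
    placement: RoiPlacement, spacing: tuple[float, float, float]
) -> tuple[int, int, int]:
    """Voxel index of the placement's central voxel."""
    if len(placement.member_voxels) == 1:
        return placement.member_voxels[0]
    r_ax, c_ax = _inplane_axes(placement.plane_axis)
    idx = [0, 0, 0]
    idx[placement.plane_axis] = placement.slice_index
    idx[r_ax] = int(round(placement.center[0] / spacing[r_ax]))
    idx[c_ax] = int(round(placement.center[1] / spacing[c_ax]))
    return tuple(idx)  # type: ignore[return-value]


def _check_aligned(volumes: Sequence[PhaseVolume], mask: LesionMask) -> None:
    ref_shape, ref_spacing = mask.data.shape, mask.spacing
    for v in volumes:
        for ax in range(3):
            if v.data.shape[ax] != ref_shape[ax]:
                raise GridMismatchError(
                    f"phase {v.phase.value}: grid shape differs from mask "
                    f"along axis {ax} ({v.data.shape[ax]} != {ref_shape[ax]})"
                )
            if not np.isclose(v.spacing[ax], ref_spacing[ax]):
                raise GridMismatchError(
                    f"phase {v.phase.value}: voxel spacing differs from mask "
                    f"along axis {ax} ({v.spacing[ax]} != {ref_spacing[ax]})"
                )


def lesion_max_wi(
    pre: PhaseVolume,
    early: PhaseVolume,
    delay: PhaseVolume,
    mask: LesionMask,
    diameter: float = DEFAULT_ROI_DIAMETER_MM,
    planes: str = "all",
    fallback: str | None = None,
    ratio_threshold: float | None = None,
    wi_threshold: float | None = None,
) -> LesionKinetics:
    """Exhaustive max-WI search over all disc ROI placements.

    Evaluates the washout index on the per-phase ROI mean signals of
    every placement and returns the placement with the highest WI; ties
    are broken by enumeration order (first placement wins).  Placements
    whose pre-contrast mean is non-positive are skipped with a warning.
    The curve class of the winner is computed with the standard
    fast-washout thresholds unless overridden.
    """
    _check_aligned([pre, early, delay], mask)
    placements = enumerate_roi_placements(
        mask, diameter=diameter, planes=planes, fallback=fallback
    )

    best: tuple[float, int] | None = None  # (wi, index into placements)
    best_sample: KineticSample | None = None
    n_skipped = 0
    # Disc means are separable per plane family: a correlation of each
    # phase with the (normalised) disc footprint evaluates every
    # placement of that family at once.
    means_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for i, p in enumerate(placements):
        if p.plane_axis not in means_cache:
            if len(p.member_voxels) == 1:  # voxel fallback: means are voxels
                means_cache[p.plane_axis] = (pre.data, early.data, delay.data)
            else:
                r_ax, c_ax = _inplane_axes(p.plane_axis)
                foot = _disc_footprint(
                    (mask.spacing[r_ax], mask.spacing[c_ax]), diameter
                )
                shape = [1, 1, 1]
                shape[r_ax], shape[c_ax] = foot.shape
                w = foot.reshape(shape).astype(float) / foot.sum()
                means_cache[p.plane_axis] = tuple(
                    ndimage.correlate(v.data.astype(float), w, mode="constant")
                    for v in (pre, early, delay)
                )
        m_pre, m_early, m_delay = means_cache[p.plane_axis]
        center = _center_voxel(p, mask.spacing)
        si_pre = float(m_pre[center])
        if si_pre <= 0:
            n_skipped += 1
            continue
        wi = (float(m_early[center]) - float(m_delay[center])) / si_pre * 100.0
        if best is None or wi > best[0]:
            best = (wi, i)
            best_sample = KineticSample(
                si_pre=si_pre,
                si_early=float(m_early[center]),
                si_delay=float(m_delay[center]),
            )
    if n_skipped:
        logger.warning(
            "skipped %d ROI placements with non-positive pre-contrast mean",
            n_skipped,
        )
    if best is None or best_sample is None:
        raise NoPlacementError(
            "every ROI placement had a non-positive pre-contrast signal"
        )
    kwargs = {}
    if ratio_threshold is not None:
        kwargs["ratio_threshold"] = ratio_threshold
    if wi_threshold is not None:
        kwargs["wi_threshold"] = wi_threshold
    return LesionKinetics(
        best_sample=best_sample,
        best_result=classify_curve(best_sample, **kwargs),
        best_placement=placements[best[1]],
        n_placements=len(placements),
    )


def _slice_feret(points_mm: np.ndarray) -> float:
    """Max pairwise distance among 2-D points (mm); 0 for < 2 points."""
    if len(points_mm) < 2:
        return 0.0
    if len(points_mm) > 400:
        try:
            hull = ConvexHull(points_mm)
            points_mm = points_mm[hull.vertices]
        except QhullError:
            pass  # collinear points: fall through to direct pdist
    return float(pdist(points_mm).max())


def longest_diameter(mask: LesionMask) -> float:
    """Longest in-plane Feret diameter over the three plane families, in mm.

    For each orthogonal plane family the maximal center-to-center
    distance between mask voxels within any single slice is computed;
    the largest value over the three families is returned.  An empty
    mask has diameter 0, as does a single voxel (center-to-center
    convention).
    """
    if mask.is_empty:
        return 0.0
    best = 0.0
    for plane_axis in range(3):
        r_ax, c_ax = _inplane_axes(plane_axis)
        sp = np.array([mask.spacing[r_ax], mask.spacing[c_ax]])
        for s in range(mask.data.shape[plane_axis]):
            sl = np.take(mask.data, s, axis=plane_axis)
            pts = np.argwhere(sl) * sp
            best = max(best, _slice_feret(pts))
    return best


def _ball_structure(spacing: tuple[float, float, float], radius_mm: float) -> np.ndarray:
    n = [max(0, int(np.floor(radius_mm / s))) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-ni, ni + 1) * s for ni, s in zip(n, spacing)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_mm**2 + 1e-12


def count_components(mask: LesionMask) -> int:
    """Number of 26-connected components of the mask."""
    labeled, n = ndimage.label(mask.data, structure=np.ones((3, 3, 3), dtype=int))
    return int(n)


def classify_shrinkage(
    mask_baseline: LesionMask,
    mask_followup: LesionMask,
    erosion_mm: float = DEFAULT_SHRINKAGE_EROSION_MM,
) -> ShrinkagePattern:
    """Concentric-vs-dendritic shrinkage proxy for a PR lesion.

    DENDRITIC if the follow-up mask fragments into more 26-connected
    components than the baseline, or if it is not fully contained in
    the morphological interior of the baseline (baseline eroded by
    ``erosion_mm``), i.e. residual tissue still hugs the original
    boundary (uneven shrinkage).  CONCENTRIC otherwise.

    The caller is responsible for only invoking this on lesions that
    qualify as PR; an empty follow-up mask is CR, not PR, and raises
    :class:`EmptyLesionError`.
    """
    if mask_followup.is_empty:
        raise EmptyLesionError(
            "follow-up mask is empty: that is CR, shrinkage pattern undefined"
        )
    if count_components(mask_followup) > count_components(mask_baseline):
        return ShrinkagePattern.DENDRITIC
    interior = ndimage.binary_erosion(
        mask_baseline.data,
        structure=_ball_structure(mask_baseline.spacing, erosion_mm),
        border_value=0,
    )
    if not bool(np.all(interior[mask_followup.data])):
        return ShrinkagePattern.DENDRITIC
    return ShrinkagePattern.CONCENTRIC


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_phase_volume(path, phase: Phase) -> PhaseVolume:
    """Load one DCE phase from a NIfTI file."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return PhaseVolume(data=data, spacing=spacing, phase=phase)


def load_mask(path) -> LesionMask:
    """Load a binary lesion mask from a NIfTI file (non-zero = lesion)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LesionMask(data=data != 0, spacing=spacing)


def save_volume(path, data: np.ndarray, spacing: tuple[float, float, float]) -> None:
    """Write a volume (or mask) as NIfTI with a diagonal affine."""
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
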