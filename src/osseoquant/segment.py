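"""Three-class greyscale segmentation and interface cleanup.

Segmentation is histogram-oriented: two global thresholds maximizing the
three-class between-class variance (multi-level Otsu) split the volume into
background/marrow, bone and implant.  The interactive slice editing of a
workstation workflow is replaced by reproducible automatic steps: a
morphological opening of the bone mask restricted to a collar around the
implant (removing thin halo-induced bone shells at the metal interface),
small-island removal, and a plane-based exclusion of implant shell regions
that sit outside the bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import ball, disk

from .volume import BACKGROUND, BONE, EXCLUDED, IMPLANT, GreyVolume, LabelVolume


@dataclass(frozen=True)
class ThresholdPair:
    """Two grey-value thresholds: background|bone and bone|implant."""

    t_bone: float
    t_implant: float

    def __post_init__(self) -> None:
        if not self.t_bone < self.t_implant:
            raise ValueError(
                f"thresholds must satisfy t_bone < t_implant, got {self.t_bone} >= {self.t_implant}"
            )


def detect_thresholds(vol: GreyVolume, nbins: int = 256) -> ThresholdPair:
    """Two thresholds maximizing 3-class between-class variance (multi-Otsu).

    Computed on a ``nbins``-bin histogram spanning the data range. Requires
    at least 3 distinct grey values.
    """
    data = vol.data
    if np.unique(data).size < 3:
        raise ValueError("degenerate histogram: fewer than 3 distinct grey values")
    hist, edges = np.histogram(data, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    raw = threshold_multiotsu(classes=3, hist=(hist, centers))

    def snap(t: float) -> float:
        # raw thresholds are centers of the last bin of the lower class; place
        # the reported threshold mid-gap between the actual populations so the
        # "value == threshold → lower class" convention cannot flip a mode
        edge = edges[int(np.searchsorted(centers, t)) + 1]
        lower = data[data < edge]
        upper = data[data >= edge]
        if lower.size == 0 or upper.size == 0:
            return float(edge)
        return float((lower.max() + upper.min()) / 2)

    return ThresholdPair(snap(raw[0]), snap(raw[1]))


def segment_materials(vol: GreyVolume, thr: ThresholdPair) -> LabelVolume:
    """Label voxels by threshold: ``<= t_bone`` background, ``<= t_implant``
    bone, above that implant.  A voxel exactly at a threshold goes to the
    lower class."""
    data = vol.data
    labels = np.full(data.shape, BACKGROUND, dtype=np.uint8)
    labels[(data > thr.t_bone) & (data <= thr.t_implant)] = BONE
    labels[data > thr.t_implant] = IMPLANT
    return LabelVolume(labels, spacing=vol.spacing, origin=vol.origin)


def clean_interface(
    labels: LabelVolume,
    opening_radius: int = 1,
    min_island: int = 27,
    collar: int = 3,
) -> LabelVolume:
    """Clean the implant-bone transition.

    Binary opening (ball of ``opening_radius``) of the bone mask, applied
    only within a ``collar``-voxel collar around the implant — this strips
    the thin spurious bone shell that the bright metal halo produces — then
    removal of bone islands smaller than ``min_island`` voxels
    (26-connectivity).  Implant voxels are never modified; removed bone
    becomes background.
    """
    lab = labels.data.copy()
    bone = lab == BONE
    implant = lab == IMPLANT
    if opening_radius > 0 and collar > 0 and implant.any() and bone.any():
        near = ndimage.binary_dilation(implant, structure=ball(collar))
        collar_mask = near & ~implant
        opened = ndimage.binary_opening(bone, structure=ball(opening_radius))
        # opening only removes voxels; restrict the removal to the collar
        bone = bone & (opened | ~collar_mask)
    if min_island > 0 and bone.any():
        cc, n = ndimage.label(bone, structure=np.ones((3, 3, 3), dtype=bool))
        sizes = np.bincount(cc.ravel())
        small = sizes < min_island
        small[0] = False
        bone = bone & ~small[cc]
    out = lab.copy()
    out[(lab == BONE) & ~bone] = BACKGROUND
    return LabelVolume(out, spacing=labels.spacing, origin=labels.origin)


def perimeter_bone_coverage(
    labels: LabelVolume, annulus_width: int = 4, bridge: int = 4
) -> np.ndarray:
    """Per-slice bone coverage of the implant perimeter.

    For each z slice containing implant, the fraction of an
    ``annulus_width``-voxel annulus just outside the in-slice implant mask
    covered by bone after dilating the bone mask by ``bridge`` voxels (the
    dilation bridges marrow gaps and trabecular spacing, so embedded slices
    score near 1 while slices outside the bone score near 0).  Slices
    without implant get NaN.
    """
    lab = labels.data
    nz = lab.shape[0]
    cov = np.full(nz, np.nan)
    se_a = disk(annulus_width)
    se_b = disk(bridge)
    for z in range(nz):
        imp = lab[z] == IMPLANT
        if not imp.any():
            continue
        ann = ndimage.binary_dilation(imp, structure=se_a) & ~imp
        if not ann.any():
            continue
        boneish = ndimage.binary_dilation(lab[z] == BONE, structure=se_b)
        cov[z] = float((ann & boneish).sum() / ann.sum())
    return cov


def exclude_outside_bone(
    labels: LabelVolume,
    plane: str | tuple = "auto",
    coverage_threshold: float = 0.5,
) -> LabelVolume:
    """Relabel non-implant voxels outside the bone as ``excluded``.

    ``plane`` is either ``"auto"`` or a ``(point, normal)`` pair in µm
    (volume coordinates, z/y/x order); the normal points toward the excluded
    side.  In auto mode the plane is perpendicular to the implant axis at
    the lowest z slice above which the implant perimeter's bone coverage
    (:func:`perimeter_bone_coverage`) stays below ``coverage_threshold`` —
    i.e. where the implant emerges from the bone. If the implant is embedded
    everywhere, nothing is relabelled.

    Only the side membership matters, so moving the plane outward never
    un-excludes a voxel.
    """
    lab = labels.data.copy()
    if isinstance(plane, str):
        if plane != "auto":
            raise ValueError(f"plane must be 'auto' or (point, normal), got {plane!r}")
        cov = perimeter_bone_coverage(labels)
        has_imp = ~np.isnan(cov)
        if not has_imp.any():
            raise ValueError("no implant present")
        imp_z = np.where(has_imp)[0]
        below = has_imp & (cov < coverage_threshold)
        # lowest z such that every implant slice at or above it is uncovered
        z_cut = None
        for z in imp_z[::-1]:
            if below[z]:
                z_cut = z
            else:
                break
        if z_cut is None:
            return LabelVolume(lab, spacing=labels.spacing, origin=labels.origin)
        excluded_side = np.zeros(lab.shape, dtype=bool)
        excluded_side[z_cut:] = True
    else:
        point, normal = plane
        normal = np.asarray(normal, dtype=float)
        if np.linalg.norm(normal) == 0:
            raise ValueError("plane normal must be non-zero")
        point = np.asarray(point, dtype=float)
        s = labels.spacing
        coords = [
            labels.origin[i] + (np.arange(lab.shape[i]) + 0.5) * s for i in range(3)
        ]
        signed = (
            (coords[0][:, None, None] - point[0]) * normal[0]
            + (coords[1][None, :, None] - point[1]) * normal[1]
            + (coords[2][None, None, :] - point[2]) * normal[2]
        )
        excluded_side = signed > 0
    mask = excluded_side & (lab != IMPLANT)
    lab[mask] = EXCLUDED
    return LabelVolume(lab, spacing=labels.spacing, origin=labels.origin)
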