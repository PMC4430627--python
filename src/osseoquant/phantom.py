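"""Synthetic µCT phantoms of a conical titanium implant embedded in bone.

The generator emulates the geometry and the dominant artifacts of a cone-beam
µCT scan of a metal implant in trabecular bone: three grey-value classes
(marrow/background, bone, metal), a bright exponentially decaying halo around
the metal (the residue of beam hardening / metallic halation), Gaussian blur
(finite spot/detector resolution) and additive Gaussian noise.  Tomographic
projection and reconstruction themselves are not simulated — the phantom *is*
the reconstructed volume.

The module also carries the small acquisition-geometry arithmetic of a
rotate-and-shoot scan protocol (projection counts, nominal voxel size from
geometric magnification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, BONE, IMPLANT, GreyVolume, LabelVolume


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Rotate-step-shoot scan geometry of a cone-beam µCT.

    Parameters
    ----------
    rotation_total : float
        Total rotation in degrees (e.g. 360).
    step : float
        Angular step between acquisition positions, degrees. Must divide
        ``rotation_total``.
    frames_per_step : int
        Number of 2D frames averaged/acquired at each angular position.
    magnification : float
        Geometric magnification (source-detector / source-object distance).
    detector_pitch : float
        Detector pixel pitch in µm.
    """

    rotation_total: float = 360.0
    step: float = 0.75
    frames_per_step: int = 3
    magnification: float = 11.5
    detector_pitch: float = 50.0

    def __post_init__(self) -> None:
        if not self.rotation_total > 0:
            raise ValueError("rotation_total must be > 0")
        if not self.step > 0:
            raise ValueError("step must be > 0")
        if self.frames_per_step < 1:
            raise ValueError("frames_per_step must be >= 1")
        if not self.magnification > 0:
            raise ValueError("magnification must be > 0")
        if not self.detector_pitch > 0:
            raise ValueError("detector_pitch must be > 0")


def projection_count(geometry: AcquisitionGeometry) -> int:
    """Number of 2D projections acquired in one scan.

    ``(rotation_total / step) * frames_per_step``; the step must divide the
    total rotation evenly.
    """
    n_steps = geometry.rotation_total / geometry.step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"step {geometry.step} does not divide rotation {geometry.rotation_total}"
        )
    return int(round(n_steps)) * geometry.frames_per_step


def nominal_voxel_size(geometry: AcquisitionGeometry) -> float:
    """Nominal reconstructed voxel size in µm: detector pitch / magnification.

    Rounded to 2 decimals for reporting, matching scanner protocol tables.
    """
    return round(geometry.detector_pitch / geometry.magnification, 2)


CONTACT_MODES = ("full", "none", "sector", "trabecular")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic implant-in-bone volume.

    The implant is a truncated cone on the z axis: maximum diameter at the
    top, tapering downwards at ``implant_taper_angle`` (an implant pressed
    tip-first into a drilled defect). Defaults mirror a small conical test
    implant: 3 mm maximum diameter, 3 mm length.

    Contact modes
    -------------
    full / none
        Bone everywhere on the lateral shell, or a marrow gap everywhere.
    sector
        Bone touches the shell only within an angular wedge covering
        ``contact_fraction`` of the circumference; elsewhere a marrow gap of
        ``gap_width`` µm (at least 3 voxels) separates shell and bone.
    trabecular
        Bone is a smoothed Gaussian random field thresholded to
        ``bone_volume_fraction``, with correlation length
        ``correlation_length`` µm — a controllable trabecular stand-in.
    """

    implant_max_diameter: float = 3000.0
    implant_length: float = 3000.0
    implant_taper_angle: float = 10.0  # degrees; tip radius must stay > 0
    voxel_size: float = 25.0
    contact_mode: str = "sector"
    contact_fraction: float = 0.5
    bone_volume_fraction: float = 0.35
    correlation_length: float = 150.0
    grey_means: tuple[float, float, float] = (40.0, 120.0, 220.0)
    noise_sigma: float = 8.0
    blur_sigma: float = 25.0  # µm
    halo_amplitude: float = 30.0
    halo_decay: float = 100.0  # µm
    gap_width: float = 150.0  # µm, marrow gap in sector/none modes
    exposed_top: bool = False
    exposed_fraction: float = 1.0 / 3.0  # top part of implant outside bone
    margin: float = 300.0  # µm of bone beyond the gap, and axial padding
    air_border: float = 150.0  # µm of air at the volume border (around the specimen)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        bg, bone, imp = self.grey_means
        if not (bg < bone < imp):
            raise ValueError("grey_means must be strictly ordered background < bone < implant")
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must be in [0, 1]")
        if self.contact_mode not in CONTACT_MODES:
            raise ValueError(f"contact_mode must be one of {CONTACT_MODES}")
        if self.implant_max_diameter / self.voxel_size < 20:
            raise ValueError(
                "voxel_size too coarse: implant diameter must span >= 20 voxels "
                f"(got {self.implant_max_diameter / self.voxel_size:.1f})"
            )
        tip_r = self.implant_max_diameter / 2 - self.implant_length * math.tan(
            math.radians(self.implant_taper_angle)
        )
        if tip_r <= 0:
            raise ValueError("taper angle too steep: implant tip radius would be <= 0")
        if not 0.0 < self.bone_volume_fraction < 1.0:
            raise ValueError("bone_volume_fraction must be in (0, 1)")


def _implant_radius_um(spec: PhantomSpec, z_from_top: np.ndarray) -> np.ndarray:
    """Cone radius (µm) at a distance ``z_from_top`` µm below the top face."""
    return spec.implant_max_diameter / 2 - z_from_top * math.tan(
        math.radians(spec.implant_taper_angle)
    )


def generate_phantom(spec: PhantomSpec) -> tuple[GreyVolume, LabelVolume, float]:
    """Build the phantom.

    Returns ``(grey, labels, true_contact_fraction)``. The true contact
    fraction is measured on the clean label grid — implant lateral-shell
    faces adjacent to bone over all lateral-shell faces — *before* any halo,
    blur or noise, so it is the geometric ground truth the measurement
    pipeline is judged against.  Fully reproducible from ``rng_seed``.
    """
    s = spec.voxel_size
    gap = max(spec.gap_width, 3 * s)  # marrow gap never thinner than 3 voxels
    r_max = spec.implant_max_diameter / 2

    # lateral half-extent: implant + gap + bone margin
    half_xy = r_max + gap + spec.margin
    n_xy = int(math.ceil(2 * half_xy / s))
    z_pad = spec.margin
    height = spec.implant_length + 2 * z_pad
    n_z = int(math.ceil(height / s))
    if n_xy < 4 or n_z < 4:
        raise ValueError("implant larger than representable volume")

    # voxel-centre coordinates, µm
    zc = (np.arange(n_z) + 0.5) * s
    yc = (np.arange(n_xy) + 0.5) * s - half_xy
    xc = (np.arange(n_xy) + 0.5) * s - half_xy
    Z = zc[:, None, None]
    Y = yc[None, :, None]
    X = xc[None, None, :]

    z_top = z_pad + spec.implant_length  # top face of the implant
    z_bot = z_pad
    in_z = (Z >= z_bot) & (Z < z_top)
    z_from_top = np.clip(z_top - Z, 0.0, spec.implant_length)
    r_at_z = _implant_radius_um(spec, z_from_top)
    R = np.sqrt(Y**2 + X**2)
    implant = in_z & (R <= r_at_z)
    if not implant.any():
        raise ValueError("implant larger than volume or degenerate geometry")

    rng = np.random.default_rng(spec.rng_seed)
    labels = np.zeros((n_z, n_xy, n_xy), dtype=np.uint8)
    labels[implant] = IMPLANT

    if spec.contact_mode in ("full", "none", "sector"):
        if spec.contact_mode == "full":
            f = 1.0
        elif spec.contact_mode == "none":
            f = 0.0
        else:
            f = spec.contact_fraction
        theta = np.mod(np.arctan2(Y, X), 2 * math.pi)
        in_wedge = theta < 2 * math.pi * f
        in_gap = (
            ~implant
            & in_z
            & (R <= r_at_z + gap)
            & ~np.broadcast_to(in_wedge, implant.shape)
        )
        bone = ~implant & ~in_gap
    else:  # trabecular
        field3 = rng.standard_normal((n_z, n_xy, n_xy))
        sigma_vox = spec.correlation_length / s
        field3 = ndimage.gaussian_filter(field3, sigma_vox)
        thresh = np.quantile(field3, 1.0 - spec.bone_volume_fraction)
        bone = (field3 > thresh) & ~implant

    if spec.exposed_top:
        bone_top = z_top - spec.exposed_fraction * spec.implant_length
        bone = bone & np.broadcast_to(Z < bone_top, bone.shape)

    if spec.air_border > 0:  # air surrounds the specimen in any real scan
        b = int(round(spec.air_border / s))
        if b > 0:
            border = np.ones((n_z, n_xy, n_xy), dtype=bool)
            border[b:-b, b:-b, b:-b] = False
            bone = bone & ~border

    labels[np.broadcast_to(bone, labels.shape) & (labels == BACKGROUND)] = BONE

    label_vol = LabelVolume(labels, spacing=s)
    true_fraction = shell_contact_fraction(label_vol)

    # grey volume: class means + halo, then blur, then noise
    means = np.asarray(spec.grey_means, dtype=np.float64)
    grey = means[np.minimum(labels, 2).astype(np.intp)]
    if spec.halo_amplitude > 0:
        dist_vox = ndimage.distance_transform_edt(~implant)
        outside = ~implant
        grey[outside] += spec.halo_amplitude * np.exp(
            -dist_vox[outside] * s / spec.halo_decay
        )
    if spec.blur_sigma > 0:
        grey = ndimage.gaussian_filter(grey, spec.blur_sigma / s)
    if spec.noise_sigma > 0:
        grey = grey + rng.normal(0.0, spec.noise_sigma, size=grey.shape)

    return GreyVolume(grey, spacing=s), label_vol, true_fraction


def shell_contact_fraction(labels: LabelVolume) -> float:
    """Fraction of the implant's lateral-shell faces adjacent to bone.

    Counts 6-neighbour label adjacencies on the grid; end-cap faces at the
    implant's extreme z slices are not part of the shell.
    """
    from .surface_bic import classify_shell, extract_boundary_faces

    shell = classify_shell(extract_boundary_faces(labels, IMPLANT), labels)
    if len(shell) == 0:
        raise ValueError("implant has no lateral shell faces")
    return float(np.mean(shell.other_label == BONE))
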