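"""In-memory containers for reconstructed grey-value volumes and material label maps.

Arrays follow the numpy convention ``(z, y, x)`` with the implant axis along
``z``.  All linear dimensions are micrometres; spacing is isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Material labels.  ``BACKGROUND`` covers both air and marrow space — the
#: segmentation cannot tell them apart, and neither counts as bone contact.
BACKGROUND = 0
BONE = 1
IMPLANT = 2
EXCLUDED = 3

VALID_LABELS = (BACKGROUND, BONE, IMPLANT, EXCLUDED)


@dataclass
class GreyVolume:
    """A 3D scalar grid with isotropic voxel spacing in µm."""

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("grey volume contains non-finite values")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "GreyVolume":
        return GreyVolume(self.data.copy(), self.spacing, self.origin)


@dataclass
class LabelVolume:
    """A 3D material map: 0=background/marrow, 1=bone, 2=implant, 3=excluded."""

    data: np.ndarray
    spacing: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must have an integer dtype")
        if not self.spacing > 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        bad = np.setdiff1d(np.unique(self.data), VALID_LABELS)
        if bad.size:
            raise ValueError(f"invalid label values {bad.tolist()}; allowed: {VALID_LABELS}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.spacing, self.origin)
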