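"""Core in-memory containers shared across the pipeline.

All images are row-major numpy arrays.  Enface-type maps carry their own
geometry (position of the optic-nerve-head centre and the physical pixel
pitch) so that millimetre-defined operations such as the 2-6 mm annulus can
be evaluated on maps of any resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "OCTVolume",
    "TextureEnfaceMap",
    "ThicknessMap",
    "EyeRecord",
    "ReconErrorFeature",
    "ROIMap",
    "GLSResult",
]


@dataclass
class OCTVolume:
    """A raster OCT scan: ``intensities[b_scan, a_scan, depth]`` plus the
    inner-limiting-membrane surface ``ilm[b_scan, a_scan]`` in depth pixels.

    ``axial_res_um`` is the axial sampling pitch (micrometres per depth
    pixel); ``mm_extent`` the lateral field of view (square, in mm).
    """

    intensities: np.ndarray
    ilm: np.ndarray
    axial_res_um: float = 2.6
    mm_extent: float = 6.0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.ilm = np.asarray(self.ilm, dtype=np.intp)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D [b_scan, a_scan, depth] grid")
        if self.ilm.shape != self.intensities.shape[:2]:
            raise ValueError("ilm surface shape must match the en-face grid")
        if self.axial_res_um <= 0:
            raise ValueError("axial_res_um must be positive")
        n_depth = self.intensities.shape[2]
        if (self.ilm < 0).any() or (self.ilm >= n_depth).any():
            raise ValueError("ilm indices out of depth range")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class _GeoMap:
    values: np.ndarray
    onh_center: tuple[float, float]  # (row, col), pixels
    mm_per_px: tuple[float, float]  # (row, col) pitch

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2D")
        if not np.isfinite(self.values).all():
            raise ValueError("map values must be finite")
        if any(s <= 0 for s in self.mm_per_px):
            raise ValueError("mm_per_px must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class TextureEnfaceMap(_GeoMap):
    """Frontal texture-intensity map in [0, 1]."""


@dataclass
class ThicknessMap(_GeoMap):
    """Frontal RNFL thickness map in micrometres (non-negative)."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if (self.values < 0).any():
            raise ValueError("thickness values must be non-negative")


@dataclass
class EyeRecord:
    """One row of the eye manifest."""

    patient_id: str
    eye_id: str
    laterality: str  # OD | OS
    diagnosis: str  # healthy | glaucoma
    age: float
    axial_length: float
    quality: float
    image_path: str = ""

    def __post_init__(self) -> None:
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.diagnosis not in ("healthy", "glaucoma"):
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")
        if self.axial_length <= 0:
            raise ValueError("axial_length must be positive")


@dataclass
class ReconErrorFeature:
    """Per-pixel reconstruction-error evidence.

    ``e_healthy`` is the squared-residual map under the healthy-trained
    autoencoder; ``e_glaucoma`` the same under the glaucoma-trained one
    (``None`` for the single-autoencoder model).
    """

    e_healthy: np.ndarray
    e_glaucoma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.e_healthy = np.asarray(self.e_healthy, dtype=np.float64)
        if self.e_healthy.ndim != 2:
            raise ValueError("error maps must be 2D")
        if (self.e_healthy < 0).any():
            raise ValueError("error maps must be non-negative")
        if self.e_glaucoma is not None:
            self.e_glaucoma = np.asarray(self.e_glaucoma, dtype=np.float64)
            if self.e_glaucoma.shape != self.e_healthy.shape:
                raise ValueError("error map shapes must match")
            if (self.e_glaucoma < 0).any():
                raise ValueError("error maps must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.e_healthy.shape

    def stack(self, mode: str = "dual") -> np.ndarray:
        """Pixel feature matrix (n_pixels, n_channels)."""
        if mode == "dual":
            if self.e_glaucoma is None:
                raise ValueError("dual mode requires both error channels")
            return np.column_stack([self.e_healthy.ravel(), self.e_glaucoma.ravel()])
        if mode == "single":
            return self.e_healthy.ravel()[:, None]
        raise ValueError(f"unknown mode {mode!r}")


HEALTHY_LIKE = 0
GLAUCOMA_LIKE = 1


@dataclass
class ROIMap:
    """Binary segmentation: 1 marks the glaucoma-like region."""

    labels: np.ndarray
    energy: float
    converged: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2D")
        if not np.isfinite(self.energy):
            raise ValueError("energy must be finite")

    @property
    def mask(self) -> np.ndarray:
        return self.labels == GLAUCOMA_LIKE

    @property
    def roi_fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class GLSResult:
    """ROI-Based Glaucoma Score and its components.

    gls = 0.5 * roi_fraction + 0.5 * intensity_term, with
    intensity_term = clamp(1 - mean_roi / mean_healthy_ref, 0, 1).
    An empty ROI scores 0 by definition.
    """

    gls: float
    roi_fraction: float
    mean_roi: float
    mean_healthy_ref: float
    intensity_term: float
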