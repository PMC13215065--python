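"""Core domain containers shared across the package.

Coordinate convention (used everywhere): pixel-center coordinates, origin at
the top-left pixel center, x rightward (columns), y downward (rows), 0-based.
Pixel centers sit at integer coordinates. Geometry leaves this module's
consumers in nanometres via ``nm_per_px``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

MITOCHONDRION = "mitochondrion"
ER = "ER"
CRISTAE = "cristae"
CELL = "cell"

ORGANELLE_CLASSES = frozenset({MITOCHONDRION, ER, CRISTAE, CELL})


class MamsQuantError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class CalibratedField:
    """One TEM raster with its nanometre-per-pixel calibration.

    Parameters
    ----------
    image_id : str
        Unique identifier of the image within a cohort.
    patient_id : str
        Identifier linking the image to a clinical record.
    raster : ndarray
        2-D grayscale intensity grid.
    nm_per_px : float
        Physical size of one pixel edge in nanometres; must be positive.
    acquisition_note : str
        Free-text provenance note.
    """

    image_id: str
    patient_id: str
    raster: np.ndarray
    nm_per_px: float
    acquisition_note: str = ""

    def __post_init__(self) -> None:
        if self.nm_per_px <= 0:
            raise ValueError(f"nm_per_px must be > 0, got {self.nm_per_px}")
        r = np.asarray(self.raster)
        if r.ndim != 2 or r.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")
        object.__setattr__(self, "raster", r)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape  # (rows, cols)

    @property
    def field_area_nm2(self) -> float:
        h, w = self.raster.shape
        return float(h * w) * self.nm_per_px**2


@dataclass
class OrganelleInstance:
    """One labeled organelle: class, binary footprint and derived contour.

    ``contour`` is the sub-pixel 0.5 iso-level boundary of the footprint as an
    ``(N, 2)`` array of (x, y) pixel coordinates, closed (first == last
    vertex). It is derived automatically when not supplied.
    """

    instance_id: str
    organelle_class: str
    footprint: np.ndarray
    contour: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.organelle_class not in ORGANELLE_CLASSES:
            raise ValueError(
                f"unknown organelle class {self.organelle_class!r}; "
                f"expected one of {sorted(ORGANELLE_CLASSES)}"
            )
        fp = np.asarray(self.footprint).astype(bool)
        if fp.ndim != 2:
            raise ValueError("footprint must be 2-D")
        if not fp.any():
            raise ValueError(
                f"instance {self.instance_id!r} has an empty footprint"
            )
        self.footprint = fp
        if self.contour is None:
            from ._contours import extract_contour

            self.contour = extract_contour(fp)

    @property
    def area_px(self) -> int:
        return int(self.footprint.sum())


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient covariates and the WHO-grade label (1–4, or None)."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    who_grade: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.who_grade is not None and self.who_grade not in (1, 2, 3, 4):
            raise ValueError(f"who_grade must be in 1..4, got {self.who_grade}")


@dataclass
class MitoRecord:
    """Per-mitochondrion measurement row.

    Shape parameters (area, perimeter, circularity, centroid), the
    matrix-to-cristae ratio, and the ER-contact quantities (MAMs positivity
    under the gap criterion, minimum membrane gap, contact length).
    """

    instance_id: str
    image_id: str
    area_nm2: float
    perimeter_nm: float
    circularity: float
    centroid_x_norm: float
    centroid_y_norm: float
    centroid_x_px: float
    centroid_y_px: float
    matrix_to_mrc_ratio: Optional[float] = None
    mam_positive: bool = False
    min_gap_nm: Optional[float] = None
    contact_length_nm: float = 0.0
    sub_resolution: bool = False
    circularity_clamped: bool = False


@dataclass
class FieldMetrics:
    """Per-image scalars: area fraction, density, MAMs-positive percentage."""

    image_id: str
    mito_area_fraction: float
    mito_density_per_100um2: float
    n_mitochondria: int
    mam_positive_percent: Optional[float] = None  # None when no mitochondria
    reference_area_nm2: float = 0.0


@dataclass
class ContactProfile:
    """Distance-to-ER profile sampled along one mitochondrial contour.

    ``arc_nm`` holds cumulative boundary arc positions and ``gap_nm`` the
    bilinearly interpolated distance to the nearest ER foreground at each
    sample. ``min_gap_nm`` is None for a field without ER.
    """

    mito_instance_id: str
    arc_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    gap_nm: np.ndarray = field(default_factory=lambda: np.empty(0))
    min_gap_nm: Optional[float] = None
    contact_length_nm: float = 0.0
    mam_positive: bool = False
    threshold_nm: float = 30.0
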