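"""Per-mitochondrion shape parameters and per-field summary metrics.

Implements the shape block of the eleven ultrastructural parameters: area,
perimeter, circularity (4πA/P²), centroid coordinates, mitochondrial area
fraction (MAF), mitochondrial density, and the matrix-to-cristae (MRC) area
ratio.

Area is foreground pixel count × nm_per_px²; perimeter is the arc length of
the simplified sub-pixel iso-contour × nm_per_px (see ``_contours``);
circularity is clamped to ≤ 1 with a flag when digitization pushes the raw
value above 1. Centroids are exported field-normalized (raw pixel centroids
kept as debug columns) so they remain comparable across magnifications.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from ._contours import simplified_perimeter_px
from .types import (
    CRISTAE,
    MITOCHONDRION,
    CalibratedField,
    FieldMetrics,
    MamsQuantError,
    MitoRecord,
    OrganelleInstance,
)


def instance_shape_metrics(
    instance: OrganelleInstance, field: CalibratedField
) -> MitoRecord:
    """Shape parameters for one mitochondrion (contact fields left unset)."""
    if instance.organelle_class != MITOCHONDRION:
        raise ValueError(
            f"shape metrics are defined for mitochondria, got {instance.organelle_class!r}"
        )
    s = field.nm_per_px
    h, w = field.raster.shape
    area_px = instance.area_px
    area_nm2 = area_px * s**2

    perim_px, sub_res = simplified_perimeter_px(instance.footprint, instance.contour)
    perimeter_nm = perim_px * s

    raw_circ = 4.0 * math.pi * area_nm2 / perimeter_nm**2
    clamped = raw_circ > 1.0
    circ = min(raw_circ, 1.0)

    rows, cols = np.nonzero(instance.footprint)
    cx = float(cols.mean())
    cy = float(rows.mean())

    return MitoRecord(
        instance_id=instance.instance_id,
        image_id=field.image_id,
        area_nm2=area_nm2,
        perimeter_nm=perimeter_nm,
        circularity=circ,
        centroid_x_norm=cx / w,
        centroid_y_norm=cy / h,
        centroid_x_px=cx,
        centroid_y_px=cy,
        sub_resolution=sub_res,
        circularity_clamped=clamped,
    )


def field_metrics(
    instances: Sequence[OrganelleInstance],
    field: CalibratedField,
    cell_roi: Optional[OrganelleInstance] = None,
) -> FieldMetrics:
    """Area fraction and density over the reference area.

    The reference area is the cell ROI when provided (the "single-cell"
    reading of density), otherwise the full field. Density is scaled to
    mitochondria per 100 µm².
    """
    s = field.nm_per_px
    if cell_roi is not None:
        ref_area_nm2 = cell_roi.area_px * s**2
    else:
        ref_area_nm2 = field.field_area_nm2
    if ref_area_nm2 <= 0:
        raise MamsQuantError("reference area is zero")

    mitos = [i for i in instances if i.organelle_class == MITOCHONDRION]
    total = sum(i.area_px for i in mitos) * s**2
    return FieldMetrics(
        image_id=field.image_id,
        mito_area_fraction=total / ref_area_nm2,
        mito_density_per_100um2=len(mitos) / ref_area_nm2 * 1e8,
        n_mitochondria=len(mitos),
        mam_positive_percent=None,  # filled once contact profiles exist
        reference_area_nm2=ref_area_nm2,
    )


def matrix_to_mrc_ratio(
    mito: OrganelleInstance, cristae_instances: Sequence[OrganelleInstance]
) -> Optional[float]:
    """Matrix area over cristae area within one mitochondrion.

    Cristae footprints are clipped to the mitochondrion before measuring.
    Returns None when no cristae annotation intersects the mitochondrion;
    raises when the clipped cristae area reaches the mitochondrial area
    (annotation inconsistency).
    """
    if mito.organelle_class != MITOCHONDRION:
        raise ValueError("first argument must be a mitochondrion instance")
    cristae_px = 0
    for cr in cristae_instances:
        if cr.organelle_class != CRISTAE:
            continue
        cristae_px += int((cr.footprint & mito.footprint).sum())
    if cristae_px == 0:
        return None
    mito_px = mito.area_px
    if cristae_px >= mito_px:
        raise MamsQuantError(
            f"cristae area ({cristae_px} px) >= mitochondrial area ({mito_px} px) "
            f"for {mito.instance_id!r}: inconsistent annotation"
        )
    return (mito_px - cristae_px) / cristae_px
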