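"""Reading, writing and validating calibrated images and instance annotations.

Two interchangeable annotation representations are supported:

* **Label rasters** — 16-bit TIFF, 0 = background, each nonzero label one
  instance; a JSON mapping (embedded in the TIFF description or supplied
  separately) assigns labels to organelle classes.
* **Polygon JSON (COCO dialect)** — ``images`` / ``categories`` /
  ``annotations`` with polygon segmentations; holes are honored via the
  even-odd rule; invalid (self-intersecting) polygons are repaired by
  buffering to validity, counted in the load report.

``bind_cohort`` joins fields and instances to the per-patient clinical table
and exposes patient-level grouping for leakage-free splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from ._raster import rasterize_rings_evenodd
from .types import (
    ORGANELLE_CLASSES,
    CalibratedField,
    ClinicalRecord,
    MamsQuantError,
    OrganelleInstance,
)


class MaskIOError(MamsQuantError):
    """Raised on malformed or inconsistent annotation input."""


@dataclass
class LoadReport:
    """Counts of repairs/warnings accumulated while loading annotations."""

    repaired_polygons: int = 0
    warnings: list[str] = dc_field(default_factory=list)


# --------------------------------------------------------------------------
# Label rasters


def write_label_raster(instances: Sequence[OrganelleInstance], path: Union[str, Path]) -> None:
    """Write instances as a 16-bit label TIFF, one page per organelle class.

    Classes may legitimately overlap (cristae lie inside mitochondria), so
    each class gets its own label plane; instances within a class must be
    disjoint. Label values are globally unique across pages, and the page
    order plus the label → (class, instance id) map live in the description
    of the first page.
    """
    if not instances:
        shape = (1, 1)
    else:
        shape = instances[0].footprint.shape
    classes = []
    for inst in instances:
        if inst.organelle_class not in classes:
            classes.append(inst.organelle_class)
    planes = {cls: np.zeros(shape, dtype=np.uint16) for cls in classes}
    mapping: dict[str, dict[str, str]] = {}
    k = 0
    for inst in instances:
        if inst.footprint.shape != shape:
            raise MaskIOError("all instances must share one raster grid")
        plane = planes[inst.organelle_class]
        if (plane[inst.footprint] != 0).any():
            raise MaskIOError(
                f"instance {inst.instance_id!r} overlaps another "
                f"{inst.organelle_class} instance"
            )
        k += 1
        plane[inst.footprint] = k
        mapping[str(k)] = {
            "class": inst.organelle_class,
            "instance_id": inst.instance_id,
        }
    stack = (
        np.stack([planes[c] for c in classes])
        if classes
        else np.zeros((1, *shape), dtype=np.uint16)
    )
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        description=json.dumps({"labels": mapping, "pages": classes}),
    )


def load_label_raster(
    path: Union[str, Path],
    class_partition: Optional[Mapping[str, Iterable[int]]] = None,
) -> list[OrganelleInstance]:
    """Load instances from a label raster.

    ``class_partition`` maps class name → iterable of label values; when
    None, the label map embedded in the TIFF description is used. Labels
    present in the raster but absent from the mapping are a hard error.
    """
    with tifffile.TiffFile(path) as tif:
        labels = tif.asarray()
        desc = tif.pages[0].description
    if not np.issubdtype(labels.dtype, np.integer):
        raise MaskIOError("label raster must be integer-valued")
    if labels.ndim == 2:
        labels = labels[None]
    elif labels.ndim != 3:
        raise MaskIOError("label raster must be 2-D or a stack of 2-D planes")

    label_to_class: dict[int, str] = {}
    label_to_id: dict[int, str] = {}
    if class_partition is not None:
        for cls, ids in class_partition.items():
            if cls not in ORGANELLE_CLASSES:
                raise MaskIOError(f"unknown organelle class {cls!r}")
            for v in ids:
                label_to_class[int(v)] = cls
    elif desc:
        try:
            mapping = json.loads(desc)["labels"]
        except (json.JSONDecodeError, KeyError) as exc:
            raise MaskIOError("TIFF description lacks a label map; "
                              "pass class_partition explicitly") from exc
        for v, meta in mapping.items():
            label_to_class[int(v)] = meta["class"]
            label_to_id[int(v)] = meta.get("instance_id", f"label_{v}")
    else:
        raise MaskIOError("no class partition supplied and none embedded in the TIFF")

    present = sorted(int(v) for v in np.unique(labels) if v != 0)
    orphans = [v for v in present if v not in label_to_class]
    if orphans:
        raise MaskIOError(f"labels present in raster but absent from metadata: {orphans}")

    out = []
    for v in present:
        footprint = (labels == v).any(axis=0)
        out.append(
            OrganelleInstance(
                instance_id=label_to_id.get(v, f"label_{v}"),
                organelle_class=label_to_class[v],
                footprint=footprint,
            )
        )
    return out


# --------------------------------------------------------------------------
# Polygon JSON (COCO dialect)

_CATEGORY_IDS = {"mitochondrion": 1, "ER": 2, "cristae": 3, "cell": 4}


def _mask_to_rings(footprint: np.ndarray) -> list[list[float]]:
    """All 0.5 iso-contours of a footprint as flat [x1, y1, x2, y2, ...] rings."""
    padded = np.pad(footprint, 1).astype(float)
    rings = []
    for c in measure.find_contours(padded, 0.5):
        xy = (c - 1.0)[:, ::-1]
        rings.append(np.round(xy, 3).ravel().tolist())
    return rings


def write_polygon_annotations(
    fields: Sequence[CalibratedField],
    instances_by_image: Mapping[str, Sequence[OrganelleInstance]],
    path: Union[str, Path],
) -> None:
    """Export fields + instances as COCO-dialect polygon JSON."""
    images = []
    annotations = []
    ann_id = 1
    for k, fld in enumerate(fields, start=1):
        h, w = fld.raster.shape
        images.append(
            dict(
                id=k,
                file_name=f"{fld.image_id}.tiff",
                image_id=fld.image_id,
                patient_id=fld.patient_id,
                width=w,
                height=h,
                nm_per_px=fld.nm_per_px,
            )
        )
        for inst in instances_by_image.get(fld.image_id, []):
            annotations.append(
                dict(
                    id=ann_id,
                    image_id=k,
                    category_id=_CATEGORY_IDS[inst.organelle_class],
                    instance_id=inst.instance_id,
                    segmentation=_mask_to_rings(inst.footprint),
                    area=int(inst.area_px),
                    iscrowd=0,
                )
            )
            ann_id += 1
    doc = dict(
        images=images,
        categories=[dict(id=v, name=k) for k, v in _CATEGORY_IDS.items()],
        annotations=annotations,
    )
    Path(path).write_text(json.dumps(doc))


def _repair_ring(xy: np.ndarray, report: LoadReport) -> list[np.ndarray]:
    """Return valid ring(s) for one polygon ring, repairing self-intersections."""
    from shapely.geometry import MultiPolygon, Polygon

    poly = Polygon(xy)
    if poly.is_valid:
        return [xy]
    fixed = poly.buffer(0)
    if fixed.is_empty:
        raise MaskIOError("unrepairable self-intersecting polygon")
    report.repaired_polygons += 1
    geoms = fixed.geoms if isinstance(fixed, MultiPolygon) else [fixed]
    return [np.asarray(g.exterior.coords) for g in geoms]


def load_polygon_annotations(
    path: Union[str, Path],
) -> tuple[dict[str, list[OrganelleInstance]], LoadReport]:
    """Load COCO-dialect polygon annotations, rasterized per image grid.

    Returns ``(instances_by_image_id, report)``. Holes are honored via the
    even-odd rule (XOR of ring interiors).
    """
    doc = json.loads(Path(path).read_text())
    report = LoadReport()
    cat_names = {c["id"]: c["name"] for c in doc.get("categories", [])}
    img_meta = {}
    for im in doc["images"]:
        img_meta[im["id"]] = im
    out: dict[str, list[OrganelleInstance]] = {
        im.get("image_id", str(im["id"])): [] for im in doc["images"]
    }
    for ann in doc["annotations"]:
        im = img_meta[ann["image_id"]]
        shape = (im["height"], im["width"])
        rings = []
        for flat in ann["segmentation"]:
            xy = np.asarray(flat, dtype=float).reshape(-1, 2)
            if len(xy) < 3:
                report.warnings.append(f"annotation {ann['id']}: degenerate ring skipped")
                continue
            rings.extend(_repair_ring(xy, report))
        mask = rasterize_rings_evenodd(rings, shape)
        if not mask.any():
            report.warnings.append(f"annotation {ann['id']}: empty after rasterization, skipped")
            continue
        cls = cat_names.get(ann["category_id"])
        if cls not in ORGANELLE_CLASSES:
            raise MaskIOError(f"annotation {ann['id']}: unknown category {cls!r}")
        iid = ann.get("instance_id", f"ann_{ann['id']}")
        out[im.get("image_id", str(im["id"]))].append(OrganelleInstance(iid, cls, mask))
    for image_id, insts in out.items():
        _check_class_disjoint(insts, image_id)
    return out, report


def _check_class_disjoint(instances: Sequence[OrganelleInstance], image_id: str) -> None:
    by_class: dict[str, np.ndarray] = {}
    for inst in instances:
        acc = by_class.setdefault(inst.organelle_class, np.zeros(inst.footprint.shape, np.uint8))
        acc += inst.footprint
    for cls, acc in by_class.items():
        if (acc > 1).any():
            raise MaskIOError(
                f"image {image_id!r}: overlapping {cls} instances ({int((acc > 1).sum())} px)"
            )


# --------------------------------------------------------------------------
# Field I/O and cohort binding


def write_field_tiff(field: CalibratedField, path: Union[str, Path]) -> None:
    meta = dict(
        image_id=field.image_id,
        patient_id=field.patient_id,
        nm_per_px=field.nm_per_px,
        acquisition_note=field.acquisition_note,
    )
    tifffile.imwrite(path, field.raster, description=json.dumps(meta))


def read_field_tiff(
    path: Union[str, Path],
    nm_per_px: Optional[float] = None,
    image_id: Optional[str] = None,
    patient_id: str = "",
) -> CalibratedField:
    with tifffile.TiffFile(path) as tif:
        raster = tif.asarray()
        desc = tif.pages[0].description
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
    scale = nm_per_px if nm_per_px is not None else meta.get("nm_per_px")
    if scale is None:
        raise MaskIOError(f"{path}: no nm_per_px calibration supplied or embedded")
    return CalibratedField(
        image_id=image_id or meta.get("image_id", Path(path).stem),
        patient_id=patient_id or meta.get("patient_id", ""),
        raster=raster,
        nm_per_px=float(scale),
        acquisition_note=meta.get("acquisition_note", ""),
    )


@dataclass
class Cohort:
    """Bound index of fields, instances and clinical records.

    Supports patient-level grouping: ``images_of`` and ``patients`` are the
    primitives leakage-free splitting builds on.
    """

    fields: dict[str, CalibratedField]
    instances: dict[str, list[OrganelleInstance]]
    clinical: dict[str, ClinicalRecord]
    warnings: list[str] = dc_field(default_factory=list)

    @property
    def patients(self) -> list[str]:
        return sorted({f.patient_id for f in self.fields.values()})

    def images_of(self, patient_id: str) -> list[str]:
        return sorted(
            iid for iid, f in self.fields.items() if f.patient_id == patient_id
        )

    def record_of(self, image_id: str) -> ClinicalRecord:
        return self.clinical[self.fields[image_id].patient_id]


def read_clinical_csv(path: Union[str, Path]) -> dict[str, ClinicalRecord]:
    df = pd.read_csv(path)
    return clinical_from_frame(df)


def clinical_from_frame(df: pd.DataFrame) -> dict[str, ClinicalRecord]:
    required = {"patient_id", "age", "sex", "who_grade"}
    missing = required - set(df.columns)
    if missing:
        raise MaskIOError(f"clinical table missing columns: {sorted(missing)}")
    out: dict[str, ClinicalRecord] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in out:
            raise MaskIOError(f"duplicate patient_id {pid!r} in clinical table")
        grade = row["who_grade"]
        grade = None if pd.isna(grade) else int(grade)
        out[pid] = ClinicalRecord(pid, float(row["age"]), str(row["sex"]), grade)
    return out


def bind_cohort(
    fields: Sequence[CalibratedField],
    instances_by_image: Mapping[str, Sequence[OrganelleInstance]],
    clinical: Union[pd.DataFrame, Mapping[str, ClinicalRecord], str, Path],
) -> Cohort:
    """Join fields + instances + clinical table into a validated cohort.

    Errors: duplicate image ids; an image whose patient is absent from the
    clinical table. A patient with no images is only a warning.
    """
    if isinstance(clinical, (str, Path)):
        records = read_clinical_csv(clinical)
    elif isinstance(clinical, pd.DataFrame):
        records = clinical_from_frame(clinical)
    else:
        records = dict(clinical)

    field_map: dict[str, CalibratedField] = {}
    for f in fields:
        if f.image_id in field_map:
            raise MaskIOError(f"duplicate image_id {f.image_id!r}")
        if f.patient_id not in records:
            raise MaskIOError(
                f"image {f.image_id!r} references unknown patient {f.patient_id!r}"
            )
        field_map[f.image_id] = f

    warnings = []
    with_images = {f.patient_id for f in fields}
    for pid in records:
        if pid not in with_images:
            warnings.append(f"patient {pid!r} has no images")

    inst_map = {iid: list(instances_by_image.get(iid, [])) for iid in field_map}
    for iid, insts in inst_map.items():
        _check_class_disjoint(insts, iid)
    return Cohort(field_map, inst_map, records, warnings)
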