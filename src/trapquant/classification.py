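"""Threshold classification of objects as NETs and summary statistics.

All four criteria are "increase" criteria: an enabled criterion passes iff
the feature value is >= its threshold (inclusive, so interactive and batch
runs agree bit-for-bit at the boundary), and an object is a NET iff every
enabled criterion passes. Disabled criteria are recorded as passing so the
conjunction is unaffected, with the enabled flag carried into the output
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ClassifierConfig, FeatureName
from .features import FeatureVector
from .segmentation import SegmentedObject


@dataclass
class Prediction:
    object_id: str
    per_criterion: dict[str, bool]
    enabled: dict[str, bool]
    is_net: bool


@dataclass
class SummaryStats:
    n_objects: int
    n_nets: int
    pct_nets: float
    pct_net_area: float
    empty: bool = False  # no objects: percentages reported as 0 with this flag


def classify(fv: FeatureVector, cfg: ClassifierConfig, object_id: str = "") -> Prediction:
    per: dict[str, bool] = {}
    enabled: dict[str, bool] = {}
    is_net = True
    for crit in cfg.criteria:
        name = crit.feature.value
        enabled[name] = crit.enabled
        passes = True if not crit.enabled else fv.value(name) >= crit.threshold
        per[name] = passes
        if crit.enabled and not passes:
            is_net = False
    return Prediction(object_id=object_id, per_criterion=per, enabled=enabled, is_net=is_net)


def classify_objects(
    features: dict[str, FeatureVector], cfg: ClassifierConfig
) -> dict[str, Prediction]:
    return {oid: classify(fv, cfg, object_id=oid) for oid, fv in sorted(features.items())}


def _object_area(obj: SegmentedObject) -> int:
    return int(obj.union_mask.sum())


def summarize(
    objects: list[SegmentedObject], predictions: dict[str, Prediction]
) -> SummaryStats:
    """Dataset- or field-level counts: objects, NETs, % NETs, % NET area.

    Object area is the pixel count of the union of the DNA and protein masks;
    ``pct_net_area`` is the share of total object area belonging to
    NET-classified objects.
    """
    n = len(objects)
    if n == 0:
        return SummaryStats(0, 0, 0.0, 0.0, empty=True)
    areas = np.array([_object_area(o) for o in objects], dtype=np.int64)
    is_net = np.array([predictions[o.object_id].is_net for o in objects], dtype=bool)
    n_nets = int(is_net.sum())
    total = int(areas.sum())
    net_area = int(areas[is_net].sum())
    return SummaryStats(
        n_objects=n,
        n_nets=n_nets,
        pct_nets=100.0 * n_nets / n,
        pct_net_area=100.0 * net_area / total if total else 0.0,
    )


def summarize_fields(
    objects: list[SegmentedObject], predictions: dict[str, Prediction]
) -> dict[str, SummaryStats]:
    by_field: dict[str, list[SegmentedObject]] = {}
    for obj in objects:
        by_field.setdefault(obj.field_id, []).append(obj)
    return {fid: summarize(objs, predictions) for fid, objs in sorted(by_field.items())}


def threshold_sensitivity(
    features: dict[str, FeatureVector],
    cfg: ClassifierConfig,
    feature: FeatureName | str,
    grid: list[float],
) -> pd.DataFrame:
    """NET counts along an ascending grid of thresholds for one feature.

    Because every criterion is an inclusive >= test joined by conjunction,
    the count is non-increasing along the grid.
    """
    feature = FeatureName(feature)
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be sorted ascending")
    rows = []
    for t in grid:
        crit = cfg.criterion(feature).model_copy(update={"threshold": float(t)})
        cfg_t = cfg.with_criteria(
            [crit if c.feature == feature else c for c in cfg.criteria]
        )
        preds = classify_objects(features, cfg_t)
        rows.append({"threshold": float(t), "n_nets": sum(p.is_net for p in preds.values())})
    return pd.DataFrame(rows, columns=["threshold", "n_nets"])


def build_object_records(
    dataset: str,
    objects: list[SegmentedObject],
    features: dict[str, FeatureVector],
    predictions: dict[str, Prediction],
) -> list[dict[str, object]]:
    """Rows for :func:`trapquant.io_formats.write_object_table`."""
    records = []
    for obj in objects:
        fv = features[obj.object_id]
        pred = predictions[obj.object_id]
        r0, r1, c0, c1 = obj.bbox
        cy, cx = obj.centroid
        rec: dict[str, object] = {
            "dataset": dataset,
            "field_id": obj.field_id,
            "object_id": obj.object_id,
            "centroid_row": cy,
            "centroid_col": cx,
            "bbox_r0": r0,
            "bbox_r1": r1,
            "bbox_c0": c0,
            "bbox_c1": c1,
            "protein_area_px": fv.protein_area,
            "dna_area_px": fv.dna_area,
            "area_ratio": fv.area_ratio,
            "dna_deformation": fv.dna_deformation,
            "dna_radius_std_px": fv.dna_radius_std,
            "dna_radius_cv": fv.dna_radius_cv,
            "is_net": pred.is_net,
        }
        for name in [f.value for f in FeatureName]:
            rec[f"pass_{name}"] = pred.per_criterion[name]
            rec[f"enabled_{name}"] = pred.enabled[name]
        records.append(rec)
    return records
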