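"""Annotation sampling, confusion-matrix validation, automatic thresholds.

Human annotators assign one of six labels to randomly sampled objects. Only
two labels enter the confusion matrix: an object labeled NET is a true
positive if predicted NET and a false negative otherwise, and an object
labeled NEUTROPHIL is a false positive if predicted NET and a true negative
otherwise. Accuracy is (TP+TN)/(TP+FN+TN+FP) and the false discovery rate is
FP/(TP+FP) (0 when there are no positive predictions). The remaining labels
are excluded from ACC/FDR but still reported via per-label NET-prediction
rates, since e.g. intact NETotic cells are biologically interesting even
though they are deliberately not counted as NETs.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import CriterionSpec, FeatureName
from .errors import (
    FittingError,
    ImageReadError,
    MissingPredictionError,
    SampleSizeError,
)
from .features import FeatureVector, extract_crop
from .classification import Prediction
from .io_formats import FieldOfView
from .segmentation import SegmentedObject


class AnnotationLabel(str, Enum):
    NET = "NET"
    INTACT_NETOTIC = "Intact NETotic"
    MULTIPLE_INTACT_CELLS = "Multiple intact cells"
    NEUTROPHIL = "Neutrophil"
    NOT_A_CELL = "Not a cell"
    UNKNOWN = "Unknown"


@dataclass(frozen=True)
class Annotation:
    object_id: str
    dataset: str
    annotator_id: str
    label: AnnotationLabel
    timestamp: str = ""  # ISO-8601


@dataclass
class ObjectRef:
    dataset: str
    object_id: str


@dataclass
class SampleResult:
    items: list[ObjectRef]
    seed: int


@dataclass
class ValidationReport:
    tp: int
    fn: int
    fp: int
    tn: int
    acc: float  # NaN when no NET/NEUTROPHIL annotations are present
    fdr: float
    per_label_net_rate: dict[str, float]
    n_excluded: int
    empty: bool = False


def sample_objects(
    pools: Mapping[str, Sequence[str]],
    n: int,
    seed: int,
    per_dataset_quota: Mapping[str, int] | None = None,
) -> SampleResult:
    """Uniform sample without replacement over pooled objects, or per-quota.

    ``pools`` maps dataset name to its object ids. The presentation order is
    randomized and the whole draw is reproducible from ``seed`` (NumPy
    PCG64 generator).
    """
    rng = np.random.default_rng(seed)
    pool = [ObjectRef(ds, oid) for ds in sorted(pools) for oid in sorted(pools[ds])]
    if per_dataset_quota is None:
        if n > len(pool):
            raise SampleSizeError(f"requested {n} objects but only {len(pool)} available")
        idx = rng.permutation(len(pool))[:n]
        return SampleResult(items=[pool[i] for i in idx], seed=seed)

    if sum(per_dataset_quota.values()) != n:
        raise SampleSizeError("per-dataset quotas must sum to n")
    chosen: list[ObjectRef] = []
    for ds in sorted(per_dataset_quota):
        ids = sorted(pools.get(ds, []))
        q = per_dataset_quota[ds]
        if q > len(ids):
            raise SampleSizeError(f"quota {q} for dataset {ds!r} exceeds its {len(ids)} objects")
        idx = rng.permutation(len(ids))[:q]
        chosen.extend(ObjectRef(ds, ids[i]) for i in idx)
    order = rng.permutation(len(chosen))
    return SampleResult(items=[chosen[i] for i in order], seed=seed)


def validate(
    annotations: Iterable[Annotation], predictions: Mapping[str, Prediction | bool]
) -> ValidationReport:
    """Confusion counts, accuracy and FDR for a set of annotations.

    Annotations from multiple annotators are pooled as given; to validate
    per annotator, filter the annotation list before calling (see
    :func:`validate_per_annotator`).
    """
    tp = fn = fp = tn = excluded = 0
    label_counts: dict[str, list[int]] = {}  # label -> [n, n predicted NET]
    for ann in annotations:
        if ann.object_id not in predictions:
            raise MissingPredictionError(f"no prediction for annotated object {ann.object_id!r}")
        pred = predictions[ann.object_id]
        is_net = pred.is_net if isinstance(pred, Prediction) else bool(pred)
        stats = label_counts.setdefault(ann.label.value, [0, 0])
        stats[0] += 1
        stats[1] += int(is_net)
        if ann.label == AnnotationLabel.NET:
            tp += int(is_net)
            fn += int(not is_net)
        elif ann.label == AnnotationLabel.NEUTROPHIL:
            fp += int(is_net)
            tn += int(not is_net)
        else:
            excluded += 1
    total = tp + fn + tn + fp
    acc = (tp + tn) / total if total else math.nan
    fdr = fp / (tp + fp) if (tp + fp) else 0.0
    rates = {lab: c[1] / c[0] for lab, c in sorted(label_counts.items())}
    return ValidationReport(
        tp=tp, fn=fn, fp=fp, tn=tn, acc=acc, fdr=fdr,
        per_label_net_rate=rates, n_excluded=excluded, empty=(total == 0),
    )


def validate_per_annotator(
    annotations: Sequence[Annotation], predictions: Mapping[str, Prediction | bool]
) -> dict[str, ValidationReport]:
    by: dict[str, list[Annotation]] = {}
    for ann in annotations:
        by.setdefault(ann.annotator_id, []).append(ann)
    return {a: validate(anns, predictions) for a, anns in sorted(by.items())}


# ---------------------------------------------------------------------------
# automatic threshold fitting


@dataclass
class FitResult:
    criteria: list[CriterionSpec]
    accuracy: float
    fdr: float
    n_positive: int
    n_negative: int
    sweeps: int


_FIT_FEATURES = [f.value for f in FeatureName]


def _candidates(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique values plus finite sentinels.

    The low sentinel (min - 1) passes every observed object; the high
    sentinel (max + 1) fails every observed object. Finite sentinels stand in
    for -inf/+inf because configuration thresholds must be finite.
    """
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def _score(pred: np.ndarray, y: np.ndarray, fdr_zero: bool) -> tuple:
    """Objective key (higher is better). ``pred``/``y`` boolean arrays."""
    acc = float((pred == y).mean())
    n_pos = int(pred.sum())
    fp = int((pred & ~y).sum())
    fdr = fp / n_pos if n_pos else 0.0
    if fdr_zero:
        return (1 if fdr == 0.0 else 0, acc)
    return (acc,)


def auto_thresholds(
    annotations: Iterable[Annotation],
    features: Mapping[str, FeatureVector],
    positive_label: AnnotationLabel = AnnotationLabel.NET,
    negative_label: AnnotationLabel = AnnotationLabel.NEUTROPHIL,
    objective: str = "max_accuracy",
    max_sweeps: int = 10,
) -> FitResult:
    """Fit the four criterion thresholds from a labeled annotation set.

    Deterministic block coordinate ascent: candidate thresholds per feature
    are the midpoints between consecutive sorted unique training values
    (plus sentinels); the search starts from the best single-feature
    classifier (all other features at the always-pass sentinel) and then
    sweeps every unordered pair of features, each step solving that pair
    exactly by exhaustive 2-D search given the other thresholds. Ties are
    broken toward higher thresholds. Pairwise (rather than one-at-a-time)
    ascent makes the search exact whenever at most two features carry
    information, and never worse than single-coordinate ascent otherwise.
    Objectives: ``max_accuracy`` or ``max_accuracy_fdr0`` (maximize accuracy
    subject to zero training FDR; always feasible since predicting nothing
    has FDR 0 by convention).
    """
    if objective not in ("max_accuracy", "max_accuracy_fdr0"):
        raise ValueError(f"unknown objective {objective!r}")
    fdr_zero = objective == "max_accuracy_fdr0"

    rows: list[tuple[list[float], bool]] = []
    for ann in annotations:
        if ann.label not in (positive_label, negative_label):
            continue
        fv = features.get(ann.object_id)
        if fv is None:
            raise MissingPredictionError(f"no features for annotated object {ann.object_id!r}")
        rows.append(([fv.value(f) for f in _FIT_FEATURES], ann.label == positive_label))
    if not rows:
        raise FittingError("no annotations with the positive/negative labels")
    x = np.array([r[0] for r in rows], dtype=np.float64)
    y = np.array([r[1] for r in rows], dtype=bool)
    if y.all() or not y.any():
        raise FittingError("both a positive and a negative class are required for fitting")

    n = len(y)
    n_feat = len(_FIT_FEATURES)
    cands = [_candidates(x[:, j]) for j in range(n_feat)]
    # pass_mats[j][i, k] = does object i pass candidate k of feature j
    pass_mats = [x[:, j : j + 1] >= cands[j][None, :] for j in range(n_feat)]
    n_neg = int((~y).sum())

    def key_grid(tp: np.ndarray, fp: np.ndarray) -> np.ndarray:
        """Scalar objective on a grid; higher is better, encoded as a float."""
        acc = (tp + (n_neg - fp)) / n
        if fdr_zero:
            return np.where(fp == 0, 1.0 + acc, acc - 1.0)  # infeasible cells rank below all feasible
        return acc

    # best single-feature start (others at the always-pass sentinel, index 0)
    idx = [0] * n_feat
    best = (-np.inf, 0, 0)
    for j in range(n_feat):
        tp = (pass_mats[j] & y[:, None]).sum(axis=0)
        fp = (pass_mats[j] & ~y[:, None]).sum(axis=0)
        keys = key_grid(tp, fp)
        k = int(np.flatnonzero(keys == keys.max()).max())  # tie -> higher threshold
        if (keys[k], j, k) > best:
            best = (float(keys[k]), j, k)
    idx[best[1]] = best[2]
    current = best[0]

    pairs = [(a, b) for a in range(n_feat) for b in range(a + 1, n_feat)]
    sweeps = 0
    for sweep in range(max_sweeps):
        improved = False
        for a, b in pairs:
            base = np.ones(n, dtype=bool)
            for j in range(n_feat):
                if j not in (a, b):
                    base &= pass_mats[j][:, idx[j]]
            pa_pos = (pass_mats[a] & (base & y)[:, None]).astype(np.int64)
            pa_neg = (pass_mats[a] & (base & ~y)[:, None]).astype(np.int64)
            pb = pass_mats[b].astype(np.int64)
            tp = pa_pos.T @ pb  # tp[i, k] for (candidate i of a, candidate k of b)
            fp = pa_neg.T @ pb
            keys = key_grid(tp, fp)
            flat = np.flatnonzero(keys == keys.max())
            pick = flat.max()  # row-major: ties -> higher threshold of a, then of b
            i, k = divmod(int(pick), keys.shape[1])
            if keys[i, k] > current or (keys[i, k] == current and (i, k) > (idx[a], idx[b])):
                if keys[i, k] > current:
                    improved = True
                idx[a], idx[b] = i, k
                current = float(keys[i, k])
        sweeps = sweep + 1
        if not improved:
            break

    thresholds = [float(cands[j][idx[j]]) for j in range(n_feat)]
    pred = np.all(x >= np.asarray(thresholds)[None, :], axis=1)
    fp = int((pred & ~y).sum())
    n_pos = int(pred.sum())
    criteria = [
        CriterionSpec(feature=FeatureName(f), threshold=float(t), enabled=True)
        for f, t in zip(_FIT_FEATURES, thresholds)
    ]
    return FitResult(
        criteria=criteria,
        accuracy=float((pred == y).mean()),
        fdr=fp / n_pos if n_pos else 0.0,
        n_positive=int(y.sum()),
        n_negative=int((~y).sum()),
        sweeps=sweeps,
    )


# ---------------------------------------------------------------------------
# annotation table I/O and crop export

ANNOTATION_COLUMNS = ["dataset", "object_id", "annotator_id", "label", "timestamp"]


def write_annotations(annotations: Sequence[Annotation], path: str | Path) -> None:
    rows = [
        {
            "dataset": a.dataset,
            "object_id": a.object_id,
            "annotator_id": a.annotator_id,
            "label": a.label.value,
            "timestamp": a.timestamp,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False, lineterminator="\n")


def read_annotations(path: str | Path) -> list[Annotation]:
    out: list[Annotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Annotation(
                    object_id=row["object_id"],
                    dataset=row["dataset"],
                    annotator_id=row["annotator_id"],
                    label=AnnotationLabel(row["label"]),
                    timestamp=row.get("timestamp", "") or "",
                )
            )
    return out


def export_annotated_crops(
    annotations: Sequence[Annotation],
    objects: Mapping[str, SegmentedObject],
    fovs: Mapping[str, FieldOfView],
    out_dir: str | Path,
    crop_radius: int = 32,
    features: Mapping[str, FeatureVector] | None = None,
) -> Path:
    """Write one fixed-size 2-channel TIFF crop per annotation plus a manifest.

    Crops are centered on the object centroid and zero-padded at image
    borders so every crop has shape (2, 2r+1, 2r+1). Returns the manifest
    path; the manifest is byte-identical across re-exports.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ImageReadError(f"cannot create output directory {out_dir}: {exc}") from exc
    rows = []
    ordered = sorted(annotations, key=lambda a: (a.dataset, a.object_id, a.annotator_id))
    for ann in ordered:
        obj = objects[ann.object_id]
        fov = fovs[obj.field_id]
        cy, cx = obj.centroid
        center = (int(round(cy)), int(round(cx)))
        crop = np.stack(
            [extract_crop(fov.dna, center, crop_radius), extract_crop(fov.protein, center, crop_radius)]
        )
        fname = f"{ann.object_id}_{ann.annotator_id}.tif".replace(":", "_").replace("/", "_")
        tifffile.imwrite(out_dir / fname, crop)
        row: dict[str, object] = {
            "crop_path": fname,
            "dataset": ann.dataset,
            "object_id": ann.object_id,
            "annotator_id": ann.annotator_id,
            "label": ann.label.value,
        }
        if features is not None and ann.object_id in features:
            fv = features[ann.object_id]
            row.update(
                protein_area_px=fv.protein_area,
                dna_area_px=fv.dna_area,
                area_ratio=fv.area_ratio,
                dna_deformation=fv.dna_deformation,
                dna_radius_std_px=fv.dna_radius_std,
                dna_radius_cv=fv.dna_radius_cv,
            )
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    cols = ["crop_path", "dataset", "object_id", "annotator_id", "label"]
    if features is not None:
        cols += [
            "protein_area_px", "dna_area_px", "area_ratio",
            "dna_deformation", "dna_radius_std_px", "dna_radius_cv",
        ]
    pd.DataFrame(rows, columns=cols).to_csv(manifest, index=False, lineterminator="\n")
    return manifest
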