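"""High-level pipeline: segment -> features -> classify -> summarize.

Thin composition layer used by the CLI and the acceptance script; all the
science lives in the individual modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classification import (
    Prediction,
    SummaryStats,
    build_object_records,
    classify_objects,
    summarize,
    summarize_fields,
)
from .config import ClassifierConfig
from .features import FeatureVector, compute_features
from .io_formats import Dataset, write_object_table
from .segmentation import ExclusionLog, SegmentedObject, segment_field


@dataclass
class RunResult:
    dataset: str
    objects: list[SegmentedObject]
    features: dict[str, FeatureVector]
    predictions: dict[str, Prediction]
    summary: SummaryStats
    field_summaries: dict[str, SummaryStats]
    exclusions: dict[str, ExclusionLog] = field(default_factory=dict)

    def object_records(self) -> list[dict[str, object]]:
        return build_object_records(self.dataset, self.objects, self.features, self.predictions)

    def write_objects_csv(self, path) -> None:
        write_object_table(self.object_records(), path)


def run_dataset(ds: Dataset, cfg: ClassifierConfig) -> RunResult:
    """Run the full per-object analysis over all non-excluded fields."""
    objects: list[SegmentedObject] = []
    exclusions: dict[str, ExclusionLog] = {}
    for fov in ds.active_fields:
        objs, log = segment_field(fov, cfg.segmentation)
        objects.extend(objs)
        exclusions[fov.id] = log
    features = {obj.object_id: compute_features(obj) for obj in objects}
    predictions = classify_objects(features, cfg)
    return RunResult(
        dataset=ds.name,
        objects=objects,
        features=features,
        predictions=predictions,
        summary=summarize(objects, predictions),
        field_summaries=summarize_fields(objects, predictions),
        exclusions=exclusions,
    )
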