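"""Configuration models.

A :class:`ClassifierConfig` bundles everything needed to reproduce a run:
how each channel is binarized, how merged cells are split, and the four
morphological criteria with their thresholds. Configurations are calibrated
once on a negative-control dataset (or fitted from annotations) and then
reused unchanged across datasets acquired with the same imaging protocol.
"""

from __future__ import annotations

import math
from enum import Enum

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

SCHEMA_VERSION = "1"


class BinarizeMethod(str, Enum):
    OTSU = "otsu"
    ADAPTIVE = "adaptive"


class FeatureName(str, Enum):
    """The four per-object features the classifier thresholds."""

    PROTEIN_AREA = "protein_area"
    AREA_RATIO = "area_ratio"
    DNA_DEFORMATION = "dna_deformation"
    DNA_RADIUS_STD = "dna_radius_std"


class BinarizerSpec(BaseModel):
    """How one channel is turned into a foreground mask.

    ``t_percent`` only applies to the adaptive method: a pixel is foreground
    iff its intensity is at least ``local_mean * (1 - t_percent/100)``, so a
    negative percentage demands intensity strictly above the local mean.
    ``window`` is the full side length of the local-mean neighborhood; when
    absent it defaults to 1/8 of the mean image dimension.
    """

    model_config = ConfigDict(extra="forbid")

    method: BinarizeMethod = BinarizeMethod.OTSU
    t_percent: float = 0.0
    window: int | None = None

    @field_validator("t_percent")
    @classmethod
    def _t_in_range(cls, v: float) -> float:
        if not math.isfinite(v) or not -100.0 <= v <= 100.0:
            raise ValueError("t_percent must be a finite value in [-100, 100]")
        return v

    @field_validator("window")
    @classmethod
    def _window_min(cls, v: int | None) -> int | None:
        if v is not None and v < 3:
            raise ValueError("window must be >= 3 when given")
        return v


class SegmentationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    dna: BinarizerSpec = BinarizerSpec()
    protein: BinarizerSpec = BinarizerSpec()
    #: connected components smaller than this (pixels) are dropped as debris
    min_object_area: int = 20
    #: DNA segments in one protein segment are watershed-split when their
    #: centroids are more than this many pixels apart
    split_distance: float = 5.0

    @field_validator("min_object_area")
    @classmethod
    def _area_nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("min_object_area must be >= 0")
        return v

    @field_validator("split_distance")
    @classmethod
    def _split_pos(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("split_distance must be > 0")
        return v


class CriterionSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    feature: FeatureName
    threshold: float
    enabled: bool = True

    @field_validator("threshold")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("threshold must be finite")
        return v


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    segmentation: SegmentationConfig = SegmentationConfig()
    criteria: list[CriterionSpec]

    @model_validator(mode="after")
    def _one_per_feature(self) -> "ClassifierConfig":
        feats = [c.feature for c in self.criteria]
        if sorted(feats, key=lambda f: f.value) != sorted(FeatureName, key=lambda f: f.value):
            raise ValueError("criteria must contain exactly one entry per feature")
        if not any(c.enabled for c in self.criteria):
            raise ValueError("at least one criterion must be enabled")
        return self

    def criterion(self, feature: FeatureName | str) -> CriterionSpec:
        feature = FeatureName(feature)
        for c in self.criteria:
            if c.feature == feature:
                return c
        raise KeyError(feature)  # unreachable given the validator

    def with_criteria(self, criteria: list[CriterionSpec]) -> "ClassifierConfig":
        return self.model_copy(update={"criteria": [c.model_copy() for c in criteria]})


def default_config() -> ClassifierConfig:
    """A starting configuration: Otsu on both channels, permissive thresholds.

    The thresholds of 0 pass every object and are meant to be calibrated on
    control data (``cmd_configure``) or fitted from annotations
    (``auto_thresholds``) before any biological conclusion is drawn.
    """
    return ClassifierConfig(
        criteria=[CriterionSpec(feature=f, threshold=0.0, enabled=True) for f in FeatureName]
    )
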