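import numpy as np
import pytest

from trapquant.config import ClassifierConfig, CriterionSpec, FeatureName
from trapquant.pipeline import run_dataset
from trapquant.io_formats import Dataset
from trapquant.segmentation import SegmentedObject
from trapquant.synthetic import default_separable_spec, generate_fields


def disk_mask(radius: float, pad: int = 2) -> np.ndarray:
    hw = int(np.ceil(radius)) + pad
    yy, xx = np.mgrid[-hw : hw + 1, -hw : hw + 1]
    return yy * yy + xx * xx <= radius * radius


def star_mask(r0: float, amplitude: float = 0.4, arms: int = 4, pad: int = 2) -> np.ndarray:
    hw = int(np.ceil(r0 * (1 + amplitude))) + pad
    yy, xx = np.mgrid[-hw : hw + 1, -hw : hw + 1]
    theta = np.arctan2(yy, xx)
    r = r0 * (1 + amplitude * np.cos(arms * theta))
    return np.hypot(yy, xx) <= r


def make_object(protein_mask, dna_mask, object_id="obj", field_id="f", offset=(0, 0)):
    return SegmentedObject(
        object_id=object_id,
        field_id=field_id,
        offset=offset,
        protein_mask=np.asarray(protein_mask, dtype=bool),
        dna_mask=np.asarray(dna_mask, dtype=bool),
    )


def permissive_config(**criteria) -> ClassifierConfig:
    """Config with all criteria enabled; thresholds default to 0 (pass-all)."""
    return ClassifierConfig(
        criteria=[
            CriterionSpec(feature=f, threshold=float(criteria.get(f.value, 0.0)), enabled=True)
            for f in FeatureName
        ]
    )


@pytest.fixture(scope="session")
def separable_fields():
    """Three synthetic fields (~200 objects, 30% NETs) with ground truth."""
    spec = default_separable_spec().model_copy(update={"seed": 7})
    return generate_fields(spec, 3, id_prefix="fx")


@pytest.fixture(scope="session")
def separable_run(separable_fields):
    """Full pipeline run (permissive thresholds) over the three fields."""
    ds = Dataset(name="fx", fields=[fov for fov, _ in separable_fields])
    return run_dataset(ds, permissive_config())


@pytest.fixture(scope="session")
def ground_truths(separable_fields):
    return {fov.id: gt for fov, gt in separable_fields}
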