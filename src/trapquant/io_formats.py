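"""Image, configuration and table input/output.

Fields of view are read from TIFF (8/16-bit, single- or multi-page) or PNG
files. Intensities are kept on their native scale — no rescaling happens at
read time, so Otsu and adaptive thresholds always operate on raw camera
values and a configuration calibrated on one dataset transfers unchanged to
another acquired with the same protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .config import SCHEMA_VERSION, ClassifierConfig
from .errors import (
    ConfigFileError,
    ConfigurationError,
    ImageReadError,
    LookupFieldError,
    SchemaVersionError,
)


class ChannelRole(str, Enum):
    DNA = "dna"
    NET_PROTEIN = "net_protein"
    IGNORED = "ignored"


@dataclass
class FieldOfView:
    """One microscopy field: per-channel 2D intensity arrays plus roles.

    A field used for analysis must carry exactly one DNA and one NET-protein
    channel; additional channels may be present with role IGNORED.
    """

    id: str
    channels: list[np.ndarray]
    roles: list[ChannelRole]
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if len(self.channels) != len(self.roles):
            raise ConfigurationError(
                f"field {self.id!r}: {len(self.channels)} channels but {len(self.roles)} roles"
            )
        if not self.channels:
            raise ConfigurationError(f"field {self.id!r}: no channels")
        shape = np.asarray(self.channels[0]).shape
        for i, ch in enumerate(self.channels):
            ch = np.asarray(ch)
            if ch.ndim != 2:
                raise ConfigurationError(f"field {self.id!r}: channel {i} is not 2-D")
            if ch.shape != shape:
                raise ConfigurationError(f"field {self.id!r}: channel shapes differ")
            if not np.all(np.isfinite(ch.astype(np.float64, copy=False))) or ch.min() < 0:
                raise ConfigurationError(f"field {self.id!r}: intensities must be finite and >= 0")
            self.channels[i] = ch
        h, w = shape
        if h < 8 or w < 8:
            raise ConfigurationError(f"field {self.id!r}: image must be at least 8x8, got {h}x{w}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels[0].shape  # type: ignore[return-value]

    def _channel_for(self, role: ChannelRole) -> np.ndarray:
        idx = [i for i, r in enumerate(self.roles) if r == role]
        if len(idx) != 1:
            raise ConfigurationError(
                f"field {self.id!r}: expected exactly one {role.value} channel, found {len(idx)}"
            )
        return self.channels[idx[0]]

    @property
    def dna(self) -> np.ndarray:
        return self._channel_for(ChannelRole.DNA)

    @property
    def protein(self) -> np.ndarray:
        return self._channel_for(ChannelRole.NET_PROTEIN)


@dataclass
class Dataset:
    name: str
    fields: list[FieldOfView] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [f.id for f in self.fields]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"dataset {self.name!r}: duplicate field ids")

    def get(self, field_id: str) -> FieldOfView:
        for f in self.fields:
            if f.id == field_id:
                return f
        raise LookupFieldError(f"unknown field id {field_id!r} in dataset {self.name!r}")

    @property
    def active_fields(self) -> list[FieldOfView]:
        return [f for f in self.fields if not f.excluded]


def _read_pages(path: Path) -> list[np.ndarray]:
    """Read a TIFF or PNG file as a list of 2-D pages.

    A page with a trailing channel axis (H, W, C) is split into C planes so a
    single multi-channel image can also fill one field of view.
    """
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            with tifffile.TiffFile(str(path)) as tf:
                arrays = [p.asarray() for p in tf.pages]
        elif suffix == ".png":
            import imageio.v3 as iio

            arrays = [iio.imread(str(path))]
        else:
            raise ImageReadError(f"unsupported image format: {path}")
    except ImageReadError:
        raise
    except Exception as exc:  # noqa: BLE001 - reraise with the path attached
        raise ImageReadError(f"could not read image file {path}: {exc}") from exc

    pages: list[np.ndarray] = []
    for arr in arrays:
        arr = np.asarray(arr)
        if arr.ndim == 2:
            pages.append(arr)
        elif arr.ndim == 3 and arr.shape[-1] <= 4:
            pages.extend(arr[..., c] for c in range(arr.shape[-1]))
        elif arr.ndim == 3:
            pages.extend(arr[c] for c in range(arr.shape[0]))
        else:
            raise ImageReadError(f"cannot interpret array of shape {arr.shape} in {path}")
    return pages


def read_images(
    paths: Sequence[str | Path],
    role_map: Mapping[int, ChannelRole | str],
    name: str = "dataset",
) -> Dataset:
    """Load image files into a :class:`Dataset`.

    Pages are collected from the files in the given order and grouped into
    fields of view by the arity of ``role_map``: role_map {0: DNA, 1:
    NET_PROTEIN} groups consecutive pairs of pages, whether they come from
    two single-page files, one two-page TIFF, or one (H, W, 2) array.
    Bit depth is preserved; values are never rescaled.
    """
    if not role_map:
        raise ConfigurationError("role_map must not be empty")
    arity = len(role_map)
    if sorted(role_map) != list(range(arity)):
        raise ConfigurationError("role_map keys must be 0..k-1")
    roles = [ChannelRole(role_map[i]) for i in range(arity)]
    if roles.count(ChannelRole.DNA) != 1 or roles.count(ChannelRole.NET_PROTEIN) != 1:
        raise ConfigurationError("role_map must assign exactly one DNA and one NET_PROTEIN channel")

    pages: list[tuple[str, int, np.ndarray]] = []  # (stem, page index within file, array)
    provenance: dict[str, str] = {}
    for path in paths:
        path = Path(path)
        file_pages = _read_pages(path)
        provenance[path.name] = str(path)
        pages.extend((path.stem, i, arr) for i, arr in enumerate(file_pages))

    if len(pages) % arity != 0:
        raise ConfigurationError(
            f"{len(pages)} pages cannot be grouped into fields of {arity} channels"
        )

    fields: list[FieldOfView] = []
    seen: set[str] = set()
    for g in range(len(pages) // arity):
        group = pages[g * arity : (g + 1) * arity]
        stem, page_idx, _ = group[0]
        fid = f"{stem}:p{page_idx}"
        if fid in seen:  # same stem reused across directories
            fid = f"{fid}#{g}"
        seen.add(fid)
        fields.append(FieldOfView(id=fid, channels=[a for _, _, a in group], roles=list(roles)))
    return Dataset(name=name, fields=fields, provenance=provenance)


def exclude_field(ds: Dataset, field_id: str, reason: str) -> Dataset:
    """Mark one field as excluded; idempotent, the reason is updated in place.

    Excluded fields are skipped by every downstream operation but remain in
    the dataset for provenance.
    """
    fov = ds.get(field_id)
    fov.excluded = True
    fov.exclusion_reason = reason
    return ds


def save_config(cfg: ClassifierConfig, path: str | Path) -> None:
    Path(path).write_text(cfg.model_dump_json(indent=2) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> ClassifierConfig:
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigFileError(f"could not parse configuration file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigFileError(f"configuration file {path} is not a JSON object")
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"configuration schema version {version!r} does not match expected {SCHEMA_VERSION!r}"
        )
    try:
        return ClassifierConfig.model_validate(data)
    except ValueError as exc:
        raise ConfigFileError(f"invalid configuration in {path}: {exc}") from exc


#: column order of the per-object output table
OBJECT_TABLE_COLUMNS = [
    "dataset",
    "field_id",
    "object_id",
    "centroid_row",
    "centroid_col",
    "bbox_r0",
    "bbox_r1",
    "bbox_c0",
    "bbox_c1",
    "protein_area_px",
    "dna_area_px",
    "area_ratio",
    "dna_deformation",
    "dna_radius_std_px",
    "dna_radius_cv",
    "pass_protein_area",
    "pass_area_ratio",
    "pass_dna_deformation",
    "pass_dna_radius_std",
    "enabled_protein_area",
    "enabled_area_ratio",
    "enabled_dna_deformation",
    "enabled_dna_radius_std",
    "is_net",
]


def write_object_table(records: Iterable[Mapping[str, object]], path: str | Path) -> None:
    """Write the per-object CSV (RFC-4180, UTF-8, '.' decimal separator).

    Rows are sorted by (dataset, field_id, object_id) so the output is
    deterministic for identical inputs; zero records yield a header-only file.
    """
    df = pd.DataFrame(list(records), columns=OBJECT_TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["dataset", "field_id", "object_id"], kind="mergesort")
    try:
        df.to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise ImageReadError(f"could not write table to {path}: {exc}") from exc
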