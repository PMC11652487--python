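"""Two-channel segmentation of candidate cells and NETs.

The DNA channel and the NET-associated-protein channel are binarized
independently (Otsu or local-mean adaptive thresholding with a signed
percentage), DNA material is paired with the protein component it overlaps
most, and protein components containing several well-separated DNA segments
are split by marker-based watershed. The result is one
:class:`SegmentedObject` per candidate cell/NET.

Adaptive rule
-------------
A pixel ``p`` is foreground iff ``p >= m * (1 - t/100)`` where ``m`` is the
mean over the square neighborhood of Chebyshev radius ``window // 2``
(mirror-padded at the borders). A negative ``t`` therefore demands intensity
above the local mean by ``|t|`` percent — the setting used on noisy, diffuse
channels. Local sums are accumulated in int64 via an integral image, so for
integer images the mean is bit-identical to a direct per-pixel average.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from .config import BinarizeMethod, BinarizerSpec, SegmentationConfig
from .errors import ConfigurationError
from .io_formats import FieldOfView

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity throughout


def default_window(h: int, w: int) -> int:
    """Adaptive-threshold window: 1/8 of the mean image dimension.

    Rounded half away from zero; clamped below at 3 so the neighborhood is
    never degenerate on tiny images.
    """
    if h < 8 or w < 8:
        raise ConfigurationError("image must be at least 8x8")
    value = (h + w) / 2 / 8
    rounded = int(math.floor(value + 0.5))
    return max(rounded, 3)


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of the image's value range.

    Returns the center of the highest histogram bin assigned to the
    background class by the split that maximizes between-class variance
    (first maximum on ties).
    """
    img = np.asarray(img)
    hist, edges = np.histogram(img.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2.0
    hist = hist.astype(np.float64)
    w1 = np.cumsum(hist)[:-1]  # background weight for split after bin i
    w2 = hist.sum() - w1
    csum = np.cumsum(hist * centers)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = csum / w1
        m2 = (np.sum(hist * centers) - csum) / w2
        var = w1 * w2 * (m1 - m2) ** 2
    var[(w1 == 0) | (w2 == 0)] = -np.inf
    return float(centers[int(np.argmax(var))])


def binarize_otsu(img: np.ndarray) -> np.ndarray:
    """Foreground mask via Otsu's threshold on a 256-bin histogram.

    The threshold maximizes between-class variance; pixels strictly above it
    are foreground. A constant image yields an all-background mask and a
    warning rather than an exception.
    """
    img = np.asarray(img)
    if img.min() == img.max():
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    return img > otsu_threshold(img)


def _local_mean(img: np.ndarray, window: int) -> np.ndarray:
    """Windowed mean with mirror (symmetric) padding via an integral image."""
    r = window // 2
    side = 2 * r + 1
    pad = np.pad(img, r, mode="symmetric")
    if np.issubdtype(img.dtype, np.integer) or img.dtype == bool:
        pad = pad.astype(np.int64)
    else:
        pad = pad.astype(np.float64)
    ii = np.zeros((pad.shape[0] + 1, pad.shape[1] + 1), dtype=pad.dtype)
    ii[1:, 1:] = pad.cumsum(axis=0).cumsum(axis=1)
    sums = ii[side:, side:] - ii[:-side, side:] - ii[side:, :-side] + ii[:-side, :-side]
    return sums / float(side * side)


def binarize_adaptive(img: np.ndarray, t_percent: float, window: int) -> np.ndarray:
    """Local-mean adaptive threshold with a signed percentage.

    Foreground iff ``intensity >= local_mean * (1 - t_percent/100)``.
    """
    if window < 3:
        raise ConfigurationError("window must be >= 3")
    img = np.asarray(img)
    m = _local_mean(img, window)
    return img.astype(np.float64) >= m * (1.0 - t_percent / 100.0)


def binarize(img: np.ndarray, spec: BinarizerSpec) -> np.ndarray:
    if spec.method == BinarizeMethod.OTSU:
        return binarize_otsu(img)
    h, w = img.shape
    window = spec.window if spec.window is not None else default_window(h, w)
    return binarize_adaptive(img, spec.t_percent, window)


@dataclass
class SegmentedObject:
    """One candidate cell/NET: a protein component with its DNA material.

    Masks are cropped to a common frame whose top-left corner in the full
    image is ``offset``; the bounding box is half-open in global pixel
    coordinates and the centroid is the mean coordinate of the union mask.
    """

    object_id: str
    field_id: str
    offset: tuple[int, int]
    protein_mask: np.ndarray
    dna_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.protein_mask.shape != self.dna_mask.shape:
            raise ValueError("protein and dna masks must share the crop frame")
        if not self.protein_mask.any():
            raise ValueError("protein mask must contain at least one pixel")

    @property
    def union_mask(self) -> np.ndarray:
        return self.protein_mask | self.dna_mask

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1), half-open, in global coordinates."""
        r0, c0 = self.offset
        h, w = self.protein_mask.shape
        return (r0, r0 + h, c0, c0 + w)

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.union_mask)
        return (float(rr.mean()) + self.offset[0], float(cc.mean()) + self.offset[1])

    @property
    def raster_key(self) -> tuple[int, int]:
        """Global (row, col) of the first protein pixel in raster order."""
        rr, cc = np.nonzero(self.protein_mask)
        i = np.lexsort((cc, rr))[0]
        return (int(rr[i]) + self.offset[0], int(cc[i]) + self.offset[1])


@dataclass
class ExclusionRecord:
    kind: str  # e.g. "dna_without_protein", "protein_without_dna", "below_min_area"
    channel: str
    detail: str


@dataclass
class ExclusionLog:
    records: list[ExclusionRecord] = field(default_factory=list)

    def add(self, kind: str, channel: str, detail: str) -> None:
        self.records.append(ExclusionRecord(kind, channel, detail))

    def count(self, kind: str | None = None) -> int:
        return len([r for r in self.records if kind is None or r.kind == kind])


def _drop_small(labels: np.ndarray, n: int, min_area: int, channel: str, log: ExclusionLog) -> np.ndarray:
    if n == 0 or min_area <= 0:
        return labels
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    small = np.flatnonzero(areas[1:] < min_area) + 1
    for lab in small:
        log.add("below_min_area", channel, f"component {lab} area {areas[lab]} < {min_area}")
    if small.size:
        labels = np.where(np.isin(labels, small), 0, labels)
    return labels


def pair_objects(
    dna_mask: np.ndarray,
    protein_mask: np.ndarray,
    cfg: SegmentationConfig,
    field_id: str = "field",
) -> tuple[list[SegmentedObject], ExclusionLog]:
    """Pair DNA components with the protein component they overlap most.

    Each DNA component is assigned to the 8-connected protein component with
    maximal pixel overlap (ties go to the lower protein label). Protein
    components with at least one assigned DNA component become objects; the
    rest — and DNA with no protein overlap — are logged and excluded.
    """
    if dna_mask.shape != protein_mask.shape:
        raise ValueError("masks must share shape")
    log = ExclusionLog()
    dna_lab, n_d = ndi.label(dna_mask, structure=_STRUCT8)
    pro_lab, n_p = ndi.label(protein_mask, structure=_STRUCT8)
    dna_lab = _drop_small(dna_lab, n_d, cfg.min_object_area, "dna", log)
    pro_lab = _drop_small(pro_lab, n_p, cfg.min_object_area, "protein", log)

    both = (dna_lab > 0) & (pro_lab > 0)
    assignment: dict[int, tuple[int, int]] = {}  # dna label -> (best protein label, overlap)
    if both.any():
        pairs = np.stack([dna_lab[both], pro_lab[both]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        for (d, p), c in zip(uniq, counts):
            d, p, c = int(d), int(p), int(c)
            cur = assignment.get(d)
            # max overlap wins; on a tie the lower protein label wins
            if cur is None or c > cur[1] or (c == cur[1] and p < cur[0]):
                assignment[d] = (p, c)

    by_protein: dict[int, list[int]] = {}
    for d in range(1, n_d + 1):
        if not (dna_lab == d).any():
            continue  # dropped as debris
        if d in assignment:
            by_protein.setdefault(assignment[d][0], []).append(d)
        else:
            log.add("dna_without_protein", "dna", f"dna component {d} overlaps no protein component")

    objects: list[SegmentedObject] = []
    pro_slices = ndi.find_objects(pro_lab)
    dna_slices = ndi.find_objects(dna_lab)
    for p in range(1, n_p + 1):
        if pro_slices[p - 1] is None:
            continue  # dropped as debris
        if p not in by_protein:
            log.add("protein_without_dna", "protein", f"protein component {p} contains no DNA")
            continue
        dlist = sorted(by_protein[p])
        sl = pro_slices[p - 1]
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        for d in dlist:
            dsl = dna_slices[d - 1]
            r0, r1 = min(r0, dsl[0].start), max(r1, dsl[0].stop)
            c0, c1 = min(c0, dsl[1].start), max(c1, dsl[1].stop)
        crop = (slice(r0, r1), slice(c0, c1))
        pmask = pro_lab[crop] == p
        dmask = np.isin(dna_lab[crop], dlist)
        objects.append(
            SegmentedObject(
                object_id=f"{field_id}-p{p}",
                field_id=field_id,
                offset=(r0, c0),
                protein_mask=pmask,
                dna_mask=dmask,
            )
        )
    return objects, log


def split_merged(obj: SegmentedObject, cfg: SegmentationConfig) -> list[SegmentedObject]:
    """Watershed-split a protein component containing separated DNA segments.

    The split triggers only when the object holds >= 2 DNA components whose
    minimum pairwise centroid distance strictly exceeds ``split_distance``
    (default 5 px). Markers are the DNA components and the elevation map is
    the negated Euclidean distance transform of the protein mask, so basins
    follow the protein geometry. Protein pixels are conserved exactly and the
    number of output objects equals the number of DNA components.
    """
    dlab, n_d = ndi.label(obj.dna_mask, structure=_STRUCT8)
    if n_d < 2:
        return [obj]
    centroids = np.array(ndi.center_of_mass(obj.dna_mask, dlab, range(1, n_d + 1)))
    diff = centroids[:, None, :] - centroids[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    min_dist = dist[np.triu_indices(n_d, k=1)].min()
    if min_dist <= cfg.split_distance:
        return [obj]

    edt = ndi.distance_transform_edt(obj.protein_mask)
    markers = np.where(obj.protein_mask, dlab, 0)
    basins = watershed(-edt, markers=markers, mask=obj.protein_mask, connectivity=2)

    out: list[SegmentedObject] = []
    for d in range(1, n_d + 1):
        pmask = basins == d
        dmask = dlab == d
        rr, cc = np.nonzero(pmask | dmask)
        r0, r1 = int(rr.min()), int(rr.max()) + 1
        c0, c1 = int(cc.min()), int(cc.max()) + 1
        out.append(
            SegmentedObject(
                object_id=f"{obj.object_id}-s{d}",
                field_id=obj.field_id,
                offset=(obj.offset[0] + r0, obj.offset[1] + c0),
                protein_mask=pmask[r0:r1, c0:c1],
                dna_mask=dmask[r0:r1, c0:c1],
            )
        )
    return out


def segment_field(
    fov: FieldOfView, cfg: SegmentationConfig
) -> tuple[list[SegmentedObject], ExclusionLog]:
    """Binarize both channels, pair DNA with protein, split merged objects.

    Object ids are deterministic: the field id plus a running index in raster
    order of each object's first protein pixel, so they do not depend on
    component traversal order.
    """
    if fov.excluded:
        raise ConfigurationError(f"field {fov.id!r} is excluded: {fov.exclusion_reason}")
    dna_mask = binarize(fov.dna, cfg.dna)
    protein_mask = binarize(fov.protein, cfg.protein)
    paired, log = pair_objects(dna_mask, protein_mask, cfg, field_id=fov.id)
    split: list[SegmentedObject] = []
    for obj in paired:
        split.extend(split_merged(obj, cfg))
    split.sort(key=lambda o: o.raster_key)
    for i, obj in enumerate(split):
        obj.object_id = f"{fov.id}-{i:04d}"
    return split, log
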