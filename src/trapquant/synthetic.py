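"""Synthetic two-channel micrograph generator with ground truth.

Emulates the two stain patterns the pipeline consumes: DAPI-like nuclei
(near-circular DNA disks) inside neutrophil-elastase-like cell bodies
(larger protein disks), and NET-like structures — irregular, star-shaped
DNA blobs whose boundary radius is modulated by seeded low-order sinusoids,
surrounded by diffuse protein halos with a larger footprint than any intact
cell. Objects are placed on a jittered grid so centers are separated by more
than twice the largest radius (no merged objects unless constructed
explicitly), Gaussian read noise is applied last, and everything is
reproducible from the spec seed.

What this does *not* emulate: intact-NETotic intermediates, overlapping or
embedded cells, uneven illumination, and out-of-focus light. Tests passing
on these fixtures therefore demonstrate algorithmic correctness, not
performance on real micrographs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .errors import PlacementError
from .features import FeatureVector, compute_features
from .io_formats import ChannelRole, FieldOfView
from .segmentation import SegmentedObject


class NeutrophilGeometry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dna_radius_px: tuple[float, float] = (5.0, 6.5)
    protein_radius_px: tuple[float, float] = (9.0, 11.0)


class NetGeometry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    blob_radius_px: tuple[float, float] = (11.0, 13.0)
    irregularity: float = 0.5
    protein_halo_px: tuple[float, float] = (4.0, 5.0)

    @field_validator("irregularity")
    @classmethod
    def _irr_range(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("irregularity must be in [0, 1]")
        return v


class Intensities(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dna_fg: float = 3000.0
    protein_fg: float = 2500.0
    background: float = 100.0


class Noise(BaseModel):
    model_config = ConfigDict(extra="forbid")
    gaussian_sd: float = 60.0  # ~2% of the DNA foreground mean
    poisson: bool = False


class FixtureSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    image_size: tuple[int, int] = (768, 768)
    n_cells: int = 67
    net_fraction: float = 0.3
    neutrophil_geometry: NeutrophilGeometry = NeutrophilGeometry()
    net_geometry: NetGeometry = NetGeometry()
    intensities: Intensities = Intensities()
    noise: Noise = Noise()
    seed: int = 0

    @field_validator("net_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("net_fraction must be in [0, 1]")
        return v

    @field_validator("neutrophil_geometry")
    @classmethod
    def _radii_neu(cls, v: NeutrophilGeometry) -> NeutrophilGeometry:
        for lo, hi in (v.dna_radius_px, v.protein_radius_px):
            if lo < 2 or hi < lo:
                raise ValueError("radii must be >= 2 with lo <= hi")
        return v

    @property
    def max_radius(self) -> float:
        return max(
            self.neutrophil_geometry.protein_radius_px[1],
            (self.net_geometry.blob_radius_px[1] + self.net_geometry.protein_halo_px[1])
            * (1.0 + self.net_geometry.irregularity),
        )


@dataclass
class TrueObject:
    index: int
    label: str  # "NET" or "NEUTROPHIL"
    centroid: tuple[float, float]
    offset: tuple[int, int]
    dna_mask: np.ndarray
    protein_mask: np.ndarray

    def as_segmented(self, field_id: str = "truth") -> SegmentedObject:
        return SegmentedObject(
            object_id=f"{field_id}-true{self.index:04d}",
            field_id=field_id,
            offset=self.offset,
            protein_mask=self.protein_mask,
            dna_mask=self.dna_mask,
        )


@dataclass
class GroundTruth:
    objects: list[TrueObject]
    dna_labels: np.ndarray  # int32, 0 = background, i = objects[i-1]
    protein_labels: np.ndarray


def _star_radius(theta: np.ndarray, r0: float, irregularity: float, phases: np.ndarray) -> np.ndarray:
    """Boundary radius of a star-like blob: low-order sinusoidal modulation."""
    mod = (
        0.5 * np.sin(2 * theta + phases[0])
        + 0.3 * np.sin(3 * theta + phases[1])
        + 0.2 * np.sin(5 * theta + phases[2])
    )
    return np.maximum(r0 * (1.0 + irregularity * mod), 2.0)


def _rasterize_star(r0: float, irregularity: float, phases: np.ndarray) -> np.ndarray:
    hw = int(math.ceil(r0 * (1.0 + irregularity))) + 1
    yy, xx = np.mgrid[-hw : hw + 1, -hw : hw + 1]
    theta = np.arctan2(yy, xx)
    return np.hypot(yy, xx) <= _star_radius(theta, r0, irregularity, phases)


def _rasterize_disk(r: float) -> np.ndarray:
    hw = int(math.ceil(r)) + 1
    yy, xx = np.mgrid[-hw : hw + 1, -hw : hw + 1]
    return yy * yy + xx * xx <= r * r


def _paste(canvas: np.ndarray, mask: np.ndarray, center: tuple[int, int], value: int) -> tuple[int, int]:
    hw = mask.shape[0] // 2
    r0, c0 = center[0] - hw, center[1] - hw
    canvas[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]][mask] = value
    return r0, c0


def generate_field(spec: FixtureSpec, field_id: str = "synthetic:p0") -> tuple[FieldOfView, GroundTruth]:
    """Draw one field of view plus its ground truth from the spec seed.

    The number of NETs is ``round(n_cells * net_fraction)`` so the true NET
    percentage of a field is fixed, not binomial; which grid slots become
    NETs is random.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    max_r = spec.max_radius
    jitter = 2
    pitch = int(math.ceil(2 * max_r)) + 2 + 2 * jitter
    margin = int(math.ceil(max_r)) + jitter + 1
    rows = np.arange(margin, h - margin + 1, pitch)
    cols = np.arange(margin, w - margin + 1, pitch)
    slots = [(int(r), int(c)) for r in rows for c in cols]
    if spec.n_cells > len(slots):
        raise PlacementError(
            f"cannot place {spec.n_cells} objects of radius <= {max_r:.1f} "
            f"in a {h}x{w} image ({len(slots)} slots)"
        )
    order = rng.permutation(len(slots))[: spec.n_cells]
    n_nets = int(round(spec.n_cells * spec.net_fraction))
    labels = np.array(["NET"] * n_nets + ["NEUTROPHIL"] * (spec.n_cells - n_nets))
    rng.shuffle(labels)

    dna_lab = np.zeros((h, w), dtype=np.int32)
    pro_lab = np.zeros((h, w), dtype=np.int32)
    objects: list[TrueObject] = []
    for i, slot_idx in enumerate(order):
        base = slots[slot_idx]
        center = (
            base[0] + int(rng.integers(-jitter, jitter + 1)),
            base[1] + int(rng.integers(-jitter, jitter + 1)),
        )
        label = str(labels[i])
        if label == "NEUTROPHIL":
            g = spec.neutrophil_geometry
            dna = _rasterize_disk(float(rng.uniform(*g.dna_radius_px)))
            pro = _rasterize_disk(float(rng.uniform(*g.protein_radius_px)))
        else:
            g = spec.net_geometry
            r0 = float(rng.uniform(*g.blob_radius_px))
            halo = float(rng.uniform(*g.protein_halo_px))
            phases = rng.uniform(0, 2 * np.pi, size=3)
            dna = _rasterize_star(r0, g.irregularity, phases)
            pro = _rasterize_star(r0 + halo, g.irregularity, phases)
        _paste(dna_lab, dna, center, i + 1)
        pr0, pc0 = _paste(pro_lab, pro, center, i + 1)

        crop = (dna_lab == i + 1) | (pro_lab == i + 1)
        rr, cc = np.nonzero(crop)
        r0_, r1_ = int(rr.min()), int(rr.max()) + 1
        c0_, c1_ = int(cc.min()), int(cc.max()) + 1
        objects.append(
            TrueObject(
                index=i + 1,
                label=label,
                centroid=(float(center[0]), float(center[1])),
                offset=(r0_, c0_),
                dna_mask=dna_lab[r0_:r1_, c0_:c1_] == i + 1,
                protein_mask=pro_lab[r0_:r1_, c0_:c1_] == i + 1,
            )
        )

    intens = spec.intensities
    dna_img = np.full((h, w), intens.background, dtype=np.float64)
    pro_img = np.full((h, w), intens.background, dtype=np.float64)
    for obj in objects:
        sl = (slice(obj.offset[0], obj.offset[0] + obj.dna_mask.shape[0]),
              slice(obj.offset[1], obj.offset[1] + obj.dna_mask.shape[1]))
        dna_img[sl][obj.dna_mask] = intens.dna_fg
        # NET protein halos are dimmer/diffuse compared to intact cell bodies
        level = intens.protein_fg * (0.7 if obj.label == "NET" else 1.0)
        pro_img[sl][obj.protein_mask] = level
    if spec.noise.poisson:
        dna_img = rng.poisson(dna_img).astype(np.float64)
        pro_img = rng.poisson(pro_img).astype(np.float64)
    if spec.noise.gaussian_sd > 0:
        dna_img += rng.normal(0.0, spec.noise.gaussian_sd, size=(h, w))
        pro_img += rng.normal(0.0, spec.noise.gaussian_sd, size=(h, w))
    dna_u16 = np.clip(np.rint(dna_img), 0, 65535).astype(np.uint16)
    pro_u16 = np.clip(np.rint(pro_img), 0, 65535).astype(np.uint16)

    fov = FieldOfView(
        id=field_id,
        channels=[dna_u16, pro_u16],
        roles=[ChannelRole.DNA, ChannelRole.NET_PROTEIN],
    )
    return fov, GroundTruth(objects=objects, dna_labels=dna_lab, protein_labels=pro_lab)


def generate_fields(
    spec: FixtureSpec, n_fields: int, id_prefix: str = "synthetic"
) -> list[tuple[FieldOfView, GroundTruth]]:
    """Generate several fields, deriving one sub-seed per field from the spec seed."""
    out = []
    for i in range(n_fields):
        sub = spec.model_copy(update={"seed": (spec.seed * 1009 + i) % (2**31 - 1)})
        out.append(generate_field(sub, field_id=f"{id_prefix}:p{i}"))
    return out


def default_separable_spec(seed: int = 0) -> FixtureSpec:
    """The documented spec used across the test suite.

    Its geometry guarantees well-separated feature distributions: NET
    ground-truth protein areas and DNA radius spreads exceed the neutrophil
    values by several population standard deviations, so threshold fitting
    on these fixtures must reach perfect training accuracy.
    """
    return FixtureSpec(seed=seed)


def true_features(gt: GroundTruth, field_id: str = "truth") -> dict[str, FeatureVector]:
    """Features computed on the ground-truth masks (not on segmentations)."""
    return {
        obj.as_segmented(field_id).object_id: compute_features(obj.as_segmented(field_id))
        for obj in gt.objects
    }


def true_label_for(obj: SegmentedObject, gt: GroundTruth) -> str | None:
    """Ground-truth label of a segmented object by maximal protein-label overlap."""
    r0, r1, c0, c1 = obj.bbox
    sub = gt.protein_labels[r0:r1, c0:c1]
    vals = sub[obj.union_mask & (sub > 0)]
    if vals.size == 0:
        sub = gt.dna_labels[r0:r1, c0:c1]
        vals = sub[obj.union_mask & (sub > 0)]
    if vals.size == 0:
        return None
    lab = int(np.bincount(vals).argmax())
    return gt.objects[lab - 1].label
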