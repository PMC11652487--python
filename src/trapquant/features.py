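"""Per-object morphological features and radial intensity profiles.

The classifier consumes four measurements per object, all in pixel units:

* ``protein_area`` — size of the NET-protein mask. NETs spread the
  NET-associated protein over a much larger footprint than intact cells.
* ``area_ratio`` — DNA area relative to protein area; expelled chromatin
  grows faster than the protein footprint.
* ``dna_deformation`` — inverse circularity P^2 / (4*pi*A) of the DNA mask
  (1 for a disk, larger for irregular shapes). Perimeter uses the Crofton
  estimator so values are reproducible across platforms.
* ``dna_radius_std`` — population standard deviation of the distances from
  DNA boundary pixels to the DNA centroid; the fourth criterion, sensitive
  to star-like chromatin protrusions even when overall circularity is mild.

``dna_radius_cv`` (std / mean radius) is also computed and exposed for
scale-robust configurations, though the default criterion uses the raw std.

Radial profiles bin a fixed-size square crop around the object centroid by
distance to the center and take the mean intensity per bin, giving a
rotation-invariant descriptor used for unbiased 2-D embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import perimeter_crofton

from .io_formats import FieldOfView
from .segmentation import SegmentedObject

_STRUCT8 = np.ones((3, 3), dtype=bool)

#: default number of radial bins and crop half-side for profiles (pixels)
DEFAULT_N_BINS = 16
DEFAULT_CROP_RADIUS = 40


@dataclass(frozen=True)
class FeatureVector:
    protein_area: float
    dna_area: float
    area_ratio: float
    dna_deformation: float
    dna_radius_std: float
    dna_radius_cv: float
    degenerate: bool = False  # single-pixel DNA mask: radius/deformation undefined

    def value(self, feature: str) -> float:
        return float(getattr(self, str(feature)))


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels 8-adjacent to background (image border counts as background)."""
    eroded = ndi.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    return mask & ~eroded


def compute_features(obj: SegmentedObject) -> FeatureVector:
    protein_area = int(obj.protein_mask.sum())
    dna_area = int(obj.dna_mask.sum())
    if protein_area < 1 or dna_area < 1:
        raise ValueError(f"object {obj.object_id}: masks must be non-empty")
    area_ratio = dna_area / protein_area

    if dna_area == 1:
        return FeatureVector(protein_area, dna_area, area_ratio, 1.0, 0.0, 0.0, degenerate=True)

    # deformation on the largest 8-connected DNA component (ties: lower label)
    dlab, n_d = ndi.label(obj.dna_mask, structure=_STRUCT8)
    areas = np.bincount(dlab.ravel(), minlength=n_d + 1)[1:]
    largest = int(np.argmax(areas)) + 1
    comp = dlab == largest
    comp_area = int(areas[largest - 1])
    if comp_area == 1:
        deformation = 1.0
    else:
        # pad so components touching the crop edge keep their full boundary
        perim = float(perimeter_crofton(np.pad(comp, 1), directions=4))
        deformation = perim**2 / (4.0 * np.pi * comp_area)

    # radius spread from the centroid of the whole DNA mask
    rr, cc = np.nonzero(obj.dna_mask)
    cy, cx = rr.mean(), cc.mean()
    br, bc = np.nonzero(boundary_pixels(obj.dna_mask))
    dists = np.hypot(br - cy, bc - cx)
    radius_std = float(dists.std())  # population std
    mean_radius = float(dists.mean())
    radius_cv = radius_std / mean_radius if mean_radius > 0 else 0.0
    return FeatureVector(protein_area, dna_area, area_ratio, deformation, radius_std, radius_cv)


def profile_from_crop(crop: np.ndarray, n_bins: int, crop_radius: float) -> np.ndarray:
    """Radial bin means of a square (2R+1)x(2R+1) crop centered on its middle pixel.

    Pixels are binned by Euclidean distance d to the center into
    ``[k*R/n_bins, (k+1)*R/n_bins)``; pixels with d >= R are discarded and an
    empty bin contributes 0. For integer-valued crops the result is exactly
    invariant under 0/90/180/270-degree rotation and transposition, because
    those operations permute pixels within bins and the per-bin sums are
    exact in float64.
    """
    crop = np.asarray(crop)
    h, w = crop.shape
    if h != w or h % 2 != 1:
        raise ValueError("crop must be square with odd side (2*crop_radius + 1)")
    r = h // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(yy, xx)
    keep = d < crop_radius
    bins = np.floor(d[keep] * n_bins / crop_radius).astype(np.intp)
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=crop[keep].astype(np.float64), minlength=n_bins)
    out = np.zeros(n_bins, dtype=np.float64)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    return out


def radial_profile(
    obj: SegmentedObject,
    fov: FieldOfView,
    n_bins: int = DEFAULT_N_BINS,
    crop_radius: int = DEFAULT_CROP_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel radial profiles (DNA, protein) around the object centroid.

    The crop is centered on the pixel nearest the centroid and zero-padded
    beyond the image border so objects near the edge yield profiles of the
    same length as interior objects.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if crop_radius < n_bins:
        raise ValueError("crop_radius must be >= n_bins")
    cy, cx = obj.centroid
    ci, cj = int(round(cy)), int(round(cx))
    out = []
    for img in (fov.dna, fov.protein):
        crop = extract_crop(img, (ci, cj), crop_radius)
        out.append(profile_from_crop(crop, n_bins, crop_radius))
    return out[0], out[1]


def extract_crop(img: np.ndarray, center: tuple[int, int], radius: int) -> np.ndarray:
    """Square (2r+1)-sided crop centered on ``center``, zero-padded at borders."""
    ci, cj = center
    h, w = img.shape
    crop = np.zeros((2 * radius + 1, 2 * radius + 1), dtype=img.dtype)
    r0, r1 = max(0, ci - radius), min(h, ci + radius + 1)
    c0, c1 = max(0, cj - radius), min(w, cj + radius + 1)
    if r0 < r1 and c0 < c1:
        crop[r0 - (ci - radius) : r1 - (ci - radius), c0 - (cj - radius) : c1 - (cj - radius)] = img[
            r0:r1, c0:c1
        ]
    return crop


def profile_matrix(
    objects: list[SegmentedObject],
    fovs: dict[str, FieldOfView],
    n_bins: int = DEFAULT_N_BINS,
    crop_radius: int = DEFAULT_CROP_RADIUS,
) -> np.ndarray:
    """Stack per-object embedding inputs: DNA profile concatenated with protein."""
    rows = []
    for obj in objects:
        dna, pro = radial_profile(obj, fovs[obj.field_id], n_bins, crop_radius)
        rows.append(np.concatenate([dna, pro]))
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), 2 * n_bins)
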