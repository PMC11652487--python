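"""Independent brute-force reference implementations used only by tests.

Everything here is written as plainly as possible — per-pixel loops,
exhaustive searches — and deliberately shares no code with the package.
"""

import numpy as np

# Crofton perimeter coefficients for 4 directions, indexed by the 2x2
# configuration code c = m(i,j) + 4*m(i,j+1) + 2*m(i+1,j) + 8*m(i+1,j+1).
SQ2 = np.sqrt(2.0)
CROFTON4 = [
    0.0,
    np.pi / 4 * (1 + 1 / SQ2),
    np.pi / (4 * SQ2),
    np.pi / (2 * SQ2),
    0.0,
    np.pi / 4 * (1 + 1 / SQ2),
    0.0,
    np.pi / (4 * SQ2),
    np.pi / 4,
    np.pi / 2,
    np.pi / (4 * SQ2),
    np.pi / (4 * SQ2),
    np.pi / 4,
    np.pi / 2,
    0.0,
    0.0,
]


def otsu_mask(img):
    """Exhaustive search over 256 candidate thresholds (bin centers)."""
    hist, edges = np.histogram(np.asarray(img).ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    p = hist / hist.sum()
    best_t, best_v = None, -1.0
    for i in range(255):
        w0 = p[: i + 1].sum()
        w1 = 1.0 - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (p[: i + 1] * centers[: i + 1]).sum() / w0
        m1 = (p[i + 1 :] * centers[i + 1 :]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, centers[i]
    return np.asarray(img) > best_t


def adaptive_mask(img, t_percent, window):
    """Naive O(H*W*window^2) windowed-mean thresholding with mirror edges."""
    img = np.asarray(img)
    h, w = img.shape
    r = window // 2
    side = 2 * r + 1
    pad = np.pad(img.astype(np.int64), r, mode="symmetric")
    out = np.zeros((h, w), dtype=bool)
    factor = 1.0 - t_percent / 100.0
    for i in range(h):
        for j in range(w):
            s = int(pad[i : i + side, j : j + side].sum())
            m = s / (side * side)
            out[i, j] = img[i, j] >= m * factor
    return out


def crofton_perimeter(mask):
    """Per-pixel 2x2 configuration count, mirroring the published estimator."""
    mask = np.asarray(mask).astype(np.int64)
    padded = np.pad(mask, ((0, 1), (0, 1)))
    h, w = mask.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            code = (
                padded[i, j]
                + 4 * padded[i, j + 1]
                + 2 * padded[i + 1, j]
                + 8 * padded[i + 1, j + 1]
            )
            total += CROFTON4[code]
    return total


def naive_features(protein_mask, dna_mask):
    """Per-pixel loop re-implementation of the five object features."""
    protein_area = int(np.asarray(protein_mask).sum())
    dna = np.asarray(dna_mask).astype(bool)
    dna_area = int(dna.sum())
    area_ratio = dna_area / protein_area

    # largest 8-connected DNA component by flood fill
    h, w = dna.shape
    labels = np.zeros((h, w), dtype=int)
    next_label = 0
    for si in range(h):
        for sj in range(w):
            if dna[si, sj] and labels[si, sj] == 0:
                next_label += 1
                stack = [(si, sj)]
                labels[si, sj] = next_label
                while stack:
                    ci, cj = stack.pop()
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = ci + di, cj + dj
                            if 0 <= ni < h and 0 <= nj < w and dna[ni, nj] and labels[ni, nj] == 0:
                                labels[ni, nj] = next_label
                                stack.append((ni, nj))
    sizes = [(labels == k).sum() for k in range(1, next_label + 1)]
    comp = labels == (int(np.argmax(sizes)) + 1)
    comp_area = int(comp.sum())
    if comp_area == 1:
        deformation = 1.0
    else:
        # pad so border pixels contribute full 2x2 configurations
        perim = crofton_perimeter(np.pad(comp, 1))
        deformation = perim**2 / (4 * np.pi * comp_area)

    ys, xs = np.nonzero(dna)
    cy, cx = ys.mean(), xs.mean()
    boundary = []
    for i, j in zip(ys, xs):
        on_edge = False
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                ni, nj = i + di, j + dj
                if not (0 <= ni < h and 0 <= nj < w) or not dna[ni, nj]:
                    on_edge = True
        if on_edge:
            boundary.append((i, j))
    dists = np.array([np.hypot(i - cy, j - cx) for i, j in boundary])
    radius_std = float(dists.std())
    mean_r = float(dists.mean())
    radius_cv = radius_std / mean_r if mean_r > 0 else 0.0
    return protein_area, dna_area, area_ratio, deformation, radius_std, radius_cv


def radial_bin_means(crop, n_bins, crop_radius):
    """Naive per-pixel radial binning of an odd square crop."""
    crop = np.asarray(crop, dtype=np.float64)
    r = crop.shape[0] // 2
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for i in range(crop.shape[0]):
        for j in range(crop.shape[1]):
            d = np.hypot(i - r, j - r)
            if d >= crop_radius:
                continue
            b = int(d * n_bins // crop_radius)
            sums[b] += crop[i, j]
            counts[b] += 1
    out = np.zeros(n_bins)
    for b in range(n_bins):
        if counts[b]:
            out[b] = sums[b] / counts[b]
    return out
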