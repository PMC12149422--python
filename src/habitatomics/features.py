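"""IBSI-style radiomic feature extraction for whole tumors and habitats.

Implements the core feature bank computed per region (entire mask VOI_e and
the two habitat subregions VOI_1/VOI_2): first-order intensity statistics,
3-D shape descriptors, and gray-level texture matrices (GLCM over the 13
unique 3-D directions at distance 1, GLRLM averaged over the same
directions, GLSZM with 26-connected zones). Intensities are resampled to
isotropic 1 mm and discretized to a fixed count of 25 gray levels over the
per-region min-max before any texture matrix is built.

Texture matrices are accumulated strictly inside the region: voxel pairs,
runs and zones never cross the region boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

__all__ = [
    "PreprocessSpec",
    "resample",
    "discretize",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "shape_features",
    "extract_features",
    "extract_all",
    "DIRECTIONS_13",
]

#: the 13 unique 3-D direction offsets at Chebyshev distance 1
DIRECTIONS_13: list[tuple[int, int, int]] = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class PreprocessSpec:
    """Resampling and discretization settings applied before extraction."""

    target_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_gray_levels: int = 25

    def validate(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if self.n_gray_levels < 2:
            raise ValueError("n_gray_levels must be >= 2")


def resample(
    volume: np.ndarray,
    spacing,
    target_spacing=(1.0, 1.0, 1.0),
    order: int = 1,
) -> np.ndarray:
    """Resample a volume to ``target_spacing`` (trilinear by default).

    Use ``order=0`` (nearest neighbor) for masks and label maps so they
    stay integer-valued.
    """
    if spacing is None or any(s is None or s <= 0 for s in spacing):
        raise ValueError("valid voxel spacing metadata is required for resampling")
    factors = [s / t for s, t in zip(spacing, target_spacing)]
    arr = np.asarray(volume)
    was_bool = arr.dtype == bool
    out = ndimage.zoom(arr.astype(float), factors, order=order, mode="nearest")
    if was_bool:
        return out > 0.5
    if order == 0:
        return np.rint(out).astype(arr.dtype)
    return out


def discretize(values: np.ndarray, n_levels: int = 25) -> np.ndarray:
    """Fixed-bin-count discretization to integer gray levels 1..n_levels.

    Level = floor(n_levels * (x - min) / (max - min)) + 1, clamped; a
    constant region maps entirely to level 1.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot discretize an empty region")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    levels = np.floor(n_levels * (values - lo) / (hi - lo)).astype(np.int64) + 1
    return np.clip(levels, 1, n_levels)


def first_order_features(values: np.ndarray, n_levels: int = 25) -> dict[str, float]:
    """First-order intensity statistics over a region's raw voxel values.

    Entropy and uniformity are computed on the discretized histogram
    (log base 2 for entropy); variance and moments use the population
    convention; skewness and kurtosis are defined as 0 for a constant
    region.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty region")
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(np.mean(((x - mean) / sd) ** 3))
        kurt = float(np.mean(((x - mean) / sd) ** 4))
    else:
        skew = kurt = 0.0
    levels = discretize(x, n_levels)
    p = np.bincount(levels, minlength=n_levels + 1)[1:].astype(float)
    p /= p.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    p10, p90 = np.percentile(x, [10, 90])
    mid = x[(x >= p10) & (x <= p90)]
    return {
        "Mean": float(mean),
        "Median": float(np.median(x)),
        "Variance": float(var),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float(np.sum(x**2)),
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(mid - mid.mean())))
        if mid.size
        else 0.0,
        "Uniformity": float(np.sum(p**2)),
    }


def _shift_slices(shape, d):
    """Slicing pairs (src, dst) so that dst voxels have src = dst + d in bounds."""
    src, dst = [], []
    for n, dd in zip(shape, d):
        if dd >= 0:
            dst.append(slice(0, n - dd))
            src.append(slice(dd, n))
        else:
            dst.append(slice(-dd, n))
            src.append(slice(0, n + dd))
    return tuple(src), tuple(dst)


def glcm_matrix(disc: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction offset.

    ``disc`` holds gray levels 1..n_levels inside the region and 0 outside;
    pairs with either endpoint outside the region are ignored.
    """
    src, dst = _shift_slices(disc.shape, direction)
    a = disc[dst]
    b = disc[src]
    ok = (a > 0) & (b > 0)
    counts = np.bincount(
        (a[ok] - 1) * n_levels + (b[ok] - 1), minlength=n_levels * n_levels
    ).reshape(n_levels, n_levels).astype(float)
    counts = counts + counts.T
    total = counts.sum()
    return counts / total if total > 0 else counts


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    L = P.shape[0]
    i = np.arange(1, L + 1)[:, None]
    j = np.arange(1, L + 1)[None, :]
    pi = P.sum(axis=1)
    mu_i = float((i[:, 0] * pi).sum())
    sigma_i = float(np.sqrt(((i[:, 0] - mu_i) ** 2 * pi).sum()))
    nz = P[P > 0]
    corr_num = float(((i - mu_i) * (j - mu_i) * P).sum())
    correlation = corr_num / sigma_i**2 if sigma_i > 1e-12 else 1.0
    return {
        "Contrast": float(((i - j) ** 2 * P).sum()),
        "Dissimilarity": float((np.abs(i - j) * P).sum()),
        "Homogeneity": float((P / (1.0 + (i - j) ** 2)).sum()),
        "Energy": float((P**2).sum()),
        "JointEntropy": float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0,
        "Correlation": correlation,
        "ClusterShade": float(((i + j - 2 * mu_i) ** 3 * P).sum()),
        "ClusterProminence": float(((i + j - 2 * mu_i) ** 4 * P).sum()),
    }


def glcm_features(disc: np.ndarray, n_levels: int = 25) -> dict[str, float]:
    """GLCM features averaged over the 13 3-D directions at distance 1."""
    if int((disc > 0).sum()) < 2:
        raise ValueError("GLCM requires a region of at least 2 voxels")
    per_dir = []
    for d in DIRECTIONS_13:
        P = glcm_matrix(disc, d, n_levels)
        if P.sum() == 0:  # no in-region pair along this direction
            continue
        per_dir.append(_glcm_features_single(P))
    if not per_dir:
        raise ValueError("no co-occurring voxel pairs in any direction")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def _runs_along(disc: np.ndarray, d) -> list[tuple[int, int]]:
    """Maximal constant-gray-level runs along direction ``d`` inside the region."""
    shape = disc.shape
    # predecessor value (voxel at v - d), 0 when out of bounds
    pred = np.zeros_like(disc)
    src, dst = _shift_slices(shape, tuple(-x for x in d))
    pred[dst] = disc[src]
    starts = np.argwhere((disc > 0) & (pred != disc))
    runs = []
    dd = np.asarray(d)
    for v in starts:
        g = disc[tuple(v)]
        length = 1
        w = v + dd
        while (
            np.all(w >= 0)
            and np.all(w < shape)
            and disc[tuple(w)] == g
        ):
            length += 1
            w = w + dd
        runs.append((int(g), length))
    return runs


def _rl_features(runs: list[tuple[int, int]], n_voxels: int) -> dict[str, float]:
    g = np.array([r[0] for r in runs], dtype=float)
    ln = np.array([r[1] for r in runs], dtype=float)
    nr = float(len(runs))
    gl_counts = np.bincount(g.astype(int))
    rl_counts = np.bincount(ln.astype(int))
    return {
        "ShortRunEmphasis": float(np.sum(1.0 / ln**2) / nr),
        "LongRunEmphasis": float(np.sum(ln**2) / nr),
        "GrayLevelNonUniformity": float(np.sum(gl_counts.astype(float) ** 2) / nr),
        "RunLengthNonUniformity": float(np.sum(rl_counts.astype(float) ** 2) / nr),
        "RunPercentage": nr / n_voxels,
        "LowGrayLevelRunEmphasis": float(np.sum(1.0 / g**2) / nr),
        "HighGrayLevelRunEmphasis": float(np.sum(g**2) / nr),
    }


def glrlm_features(disc: np.ndarray) -> dict[str, float]:
    """Run-length features, averaged over the 13 3-D directions."""
    n_voxels = int((disc > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty region")
    per_dir = [
        _rl_features(_runs_along(disc, d), n_voxels) for d in DIRECTIONS_13
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in per_dir[0]}


def glszm_features(disc: np.ndarray) -> dict[str, float]:
    """Size-zone features; zones are 26-connected components of equal gray level."""
    n_voxels = int((disc > 0).sum())
    if n_voxels == 0:
        raise ValueError("empty region")
    zones: list[tuple[int, int]] = []  # (gray level, zone size)
    for g in np.unique(disc[disc > 0]):
        lab, n_comp = ndimage.label(disc == g, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((int(g), int(s)) for s in sizes)
    gl = np.array([z[0] for z in zones], dtype=float)
    sz = np.array([z[1] for z in zones], dtype=float)
    nz = float(len(zones))
    gl_counts = np.bincount(gl.astype(int))
    sz_counts = np.bincount(sz.astype(int))
    return {
        "SmallAreaEmphasis": float(np.sum(1.0 / sz**2) / nz),
        "LargeAreaEmphasis": float(np.sum(sz**2) / nz),
        "GrayLevelNonUniformity": float(np.sum(gl_counts.astype(float) ** 2) / nz),
        "SizeZoneNonUniformity": float(np.sum(sz_counts.astype(float) ** 2) / nz),
        "ZonePercentage": nz / n_voxels,
        "LowGrayLevelZoneEmphasis": float(np.sum(1.0 / gl**2) / nz),
        "HighGrayLevelZoneEmphasis": float(np.sum(gl**2) / nz),
    }


def shape_features(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> dict[str, float]:
    """3-D shape descriptors of a binary mask.

    Volume is voxel count times voxel volume; surface area counts exposed
    voxel faces; sphericity is pi^(1/3) (6V)^(2/3) / A; axis lengths are
    4 sqrt(lambda) from the PCA of physical voxel coordinates.
    """
    mask = mask.astype(bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    sx, sy, sz = (float(s) for s in spacing)
    voxel_volume = sx * sy * sz
    volume = n * voxel_volume

    face_areas = (sy * sz, sx * sz, sx * sy)
    surface = 0.0
    padded = np.pad(mask, 1)
    for axis, area in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        surface += float(np.abs(diff).sum()) * area

    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / surface

    coords = np.argwhere(mask).astype(float) * np.array([sx, sy, sz])
    if n == 1:
        max_diam = 0.0
        axes = np.zeros(3)
    else:
        try:
            hull_pts = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (coplanar/collinear) regions
            hull_pts = coords
        max_diam = float(pdist(hull_pts).max()) if len(hull_pts) > 1 else 0.0
        eigvals = np.sort(np.linalg.eigvalsh(np.cov(coords.T, bias=False)))[::-1]
        axes = 4.0 * np.sqrt(np.maximum(eigvals, 0.0))
    return {
        "Volume": volume,
        "SurfaceArea": surface,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": max_diam,
        "MajorAxisLength": float(axes[0]),
        "MinorAxisLength": float(axes[1]),
        "LeastAxisLength": float(axes[2]),
    }


def extract_features(
    image: np.ndarray,
    region_mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    n_levels: int = 25,
) -> dict[str, float]:
    """The full feature bank for a single region, keys ``family_Feature``."""
    region_mask = region_mask.astype(bool)
    if region_mask.shape != image.shape:
        raise ValueError("region mask grid does not match the image grid")
    values = image[region_mask]
    disc = np.zeros(image.shape, dtype=np.int64)
    disc[region_mask] = discretize(values, n_levels)
    out: dict[str, float] = {}
    out.update({f"firstorder_{k}": v for k, v in first_order_features(values, n_levels).items()})
    out.update({f"shape_{k}": v for k, v in shape_features(region_mask, spacing).items()})
    out.update({f"glcm_{k}": v for k, v in glcm_features(disc, n_levels).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(disc).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(disc).items()})
    return out


def extract_all(
    image: np.ndarray,
    habitat_labels: np.ndarray,
    mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    n_levels: int = 25,
    min_voxels: int = 10,
    patient_id: str = "P0000",
):
    """Feature rows for VOI_e (entire mask), VOI_1 and VOI_2.

    A subregion smaller than ``min_voxels`` is flagged ``excluded`` with no
    feature values (mirroring cohort exclusion for unsegmentable
    subregions); such rows are dropped by downstream selection.
    """
    import pandas as pd

    if habitat_labels.shape != image.shape or mask.shape != image.shape:
        raise ValueError("habitat labels, mask and image grids are misaligned")
    regions = {
        "VOIe": mask.astype(bool),
        "VOI1": habitat_labels == 1,
        "VOI2": habitat_labels == 2,
    }
    rows = []
    for region, rmask in regions.items():
        n = int(rmask.sum())
        row: dict = {"patient_id": patient_id, "region": region, "n_voxels": n}
        if n < max(min_voxels, 2):
            row["excluded"] = True
        else:
            row["excluded"] = False
            row.update(extract_features(image, rmask, spacing, n_levels))
        rows.append(row)
    return pd.DataFrame(rows)
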