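"""Per-nucleus descriptors: polar transform, histogram and Haralick features.

The discriminating signal between cell-cycle phases is the spatial pattern of
PCNA replication foci inside the nucleus (uniform in G, many small foci in
early S, peripheral foci in mid S, few large central foci in late S). The
nucleus has no preferred orientation, so every feature must be rotation
invariant. Histogram-type features are invariant by construction; directional
texture features are made invariant by computing them on the *polar image* of
the segment (radius on the x axis, angle on the y axis), which turns a
rotation of the nucleus into a cyclic shift along the angle axis.

Feature sets:

``basic_hist``
    min, max, mean, variance, skewness, kurtosis of the masked intensities,
    plus the mean of each radial zone of the polar image (location
    distribution of the foci).
``haralick_polar``
    104 values: 13 Haralick statistics for each combination of polar stripe
    (inner/outer radius half) x direction (radius/angle) x pair distance
    (1, 2).
``hist_intensity`` / ``hist_curvature``
    64-bin histograms of normalized intensity and of intensity-surface
    principal curvature (Hessian eigenvalues); their concatenation is the
    128-dim comparison set (``ersoy``).
``proposed``
    ``basic_hist`` concatenated with ``haralick_polar``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import measure as skmeasure

from .io_config import IntensityImage, PipelineConfig

logger = logging.getLogger("pcnaphase")

FEATURE_SET_IDS = ("basic_hist", "haralick_polar", "hist_intensity",
                   "hist_curvature", "proposed", "ersoy")

HARALICK_NAMES = (
    "asm", "contrast", "correlation", "variance", "idm", "sum_average",
    "sum_variance", "sum_entropy", "entropy", "difference_variance",
    "difference_entropy", "imc1", "imc2",
)


@dataclass
class NucleusSegment:
    """One segmented nucleus: mask crop, its placement, and intensities."""

    id: int
    mask: np.ndarray            # boolean, bbox-local
    bbox: tuple[int, int, int, int]   # (row0, col0, row1, col1), half-open
    centroid: tuple[float, float]     # (x, y), global coordinates
    intensities: np.ndarray     # 1-D masked intensity sample

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def segments_from_labels(image: IntensityImage | np.ndarray,
                         labels: np.ndarray) -> list[NucleusSegment]:
    """Build one :class:`NucleusSegment` per label, in label order."""
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    labels = np.asarray(labels)
    segments = []
    for obj_id, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == obj_id
        rows, cols = np.nonzero(mask)
        cy = rows.mean() + sl[0].start
        cx = cols.mean() + sl[1].start
        segments.append(NucleusSegment(
            id=obj_id, mask=mask,
            bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            centroid=(float(cx), float(cy)),
            intensities=pixels[sl][mask].astype(np.float64),
        ))
    return segments


@dataclass
class PolarImage:
    """Resampling of a segment onto (radius, angle) axes.

    ``values[i, j]`` is the intensity at angle ``2*pi*i/n_angle`` and radius
    ``(j + 0.5) / n_radius * r_max`` from the centroid; ``valid`` flags
    samples inside the segment mask. The angle axis is sampled finely enough
    (``n_angle >= ceil(2*pi*r_max)``) that every segment pixel is visited at
    least once.
    """

    values: np.ndarray          # (n_angle, n_radius)
    valid: np.ndarray           # boolean, same shape
    center: tuple[float, float]
    r_max: float


def to_polar(image: IntensityImage | np.ndarray, segment: NucleusSegment,
             n_radius: int = 32) -> PolarImage:
    """Bilinear polar resampling of one nucleus about its centroid."""
    if segment.area == 0:
        raise ValueError("zero-area segment")
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    r0, c0, r1, c1 = segment.bbox
    cx, cy = segment.centroid
    # r_max from the sub-pixel boundary: stable under rotation/resampling
    padded = np.pad(segment.mask.astype(np.float64), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if contours:
        boundary = max(contours, key=len)
        bx = boundary[:, 1] - 1.0 + c0
        by = boundary[:, 0] - 1.0 + r0
        r_max = float(np.hypot(bx - cx, by - cy).max())
    else:
        rows, cols = np.nonzero(segment.mask)
        r_max = float(np.hypot(cols + c0 - cx, rows + r0 - cy).max()) + 0.5
    # multiple of 4 so a 90-degree rotation is an exact cyclic shift
    n_angle = max(4 * int(np.ceil(np.pi * r_max / 2)), 16)
    radii = (np.arange(n_radius) + 0.5) / n_radius * r_max
    angles = 2 * np.pi * np.arange(n_angle) / n_angle
    xs = cx + radii[None, :] * np.cos(angles[:, None])
    ys = cy + radii[None, :] * np.sin(angles[:, None])
    values = ndi.map_coordinates(pixels.astype(np.float64), [ys, xs],
                                 order=1, mode="nearest")
    full_mask = np.zeros(pixels.shape, dtype=np.float64)
    full_mask[r0:r1, c0:c1][segment.mask] = 1.0
    # conservative validity: the whole bilinear support of a sample must lie
    # inside the mask, so no background leaks into valid intensities
    valid = ndi.map_coordinates(full_mask, [ys, xs], order=1,
                                mode="constant") > 1.0 - 1e-9
    return PolarImage(values=values, valid=valid, center=(cx, cy), r_max=r_max)


def zone_means(polar: PolarImage, n_zones: int = 8) -> np.ndarray:
    """Mean valid intensity in each of ``n_zones`` equal radius bands,
    inner to outer. An empty zone borrows the nearest valid zone's value."""
    if n_zones < 2:
        raise ValueError("n_zones must be >= 2")
    n_radius = polar.values.shape[1]
    edges = np.linspace(0, n_radius, n_zones + 1).astype(int)
    means = np.full(n_zones, np.nan)
    for z in range(n_zones):
        sl = slice(edges[z], max(edges[z + 1], edges[z] + 1))
        v = polar.values[:, sl][polar.valid[:, sl]]
        if v.size:
            means[z] = v.mean()
    if np.isnan(means).any():
        valid_idx = np.flatnonzero(~np.isnan(means))
        if valid_idx.size == 0:
            raise ValueError("polar image has no valid samples")
        for z in np.flatnonzero(np.isnan(means)):
            nearest = valid_idx[np.argmin(np.abs(valid_idx - z))]
            means[z] = means[nearest]
            logger.warning("zone %d empty; borrowed zone %d", z, nearest)
    return means


def basic_histogram_features(segment: NucleusSegment) -> np.ndarray:
    """Min, max, mean, population variance, skewness, kurtosis of the masked
    intensities. Skewness/kurtosis are the standardized 3rd/4th central
    moments (kurtosis non-excess, so a Gaussian gives ~3); a zero-variance
    sample yields skewness = kurtosis = 0 by convention."""
    v = segment.intensities
    if v.size < 2:
        raise ValueError("segment needs >= 2 pixels")
    mean = v.mean()
    var = v.var()
    if var <= 0:
        skew = kurt = 0.0
    else:
        c = v - mean
        skew = float((c ** 3).mean() / var ** 1.5)
        kurt = float((c ** 4).mean() / var ** 2)
    return np.array([v.min(), v.max(), mean, var, skew, kurt], dtype=np.float64)


def intensity_histogram(segment: NucleusSegment, n_bins: int = 64) -> np.ndarray:
    """Min-max-normalized intensity histogram, frequencies summing to 1.
    A constant segment puts all mass in the first bin."""
    v = segment.intensities
    if v.size == 0:
        raise ValueError("empty segment")
    lo, hi = v.min(), v.max()
    if hi <= lo:
        h = np.zeros(n_bins)
        h[0] = 1.0
        logger.warning("constant segment %d: degenerate intensity histogram",
                       segment.id)
        return h
    h, _ = np.histogram((v - lo) / (hi - lo), bins=n_bins, range=(0.0, 1.0))
    return h / h.sum()


def principal_curvatures(image: IntensityImage | np.ndarray,
                         segment: NucleusSegment, sigma: float) -> np.ndarray:
    """Both Hessian eigenvalues of the Gaussian-smoothed intensity surface at
    every masked pixel, pooled into one sample (2 values per pixel).

    Foci appear as strong negative-curvature extrema; flat regions are ~0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    r0, c0, r1, c1 = segment.bbox
    pad = int(np.ceil(4 * sigma))
    if (r1 - r0) < pad or (c1 - c0) < pad:
        raise ValueError(f"segment smaller than the {pad}-px filter support")
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r1 + pad, pixels.shape[0]), min(c1 + pad, pixels.shape[1])
    crop = pixels[rr0:rr1, cc0:cc1].astype(np.float64)
    ixx = ndi.gaussian_filter(crop, sigma, order=(0, 2))
    iyy = ndi.gaussian_filter(crop, sigma, order=(2, 0))
    ixy = ndi.gaussian_filter(crop, sigma, order=(1, 1))
    sub = (slice(r0 - rr0, r0 - rr0 + (r1 - r0)),
           slice(c0 - cc0, c0 - cc0 + (c1 - c0)))
    m = segment.mask
    a, b, c = ixx[sub][m], iyy[sub][m], ixy[sub][m]
    half_tr = 0.5 * (a + b)
    root = np.sqrt(0.25 * (a - b) ** 2 + c ** 2)
    return np.concatenate([half_tr + root, half_tr - root])


def curvature_histogram(image: IntensityImage | np.ndarray,
                        segment: NucleusSegment, sigma: float = 1.5,
                        n_bins: int = 64) -> np.ndarray:
    """64-bin histogram of intensity-surface principal curvature, over a
    symmetric range clipped at the 99th percentile of |curvature|;
    frequencies sum to 1 (clipped values land in the edge bins)."""
    k = principal_curvatures(image, segment, sigma)
    c = float(np.percentile(np.abs(k), 99))
    if c <= 0:
        c = max(float(np.abs(k).max()), 1e-12)
    h, _ = np.histogram(np.clip(k, -c, c), bins=n_bins, range=(-c, c))
    return h / h.sum()


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

@dataclass
class GLCM:
    """Symmetric normalized gray-level co-occurrence matrix built from valid
    polar-pixel pairs only."""

    levels: int
    distance: int
    direction: str              # "horizontal" (radius) | "vertical" (angle)
    matrix: np.ndarray          # (levels, levels), entries sum to 1


def _quantize(values: np.ndarray, valid: np.ndarray, levels: int) -> np.ndarray:
    """Bin valid intensities into ``levels`` gray levels over a robust
    (2nd-98th percentile) range; the percentile range keeps the binning
    stable against the few extreme edge samples whose depth depends on
    mask discretization."""
    v = values[valid]
    if v.size == 0:
        return np.zeros_like(values, dtype=np.int64)
    lo, hi = np.percentile(v, [2.0, 98.0])
    if hi - lo <= 1e-9 * max(1.0, abs(hi)):  # constant up to float jitter
        return np.zeros_like(values, dtype=np.int64)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def glcm(polar: PolarImage, levels: int = 32, d: int = 1,
         direction: str = "horizontal") -> GLCM:
    """Co-occurrence of quantized intensities at offset ``d`` along one polar
    axis. ``horizontal`` pairs along the radius (x) axis; ``vertical`` pairs
    along the cyclic angle (y) axis, wrapping around. Counts are
    symmetrized and normalized to sum 1; both pixels of a pair must be valid.
    """
    if levels < 2 or d < 1:
        raise ValueError("levels must be >= 2 and d >= 1")
    q = _quantize(polar.values, polar.valid, levels)
    valid = polar.valid
    if direction == "horizontal":
        a, b = q[:, :-d], q[:, d:]
        va, vb = valid[:, :-d], valid[:, d:]
    elif direction == "vertical":
        a, b = q, np.roll(q, -d, axis=0)
        va, vb = valid, np.roll(valid, -d, axis=0)
    else:
        raise ValueError(f"unknown GLCM direction {direction!r}")
    ok = va & vb
    if not ok.any():
        raise ValueError("no valid pixel pairs for GLCM")
    i, j = a[ok], b[ok]
    mat = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(mat, (i, j), 1.0)
    mat = mat + mat.T
    mat /= mat.sum()
    return GLCM(levels=levels, distance=d, direction=direction, matrix=mat)


def haralick_features(g: GLCM | np.ndarray) -> np.ndarray:
    """The 13 classical Haralick texture statistics of a normalized GLCM
    (the numerically unstable maximal correlation coefficient is excluded).

    Degenerate conventions for finiteness: correlation of a zero-variance
    GLCM is 1; the information measures of correlation are 0 when the
    marginal entropy vanishes. Natural logarithms throughout.
    """
    p = g.matrix if isinstance(g, GLCM) else np.asarray(g, dtype=np.float64)
    n = p.shape[0]
    if p.shape != (n, n) or abs(p.sum() - 1.0) > 1e-8 or (p < 0).any():
        raise ValueError("GLCM must be square, non-negative, summing to 1")
    idx = np.arange(n, dtype=np.float64)
    i = idx[:, None] * np.ones((1, n))
    j = np.ones((n, 1)) * idx[None, :]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.dot(idx, px))
    mu_y = float(np.dot(idx, py))
    sd_x = float(np.sqrt(np.dot((idx - mu_x) ** 2, px)))
    sd_y = float(np.sqrt(np.dot((idx - mu_y) ** 2, py)))

    def xlogx(v):
        v = np.asarray(v)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log(v[nz])
        return out

    # p_{x+y}(k), k = 0 .. 2n-2 ; p_{x-y}(k), k = 0 .. n-1
    ksum = (i + j).astype(np.int64)
    kdiff = np.abs(i - j).astype(np.int64)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=n)
    ks = np.arange(2 * n - 1, dtype=np.float64)
    kd = np.arange(n, dtype=np.float64)

    asm = float((p ** 2).sum())
    contrast = float(np.dot(kd ** 2, p_diff))
    if sd_x * sd_y > 0:
        correlation = float(((i - mu_x) * (j - mu_y) * p).sum() / (sd_x * sd_y))
    else:
        correlation = 1.0
    variance = float(((i - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2)).sum())
    sum_avg = float(np.dot(ks, p_sum))
    sum_var = float(np.dot((ks - sum_avg) ** 2, p_sum))
    sum_ent = float(-xlogx(p_sum).sum())
    entropy = float(-xlogx(p).sum())
    diff_mean = float(np.dot(kd, p_diff))
    diff_var = float(np.dot((kd - diff_mean) ** 2, p_diff))
    diff_ent = float(-xlogx(p_diff).sum())
    hx = float(-xlogx(px).sum())
    hy = float(-xlogx(py).sum())
    pxy = px[:, None] * py[None, :]
    nzb = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nzb] * np.log(pxy[nzb])).sum())
    hxy2 = float(-xlogx(pxy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))
    return np.array([asm, contrast, correlation, variance, idm, sum_avg,
                     sum_var, sum_ent, entropy, diff_var, diff_ent,
                     imc1, imc2], dtype=np.float64)


def haralick_polar_vector(image: IntensityImage | np.ndarray,
                          segment: NucleusSegment,
                          config: PipelineConfig | None = None
                          ) -> tuple[np.ndarray, list[str]]:
    """The 104-dim rotation-invariant texture descriptor.

    The polar image is split into two equal-width radius stripes (inner,
    outer); for each stripe x direction {horizontal, vertical} x distance
    {1, 2}, the 13 Haralick statistics are computed on the stripe's GLCM:
    2 x 2 x 2 x 13 = 104 values, ordered stripe-major, then direction, then
    distance, then statistic.
    """
    config = config or PipelineConfig()
    fp = config.features
    polar = to_polar(image, segment, config.polar.n_radius)
    n_radius = polar.values.shape[1]
    half = n_radius // 2
    max_d = max(fp.glcm_distances)
    if half <= max_d:
        raise ValueError("polar stripe narrower than the maximal GLCM distance")
    stripes = {
        "inner": (polar.values[:, :half], polar.valid[:, :half]),
        "outer": (polar.values[:, half:], polar.valid[:, half:]),
    }
    values: list[float] = []
    names: list[str] = []
    for stripe, (vals, valid) in stripes.items():
        sub = PolarImage(values=vals, valid=valid, center=polar.center,
                         r_max=polar.r_max)
        for direction in ("horizontal", "vertical"):
            for d in fp.glcm_distances:
                g = glcm(sub, fp.glcm_levels, d, direction)
                feats = haralick_features(g)
                values.extend(feats.tolist())
                names.extend(f"har_{stripe}_{direction[0]}_d{d}_{nm}"
                             for nm in HARALICK_NAMES)
    return np.asarray(values), names


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _basic_hist_block(image, segment, config) -> tuple[np.ndarray, list[str]]:
    vals = basic_histogram_features(segment)
    names = ["min", "max", "mean", "variance", "skewness", "kurtosis"]
    if config.features.include_zone_means:
        polar = to_polar(image, segment, config.polar.n_radius)
        zm = zone_means(polar, config.polar.n_zones)
        vals = np.concatenate([vals, zm])
        names += [f"zone_mean_{z}" for z in range(len(zm))]
    return vals, names


def assemble_features(image: IntensityImage | np.ndarray,
                      segment: NucleusSegment, feature_set_id: str,
                      config: PipelineConfig | None = None
                      ) -> tuple[np.ndarray, list[str]]:
    """Compute one named feature vector for a nucleus.

    ``proposed`` = basic_hist (with zone means) + haralick_polar;
    ``ersoy`` = hist_intensity + hist_curvature (the 128-dim comparison set).
    """
    config = config or PipelineConfig()
    fp = config.features
    if feature_set_id not in FEATURE_SET_IDS:
        raise ValueError(f"unknown feature set {feature_set_id!r}; "
                         f"expected one of {FEATURE_SET_IDS}")
    if feature_set_id == "basic_hist":
        return _basic_hist_block(image, segment, config)
    if feature_set_id == "haralick_polar":
        return haralick_polar_vector(image, segment, config)
    if feature_set_id == "hist_intensity":
        v = intensity_histogram(segment, fp.n_histogram_bins)
        return v, [f"ihist_{b}" for b in range(len(v))]
    if feature_set_id == "hist_curvature":
        v = curvature_histogram(image, segment, fp.curvature_sigma,
                                fp.n_histogram_bins)
        return v, [f"chist_{b}" for b in range(len(v))]
    if feature_set_id == "proposed":
        v1, n1 = _basic_hist_block(image, segment, config)
        v2, n2 = haralick_polar_vector(image, segment, config)
        return np.concatenate([v1, v2]), n1 + n2
    # ersoy
    v1, n1 = assemble_features(image, segment, "hist_intensity", config)
    v2, n2 = assemble_features(image, segment, "hist_curvature", config)
    return np.concatenate([v1, v2]), n1 + n2


def compute_feature_table(image: IntensityImage | np.ndarray,
                          labels: np.ndarray, feature_set_id: str = "proposed",
                          config: PipelineConfig | None = None):
    """Feature matrix for every labelled nucleus: DataFrame indexed by
    segment id with named feature columns."""
    import pandas as pd

    config = config or PipelineConfig()
    rows, index, names = [], [], None
    for segment in segments_from_labels(image, labels):
        vals, names = assemble_features(image, segment, feature_set_id, config)
        rows.append(vals)
        index.append(segment.id)
    if not rows:
        raise ValueError("no segments in label mask")
    return pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="segment_id"),
                        columns=names)
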