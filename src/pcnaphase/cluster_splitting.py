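"""Splitting touching-nucleus clusters between concave contour points.

Touching nuclei merge into single segments during thresholding. The geometric
splitter locates concavities (curvature maxima of the segment outline), forms
chord hypotheses between concave point pairs subject to four admissibility
constraints (anti-parallel normals, non-intersecting interior chords, convex
parts, minimal cluster size), scores hypotheses with a convexity-deficit plus
chord-length cost, and accepts the best hypothesis only if it beats leaving
the object unsplit by a margin. A classical watershed on the negated
Euclidean distance transform is provided as the comparison baseline; it
splits circular objects well but is sensitive to fringy segmentation borders.

The cost of a hypothesis with parts :math:`S_1..S_n` and chords :math:`c_j`:

.. math::
    J = \\sum_i \\Big(1 - \\frac{|S_i|}{|\\mathrm{conv}(S_i)|}\\Big)
        + \\lambda \\frac{\\sum_j \\mathrm{len}(c_j)}{\\mathrm{perimeter}}

Lower is better; a perfect split of overlapping convex nuclei has near-zero
convexity deficit and short chords.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage.feature import peak_local_max
from skimage.morphology import convex_hull_image
from skimage.segmentation import watershed

from .io_config import PipelineConfig, SplittingParams

logger = logging.getLogger("pcnaphase")


@dataclass
class Contour:
    """Closed boundary polyline of one labelled object, counter-clockwise
    in (x, y) coordinates (positive shoelace area); first point not repeated."""

    points: np.ndarray          # (N, 2) float, columns (x, y)
    source_label: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("contour points must be (N, 2)")
        if len(self.points) < 8:
            raise ValueError("contour has fewer than 8 points")

    @property
    def length(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def signed_area(self) -> float:
        x, y = self.points[:, 0], self.points[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        return float(0.5 * np.sum(x * yn - xn * y))


@dataclass(frozen=True)
class SplitPoint:
    """A concavity on the contour: candidate endpoint of a split chord."""

    contour_index: int
    position: tuple[float, float]       # (x, y)
    curvature: float                    # concave-positive [1/px]
    inward_normal: tuple[float, float]  # unit vector into the object


@dataclass
class SplitHypothesis:
    """A candidate partition of a cluster into ``n_parts`` pixel sets."""

    n_parts: int
    split_pairs: tuple[tuple[SplitPoint, SplitPoint], ...]
    parts: list[np.ndarray]             # boolean masks, full image shape
    constraint_flags: dict = field(default_factory=dict)
    cost: float = np.inf

    @property
    def admissible(self) -> bool:
        return all(self.constraint_flags.get(k, False) for k in
                   ("anti_parallel", "non_intersection", "convexity", "size"))


def extract_contour(labels: np.ndarray, label: int) -> Contour:
    """Outer boundary of one labelled object at half-pixel resolution,
    counter-clockwise; interior holes are ignored."""
    labels = np.asarray(labels)
    mask = labels == label
    if not mask.any():
        raise ValueError(f"label {label} absent from mask")
    padded = np.pad(mask.astype(np.float64), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError(f"label {label}: no contour found")
    rc = max(contours, key=len)         # outer boundary; holes are shorter
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    pts = np.column_stack([rc[:, 1] - 1.0, rc[:, 0] - 1.0])  # (x, y), unpad
    c = Contour(pts, source_label=int(label))
    if c.signed_area() < 0:
        c.points = c.points[::-1].copy()
    return c


def contour_curvature(contour: Contour, smoothing_scale: float) -> np.ndarray:
    """Signed curvature per vertex of the Gaussian-smoothed closed polyline.

    Sign convention: concavities of the object are positive, so a convex
    circle of radius r has curvature ``-1/r`` everywhere.
    """
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    pts = contour.points
    seg = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    mean_step = float(np.hypot(seg[:, 0], seg[:, 1]).mean())
    sigma = smoothing_scale / max(mean_step, 1e-9)
    if sigma > 0:
        x = ndi.gaussian_filter1d(pts[:, 0], sigma, mode="wrap")
        y = ndi.gaussian_filter1d(pts[:, 1], sigma, mode="wrap")
    else:
        x, y = pts[:, 0], pts[:, 1]
    dx = ndi.gaussian_filter1d(x, max(sigma, 1.0), order=1, mode="wrap")
    dy = ndi.gaussian_filter1d(y, max(sigma, 1.0), order=1, mode="wrap")
    ddx = ndi.gaussian_filter1d(x, max(sigma, 1.0), order=2, mode="wrap")
    ddy = ndi.gaussian_filter1d(y, max(sigma, 1.0), order=2, mode="wrap")
    speed2 = dx * dx + dy * dy
    # filters above are in units of vertex index; curvature needs arc length
    kappa = (dx * ddy - dy * ddx) / np.maximum(speed2, 1e-12) ** 1.5
    return -kappa  # CCW convex -> negative


def _inward_normals(contour: Contour, sigma_vertices: float) -> np.ndarray:
    pts = contour.points
    dx = ndi.gaussian_filter1d(pts[:, 0], max(sigma_vertices, 1.0), order=1, mode="wrap")
    dy = ndi.gaussian_filter1d(pts[:, 1], max(sigma_vertices, 1.0), order=1, mode="wrap")
    t = np.column_stack([dx, dy])
    t /= np.maximum(np.hypot(t[:, 0], t[:, 1]), 1e-12)[:, None]
    # CCW (positive shoelace): interior is to the left of travel
    return np.column_stack([-t[:, 1], t[:, 0]])


def find_split_points(contour: Contour, kappa_min: float,
                      smoothing_scale: float = 2.0,
                      nms_window: int = 5,
                      max_points: int | None = 12) -> list[SplitPoint]:
    """Concave curvature maxima above ``kappa_min``, non-maximum-suppressed
    within a circular window of ``nms_window`` vertices. At most
    ``max_points`` strongest concavities are returned (combinatorial guard
    for the hypothesis search)."""
    kappa = contour_curvature(contour, smoothing_scale)
    n = len(kappa)
    seg = np.diff(np.vstack([contour.points, contour.points[:1]]), axis=0)
    mean_step = float(np.hypot(seg[:, 0], seg[:, 1]).mean())
    normals = _inward_normals(contour, smoothing_scale / max(mean_step, 1e-9))
    out: list[SplitPoint] = []
    for i in range(n):
        if kappa[i] < kappa_min:
            continue
        window = kappa[(np.arange(i - nms_window, i + nms_window + 1)) % n]
        if kappa[i] < window.max():
            continue
        if kappa[i] == window.max():
            # tie within window: keep only the lowest index
            idx = np.arange(i - nms_window, i + nms_window + 1) % n
            winners = idx[window == window.max()]
            if i != winners.min() and kappa[(i - 1) % n] == kappa[i]:
                continue
        out.append(SplitPoint(
            contour_index=i,
            position=(float(contour.points[i, 0]), float(contour.points[i, 1])),
            curvature=float(kappa[i]),
            inward_normal=(float(normals[i, 0]), float(normals[i, 1])),
        ))
    if max_points is not None and len(out) > max_points:
        out = sorted(out, key=lambda p: -p.curvature)[:max_points]
        out.sort(key=lambda p: p.contour_index)
    return out


# ---------------------------------------------------------------------------
# Constraints
# ---------------------------------------------------------------------------

def anti_parallel(p: SplitPoint, q: SplitPoint, theta_max_deg: float) -> bool:
    """True iff each point's inward normal points toward the partner within
    ``theta_max_deg``; rejects point pairs on the same side of the object."""
    u = np.array(q.position) - np.array(p.position)
    norm = np.hypot(*u)
    if norm < 1e-9:
        return False
    u = u / norm
    cos_max = np.cos(np.deg2rad(theta_max_deg))
    ok_p = float(np.dot(p.inward_normal, u)) >= cos_max
    ok_q = float(np.dot(q.inward_normal, -u)) >= cos_max
    return ok_p and ok_q


def _segments_cross(a1, a2, b1, b2) -> bool:
    """Proper intersection test for open segments (shared endpoints allowed)."""
    def orient(p, q, r):
        return np.sign((q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0]))
    if any(np.allclose(x, y) for x in (a1, a2) for y in (b1, b2)):
        return False
    return (orient(a1, a2, b1) * orient(a1, a2, b2) < 0
            and orient(b1, b2, a1) * orient(b1, b2, a2) < 0)


def chord_interior(mask: np.ndarray, p: SplitPoint, q: SplitPoint,
                   margin: float = 1.5) -> bool:
    """True iff the open chord (excluding a margin near the endpoints) stays
    inside the object."""
    a = np.array(p.position)
    b = np.array(q.position)
    length = np.hypot(*(b - a))
    if length <= 2 * margin:
        return True
    n = max(int(length), 2)
    ts = np.linspace(margin / length, 1 - margin / length, n)
    pts = a[None, :] + ts[:, None] * (b - a)[None, :]
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[0] - 1)
    return bool(mask[rows, cols].all())


def solidity(mask: np.ndarray) -> float:
    """Area over convex-hull area of a boolean mask."""
    area = int(mask.sum())
    if area == 0:
        return 0.0
    if area < 6:
        return 1.0  # too few pixels for a meaningful hull; trivially convex
    rows, cols = np.nonzero(mask)
    sl = (slice(rows.min(), rows.max() + 1), slice(cols.min(), cols.max() + 1))
    # pixel-center hull: a rasterized convex shape scores exactly 1
    hull = convex_hull_image(mask[sl], offset_coordinates=False)
    return area / float(hull.sum())


def _cut_mask(mask: np.ndarray,
              pairs: tuple[tuple[SplitPoint, SplitPoint], ...],
              n_parts: int) -> list[np.ndarray] | None:
    """Cut the mask along straight chords; pixels on a chord go to the part
    on the chord's left (fallback: nearest part). Returns ``n_parts`` full-
    size boolean masks or None if the cut does not yield ``n_parts`` pieces."""
    barrier = np.zeros_like(mask, dtype=bool)
    for p, q in pairs:
        a = np.array(p.position, dtype=float)
        b = np.array(q.position, dtype=float)
        u = b - a
        norm = np.hypot(*u)
        if norm > 1e-9:
            # overshoot both endpoints so the barrier reaches the background
            # (contour vertices sit half a pixel outside the mask)
            u = u / norm
            a = a - 2.0 * u
            b = b + 2.0 * u
        rr, cc = skdraw.line(int(round(a[1])), int(round(a[0])),
                             int(round(b[1])), int(round(b[0])))
        inside = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
        barrier[rr[inside], cc[inside]] = True
    barrier &= mask
    cut = mask & ~barrier
    # 4-connectivity so that the 8-connected chord raster truly separates
    lab, n = ndi.label(cut, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n < n_parts:
        return None
    if n > n_parts:
        # the barrier may shave small corner slivers off; keep the n_parts
        # largest pieces and fold each sliver into its nearest kept piece
        sizes = np.bincount(lab.ravel())[1:]
        order = np.argsort(sizes, kind="stable")[::-1] + 1
        keep = set(order[:n_parts].tolist())
        if sizes[order[n_parts - 1] - 1] < 6:
            return None  # a "part" that is itself a sliver: not a real cut
        remap = np.zeros(n + 1, dtype=np.int32)
        for rank, old in enumerate(sorted(keep), start=1):
            remap[old] = rank
        kept_lab = remap[lab]
        sliver = (lab > 0) & (kept_lab == 0)
        if sliver.any():
            _, (ir, ic) = ndi.distance_transform_edt(kept_lab == 0,
                                                     return_indices=True)
            kept_lab[sliver] = kept_lab[ir[sliver], ic[sliver]]
        lab = kept_lab
        n = n_parts
    # assign barrier pixels: prefer the neighbor on the chord's left
    rows, cols = np.nonzero(barrier)
    assigned = lab.copy()
    if rows.size:
        # nearest labelled pixel by EDT (deterministic) with left-preference pass
        for p, q in pairs:
            d = np.array(q.position) - np.array(p.position)
            nrm = np.hypot(*d)
            if nrm < 1e-9:
                continue
            left = np.array([d[1], -d[0]]) / nrm
            sc, sr = int(np.round(left[0])), int(np.round(left[1]))
            r2 = np.clip(rows + sr, 0, mask.shape[0] - 1)
            c2 = np.clip(cols + sc, 0, mask.shape[1] - 1)
            vals = assigned[r2, c2]
            sel = (assigned[rows, cols] == 0) & (vals > 0)
            assigned[rows[sel], cols[sel]] = vals[sel]
        still = assigned == 0
        still &= mask
        if still.any():
            _, (ir, ic) = ndi.distance_transform_edt(lab == 0, return_indices=True)
            assigned[still] = lab[ir[still], ic[still]]
    return [assigned == i for i in range(1, n_parts + 1)]


def check_constraints(mask: np.ndarray,
                      pairs: tuple[tuple[SplitPoint, SplitPoint], ...],
                      parts: list[np.ndarray] | None,
                      params: SplittingParams) -> dict:
    """Evaluate the four admissibility flags for a chord set / hypothesis."""
    n_parts = len(pairs) + 1
    flags = {
        "anti_parallel": all(anti_parallel(p, q, params.theta_max_deg)
                             for p, q in pairs),
        "non_intersection": True,
        "convexity": False,
        "size": float(mask.sum()) >= n_parts * params.min_area,
    }
    for (p1, q1), (p2, q2) in itertools.combinations(pairs, 2):
        if _segments_cross(p1.position, q1.position, p2.position, q2.position):
            flags["non_intersection"] = False
    if flags["non_intersection"]:
        flags["non_intersection"] = all(chord_interior(mask, p, q) for p, q in pairs)
    if parts is not None and len(parts) == n_parts:
        flags["convexity"] = all(solidity(pm) >= params.c_min for pm in parts)
    return flags


def hypothesis_cost(h: SplitHypothesis, perimeter: float,
                    chord_weight: float) -> float:
    """Convexity deficit of the parts plus weighted relative chord length."""
    if not h.admissible:
        raise ValueError("cost is defined only for admissible hypotheses")
    deficit = sum(1.0 - solidity(p) for p in h.parts)
    chord_len = sum(
        float(np.hypot(q.position[0] - p.position[0], q.position[1] - p.position[1]))
        for p, q in h.split_pairs)
    return deficit + chord_weight * chord_len / max(perimeter, 1e-9)


def candidate_chords(mask: np.ndarray, points: list[SplitPoint],
                     params: SplittingParams) -> list[tuple[SplitPoint, SplitPoint]]:
    """Split-point pairs passing the anti-parallel and interior checks."""
    return [
        (p, q) for p, q in itertools.combinations(points, 2)
        if anti_parallel(p, q, params.theta_max_deg)
        and chord_interior(mask, p, q)
    ]


def _enumerate_hypotheses(mask: np.ndarray, points: list[SplitPoint],
                          n_parts: int, params: SplittingParams,
                          perimeter: float,
                          chords_pool: list | None = None
                          ) -> list[SplitHypothesis]:
    """All admissible hypotheses with ``n_parts`` parts (``n_parts - 1``
    chords drawn from anti-parallel point pairs)."""
    cand_pairs = (chords_pool if chords_pool is not None
                  else candidate_chords(mask, points, params))
    combos = itertools.combinations(cand_pairs, n_parts - 1)
    hypotheses: list[SplitHypothesis] = []
    n_seen = 0
    for chords in combos:
        n_seen += 1
        if n_seen > params.max_hypotheses:
            logger.warning("hypothesis enumeration capped at %d", params.max_hypotheses)
            break
        used = [pt.contour_index for pq in chords for pt in pq]
        if len(set(used)) < len(used):
            continue  # a split point may anchor only one chord
        parts = _cut_mask(mask, chords, n_parts)
        if parts is None:
            continue
        flags = check_constraints(mask, chords, parts, params)
        h = SplitHypothesis(n_parts=n_parts, split_pairs=chords, parts=parts,
                            constraint_flags=flags)
        if h.admissible:
            h.cost = hypothesis_cost(h, perimeter, params.chord_weight)
            hypotheses.append(h)
    return hypotheses


def split_cluster(labels: np.ndarray, label: int,
                  config: PipelineConfig | None = None) -> list[np.ndarray]:
    """Split one labelled object into nucleus parts by the geometric method.

    Iterates n = 2, 3, ... ``n_max``: at each n all admissible hypotheses
    from split-point chords are enumerated and the minimum-cost one kept;
    the search stops when increasing n no longer reduces the cost. The best
    split is accepted only if it improves on the unsplit object's convexity
    deficit by the margin ``accept_margin``; otherwise the object is
    returned unsplit. Deterministic given the configuration.
    """
    config = config or PipelineConfig()
    params = config.splitting
    mask = np.asarray(labels) == label
    if not mask.any():
        raise ValueError(f"label {label} absent from mask")
    try:
        contour = extract_contour(labels, label)
    except ValueError:
        return [mask]
    points = find_split_points(contour, params.kappa_min,
                               params.curvature_sigma, params.nms_window,
                               params.max_split_points)
    if len(points) < 2:
        return [mask]
    perimeter = contour.length
    unsplit_cost = 1.0 - solidity(mask)
    best: SplitHypothesis | None = None
    prev_cost = np.inf
    pool = candidate_chords(mask, points, params)
    for n_parts in range(2, params.n_max + 1):
        if len(points) < 2 * (n_parts - 1):
            break
        hyps = _enumerate_hypotheses(mask, points, n_parts, params, perimeter,
                                     chords_pool=pool)
        if not hyps:
            break
        if n_parts == 2:
            # prune the chord pool for higher n by single-chord cost
            # (combinatorial guard on jagged contours)
            ranked = sorted(hyps, key=lambda h: h.cost)
            good = [h.split_pairs[0] for h in ranked]
            rest = [c for c in pool
                    if all(c is not g for g in good)]
            pool = (good + rest)[:16]
        top = min(hyps, key=lambda h: h.cost)
        if top.cost >= prev_cost:
            break
        prev_cost = top.cost
        best = top
    if best is None or best.cost >= unsplit_cost - params.accept_margin:
        logger.info("split_cluster label=%d: kept unsplit (cost %.3f)",
                    label, unsplit_cost)
        return [mask]
    logger.info("split_cluster label=%d: %d parts, cost %.3f vs unsplit %.3f",
                label, best.n_parts, best.cost, unsplit_cost)
    return best.parts


def watershed_split(labels: np.ndarray, label: int,
                    min_distance: int = 5) -> list[np.ndarray]:
    """Baseline: watershed of the negated Euclidean distance transform of the
    object's mask, seeded at distance-map regional maxima."""
    mask = np.asarray(labels) == label
    if not mask.any():
        raise ValueError(f"label {label} absent from mask")
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=mask,
                           exclude_border=False)
    if len(peaks) <= 1:
        return [mask]
    markers = np.zeros_like(mask, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    ws = watershed(-dist, markers, mask=mask)
    return [ws == i for i in range(1, len(peaks) + 1) if (ws == i).any()]


def split_labels(labels: np.ndarray, config: PipelineConfig | None = None,
                 method: str = "geometric") -> np.ndarray:
    """Apply cluster splitting to every object of a label mask; the result is
    relabeled 1..K in raster order. ``method``: geometric | watershed."""
    config = config or PipelineConfig()
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for label in range(1, int(labels.max()) + 1):
        if not (labels == label).any():
            continue
        if method == "geometric":
            parts = split_cluster(labels, label, config)
        elif method == "watershed":
            parts = watershed_split(labels, label)
        else:
            raise ValueError(f"unknown split method {method!r}")
        for part in parts:
            out[part] = next_label
            next_label += 1
    return _relabel_raster(out)


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    n = int(labels.max())
    if n == 0:
        return labels.astype(np.int32)
    flat = labels.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    first[flat[nz[::-1]]] = nz[::-1]
    present = np.flatnonzero(first[1:] < flat.size)
    order = present[np.argsort(first[1:][present], kind="stable")]
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order + 1] = np.arange(1, len(order) + 1)
    return remap[labels]
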