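"""Synthetic fluorescence scenes of PCNA-immunolabeled nuclei.

Generates images that emulate the four phase-specific PCNA distribution
patterns so that every pipeline stage is testable with exact ground truth:

* ``G``: PCNA spread homogeneously over the whole nucleus (smooth signal,
  no foci);
* ``EARLY_S``: many small foci (80-150, Gaussian width 0.8-1.5 px) spread
  uniformly over the nucleus;
* ``MID_S``: foci at the nuclear periphery (40-100, width 1-2 px, normalized
  radius 0.75-0.98);
* ``LATE_S``: few large foci near the center (5-15, width 2-4 px, normalized
  radius < 0.5).

Nuclei are ellipses with random axes and orientation; a configurable fraction
is placed in touching pairs with a controlled overlap depth, which the
cluster-splitting stage must resolve. The composite is blurred with a
mode-specific Gaussian PSF (confocal narrow, widefield wide, plus an
out-of-focus haze in widefield), then Poisson and Gaussian noise are applied.
Foci are isotropic Gaussians with log-normal amplitudes — a deliberately
simple model of replication foci, not physically accurate optics.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

from .io_config import (IntensityImage, PhaseLabel, PointAnnotation,
                        write_annotations, write_image)

logger = logging.getLogger("pcnaphase")

#: Per-phase focus parameters: (count range, width range [px], radial placement)
PHASE_FOCUS_SPECS = {
    PhaseLabel.G: (None, None, None),
    PhaseLabel.EARLY_S: ((80, 150), (0.8, 1.5), (0.0, 1.0)),
    PhaseLabel.MID_S: ((40, 100), (1.0, 2.0), (0.75, 0.98)),
    PhaseLabel.LATE_S: ((5, 15), (2.0, 4.0), (0.0, 0.5)),
}

#: Class proportions of the real populations the tool targets (G-dominant,
#: mid-S scarce), for stress-testing classifiers under imbalance.
PAPER_LIKE_MIX = (354 / 654, 138 / 654, 48 / 654, 114 / 654)

PRESETS = {
    "confocal-balanced": dict(mode="confocal"),
    "widefield-balanced": dict(mode="widefield"),
    "paper-like": dict(mode="confocal", phase_mix=PAPER_LIKE_MIX),
}


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene; the generator is a pure function
    of this spec."""

    size: tuple[int, int] = (384, 384)          # (rows, cols)
    n_nuclei: int = 20
    phase_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    axes_range: tuple[float, float] = (8.0, 13.0)   # semi-axis range [px]
    cluster_fraction: float = 0.25        # fraction of nuclei placed in pairs
    overlap_depth_range: tuple[float, float] = (0.15, 0.30)  # x minor axis
    mode: str = "confocal"                # confocal | widefield
    psf_sigma: dict = field(default_factory=lambda: {"confocal": 0.8,
                                                     "widefield": 2.0})
    background: float = 40.0
    base_signal: float = 300.0            # nuclear signal above background
    granularity: float = 0.12             # chromatin speckle amplitude (rel.)
    focus_amplitude: float = 150.0        # median focus peak height
    poisson_scale: float = 0.5            # photons per intensity unit
    gaussian_sd_frac: float = 0.02        # of dynamic range
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phase_mix) - 1.0) > 1e-6:
            raise ValueError("phase_mix must sum to 1")
        if self.mode not in ("confocal", "widefield"):
            raise ValueError("mode must be confocal or widefield")
        if self.axes_range[0] <= 0 or self.axes_range[1] < self.axes_range[0]:
            raise ValueError("invalid axes_range")
        d0, d1 = self.overlap_depth_range
        if not (0 < d0 <= d1 < 1):
            raise ValueError("overlap depth must be a fraction of the minor axis in (0,1)")
        if self.psf_sigma["widefield"] <= self.psf_sigma["confocal"]:
            raise ValueError("widefield PSF must be wider than confocal")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        data = json.loads(text)
        for key in ("size", "phase_mix", "axes_range", "overlap_depth_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class SyntheticScene:
    image: IntensityImage
    truth_labels: np.ndarray                 # instance mask, pre-noise
    annotations: list[PointAnnotation]       # centroid + phase per nucleus
    spec: SceneSpec


def _sample_in_ellipse(rng: np.random.Generator, n: int, a: float, b: float,
                       r_range: tuple[float, float]) -> np.ndarray:
    """n points in canonical ellipse coords, at normalized radius in r_range
    (area-uniform within the band)."""
    lo, hi = r_range
    u = rng.uniform(lo ** 2, hi ** 2, n)
    r = np.sqrt(u)
    phi = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * a * np.cos(phi), r * b * np.sin(phi)])


def generate_nucleus(phase: PhaseLabel, spec: SceneSpec,
                     rng: np.random.Generator,
                     orientation: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """One nucleus on a local grid: (mask, noise-free texture, centroid).

    The texture is the base nuclear signal plus the phase-specific focus
    pattern; G nuclei get a smooth low-amplitude large-scale modulation
    instead of foci. ``orientation`` overrides the random in-plane angle
    without disturbing the rng stream; the same rng state with two
    orientations yields the *same* nucleus rendered at two angles (the
    rotation-invariance harness).
    """
    if phase not in PHASE_FOCUS_SPECS:
        raise ValueError(f"unknown phase {phase}")
    a = rng.uniform(*spec.axes_range)
    b = rng.uniform(*spec.axes_range)
    if b > a:
        a, b = b, a   # a = major semi-axis
    if not (spec.axes_range[0] <= a <= spec.axes_range[1]):
        raise ValueError("sampled axes outside spec range")
    theta = rng.uniform(0, np.pi)
    if orientation is not None:
        theta = float(orientation)
    half = int(np.ceil(a)) + 3
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xx + st * yy       # canonical ellipse coordinates
    v = -st * xx + ct * yy
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    texture = np.zeros_like(xx)
    texture[mask] = spec.base_signal
    # granular chromatin texture of the nucleoplasm, common to all phases,
    # anchored in canonical (rotating) coordinates
    grain_field = ndi.gaussian_filter(rng.normal(0, 1, (64, 64)), 1.2)
    grain = ndi.map_coordinates(grain_field, [v + 32, u + 32], order=1,
                                mode="wrap")
    grain /= max(grain[mask].std(), 1e-9)
    texture[mask] *= np.clip(1.0 + spec.granularity * grain[mask], 0.2, None)
    count_range, width_range, r_range = PHASE_FOCUS_SPECS[phase]
    if count_range is None:
        # G: homogeneous PCNA with gentle large-scale variation on top
        bump_field = ndi.gaussian_filter(rng.normal(0, 1, (64, 64)), 4.0)
        bumps = ndi.map_coordinates(bump_field, [v + 32, u + 32], order=1,
                                    mode="wrap")
        bumps /= max(np.abs(bumps[mask]).max(), 1e-9)
        texture[mask] *= 1.0 + 0.08 * bumps[mask]
    else:
        n_foci = int(rng.integers(count_range[0], count_range[1] + 1))
        widths = rng.uniform(width_range[0], width_range[1], n_foci)
        amps = spec.focus_amplitude * rng.lognormal(mean=0.0, sigma=0.4,
                                                    size=n_foci)
        uv = _sample_in_ellipse(rng, n_foci, a, b, r_range)
        # back to grid coordinates
        fx = ct * uv[:, 0] - st * uv[:, 1]
        fy = st * uv[:, 0] + ct * uv[:, 1]
        foci = np.zeros_like(texture)
        for x0, y0, w, amp in zip(fx, fy, widths, amps):
            r2 = (xx - x0) ** 2 + (yy - y0) ** 2
            foci += amp * np.exp(-r2 / (2 * w * w))
        foci[~mask] = 0.0
        # PCNA redistributes from the diffuse pool into replication foci:
        # dim the nucleoplasm (and cap the focus pool) so the nuclear mean
        # stays near base_signal regardless of phase
        # the nucleoplasm keeps at least half the diffuse signal so nuclei
        # remain contiguous above background, as in real immunofluorescence
        focus_mean = foci[mask].mean()
        max_focus_mean = 0.5 * spec.base_signal
        if focus_mean > max_focus_mean:
            foci *= max_focus_mean / focus_mean
            focus_mean = max_focus_mean
        texture[mask] *= 1.0 - focus_mean / spec.base_signal
        texture += foci
    rows, cols = np.nonzero(mask)
    centroid = (float(cols.mean()), float(rows.mean()))  # local (x, y)
    return mask, texture, centroid


def _place(rng: np.random.Generator, spec: SceneSpec):
    """Plan nucleus placements: singles plus touching pairs."""
    h, w = spec.size
    n = spec.n_nuclei
    n_pairs = int(np.floor(spec.cluster_fraction * n / 2))
    n_singles = n - 2 * n_pairs
    return n_singles, n_pairs


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a full scene from its spec. Deterministic: the same spec
    (including ``rng_seed``) yields a byte-identical scene."""
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.size
    n_singles, n_pairs = _place(rng, spec)
    phases = [PhaseLabel[list(PhaseLabel.__members__)[i]]
              for i in rng.choice(4, size=spec.n_nuclei, p=spec.phase_mix)]
    composite = np.full((h, w), spec.background, dtype=np.float64)
    truth = np.zeros((h, w), dtype=np.int32)
    occupancy = np.zeros((h, w), dtype=bool)
    annotations: list[PointAnnotation] = []
    margin = int(spec.axes_range[1] * 2 + 6)
    if n_pairs > 0 and (h - 2 * margin < 4 or w - 2 * margin < 4):
        raise RuntimeError("image too small for nucleus pairs; "
                           "try a larger image or fewer nuclei")
    next_label = 1
    phase_iter = iter(phases)

    def paste(mask, texture, r0, c0, label):
        hh, ww = mask.shape
        sl = (slice(r0, r0 + hh), slice(c0, c0 + ww))
        region = composite[sl]
        region[mask] += texture[mask]
        free = mask & (truth[sl] == 0)
        truth[sl][free] = label
        occupancy[sl] |= ndi.binary_dilation(mask, iterations=2)

    def try_place_single(mask, max_tries=200):
        hh, ww = mask.shape
        if h - hh - 4 <= 2 or w - ww - 4 <= 2:
            return None
        for _ in range(max_tries):
            r0 = int(rng.integers(2, h - hh - 2))
            c0 = int(rng.integers(2, w - ww - 2))
            region = occupancy[r0:r0 + hh, c0:c0 + ww]
            if not (region & mask).any():
                return r0, c0
        return None

    # touching pairs first (they need the most room)
    for _ in range(n_pairs):
        p1, p2 = next(phase_iter), next(phase_iter)
        m1, t1, cen1 = generate_nucleus(p1, spec, rng)
        m2, t2, cen2 = generate_nucleus(p2, spec, rng)
        placed = False
        for _ in range(200):
            depth_frac = rng.uniform(*spec.overlap_depth_range)
            angle = rng.uniform(0, 2 * np.pi)
            # effective radii of each mask along the contact direction
            r1 = _radius_along(m1, cen1, angle)
            r2 = _radius_along(m2, cen2, angle + np.pi)
            minor = min(_minor_axis(m1), _minor_axis(m2))
            dist = r1 + r2 - depth_frac * minor
            r0 = int(rng.integers(margin, h - margin))
            c0 = int(rng.integers(margin, w - margin))
            dr = int(round(np.sin(angle) * dist))
            dc = int(round(np.cos(angle) * dist))
            spots = []
            ok = True
            for (mm, cen, rr, cc) in ((m1, cen1, r0, c0),
                                      (m2, cen2, r0 + dr, c0 + dc)):
                rr0 = int(round(rr - cen[1]))
                cc0 = int(round(cc - cen[0]))
                hh, ww = mm.shape
                if not (0 <= rr0 and rr0 + hh < h and 0 <= cc0 and cc0 + ww < w):
                    ok = False
                    break
                spots.append((rr0, cc0))
            if not ok:
                continue
            pair_region = np.zeros((h, w), dtype=bool)
            for (mm, (rr0, cc0)) in zip((m1, m2), spots):
                hh, ww = mm.shape
                pair_region[rr0:rr0 + hh, cc0:cc0 + ww] |= mm
            if (pair_region & occupancy).any():
                continue
            for (mm, tt, cen, (rr0, cc0), ph) in zip(
                    (m1, m2), (t1, t2), (cen1, cen2), spots, (p1, p2)):
                paste(mm, tt, rr0, cc0, next_label)
                annotations.append(PointAnnotation(
                    x=cc0 + cen[0], y=rr0 + cen[1], label=ph))
                next_label += 1
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place a nucleus pair; "
                               "try a larger image or fewer nuclei")

    for _ in range(n_singles):
        phase = next(phase_iter)
        mask, texture, cen = generate_nucleus(phase, spec, rng)
        spot = try_place_single(mask)
        if spot is None:
            raise RuntimeError("could not place a nucleus; "
                               "try a larger image or fewer nuclei")
        r0, c0 = spot
        paste(mask, texture, r0, c0, next_label)
        annotations.append(PointAnnotation(x=c0 + cen[0], y=r0 + cen[1],
                                           label=phase))
        next_label += 1

    sigma = spec.psf_sigma[spec.mode]
    blurred = ndi.gaussian_filter(composite, sigma)
    if spec.mode == "widefield":
        # out-of-focus haze: strongly blurred copy of the signal
        haze = ndi.gaussian_filter(composite - spec.background, 12.0)
        blurred = blurred + 0.35 * haze
    if spec.poisson_scale > 0:
        blurred = rng.poisson(np.maximum(blurred, 0) * spec.poisson_scale
                              ) / spec.poisson_scale
    dyn = max(blurred.max() - spec.background, 1.0)
    noisy = blurred + rng.normal(0, spec.gaussian_sd_frac * dyn, blurred.shape)
    image = IntensityImage(np.clip(noisy, 0, None), bit_depth_hint="float",
                           id=f"synthetic_seed{spec.rng_seed}")
    logger.info("generate_scene seed=%d mode=%s n=%d (%d singles, %d pairs)",
                spec.rng_seed, spec.mode, spec.n_nuclei, n_singles, n_pairs)
    return SyntheticScene(image=image, truth_labels=truth,
                          annotations=annotations, spec=spec)


def _minor_axis(mask: np.ndarray) -> float:
    rows, cols = np.nonzero(mask)
    d = np.hypot(rows - rows.mean(), cols - cols.mean())
    # semi-minor axis of the equivalent ellipse via area / max radius
    return mask.sum() / (np.pi * max(d.max(), 1e-9))


def _radius_along(mask: np.ndarray, centroid: tuple[float, float],
                  angle: float) -> float:
    """Extent of the mask from its centroid along a direction."""
    rows, cols = np.nonzero(mask)
    dx = cols - centroid[0]
    dy = rows - centroid[1]
    proj = dx * np.cos(angle) + dy * np.sin(angle)
    return float(proj.max())


def write_scene(scene: SyntheticScene, out_dir) -> dict[str, Path]:
    """Write image.tif (16-bit), truth_labels.tif, annotations.csv, spec.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.tif",
        "truth_labels": out / "truth_labels.tif",
        "annotations": out / "annotations.csv",
        "spec": out / "spec.json",
    }
    img16 = np.clip(np.round(scene.image.pixels), 0, 65535).astype(np.uint16)
    write_image(paths["image"], img16)
    write_image(paths["truth_labels"], scene.truth_labels.astype(np.uint16))
    write_annotations(paths["annotations"], scene.annotations)
    paths["spec"].write_text(scene.spec.to_json())
    return paths


def _render_tile(mask: np.ndarray, texture: np.ndarray, spec: SceneSpec,
                 rng: np.random.Generator | None = None
                 ) -> tuple[IntensityImage, np.ndarray]:
    """Place one nucleus on a padded background tile and apply the PSF and,
    if ``rng`` is given, the noise model."""
    pad = 6
    tile = np.full((mask.shape[0] + 2 * pad, mask.shape[1] + 2 * pad),
                   spec.background)
    tile[pad:-pad, pad:-pad] += texture
    full_mask = np.zeros(tile.shape, dtype=bool)
    full_mask[pad:-pad, pad:-pad] = mask
    sigma = spec.psf_sigma[spec.mode]
    blurred = ndi.gaussian_filter(tile, sigma)
    if spec.mode == "widefield":
        haze = ndi.gaussian_filter(tile - spec.background, 12.0)
        blurred = blurred + 0.35 * haze
    if rng is not None and spec.poisson_scale > 0:
        blurred = rng.poisson(np.maximum(blurred, 0) * spec.poisson_scale
                              ) / spec.poisson_scale
    if rng is not None and spec.gaussian_sd_frac > 0:
        dyn = max(blurred.max() - spec.background, 1.0)
        blurred = blurred + rng.normal(0, spec.gaussian_sd_frac * dyn,
                                       blurred.shape)
    return IntensityImage(np.clip(blurred, 0, None)), full_mask


def rotated_nucleus_pair(phase: PhaseLabel, spec: SceneSpec, seed: int,
                         angle_deg: float
                         ) -> tuple[tuple[IntensityImage, np.ndarray],
                                    tuple[IntensityImage, np.ndarray]]:
    """The same nucleus rendered at two in-plane orientations.

    Both renderings sample the identical continuous nucleus model (ellipse,
    chromatin field, focus positions) on the pixel grid, so differences
    between them measure only the grid sampling — the proper input for
    rotation-invariance checks of the feature chain. Rendered noise-free.
    """
    tiles = []
    for theta in (0.0, np.deg2rad(angle_deg)):
        rng = np.random.default_rng(seed)
        mask, texture, _ = generate_nucleus(phase, spec, rng,
                                            orientation=theta)
        tiles.append(_render_tile(mask, texture, spec, rng=None))
    return tiles[0], tiles[1]


def fringed_ellipse(rng: np.random.Generator,
                    axes_range: tuple[float, float] = (8.0, 13.0),
                    boundary_sigma: float = 1.5,
                    angular_smoothing: float = 1.5) -> np.ndarray:
    """A single ellipse mask with a fringy border: the radial boundary is
    perturbed by angular noise of sd ``boundary_sigma`` px (correlation
    ``angular_smoothing`` degrees). Emulates ragged thresholding artifacts
    that destabilize watershed splitting."""
    a, b = rng.uniform(*axes_range, 2)
    if b > a:
        a, b = b, a
    theta = rng.uniform(0, np.pi)
    half = int(np.ceil(a + 4 * boundary_sigma)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * xx + st * yy
    v = -st * xx + ct * yy
    ang = np.arctan2(v, u)
    prof = rng.normal(0, 1, 360)
    prof = ndi.gaussian_filter1d(prof, angular_smoothing, mode="wrap")
    prof *= boundary_sigma / max(prof.std(), 1e-9)
    idx = ((ang + np.pi) / (2 * np.pi) * 360).astype(int) % 360
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    mask = (r - 1.0 - prof[idx] / b) <= 0
    lab, n = ndi.label(mask)
    if n == 0:
        return fringed_ellipse(rng, axes_range, boundary_sigma,
                               angular_smoothing)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def generate_nucleus_bank(n_per_class: int, spec: SceneSpec | None = None,
                          seed: int = 42
                          ) -> list[tuple[IntensityImage, np.ndarray, PhaseLabel]]:
    """Isolated nuclei on small tiles with their truth masks — the input of
    the classification benchmark (segmentation-independent).

    Each tile receives the same PSF/noise treatment as a full scene.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(seed)
    out = []
    sigma = spec.psf_sigma[spec.mode]
    for phase in PhaseLabel:
        for _ in range(n_per_class):
            mask, texture, cen = generate_nucleus(phase, spec, rng)
            pad = 6
            tile = np.full((mask.shape[0] + 2 * pad, mask.shape[1] + 2 * pad),
                           spec.background)
            tile[pad:-pad, pad:-pad] += texture
            full_mask = np.zeros(tile.shape, dtype=bool)
            full_mask[pad:-pad, pad:-pad] = mask
            blurred = ndi.gaussian_filter(tile, sigma)
            if spec.mode == "widefield":
                haze = ndi.gaussian_filter(tile - spec.background, 12.0)
                blurred = blurred + 0.35 * haze
            if spec.poisson_scale > 0:
                blurred = rng.poisson(np.maximum(blurred, 0) * spec.poisson_scale
                                      ) / spec.poisson_scale
            dyn = max(blurred.max() - spec.background, 1.0)
            noisy = blurred + rng.normal(0, spec.gaussian_sd_frac * dyn,
                                         blurred.shape)
            img = IntensityImage(np.clip(noisy, 0, None),
                                 id=f"bank_{phase.name}")
            out.append((img, full_mask, phase))
    return out
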