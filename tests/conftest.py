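"""Shared fixtures: toy geometries, generator scenes, and the two session
benchmarks (splitting and classification) reused by several test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from pcnaphase.classification import cross_validate
from pcnaphase.cluster_splitting import split_labels
from pcnaphase.evaluation import match_annotations, segmentation_rates
from pcnaphase.features import assemble_features, segments_from_labels
from pcnaphase.io_config import IntensityImage, PipelineConfig
from pcnaphase.segmentation import filter_by_size, segment_image
from pcnaphase.synthetic_data import (SceneSpec, fringed_ellipse,
                                      generate_nucleus_bank, generate_scene)

warnings.filterwarnings("ignore", message="Failed to get convex hull")


@pytest.fixture()
def config() -> PipelineConfig:
    return PipelineConfig()


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius ** 2


@pytest.fixture()
def two_disc_cluster():
    """Two overlapping discs (radius 20, centers 30 apart) as one label."""
    mask = disc_mask((60, 100), (35, 30), 20) | disc_mask((60, 100), (65, 30), 20)
    return mask.astype(np.int32)


@pytest.fixture()
def three_disc_chain():
    mask = (disc_mask((60, 130), (30, 30), 20)
            | disc_mask((60, 130), (60, 30), 20)
            | disc_mask((60, 130), (90, 30), 20))
    return mask.astype(np.int32)


@pytest.fixture()
def ellipse_labels():
    """A single convex ellipse label mask."""
    yy, xx = np.mgrid[:50, :60]
    mask = ((xx - 30) / 22.0) ** 2 + ((yy - 25) / 14.0) ** 2 <= 1
    return mask.astype(np.int32)


def nucleus_segment(image: IntensityImage, mask: np.ndarray):
    return segments_from_labels(image, mask.astype(int))[0]


# ---------------------------------------------------------------------------
# Session benchmarks
# ---------------------------------------------------------------------------

SPLIT_BENCH_SEED = 11
SPLIT_BENCH_SCENES = 100
CLASS_BENCH_SEED = 42


@pytest.fixture(scope="session")
def split_benchmark():
    """Segmentation rates of the geometric and watershed splitters over
    synthetic scenes of 10 single ellipses + 5 two-nucleus clusters each
    (overlap depth 15-30% of the minor axis)."""
    cfg = PipelineConfig()
    counts = {"geometric": np.zeros(2), "watershed": np.zeros(2)}
    n_ann = 0
    rng = np.random.default_rng(SPLIT_BENCH_SEED)
    scene_seeds = rng.integers(0, 2 ** 31 - 1, SPLIT_BENCH_SCENES)
    for seed in scene_seeds:
        spec = SceneSpec(n_nuclei=20, cluster_fraction=0.5, rng_seed=int(seed))
        scene = generate_scene(spec)
        labels = segment_image(scene.image, cfg)
        n_ann += len(scene.annotations)
        for method in counts:
            out = split_labels(labels, cfg, method=method)
            out, _, _ = filter_by_size(out, cfg.splitting.min_area,
                                       cfg.splitting.max_area)
            r = segmentation_rates(match_annotations(out, scene.annotations))
            counts[method] += [r.n_fragments_unmatched,
                               r.n_multimatched_segments]
    result = {}
    for method, (unmatched, multi) in counts.items():
        over = unmatched / n_ann
        under = multi / n_ann
        result[method] = {"over": over, "under": under,
                          "correct": 1.0 - over - under}
    return result


@pytest.fixture(scope="session")
def fringe_benchmark():
    """Split counts of both methods on 100 boundary-noise-perturbed single
    ellipses (radial noise sd 1.5 px, seed 11)."""
    from pcnaphase.cluster_splitting import split_cluster, watershed_split

    cfg = PipelineConfig()
    rng = np.random.default_rng(SPLIT_BENCH_SEED)
    geo = ws = 0
    n = 100
    for _ in range(n):
        lab = fringed_ellipse(rng).astype(np.int32)
        geo += len(split_cluster(lab, 1, cfg)) > 1
        ws += len(watershed_split(lab, 1)) > 1
    return {"geometric": geo / n, "watershed": ws / n, "n": n}


def feature_table(bank, set_id, cfg=None):
    cfg = cfg or PipelineConfig()
    rows, ys, names = [], [], None
    for img, mask, phase in bank:
        seg = segments_from_labels(img, mask.astype(int))[0]
        v, names = assemble_features(img, seg, set_id, cfg)
        rows.append(v)
        ys.append(phase.name)
    return pd.DataFrame(np.vstack(rows), columns=names), np.array(ys)


@pytest.fixture(scope="session")
def class_benchmark():
    """Cross-validated phase classification on the 400-nucleus balanced
    benchmark (100/class), confocal and widefield, proposed and comparison
    feature sets."""
    out = {}
    for mode in ("confocal", "widefield"):
        bank = generate_nucleus_bank(100, SceneSpec(mode=mode),
                                     seed=CLASS_BENCH_SEED)
        x_prop, y = feature_table(bank, "proposed")
        x_ersoy, _ = feature_table(bank, "ersoy")
        out[mode] = {
            "tree": cross_validate(x_prop, y, k=10, kind="decision_tree",
                                   seed=CLASS_BENCH_SEED),
            "tree_ersoy": cross_validate(x_ersoy, y, k=10,
                                         kind="decision_tree",
                                         seed=CLASS_BENCH_SEED),
            "features": x_prop,
            "labels": y,
        }
    return out
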