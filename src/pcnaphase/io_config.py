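"""Image, annotation and configuration I/O for the PCNA phase pipeline.

Coordinate convention used throughout the package: ``(x, y) = (column, row)``,
0-based, with pixel centers at integer coordinates. An annotation at
``(x, y)`` therefore refers to ``pixels[round(y), round(x)]``.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("pcnaphase")


class PhaseLabel(enum.Enum):
    """Cell-cycle phase of a nucleus, read from the PCNA distribution pattern.

    ``G`` covers both gap phases (G1/G2): PCNA spread homogeneously over the
    nucleus. The three S sub-stages follow the canonical replication-foci
    progression: many small uniform foci (early), peripheral foci (mid),
    few large central foci (late).
    """

    G = "G"
    EARLY_S = "EARLY_S"
    MID_S = "MID_S"
    LATE_S = "LATE_S"

    @classmethod
    def parse(cls, text: str) -> "PhaseLabel":
        key = str(text).strip().upper().replace(" ", "_").replace("-", "_")
        try:
            return cls[key]
        except KeyError:
            raise ValueError(
                f"unknown phase label {text!r}; expected one of "
                f"{[m.name for m in cls]}"
            ) from None


#: Fixed label order used for confusion matrices and reports.
PHASE_ORDER: tuple[PhaseLabel, ...] = (
    PhaseLabel.G,
    PhaseLabel.EARLY_S,
    PhaseLabel.MID_S,
    PhaseLabel.LATE_S,
)


@dataclass
class IntensityImage:
    """A single-channel fluorescence image with non-negative finite pixels."""

    pixels: np.ndarray
    bit_depth_hint: int | str = "float"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("IntensityImage requires a 2-D single-channel array")
        if self.pixels.shape[0] < 2 or self.pixels.shape[1] < 2:
            raise ValueError("IntensityImage must be at least 2x2 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("IntensityImage pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("IntensityImage pixels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PointAnnotation:
    """Ground-truth point marker: one click per nucleus, with its phase."""

    x: float
    y: float
    label: PhaseLabel


def read_image(path: str | Path) -> IntensityImage:
    """Read a single-channel TIFF (or PNG) into an :class:`IntensityImage`.

    The original dynamic range is preserved; multi-channel (RGB) inputs are
    rejected because the pipeline operates on one fluorescence channel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(
            f"single channel required: {path} has shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        hint: int | str = int(arr.dtype.itemsize * 8)
    else:
        hint = "float"
    img = IntensityImage(arr.astype(np.float64), bit_depth_hint=hint, id=path.stem)
    logger.info("read_image id=%s shape=%s bit_depth=%s", img.id, img.shape, hint)
    return img


def write_image(path: str | Path, image: IntensityImage | np.ndarray,
                dtype: np.dtype | type | None = None) -> None:
    """Write an image/mask as TIFF (or PNG); integer round trips are lossless."""
    path = Path(path)
    arr = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    if dtype is not None:
        arr = arr.astype(dtype)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr)


def read_annotations(path: str | Path,
                     image: IntensityImage | None = None) -> list[PointAnnotation]:
    """Read point annotations from a CSV with header columns ``x,y,label``.

    Labels are parsed case-insensitively into :class:`PhaseLabel`. Bounds are
    checked only when ``image`` is supplied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    df = pd.read_csv(path)
    required = {"x", "y", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation CSV must have columns x,y,label; got {list(df.columns)}")
    out: list[PointAnnotation] = []
    for i, row in df.iterrows():
        try:
            label = PhaseLabel.parse(row["label"])
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from None
        ann = PointAnnotation(float(row["x"]), float(row["y"]), label)
        if image is not None:
            h, w = image.shape
            if not (0 <= ann.x <= w - 1 and 0 <= ann.y <= h - 1):
                raise ValueError(
                    f"row {i}: annotation ({ann.x}, {ann.y}) outside image bounds {w}x{h}"
                )
        out.append(ann)
    logger.info("read_annotations path=%s n=%d", path, len(out))
    return out


def write_annotations(path: str | Path, annotations: Iterable[PointAnnotation]) -> None:
    df = pd.DataFrame(
        [{"x": a.x, "y": a.y, "label": a.label.name} for a in annotations],
        columns=["x", "y", "label"],
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    n_bins: int = 256            # histogram bins for the Li threshold
    connectivity: int = 8        # 4 or 8 for component labelling
    presmooth_sigma: float = 0.0  # Gaussian pre-smoothing; 0 = off (confocal)


@dataclass
class SplittingParams:
    curvature_sigma: float = 1.0   # contour smoothing scale [px]
    kappa_min: float = 0.12        # concavity threshold [1/px]
    nms_window: int = 5            # non-maximum suppression window [vertices]
    max_split_points: int = 12     # strongest concavities kept per contour
    theta_max_deg: float = 75.0    # anti-parallel constraint half-angle
    c_min: float = 0.85            # minimal part solidity (convexity constraint)
    min_area: float = 120.0        # nucleus area range [px^2]
    max_area: float = 4000.0
    n_max: int = 4                 # maximal number of parts per cluster
    chord_weight: float = 0.15     # lambda: chord-length penalty weight
    accept_margin: float = 0.01    # epsilon: required improvement over unsplit
    max_hypotheses: int = 10_000   # combinatorial guard


@dataclass
class PolarParams:
    n_radius: int = 32
    n_zones: int = 8


@dataclass
class FeatureParams:
    glcm_levels: int = 32
    glcm_distances: tuple[int, ...] = (1, 2)
    curvature_sigma: float = 1.5   # Hessian scale for surface curvature [px]
    n_histogram_bins: int = 64
    include_zone_means: bool = True


@dataclass
class ClassifierParams:
    kind: str = "decision_tree"    # decision_tree | svm | adaboost
    depth_limit: int = 12
    min_entropy: float = 0.0
    svm_C: float = 1.0
    svm_kernel: str = "linear"
    boosting_rounds: int = 50
    cv_folds: int = 10
    stratify: bool = False


@dataclass
class PipelineConfig:
    """Validated bag of parameters for every pipeline stage."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    splitting: SplittingParams = field(default_factory=SplittingParams)
    polar: PolarParams = field(default_factory=PolarParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        s = self.segmentation
        if s.n_bins < 2:
            raise ValueError("segmentation.n_bins must be >= 2")
        if s.connectivity not in (4, 8):
            raise ValueError("segmentation.connectivity must be 4 or 8")
        if s.presmooth_sigma < 0:
            raise ValueError("segmentation.presmooth_sigma must be >= 0")
        p = self.splitting
        for name in ("curvature_sigma", "kappa_min", "theta_max_deg", "c_min",
                     "min_area", "max_area", "chord_weight", "accept_margin"):
            if getattr(p, name) < 0:
                raise ValueError(f"splitting.{name} must be non-negative")
        if p.min_area >= p.max_area:
            raise ValueError("splitting.min_area must be < splitting.max_area")
        if p.n_max < 2:
            raise ValueError("splitting.n_max must be >= 2")
        if self.polar.n_zones < 2:
            raise ValueError("polar.n_zones must be >= 2")
        if self.polar.n_radius < 4:
            raise ValueError("polar.n_radius must be >= 4")
        f = self.features
        if f.glcm_levels < 2:
            raise ValueError("features.glcm_levels must be >= 2")
        if any(d < 1 for d in f.glcm_distances):
            raise ValueError("features.glcm_distances must be >= 1")
        if f.curvature_sigma <= 0:
            raise ValueError("features.curvature_sigma must be > 0")
        c = self.classifier
        if c.kind not in ("decision_tree", "svm", "adaboost"):
            raise ValueError(f"unknown classifier kind {c.kind!r}")
        if c.svm_C <= 0:
            raise ValueError("classifier.svm_C must be > 0")
        if c.boosting_rounds < 1 or c.cv_folds < 2 or c.depth_limit < 0:
            raise ValueError("classifier params out of range")
        if self.rng_seed < 0:
            raise ValueError("rng_seed must be non-negative")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        cfg = cls()
        sections = {
            "segmentation": cfg.segmentation,
            "splitting": cfg.splitting,
            "polar": cfg.polar,
            "features": cfg.features,
            "classifier": cfg.classifier,
        }
        for key, value in (data or {}).items():
            if key == "rng_seed":
                cfg.rng_seed = int(value)
            elif key in sections:
                section = sections[key]
                valid = {f.name for f in dataclasses.fields(section)}
                for k, v in (value or {}).items():
                    if k not in valid:
                        raise ValueError(f"unknown config key {key}.{k}")
                    if isinstance(v, list):
                        v = tuple(v)
                    setattr(section, k, v)
            else:
                raise ValueError(f"unknown config section {key!r}")
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file; unspecified fields take defaults.

    ``None`` or an empty file yields the all-defaults configuration, so every
    pipeline stage is runnable without a config file.
    """
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    cfg = PipelineConfig.from_dict(data)
    logger.info("load_config path=%s config=%s", path, json.dumps(cfg.to_dict()))
    return cfg
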