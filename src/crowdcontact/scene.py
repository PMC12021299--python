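"""Synthetic pedestrian-scene generator.

Real surveillance detections of pedestrians on a ground plane are not
publicly available, so this module generates detection tables with the same
statistical structure: still frames from fixed cameras, each frame holding a
small crowd of pedestrians at metric (x, y) coordinates inside the camera's
walkable viewshed.  Three mechanisms shape the point pattern:

1. **Crowd size** per frame is drawn from an overdispersed count
   distribution (default: negative binomial truncated to [2, 67], calibrated
   to a median of 7 persons and an SD of about 7.7).
2. **Companion groups** (households, dyads walking together) partition each
   crowd; members of a group stay within a fixed spacing band of their group
   anchor.
3. **Anchor attraction**: group anchors are laid down by a sequential
   parent-offspring process.  Each new anchor attaches to a previously
   placed anchor with probability ``c / (1 + c)`` (``c`` =
   ``clustering_strength``) and is scattered around it with an isotropic
   Gaussian; otherwise it is placed uniformly.  At ``c = 0`` with singleton
   groups the pattern reduces exactly to uniform independent placement,
   which is the random-placement null model's geometry.

All randomness flows from a single root seed through per-camera and
per-frame child streams, so output is reproducible and independent of
generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViewshedSpec",
    "GeneratorConfig",
    "FrameRecord",
    "DETECTION_COLUMNS",
    "sample_crowd_sizes",
    "generate_frame",
    "generate_dataset",
    "default_viewsheds",
    "simulate_lpm_persons",
    "degrade_detections",
]

DETECTION_COLUMNS = ["camera_id", "frame_id", "person_id", "x_m", "y_m"]

#: Default distribution of companion-group sizes (index 0 = singletons).
DEFAULT_GROUP_SIZE_DIST = (0.55, 0.30, 0.10, 0.05)


@dataclass(frozen=True)
class ViewshedSpec:
    """Walkable ground-plane rectangle seen by one camera.

    Only the area is empirically anchored (about 650 m2 on average for the
    street cameras this emulates); the aspect ratio of the bounding
    rectangle is a free geometric choice with second-order effects.
    """

    camera_id: str
    area_m2: float = 650.0
    aspect_ratio: float = 2.0

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError(f"area_m2 must be positive, got {self.area_m2}")
        if not self.aspect_ratio > 0:
            raise ValueError(f"aspect_ratio must be positive, got {self.aspect_ratio}")

    @property
    def width_m(self) -> float:
        return math.sqrt(self.area_m2 * self.aspect_ratio)

    @property
    def height_m(self) -> float:
        return math.sqrt(self.area_m2 / self.aspect_ratio)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic scene generator.

    Attributes
    ----------
    n_cameras, frames_per_camera
        Layout of the generated dataset.
    crowd_dist
        Distribution spec for per-frame person counts, as a mapping with a
        ``family`` key.  Supported families: ``nbinom`` (keys ``dispersion``
        and ``mean``, pre-truncation), ``point`` (key ``value``) and
        ``uniform`` (keys ``low`` and ``high``, inclusive integers).
    crowd_range
        Inclusive truncation bounds for crowd sizes; the lower bound must be
        at least 2 because single-person frames carry no proximity
        information and are excluded downstream.
    group_size_dist
        Probability vector over companion-group sizes 1..len(dist).
    within_group_spacing_m
        Uniform band (meters) for the distance of a group member from its
        group anchor.
    clustering_strength
        Nonnegative attraction knob ``c``; a new group anchor attaches to an
        existing one with probability ``c / (1 + c)``.
    cluster_scale_m
        Gaussian scatter (meters) of an attached anchor around its parent.
    threshold_m
        Distancing threshold (1.5 m under the Dutch COVID-19 guideline);
        carried here so generator calibration and scoring agree.
    seed
        Root seed for all child streams.
    """

    n_cameras: int = 49
    frames_per_camera: int = 100
    crowd_dist: Mapping[str, float] = field(
        default_factory=lambda: {"family": "nbinom", "dispersion": 1.2, "mean": 8.0}
    )
    crowd_range: tuple[int, int] = (2, 67)
    group_size_dist: tuple[float, ...] = DEFAULT_GROUP_SIZE_DIST
    within_group_spacing_m: tuple[float, float] = (0.5, 3.0)
    clustering_strength: float = 0.3
    cluster_scale_m: float = 2.0
    threshold_m: float = 1.5
    seed: int = 0
    area_m2: float = 650.0
    aspect_ratio: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cameras < 1 or self.frames_per_camera < 1:
            raise ValueError("n_cameras and frames_per_camera must be positive")
        lo, hi = self.crowd_range
        if lo < 2:
            raise ValueError("crowd_range lower bound must be >= 2")
        if hi < lo:
            raise ValueError("crowd_range must be nondecreasing")
        p = np.asarray(self.group_size_dist, dtype=float)
        if p.ndim != 1 or p.size == 0 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("group_size_dist must be a probability vector")
        a, b = self.within_group_spacing_m
        if not (0 <= a <= b):
            raise ValueError("within_group_spacing_m must satisfy 0 <= low <= high")
        if self.clustering_strength < 0:
            raise ValueError("clustering_strength must be nonnegative")
        if not self.threshold_m > 0:
            raise ValueError("threshold_m must be positive")

    @classmethod
    def uniform(cls, **overrides) -> "GeneratorConfig":
        """Config whose placement is uniform i.i.d. (the null geometry).

        Singleton groups and zero anchor attraction; all other parameters as
        in the default calibration unless overridden.
        """
        base = dict(clustering_strength=0.0, group_size_dist=(1.0,))
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


@dataclass
class FrameRecord:
    """All detections of a single still frame, with optional group labels.

    ``group_id`` records which companion group each person belongs to.  It
    exists for generator validation only and is never used by the scoring
    or inference stages (the emulated detector cannot see group membership).
    """

    camera_id: str
    frame_id: str
    x_m: np.ndarray
    y_m: np.ndarray
    person_id: np.ndarray
    group_id: np.ndarray | None = None

    @property
    def n_present(self) -> int:
        return len(self.x_m)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_m, self.y_m])

    def to_table(self, include_groups: bool = False) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "camera_id": self.camera_id,
                "frame_id": self.frame_id,
                "person_id": self.person_id,
                "x_m": self.x_m,
                "y_m": self.y_m,
            }
        )
        if include_groups and self.group_id is not None:
            out["group_id"] = self.group_id
        return out


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _crowd_support_pmf(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Support and probabilities of the truncated crowd-size distribution."""
    lo, hi = config.crowd_range
    spec = dict(config.crowd_dist)
    family = spec.get("family", "nbinom")
    k = np.arange(lo, hi + 1)
    if family == "nbinom":
        r = float(spec["dispersion"])
        mu = float(spec["mean"])
        if r <= 0 or mu <= 0:
            raise ValueError("nbinom crowd_dist needs positive dispersion and mean")
        p = r / (r + mu)
        pmf = stats.nbinom.pmf(k, r, p)
    elif family == "point":
        v = int(spec["value"])
        pmf = (k == v).astype(float)
    elif family == "uniform":
        low, high = int(spec["low"]), int(spec["high"])
        pmf = ((k >= low) & (k <= high)).astype(float)
    else:
        raise ValueError(f"unknown crowd_dist family {family!r}")
    total = pmf.sum()
    if total < 1e-12:
        raise ValueError(
            f"crowd_dist has (near-)zero mass inside crowd_range {config.crowd_range}"
        )
    return k, pmf / total


def sample_crowd_sizes(config: GeneratorConfig, count: int, rng) -> np.ndarray:
    """Draw ``count`` per-frame person counts from the truncated crowd-size law.

    Sampling is exact inverse-CDF on the truncated support, so the draws
    match the truncated distribution without rejection and are fully
    deterministic given the generator state.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    rng = _as_rng(rng)
    support, pmf = _crowd_support_pmf(config)
    return rng.choice(support, size=count, p=pmf)


def _sample_group_sizes(n: int, probs: np.ndarray, rng: np.random.Generator) -> list[int]:
    """Partition n persons into companion groups; the last group is trimmed."""
    sizes: list[int] = []
    total = 0
    support = np.arange(1, len(probs) + 1)
    while total < n:
        s = int(rng.choice(support, p=probs))
        sizes.append(s)
        total += s
    sizes[-1] -= total - n
    return [s for s in sizes if s > 0]


def _place_in_rect(
    propose, width: float, height: float, rng: np.random.Generator, max_tries: int = 50
) -> np.ndarray:
    """Rejection-sample a proposal into the rectangle, clipping as last resort."""
    for _ in range(max_tries):
        pos = propose()
        if 0.0 <= pos[0] <= width and 0.0 <= pos[1] <= height:
            return pos
    return np.clip(propose(), [0.0, 0.0], [width, height])


def generate_frame(
    n: int,
    viewshed: ViewshedSpec,
    config: GeneratorConfig,
    rng,
    frame_id: str = "f0",
) -> FrameRecord:
    """Place ``n`` pedestrians in one still frame of ``viewshed``.

    Persons are partitioned into companion groups; group anchors follow the
    sequential parent-offspring attraction process; remaining members are
    placed at a uniform distance within the companion-spacing band of their
    anchor, at a uniform angle.  Off-rectangle proposals are rejection
    sampled back inside.
    """
    lo, hi = config.crowd_range
    if n < 2:
        raise ValueError("a frame needs at least 2 persons")
    if not (lo <= n <= hi):
        raise ValueError(f"n={n} outside crowd_range {config.crowd_range}")
    w, h = viewshed.width_m, viewshed.height_m
    a, b = config.within_group_spacing_m
    if b >= min(w, h):
        raise ValueError("within_group_spacing_m upper bound exceeds the viewshed")
    rng = _as_rng(rng)

    probs = np.asarray(config.group_size_dist, dtype=float)
    sizes = _sample_group_sizes(n, probs, rng)

    c = config.clustering_strength
    attach_p = c / (1.0 + c)
    sigma = config.cluster_scale_m
    anchors: list[np.ndarray] = []
    for _ in sizes:
        if anchors and rng.random() < attach_p:
            parent = anchors[int(rng.integers(len(anchors)))]
            pos = _place_in_rect(
                lambda: parent + rng.normal(0.0, sigma, size=2), w, h, rng
            )
        else:
            pos = rng.uniform([0.0, 0.0], [w, h])
        anchors.append(np.asarray(pos, dtype=float))

    xs, ys, gids = [], [], []
    for g, (anchor, size) in enumerate(zip(anchors, sizes)):
        xs.append(anchor[0])
        ys.append(anchor[1])
        gids.append(g)
        for _ in range(size - 1):
            def propose() -> np.ndarray:
                r = rng.uniform(a, b)
                theta = rng.uniform(0.0, 2.0 * np.pi)
                return anchor + r * np.array([np.cos(theta), np.sin(theta)])

            pos = _place_in_rect(propose, w, h, rng)
            xs.append(pos[0])
            ys.append(pos[1])
            gids.append(g)

    return FrameRecord(
        camera_id=viewshed.camera_id,
        frame_id=frame_id,
        x_m=np.asarray(xs),
        y_m=np.asarray(ys),
        person_id=np.arange(n),
        group_id=np.asarray(gids),
    )


def default_viewsheds(config: GeneratorConfig) -> list[ViewshedSpec]:
    """One viewshed per camera, all at the configured area and aspect."""
    return [
        ViewshedSpec(f"cam{i + 1:02d}", config.area_m2, config.aspect_ratio)
        for i in range(config.n_cameras)
    ]


def generate_dataset(
    config: GeneratorConfig,
    viewsheds: Sequence[ViewshedSpec] | None = None,
    include_groups: bool = False,
) -> pd.DataFrame:
    """Generate the flat detection table for a whole camera network.

    Each camera draws its crowd sizes from a dedicated child stream and each
    frame is generated from its own child stream, all derived from
    ``config.seed``, so the table is reproducible byte-for-byte and
    insensitive to generation order.
    """
    if viewsheds is None:
        viewsheds = default_viewsheds(config)
    if len(viewsheds) == 0:
        raise ValueError("need at least one viewshed")
    ids = [v.camera_id for v in viewsheds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate camera_id in viewsheds")

    root = int(config.seed)
    tables = []
    for ci, vs in enumerate(viewsheds):
        size_rng = np.random.default_rng(np.random.SeedSequence([root, ci]))
        sizes = sample_crowd_sizes(config, config.frames_per_camera, size_rng)
        for fi, n in enumerate(sizes):
            frame_rng = np.random.default_rng(np.random.SeedSequence([root, ci, fi]))
            rec = generate_frame(int(n), vs, config, frame_rng, frame_id=f"f{fi:05d}")
            tables.append(rec.to_table(include_groups=include_groups))
    return pd.concat(tables, ignore_index=True)


def simulate_lpm_persons(
    slope: float,
    intercept: float,
    n_frames: int,
    config: GeneratorConfig,
    rng,
) -> pd.DataFrame:
    """Person table whose violation indicator follows a known linear law.

    For parameter-recovery studies: frames draw their crowd size ``n`` from
    the configured crowd-size distribution and every person in a frame
    violates independently with probability ``intercept + slope * n``
    (clipped to [0, 1]).  The returned table has the person-outcome schema
    the clustered linear probability model consumes.
    """
    rng = _as_rng(rng)
    sizes = sample_crowd_sizes(config, n_frames, rng)
    frame_ids = np.repeat([f"f{i:05d}" for i in range(n_frames)], sizes)
    n_present = np.repeat(sizes, sizes)
    p = np.clip(intercept + slope * n_present, 0.0, 1.0)
    violation = (rng.random(p.size) < p).astype(np.int8)
    person_id = np.concatenate([np.arange(s) for s in sizes])
    return pd.DataFrame(
        {
            "camera_id": "cam01",
            "frame_id": frame_ids,
            "person_id": person_id,
            "n_present": n_present.astype(int),
            "violation": violation,
        }
    )


def degrade_detections(detections: pd.DataFrame, drop_frac: float, rng) -> pd.DataFrame:
    """Randomly drop a fraction of detection rows (a deliberately worse rater).

    Emulates an imperfect detector for reliability studies: each detection
    is removed with probability ``drop_frac``; frame membership is otherwise
    untouched.  The result may contain frames with fewer than 2 persons and
    should be re-filtered before scoring.
    """
    if not 0.0 <= drop_frac < 1.0:
        raise ValueError("drop_frac must be in [0, 1)")
    rng = _as_rng(rng)
    keep = rng.random(len(detections)) >= drop_frac
    return detections.loc[keep].reset_index(drop=True)
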