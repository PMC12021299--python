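"""Random-placement null model for close-pair counts.

How many 1.5-m violations arise from geometry alone?  The null model
positions ``n`` individuals uniformly and independently in a rectangle of
walkable area ``A`` (neither attracted nor repelled by one another) and
counts pairs closer than the threshold ``d``.  Comparing observed violation
counts with this baseline separates geometric necessity from behavioral
attraction: an observed curve above the null means people stand closer than
random navigation would produce.

Without edge effects the expected violating-pair count is the closed form

    E[pairs] = C(n, 2) * pi * d^2 / A,

exact on a torus and an upper bound for a plain rectangle (points near a
wall have part of their d-ball outside).  For n = 2 on a plain rectangle
the exact close-pair probability has a classical closed form (rectangle
line-picking), used here as an oracle for the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NullModelConfig",
    "NullModelResult",
    "simulate_random_placement",
    "expected_pairs_analytic",
    "rect_close_pair_probability",
    "capacity_linear_convention",
    "capacity_hex_packing",
    "personal_space",
    "compare_observed_to_null",
]

DEFAULT_N_VALUES = tuple(range(2, 68, 5))


@dataclass
class NullModelConfig:
    """Configuration of the random-placement simulation.

    ``area_m2`` defaults to the 650 m2 average street viewshed, with 300
    and 150 m2 as the standard reduced-area variants.  ``boundary`` is
    ``plain`` (literal rectangle, default) or ``torus`` (periodic wrap, an
    analytic-validation device with no edge effects).
    """

    area_m2: float = 650.0
    aspect_ratio: float = 2.0
    threshold_m: float = 1.5
    n_values: tuple[int, ...] = DEFAULT_N_VALUES
    replicates: int = 10_000
    seed: int = 0
    boundary: str = "plain"

    def __post_init__(self) -> None:
        if not self.area_m2 > 0:
            raise ValueError("area_m2 must be positive")
        if not self.aspect_ratio > 0:
            raise ValueError("aspect_ratio must be positive")
        if self.threshold_m < 0:
            # zero is allowed as a degenerate check (no pair can violate)
            raise ValueError("threshold_m must be nonnegative")
        if any(n < 2 for n in self.n_values):
            raise ValueError("all n_values must be >= 2")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.boundary not in ("plain", "torus"):
            raise ValueError("boundary must be 'plain' or 'torus'")

    @property
    def width_m(self) -> float:
        return math.sqrt(self.area_m2 * self.aspect_ratio)

    @property
    def height_m(self) -> float:
        return math.sqrt(self.area_m2 / self.aspect_ratio)


@dataclass
class NullModelResult:
    """Simulated null curves: per crowd size n, mean violating pairs/persons."""

    area_m2: float
    aspect_ratio: float
    threshold_m: float
    boundary: str
    replicates: int
    table: pd.DataFrame  # columns: n, mean_pairs, mean_violators, mc_se_pairs, mc_se_violators

    def mean_pairs(self, n: int) -> float:
        row = self.table.loc[self.table["n"] == n]
        if row.empty:
            raise KeyError(f"n={n} not simulated")
        return float(row["mean_pairs"].iloc[0])


def _simulate_one_n(
    n: int,
    cfg: NullModelConfig,
    rng: np.random.Generator,
    chunk_bytes: float = 6e7,
) -> tuple[float, float, float, float]:
    """Means and MC standard errors of pair and violator counts at one n."""
    w, h = cfg.width_m, cfg.height_m
    d2 = cfg.threshold_m**2
    reps = cfg.replicates
    chunk = max(1, int(chunk_bytes / (n * n * 8)))
    pairs_all = np.empty(reps)
    viol_all = np.empty(reps)
    done = 0
    iu, ju = np.triu_indices(n, k=1)
    while done < reps:
        r = min(chunk, reps - done)
        pts = rng.random((r, n, 2)) * np.array([w, h])
        dx = np.abs(pts[:, :, None, 0] - pts[:, None, :, 0])
        dy = np.abs(pts[:, :, None, 1] - pts[:, None, :, 1])
        if cfg.boundary == "torus":
            dx = np.minimum(dx, w - dx)
            dy = np.minimum(dy, h - dy)
        close = dx**2 + dy**2 <= d2
        pairs_all[done : done + r] = close[:, iu, ju].sum(axis=1)
        np.einsum("rii->ri", close)[:] = False  # a person is not their own neighbor
        viol_all[done : done + r] = close.any(axis=2).sum(axis=1)
        done += r
    se = lambda v: float(v.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return float(pairs_all.mean()), float(viol_all.mean()), se(pairs_all), se(viol_all)


def simulate_random_placement(config: NullModelConfig) -> NullModelResult:
    """Monte-Carlo null curves over ``config.n_values``.

    Each crowd size uses its own child RNG stream derived from the root
    seed, so adding or reordering n values never changes other rows.
    """
    rows = []
    for n in config.n_values:
        rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), int(n)]))
        mp, mv, sp, sv = _simulate_one_n(int(n), config, rng)
        rows.append((int(n), mp, mv, sp, sv))
    table = pd.DataFrame(
        rows, columns=["n", "mean_pairs", "mean_violators", "mc_se_pairs", "mc_se_violators"]
    )
    return NullModelResult(
        area_m2=config.area_m2,
        aspect_ratio=config.aspect_ratio,
        threshold_m=config.threshold_m,
        boundary=config.boundary,
        replicates=config.replicates,
        table=table,
    )


def expected_pairs_analytic(n: int, area_m2: float, threshold_m: float) -> float:
    """Boundary-free expected violating pairs: C(n,2) * pi * d^2 / A.

    Exact on a torus; an upper bound for a plain rectangle (edge effects
    only remove d-ball coverage).
    """
    if area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    if n < 2:
        return 0.0
    return math.comb(n, 2) * math.pi * threshold_m**2 / area_m2


def rect_close_pair_probability(threshold_m: float, width_m: float, height_m: float) -> float:
    """Exact P(distance <= d) for two uniform points in a plain rectangle.

    Classical rectangle line-picking CDF, valid for d <= min(width, height):

        F(d) = [pi*w*h*d^2 - (4/3)(w+h) d^3 + d^4/2] / (w^2 h^2)
    """
    d, w, h = threshold_m, width_m, height_m
    if not (0 <= d <= min(w, h)):
        raise ValueError("closed form requires 0 <= d <= min(width, height)")
    return (math.pi * w * h * d**2 - (4.0 / 3.0) * (w + h) * d**3 + 0.5 * d**4) / (w**2 * h**2)


def capacity_linear_convention(area_m2: float, threshold_m: float) -> int:
    """Nominal violation-free capacity: floor(area / threshold).

    Under this linear convention a 650 m2 street at a 1.5 m threshold
    nominally holds 433 persons.  It is not a geometric packing bound; see
    :func:`capacity_hex_packing` for the disc-packing alternative.
    """
    if area_m2 <= 0 or threshold_m <= 0:
        raise ValueError("inputs must be positive")
    return math.floor(area_m2 / threshold_m)


def capacity_hex_packing(area_m2: float, threshold_m: float) -> int:
    """Hexagonal-packing capacity: floor(area * 2 / (sqrt(3) * d^2)).

    Maximum number of points with pairwise distance > d packable into area
    A at the optimal planar packing density (ignoring boundary loss); the
    geometrically grounded alternative to the linear convention.
    """
    if area_m2 <= 0 or threshold_m <= 0:
        raise ValueError("inputs must be positive")
    return math.floor(area_m2 * 2.0 / (math.sqrt(3.0) * threshold_m**2))


def personal_space(area_m2: float, n_present: int) -> float:
    """Average personal space: area / persons (display-rounded to integer m2)."""
    if n_present < 1:
        raise ValueError("n_present must be >= 1")
    return area_m2 / n_present


def compare_observed_to_null(
    frame_table: pd.DataFrame, null_results: Sequence[NullModelResult]
) -> pd.DataFrame:
    """Overlay observed violation counts on the null curves.

    Per crowd size n present in the data and per null curve: the observed
    mean violating-pair and violator counts, the matching null means
    (linearly interpolated where n was not simulated, flagged in the
    ``interpolated`` column), and the observed-minus-null gap whose sign is
    the behavioral-attraction diagnostic.
    """
    if len(frame_table) == 0:
        raise ValueError("empty frame table")
    if len(null_results) == 0:
        raise ValueError("need at least one null result")
    g = frame_table.groupby("n_present")
    obs = g.agg(
        n_frames=("n_violating_pairs", "size"),
        obs_mean_pairs=("n_violating_pairs", "mean"),
        obs_mean_violators=("n_violators", "mean"),
        obs_sd_pairs=("n_violating_pairs", "std"),
    ).reset_index()
    obs["obs_sd_pairs"] = obs["obs_sd_pairs"].fillna(0.0)
    obs["obs_se_pairs"] = obs["obs_sd_pairs"] / np.sqrt(obs["n_frames"])

    parts = []
    for res in null_results:
        t = res.table.sort_values("n")
        part = obs.copy()
        part["area_m2"] = res.area_m2
        part["boundary"] = res.boundary
        part["null_mean_pairs"] = np.interp(part["n_present"], t["n"], t["mean_pairs"])
        part["null_mean_violators"] = np.interp(
            part["n_present"], t["n"], t["mean_violators"]
        )
        part["null_mc_se_pairs"] = np.interp(part["n_present"], t["n"], t["mc_se_pairs"])
        part["interpolated"] = ~part["n_present"].isin(t["n"])
        part["gap_pairs"] = part["obs_mean_pairs"] - part["null_mean_pairs"]
        part["gap_violators"] = part["obs_mean_violators"] - part["null_mean_violators"]
        parts.append(part)
    return pd.concat(parts, ignore_index=True).drop(columns=["obs_sd_pairs"])
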