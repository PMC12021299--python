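"""Statistical battery for the crowding-violation association.

* Linear probability model (LPM): OLS of a binary violation indicator on
  the number of persons present, with cluster-robust (CR1 sandwich)
  standard errors, persons clustered within still frames; optional camera
  fixed effects via the within transformation.  The LPM slope is the change
  in violation probability per additional person present.
* Frame-level OLS of the per-frame violator count on persons present, with
  conventional standard errors and R-squared — the aggregation remedy for
  the mechanical within-frame dependence of individual outcomes.
* Winsorizing of the crowding measure at the Tukey outer fence
  (Q3 + 3 x IQR, type-7 quartiles).
* Binned scatterplots: equal-count quantile bins of the predictor with
  within-bin means, the standard nonparametric visualization of a
  conditional expectation.
* Krippendorff's alpha (interval or ratio level) for rater agreement on
  per-frame violation counts.

Confidence intervals use normal quantiles throughout; with tens of
thousands of clusters the difference from t quantiles is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "LpmFit",
    "AggFit",
    "WinsorResult",
    "BinnedSeries",
    "ReliabilityResult",
    "CameraFits",
    "fit_lpm_clustered",
    "fit_frame_ols",
    "winsorize_upper",
    "binscatter",
    "fit_per_camera",
    "krippendorff_alpha",
    "fits_table",
]


@dataclass(frozen=True)
class LpmFit:
    """Linear probability model fit with cluster-robust inference."""

    slope: float
    intercept: float
    se_cluster: float
    ci_level: float
    ci_low: float
    ci_high: float
    n_obs: int
    n_clusters: int
    outcome_name: str
    fixed_effects: str = "none"


@dataclass(frozen=True)
class AggFit:
    """Frame-level OLS fit (violations per frame on persons present)."""

    slope: float
    intercept: float
    se: float
    ci_level: float
    ci_low: float
    ci_high: float
    r_squared: float
    n_frames: int


@dataclass(frozen=True)
class WinsorResult:
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    n_capped: int
    values: np.ndarray


@dataclass(frozen=True)
class BinnedSeries:
    n_bins: int
    bin_x_means: np.ndarray
    bin_y_means: np.ndarray
    bin_counts: np.ndarray


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    metric_level: str
    n_units: int
    degenerate: bool = False


class CameraFits(NamedTuple):
    camera_id: str
    lpm: LpmFit | None
    agg: AggFit | None
    error: str | None


def _z(ci_level: float) -> float:
    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    return float(norm.ppf(0.5 + ci_level / 2.0))


def fit_lpm_clustered(
    person_table: pd.DataFrame,
    outcome: str = "violation",
    predictor: str = "n_present",
    cluster_cols: Sequence[str] = ("camera_id", "frame_id"),
    ci_level: float = 0.9995,
    fixed_effects: str = "none",
    small_sample: bool = True,
) -> LpmFit:
    """OLS of a binary outcome on crowding with cluster-robust variance.

    Clusters are still frames (persons in the same frame share the
    scene, so their outcomes are dependent).  The sandwich variance uses
    the CR1 small-sample scaling G/(G-1) x (N-1)/(N-k) (Stata's default);
    pass ``small_sample=False`` for plain CR0.  ``fixed_effects="camera"``
    demeans outcome and predictor within camera before fitting, which is
    exact for the slope.

    Raises if there are fewer than 2 clusters or the predictor is constant.
    """
    if fixed_effects not in ("none", "camera"):
        raise ValueError("fixed_effects must be 'none' or 'camera'")
    y = person_table[outcome].to_numpy(dtype=float)
    x = person_table[predictor].to_numpy(dtype=float)
    groups = person_table.groupby(list(cluster_cols), sort=False).ngroup().to_numpy()
    n_clusters = int(groups.max()) + 1 if len(groups) else 0
    if n_clusters < 2:
        raise ValueError("cluster-robust inference needs at least 2 clusters")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; the slope is not identified")

    if fixed_effects == "camera":
        cam = person_table["camera_id"]
        y = y - pd.Series(y).groupby(cam.values).transform("mean").to_numpy()
        x = x - pd.Series(x).groupby(cam.values).transform("mean").to_numpy()

    X = sm.add_constant(x)
    with np.errstate(invalid="ignore"):
        res = sm.OLS(y, X).fit(
            cov_type="cluster",
            cov_kwds={"groups": groups, "use_correction": small_sample},
        )
    slope = float(res.params[1])
    # the sandwich diagonal can be a tiny negative number (floating error)
    # when the true cluster-robust variance is zero
    se = float(np.sqrt(max(np.asarray(res.cov_params())[1, 1], 0.0)))
    z = _z(ci_level)
    return LpmFit(
        slope=slope,
        intercept=float(res.params[0]),
        se_cluster=se,
        ci_level=ci_level,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        n_obs=int(len(y)),
        n_clusters=n_clusters,
        outcome_name=outcome,
        fixed_effects=fixed_effects,
    )


def fit_frame_ols(
    frame_table: pd.DataFrame,
    ci_level: float = 0.995,
    outcome: str = "n_violators",
) -> AggFit:
    """OLS of the per-frame violation count on persons present."""
    if len(frame_table) < 3:
        raise ValueError("frame-level OLS needs at least 3 frames")
    x = frame_table["n_present"].to_numpy(dtype=float)
    y = frame_table[outcome].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("n_present has zero variance across frames")
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    se = float(res.bse[1])
    z = _z(ci_level)
    return AggFit(
        slope=slope,
        intercept=float(res.params[0]),
        se=se,
        ci_level=ci_level,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        r_squared=float(res.rsquared),
        n_frames=int(len(y)),
    )


def winsorize_upper(values: Iterable[float]) -> WinsorResult:
    """Cap values above the Tukey outer fence Q3 + 3 x IQR.

    Quartiles use linear interpolation (type-7, the numpy default); values
    at or below the fence are untouched, so the operation is idempotent.
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if v.size == 0:
        raise ValueError("winsorize_upper: empty input")
    if v.size < 4 or not np.isfinite(v).all():
        raise ValueError("winsorize_upper needs at least 4 finite values")
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    fence = q3 + 3.0 * iqr
    capped = np.minimum(v, fence)
    return WinsorResult(
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        upper_fence=float(fence),
        n_capped=int((v > fence).sum()),
        values=capped,
    )


def binscatter(x: Iterable[float], y: Iterable[float], n_bins: int = 20) -> BinnedSeries:
    """Equal-count quantile binning: within-bin means of x and y.

    Observations are sorted by x (stable sort) and split into ``n_bins``
    consecutive chunks whose sizes differ by at most one; the per-chunk
    means are returned in ascending-x order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > np.unique(x).size:
        raise ValueError("n_bins exceeds the number of distinct x values")
    order = np.argsort(x, kind="stable")
    chunks = np.array_split(order, n_bins)
    return BinnedSeries(
        n_bins=n_bins,
        bin_x_means=np.array([x[c].mean() for c in chunks]),
        bin_y_means=np.array([y[c].mean() for c in chunks]),
        bin_counts=np.array([len(c) for c in chunks]),
    )


def fit_per_camera(
    person_table: pd.DataFrame,
    frame_table: pd.DataFrame,
    ci_level_person: float = 0.9995,
    ci_level_frame: float = 0.995,
) -> list[CameraFits]:
    """Person-level LPM and frame-level OLS separately for each camera.

    Cameras whose data fail a fit precondition (too few frames, constant
    crowding) are reported with the error message rather than dropped.
    """
    out: list[CameraFits] = []
    cameras = person_table["camera_id"].drop_duplicates().tolist()
    for cam in cameras:
        p = person_table[person_table["camera_id"] == cam]
        f = frame_table[frame_table["camera_id"] == cam]
        lpm = agg = None
        errs = []
        try:
            lpm = fit_lpm_clustered(p, ci_level=ci_level_person)
        except ValueError as e:
            errs.append(f"lpm: {e}")
        try:
            agg = fit_frame_ols(f, ci_level=ci_level_frame)
        except ValueError as e:
            errs.append(f"ols: {e}")
        out.append(CameraFits(cam, lpm, agg, "; ".join(errs) or None))
    return out


def krippendorff_alpha(
    ratings_a: Iterable[float],
    ratings_b: Iterable[float],
    metric_level: str = "interval",
) -> ReliabilityResult:
    """Krippendorff's alpha for two aligned raters.

    alpha = 1 - D_o / D_e with the full coincidence-matrix computation:
    observed disagreement D_o pools within-unit value pairs, expected
    disagreement D_e pools all value pairs regardless of unit.  Interval
    level uses squared differences; ratio level uses squared relative
    differences.  If every rating in the whole matrix is identical the
    expected disagreement is zero and alpha is 1 by convention (flagged
    ``degenerate``).
    """
    if metric_level not in ("interval", "ratio"):
        raise ValueError("metric_level must be 'interval' or 'ratio'")
    a = np.asarray(list(ratings_a), dtype=float)
    b = np.asarray(list(ratings_b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be aligned equal-length vectors")
    n_units = a.size
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("ratings must be finite")

    pooled = np.concatenate([a, b])
    vals, inv = np.unique(pooled, return_inverse=True)
    n_c = np.bincount(inv).astype(float)  # pooled value frequencies
    n_total = pooled.size  # = 2 x units; every unit fully rated

    if metric_level == "interval":
        delta = (vals[:, None] - vals[None, :]) ** 2
    else:
        denom = vals[:, None] + vals[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = ((vals[:, None] - vals[None, :]) / denom) ** 2
        delta = np.nan_to_num(delta)

    d_e = float(n_c @ delta @ n_c) / (n_total * (n_total - 1))
    if d_e == 0.0:
        return ReliabilityResult(1.0, metric_level, n_units, degenerate=True)

    ia, ib = inv[:n_units], inv[n_units:]
    # two raters: each unit contributes its ordered value pair twice, /(m_u-1)=1
    d_o = float(2.0 * delta[ia, ib].sum()) / n_total
    return ReliabilityResult(1.0 - d_o / d_e, metric_level, n_units)


def fits_table(named_fits: Sequence[tuple[str, LpmFit | AggFit]]) -> pd.DataFrame:
    """Flatten fits into the standard results table (one row per model)."""
    rows = []
    for name, fit in named_fits:
        if isinstance(fit, LpmFit):
            rows.append(
                dict(
                    model=name,
                    outcome=fit.outcome_name,
                    fixed_effects=fit.fixed_effects,
                    slope=fit.slope,
                    se=fit.se_cluster,
                    ci_level=fit.ci_level,
                    ci_low=fit.ci_low,
                    ci_high=fit.ci_high,
                    n=fit.n_obs,
                    clusters=fit.n_clusters,
                    r_squared=np.nan,
                )
            )
        else:
            rows.append(
                dict(
                    model=name,
                    outcome="n_violators",
                    fixed_effects="none",
                    slope=fit.slope,
                    se=fit.se,
                    ci_level=fit.ci_level,
                    ci_low=fit.ci_low,
                    ci_high=fit.ci_high,
                    n=fit.n_frames,
                    clusters=np.nan,
                    r_squared=fit.r_squared,
                )
            )
    return pd.DataFrame(rows)
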