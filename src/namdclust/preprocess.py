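"""Scaling, temporal resampling, and random subsampling of feature tables.

Feature tables are DataFrames indexed by ``(traj, time)``.  Two scalers are
provided: z-score standardization, x -> (x - mu)/sigma with population
sigma, and min-max scaling to a fixed range.  SOAP descriptors are a
coherent spectral series whose relative magnitudes carry the structure, so
scaling them feature-wise is refused unless explicitly forced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ScalerParams",
    "zscore_scale",
    "minmax_scale",
    "apply_scaler",
    "resample_by_stride",
    "random_subsample",
]


@dataclass(frozen=True)
class ScalerParams:
    """Persisted per-feature scaling parameters.

    For ``kind='zscore'``: ``center`` = mu, ``scale`` = population sigma.
    For ``kind='minmax'``: ``center`` = column minimum, ``scale`` = max - min,
    plus the target ``feature_range``.  Zero ``scale`` marks a constant
    column (mapped to 0 for z-score, the range midpoint for min-max).
    """

    kind: str
    columns: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    feature_range: tuple[float, float] = (0.0, 1.0)

    def transform(self, t: pd.DataFrame) -> pd.DataFrame:
        if tuple(t.columns) != self.columns:
            raise DataError("table columns do not match the scaler's")
        x = t.to_numpy(dtype=float)
        safe = np.where(self.scale > 0, self.scale, 1.0)
        if self.kind == "zscore":
            out = (x - self.center) / safe
            out[:, self.scale == 0] = 0.0
        elif self.kind == "minmax":
            lo, hi = self.feature_range
            out = lo + (x - self.center) / safe * (hi - lo)
            out[:, self.scale == 0] = 0.5 * (lo + hi)
        else:
            raise ConfigError(f"unknown scaler kind {self.kind!r}")
        return pd.DataFrame(out, index=t.index, columns=t.columns)

    def inverse_transform(self, t: pd.DataFrame) -> pd.DataFrame:
        x = t.to_numpy(dtype=float)
        if self.kind == "zscore":
            out = x * self.scale + self.center
        elif self.kind == "minmax":
            lo, hi = self.feature_range
            out = (x - lo) / (hi - lo) * self.scale + self.center
        else:
            raise ConfigError(f"unknown scaler kind {self.kind!r}")
        out[:, self.scale == 0] = np.broadcast_to(
            self.center, x.shape
        )[:, self.scale == 0]
        return pd.DataFrame(out, index=t.index, columns=t.columns)


def zscore_scale(t: pd.DataFrame) -> tuple[pd.DataFrame, ScalerParams]:
    """Standardize each column to mean 0, (population) standard deviation 1.

    Constant columns (sigma = 0) are mapped to 0 with a logged warning.
    """
    if t.empty:
        raise DataError("cannot scale an empty table")
    x = t.to_numpy(dtype=float)
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=0)
    if np.any(sigma == 0):
        const = [c for c, s in zip(t.columns, sigma) if s == 0]
        logger.warning("constant columns mapped to 0 under z-score: %s", const)
    params = ScalerParams("zscore", tuple(t.columns), mu, sigma)
    return params.transform(t), params


def minmax_scale(
    t: pd.DataFrame, feature_range: tuple[float, float] = (0.0, 1.0)
) -> tuple[pd.DataFrame, ScalerParams]:
    """Rescale each column linearly into ``feature_range``.

    Constant columns map to the range midpoint.
    """
    if t.empty:
        raise DataError("cannot scale an empty table")
    lo, hi = feature_range
    if hi <= lo:
        raise ConfigError("feature_range must satisfy max > min")
    x = t.to_numpy(dtype=float)
    cmin = x.min(axis=0)
    crange = x.max(axis=0) - cmin
    if np.any(crange == 0):
        const = [c for c, s in zip(t.columns, crange) if s == 0]
        logger.warning("constant columns mapped to range midpoint: %s", const)
    params = ScalerParams("minmax", tuple(t.columns), cmin, crange, (lo, hi))
    return params.transform(t), params


def apply_scaler(
    t: pd.DataFrame,
    kind: str,
    descriptor: str | None = None,
    force: bool = False,
    feature_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[pd.DataFrame, ScalerParams | None]:
    """Dispatch on scaler kind, honoring the no-scaling rule for SOAP.

    SOAP tables keep ``kind='none'`` by default; requesting z-score or
    min-max on a SOAP descriptor raises unless ``force=True``.
    """
    if kind == "none":
        return t, None
    if descriptor == "soap" and not force:
        raise ConfigError(
            "feature-wise scaling would break the SOAP spectral series; "
            "pass force=True (config: force_scale) to override"
        )
    if kind == "zscore":
        return zscore_scale(t)
    if kind == "minmax":
        return minmax_scale(t, feature_range)
    raise ConfigError(f"unknown scaler {kind!r}; choose zscore, minmax or none")


def resample_by_stride(t: pd.DataFrame, stride_fs: float) -> pd.DataFrame:
    """Keep frames whose time is an integer multiple of ``stride_fs``.

    Times are matched within 1e-6 fs, per trajectory.  A stride smaller
    than the native time step leaves the table unchanged with a warning.
    """
    if stride_fs <= 0:
        raise ConfigError("stride_fs must be positive")
    times = t.index.get_level_values("time").to_numpy(dtype=float)
    trajs = t.index.get_level_values("traj").to_numpy()
    native = np.inf
    for traj in np.unique(trajs):
        tt = np.sort(times[trajs == traj])
        if tt.size > 1:
            native = min(native, float(np.min(np.diff(tt))))
    if np.isfinite(native) and stride_fs < native - 1e-9:
        logger.warning(
            "stride %.6g fs below native step %.6g fs; table returned unchanged",
            stride_fs,
            native,
        )
        return t
    keep = np.abs(times - np.round(times / stride_fs) * stride_fs) <= 1e-6
    return t.loc[keep]


def random_subsample(t: pd.DataFrame, n: int, seed: int) -> pd.DataFrame:
    """Uniform sample of ``n`` rows without replacement, seeded.

    The original row order is preserved among the kept rows.
    """
    if not 1 <= n <= len(t):
        raise DataError(f"subsample size {n} outside [1, {len(t)}]")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(t), size=n, replace=False))
    return t.iloc[idx]
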