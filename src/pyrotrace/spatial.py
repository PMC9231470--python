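"""Spatial and attribute pattern tests on per-artifact temperature estimates.

The archaeological question is whether artifact heating temperatures
show any structure: a spatially coherent cluster of burnt pieces in a
constrained temperature range would point at an in-place fire feature,
and a dependence on artifact size or type would hint at sampling or
taphonomic artifacts.  Both are tested with transparent permutation
machinery:

* Moran's I (row-standardized weights) with a temperature-shuffling
  permutation null for spatial autocorrelation;
* mean within-square temperature SD with a square-label-shuffling null
  for the "constrained temperature range per square" pattern;
* Spearman rank correlation per size attribute, and between-type
  variance of mean temperature, each with label permutation.

All p-values use the add-one convention p = (1 + #{perm as extreme}) /
(1 + n_perm), so p > 0 always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from pyrotrace.exceptions import InputError, UndefinedStatisticError


@dataclass(frozen=True)
class SpatialReport:
    morans_i: float
    p_perm_spatial: float
    within_square_dispersion: float | None
    p_perm_square: float | None
    n_perm: int
    seed: int
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class AttributeReport:
    size_tests: dict  # attribute -> (spearman_rho, p_perm)
    type_test: tuple[float, float] | None  # (between-type dispersion, p_perm)
    n_perm: int
    seed: int
    notes: tuple[str, ...] = ()


def _weight_matrix(coords: np.ndarray, weight_scheme, seed: int = 0) -> np.ndarray:
    """Row-standardized spatial weights.

    ``weight_scheme`` is ``"inverse_distance"`` or ``("knn", k)``.
    Duplicate coordinates under inverse distance get a deterministic
    1 cm jitter derived from ``seed``.
    """
    n = coords.shape[0]
    if isinstance(weight_scheme, (tuple, list)):
        scheme, k = weight_scheme[0], int(weight_scheme[1])
    else:
        scheme, k = weight_scheme, 4
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    if scheme == "inverse_distance":
        off = ~np.eye(n, dtype=bool)
        if np.any(d[off] == 0.0):
            rng = np.random.default_rng(seed)
            coords = coords + rng.normal(0.0, 0.01, size=coords.shape)  # 1 cm jitter
            d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros((n, n))
        for i in range(n):
            order = np.argsort(d[i], kind="stable")
            neighbors = [j for j in order if j != i][:k]
            w[i, neighbors] = 1.0
    else:
        raise InputError(f"unknown weight scheme {weight_scheme!r}")
    rowsum = w.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0.0] = 1.0
    return w / rowsum


def morans_i(
    coords,
    values,
    weight_scheme="inverse_distance",
    seed: int = 0,
    weights: np.ndarray | None = None,
) -> float:
    """Moran's I spatial autocorrelation with row-standardized weights.

    I = (n / W) · Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ² with zᵢ the centered values and
    W the total weight.  Raises :class:`UndefinedStatisticError` for
    constant values.
    """
    coords = np.asarray(coords, dtype=float)
    z = np.asarray(values, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise InputError("coords must be an (n, 2) array of planar meters")
    n = coords.shape[0]
    if n < 4:
        raise InputError("morans_i needs n >= 4 points")
    if z.shape != (n,):
        raise InputError("values must pair with coords")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise UndefinedStatisticError("constant values: Moran's I undefined")
    w = _weight_matrix(coords, weight_scheme, seed) if weights is None else weights
    total_w = float(w.sum())
    return float((n / total_w) * (z @ w @ z) / denom)


def cluster_test(
    artifacts: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    weight_scheme="inverse_distance",
    temp_col: str = "temp_mean_C",
) -> SpatialReport:
    """Permutation tests for spatial temperature patterning.

    Shuffling temperatures over fixed coordinates gives the null for
    Moran's I (one-sided, high I = clustering of like temperatures);
    shuffling square labels gives the null for the mean within-square
    SD (one-sided, low SD = squares with constrained temperature
    ranges).  The frame needs ``x_m``, ``y_m``, ``square`` and the
    temperature column; rows with missing values are dropped.
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    required = {"x_m", "y_m", temp_col}
    missing = required - set(artifacts.columns)
    if missing:
        raise InputError(f"artifact table lacks columns {sorted(missing)}")
    df = artifacts.dropna(subset=sorted(required)).reset_index(drop=True)
    if len(df) < 4:
        raise InputError("cluster_test needs >= 4 artifacts with coordinates")
    coords = df[["x_m", "y_m"]].to_numpy(dtype=float)
    temps = df[temp_col].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    w = _weight_matrix(coords, weight_scheme, seed)
    obs_i = morans_i(coords, temps, weights=w)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(temps)
        if morans_i(coords, perm, weights=w) >= obs_i:
            count += 1
    p_spatial = (1 + count) / (1 + n_perm)

    notes: list[str] = []
    disp = p_square = None
    if "square" in df.columns and df["square"].nunique() >= 2:
        squares = df["square"].to_numpy()
        obs_disp = _within_square_sd(temps, squares)
        count = 0
        for _ in range(n_perm):
            if _within_square_sd(temps, rng.permutation(squares)) <= obs_disp:
                count += 1
        disp, p_square = obs_disp, (1 + count) / (1 + n_perm)
    else:
        notes.append("square test skipped: all artifacts share one square")
    return SpatialReport(
        morans_i=obs_i, p_perm_spatial=p_spatial,
        within_square_dispersion=disp, p_perm_square=p_square,
        n_perm=n_perm, seed=seed, notes=tuple(notes),
    )


def _within_square_sd(temps: np.ndarray, squares: np.ndarray) -> float:
    """Mean of per-square sample SDs over squares with >= 2 artifacts."""
    sds = []
    for sq in np.unique(squares):
        grp = temps[squares == sq]
        if grp.size >= 2:
            sds.append(np.std(grp, ddof=1))
    if not sds:
        return float("nan")
    return float(np.mean(sds))


def attribute_test(
    temps,
    attributes: pd.DataFrame,
    types=None,
    n_perm: int = 999,
    seed: int = 0,
) -> AttributeReport:
    """Size and type dependence of estimated temperatures.

    For each attribute column, Spearman's rho with a two-sided
    permutation p (attribute values shuffled).  For the type labels,
    the statistic is the artifact-count-weighted between-type variance
    of mean temperature, with a one-sided (greater) permutation p.
    Constant attributes and single-type label lists are skipped with a
    notice rather than an error.
    """
    if n_perm < 99:
        raise InputError("n_perm must be >= 99")
    temps = np.asarray(temps, dtype=float)
    if len(attributes) != temps.size:
        raise InputError("attributes table must pair with temps")
    rng = np.random.default_rng(seed)
    notes: list[str] = []
    size_tests: dict[str, tuple[float, float]] = {}
    for col in attributes.columns:
        vals = attributes[col].to_numpy(dtype=float)
        ok = np.isfinite(vals) & np.isfinite(temps)
        if ok.sum() < 4 or np.unique(vals[ok]).size < 2:
            notes.append(f"attribute {col!r} skipped: constant or too few values")
            continue
        v, t = vals[ok], temps[ok]
        rho = float(stats.spearmanr(v, t).statistic)
        count = 0
        for _ in range(n_perm):
            if abs(float(stats.spearmanr(rng.permutation(v), t).statistic)) >= abs(rho):
                count += 1
        size_tests[col] = (rho, (1 + count) / (1 + n_perm))

    type_test = None
    if types is not None:
        labels = np.asarray(types)
        if np.unique(labels).size < 2:
            notes.append("type test skipped: fewer than 2 type labels")
        else:
            obs = _between_type_variance(temps, labels)
            count = 0
            for _ in range(n_perm):
                if _between_type_variance(temps, rng.permutation(labels)) >= obs:
                    count += 1
            type_test = (obs, (1 + count) / (1 + n_perm))
    return AttributeReport(
        size_tests=size_tests, type_test=type_test,
        n_perm=n_perm, seed=seed, notes=tuple(notes),
    )


def _between_type_variance(temps: np.ndarray, labels: np.ndarray) -> float:
    grand = temps.mean()
    total = 0.0
    for lab in np.unique(labels):
        grp = temps[labels == lab]
        total += grp.size * (grp.mean() - grand) ** 2
    return float(total / temps.size)
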