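"""Spectrum container, file I/O and the shared preprocessing recipe.

A :class:`Spectrum` is one instrument trace: a strictly increasing
wavenumber axis (cm⁻¹), matching intensities, a ``kind`` tag and free-form
metadata.  Files are read and written as JCAMP-DX (``##XYDATA=(XY..XY)``,
single block, 1/CM abscissa) or as two-column CSV with the header
``wavenumber_cm1,intensity``.

Preprocessing — common-grid interpolation, baseline removal, optional
Savitzky–Golay smoothing and normalization — is bundled into a
:class:`PreprocessRecipe` so that a trained model can carry its exact
recipe with it.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from pyrotrace.exceptions import (
    InputError,
    SpectrumDataError,
    SpectrumParseError,
)

SpectrumKind = Literal["raman_uv", "ftir_absorbance"]

#: Default wavenumber grids (min, max, step) in cm⁻¹.
RAMAN_GRID = (200.0, 1800.0, 2.0)
FTIR_GRID = (400.0, 4000.0, 4.0)


@dataclass
class Spectrum:
    """One instrument trace.

    Parameters
    ----------
    wavenumbers
        Strictly increasing axis in cm⁻¹.
    intensities
        Same length as ``wavenumbers``; finite values.
    kind
        ``"raman_uv"`` or ``"ftir_absorbance"``.
    meta
        Provenance: ``sample_id``, ``replicate_index``, instrument notes.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    kind: str = "raman_uv"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumDataError("axis and intensities must be 1-D")
        if self.wavenumbers.shape != self.intensities.shape:
            raise SpectrumDataError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise SpectrumDataError("wavenumber axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise SpectrumDataError("intensities contain non-finite values")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Return the sub-spectrum on the closed interval [lo, hi] cm⁻¹."""
        m = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if not m.any():
            raise InputError(f"window [{lo}, {hi}] cm-1 is outside the axis")
        return replace(self, wavenumbers=self.wavenumbers[m], intensities=self.intensities[m])

    def covers(self, lo: float, hi: float) -> bool:
        return bool(self.wavenumbers[0] <= lo and self.wavenumbers[-1] >= hi)


@dataclass(frozen=True)
class PreprocessRecipe:
    """Deterministic preprocessing bound to a thermometer or classifier.

    ``target_grid`` is (min, max, step) in cm⁻¹; interpolation onto it is
    linear and extrapolation is forbidden.  ``baseline`` is either
    ``"als"`` (asymmetric least squares, Eilers-style, parameters
    ``als_lam``/``als_p``) or ``"rolling_min"`` (window in points), or
    ``"none"``.  ``normalization`` is ``"max"`` (peak maximum scaled to 1),
    ``"area"`` (trapezoid area 1) or ``"vector"`` (unit Euclidean norm),
    or ``"none"``.  Optional Savitzky–Golay smoothing runs before baseline
    removal; its window must be odd and ≥ 5.
    """

    target_grid: tuple[float, float, float] = RAMAN_GRID
    baseline: str = "als"
    als_lam: float = 1e5
    als_p: float = 0.01
    rolling_min_window: int = 101
    normalization: str = "max"
    smooth_window: int | None = None
    smooth_order: int = 2

    def __post_init__(self) -> None:
        lo, hi, step = self.target_grid
        if step <= 0 or hi <= lo:
            raise InputError(f"bad target grid {self.target_grid}")
        if self.baseline not in ("als", "rolling_min", "none"):
            raise InputError(f"unknown baseline method {self.baseline!r}")
        if self.normalization not in ("max", "area", "vector", "none"):
            raise InputError(f"unknown normalization {self.normalization!r}")
        if self.smooth_window is not None:
            if self.smooth_window < 5 or self.smooth_window % 2 == 0:
                raise InputError("smoothing window must be odd and >= 5")

    def grid(self) -> np.ndarray:
        lo, hi, step = self.target_grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


def make_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive wavenumber grid from lo to hi at the given step."""
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


# ---------------------------------------------------------------------------
# file I/O


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".jdx", ".dx", ".jcm", ".jcamp"):
        return "jcampdx"
    return "csv"


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum from JCAMP-DX or two-column CSV.

    A descending abscissa is reversed so the returned axis is ascending.
    JCAMP header fields are captured into ``Spectrum.meta``.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    text = path.read_text(encoding="utf-8")
    if fmt == "jcampdx":
        x, y, meta, kind = _parse_jcamp(text)
    elif fmt == "csv":
        x, y = _parse_csv(text)
        meta, kind = {}, "raman_uv"
    else:
        raise InputError(f"unknown spectrum format {fmt!r}")
    meta.setdefault("path", str(path))
    if x.size >= 2 and x[0] > x[-1]:
        x, y = x[::-1].copy(), y[::-1].copy()
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    if x.size >= 2 and np.any(np.diff(x) <= 0):
        raise SpectrumDataError(f"{path}: duplicate wavenumbers after sorting")
    return Spectrum(x, y, kind=kind, meta=meta)


def _parse_csv(text: str) -> tuple[np.ndarray, np.ndarray]:
    rows = list(csv.reader(io.StringIO(text)))
    xs, ys = [], []
    for lineno, row in enumerate(rows, start=1):
        if not row or not "".join(row).strip():
            continue
        cells = [c.strip() for c in row[:2]]
        if lineno == 1 and not _is_number(cells[0]):
            continue  # header line
        try:
            xs.append(float(cells[0]))
            ys.append(float(cells[1]))
        except (ValueError, IndexError) as exc:
            raise SpectrumParseError(f"CSV line {lineno}: cannot parse {row!r}") from exc
    if not xs:
        raise SpectrumParseError("CSV contains no data rows")
    return np.array(xs), np.array(ys)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _parse_jcamp(text: str) -> tuple[np.ndarray, np.ndarray, dict, str]:
    meta: dict = {}
    xs: list[float] = []
    ys: list[float] = []
    mode = None  # None | "xyxy" | "xpp"
    firstx = lastx = None
    npoints = None
    yfactor = 1.0
    xfactor = 1.0
    xpp_rows: list[list[float]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "END":
                break
            if key in ("XYDATA", "XYPOINTS"):
                mode = "xpp" if "++" in value else "xyxy"
                continue
            mode = None
            meta[key.lower()] = value
            if key == "FIRSTX":
                firstx = float(value)
            elif key == "LASTX":
                lastx = float(value)
            elif key == "NPOINTS":
                npoints = int(float(value))
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "XFACTOR":
                xfactor = float(value)
            continue
        if mode == "xyxy":
            parts = [p for p in line.replace(";", " ").replace(",", " ").split() if p]
            if len(parts) % 2 != 0:
                raise SpectrumParseError(f"JCAMP line {lineno}: odd token count in XY pairs")
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise SpectrumParseError(f"JCAMP line {lineno}: non-numeric token") from exc
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
        elif mode == "xpp":
            parts = line.replace(",", " ").split()
            try:
                xpp_rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SpectrumParseError(f"JCAMP line {lineno}: non-numeric token") from exc
    if mode is None and not xs and not xpp_rows:
        raise SpectrumParseError("no ##XYDATA or ##XYPOINTS block found")
    if xpp_rows:
        if firstx is None or lastx is None or npoints is None:
            raise SpectrumParseError("X++(Y..Y) data requires FIRSTX, LASTX and NPOINTS")
        yvals = [v for row in xpp_rows for v in row[1:]]
        if len(yvals) != npoints:
            raise SpectrumParseError(
                f"NPOINTS={npoints} but {len(yvals)} Y values present"
            )
        x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
        y = np.array(yvals) * yfactor
    else:
        x = np.array(xs) * xfactor
        y = np.array(ys) * yfactor
    kind = "ftir_absorbance" if "infrared" in meta.get("datatype", "").lower() else "raman_uv"
    if "sample_id" not in meta and "title" in meta:
        meta["sample_id"] = meta["title"]
    return x, y, meta, kind


def write_spectrum(spectrum: Spectrum, path: str | Path, format: str | None = None) -> None:
    """Write a spectrum as JCAMP-DX (XY pairs, 1/CM) or two-column CSV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        lines = ["wavenumber_cm1,intensity"]
        lines += [
            f"{x:.6f},{y:.10g}"
            for x, y in zip(spectrum.wavenumbers, spectrum.intensities)
        ]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    if fmt != "jcampdx":
        raise InputError(f"unknown spectrum format {fmt!r}")
    title = str(spectrum.meta.get("sample_id", path.stem))
    datatype = (
        "INFRARED SPECTRUM" if spectrum.kind == "ftir_absorbance" else "RAMAN SPECTRUM"
    )
    header = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        f"##DATA TYPE={datatype}",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE" if spectrum.kind == "ftir_absorbance" else "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={spectrum.wavenumbers[0]:.6f}",
        f"##LASTX={spectrum.wavenumbers[-1]:.6f}",
        f"##NPOINTS={len(spectrum)}",
        "##XYDATA=(XY..XY)",
    ]
    body = [
        f"{x:.6f}, {y:.10g}"
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities)
    ]
    path.write_text("\n".join(header + body + ["##END="]) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# preprocessing


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01, niter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline (Eilers & Boelens).

    Minimizes sum(w (y-z)^2) + lam * sum((Δ²z)^2) with asymmetric weights:
    p for points above the baseline, 1-p below.
    """
    n = y.size
    if n < 3:
        return np.zeros_like(y)
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y.copy()
    for _ in range(niter):
        wmat = sparse.diags(w)
        z = spsolve((wmat + dtd).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    return z


def rolling_min_baseline(y: np.ndarray, window: int) -> np.ndarray:
    """Rolling-minimum baseline, smoothed by a same-width moving average."""
    from scipy.ndimage import minimum_filter1d, uniform_filter1d

    mn = minimum_filter1d(y, size=window, mode="nearest")
    return uniform_filter1d(mn, size=window, mode="nearest")


def preprocess(spectrum: Spectrum, recipe: PreprocessRecipe) -> Spectrum:
    """Apply a recipe: regrid → smooth → baseline-subtract → normalize.

    The input must cover the recipe's target grid; extrapolation is
    refused with an :class:`InputError` naming the missing range.
    Output is deterministic and idempotent on the target grid up to the
    normalization invariant.
    """
    grid = recipe.grid()
    if not spectrum.covers(grid[0], grid[-1]):
        raise InputError(
            f"spectrum covers [{spectrum.wavenumbers[0]:.1f}, "
            f"{spectrum.wavenumbers[-1]:.1f}] cm-1 but the recipe needs "
            f"[{grid[0]:.1f}, {grid[-1]:.1f}] cm-1"
        )
    y = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    if recipe.smooth_window is not None:
        y = savgol_filter(y, recipe.smooth_window, recipe.smooth_order)
    if recipe.baseline == "als":
        y = y - als_baseline(y, recipe.als_lam, recipe.als_p)
    elif recipe.baseline == "rolling_min":
        y = y - rolling_min_baseline(y, recipe.rolling_min_window)
    if recipe.normalization == "max":
        peak = np.max(np.abs(y))
        if peak > 0:
            y = y / peak
    elif recipe.normalization == "area":
        area = np.trapezoid(np.abs(y), grid)
        if area > 0:
            y = y / area
    elif recipe.normalization == "vector":
        nrm = float(np.linalg.norm(y))
        if nrm > 0:
            y = y / nrm
    return Spectrum(grid, y, kind=spectrum.kind, meta=dict(spectrum.meta))


def estimate_noise(spectrum: Spectrum, quiet_window: tuple[float, float]) -> float:
    """Robust noise SD in a signal-free window.

    Detrends the window with a first-order fit, then returns
    1.4826 × median(|residual − median(residual)|).  Requires ≥ 20 points.
    """
    lo, hi = quiet_window
    sub = spectrum.crop(lo, hi)
    if len(sub) < 20:
        raise InputError(
            f"quiet window [{lo}, {hi}] has {len(sub)} points; >= 20 required"
        )
    coeff = np.polyfit(sub.wavenumbers, sub.intensities, 1)
    resid = sub.intensities - np.polyval(coeff, sub.wavenumbers)
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)
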