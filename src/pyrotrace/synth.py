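"""Synthetic Raman/FTIR spectra with known latent heating temperatures.

The generator emulates the four diagnostic heat responses the pipeline
relies on, each as a smooth parametric response of temperature T (°C):

* flint UV Raman — the moganite band (~501 cm⁻¹) shrinks relative to the
  α-quartz main band (~465 cm⁻¹) with heating (logistic decay); the
  disordered/graphitic carbon D (~1,350 cm⁻¹) and G (~1,600 cm⁻¹) bands
  rise then fall; the quartz band broadens linearly;
* bone/tusk FTIR — a 630 cm⁻¹ hydroxyl libration band appears if and
  only if T reaches the hydroxylation onset (600 °C by default), on top
  of the usual bioapatite bands (phosphate ν4 doublet, ν3, carbonate)
  and a collagen amide I band that decays with heating;
* sediment FTIR — clay structural-water bands near 3,600–3,700 cm⁻¹
  vanish smoothly above the clay dehydroxylation onset (450 °C default)
  and are fully absent 100 °C past it, over quartz/clay/calcite
  framework bands.

Bands are pseudo-Voigt; inter-source flint variability enters through
per-source moganite fraction, carbon load, baseline shape and
multiplicative jitter on the heat-response parameters.  Every generator
is a pure function of its arguments and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from pyrotrace.exceptions import DomainError, InputError
from pyrotrace.spectra import FTIR_GRID, RAMAN_GRID, Spectrum, make_grid, write_spectrum

TEMP_MIN, TEMP_MAX = 20.0, 1200.0

#: Default calibration temperatures for simulated heating experiments (°C).
DEFAULT_TRAIN_TEMPS = (20.0, 200.0, 300.0, 400.0, 500.0, 600.0, 700.0, 800.0, 900.0)

#: Replicate Raman spectra recorded per lithic sample.
DEFAULT_N_REPLICATES = 27


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def pseudo_voigt(
    x: np.ndarray, center: float, fwhm: float, amplitude: float, eta_gauss: float = 0.7
) -> np.ndarray:
    """Unit-height pseudo-Voigt band scaled to ``amplitude``.

    ``eta_gauss`` is the Gaussian fraction; the Lorentzian fraction is
    ``1 - eta_gauss``.
    """
    if fwhm <= 0:
        raise InputError("fwhm must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    gamma = fwhm / 2.0
    g = np.exp(-0.5 * ((x - center) / sigma) ** 2)
    lo = 1.0 / (1.0 + ((x - center) / gamma) ** 2)
    return amplitude * (eta_gauss * g + (1.0 - eta_gauss) * lo)


@dataclass(frozen=True)
class HeatResponseParams:
    """Parameters of the temperature-response functions (all °C-based).

    The logistic transitions are parameterized by a midpoint (T50) and a
    width; widths must be positive and onsets lie in [0, 1200] °C.
    """

    moganite_decay_T50: float = 425.0
    moganite_decay_width: float = 80.0
    dg_growth_T50: float = 350.0
    dg_growth_width: float = 60.0
    dg_peak_T: float = 600.0
    dg_decline_width: float = 150.0
    quartz_width_slope: float = 1.0  # cm-1 per 100 C
    quartz_width_base: float = 8.0  # cm-1 FWHM at 20 C
    hydroxyl_onset_T: float = 600.0  # bone
    clay_dehydrox_onset_T: float = 450.0  # sediment

    def __post_init__(self) -> None:
        for name in ("moganite_decay_width", "dg_growth_width", "dg_decline_width"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be > 0")
        for name in ("hydroxyl_onset_T", "clay_dehydrox_onset_T"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1200.0:
                raise InputError(f"{name}={v} outside [0, 1200] C")

    # response functions -------------------------------------------------
    def moganite_retention(self, temp: float) -> float:
        """Fraction of the unheated moganite/quartz ratio surviving at temp.

        Strictly decreasing logistic in temp; ~1 at room temperature,
        ~0 at the high-temperature asymptote.
        """
        return float(_sigmoid((self.moganite_decay_T50 - temp) / self.moganite_decay_width))

    def dg_response(self, temp: float) -> float:
        """Rise-then-fall response of the carbon D/G band amplitudes."""
        rise = _sigmoid((temp - self.dg_growth_T50) / self.dg_growth_width)
        fall = _sigmoid((self.dg_peak_T + self.dg_decline_width - temp) / self.dg_decline_width)
        return float(rise * fall)

    def quartz_fwhm(self, temp: float) -> float:
        """α-quartz main-band FWHM (cm⁻¹), increasing linearly with temp."""
        return self.quartz_width_base + self.quartz_width_slope * (temp - 20.0) / 100.0

    def hydroxyl_amplitude(self, temp: float) -> float:
        """630 cm⁻¹ band amplitude factor: 0 below onset, > 0 and
        non-decreasing at/above onset.

        The band marks a recrystallization transition, so it appears at
        half strength right at the onset and grows with further heating
        rather than ramping up from zero.
        """
        if temp < self.hydroxyl_onset_T:
            return 0.0
        frac = min(1.0, (temp - self.hydroxyl_onset_T) / 300.0)
        return 0.5 + 0.5 * frac

    def clay_water_retention(self, temp: float) -> float:
        """Clay structural-water retention: 1 at/below onset, smoothstep
        to exactly 0 at onset + 100 °C."""
        t0 = self.clay_dehydrox_onset_T
        r = np.clip((temp - t0) / 100.0, 0.0, 1.0)
        return float(1.0 - r * r * (3.0 - 2.0 * r))

    def jittered(self, multipliers: dict[str, float]) -> "HeatResponseParams":
        """Per-source perturbed copy; multipliers must lie in [0.5, 2.0]."""
        updates = {}
        for key, m in multipliers.items():
            if not 0.5 <= m <= 2.0:
                raise InputError(f"jitter multiplier {key}={m} outside [0.5, 2.0]")
            updates[key] = getattr(self, key) * m
        return replace(self, **updates)


@dataclass(frozen=True)
class FlintSource:
    """One flint raw-material source with its intrinsic variability."""

    source_id: str
    moganite_fraction: float = 0.6
    carbon_load: float = 1.0
    baseline_shape_coeffs: tuple[float, ...] = (0.15, -0.05, 0.02)
    response_jitter: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.moganite_fraction <= 1.0:
            raise InputError("moganite_fraction must lie in [0, 1]")
        if self.carbon_load < 0:
            raise InputError("carbon_load must be >= 0")
        for key, m in self.response_jitter.items():
            if not 0.5 <= m <= 2.0:
                raise InputError(f"jitter multiplier {key}={m} outside [0.5, 2.0]")


@dataclass(frozen=True)
class SyntheticSample:
    """Declarative description of one simulated sample."""

    sample_id: str
    material: str  # flint | bone | tusk | sediment
    true_temperature: float
    source: object = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.material not in ("flint", "bone", "tusk", "sediment"):
            raise InputError(f"unknown material {self.material!r}")
        if self.true_temperature < TEMP_MIN:
            raise InputError(f"true_temperature must be >= {TEMP_MIN} C")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")


def random_source(source_id: str, rng: np.random.Generator) -> FlintSource:
    """Draw a flint source with realistic between-source spread."""
    jitter_keys = ("moganite_decay_T50", "dg_growth_T50", "dg_peak_T", "quartz_width_slope")
    jitter = {k: float(np.clip(rng.lognormal(0.0, 0.08), 0.8, 1.25)) for k in jitter_keys}
    return FlintSource(
        source_id=source_id,
        moganite_fraction=float(rng.uniform(0.3, 0.9)),
        carbon_load=float(rng.uniform(0.5, 1.5)),
        baseline_shape_coeffs=tuple(rng.normal(0.0, 0.08, size=3).round(6)),
        response_jitter=jitter,
    )


def _check_temp(temp: float) -> None:
    if not TEMP_MIN <= temp <= TEMP_MAX:
        raise DomainError(f"temperature {temp} C outside [{TEMP_MIN}, {TEMP_MAX}] C")


# ---------------------------------------------------------------------------
# spectrum simulators


def simulate_flint_raman(
    temp: float,
    source: FlintSource,
    grid: np.ndarray | None = None,
    seed: int = 0,
    params: HeatResponseParams = HeatResponseParams(),
    snr: float | None = 50.0,
    eta_gauss: float = 0.7,
) -> Spectrum:
    """Simulate one UV Raman spectrum of flint heated to ``temp`` °C.

    The spectrum is a smooth polynomial baseline plus pseudo-Voigt bands:
    α-quartz (465 cm⁻¹, width increasing with temp), moganite (501 cm⁻¹,
    amplitude relative to quartz decaying logistically with temp), and
    carbon D/G bands (1,350/1,600 cm⁻¹, rise-then-fall with temp), with
    additive Gaussian noise at the requested SNR (``snr=None`` disables
    noise).  Identical arguments yield bit-identical output.
    """
    _check_temp(temp)
    if grid is None:
        grid = make_grid(*RAMAN_GRID)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise InputError("grid must be a strictly increasing 1-D array")
    if grid[0] > 200.0 or grid[-1] < 1800.0:
        raise InputError(
            f"grid [{grid[0]}, {grid[-1]}] cm-1 must cover at least [200, 1800] cm-1"
        )
    p = params.jittered(source.response_jitter)
    quartz_amp = 1.0
    mog_amp = source.moganite_fraction * p.moganite_retention(temp) * quartz_amp
    dg = p.dg_response(temp)
    d_amp = 0.8 * source.carbon_load * dg
    g_amp = 0.6 * source.carbon_load * dg

    xn = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    baseline = np.polynomial.chebyshev.chebval(xn, np.asarray(source.baseline_shape_coeffs))
    baseline = baseline - baseline.min() + 0.05  # keep counts positive

    y = baseline.copy()
    y += pseudo_voigt(grid, 465.0, p.quartz_fwhm(temp), quartz_amp, eta_gauss)
    y += pseudo_voigt(grid, 501.0, 12.0, mog_amp, eta_gauss)
    y += pseudo_voigt(grid, 1350.0, 180.0, d_amp, eta_gauss)
    y += pseudo_voigt(grid, 1600.0, 90.0, g_amp, eta_gauss)
    if snr is not None:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, quartz_amp / snr, size=grid.size)
    return Spectrum(
        grid,
        y,
        kind="raman_uv",
        meta={
            "material": "flint",
            "source_id": source.source_id,
            "true_temperature": temp,
            "seed": seed,
        },
    )


def simulate_bone_ftir(
    temp: float,
    tissue: str = "bone",
    seed: int = 0,
    params: HeatResponseParams = HeatResponseParams(),
    snr: float | None = 100.0,
    eta_gauss: float = 0.85,
) -> Spectrum:
    """Simulate an FTIR absorbance spectrum of bone or tusk.

    Bioapatite bands (phosphate ν4 doublet at 565/603 cm⁻¹, ν3 at
    1,035 cm⁻¹, carbonate at 872/1,415 cm⁻¹) are always present; the
    collagen amide I band (1,660 cm⁻¹) decays with heating.  The
    heat-induced hydroxyl band at 630 cm⁻¹ has amplitude exactly 0 below
    the hydroxylation onset and > 0 (non-decreasing in temp) at or above
    it.  The ``tissue="tusk"`` flag narrows the ν4 bands (cosmetic only).
    KBr-pellet apatite bands are close to Gaussian, hence the high
    default Gaussian fraction: it keeps the valley between the ν4
    shoulder and the 630 cm⁻¹ band as distinct as measured spectra show.
    """
    _check_temp(temp)
    if tissue not in ("bone", "tusk"):
        raise InputError(f"tissue must be 'bone' or 'tusk', got {tissue!r}")
    grid = make_grid(*FTIR_GRID)
    nu4_fwhm = 10.0 if tissue == "tusk" else 14.0
    collagen = float(_sigmoid((350.0 - temp) / 60.0))
    y = np.zeros_like(grid)
    y += pseudo_voigt(grid, 565.0, nu4_fwhm, 0.50, eta_gauss)
    y += pseudo_voigt(grid, 603.0, nu4_fwhm, 0.55, eta_gauss)
    y += pseudo_voigt(grid, 1035.0, 60.0, 1.00, eta_gauss)
    y += pseudo_voigt(grid, 872.0, 12.0, 0.15, eta_gauss)
    y += pseudo_voigt(grid, 1415.0, 40.0, 0.30, eta_gauss)
    y += pseudo_voigt(grid, 1660.0, 50.0, 0.35 * collagen, eta_gauss)
    a630 = 0.20 * params.hydroxyl_amplitude(temp)
    if a630 > 0.0:
        y += pseudo_voigt(grid, 630.0, 10.0, a630, eta_gauss)
    if snr is not None:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, 1.0 / snr, size=grid.size)
    return Spectrum(
        grid,
        y,
        kind="ftir_absorbance",
        meta={"material": tissue, "true_temperature": temp, "seed": seed},
    )


def simulate_sediment_ftir(
    temp: float,
    composition: dict[str, float] | None = None,
    seed: int = 0,
    params: HeatResponseParams = HeatResponseParams(),
    snr: float | None = 100.0,
    eta_gauss: float = 0.7,
) -> Spectrum:
    """Simulate an FTIR absorbance spectrum of a quartz/clay/calcite sediment.

    ``composition`` maps ``quartz_w``, ``clay_w``, ``calcite_w`` to
    non-negative weights (at least one positive).  The clay
    structural-water bands in the 3,600–3,700 cm⁻¹ region scale with a
    smoothstep retention that is 1 at or below the dehydroxylation onset
    and exactly 0 from onset + 100 °C on.
    """
    _check_temp(temp)
    composition = dict(composition or {"quartz_w": 0.6, "clay_w": 0.4, "calcite_w": 0.0})
    unknown = set(composition) - {"quartz_w", "clay_w", "calcite_w"}
    if unknown:
        raise InputError(f"unknown composition keys {sorted(unknown)}")
    qw = composition.get("quartz_w", 0.0)
    cw = composition.get("clay_w", 0.0)
    kw = composition.get("calcite_w", 0.0)
    if min(qw, cw, kw) < 0 or max(qw, cw, kw) <= 0:
        raise InputError("composition weights must be >= 0 with at least one > 0")
    grid = make_grid(*FTIR_GRID)
    y = np.zeros_like(grid)
    # alpha-quartz framework bands
    y += qw * pseudo_voigt(grid, 1084.0, 70.0, 1.00, eta_gauss)
    y += qw * pseudo_voigt(grid, 797.0, 12.0, 0.25, eta_gauss)
    y += qw * pseudo_voigt(grid, 778.0, 12.0, 0.22, eta_gauss)
    y += qw * pseudo_voigt(grid, 694.0, 10.0, 0.12, eta_gauss)
    # clay: Si-O stretch, Al-OH deformation (915), structural-water OH
    # bands; the hydroxyl-linked bands all fade with dehydroxylation
    retention = params.clay_water_retention(temp)
    y += cw * pseudo_voigt(grid, 1032.0, 55.0, 1.00, eta_gauss)
    y += cw * retention * pseudo_voigt(grid, 915.0, 25.0, 0.30, eta_gauss)
    y += cw * retention * pseudo_voigt(grid, 3620.0, 25.0, 0.25, eta_gauss)
    y += cw * retention * pseudo_voigt(grid, 3695.0, 20.0, 0.18, eta_gauss)
    # calcite
    y += kw * pseudo_voigt(grid, 1420.0, 90.0, 1.00, eta_gauss)
    y += kw * pseudo_voigt(grid, 874.0, 12.0, 0.25, eta_gauss)
    y += kw * pseudo_voigt(grid, 713.0, 8.0, 0.12, eta_gauss)
    if snr is not None:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, 1.0 / snr, size=grid.size)
    return Spectrum(
        grid,
        y,
        kind="ftir_absorbance",
        meta={
            "material": "sediment",
            "true_temperature": temp,
            "composition": composition,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# site-level simulation


@dataclass(frozen=True)
class SiteLayout:
    """Excavation grid of 5 × 5 m squares, labeled row-letter + column."""

    rows: tuple[str, ...] = ("K", "L")
    cols: tuple[int, ...] = (3, 4, 5)
    square_size_m: float = 5.0
    elevation_m: float = 14.5

    def square_of(self, x: float, y: float) -> str:
        i = min(int(y // self.square_size_m), len(self.rows) - 1)
        j = min(int(x // self.square_size_m), len(self.cols) - 1)
        return f"{self.rows[i]}{self.cols[j]}"

    @property
    def extent(self) -> tuple[float, float]:
        return (len(self.cols) * self.square_size_m, len(self.rows) * self.square_size_m)


def _temp_field_sampler(temp_field, layout: SiteLayout, rng: np.random.Generator):
    """Return f(x, y) -> true temperature for the chosen field.

    ``temp_field`` is 'homogeneous', 'patchy', 'random', or a tuple
    ('homogeneous', value) to set the uniform temperature.
    """
    value = 300.0
    if isinstance(temp_field, (tuple, list)):
        temp_field, value = temp_field[0], float(temp_field[1])
    ex, ey = layout.extent
    if temp_field == "homogeneous":
        return lambda x, y: value
    if temp_field == "random":
        return lambda x, y: float(rng.uniform(20.0, 900.0))
    if temp_field == "patchy":
        cx = float(rng.uniform(1.0, ex - 1.0))
        cy = float(rng.uniform(1.0, ey - 1.0))
        radius = 2.0  # one ~2 m hot patch over a cool background

        def sample(x: float, y: float) -> float:
            if (x - cx) ** 2 + (y - cy) ** 2 <= radius**2:
                return float(rng.uniform(600.0, 800.0))
            return float(rng.uniform(20.0, 150.0))

        return sample
    raise InputError(f"unknown temp_field {temp_field!r}")


def simulate_site(
    n_artifacts: int,
    n_fauna: int = 0,
    temp_field="random",
    layout: SiteLayout = SiteLayout(),
    seed: int = 0,
    n_sources: int = 4,
    n_replicates: int = DEFAULT_N_REPLICATES,
    n_fauna_burnt: int | None = None,
    snr_raman: float | None = 50.0,
    snr_ftir: float | None = 100.0,
    params: HeatResponseParams = HeatResponseParams(),
) -> tuple[pd.DataFrame, dict[str, list[Spectrum]]]:
    """Simulate an excavated assemblage with known heating truth.

    Each lithic gets planar coordinates inside the excavation grid, size
    attributes drawn from log-normal defaults, a type label, a true
    temperature from ``temp_field``, and ``n_replicates`` Raman spectra;
    each faunal fragment gets one FTIR spectrum.  When ``n_fauna_burnt``
    is given, exactly that many fauna are heated past the hydroxylation
    onset regardless of the field (they are additionally clustered into
    one square, as burnt material concentrates in real assemblages).

    Returns the truth table and a ``sample_id -> [Spectrum, ...]`` bundle.
    """
    if n_artifacts < 1 or n_fauna < 0:
        raise InputError("n_artifacts must be >= 1 and n_fauna >= 0")
    if n_fauna_burnt is not None and n_fauna_burnt > n_fauna:
        raise InputError("n_fauna_burnt exceeds n_fauna")
    rng = np.random.default_rng(seed)
    sources = [random_source(f"src{i:02d}", rng) for i in range(n_sources)]
    field_fn = _temp_field_sampler(temp_field, layout, rng)
    ex, ey = layout.extent
    type_labels = ("flake", "retouched_flake", "core", "handaxe")
    type_probs = (0.60, 0.30, 0.05, 0.05)

    records = []
    bundle: dict[str, list[Spectrum]] = {}
    for i in range(n_artifacts):
        sid = f"lithic{i + 1:03d}"
        x = float(rng.uniform(0.0, ex))
        y = float(rng.uniform(0.0, ey))
        z = float(layout.elevation_m + rng.normal(0.0, 0.05))
        temp = field_fn(x, y)
        source = sources[int(rng.integers(len(sources)))]
        length = float(rng.lognormal(np.log(35.0), 0.4))  # mm
        thickness = float(rng.lognormal(np.log(8.0), 0.4))
        surface_area = float(0.6 * length**2 * rng.lognormal(0.0, 0.2))
        records.append(
            {
                "sample_id": sid,
                "material": "flint",
                "type": type_labels[int(rng.choice(len(type_labels), p=type_probs))],
                "square": layout.square_of(x, y),
                "x_m": round(x, 3),
                "y_m": round(y, 3),
                "z_m": round(z, 3),
                "length_mm": round(length, 2),
                "thickness_mm": round(thickness, 2),
                "surface_area_mm2": round(surface_area, 1),
                "source_id": source.source_id,
                "n_replicates": n_replicates,
                "true_temperature_C": round(temp, 2),
            }
        )
        bundle[sid] = [
            simulate_flint_raman(
                temp,
                source,
                seed=int(rng.integers(2**31 - 1)),
                params=params,
                snr=snr_raman,
            )
            for _ in range(n_replicates)
        ]
        for k, sp in enumerate(bundle[sid]):
            sp.meta["sample_id"] = sid
            sp.meta["replicate_index"] = k

    burnt_idx: set[int] = set()
    if n_fauna_burnt:
        burnt_idx = set(range(n_fauna_burnt))  # clustered below
        burnt_square = f"{layout.rows[-1]}{layout.cols[-1]}"
    for i in range(n_fauna):
        sid = f"fauna{i + 1:03d}"
        tissue = "tusk" if rng.random() < 0.3 else "bone"
        if n_fauna_burnt is None:
            x = float(rng.uniform(0.0, ex))
            y = float(rng.uniform(0.0, ey))
            temp = field_fn(x, y)
        elif i in burnt_idx:
            tissue = "tusk"  # burnt remains are tusk in the emulated assemblage
            x = float(rng.uniform(ex - layout.square_size_m, ex))
            y = float(rng.uniform(ey - layout.square_size_m, ey))
            temp = float(rng.uniform(650.0, 900.0))
        else:
            x = float(rng.uniform(0.0, ex))
            y = float(rng.uniform(0.0, ey))
            temp = float(rng.uniform(20.0, 450.0))
        z = float(layout.elevation_m + rng.normal(0.0, 0.05))
        color = rng.choice(("dark_brown", "gray", "white"), p=(0.5, 0.3, 0.2))
        records.append(
            {
                "sample_id": sid,
                "material": tissue,
                "type": "faunal_fragment",
                "square": layout.square_of(x, y),
                "x_m": round(x, 3),
                "y_m": round(y, 3),
                "z_m": round(z, 3),
                "length_mm": round(float(rng.uniform(5.0, 20.0)), 2),
                "thickness_mm": np.nan,
                "surface_area_mm2": np.nan,
                "source_id": str(color),  # color stored, deliberately non-diagnostic
                "n_replicates": 1,
                "true_temperature_C": round(temp, 2),
            }
        )
        sp = simulate_bone_ftir(
            temp, tissue=tissue, seed=int(rng.integers(2**31 - 1)), params=params, snr=snr_ftir
        )
        sp.meta["sample_id"] = sid
        bundle[sid] = [sp]
    table = pd.DataFrame.from_records(records)
    return table, bundle


def write_bundle(
    table: pd.DataFrame,
    bundle: dict[str, list[Spectrum]],
    outdir: str | Path,
    format: str = "jcampdx",
) -> Path:
    """Write a simulated assemblage to disk.

    Spectra go to ``<outdir>/spectra`` as JCAMP-DX (default) or CSV, the
    truth table to ``truth.csv``, and a manifest mapping sample ids to
    spectrum files to ``manifest.json``.  Returns the manifest path.
    """
    outdir = Path(outdir)
    specdir = outdir / "spectra"
    specdir.mkdir(parents=True, exist_ok=True)
    ext = ".jdx" if format == "jcampdx" else ".csv"
    manifest: dict[str, list[str]] = {}
    for sid, spectra in bundle.items():
        files = []
        for k, sp in enumerate(spectra):
            name = f"{sid}_rep{k:02d}{ext}"
            write_spectrum(sp, specdir / name, format=format)
            files.append(f"spectra/{name}")
        manifest[sid] = files
    table.to_csv(outdir / "truth.csv", index=False)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps({"format": format, "samples": manifest}, indent=2, sort_keys=True),
        encoding="utf-8",
    )
    return manifest_path
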