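"""Rule-based FTIR burn diagnostics for faunal remains and sediments.

Two field rules are operationalized:

* **Bone/tusk**: a hydroxyl libration band at 630 cm⁻¹ appears only
  after the bone mineral recrystallizes at ≥ 600 °C, so its presence is
  read as ``heated_above_600C``.  Color is deliberately not an input —
  white (calcined-looking) fragments are not diagnostic.
* **Sediment**: clay structural water (OH bands near 3,600–3,700 cm⁻¹)
  is lost irreversibly above ~400 °C, so a clay-bearing sediment that
  still shows those bands was ``not_heated_above_400C``; anything else
  is ``indeterminate``.

Peak presence is an SNR criterion on the prominence above a local
linear baseline drawn between the window-edge minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pyrotrace.exceptions import InputError
from pyrotrace.spectra import Spectrum, estimate_noise

#: Default quiet window (cm⁻¹) for FTIR noise estimation: free of
#: apatite, quartz, clay and calcite bands.
FTIR_QUIET_WINDOW = (1900.0, 2400.0)


@dataclass(frozen=True)
class PeakCall:
    """Outcome of a windowed peak search."""

    center_found: float
    prominence: float
    snr: float
    present: bool


@dataclass(frozen=True)
class BurnCall:
    sample_id: str
    peak630: PeakCall
    verdict: str  # heated_above_600C | not_heated_above_600C
    apatitic: bool = True
    notes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        expected = "heated_above_600C" if self.peak630.present else "not_heated_above_600C"
        assert self.verdict == expected


@dataclass(frozen=True)
class SedimentCall:
    sample_id: str
    phases: frozenset
    clay_water_present: bool
    verdict: str  # not_heated_above_400C | indeterminate
    peak_calls: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.verdict == "not_heated_above_400C":
            assert "clay" in self.phases and self.clay_water_present


def detect_peak(
    spectrum: Spectrum,
    center: float,
    half_window: float = 10.0,
    snr_threshold: float = 3.0,
    window: tuple[float, float] | None = None,
    quiet_window: tuple[float, float] = FTIR_QUIET_WINDOW,
    noise_floor: float = 1e-12,
) -> PeakCall:
    """Windowed peak detection with a local linear baseline.

    The search window is ``[center − half_window, center + half_window]``
    unless ``window`` overrides it (used where a neighboring band forces
    an asymmetric window).  The signal is lightly smoothed (3-point
    moving average) so a single noise spike cannot carry a call; the
    candidate is the smoothed maximum inside the window; the local
    baseline is the straight line between the minima flanking it on
    either side (topographic prominence — robust when the peak rides on
    the convex shoulder of a neighboring band, where a chord through the
    window edges would swallow the peak's flanks).  SNR is prominence
    divided by the robust noise estimate from ``quiet_window``;
    ``present`` requires SNR ≥ threshold.  A maximum sitting on the
    window edge is a shoulder, not a peak: prominence 0.
    """
    lo, hi = window if window is not None else (center - half_window, center + half_window)
    if not spectrum.covers(lo, hi):
        raise InputError(f"window [{lo}, {hi}] cm-1 outside the spectrum axis")
    sub = spectrum.crop(lo, hi)
    x, y = sub.wavenumbers, sub.intensities
    if x.size < 5:
        raise InputError(f"window [{lo}, {hi}] cm-1 holds {x.size} points; >= 5 required")
    if x.size >= 7:
        from scipy.ndimage import uniform_filter1d

        ysm = uniform_filter1d(y, size=3, mode="nearest")
    else:
        ysm = y
    i_max = int(np.argmax(ysm[1:-1])) + 1  # edge max = shoulder, not peak
    left = ysm[: i_max + 1]
    right = ysm[i_max:]
    i_lo = int(np.argmin(left))
    i_hi = i_max + int(np.argmin(right))
    if x[i_hi] == x[i_lo]:
        base_at_max = ysm[i_lo]
    else:
        slope = (ysm[i_hi] - ysm[i_lo]) / (x[i_hi] - x[i_lo])
        base_at_max = ysm[i_lo] + slope * (x[i_max] - x[i_lo])
    prominence = float(max(ysm[i_max] - base_at_max, 0.0))
    noise = max(estimate_noise(spectrum, quiet_window), noise_floor)
    snr = prominence / noise
    return PeakCall(
        center_found=float(x[i_max]),
        prominence=prominence,
        snr=float(snr),
        present=bool(snr >= snr_threshold),
    )


def classify_bone(
    spectrum: Spectrum,
    sample_id: str = "",
    snr_threshold: float = 3.0,
    quiet_window: tuple[float, float] = FTIR_QUIET_WINDOW,
) -> BurnCall:
    """Call heat exposure > 600 °C from the 630 cm⁻¹ hydroxylation band.

    The 630 cm⁻¹ search window is asymmetric — its left edge is held at
    615 cm⁻¹ so the phosphate ν4 shoulder at 603 cm⁻¹ cannot masquerade
    as the hydroxyl band.  Phosphate ν4 presence is also reported as a
    bioapatite sanity flag; its absence adds a warning note but the
    verdict is still computed.
    """
    if not spectrum.covers(560.0, 700.0):
        raise InputError("bone classification needs coverage of 560-700 cm-1")
    sid = sample_id or str(spectrum.meta.get("sample_id", ""))
    peak630 = detect_peak(
        spectrum, 630.0, snr_threshold=snr_threshold,
        window=(615.0, 640.0), quiet_window=quiet_window,
    )
    nu4 = detect_peak(
        spectrum, 603.0, half_window=15.0, snr_threshold=snr_threshold,
        quiet_window=quiet_window,
    )
    notes: tuple[str, ...] = ()
    if not nu4.present:
        notes = ("phosphate nu4 bands missing: not apatitic material",)
    verdict = "heated_above_600C" if peak630.present else "not_heated_above_600C"
    return BurnCall(sample_id=sid, peak630=peak630, verdict=verdict,
                    apatitic=nu4.present, notes=notes)


#: Sediment phase fingerprints: phase -> list of (center, half_window,
#: required) peaks.  The phase is called when all required peaks pass.
PHASE_BANDS = {
    # clay is identified from the Al-OH deformation band at 915 cm-1:
    # the Si-O stretch at 1,032 cm-1 is routinely shadowed by the quartz
    # 1,084 cm-1 band in quartz-rich sediments
    "alpha_quartz": [(1084.0, 40.0, True), (797.0, 10.0, True), (778.0, 10.0, True)],
    "clay": [(915.0, 20.0, True), (1032.0, 25.0, False)],
    "calcite": [(1420.0, 50.0, True), (874.0, 10.0, False), (713.0, 10.0, False)],
}

CLAY_WATER_WINDOW = (3580.0, 3710.0)


def classify_sediment(
    spectrum: Spectrum,
    sample_id: str = "",
    snr_threshold: float = 3.0,
    quiet_window: tuple[float, float] = FTIR_QUIET_WINDOW,
) -> SedimentCall:
    """Phase identification plus the clay-structural-water temperature bound.

    Quartz, clay and calcite are called from their fingerprint bands;
    clay structural water is searched over 3,580–3,710 cm⁻¹.  The
    verdict ``not_heated_above_400C`` requires both a clay phase call
    and surviving structural water; otherwise the sample is
    ``indeterminate`` (the rule has nothing to say).
    """
    if not spectrum.covers(400.0, 4000.0):
        raise InputError("sediment classification needs coverage of 400-4000 cm-1")
    sid = sample_id or str(spectrum.meta.get("sample_id", ""))
    calls: dict[str, PeakCall] = {}
    phases = set()
    for phase, bands in PHASE_BANDS.items():
        ok = True
        corroborating = 0
        for center, hw, required in bands:
            call = detect_peak(spectrum, center, half_window=hw,
                               snr_threshold=snr_threshold, quiet_window=quiet_window)
            calls[f"{phase}_{int(center)}"] = call
            if required and not call.present:
                ok = False
            if not required and call.present:
                corroborating += 1
        if phase == "calcite":
            ok = ok and corroborating >= 1  # 1420 alone is ambiguous
        if ok:
            phases.add(phase)
    lo, hi = CLAY_WATER_WINDOW
    water = detect_peak(spectrum, 0.5 * (lo + hi), window=(lo, hi),
                        snr_threshold=snr_threshold, quiet_window=quiet_window)
    calls["clay_water"] = water
    if "clay" in phases and water.present:
        verdict = "not_heated_above_400C"
    else:
        verdict = "indeterminate"
    return SedimentCall(
        sample_id=sid,
        phases=frozenset(phases),
        clay_water_present=water.present,
        verdict=verdict,
        peak_calls=calls,
    )
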