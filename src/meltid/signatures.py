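"""Derivative fluorescent signatures and marker-based temperature correction.

The classifiable object is not the raw melt curve but its first derivative
dF/dT on a fixed temperature grid: each probe-target dissociation appears as
a negative trough centred at its melting temperature.  Differentiation uses
Savitzky-Golay local-polynomial smoothing, the standard estimator for noisy
instrument derivatives.  BS1 carries an internal temperature marker whose
trough is the rightmost in the signature; detecting it and shifting both
channels so it lands on its nominal position removes run-to-run instrument
temperature drift before QC and classification.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .meltsim import MARKER_TM, AcquisitionGrid, RawMeltCurve, RunRecord, SegmentModel

__all__ = ["Signature", "SignatureConfig", "ProcessedRun",
           "derivative_signature", "detect_tm_marker", "temperature_correct",
           "resample", "process_run", "analytic_derivative"]


@dataclass
class Signature:
    """A first-derivative fluorescence trace on an acquisition grid."""

    grid: AcquisitionGrid
    values: np.ndarray
    channel: str
    tm_detected: float | None = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.grid.n_points:
            raise ValueError("signature length does not match its grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signature contains non-finite values")


@dataclass(frozen=True)
class SignatureConfig:
    """Tunables of signature extraction.

    ``window=None`` picks the odd window spanning ~0.35 degC of the curve's
    grid (31 points at the default spacing) — several times narrower than a
    melt transition, so troughs are not attenuated, while suppressing
    differentiated instrument noise far below the energy-based QC
    thresholds.  ``normalize`` optionally min-max scales each segment; off
    by default so that amplitude variation (a known weakness of
    melt-signature classification with degraded DNA) is preserved.
    """

    window: int | None = None
    polyorder: int = 2
    reference_tm: float = MARKER_TM
    marker_search_halfwidth: float = 3.0
    marker_prominence: float = 0.05
    normalize: bool = False


@dataclass
class ProcessedRun:
    """One run after signature extraction and temperature correction."""

    run_id: str
    specimen_id: str
    species_name: str | None
    replicate: int
    sample_condition: str
    bs1: Signature
    bs2: Signature
    tm_ok: bool


#: Temperature span (degC) targeted by the automatic smoothing window.
_AUTO_WINDOW_SPAN = 0.35


def auto_window(step: float, span: float = _AUTO_WINDOW_SPAN,
                minimum: int = 7) -> int:
    """Odd Savitzky-Golay window spanning roughly ``span`` degC."""
    w = max(int(round(span / step)), minimum)
    return w + 1 if w % 2 == 0 else w


def derivative_signature(curve: RawMeltCurve, window: int | None = None,
                         polyorder: int = 2) -> Signature:
    """Savitzky-Golay first derivative of a raw melt curve."""
    n = len(curve.fluorescence)
    temps = curve.temperatures
    delta = (temps[-1] - temps[0]) / (n - 1)
    if window is None:
        window = auto_window(delta)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed the polynomial order")
    if n < window:
        raise ValueError(f"curve of {n} points is shorter than window {window}")
    vals = savgol_filter(curve.fluorescence, window, polyorder, deriv=1,
                         delta=delta, mode="interp")
    grid = AcquisitionGrid(float(temps[0]), float(temps[-1]), n)
    return Signature(grid=grid, values=vals, channel=curve.channel)


def detect_tm_marker(sig: Signature, search_window: tuple[float, float] | None = None,
                     prominence: float = 0.05,
                     edge_margin: int | None = None) -> float | None:
    """Temperature of the rightmost qualifying trough (the internal marker).

    Returns None when no trough of sufficient prominence lies inside the
    search window (e.g. a flat, failed signature).  ``edge_margin`` grid
    points at either end are excluded (default ~0.15 degC worth): the
    smoothing filter's edge polynomials amplify noise there and can fake a
    trough.
    """
    if sig.channel != "BS1":
        raise ValueError("the temperature marker lives in the BS1 channel")
    lo, hi = search_window or (MARKER_TM - 3.0, MARKER_TM + 3.0)
    temps = sig.grid.temperatures
    if edge_margin is None:
        edge_margin = max(int(np.ceil(0.15 / sig.grid.step)), 2)
    mask = (temps >= lo) & (temps <= hi)
    mask[:edge_margin] = False
    mask[-edge_margin:] = False
    idx = np.nonzero(mask)[0]
    if idx.size < 3:
        return None
    peaks, _ = find_peaks(-sig.values[idx], prominence=prominence)
    if peaks.size == 0:
        return None
    return float(temps[idx[peaks[-1]]])


def temperature_correct(bs1: Signature, bs2: Signature,
                        reference_tm: float = MARKER_TM) -> tuple[Signature, Signature]:
    """Rigidly shift both channels so the detected marker sits at its nominal
    temperature; regions shifted past the grid edge are zero-filled."""
    if bs1.tm_detected is None:
        raise ValueError("BS1 has no detected marker; run fails temperature correction")
    shift = reference_tm - bs1.tm_detected
    out = []
    for sig in (bs1, bs2):
        temps = sig.grid.temperatures
        vals = np.interp(temps - shift, temps, sig.values, left=0.0, right=0.0)
        out.append(replace(sig, values=vals, corrected=True,
                           tm_detected=reference_tm if sig.channel == "BS1" else None))
    return out[0], out[1]


def resample(sig: Signature, grid: AcquisitionGrid) -> Signature:
    """Linear re-interpolation onto another grid (zero fill outside range)."""
    vals = np.interp(grid.temperatures, sig.grid.temperatures, sig.values,
                     left=0.0, right=0.0)
    return Signature(grid=grid, values=vals, channel=sig.channel,
                     tm_detected=sig.tm_detected, corrected=sig.corrected)


def process_run(run: RunRecord, config: SignatureConfig | None = None) -> ProcessedRun:
    """Raw run -> corrected signature pair.

    ``tm_ok`` is False when the marker trough cannot be found, in which case
    the uncorrected signatures are carried through for QC to reject.
    """
    config = config or SignatureConfig()
    bs1 = derivative_signature(run.bs1_curve, config.window, config.polyorder)
    bs2 = derivative_signature(run.bs2_curve, config.window, config.polyorder)
    tm = detect_tm_marker(
        bs1, (config.reference_tm - config.marker_search_halfwidth,
              config.reference_tm + config.marker_search_halfwidth),
        config.marker_prominence)
    tm_ok = tm is not None
    if tm_ok:
        bs1.tm_detected = tm
        bs1, bs2 = temperature_correct(bs1, bs2, config.reference_tm)
    if config.normalize:
        for sig in (bs1, bs2):
            span = np.ptp(sig.values)
            if span > 0:
                sig.values = (sig.values - sig.values.max()) / span
    return ProcessedRun(run_id=run.run_id, specimen_id=run.specimen_id,
                        species_name=run.species_name, replicate=run.replicate,
                        sample_condition=run.sample_condition,
                        bs1=bs1, bs2=bs2, tm_ok=tm_ok)


def analytic_derivative(segment: SegmentModel, grid: AcquisitionGrid) -> np.ndarray:
    """Closed-form dF/dT of a noise-free segment model (test oracle and
    visual-distinguishability reference)."""
    temps = grid.temperatures
    d = np.full(grid.n_points, segment.baseline_slope, dtype=float)
    for c in segment.all_components():
        s = 1.0 / (1.0 + np.exp(-(c.tm - temps) / c.width))
        d -= (c.amplitude / c.width) * s * (1.0 - s)
    return d
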