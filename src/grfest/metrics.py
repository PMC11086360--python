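"""Signal filtering, phase normalization, body-size normalization, and the
validation statistics (Pearson rho with qualitative bands, RMSE, rRMSE).

Curves are compared on a 101-sample contact-phase grid (0-100% between heel
strike and toe-off), with forces in %BW (percent body weight) and moments in
%BW*BH (body weight times body height).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, lfilter

G = 9.81


class EventDetectionError(ValueError):
    """No contact episode found in the vertical GRF series."""


@dataclass
class MetricsReport:
    rho: float                      # Pearson correlation (nan if undefined)
    rho_class: str                  # weak | moderate | strong | excellent | undefined
    rmse: float                     # channel units
    rrmse: float                    # percent


@dataclass
class PhaseSeries:
    """101 samples over 0-100% of the contact phase."""

    values: np.ndarray
    events: tuple[float, float]     # (heel_strike, toe_off) times, s

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (101,):
            raise ValueError("phase series must have exactly 101 samples")

    @property
    def phase(self) -> np.ndarray:
        return np.linspace(0.0, 100.0, 101)


def butterworth_lowpass(series, rate: float, order: int = 4,
                        cutoff: float = 18.0, zero_phase: bool = True):
    """4th-order Butterworth low-pass (-3 dB at the cutoff), applied
    forward-backward by default so the offline processing adds no phase lag;
    ``zero_phase=False`` gives the single-pass filter."""
    series = np.asarray(series, dtype=float)
    if rate <= 2.0 * cutoff:
        raise ValueError("sampling rate must exceed twice the cutoff")
    b, a = butter(order, cutoff, fs=rate)
    if zero_phase:
        if series.shape[0] <= 3 * max(len(a), len(b)):
            raise ValueError("series too short for zero-phase filtering")
        return filtfilt(b, a, series, axis=0)
    return lfilter(b, a, series, axis=0)


def detect_events(grf_z, t, threshold: float = 20.0) -> tuple[float, float]:
    """Contact episode boundaries: first rise above and last fall below the
    threshold (N), with linear interpolation of the crossing times.  A series
    that starts (ends) above the threshold begins (ends) its episode at the
    series boundary."""
    grf_z = np.asarray(grf_z, dtype=float)
    t = np.asarray(t, dtype=float)
    above = grf_z > threshold
    if not above.any():
        raise EventDetectionError("vertical GRF never exceeds the threshold")
    i0 = int(np.argmax(above))
    if i0 == 0:
        hs = t[0]
    else:
        f = (threshold - grf_z[i0 - 1]) / (grf_z[i0] - grf_z[i0 - 1])
        hs = t[i0 - 1] + f * (t[i0] - t[i0 - 1])
    i1 = len(grf_z) - 1 - int(np.argmax(above[::-1]))
    if i1 == len(grf_z) - 1:
        to = t[-1]
    else:
        f = (grf_z[i1] - threshold) / (grf_z[i1] - grf_z[i1 + 1])
        to = t[i1] + f * (t[i1 + 1] - t[i1])
    return hs, to


def phase_normalize(series, t, events: tuple[float, float]) -> PhaseSeries:
    """Linear-time resampling to 101 points between the events."""
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    hs, to = events
    if not (t[0] - 1e-9 <= hs < to <= t[-1] + 1e-9):
        raise ValueError("events out of order or outside the series span")
    ph_t = np.linspace(hs, to, 101)
    return PhaseSeries(values=np.interp(ph_t, t, series), events=(hs, to))


def normalize_grf(force_n, weight_kg: float) -> np.ndarray:
    """Force in percent body weight."""
    return np.asarray(force_n, dtype=float) / (weight_kg * G) * 100.0


def normalize_grm(moment_nm, weight_kg: float, height_m: float) -> np.ndarray:
    """Moment in percent body weight x body height."""
    return np.asarray(moment_nm, dtype=float) / (weight_kg * G * height_m) * 100.0


def classify_correlation(rho: float) -> str:
    """Qualitative bands: weak (<=0.35), moderate (<=0.67), strong (<=0.9),
    excellent (>0.9); classified on the signed value, so negative
    correlations land in 'weak'."""
    if np.isnan(rho):
        return "undefined"
    if rho <= 0.35:
        return "weak"
    if rho <= 0.67:
        return "moderate"
    if rho <= 0.9:
        return "strong"
    return "excellent"


def compare(est, ref) -> MetricsReport:
    """Pearson rho, RMSE, and rRMSE (RMSE over the mean of the two ranges,
    as a percent) between two equal-length curves."""
    est = est.values if isinstance(est, PhaseSeries) else np.asarray(est, dtype=float)
    ref = ref.values if isinstance(ref, PhaseSeries) else np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("compare requires equal-length series")
    rmse = float(np.sqrt(np.mean((est - ref) ** 2)))
    mean_range = 0.5 * ((est.max() - est.min()) + (ref.max() - ref.min()))
    rrmse = float(rmse / mean_range * 100.0) if mean_range > 0 else np.nan
    if est.std() == 0 or ref.std() == 0:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(est, ref)[0, 1])
    return MetricsReport(rho=rho, rho_class=classify_correlation(rho),
                         rmse=rmse, rrmse=rrmse)
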