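"""Filtering, resampling, and IMU-to-mocap time synchronization.

The IMUs start recording after motion capture (observed delays of
90-180 ms), so each IMU stream carries an unknown start offset relative to
the lab clock.  The offset is recovered by maximizing the normalized
cross-correlation between segment-angle series during a calibration
maneuver (a hard step followed by a forward/backward leg swing), with
parabolic refinement of the correlation peak for sub-sample resolution.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.signal

from .dataio import TrialTable

__all__ = [
    "LagEstimate",
    "butter_lowpass_bidirectional",
    "resample_linear",
    "estimate_lag",
    "apply_lag",
]


@dataclasses.dataclass
class LagEstimate:
    """Result of cross-correlation synchronization.

    lag : seconds; positive means the moving (IMU) stream starts later,
    i.e. moving-stream time ``t`` corresponds to reference time ``t + lag``.
    peak_correlation : signed normalized correlation at the peak of
    ``|r|``; a value near -1 flags a sign-convention mismatch.
    """

    lag: float
    peak_correlation: float

    def __post_init__(self) -> None:
        if abs(self.peak_correlation) > 1 + 1e-9:
            raise ValueError("|peak_correlation| must be <= 1")


def butter_lowpass_bidirectional(x: np.ndarray, cutoff: float,
                                 sample_rate: float, order: int = 4
                                 ) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward).

    Uses reflective (odd) padding of length 3*order, standard zero-phase
    practice; output has the same length as the input.
    """
    if cutoff >= sample_rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below Nyquist {sample_rate / 2} Hz")
    x = np.asarray(x, dtype=float)
    sos = scipy.signal.butter(order, cutoff, btype="low", fs=sample_rate,
                              output="sos")
    padlen = 3 * order
    if x.shape[-1] <= 3 * padlen:
        raise ValueError("series too short for the filter pad length")
    return scipy.signal.sosfiltfilt(sos, x, padlen=padlen)


def filter_table(table: TrialTable, cutoff: float, order: int = 4,
                 columns=None) -> TrialTable:
    """Low-pass filter selected columns of a TrialTable (zero phase)."""
    data = table.data.copy()
    for c in (columns or data.columns):
        data[c] = butter_lowpass_bidirectional(
            data[c].to_numpy(), cutoff, table.sample_rate, order)
    return table.copy_with(data=data)


def resample_linear(t: np.ndarray, y: np.ndarray, target_rate: float,
                    t_start: float | None = None, t_end: float | None = None):
    """Linearly resample ``y(t)`` onto a uniform grid at ``target_rate``.

    Returns ``(t_new, y_new)``.  Values at original sample times are
    preserved when the target grid contains them.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be > 0")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    lo = t[0] if t_start is None else max(t_start, t[0])
    hi = t[-1] if t_end is None else min(t_end, t[-1])
    n = int(np.floor((hi - lo) * target_rate + 1e-9)) + 1
    t_new = lo + np.arange(n) / target_rate
    return t_new, np.interp(t_new, t, y)


def _parabolic_refine(r: np.ndarray, k: int) -> float:
    """Sub-sample offset of the extremum of r around integer index k."""
    if k <= 0 or k >= len(r) - 1:
        return 0.0
    y0, y1, y2 = r[k - 1], r[k], r[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return 0.0
    delta = 0.5 * (y0 - y2) / denom
    return float(np.clip(delta, -0.5, 0.5))


def estimate_lag(reference: np.ndarray, moving: np.ndarray,
                 sample_rate: float, max_lag: float) -> LagEstimate:
    """Estimate the start delay of ``moving`` relative to ``reference``.

    Both series must share ``sample_rate`` and nominally cover the same
    event (the calibration maneuver).  The lag maximizing ``|r(tau)|`` over
    ``[-max_lag, +max_lag]`` is refined by parabolic interpolation of the
    three points around the integer-lag peak.

    Positive lag means ``moving`` starts later: ``moving(t)`` lines up with
    ``reference(t + lag)``.
    """
    a = np.asarray(reference, dtype=float)
    b = np.asarray(moving, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("no correlation structure (zero-variance input)")
    max_shift = int(round(max_lag * sample_rate))
    if min(len(a), len(b)) <= 2 * max_shift:
        raise ValueError("overlap must exceed 2 * max_lag")
    # full cross-correlation; index len(b)-1 corresponds to zero shift
    r = scipy.signal.correlate(a, b, mode="full")
    lags = scipy.signal.correlation_lags(len(a), len(b), mode="full")
    sel = np.abs(lags) <= max_shift
    r = r[sel]
    lags = lags[sel]
    # normalize by the overlapping-sample energies so |r| <= 1
    norm = np.empty_like(r)
    for i, L in enumerate(lags):
        if L >= 0:
            aa, bb = a[L:L + len(b)], b[:len(a) - L]
        else:
            aa, bb = a[:len(b) + L], b[-L:len(a) - L if len(a) - L < len(b) else None]
        m = min(len(aa), len(bb))
        aa, bb = aa[:m], bb[:m]
        denom = np.sqrt(np.sum(aa * aa) * np.sum(bb * bb))
        norm[i] = r[i] / denom if denom > 0 else 0.0
    k = int(np.argmax(np.abs(norm)))
    delta = _parabolic_refine(np.abs(norm), k)
    lag = (lags[k] + delta) / sample_rate
    peak = float(np.clip(norm[k], -1.0, 1.0))
    return LagEstimate(lag=float(lag), peak_correlation=peak)


def apply_lag(moving: TrialTable, lag: float) -> TrialTable:
    """Shift a stream's clock onto the reference clock.

    With positive ``lag`` (stream started ``lag`` seconds late), sample
    times become ``t + lag`` in reference time, implemented by adjusting
    ``t0``; no samples are dropped or interpolated here — consumers index
    by time.
    """
    if abs(lag) >= moving.duration:
        raise ValueError("|lag| must be smaller than the series duration")
    return moving.copy_with(t0=moving.t0 + lag)
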