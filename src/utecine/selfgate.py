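"""Self-gating: motion signals from the k-space-center navigator.

The first sample of every center-out spoke sits at k = 0 and is acquired
once per TR with constant encoding, so its magnitude time series records
every bulk-signal disturbance: cardiac contraction (blood/myocardial
area changes) and respiration (tissue moving through the slice).  This
module detrends that series, separates it into respiratory and cardiac
band-limited components with zero-phase filters, estimates both rates
from the periodogram, assigns a cardiac phase to every spoke by
peak-to-peak linear interpolation, and flags spokes acquired during
inspiration for rejection.

All processing is deterministic and invariant to global scaling of the
navigator; no absolute signal thresholds are used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, find_peaks, periodogram, sosfiltfilt

from .sequencer import SpokeSet

__all__ = [
    "NavigatorSeries",
    "GatingResult",
    "extract_navigator",
    "separate_motion_components",
    "estimate_rate",
    "assign_cardiac_phase",
    "respiratory_gate",
    "gate_spokes",
    "RESP_BAND",
    "CARDIAC_BAND",
]

#: default respiratory band, Hz (anesthetized mouse: ~0.5-3 Hz)
RESP_BAND = (0.5, 3.0)
#: default cardiac band, Hz.  The lower edge brackets mouse heart rates
#: (>400 bpm = 6.7 Hz); the upper edge deliberately admits the 2nd/3rd
#: harmonics of an 8 Hz heartbeat so the filtered navigator keeps the
#: sharp end-diastolic peak of the asymmetric contraction waveform
#: (a fundamental-only signal peaks visibly earlier in the cycle).
CARDIAC_BAND = (4.0, 26.0)


@dataclass
class NavigatorSeries:
    """The k = 0 sample of every spoke of one slice."""

    value: np.ndarray         # complex per spoke
    time: np.ndarray          # s per spoke
    sampling_rate: float      # Hz, = 1000/TR

    def __post_init__(self):
        if len(self.value) != len(self.time):
            raise ValueError("value and time must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


@dataclass
class GatingResult:
    """Per-spoke gating decisions plus global rate estimates."""

    cardiac_phase: np.ndarray   # [0,1) per spoke
    resp_phase: np.ndarray      # [0,1) per spoke
    accepted: np.ndarray        # bool per spoke
    cardiac_rate: float         # Hz
    resp_rate: float            # Hz
    n_rejected_resp: int
    n_rejected_edge: int
    slice_index: np.ndarray | None = None
    time: np.ndarray | None = None
    nav_mag: np.ndarray | None = None

    def __post_init__(self):
        if self.cardiac_rate <= self.resp_rate:
            raise ValueError("cardiac rate must exceed respiratory rate")

    @property
    def n_spokes(self) -> int:
        return len(self.cardiac_phase)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.n_spokes
        return pd.DataFrame({
            "spoke_index": np.arange(n),
            "slice": self.slice_index if self.slice_index is not None else np.zeros(n, int),
            "time_s": self.time if self.time is not None else np.full(n, np.nan),
            "nav_mag": self.nav_mag if self.nav_mag is not None else np.full(n, np.nan),
            "resp_phase": self.resp_phase,
            "cardiac_phase": self.cardiac_phase,
            "accepted": self.accepted,
            "frame": np.full(n, -1),
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------

def extract_navigator(spokes: SpokeSet, slice_index: int | None = None) -> NavigatorSeries:
    """The navigator series: data[:, 0] of (one slice of) a SpokeSet."""
    if spokes.n_spokes == 0:
        raise ValueError("empty SpokeSet")
    if slice_index is not None:
        spokes = spokes.for_slice(slice_index)
    elif len(spokes.slices) > 1:
        raise ValueError("multi-slice SpokeSet: pass slice_index")
    return NavigatorSeries(value=spokes.data[:, 0].copy(),
                           time=spokes.time.copy(),
                           sampling_rate=spokes.params.navigator_rate)


def _bandpass(x: np.ndarray, band, fs: float) -> np.ndarray:
    lo, hi = band
    sos = butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def separate_motion_components(nav: NavigatorSeries,
                               resp_band=RESP_BAND,
                               cardiac_band=CARDIAC_BAND,
                               baseline_window_s: float = 2.0):
    """Split |navigator| into respiratory and cardiac signals.

    A sliding-mean baseline (window >= 2 respiratory periods) is removed
    first, then each component is extracted by a zero-phase Butterworth
    band-pass, so the outputs are aligned with the spoke times (no group
    delay).
    """
    fs = nav.sampling_rate
    nyq = fs / 2.0
    for band in (resp_band, cardiac_band):
        if not (0 < band[0] < band[1] < nyq):
            raise ValueError(f"band {band} invalid for sampling rate {fs} Hz")
    if resp_band[1] > cardiac_band[0]:
        raise ValueError("respiratory and cardiac bands must be disjoint")
    mag = np.abs(nav.value).astype(float)
    win = max(3, int(round(baseline_window_s * fs)))
    detr = mag - uniform_filter1d(mag, size=win, mode="nearest")
    return _bandpass(detr, resp_band, fs), _bandpass(detr, cardiac_band, fs)


def estimate_rate(signal: np.ndarray, sampling_rate: float, band) -> float:
    """Dominant in-band frequency of a zero-padded periodogram, Hz.

    The peak bin is refined by local quadratic interpolation.  A flat
    signal (no in-band peak above the noise floor) raises ValueError.
    """
    signal = np.asarray(signal, dtype=float)
    if len(signal) < 4 * sampling_rate / band[0]:
        raise ValueError("signal shorter than 4 periods of the band's lower edge")
    nfft = int(2 ** np.ceil(np.log2(8 * len(signal))))
    f, p = periodogram(signal, fs=sampling_rate, nfft=nfft, detrend="constant")
    sel = (f >= band[0]) & (f <= band[1])
    fi, pi = f[sel], p[sel]
    if pi.size == 0 or pi.max() <= 0:
        raise ValueError("no in-band spectral peak above the noise floor")
    med = np.median(pi)
    imax = int(np.argmax(pi))
    if med > 0 and pi[imax] < 10.0 * med:
        raise ValueError("no in-band spectral peak above the noise floor")
    # quadratic refinement on log power
    if 0 < imax < len(pi) - 1:
        y0, y1, y2 = np.log(pi[imax - 1:imax + 2] + 1e-300)
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = fi[1] - fi[0]
    return float(fi[imax] + delta * df)


def _refined_peak_times(signal: np.ndarray, times: np.ndarray, peaks: np.ndarray):
    """Sub-sample peak times via a parabola through each peak triplet."""
    dt = times[1] - times[0]
    out = times[peaks].astype(float)
    ok = (peaks > 0) & (peaks < len(signal) - 1)
    y0 = signal[peaks[ok] - 1]
    y1 = signal[peaks[ok]]
    y2 = signal[peaks[ok] + 1]
    denom = y0 - 2 * y1 + y2
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom != 0, 0.5 * (y0 - y2) / denom, 0.0)
    out[ok] += np.clip(delta, -0.5, 0.5) * dt
    return out


def assign_cardiac_phase(cardiac_signal: np.ndarray, times: np.ndarray,
                         expected_rate: float):
    """Cardiac phase in [0,1) per spoke from filtered-signal peaks.

    Peaks (end-diastole) are detected with a minimum separation of
    0.6/expected_rate; the phase between consecutive peaks is linear in
    time.  Spokes outside the first/last peak are extrapolated with the
    median beat interval; the edge flag marks extrapolations beyond 1.5
    median intervals.

    Returns (phase, peak_times, edge_flags).
    """
    cardiac_signal = np.asarray(cardiac_signal, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = times[1] - times[0]
    dist = max(1, int(round(0.6 / expected_rate / dt)))
    peaks, _ = find_peaks(cardiac_signal, distance=dist)
    if len(peaks) < 2:
        raise ValueError("fewer than 2 cardiac peaks detected")
    pt = _refined_peak_times(cardiac_signal, times, peaks)
    med = float(np.median(np.diff(pt)))
    # continuous beat coordinate: k at peak k, linear in between,
    # median-interval slope outside the detected range
    beat = np.interp(times, pt, np.arange(len(pt), dtype=float))
    before = times < pt[0]
    after = times > pt[-1]
    beat[before] = (times[before] - pt[0]) / med
    beat[after] = (len(pt) - 1) + (times[after] - pt[-1]) / med
    phase = beat % 1.0
    extrap = np.zeros(len(times))
    extrap[before] = (pt[0] - times[before]) / med
    extrap[after] = (times[after] - pt[-1]) / med
    edge = extrap > 1.5
    return phase, pt, edge


def respiratory_gate(resp_signal: np.ndarray, accept_fraction: float = 0.7,
                     times: np.ndarray | None = None,
                     expected_rate: float | None = None):
    """Accept the quiescent (end-expiration) fraction of spokes.

    The end-expiration plateau is located as the mode of the respiratory
    signal's histogram (the value where the most time is spent); the
    accept_fraction of spokes closest to that plateau is kept.  Returns
    (accepted, resp_phase); phases are peak-to-peak linear as for the
    cardiac channel when times/expected_rate are given, else zeros.
    """
    if not 0.0 < accept_fraction <= 1.0:
        raise ValueError("accept_fraction must lie in (0, 1]")
    x = np.asarray(resp_signal, dtype=float)
    n = len(x)
    span = x.max() - x.min()
    if span < 1e-12 * max(1.0, np.abs(x).max()):
        if accept_fraction < 1.0:
            warnings.warn("degenerate (constant) respiratory signal: accepting all spokes")
        return np.ones(n, dtype=bool), np.zeros(n)
    hist, edges = np.histogram(x, bins=64)
    k = int(np.argmax(hist))
    center = 0.5 * (edges[k] + edges[k + 1])
    dist = np.abs(x - center)
    if accept_fraction >= 1.0:
        accepted = np.ones(n, dtype=bool)
    else:
        thr = np.quantile(dist, accept_fraction)
        accepted = dist <= thr
    resp_phase = np.zeros(n)
    if times is not None and expected_rate is not None:
        try:
            resp_phase, _, _ = assign_cardiac_phase(x, times, expected_rate)
        except ValueError:
            warnings.warn("too few respiratory peaks; respiratory phases set to 0")
    return accepted, resp_phase


def gate_spokes(spokes: SpokeSet,
                resp_band=RESP_BAND,
                cardiac_band=CARDIAC_BAND,
                accept_fraction: float = 0.7) -> GatingResult:
    """Full self-gating of a (possibly multi-slice) SpokeSet.

    Each slice is gated independently from its own navigator; the
    reported rates are the means over slices.
    """
    n = spokes.n_spokes
    cardiac_phase = np.zeros(n)
    resp_phase = np.zeros(n)
    accepted = np.zeros(n, dtype=bool)
    nav_mag = np.zeros(n)
    edge_total = 0
    c_rates, r_rates = [], []
    for s in spokes.slices:
        m = spokes.slice_index == s
        nav = extract_navigator(spokes, slice_index=int(s))
        resp_sig, card_sig = separate_motion_components(nav, resp_band, cardiac_band)
        c_rate = estimate_rate(card_sig, nav.sampling_rate, cardiac_band)
        try:
            r_rate = estimate_rate(resp_sig, nav.sampling_rate, resp_band)
        except ValueError:
            r_rate = np.nan
        phase, _, edge = assign_cardiac_phase(card_sig, nav.time, c_rate)
        acc, rphase = respiratory_gate(resp_sig, accept_fraction, nav.time,
                                       r_rate if np.isfinite(r_rate) else None)
        cardiac_phase[m] = phase
        resp_phase[m] = rphase
        accepted[m] = acc
        nav_mag[m] = np.abs(nav.value)
        edge_total += int(edge.sum())
        c_rates.append(c_rate)
        r_rates.append(r_rate)
    resp_rate = float(np.nanmean(r_rates))
    if not np.isfinite(resp_rate):
        resp_rate = 1e-6  # degenerate: no detectable respiration
    return GatingResult(
        cardiac_phase=cardiac_phase,
        resp_phase=resp_phase,
        accepted=accepted,
        cardiac_rate=float(np.mean(c_rates)),
        resp_rate=resp_rate,
        n_rejected_resp=int((~accepted).sum()),
        n_rejected_edge=edge_total,
        slice_index=spokes.slice_index.copy(),
        time=spokes.time.copy(),
        nav_mag=nav_mag,
    )
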