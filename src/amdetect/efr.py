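"""Envelope-following-response and ABR analysis.

EFR phase locking is quantified by the amplitude-normalized FFT peak
within +/-3 Hz of the modulation rate, computed over the waveform from
10 ms after stimulus onset to 10 ms before offset (rectangular window,
no taper). The noise floor is the same measure on the unmodulated
condition; depth thresholds use the twice-noise-floor criterion on an
exponential amplitude-vs-depth fit (with the discrete lowest qualifying
depth also reported). ABR click analysis extracts per-level peak
amplitude/latency and a threshold from an explicit k*SD-of-baseline
criterion standing in for the original visual judgment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .stimuli import is_unmodulated

__all__ = [
    "EFRResult",
    "ABRResult",
    "efr_fft_peak",
    "efr_threshold",
    "abr_metrics",
]

SEARCH_BAND_HZ = 3.0
ANALYSIS_PAD_S = 0.010


def efr_fft_peak(rec) -> float:
    """Peak amplitude-normalized FFT magnitude near the modulation rate.

    The analysis window runs from onset + 10 ms to offset - 10 ms; the
    peak is the maximum magnitude over frequency bins within
    [rate - 3 Hz, rate + 3 Hz] (nearest bin if the window is too short to
    place a bin inside the band). Amplitudes are normalized so a pure
    sinusoid of amplitude a returns ~a.
    """
    t0 = rec.onset_s + ANALYSIS_PAD_S
    t1 = rec.offset_s - ANALYSIS_PAD_S
    if t1 - t0 <= 2.0 / rec.rate_hz:
        raise ValueError("analysis window shorter than two modulation periods")
    i0 = int(round(t0 * rec.fs))
    i1 = int(round(t1 * rec.fs))
    seg = np.asarray(rec.waveform_uv[i0:i1], float)
    spec = np.abs(np.fft.rfft(seg)) * 2.0 / seg.size
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / rec.fs)
    band = np.abs(freqs - rec.rate_hz) <= SEARCH_BAND_HZ
    if not band.any():
        band[np.argmin(np.abs(freqs - rec.rate_hz))] = True
    return float(np.max(spec[band]))


@dataclass
class EFRResult:
    rate_hz: float
    depths_db: np.ndarray
    amplitudes: np.ndarray
    noise_floor: float
    normalized: np.ndarray
    fit_a: float
    fit_b: float
    threshold_db: float | None
    threshold_db_discrete: float | None
    flag: str = "ok"


def efr_threshold(recordings, rate_hz: float) -> EFRResult:
    """Depth threshold from the twice-noise-floor criterion at one AM rate.

    ``recordings`` must contain the unmodulated condition (noise floor)
    and at least three modulated depths. Amplitudes over depth are fitted
    with an exponential ``a(d) = A*exp(B*d)`` in dB depth; the threshold
    is the lowest depth (evaluated on the fitted curve within the tested
    range) whose amplitude reaches twice the floor. The discrete lowest
    qualifying tested depth is reported alongside.
    """
    recs = [r for r in recordings if r.rate_hz == rate_hz]
    floor_recs = [r for r in recs if is_unmodulated(r.depth_db)]
    mod_recs = sorted(
        (r for r in recs if not is_unmodulated(r.depth_db)), key=lambda r: r.depth_db
    )
    if not floor_recs:
        raise ValueError("noise floor requires an unmodulated recording")
    if len(mod_recs) < 3:
        raise ValueError("need >=3 modulated depths")
    floor = float(np.mean([efr_fft_peak(r) for r in floor_recs]))
    depths = np.array([r.depth_db for r in mod_recs], float)
    amps = np.array([efr_fft_peak(r) for r in mod_recs], float)
    norm = amps / amps.max() if amps.max() > 0 else amps
    # exponential fit in dB depth
    try:
        p0 = (max(amps.max(), 1e-9), 0.1)
        (fa, fb), _ = optimize.curve_fit(
            lambda d, a, b: a * np.exp(b * d), depths, amps, p0=p0, maxfev=20_000
        )
    except RuntimeError:
        fa, fb = np.nan, np.nan
    criterion = 2.0 * floor
    thr_fit = None
    # a defined threshold requires amplitude to grow with depth (B > 0);
    # a flat or inverted fit means the measurements are noise-dominated
    if np.isfinite(fa) and fa > 0 and fb > 0:
        grid = np.linspace(depths.min(), depths.max(), 2001)
        fit_vals = fa * np.exp(fb * grid)
        qualifying = grid[fit_vals >= criterion]
        if qualifying.size:
            thr_fit = float(qualifying.min())
    qualifying_d = depths[amps >= criterion]
    thr_disc = float(qualifying_d.min()) if qualifying_d.size else None
    flag = "ok" if thr_fit is not None else "undefined"
    return EFRResult(
        rate_hz=float(rate_hz), depths_db=depths, amplitudes=amps,
        noise_floor=floor, normalized=norm, fit_a=float(fa), fit_b=float(fb),
        threshold_db=thr_fit, threshold_db_discrete=thr_disc, flag=flag,
    )


@dataclass
class ABRResult:
    animal_id: str
    levels_db_spl: np.ndarray
    amplitudes_uv: np.ndarray
    latencies_ms: np.ndarray
    threshold_db_spl: float | None
    sensation_levels_db: np.ndarray = field(default=None)
    flag: str = "ok"


def abr_metrics(abr, k_sd: float = 4.0, response_window_s: tuple = (0.001, 0.008)) -> ABRResult:
    """Per-level ABR peak amplitude/latency and a k*SD-criterion threshold.

    ``abr`` supplies ``traces_uv`` (level -> waveform), ``fs`` and
    ``click_t_s``. The baseline is the pre-click segment of each trace;
    a level is responsive when its peak absolute deflection in the
    post-click window exceeds ``k_sd`` baseline SDs. The threshold is the
    lowest level of the contiguous responsive run ending at the highest
    level, mirroring the descending-ladder endpoint.
    """
    levels = np.array(sorted(abr.traces_uv, reverse=True), float)
    if levels.size == 0:
        raise ValueError("no ABR traces supplied")
    fs = abr.fs
    i_click = int(round(abr.click_t_s * fs))
    if i_click < 2:
        raise ValueError("no pre-click baseline segment in the traces")
    amps, lats, responsive = [], [], []
    for level in levels:
        tr = np.asarray(abr.traces_uv[level], float)
        base_sd = float(np.std(tr[:i_click]))
        j0 = i_click + int(round(response_window_s[0] * fs))
        j1 = i_click + int(round(response_window_s[1] * fs))
        seg = tr[j0:j1]
        peak_i = int(np.argmax(np.abs(seg)))
        amps.append(float(np.abs(seg[peak_i])))
        lats.append((j0 + peak_i - i_click) / fs * 1000.0)
        responsive.append(amps[-1] > k_sd * base_sd)
    amps = np.array(amps)
    lats = np.array(lats)
    responsive = np.array(responsive)
    threshold = None
    for level, resp in zip(levels, responsive):  # descending ladder
        if resp:
            threshold = float(level)
        else:
            break
    flag = "ok" if threshold is not None else "no-response"
    sl = levels - threshold if threshold is not None else None
    return ABRResult(
        animal_id=getattr(abr, "animal_id", ""), levels_db_spl=levels,
        amplitudes_uv=amps, latencies_ms=lats, threshold_db_spl=threshold,
        sensation_levels_db=sl, flag=flag,
    )
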