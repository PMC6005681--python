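"""Single-unit neurometrics.

Spontaneous/driven firing rate with a best-window search (25-1000 ms in
25 ms steps from the AM transition), firing-rate d', monotonicity index,
vector strength with the Rayleigh test, trial-to-trial CV, neurometric
threshold interpolation at d' = 1, and ROC-based choice probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import UNMODULATED, is_unmodulated

__all__ = [
    "BEST_WINDOWS_MS",
    "NeurometricFunction",
    "spontaneous_rate",
    "window_counts",
    "best_window_dprime",
    "monotonicity_index",
    "vector_strength",
    "unit_cv",
    "neurometric_threshold",
    "choice_probability",
]

BEST_WINDOWS_MS = np.arange(25, 1001, 25)
RAYLEIGH_ALPHA = 0.001


def spontaneous_rate(unit) -> float:
    """Mean rate (Hz) in the 200 ms window preceding the nose poke."""
    t0 = unit.nose_poke_t - 0.2
    t1 = unit.nose_poke_t
    counts = [np.sum((s >= t0) & (s < t1)) for s in unit.spikes]
    return float(np.mean(counts) / 0.2)


def window_counts(unit, window_s: float) -> np.ndarray:
    """Spike count per trial in [0, window_s) after the AM transition."""
    return np.array([np.sum((s >= 0.0) & (s < window_s)) for s in unit.spikes])


def _go_nogo_masks(trials: pd.DataFrame):
    is_go = (trials["type"] == "go").to_numpy()
    depths = trials["depth_db"].to_numpy(float)
    return is_go, depths


def best_window_dprime(unit, windows_ms=BEST_WINDOWS_MS) -> dict:
    """Best-window firing-rate neurometric function.

    For each candidate window starting at the AM transition, trial firing
    rates are computed for every Go depth and the Nogo; d'(depth) is the
    Go-minus-Nogo mean difference normalized by the SD pooled across all
    stimuli of the rate. The best window maximizes the maximum |d'| over
    depths; reported d' values are absolute.

    Returns a dict with ``best_window_ms``, ``depths_db``, ``dprime``
    (absolute), ``dprime_signed``, ``fr_mean``/``fr_sd`` per depth (at the
    best window), ``fr_nogo``, and a ``degenerate`` flag set when the
    pooled SD is zero.
    """
    is_go, depths = _go_nogo_masks(unit.trials)
    if not is_go.any() or is_go.all():
        raise ValueError("unit trials must include both Go and Nogo conditions")
    go_depths = np.sort(np.unique(depths[is_go]))
    windows_s = np.asarray(windows_ms, float) / 1000.0
    # (trials x windows) rates in one pass via sorted-spike bisection
    counts = np.empty((len(unit.spikes), windows_s.size))
    for i, s in enumerate(unit.spikes):
        counts[i] = np.searchsorted(s, windows_s) - np.searchsorted(s, 0.0)
    rates = counts / windows_s
    masks = [is_go & (depths == d) for d in go_depths]
    pooled_sd = rates.std(axis=0, ddof=1)                    # per window
    nogo_mean = rates[~is_go].mean(axis=0)
    go_mean = np.vstack([rates[m].mean(axis=0) for m in masks])
    with np.errstate(divide="ignore", invalid="ignore"):
        d_signed = np.where(pooled_sd > 0, (go_mean - nogo_mean) / pooled_sd, 0.0)
    scores = np.max(np.abs(d_signed), axis=0)
    j = int(np.argmax(scores))
    return {
        "best_window_ms": int(windows_ms[j]),
        "depths_db": go_depths,
        "dprime_signed": d_signed[:, j],
        "dprime": np.abs(d_signed[:, j]),
        "fr_mean": go_mean[:, j],
        "fr_sd": np.array([rates[m, j].std(ddof=1) for m in masks]),
        "fr_nogo": float(nogo_mean[j]),
        "degenerate": bool(pooled_sd[j] == 0.0),
    }


def monotonicity_index(depths_db, fr) -> tuple[float, str]:
    """MI = 100 * FR(0 dB) / max FR over depths; class from the 50% rule.

    MI > 50 -> "increasing"; MI <= 50 -> "decreasing".
    """
    depths_db = np.asarray(depths_db, float)
    fr = np.asarray(fr, float)
    if 0.0 not in depths_db:
        raise ValueError("MI requires a firing rate at 0 dB (full depth)")
    fr_max = float(np.max(fr))
    if fr_max <= 0:
        raise ValueError("maximum firing rate is zero; MI undefined")
    mi = 100.0 * float(fr[depths_db == 0.0][0]) / fr_max
    return mi, ("increasing" if mi > 50.0 else "decreasing")


def vector_strength(spike_times, f_hz: float) -> tuple[float, float, bool]:
    """Vector strength at f_hz with the Rayleigh uniformity test.

    Returns ``(vs, rayleigh_stat, significant)`` where the Rayleigh
    statistic is ``2*n*VS**2`` and significance is assessed at p < 0.001
    via the large-sample approximation ``p = exp(-n*VS**2)``.
    """
    t = np.asarray(spike_times, float)
    n = t.size
    if n == 0:
        raise ValueError("vector strength undefined for an empty spike train")
    phases = 2.0 * np.pi * f_hz * t
    vs = float(np.abs(np.mean(np.exp(1j * phases))))
    rayleigh = 2.0 * n * vs**2
    p = np.exp(-n * vs**2)
    return vs, rayleigh, bool(p < RAYLEIGH_ALPHA)


def unit_cv(unit, window_ms: int | None = None) -> dict:
    """Trial-to-trial firing-rate CV per stimulus condition.

    CV = SD of trial FRs / mean trial FR, computed in the unit's best
    window (or ``window_ms``). The unit-level summary ``cv`` is taken at
    the condition with maximal driven FR; all per-condition values are
    returned so alternative summaries stay testable.
    """
    if window_ms is None:
        window_ms = best_window_dprime(unit)["best_window_ms"]
    rate = window_counts(unit, window_ms / 1000.0) / (window_ms / 1000.0)
    is_go, depths = _go_nogo_masks(unit.trials)
    conditions = [("nogo", ~is_go)] + [
        (d, is_go & (depths == d)) for d in np.sort(np.unique(depths[is_go]))
    ]
    per_condition = {}
    for label, mask in conditions:
        r = rate[mask]
        mu = float(np.mean(r))
        if mu == 0.0:
            per_condition[label] = {"cv": np.nan, "mean_fr": 0.0, "flag": "zero-mean"}
        else:
            per_condition[label] = {
                "cv": float(np.std(r, ddof=1) / mu), "mean_fr": mu, "flag": "ok",
            }
    valid = {k: v for k, v in per_condition.items() if v["flag"] == "ok"}
    if not valid:
        return {"cv": np.nan, "window_ms": window_ms, "per_condition": per_condition}
    top = max(valid, key=lambda k: valid[k]["mean_fr"])
    return {"cv": valid[top]["cv"], "condition": top, "window_ms": window_ms,
            "per_condition": per_condition}


def neurometric_threshold(depths_db, dprime) -> tuple[float | None, str]:
    """Interpolated depth at which the neurometric function crosses d' = 1.

    Requires at least one depth with d' > 1; interpolates linearly in dB
    between the greatest d' below 1 and the smallest d' above 1. If even
    the lowest tested depth exceeds 1, the threshold is that depth with a
    ``"below-range"`` flag. Returns ``(None, "undefined")`` when no depth
    reaches d' > 1.
    """
    depths_db = np.asarray(depths_db, float)
    dprime = np.asarray(dprime, float)
    order = np.argsort(depths_db)
    depths_db, dprime = depths_db[order], dprime[order]
    exact = depths_db[dprime == 1.0]
    if exact.size:
        return float(exact.min()), "ok"
    if not np.any(dprime > 1.0):
        return None, "undefined"
    if dprime[0] >= 1.0:
        return float(depths_db[0]), "below-range"
    below = dprime < 1.0
    above = dprime > 1.0
    i = np.where(below)[0][np.argmax(dprime[below])]      # greatest d' below 1
    j = np.where(above)[0][np.argmin(dprime[above])]      # smallest d' above 1
    x0, y0 = depths_db[i], dprime[i]
    x1, y1 = depths_db[j], dprime[j]
    thr = x0 + (1.0 - y0) * (x1 - x0) / (y1 - y0)
    return float(thr), "ok"


def choice_probability(
    unit,
    window: tuple[float, float] = (0.0, 0.4),
    depths_db=None,
    hit_rate_band: tuple[float, float] = (0.2, 0.8),
) -> dict:
    """ROC-based choice probability over one response window.

    Compares firing-rate distributions on trials where the animal reported
    modulation (went to the spout) vs withheld, restricted to Go depths
    near the psychometric threshold — by default those whose observed hit
    rate falls in [0.2, 0.8] (guaranteeing both choice classes exist). CP
    is the probability that a random report-trial FR exceeds a random
    no-report FR, with ties counted 1/2 (the Mann-Whitney U statistic
    normalized by n1*n2).
    """
    t0, t1 = window
    trials = unit.trials
    is_go = (trials["type"] == "go").to_numpy()
    depths = trials["depth_db"].to_numpy(float)
    responded = (trials["response"] == "spout").to_numpy()
    if depths_db is None:
        depths_db = []
        for d in np.unique(depths[is_go]):
            hr = float(np.mean(responded[is_go & (depths == d)]))
            if hit_rate_band[0] <= hr <= hit_rate_band[1]:
                depths_db.append(d)
    depths_db = np.asarray(depths_db, float)
    include = is_go & np.isin(depths, depths_db)
    fr = np.array([np.sum((s >= t0) & (s < t1)) for s in unit.spikes]) / (t1 - t0)
    report = fr[include & responded]
    no_report = fr[include & ~responded]
    if report.size == 0 or no_report.size == 0:
        return {"cp": np.nan, "n_report": int(report.size),
                "n_no_report": int(no_report.size), "flag": "missing-class"}
    # U/(n1*n2) via rank sums; ties handled by midranks
    ranks = stats.rankdata(np.concatenate([report, no_report]))
    u = float(np.sum(ranks[: report.size]) - report.size * (report.size + 1) / 2.0)
    cp = u / (report.size * no_report.size)
    flag = "ok"
    if min(report.size, no_report.size) < 5:
        flag = "low-power"
    return {"cp": float(cp), "n_report": int(report.size),
            "n_no_report": int(no_report.size), "flag": flag,
            "depths_db": depths_db}


def unit_metrics_table(units, windows_ms=BEST_WINDOWS_MS) -> pd.DataFrame:
    """Tidy per-unit metric table (one row per unit)."""
    rows = []
    for u in units:
        nm = best_window_dprime(u, windows_ms)
        thr, thr_flag = neurometric_threshold(nm["depths_db"], nm["dprime"])
        mi, mclass = monotonicity_index(
            nm["depths_db"], nm["fr_mean"]
        ) if 0.0 in nm["depths_db"] else (np.nan, "n/a")
        cv = unit_cv(u, nm["best_window_ms"])
        go_spikes = np.concatenate(
            [s[(s >= 0) & (s < u.am_duration_s)]
             for s, t in zip(u.spikes, u.trials["type"]) if t == "go"]
        )
        if go_spikes.size:
            vs, rayl, sig = vector_strength(go_spikes, u.rate_hz)
        else:
            vs, rayl, sig = np.nan, np.nan, False
        rows.append({
            "unit_id": u.unit_id, "animal_id": u.animal_id,
            "group": u.hearing_status, "rate_hz": u.rate_hz,
            "isolation": u.isolation,
            "spont_hz": spontaneous_rate(u),
            "driven_fr_hz": float(np.max(np.append(nm["fr_mean"], nm["fr_nogo"]))),
            "best_window_ms": nm["best_window_ms"],
            "max_dprime": float(np.max(nm["dprime"])),
            "threshold_db": thr if thr is not None else np.nan,
            "threshold_flag": thr_flag,
            "mi": mi, "monotonic_class": mclass,
            "vs": vs, "rayleigh": rayl, "vs_significant": sig,
            "cv": cv["cv"],
        })
    return pd.DataFrame(rows)
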