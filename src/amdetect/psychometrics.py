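"""Psychometric analysis for the Go-Nogo AM detection task.

Fits cumulative-Gaussian psychometric functions to per-depth hit
proportions, converts performance to the signal-detection metric d'
(with hit/false-alarm rates clamped to [0.05, 0.95]), extracts the
detection threshold at d' = 1, and characterizes thresholds across AM
rates with an exponential temporal modulation transfer function (TMTF),
``y(m) = A * exp(b * m)``.

The original behavioral fits used Bayesian inference with package-default
priors; here a penalized maximum-likelihood scheme (weak beta penalties
keeping guess and lapse in [0, 0.5]) delivers equivalent point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DPRIME_FLOOR",
    "DPRIME_CEILING",
    "MAX_DPRIME",
    "PsychometricFit",
    "TMTF",
    "filter_sessions",
    "compute_dprime",
    "fit_psychometric",
    "extract_threshold",
    "lapse_rate",
    "fit_tmtf",
]

DPRIME_FLOOR = 0.05
DPRIME_CEILING = 0.95
#: Maximum attainable d' given the rate clamp: 2 * z(0.95).
MAX_DPRIME = 2.0 * stats.norm.ppf(DPRIME_CEILING)

# Session inclusion criteria.
MAX_FA_RATE = 0.30          # strict: FA rate must be < 0.30
MIN_TRIALS_PER_DEPTH = 20
MIN_TOTAL_GO_TRIALS = 100   # strict: > 100 Go trials


def compute_dprime(hit_rate: float, fa_rate: float) -> float:
    """d' = z(hit) - z(fa) with both rates clamped to [0.05, 0.95].

    The clamp avoids infinite z-scores at perfect performance; as a result
    d' is bounded by ``MAX_DPRIME`` (~3.29).
    """
    hit_rate = np.asarray(hit_rate, dtype=float)
    fa_rate = np.asarray(fa_rate, dtype=float)
    if np.any((hit_rate < 0) | (hit_rate > 1)) or np.any((fa_rate < 0) | (fa_rate > 1)):
        raise ValueError("hit and false-alarm rates must lie in [0, 1]")
    h = np.clip(hit_rate, DPRIME_FLOOR, DPRIME_CEILING)
    f = np.clip(fa_rate, DPRIME_FLOOR, DPRIME_CEILING)
    out = stats.norm.ppf(h) - stats.norm.ppf(f)
    return float(out) if out.ndim == 0 else out


def session_rates(trials: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-depth Go hit proportions and the session false-alarm rate."""
    go = trials[trials["type"] == "go"]
    nogo = trials[trials["type"] == "nogo"]
    hits = go.groupby("depth_db")["outcome"].apply(lambda o: float(np.mean(o == "hit")))
    fa = float(np.mean(nogo["outcome"] == "fa")) if len(nogo) else 0.0
    return hits, fa


def filter_sessions(sessions) -> tuple[list, dict]:
    """Apply the session inclusion criteria.

    Keeps sessions with false-alarm rate < 0.30, at least 20 trials at
    every Go depth, and more than 100 Go trials in total. Returns
    ``(included, exclusions)`` where ``exclusions`` maps a session label to
    its list of failure reasons (``"false-alarm"``, ``"go-trials"``).
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions supplied")
    included, exclusions = [], {}
    for i, sess in enumerate(sessions):
        trials = sess.trials if hasattr(sess, "trials") else sess
        label = getattr(sess, "session_id", i)
        _, fa = session_rates(trials)
        go = trials[trials["type"] == "go"]
        per_depth = go.groupby("depth_db").size()
        reasons = []
        if fa >= MAX_FA_RATE:
            reasons.append("false-alarm")
        if (per_depth < MIN_TRIALS_PER_DEPTH).any() or len(go) <= MIN_TOTAL_GO_TRIALS:
            reasons.append("go-trials")
        if reasons:
            exclusions[label] = reasons
        else:
            included.append(sess)
    return included, exclusions


def _psych_curve(depth, loc, scale, guess, lapse):
    return guess + (1.0 - guess - lapse) * stats.norm.cdf((depth - loc) / scale)


@dataclass
class PsychometricFit:
    """Fitted psychometric function for one session."""

    loc: float
    scale: float
    guess: float
    lapse: float
    fa_rate: float
    depths_db: np.ndarray
    n_go: np.ndarray
    n_hit: np.ndarray
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def predict(self, depth_db) -> np.ndarray:
        """Fitted hit probability at the given depths (dB)."""
        return _psych_curve(np.asarray(depth_db, float), self.loc, self.scale,
                            self.guess, self.lapse)

    def dprime(self, depth_db) -> np.ndarray:
        """Fitted d' at the given depths, using the session FA rate."""
        return compute_dprime(self.predict(depth_db), self.fa_rate)

    @property
    def max_dprime(self) -> float:
        return float(np.max(self.dprime(self.depths_db)))


def fit_psychometric(session) -> PsychometricFit:
    """Penalized-MLE cumulative-Gaussian fit of hit proportion vs depth.

    The likelihood is binomial per depth; weak Beta(1.2, 8) penalties keep
    guess and lapse inside [0, 0.5] without dominating the data. Raises if
    fewer than three distinct depths are present; non-convergence is
    reported in the returned diagnostics, never silently.
    """
    trials = session.trials if hasattr(session, "trials") else session
    hits, fa = session_rates(trials)
    depths = np.asarray(hits.index, dtype=float)
    if len(depths) < 3:
        raise ValueError(f"need >=3 distinct Go depths, got {len(depths)}")
    go = trials[trials["type"] == "go"]
    n_go = go.groupby("depth_db").size().reindex(hits.index).to_numpy(float)
    n_hit = np.round(hits.to_numpy() * n_go)

    span = depths.max() - depths.min()

    def nll(theta):
        loc, log_scale, guess, lapse = theta
        scale = np.exp(log_scale)
        p = np.clip(_psych_curve(depths, loc, scale, guess, lapse), 1e-9, 1 - 1e-9)
        ll = np.sum(n_hit * np.log(p) + (n_go - n_hit) * np.log1p(-p))
        # Beta(1.2, 8) style penalty on guess/lapse over [0, 0.5]
        pen = 0.0
        for q in (guess, lapse):
            u = np.clip(q / 0.5, 1e-9, 1 - 1e-9)
            pen += 0.2 * np.log(u) + 7.0 * np.log1p(-u)
        return -(ll + pen)

    p_top = hits.iloc[-1]
    p_bot = hits.iloc[0]
    x0 = np.array([np.median(depths), np.log(max(span / 4.0, 0.5)),
                   min(max(p_bot, 0.01), 0.45), min(max(1 - p_top, 0.01), 0.45)])
    bounds = [(depths.min() - 3 * span - 10, depths.max() + 3 * span + 10),
              (np.log(0.1), np.log(10 * span + 10)),
              (0.0, 0.5), (0.0, 0.5)]
    best = None
    for x_init in (x0, x0 + np.array([span / 3, 0.5, 0.0, 0.0]),
                   x0 - np.array([span / 3, -0.5, 0.0, 0.0])):
        res = optimize.minimize(nll, x_init, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    loc, log_scale, guess, lapse = best.x
    return PsychometricFit(
        loc=float(loc), scale=float(np.exp(log_scale)), guess=float(guess),
        lapse=float(lapse), fa_rate=fa, depths_db=depths, n_go=n_go, n_hit=n_hit,
        converged=bool(best.success),
        diagnostics={"nll": float(best.fun), "message": str(best.message)},
    )


def extract_threshold(fit: PsychometricFit) -> tuple[float | None, str]:
    """Depth (dB) at which the fitted d' curve crosses 1.

    Returns ``(threshold_db, flag)``; flag is ``"ok"``,
    ``"below-range"`` (d' > 1 across the whole tested range, threshold set
    to the lowest tested depth), or ``"undefined"`` (d' < 1 everywhere).
    """
    lo, hi = float(fit.depths_db.min()), float(fit.depths_db.max())
    d_lo, d_hi = float(fit.dprime(lo)), float(fit.dprime(hi))
    if d_lo >= 1.0 and d_hi >= 1.0:
        return lo, "below-range"
    if d_lo < 1.0 and d_hi < 1.0:
        return None, "undefined"
    root = optimize.brentq(lambda x: float(fit.dprime(x)) - 1.0, lo, hi)
    return float(root), "ok"


def lapse_rate(session) -> float:
    """Miss proportion at the easiest (highest-depth) Go signal presented."""
    trials = session.trials if hasattr(session, "trials") else session
    go = trials[trials["type"] == "go"]
    if go.empty:
        raise ValueError("session contains no Go trials")
    easiest = go["depth_db"].max()
    at = go[go["depth_db"] == easiest]
    return float(np.mean(at["outcome"] == "miss"))


@dataclass
class TMTF:
    """Exponential threshold-vs-rate characterization y(m) = A*exp(b*m)."""

    A: float
    b: float
    rates_hz: np.ndarray
    thresholds_db: np.ndarray
    residuals: np.ndarray

    def predict(self, rate_hz) -> np.ndarray:
        return self.A * np.exp(self.b * np.asarray(rate_hz, float))


def fit_tmtf(rates_hz, thresholds_db) -> TMTF:
    """Least-squares fit of threshold (dB) vs AM rate to A*exp(b*m)."""
    m = np.asarray(rates_hz, dtype=float)
    y = np.asarray(thresholds_db, dtype=float)
    if m.size < 2:
        raise ValueError("TMTF fit needs thresholds at >=2 AM rates")
    if np.allclose(y, y[0]):
        A, b = float(np.mean(y)), 0.0
    else:
        # log-linear start when thresholds share a sign, else flat start
        if np.all(y < 0) or np.all(y > 0):
            slope, intercept = np.polyfit(m, np.log(np.abs(y)), 1)
            p0 = (np.sign(y[0]) * np.exp(intercept), slope)
        else:
            p0 = (np.mean(y), 0.0)
        (A, b), _ = optimize.curve_fit(
            lambda x, A, b: A * np.exp(b * x), m, y, p0=p0, maxfev=20_000
        )
    resid = y - A * np.exp(b * m)
    return TMTF(A=float(A), b=float(b), rates_hz=m, thresholds_db=y, residuals=resid)
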