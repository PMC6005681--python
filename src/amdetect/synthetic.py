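"""Synthetic cohorts: Go-Nogo sessions, cortical units, EFR/ABR waveforms.

Generates data with the statistical structure the analysis stages assume,
under normal-hearing (``ctl``) and conductive-loss (``hl``) presets:

* Behavioral sessions — 30% unmodulated Nogo trials randomly interleaved
  with Go trials at five AM depths bracketing the group's threshold; hit
  probability follows a cumulative-Gaussian psychometric function.
* Cortical units — doubly stochastic gamma-gain x inhomogeneous-Poisson
  spike trains with monotonically increasing or decreasing depth tuning,
  sinusoidal phase locking, and group-dependent trial-to-trial gain
  dispersion (HL > Ctl). The gamma gain is a modeling choice: it is the
  minimal mechanism letting the firing-rate CV exceed the Poisson bound.
* EFR — sinusoidal envelope-following waveforms in white noise with an
  exponential amplitude-vs-depth dependence; ABR — level-scaled template
  peaks with latency shortening at higher levels.

Everything is deterministic under the master seed: each generated object
consumes an independent child of a ``numpy`` ``SeedSequence``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import AMStimulus, UNMODULATED, depth_db_to_fraction, is_unmodulated

__all__ = [
    "PsychPreset",
    "TuningPreset",
    "EFRPreset",
    "ABRPreset",
    "CohortConfig",
    "BehavioralSession",
    "UnitRecording",
    "EFRRecording",
    "ABRRecording",
    "default_config",
    "depth_bracket",
    "generate_session",
    "draw_tuning",
    "generate_unit",
    "generate_efr",
    "generate_abr",
    "generate_cohort",
]

NOGO_PROB = 0.30

# Trial timeline (seconds, relative to the AM transition at t = 0):
NOSE_POKE_T = -0.6     # nose poke; sound onset 0.2 s later (fringe ramp)
PRE_POKE_WINDOW = 0.2  # spontaneous-rate window immediately before the poke
AM_DURATION = 1.0      # modulated portion of the stimulus
TRIAL_START = NOSE_POKE_T - PRE_POKE_WINDOW


@dataclass
class PsychPreset:
    """Ground-truth psychometric parameters for one (group, rate)."""

    threshold_db: float   # location of the cumulative Gaussian (dB depth)
    slope_db: float = 2.0  # scale of the cumulative Gaussian
    guess: float = 0.12    # false-alarm / guess rate
    lapse: float = 0.03

    def hit_prob(self, depth_db) -> np.ndarray:
        z = (np.asarray(depth_db, float) - self.threshold_db) / self.slope_db
        return self.guess + (1.0 - self.guess - self.lapse) * stats.norm.cdf(z)

    def dprime1_depth(self) -> float:
        """Depth at which the true d' (vs guess-rate FAs) crosses 1."""
        from .psychometrics import compute_dprime
        from scipy.optimize import brentq

        f = lambda d: compute_dprime(float(self.hit_prob(d)), self.guess) - 1.0
        lo, hi = self.threshold_db - 30, 0.0
        if f(hi) < 0:
            return np.nan
        if f(lo) > 0:
            return lo
        return float(brentq(f, lo, hi))


@dataclass
class TuningPreset:
    """Priors for drawing per-unit tuning parameters within one group."""

    spont_hz: tuple = (4.0, 12.0)        # uniform range
    driven_base_hz: tuple = (6.0, 14.0)
    depth_gain_hz: dict = field(default_factory=dict)  # rate -> (lo, hi)
    kappa: tuple = (0.3, 0.7)            # phase-locking index at full depth
    kappa_hz: dict = field(default_factory=dict)       # per-rate override
    gain_cv: float = 0.30                # trial-to-trial gamma-gain CV
    p_increasing: float = 0.52           # fraction of monotonically increasing units
    p_single_unit: float = 0.2


@dataclass
class EFRPreset:
    amp_uv: float = 2.0         # spectral amplitude at 0 dB depth (uV)
    decay_per_db: float = 0.35  # exponential decay of amplitude with depth (dB)
    noise_sd_uv: float = 30.0   # per-sweep white-noise SD of the raw waveform
    fs: float = 8192.0
    # 0.52 s puts the FFT analysis window (onset+10ms .. offset-10ms) at
    # exactly 0.5 s, an integer number of cycles for 64-512 Hz rates
    stim_duration_s: float = 0.52
    pad_s: float = 0.05
    n_sweeps: int = 1000

    def amplitude(self, depth_db: float) -> float:
        if is_unmodulated(depth_db):
            return 0.0
        return self.amp_uv * np.exp(self.decay_per_db * depth_db)


@dataclass
class ABRPreset:
    threshold_db_spl: float = 25.0
    amp_per_db: float = 0.12   # peak growth (uV) per dB above threshold
    latency0_ms: float = 4.2   # latency at threshold
    latency_slope_ms_per_db: float = 0.015
    noise_sd_uv: float = 0.08
    fs: float = 24414.0
    levels_db_spl: tuple = (90, 80, 70, 60, 50, 40, 30, 20, 10)


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic two-group cohort."""

    n_animals: int = 4
    groups: tuple = ("ctl", "hl")
    rates_hz: tuple = (64.0, 128.0, 256.0, 512.0)
    unit_count_range: tuple = (80, 285)
    n_trials_per_session: int = 200
    level_db_spl: dict = field(default_factory=lambda: {"ctl": 45.0, "hl": 90.0})
    level_rove_db: float = 0.0  # optional 12 dB rove (45-57 dB SPL control)
    psych: dict = field(default_factory=dict)    # (group, rate) -> PsychPreset
    tuning: dict = field(default_factory=dict)   # group -> TuningPreset
    efr: EFRPreset = field(default_factory=EFRPreset)
    abr: dict = field(default_factory=dict)      # group -> ABRPreset
    choice_coupling: float = 0.0  # >0 couples spiking gain to behavioral choice
    master_seed: int = 0


def default_config(
    n_animals: int = 4,
    unit_count_range: tuple = (80, 285),
    n_trials_per_session: int = 200,
    master_seed: int = 0,
) -> CohortConfig:
    """Cohort defaults reproducing the qualitative group contrasts.

    Behavioral thresholds are matched at 64 Hz and diverge at faster AM
    rates (HL worse); HL units carry higher trial-gain dispersion and
    weaker depth gain at 256/512 Hz; EFR parameters are identical across
    groups.
    """
    psych = {
        ("ctl", 64.0): PsychPreset(-12.0),
        ("ctl", 128.0): PsychPreset(-11.5),
        ("ctl", 256.0): PsychPreset(-10.5),
        ("ctl", 512.0): PsychPreset(-9.5),
        ("hl", 64.0): PsychPreset(-12.0),
        ("hl", 128.0): PsychPreset(-9.0),
        ("hl", 256.0): PsychPreset(-6.0),
        ("hl", 512.0): PsychPreset(-3.5),
    }
    tuning = {
        "ctl": TuningPreset(
            spont_hz=(6.0, 14.0),
            depth_gain_hz={64.0: (8.0, 16.0), 128.0: (8.0, 16.0),
                           256.0: (8.0, 16.0), 512.0: (8.0, 16.0)},
            gain_cv=0.30,
        ),
        "hl": TuningPreset(
            spont_hz=(3.0, 9.0),
            depth_gain_hz={64.0: (8.0, 16.0), 128.0: (6.0, 12.0),
                           256.0: (3.0, 7.0), 512.0: (2.0, 5.0)},
            kappa_hz={64.0: (0.3, 0.7), 128.0: (0.2, 0.45),
                      256.0: (0.1, 0.25), 512.0: (0.05, 0.15)},
            gain_cv=0.60,
        ),
    }
    abr = {"ctl": ABRPreset(threshold_db_spl=25.0),
           "hl": ABRPreset(threshold_db_spl=64.0)}
    return CohortConfig(
        n_animals=n_animals,
        unit_count_range=unit_count_range,
        n_trials_per_session=n_trials_per_session,
        psych=psych,
        tuning=tuning,
        abr=abr,
        master_seed=master_seed,
    )


def depth_bracket(threshold_db: float, n_depths: int = 5, span_db: float = 6.0):
    """Five Go depths bracketing a threshold, always ending at 0 dB."""
    lo = max(threshold_db - span_db, -15.0)
    return np.linspace(lo, 0.0, n_depths)


@dataclass
class BehavioralSession:
    """One animal's Go-Nogo session at a single AM rate."""

    animal_id: str
    hearing_status: str
    rate_hz: float
    trials: pd.DataFrame
    level_db_spl: float
    seed: int
    session_id: str = ""

    @property
    def go_depths(self) -> np.ndarray:
        return np.sort(self.trials.loc[self.trials["type"] == "go", "depth_db"].unique())


def _session_from_rng(config, animal_id, group, rate_hz, n_trials, rng, seed_label):
    preset = config.psych.get((group, float(rate_hz)))
    if preset is None:
        raise KeyError(f"no psychometric preset for group={group!r}, rate={rate_hz}")
    depths = depth_bracket(preset.threshold_db)
    is_nogo = rng.random(n_trials) < NOGO_PROB
    depth = np.where(is_nogo, np.nan, depths[rng.integers(0, len(depths), n_trials)])
    p_resp = np.where(is_nogo, preset.guess, preset.hit_prob(np.nan_to_num(depth)))
    responded = rng.random(n_trials) < p_resp
    outcome = np.where(
        is_nogo,
        np.where(responded, "fa", "cr"),
        np.where(responded, "hit", "miss"),
    )
    # group-invariant log-normal latencies; not an analysis target
    latency = rng.lognormal(mean=np.log(0.45), sigma=0.25, size=n_trials)
    level = config.level_db_spl.get(group, 45.0)
    if config.level_rove_db:
        level = level + rng.uniform(0.0, config.level_rove_db, n_trials)
    trials = pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "type": np.where(is_nogo, "nogo", "go"),
            "depth_db": depth,
            "response": np.where(responded, "spout", "repoke"),
            "outcome": outcome,
            "latency_s": latency,
            "level_db_spl": level,
        }
    )
    return BehavioralSession(
        animal_id=animal_id,
        hearing_status=group,
        rate_hz=float(rate_hz),
        trials=trials,
        level_db_spl=float(np.mean(level)),
        seed=seed_label,
        session_id=f"{animal_id}-{int(rate_hz)}Hz",
    )


def generate_session(
    config: CohortConfig,
    animal_id: str,
    group: str,
    rate_hz: float,
    n_trials: int | None = None,
    seed: int = 0,
) -> BehavioralSession:
    """Simulate one Go-Nogo session from the (group, rate) psychometric preset.

    Each trial is Nogo with probability 0.30, else Go at a depth drawn
    uniformly from the five-depth bracket; responses are independent
    Bernoulli draws from the preset psychometric function (Nogo responses
    at the guess rate).
    """
    if n_trials is None:
        n_trials = config.n_trials_per_session
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    return _session_from_rng(config, animal_id, group, rate_hz, n_trials, rng, seed)


@dataclass
class UnitRecording:
    """One unit's spike trains across the trials of a session.

    Spike times are seconds relative to the AM transition (t = 0); the
    nose poke occurs at ``nose_poke_t`` and the spontaneous window is the
    200 ms preceding it.
    """

    unit_id: str
    animal_id: str
    hearing_status: str
    rate_hz: float
    isolation: str
    spikes: list                 # one sorted float array per trial
    trials: pd.DataFrame         # copy of the session's trial table
    nose_poke_t: float = NOSE_POKE_T
    am_duration_s: float = AM_DURATION
    tuning: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.spikes) != len(self.trials):
            raise ValueError("one spike train per trial required")


def draw_tuning(preset: TuningPreset, rate_hz: float, rng) -> dict:
    """Draw one unit's tuning parameters from the group priors."""
    gain_rng = preset.depth_gain_hz.get(float(rate_hz), (6.0, 14.0))
    kappa_rng = preset.kappa_hz.get(float(rate_hz), preset.kappa)
    return {
        "monotonic": "inc" if rng.random() < preset.p_increasing else "dec",
        "spont_hz": float(rng.uniform(*preset.spont_hz)),
        "driven_base_hz": float(rng.uniform(*preset.driven_base_hz)),
        "depth_gain_hz": float(rng.uniform(*gain_rng)),
        "kappa": float(rng.uniform(*kappa_rng)),
        "gain_cv": preset.gain_cv,
        "isolation": "single" if rng.random() < preset.p_single_unit else "multi",
    }


def _depth_rate(tuning: dict, depth_db: float) -> float:
    """Mean driven rate (Hz) for one stimulus condition."""
    m = depth_db_to_fraction(depth_db)  # 0 for the unmodulated Nogo
    base, gain = tuning["driven_base_hz"], tuning["depth_gain_hz"]
    if tuning["monotonic"] == "inc":
        return base + gain * m
    return base + gain * (1.0 - m)


def _mod_poisson(rate_hz, f_hz, kappa, t0, t1, rng):
    """Inhomogeneous Poisson train with rate r*(1 + kappa*sin(2*pi*f*t))."""
    if rate_hz <= 0:
        return np.empty(0)
    r_max = rate_hz * (1.0 + kappa)
    n = rng.poisson(r_max * (t1 - t0))
    t = np.sort(rng.uniform(t0, t1, n))
    keep = rng.random(n) * (1.0 + kappa) < 1.0 + kappa * np.sin(2 * np.pi * f_hz * t)
    return t[keep]


def generate_unit(
    config: CohortConfig,
    session: BehavioralSession,
    tuning: dict,
    seed: int = 0,
    unit_id: str = "u0",
) -> UnitRecording:
    """Simulate one unit recorded across all trials of ``session``.

    Driven spikes come from a doubly stochastic process: a per-trial gamma
    gain (mean 1, CV from the group preset) multiplying a sinusoidally
    modulated Poisson rate during the AM portion; the pre-transition
    window fires at the spontaneous rate.
    """
    if tuning["kappa"] < 0 or tuning["kappa"] > 1:
        raise ValueError("kappa must lie in [0, 1]")
    for k in ("spont_hz", "driven_base_hz", "depth_gain_hz"):
        if tuning[k] < 0:
            raise ValueError(f"{k} must be nonnegative")
    rng = np.random.default_rng(seed)
    cv = tuning["gain_cv"]
    if cv <= 0:
        raise ValueError("gain_cv must be positive")
    shape = 1.0 / cv**2
    spikes = []
    for _, tr in session.trials.iterrows():
        depth = tr["depth_db"] if tr["type"] == "go" else UNMODULATED
        g = rng.gamma(shape, scale=1.0 / shape)
        if config.choice_coupling and tr["response"] == "spout":
            g *= 1.0 + config.choice_coupling
        pre = np.sort(
            rng.uniform(TRIAL_START, 0.0,
                        rng.poisson(tuning["spont_hz"] * (0.0 - TRIAL_START)))
        )
        # phase locking scales with linear modulation depth (0 for the Nogo)
        kappa_eff = tuning["kappa"] * depth_db_to_fraction(depth)
        driven = _mod_poisson(
            g * _depth_rate(tuning, depth), session.rate_hz, kappa_eff,
            0.0, AM_DURATION, rng,
        )
        spikes.append(np.concatenate([pre, driven]))
    return UnitRecording(
        unit_id=unit_id,
        animal_id=session.animal_id,
        hearing_status=session.hearing_status,
        rate_hz=session.rate_hz,
        isolation=tuning.get("isolation", "multi"),
        spikes=spikes,
        trials=session.trials.copy(),
        tuning=dict(tuning),
    )


@dataclass
class EFRRecording:
    """Averaged envelope-following waveform for one (rate, depth) stimulus."""

    waveform_uv: np.ndarray
    fs: float
    rate_hz: float
    depth_db: float
    onset_s: float
    offset_s: float
    n_sweeps: int = 1000
    electrode_config: int = 1

    def __post_init__(self):
        if self.fs <= 2 * self.rate_hz:
            raise ValueError("fs too low for the modulation rate")


def generate_efr(
    config: CohortConfig, stimulus: AMStimulus, seed: int = 0
) -> EFRRecording:
    """Sinusoid at the modulation rate in white noise, amplitude set by depth."""
    p = config.efr
    if p.fs <= 2 * stimulus.rate_hz:
        raise ValueError("EFR sampling rate too low for this AM rate")
    rng = np.random.default_rng(seed)
    n = int(round((p.stim_duration_s + 2 * p.pad_s) * p.fs))
    t = np.arange(n) / p.fs
    onset, offset = p.pad_s, p.pad_s + p.stim_duration_s
    a = p.amplitude(stimulus.depth_db)
    wave = rng.normal(0.0, p.noise_sd_uv / np.sqrt(p.n_sweeps), n)
    active = (t >= onset) & (t < offset)
    wave[active] += a * np.sin(2 * np.pi * stimulus.rate_hz * (t[active] - onset))
    return EFRRecording(
        waveform_uv=wave, fs=p.fs, rate_hz=stimulus.rate_hz,
        depth_db=stimulus.depth_db, onset_s=onset, offset_s=offset,
        n_sweeps=p.n_sweeps, electrode_config=1 if stimulus.rate_hz < 200 else 2,
    )


@dataclass
class ABRRecording:
    """Click-evoked traces across a descending level ladder for one animal."""

    animal_id: str
    hearing_status: str
    traces_uv: dict      # level (dB SPL) -> waveform array
    fs: float
    click_t_s: float     # click onset within each trace


def generate_abr(
    config: CohortConfig, animal_id: str, group: str, seed: int = 0
) -> ABRRecording:
    """Level-scaled template peak with latency shortening at higher levels."""
    p = config.abr[group]
    rng = np.random.default_rng(seed)
    click_t = 0.005
    dur = 0.015
    n = int(round(dur * p.fs))
    t = np.arange(n) / p.fs
    traces = {}
    for level in p.levels_db_spl:
        tr = rng.normal(0.0, p.noise_sd_uv, n)
        sl = level - p.threshold_db_spl  # sensation level
        if sl > 0:
            amp = p.amp_per_db * sl
            lat = (p.latency0_ms - p.latency_slope_ms_per_db * sl) / 1000.0
            peak_t = click_t + lat
            tr += amp * np.exp(-0.5 * ((t - peak_t) / 0.0003) ** 2)
        traces[float(level)] = tr
    return ABRRecording(
        animal_id=animal_id, hearing_status=group, traces_uv=traces,
        fs=p.fs, click_t_s=click_t,
    )


def generate_cohort(config: CohortConfig) -> dict:
    """Generate every session, unit, EFR and ABR for the configured cohort.

    Returns a dict with keys ``sessions`` (list of BehavioralSession),
    ``units`` (list of UnitRecording), ``efr`` (list of EFRRecording),
    ``abr`` (list of ABRRecording) and ``manifest``. Fully deterministic:
    all child seeds derive from ``config.master_seed``.
    """
    if config.n_animals < 1:
        raise ValueError("need at least one animal per group")
    lo, hi = config.unit_count_range
    if lo < 1:
        raise ValueError("unit counts must be positive")
    ss = np.random.SeedSequence(config.master_seed)
    sessions, units, efrs, abrs = [], [], [], []
    for group in config.groups:
        for a in range(config.n_animals):
            animal_id = f"{group}{a:02d}"
            (a_ss,) = ss.spawn(1)
            rng = np.random.default_rng(a_ss)
            animal_sessions = {}
            for rate in config.rates_hz:
                sess = _session_from_rng(
                    config, animal_id, group, rate,
                    config.n_trials_per_session, rng, seed_label=-1,
                )
                animal_sessions[rate] = sess
                sessions.append(sess)
            n_units = int(rng.integers(lo, hi + 1))
            preset = config.tuning[group]
            for u in range(n_units):
                rate = config.rates_hz[int(rng.integers(0, len(config.rates_hz)))]
                tuning = draw_tuning(preset, rate, rng)
                (u_ss,) = a_ss.spawn(1)
                units.append(
                    generate_unit(
                        config, animal_sessions[rate], tuning,
                        seed=u_ss, unit_id=f"{animal_id}-u{u:03d}",
                    )
                )
            for rate in config.rates_hz:
                for depth in list(depth_bracket(
                        config.psych[(group, float(rate))].threshold_db)) + [UNMODULATED]:
                    stim = AMStimulus(rate_hz=rate, depth_db=depth,
                                      level_db_spl=config.level_db_spl.get(group, 45.0))
                    (e_ss,) = a_ss.spawn(1)
                    rec = generate_efr(config, stim, seed=e_ss)
                    rec.animal_id = animal_id  # annotate for grouping
                    rec.hearing_status = group
                    efrs.append(rec)
            (abr_ss,) = a_ss.spawn(1)
            abrs.append(generate_abr(config, animal_id, group, seed=abr_ss))
    manifest = {
        "master_seed": config.master_seed,
        "n_sessions": len(sessions),
        "n_units": len(units),
        "n_efr": len(efrs),
        "n_abr": len(abrs),
        "n_objects": len(sessions) + len(units) + len(efrs) + len(abrs),
        "groups": list(config.groups),
        "rates_hz": [float(r) for r in config.rates_hz],
    }
    return {"sessions": sessions, "units": units, "efr": efrs, "abr": abrs,
            "manifest": manifest}


def config_to_dict(config: CohortConfig) -> dict:
    """YAML/JSON-serializable view of a CohortConfig."""
    d = copy.deepcopy(asdict(config))
    d["psych"] = {f"{g}:{int(r)}": v for (g, r), v in d["psych"].items()}
    return d
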