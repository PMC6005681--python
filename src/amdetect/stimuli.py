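"""AM stimulus parameterization, depth-unit conversion and envelope synthesis.

Modulation depth is expressed in dB relative to 100% (full) modulation using
the amplitude convention ``depth_db = 20*log10(m)``, so 0 dB is fully
modulated and more negative values are shallower (-6 dB ~ 50%, -9 dB ~ 35%).
The unmodulated Nogo signal is represented by the sentinel
:data:`UNMODULATED` rather than -inf so tables stay finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

#: Sentinel depth for the unmodulated (Nogo) stimulus.
UNMODULATED: float = float("nan")

#: Default sampling rate for waveform-level synthesis (Hz).
DEFAULT_FS: float = 48_000.0

#: Fringe-mode timing: linear onset ramp then an unmodulated lead-in.
FRINGE_RAMP_S: float = 0.2
FRINGE_UNMOD_S: float = 0.2


def is_unmodulated(depth_db: float) -> bool:
    """True if ``depth_db`` is the unmodulated sentinel."""
    return isinstance(depth_db, float) and math.isnan(depth_db)


@dataclass(frozen=True)
class AMStimulus:
    """Parameterization of one AM noise stimulus.

    Parameters
    ----------
    rate_hz
        Modulation rate in Hz (64, 128, 256, 512 in the task; extensible).
    depth_db
        Modulation depth in dB re 100% (<= 0), or :data:`UNMODULATED`.
    level_db_spl
        Nominal presentation level.
    fringe
        If True the stimulus has a 200 ms onset ramp followed by a 200 ms
        unmodulated lead-in before the AM transition; otherwise a 25 ms
        cosine-gated onset with the AM present from the start.
    duration_s
        Total stimulus duration (seconds).
    """

    rate_hz: float
    depth_db: float = 0.0
    level_db_spl: float = 45.0
    fringe: bool = True
    duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        if not is_unmodulated(self.depth_db) and self.depth_db > 0:
            raise ValueError(
                f"depth_db must be <= 0 dB re 100% (got {self.depth_db}); "
                "positive depths exceed full modulation"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.am_onset_s >= self.duration_s:
            raise ValueError("AM onset falls after stimulus offset")

    @property
    def am_onset_s(self) -> float:
        """Time of the unmodulated-to-AM transition relative to sound onset."""
        return FRINGE_RAMP_S + FRINGE_UNMOD_S if self.fringe else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        if is_unmodulated(self.depth_db):
            d["depth_db"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AMStimulus":
        d = dict(d)
        if d.get("depth_db") is None:
            d["depth_db"] = UNMODULATED
        return cls(**d)


def depth_db_to_fraction(depth_db: float) -> float:
    """Convert depth in dB re 100% to a linear modulation fraction m in [0, 1].

    The unmodulated sentinel maps to 0. Raises for positive dB values.
    """
    if is_unmodulated(depth_db):
        return 0.0
    if depth_db > 0:
        raise ValueError(
            f"depth_db must be <= 0 (dB re 100% depth), got {depth_db}"
        )
    return 10.0 ** (depth_db / 20.0)


def fraction_to_depth_db(m: float) -> float:
    """Inverse of :func:`depth_db_to_fraction` for m in (0, 1]; 0 -> sentinel."""
    if not 0.0 <= m <= 1.0:
        raise ValueError(f"modulation fraction must be in [0, 1], got {m}")
    if m == 0.0:
        return UNMODULATED
    return 20.0 * math.log10(m)


def am_envelope(stim: AMStimulus, fs: float = DEFAULT_FS) -> np.ndarray:
    """Sampled stimulus envelope with power-equalizing gain.

    Post-onset: ``e(t) = g*(1 + m*sin(2*pi*rate*(t - am_onset)))`` with
    ``g = 1/sqrt(1 + m**2/2)`` so the envelope RMS is depth-invariant.
    Fringe mode prepends the 200 ms linear ramp and 200 ms unmodulated
    lead-in (both at unit amplitude, scaled by the ramp only).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if fs <= 2 * stim.rate_hz:
        raise ValueError(
            f"fs={fs} must exceed twice the modulation rate {stim.rate_hz}"
        )
    m = depth_db_to_fraction(stim.depth_db)
    g = 1.0 / math.sqrt(1.0 + m * m / 2.0)
    t = np.arange(int(round(stim.duration_s * fs))) / fs
    env = np.ones_like(t)
    onset = stim.am_onset_s
    post = t >= onset
    env[post] = g * (1.0 + m * np.sin(2.0 * np.pi * stim.rate_hz * (t[post] - onset)))
    if stim.fringe:
        ramp = t < FRINGE_RAMP_S
        env[ramp] *= t[ramp] / FRINGE_RAMP_S
    else:
        rise = 0.025
        ramp = t < rise
        env[ramp] *= np.sin(0.5 * np.pi * t[ramp] / rise) ** 2
    return np.maximum(env, 0.0)


def am_waveform(
    stim: AMStimulus, fs: float = DEFAULT_FS, seed: int | None = None
) -> np.ndarray:
    """Envelope applied to a band-limited (3.5-20 kHz) noise carrier.

    Only needed for waveform-level demos; every analysis in this package
    operates on envelopes or spike trains.
    """
    from scipy.signal import butter, sosfiltfilt

    if fs <= 2 * 20_000.0:
        raise ValueError("fs too low for the 3.5-20 kHz carrier band")
    rng = np.random.default_rng(seed)
    env = am_envelope(stim, fs)
    noise = rng.standard_normal(env.size)
    sos = butter(4, [3_500.0, 20_000.0], btype="bandpass", fs=fs, output="sos")
    carrier = sosfiltfilt(sos, noise)
    carrier /= np.sqrt(np.mean(carrier**2))
    return env * carrier


@dataclass
class StimulusSet:
    """A serializable family of stimuli sharing rate/level/timing."""

    rate_hz: float
    depths_db: list = field(default_factory=list)
    level_db_spl: float = 45.0
    fringe: bool = True
    duration_s: float = 1.0

    def stimuli(self, include_nogo: bool = True) -> list:
        out = [
            AMStimulus(self.rate_hz, d, self.level_db_spl, self.fringe, self.duration_s)
            for d in self.depths_db
        ]
        if include_nogo:
            out.append(
                AMStimulus(
                    self.rate_hz, UNMODULATED, self.level_db_spl, self.fringe,
                    self.duration_s,
                )
            )
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "StimulusSet":
        return cls(**json.loads(s))
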