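"""Time-of-flight extraction: cross-correlation + Hilbert envelope peaks.

The measured trace is modelled as attenuated, delayed copies of the
reference template plus noise, Se(t) = a * Sr(t - D) + n(t); the
cross-correlation of reference and trace then peaks at lag D, and the
Hilbert envelope of the correlation makes that peak carrier-phase
independent. The anterior (near) and posterior (far) bladder-wall
echoes appear as the two dominant envelope peaks; their delays map to
distances via the pulse-echo relation d = c * t / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate, find_peaks, hilbert

from .echo import SampledSignal
from .exceptions import InvalidArgumentError, NoPosteriorEchoError

__all__ = [
    "WallRange",
    "cross_correlate",
    "hilbert_envelope",
    "detect_wall_delays",
    "delay_to_distance",
]

#: Sound speed presets (m/s): water-bath phantom and soft tissue.
SOUND_SPEED_WATER = 1480.0
SOUND_SPEED_TISSUE = 1540.0


@dataclass
class WallRange:
    """Anterior/posterior wall timing and range for one transducer."""

    transducer_id: int
    anterior_delay: float        # us (two-way)
    posterior_delay: float       # us (two-way)
    anterior_distance: float     # mm along the beam
    posterior_distance: float    # mm along the beam
    peak_quality: tuple[float, float] = (math.nan, math.nan)

    def __post_init__(self) -> None:
        if not (self.posterior_delay > self.anterior_delay):
            raise InvalidArgumentError(
                "posterior delay must exceed anterior delay"
            )

    @property
    def wall_separation_time(self) -> float:
        return self.posterior_delay - self.anterior_delay

    @classmethod
    def from_delays(
        cls,
        transducer_id: int,
        anterior_delay: float,
        posterior_delay: float,
        sound_speed: float = SOUND_SPEED_WATER,
        peak_quality: tuple[float, float] = (math.nan, math.nan),
    ) -> "WallRange":
        return cls(
            transducer_id=transducer_id,
            anterior_delay=anterior_delay,
            posterior_delay=posterior_delay,
            anterior_distance=delay_to_distance(anterior_delay, sound_speed),
            posterior_distance=delay_to_distance(posterior_delay, sound_speed),
            peak_quality=peak_quality,
        )


def cross_correlate(reference: SampledSignal, echo: SampledSignal) -> SampledSignal:
    """Full-lag cross-correlation with an explicit lag-to-time mapping.

    The returned trace's time axis is the arrival-time axis: if the echo
    contains a copy of the reference delayed by D (relative to the
    reference's own time origin), the correlation peaks at time D. An
    autocorrelation therefore peaks at time 0.
    """
    if reference.sampling_rate != echo.sampling_rate:
        raise InvalidArgumentError("sampling-rate mismatch between reference and echo")
    fs = echo.sampling_rate
    c = correlate(echo.samples, reference.samples, mode="full", method="auto")
    n_ref = len(reference)
    start = echo.start_time - reference.start_time - (n_ref - 1) / fs
    return SampledSignal(c, fs, start)


def hilbert_envelope(x: SampledSignal) -> SampledSignal:
    """Magnitude of the analytic signal (non-negative, >= |x|)."""
    if len(x) < 4:
        raise InvalidArgumentError("need at least 4 samples for an analytic signal")
    return x.copy_with(np.abs(hilbert(x.samples)))


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """3-point parabolic sub-sample peak refinement; returns offset in samples."""
    if i <= 0 or i >= y.size - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return 0.0
    offset = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(offset, -0.5, 0.5))


def detect_wall_delays(
    corr_envelope: SampledSignal,
    min_separation: float,
    threshold_frac: float = 0.02,
    subsample: bool = True,
) -> tuple[float, float, tuple[float, float]]:
    """Locate the anterior and posterior wall peaks on a correlation envelope.

    Picks the two largest envelope peaks that are at least
    ``min_separation`` (us) apart and above ``threshold_frac`` of the
    envelope maximum, returning their times in time order plus the raw
    envelope peak heights. Fewer than two qualifying peaks raises
    NoPosteriorEchoError — the empty-bladder condition.
    """
    if not (min_separation > 0):
        raise InvalidArgumentError("min_separation must be > 0")
    if not (0.0 < threshold_frac < 1.0):
        raise InvalidArgumentError("threshold_frac must be in (0, 1)")
    env = corr_envelope.samples
    fs = corr_envelope.sampling_rate
    distance = max(1, int(round(min_separation * fs)))
    height = threshold_frac * float(env.max(initial=0.0))
    if height <= 0.0:
        raise NoPosteriorEchoError("envelope is identically zero")
    peaks, props = find_peaks(env, height=height, distance=distance)
    if peaks.size < 2:
        raise NoPosteriorEchoError(
            f"found {peaks.size} qualifying peak(s); posterior wall not visible"
        )
    heights = props["peak_heights"]
    top2 = peaks[np.argsort(heights)[-2:]]
    top2.sort()
    delays = []
    quals = []
    for p in top2:
        off = _parabolic_refine(env, int(p)) if subsample else 0.0
        delays.append(corr_envelope.start_time + (p + off) / fs)
        quals.append(float(env[p]))
    return delays[0], delays[1], (quals[0], quals[1])


def delay_to_distance(delay_us: float, sound_speed: float = SOUND_SPEED_WATER) -> float:
    """Two-way delay (us) to one-way range (mm): d = c * t / 2."""
    if delay_us < 0:
        raise InvalidArgumentError("delay must be >= 0")
    if not (sound_speed > 0):
        raise InvalidArgumentError("sound_speed must be > 0")
    # c [m/s] * t [us] / 2 = c*t/2 * 1e-6 m = c*t/2000 mm
    return sound_speed * delay_us / 2000.0
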