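"""Synthetic multi-transducer bladder phantom.

Emulates an A-mode bladder scanner: a rigid head of 14 transducers fires
sequentially; each beam, treated as an ideal ray, intersects a
ground-truth ellipsoidal "bladder" and returns a two-echo trace — a
strong anterior-wall echo and a weak posterior-wall echo (by default 5%
of the anterior amplitude, the approximate fraction of the pulse that
penetrates a urine-filled anterior wall). Each channel also records an
equal-length noise-only reference track from an independent random
substream, mirroring the no-emission reference capture used to
calibrate denoising.

The default head is a two-row arc (7 + 7) of beams focused at a nominal
60 mm depth, azimuth span +/-40 deg, row elevation +/-10 deg, which
places the face about 30 mm from the surface of a 150 mL bladder. The
scanner is deliberately config-driven: no physical device is being
dimensioned here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .echo import EchoParams, SampledSignal, bandwidth_to_alpha, evaluate_echo
from .ellipsoid import EllipsoidGeometry
from .exceptions import InvalidArgumentError, PhantomConfigurationError
from .tof import SOUND_SPEED_WATER

__all__ = [
    "ScanGeometry",
    "PhantomConfig",
    "ChannelRecording",
    "ScanBundle",
    "default_scan_geometry",
    "ellipsoid_truth",
    "ray_ellipsoid_intersections",
    "synthesize_channel",
    "generate_scan",
]

DEFAULT_N_TRANSDUCERS = 14
#: ~5% of the pulse penetrates the anterior wall of a filled bladder.
DEFAULT_POSTERIOR_RATIO = 0.05
DEFAULT_TEMPLATE = EchoParams(
    amplitude=1.0,
    bandwidth_factor=bandwidth_to_alpha(0.2),   # 200 kHz bandwidth
    arrival_time=0.0,
    center_freq=1.0,                            # 1 MHz carrier
    phase=0.0,
)


@dataclass
class ScanGeometry:
    """Transducer positions (mm) and unit beam directions."""

    transducer_positions: np.ndarray    # (n, 3)
    beam_directions: np.ndarray         # (n, 3), unit norm
    layout_name: str = "custom"

    def __post_init__(self) -> None:
        self.transducer_positions = np.asarray(self.transducer_positions, float)
        self.beam_directions = np.asarray(self.beam_directions, float)
        if self.transducer_positions.shape != self.beam_directions.shape or \
                self.transducer_positions.ndim != 2 or \
                self.transducer_positions.shape[1] != 3:
            raise InvalidArgumentError("positions and directions must both be (n, 3)")
        norms = np.linalg.norm(self.beam_directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise InvalidArgumentError("beam directions must be unit-norm")

    @property
    def n_transducers(self) -> int:
        return self.transducer_positions.shape[0]


def default_scan_geometry(
    focal_depths_mm: tuple[float, float] = (55.0, 65.0),
    standoff_mm: float = 60.0,
    span_deg: float = 90.0,
    elevation_deg: float = 35.0,
    n_per_row: int = 7,
) -> ScanGeometry:
    """Two-row arc (n_per_row + n_per_row) of converging beams.

    Two deliberate geometric choices keep the downstream ellipsoid fit
    well conditioned. First, each row focuses at its own on-axis depth:
    if all 14 beams passed through a single point, their chords through
    a centered phantom would lie on a quadratic cone and the wall
    points would no longer determine the quadric uniquely. Second, the
    rows sit at a steep +/-35 deg elevation so the wall points sample
    surface curvature in both transverse directions; shallow rows leave
    one semi-axis nearly unconstrained and tiny ranging noise then
    swings the fitted volume by tens of percent.
    """
    azimuths = np.deg2rad(np.linspace(-span_deg / 2.0, span_deg / 2.0, n_per_row))
    positions, directions = [], []
    for row, depth in zip((-1.0, 1.0), focal_depths_mm):
        el = row * math.radians(elevation_deg)
        focal = np.array([0.0, 0.0, depth])
        for az in azimuths:
            u = np.array(
                [math.cos(el) * math.sin(az), math.sin(el),
                 math.cos(el) * math.cos(az)]
            )
            directions.append(u)
            positions.append(focal - standoff_mm * u)
    return ScanGeometry(
        np.array(positions), np.array(directions),
        layout_name=f"arc{2 * n_per_row}",
    )


def ellipsoid_truth(
    volume_ml: float = 150.0,
    center: tuple[float, float, float] = (0.0, 0.0, 60.0),
    axis_ratios: tuple[float, float, float] = (1.3, 1.0, 0.75),
    rotation: np.ndarray | None = None,
) -> EllipsoidGeometry:
    """Ground-truth ellipsoid of a given volume with fixed axis ratios."""
    if not (volume_ml > 0):
        raise InvalidArgumentError("volume must be > 0")
    ratios = np.sort(np.asarray(axis_ratios, float))[::-1]
    if np.any(ratios <= 0):
        raise InvalidArgumentError("axis ratios must be positive")
    s = (volume_ml * 1000.0 * 3.0 / (4.0 * math.pi * float(np.prod(ratios)))) ** (1.0 / 3.0)
    return EllipsoidGeometry(
        center=np.asarray(center, float),
        semi_axes=ratios * s,
        rotation=np.eye(3) if rotation is None else rotation,
    )


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic scan."""

    truth: EllipsoidGeometry = field(default_factory=ellipsoid_truth)
    sound_speed: float = SOUND_SPEED_WATER          # m/s
    echo_template: EchoParams = DEFAULT_TEMPLATE    # anterior-wall echo shape
    posterior_amplitude_ratio: float = DEFAULT_POSTERIOR_RATIO
    noise_snr_db: float = 10.0
    sampling_rate: float = 10.0                     # MHz
    trace_length: int = 2048
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior_amplitude_ratio <= 1.0):
            raise InvalidArgumentError("posterior_amplitude_ratio must be in [0, 1]")
        if not (self.sound_speed > 0):
            raise InvalidArgumentError("sound_speed must be > 0")
        if self.trace_length < 4:
            raise InvalidArgumentError("trace_length too short")


@dataclass
class ChannelRecording:
    transducer_id: int
    noisy: SampledSignal
    clean: SampledSignal
    noise_reference: SampledSignal
    entry_distance: float | None        # mm; None when the ray misses
    exit_distance: float | None


@dataclass
class ScanBundle:
    geometry: ScanGeometry
    config: PhantomConfig
    channels: list[ChannelRecording]
    wall_points: np.ndarray             # (m, 3) ground-truth entry/exit points

    @property
    def n_hits(self) -> int:
        return sum(1 for ch in self.channels if ch.entry_distance is not None)


def ray_ellipsoid_intersections(
    origin: np.ndarray, direction: np.ndarray, truth: EllipsoidGeometry
) -> tuple[float, float] | None:
    """Entry/exit distances (mm) of a ray with the truth ellipsoid.

    Returns None when the ray misses (tangency counts as a miss);
    distances are along the (unit) direction from the origin, both
    required positive.
    """
    d = np.asarray(direction, float)
    if not math.isclose(float(np.linalg.norm(d)), 1.0, abs_tol=1e-9):
        raise InvalidArgumentError("direction must be unit-norm")
    o = np.asarray(origin, float)
    # map to the unit-sphere frame of the ellipsoid
    Rt = truth.rotation.T
    o_ = (Rt @ (o - truth.center)) / truth.semi_axes
    d_ = (Rt @ d) / truth.semi_axes
    a = float(d_ @ d_)
    b = 2.0 * float(o_ @ d_)
    c = float(o_ @ o_) - 1.0
    disc = b * b - 4.0 * a * c
    if disc <= 0.0:
        return None
    sq = math.sqrt(disc)
    t1 = (-b - sq) / (2.0 * a)
    t2 = (-b + sq) / (2.0 * a)
    if t1 <= 0.0 or math.isclose(t1, t2, rel_tol=1e-12):
        return None
    return t1, t2


def _distance_to_delay(distance_mm: float, sound_speed: float) -> float:
    """One-way range (mm) to two-way delay (us)."""
    return 2.0 * distance_mm / (sound_speed / 1000.0)


def synthesize_channel(
    entry: float,
    exit: float,
    config: PhantomConfig,
    channel_seed: tuple[int, ...] = (0,),
) -> tuple[SampledSignal, SampledSignal, SampledSignal]:
    """Render one channel: (noisy trace, clean trace, noise reference).

    Two Gaussian echoes at two-way delays 2*entry/c and 2*exit/c, the
    posterior scaled by ``posterior_amplitude_ratio``, plus seeded white
    noise at ``noise_snr_db``; the reference track is an independent
    noise realization of the same variance.
    """
    if not (exit > entry > 0):
        raise InvalidArgumentError("need exit > entry > 0")
    fs = config.sampling_rate
    n = config.trace_length
    tpl = config.echo_template
    tau_a = _distance_to_delay(entry, config.sound_speed)
    tau_p = _distance_to_delay(exit, config.sound_speed)
    margin = 3.0 / math.sqrt(tpl.bandwidth_factor)
    if tau_p + margin > (n - 1) / fs:
        raise PhantomConfigurationError(
            f"posterior delay {tau_p:.1f} us exceeds the {((n - 1) / fs):.1f} us trace"
        )
    t = np.arange(n) / fs
    anterior = evaluate_echo(replace_tau(tpl, tau_a), t)
    clean_samples = anterior
    if config.posterior_amplitude_ratio > 0.0:
        posterior = evaluate_echo(replace_tau(tpl, tau_p), t)
        clean_samples = anterior + config.posterior_amplitude_ratio * posterior
    clean = SampledSignal(clean_samples, fs)

    if math.isinf(config.noise_snr_db):
        zeros = np.zeros(n)
        return clean.copy_with(clean_samples.copy()), clean, clean.copy_with(zeros)
    power = float(np.mean(clean_samples**2))
    sigma = math.sqrt(power / 10.0 ** (config.noise_snr_db / 10.0))
    rng_noise = np.random.default_rng([config.seed, *channel_seed, 0])
    rng_ref = np.random.default_rng([config.seed, *channel_seed, 1])
    noisy = clean.copy_with(clean_samples + sigma * rng_noise.standard_normal(n))
    reference = clean.copy_with(sigma * rng_ref.standard_normal(n))
    return noisy, clean, reference


def replace_tau(params: EchoParams, tau: float) -> EchoParams:
    return EchoParams(params.amplitude, params.bandwidth_factor, tau,
                      params.center_freq, params.phase)


def generate_scan(geometry: ScanGeometry, config: PhantomConfig) -> ScanBundle:
    """Fire every transducer in turn and bundle the recordings.

    Channels whose ray misses the truth ellipsoid record pure noise.
    Ground-truth wall points (entry/exit converted to 3-D coordinates)
    ride along for oracle comparisons.
    """
    channels: list[ChannelRecording] = []
    wall_points: list[np.ndarray] = []
    for i in range(geometry.n_transducers):
        origin = geometry.transducer_positions[i]
        direction = geometry.beam_directions[i]
        hit = ray_ellipsoid_intersections(origin, direction, config.truth)
        if hit is None:
            n = config.trace_length
            fs = config.sampling_rate
            rng_noise = np.random.default_rng([config.seed, i, 0])
            rng_ref = np.random.default_rng([config.seed, i, 1])
            # no echo: the channel records noise at an absolute floor tied
            # to the template amplitude (the transmitter still fires)
            sigma = 0.0 if math.isinf(config.noise_snr_db) else (
                config.echo_template.amplitude
                / 10.0 ** (config.noise_snr_db / 20.0)
            )
            channels.append(ChannelRecording(
                transducer_id=i,
                noisy=SampledSignal(sigma * rng_noise.standard_normal(n), fs),
                clean=SampledSignal(np.zeros(n), fs),
                noise_reference=SampledSignal(sigma * rng_ref.standard_normal(n), fs),
                entry_distance=None, exit_distance=None,
            ))
            continue
        entry, exit = hit
        noisy, clean, ref = synthesize_channel(entry, exit, config, channel_seed=(i,))
        channels.append(ChannelRecording(i, noisy, clean, ref, entry, exit))
        wall_points.append(origin + entry * direction)
        wall_points.append(origin + exit * direction)
    if not wall_points:
        raise PhantomConfigurationError("every beam misses the phantom")
    return ScanBundle(
        geometry=geometry,
        config=config,
        channels=channels,
        wall_points=np.array(wall_points),
    )
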