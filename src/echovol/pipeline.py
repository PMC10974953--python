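"""End-to-end volume estimation: denoise -> reference fit -> ToF -> ellipsoid.

Per channel: calibrate a threshold plan from the channel's noise-only
reference, denoise adaptively, fit the Gaussian echo model to build a
reference template, cross-correlate, take the Hilbert envelope, and
locate the anterior/posterior wall peaks. Wall delays become ranges
(d = c t / 2) and 3-D wall points along the ideal beam ray; the pooled
points are fitted with the ellipsoid-specific least-squares quadric and
the ellipsoid volume is the bladder-volume estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import denoise as dn
from . import ellipsoid as el
from . import fitting, tof
from .exceptions import (
    FitFailureError,
    NoEchoError,
    NoPosteriorEchoError,
)
from .phantom import ScanBundle

__all__ = ["VolumeEstimate", "estimate_volume_from_scan"]

#: Channels whose correlation-envelope anterior peak quality (normalized
#: correlation coefficient) is below this are treated as echo-free.
MIN_ANTERIOR_QUALITY = 0.2
MIN_POINTS = el.MIN_POINTS


@dataclass
class VolumeEstimate:
    geometry: el.EllipsoidGeometry
    diagnostics: el.FitDiagnostics
    wall_ranges: list[tof.WallRange]
    wall_points: np.ndarray
    n_channels_used: int
    n_channels_total: int
    skipped: dict[int, str] = field(default_factory=dict)

    @property
    def volume_ml(self) -> float:
        return self.geometry.volume_ml


def _channel_wall_range(
    channel, sound_speed: float, wavelet: str, n_levels: int, shape_beta: int,
    threshold_frac: float, subsample: bool,
) -> tof.WallRange:
    plan = dn.build_threshold_plan(
        channel.noisy, channel.noise_reference,
        wavelet_name=wavelet, n_levels=n_levels, shape_beta=shape_beta,
    )
    denoised = dn.denoise_signal(channel.noisy, plan, mode="adaptive")
    reference, fit = fitting.build_reference_signal(denoised)
    corr = tof.cross_correlate(reference, denoised)
    env = tof.hilbert_envelope(corr)
    min_sep = 2.0 / fit.theta_hat.center_freq  # two carrier periods
    ant, post, quals = tof.detect_wall_delays(
        env, min_separation=min_sep, threshold_frac=threshold_frac,
        subsample=subsample,
    )
    norm = math.sqrt(
        float(np.sum(reference.samples**2)) * float(np.sum(denoised.samples**2))
    )
    q = (quals[0] / norm, quals[1] / norm) if norm > 0 else (0.0, 0.0)
    if q[0] < MIN_ANTERIOR_QUALITY:
        raise NoEchoError(
            f"anterior correlation quality {q[0]:.3f} below "
            f"{MIN_ANTERIOR_QUALITY}: channel carries no echo"
        )
    return tof.WallRange.from_delays(
        channel.transducer_id, ant, post, sound_speed=sound_speed, peak_quality=q
    )


def estimate_volume_from_scan(
    bundle: ScanBundle,
    wavelet: str = dn.DEFAULT_WAVELET,
    n_levels: int = dn.DEFAULT_LEVELS,
    shape_beta: int = dn.DEFAULT_SHAPE_BETA,
    threshold_frac: float = 0.02,
    subsample: bool = True,
    min_points: int = MIN_POINTS,
) -> VolumeEstimate:
    """Run the full pipeline on a scan bundle.

    Channels with no posterior echo (empty bladder / missed beam) are
    skipped and recorded; if fewer than ``min_points`` wall points
    survive, NoPosteriorEchoError propagates — the bladder is flagged
    unmeasurable rather than mis-fitted.
    """
    geometry = bundle.geometry
    sound_speed = bundle.config.sound_speed
    ranges: list[tof.WallRange] = []
    points: list[np.ndarray] = []
    skipped: dict[int, str] = {}
    for ch in bundle.channels:
        try:
            wr = _channel_wall_range(
                ch, sound_speed, wavelet, n_levels, shape_beta,
                threshold_frac, subsample,
            )
        except (NoPosteriorEchoError, NoEchoError, FitFailureError) as exc:
            skipped[ch.transducer_id] = f"{type(exc).__name__}: {exc}"
            continue
        ranges.append(wr)
        origin = geometry.transducer_positions[ch.transducer_id]
        direction = geometry.beam_directions[ch.transducer_id]
        points.append(origin + wr.anterior_distance * direction)
        points.append(origin + wr.posterior_distance * direction)
    if len(points) < min_points:
        raise NoPosteriorEchoError(
            f"only {len(points)} wall points recovered (< {min_points}): "
            "bladder unmeasurable (empty or out of view)"
        )
    pts = np.array(points)
    geom, diag = el.estimate_volume(pts)
    return VolumeEstimate(
        geometry=geom,
        diagnostics=diag,
        wall_ranges=ranges,
        wall_points=pts,
        n_channels_used=len(ranges),
        n_channels_total=geometry.n_transducers,
        skipped=skipped,
    )
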