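"""Readers/writers for traces, point clouds and reports.

Text trace format: two delimited columns (time_us, amplitude) preceded by
``# sampling_rate_mhz=`` and ``# start_time_us=`` header comments; values
are written with 12 significant digits. A binary ``.npz`` container is
the bit-exact alternative.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .echo import SampledSignal
from .exceptions import InvalidArgumentError

__all__ = [
    "read_signal",
    "write_signal",
    "read_points",
    "write_points",
]

_RATE_KEY = "# sampling_rate_mhz="
_START_KEY = "# start_time_us="


class SignalParseError(InvalidArgumentError):
    """Malformed signal file (carries the offending line number)."""


def write_signal(path: str | Path, signal: SampledSignal) -> None:
    """Write a trace; ``.npz`` suffix selects the bit-exact binary form."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            samples=signal.samples,
            sampling_rate=np.float64(signal.sampling_rate),
            start_time=np.float64(signal.start_time),
        )
        return
    with open(path, "w") as fh:
        fh.write(f"{_RATE_KEY}{signal.sampling_rate!r}\n")
        fh.write(f"{_START_KEY}{signal.start_time!r}\n")
        for t, v in zip(signal.times, signal.samples):
            fh.write(f"{t:.12g}\t{v:.12g}\n")


def read_signal(path: str | Path) -> SampledSignal:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return SampledSignal(
                data["samples"],
                float(data["sampling_rate"]),
                float(data["start_time"]),
            )
    rate = None
    start = 0.0
    values = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(_RATE_KEY.strip("=").split("=")[0]) and "=" in line:
                key, _, val = line.partition("=")
                try:
                    parsed = float(val)
                except ValueError as exc:
                    raise SignalParseError(
                        f"{path}:{lineno}: bad header value {val!r}"
                    ) from exc
                if key + "=" == _RATE_KEY:
                    rate = parsed
                elif key + "=" == _START_KEY:
                    start = parsed
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise SignalParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                values.append(float(parts[1]))
            except ValueError as exc:
                raise SignalParseError(f"{path}:{lineno}: non-numeric sample") from exc
            if not np.isfinite(values[-1]):
                raise SignalParseError(f"{path}:{lineno}: non-finite sample")
    if rate is None:
        raise SignalParseError(f"{path}: missing '{_RATE_KEY}' header")
    if not values:
        raise SignalParseError(f"{path}: no samples")
    return SampledSignal(np.array(values), rate, start)


def write_points(path: str | Path, points: np.ndarray) -> None:
    """3-column delimited text (x_mm, y_mm, z_mm)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    np.savetxt(path, pts, fmt="%.12g", delimiter="\t",
               header="x_mm\ty_mm\tz_mm")


def read_points(path: str | Path) -> np.ndarray:
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise SignalParseError(
                    f"{path}:{lineno}: expected 3 columns (x y z), got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise SignalParseError(f"{path}:{lineno}: non-numeric coordinate") from exc
    if not rows:
        raise SignalParseError(f"{path}: no points")
    return np.array(rows)


def write_json_report(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
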