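"""Dynamic-acquisition framing and radioactive-decay correction.

A dynamic PET acquisition is binned into contiguous time frames, usually
specified compactly as groups ``(count, duration)``; the protocol modelled
here uses 22 frames (8 x 5, 3 x 10, 4 x 15, 6 x 30, 1 x 60 s; 370 s total).
Frame values everywhere in this package are *frame averages* of the
underlying instantaneous activity concentration, which is what a
reconstruction integrates over the frame.

Decay correction rescales the measured (physically decaying) activity to a
common reference time, by convention the scan start t = 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Physical half-life of oxygen-15 in seconds.
O15_HALF_LIFE_S = 122.24

__all__ = [
    "O15_HALF_LIFE_S",
    "FramingScheme",
    "DecaySpec",
    "build_framing",
    "decay_correction_factor",
    "protocol_framing",
]


@dataclass(frozen=True)
class FramingScheme:
    """Ordered contiguous time frames of a dynamic acquisition.

    Parameters
    ----------
    groups
        Sequence of ``(count, duration_s)`` pairs; ``count`` frames of
        ``duration_s`` seconds each, in acquisition order starting at t = 0.
    """

    groups: tuple[tuple[int, float], ...]
    starts_s: np.ndarray = field(init=False, repr=False, compare=False)
    durations_s: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("framing needs at least one (count, duration) group")
        durations = []
        for count, dur in self.groups:
            if int(count) != count or count < 1:
                raise ValueError(f"frame count must be a positive integer, got {count!r}")
            if not (dur > 0):
                raise ValueError(f"frame duration must be positive, got {dur!r}")
            durations.extend([float(dur)] * int(count))
        durations_arr = np.asarray(durations)
        starts = np.concatenate([[0.0], np.cumsum(durations_arr)[:-1]])
        object.__setattr__(self, "groups", tuple((int(c), float(d)) for c, d in self.groups))
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "durations_s", durations_arr)

    @property
    def n_frames(self) -> int:
        return len(self.durations_s)

    @property
    def total_duration_s(self) -> float:
        return float(self.starts_s[-1] + self.durations_s[-1])

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s / 2.0

    @property
    def ends_s(self) -> np.ndarray:
        return self.starts_s + self.durations_s

    def frame(self, index: int) -> tuple[float, float]:
        """Return ``(start_s, duration_s)`` of frame ``index`` (0-based)."""
        return float(self.starts_s[index]), float(self.durations_s[index])

    # -- JSON sidecar -----------------------------------------------------
    def to_sidecar(
        self,
        path: str | Path,
        *,
        decay_corrected: bool = True,
        half_life_s: float = O15_HALF_LIFE_S,
    ) -> None:
        """Write the JSON framing sidecar stored next to a 4D image."""
        payload = {
            "frame_starts_s": [float(s) for s in self.starts_s],
            "frame_durations_s": [float(d) for d in self.durations_s],
            "decay_corrected": bool(decay_corrected),
            "half_life_s": float(half_life_s),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_sidecar(cls, path: str | Path) -> "FramingScheme":
        payload = json.loads(Path(path).read_text())
        starts = np.asarray(payload["frame_starts_s"], dtype=float)
        durations = np.asarray(payload["frame_durations_s"], dtype=float)
        if starts[0] != 0.0 or not np.allclose(starts[1:], (starts + durations)[:-1]):
            raise ValueError("sidecar frames are not contiguous from t = 0")
        # Re-group identical consecutive durations for a faithful round trip.
        groups: list[tuple[int, float]] = []
        for d in durations:
            if groups and groups[-1][1] == d:
                groups[-1] = (groups[-1][0] + 1, d)
            else:
                groups.append((1, float(d)))
        return cls(groups=tuple(groups))


def build_framing(groups) -> FramingScheme:
    """Expand ``(count, duration_s)`` groups into a :class:`FramingScheme`.

    Examples
    --------
    >>> fs = build_framing([(8, 5), (3, 10), (4, 15), (6, 30), (1, 60)])
    >>> fs.n_frames, fs.total_duration_s
    (22, 370.0)
    """
    return FramingScheme(groups=tuple((c, d) for c, d in groups))


def protocol_framing() -> FramingScheme:
    """The 22-frame protocol framing: 8x5, 3x10, 4x15, 6x30, 1x60 s (370 s)."""
    return build_framing([(8, 5), (3, 10), (4, 15), (6, 30), (1, 60)])


@dataclass(frozen=True)
class DecaySpec:
    """Radioactive decay of the tracer and the correction reference time.

    ``reference_time_s`` is the time to which activities are decay-corrected;
    the convention here is injection = scan start = 0 s.
    """

    half_life_s: float = O15_HALF_LIFE_S
    reference_time_s: float = 0.0

    def __post_init__(self) -> None:
        if not (self.half_life_s > 0):
            raise ValueError("half_life_s must be positive")

    @property
    def lambda_per_s(self) -> float:
        return math.log(2.0) / self.half_life_s


def decay_correction_factor(frame: tuple[float, float], spec: DecaySpec) -> float:
    """Decay-correction factor for a frame-averaged measurement.

    For a frame starting at ``t0`` with duration ``dt`` the measured
    frame average of a decaying activity is multiplied by

        F = exp(lambda * (t0 - t_ref)) * lambda*dt / (1 - exp(-lambda*dt))

    to obtain the frame average of the decay-corrected activity. Exact for
    activity that is constant over the frame; the standard frame-wise
    correction otherwise.
    """
    t0, dt = frame
    if not (dt > 0):
        raise ValueError("frame duration must be positive")
    lam = spec.lambda_per_s
    x = lam * dt
    if x < 1e-12:  # lambda -> 0 limit
        return float(math.exp(lam * (t0 - spec.reference_time_s)))
    return float(math.exp(lam * (t0 - spec.reference_time_s)) * x / -math.expm1(-x))


def decay_correction_factors(framing: FramingScheme, spec: DecaySpec) -> np.ndarray:
    """Vector of per-frame decay-correction factors."""
    return np.array(
        [decay_correction_factor(framing.frame(i), spec) for i in range(framing.n_frames)]
    )
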