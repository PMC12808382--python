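"""Time-activity curves: extraction from a dynamic image and CSV I/O.

A time-activity curve (TAC) is the unweighted mean tracer concentration
over a volume of interest, per frame. The mean (an intensive, per-unit-
volume quantity) is the right reduction for kinetic modelling: the influx
constant K1 has units of mL blood per cm^3 *tissue* per minute and must
not depend on how large the VOI is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TimeActivityCurve", "extract_tac"]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame mean concentration with frame timing.

    Attributes
    ----------
    mid_times_s, durations_s : arrays, one entry per frame
    values : mean concentration per frame, kBq/mL
    role : ``"input"`` (arterial input function) or ``"tissue"``
    volume_mL : volume of the source VOI, if any
    """

    mid_times_s: np.ndarray
    durations_s: np.ndarray
    values: np.ndarray
    role: str = "tissue"
    volume_mL: float | None = None

    def __post_init__(self) -> None:
        mids = np.asarray(self.mid_times_s, dtype=float)
        durs = np.asarray(self.durations_s, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if not (len(mids) == len(durs) == len(vals)):
            raise ValueError("mid_times_s, durations_s and values must have equal length")
        if len(mids) and np.any(np.diff(mids) <= 0):
            raise ValueError("mid_times_s must be strictly increasing")
        if self.role not in ("input", "tissue"):
            raise ValueError(f"role must be 'input' or 'tissue', got {self.role!r}")
        object.__setattr__(self, "mid_times_s", mids)
        object.__setattr__(self, "durations_s", durs)
        object.__setattr__(self, "values", vals)

    @property
    def n_frames(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "frame_index": np.arange(self.n_frames),
                "mid_time_s": self.mid_times_s,
                "duration_s": self.durations_s,
                "concentration_kBq_per_mL": self.values,
                "role": self.role,
                "volume_mL": np.nan if self.volume_mL is None else self.volume_mL,
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeActivityCurve":
        df = pd.read_csv(path).sort_values("frame_index")
        vol = df["volume_mL"].iloc[0]
        return cls(
            mid_times_s=df["mid_time_s"].to_numpy(),
            durations_s=df["duration_s"].to_numpy(),
            values=df["concentration_kBq_per_mL"].to_numpy(),
            role=str(df["role"].iloc[0]),
            volume_mL=None if pd.isna(vol) else float(vol),
        )


def extract_tac(dyn, mask, role: str = "tissue") -> TimeActivityCurve:
    """Mean concentration over ``mask`` per frame of a dynamic image.

    Parameters
    ----------
    dyn : DynamicImage
    mask : VOIMask or boolean array on the same grid
    """
    mask_arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if mask_arr.shape != dyn.data.shape[:3]:
        raise ValueError(
            f"mask shape {mask_arr.shape} does not match image grid {dyn.data.shape[:3]}"
        )
    n = int(mask_arr.sum())
    if n == 0:
        raise ValueError("mask is empty")
    values = dyn.data[mask_arr].mean(axis=0)
    volume = getattr(mask, "volume_mL", None)
    if volume is None:
        volume = n * float(np.prod(dyn.voxel_size_mm)) / 1000.0
    return TimeActivityCurve(
        mid_times_s=dyn.framing.mid_times_s,
        durations_s=dyn.framing.durations_s,
        values=np.asarray(values, dtype=float),
        role=role,
        volume_mL=float(volume),
    )
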