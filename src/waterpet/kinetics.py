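"""One-tissue compartment model (1TCM) fitting for [15O]H2O perfusion.

The model: tissue concentration is the arterial input convolved with a
single exponential,

    C_T(t) = K1 * C_a(t - delta) (x) exp(-k2 t),

with influx K1 (perfusion, since water is freely diffusible), efflux k2,
and a blood delay delta between the artery used for the input function and
the tissue. The blood volume fraction is fixed at zero: with the high
extraction of water in muscle it is not separately identifiable and is
conventionally omitted.

Fitting uses the basis-function method: for each candidate (delay, k2) the
convolution basis B(t) = C_a(t - delta) (x) exp(-k2 t) is precomputed, and
the optimal K1 >= 0 is the closed-form weighted linear least-squares
coefficient. The best grid triple may then be polished by a continuous
(K1, k2) optimizer at the chosen delay. Weights default to frame durations
(longer frames collect more counts, hence are more precise).

K1 is reported in mL/100 cm^3/min, the conventional display scale for
muscle perfusion; k2 in 1/min; delay in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .framing import FramingScheme
from .tac import TimeActivityCurve

__all__ = [
    "FitConfig",
    "KineticResult",
    "fit_1tcm",
    "convolve_exp",
    "convert_k1_units",
]


def convert_k1_units(k1_mL_per_cm3_min: float) -> float:
    """Convert K1 from mL/cm^3/min to the display unit mL/100 cm^3/min."""
    if np.any(np.asarray(k1_mL_per_cm3_min) < 0):
        raise ValueError("K1 must be non-negative")
    return 100.0 * k1_mL_per_cm3_min


def _exp_conv_uniform(values: np.ndarray, k_per_s: float, h: float) -> np.ndarray:
    """Convolve a piecewise-linear signal on a uniform grid with exp(-k t).

    Returns y(t_i) = int_0^{t_i} f(s) exp(-k (t_i - s)) ds, exact for f
    piecewise linear between grid points (spacing ``h`` seconds).
    """
    if k_per_s < 0:
        raise ValueError("decay rate must be non-negative")
    x = k_per_s * h
    if x < 1e-8:
        # series to avoid catastrophic cancellation as k -> 0 (trapezoid limit)
        g1 = h * (1.0 - x / 2.0 + x * x / 6.0)
        g2 = (h / 2.0) * (1.0 - x / 3.0 + x * x / 12.0)
    else:
        one_minus_e = -math.expm1(-x)
        e = math.exp(-x)
        g1 = one_minus_e / k_per_s
        g2 = (h * one_minus_e / k_per_s - (one_minus_e - x * e) / (k_per_s * k_per_s)) / h
    # y[n] = e^{-x} y[n-1] + c0 f[n-1] + c1 f[n]
    c0 = g1 - g2
    c1 = g2
    decay = math.exp(-x) if x >= 1e-8 else math.exp(-x)
    inc = np.empty_like(values)
    inc[0] = 0.0
    inc[1:] = c0 * values[:-1] + c1 * values[1:]
    return signal.lfilter([1.0], [1.0, -decay], inc)


def _frame_average_from_fine(
    y_fine: np.ndarray,
    h: float,
    framing: FramingScheme,
    shift_s: float = 0.0,
) -> np.ndarray:
    """Frame averages of a fine-grid curve, optionally right-shifted in time.

    A right shift by ``shift_s`` means evaluating y(t - shift); y is taken
    as zero for t < 0.
    """
    # cumulative trapezoid integral with Y[0] = 0
    Y = np.concatenate([[0.0], np.cumsum((y_fine[1:] + y_fine[:-1]) * (h / 2.0))])
    t_fine = np.arange(len(Y)) * h
    lo = np.interp(framing.starts_s - shift_s, t_fine, Y)
    hi = np.interp(framing.ends_s - shift_s, t_fine, Y)
    return (hi - lo) / framing.durations_s


def _input_on_fine_grid(
    input_fn: TimeActivityCurve, end_s: float, h: float
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear interpolation of the input TAC onto a uniform grid.

    Before the first mid-time the input ramps linearly from zero at t = 0
    (the tracer has not arrived yet); after the last mid-time it is held at
    the last value.
    """
    n = int(round(end_s / h)) + 1
    t = np.arange(n) * h
    mids = input_fn.mid_times_s
    vals = input_fn.values
    if mids[0] > 0:
        mids = np.concatenate([[0.0], mids])
        vals = np.concatenate([[0.0], vals])
    return t, np.interp(t, mids, vals)


def convolve_exp(
    input_fn: TimeActivityCurve,
    k2_per_min: float,
    fine_step_s: float = 0.05,
    framing: FramingScheme | None = None,
) -> np.ndarray:
    """Convolve an input curve with exp(-k2 t), returned as frame averages.

    The input is interpolated piecewise-linearly onto a fine uniform grid,
    each linear segment is convolved analytically with the exponential, and
    the result is resampled as frame averages over ``framing`` (defaulting
    to the input's own frames).

    Returns the frame-averaged values of
    ``int_0^t C_a(s) exp(-k2 (t - s)) ds`` in (kBq/mL)*s.
    """
    if not (fine_step_s > 0):
        raise ValueError("fine_step_s must be positive")
    if framing is None:
        starts = input_fn.mid_times_s - input_fn.durations_s / 2.0
        groups = [(1, float(d)) for d in input_fn.durations_s]
        if abs(starts[0]) > 1e-9:
            raise ValueError("input frames must start at t = 0 when no framing is given")
        framing = FramingScheme(groups=tuple(groups))
    end = framing.total_duration_s
    _, fine = _input_on_fine_grid(input_fn, end, fine_step_s)
    y = _exp_conv_uniform(fine, k2_per_min / 60.0, fine_step_s)
    return _frame_average_from_fine(y, fine_step_s, framing)


@dataclass(frozen=True)
class FitConfig:
    """Settings of the basis-function 1TCM fit.

    delay grid in seconds; k2 basis grid log-spaced in 1/min. Frame-duration
    weighting is the default (uniform available for sensitivity analysis).
    """

    delay_min_s: float = 0.0
    delay_max_s: float = 15.0
    delay_step_s: float = 0.5
    k2_min_per_min: float = 0.01
    k2_max_per_min: float = 3.0
    n_k2: int = 64
    weighting: str = "frame-duration"
    fine_step_s: float = 0.05
    polish: bool = True

    def __post_init__(self) -> None:
        if not (self.delay_step_s > 0 and self.fine_step_s > 0):
            raise ValueError("grid steps must be positive")
        if self.delay_max_s < self.delay_min_s:
            raise ValueError("empty delay grid")
        if not (0 < self.k2_min_per_min < self.k2_max_per_min) or self.n_k2 < 1:
            raise ValueError("invalid k2 grid")
        if self.weighting not in ("frame-duration", "uniform"):
            raise ValueError("weighting must be 'frame-duration' or 'uniform'")

    @property
    def delay_grid_s(self) -> np.ndarray:
        n = int(round((self.delay_max_s - self.delay_min_s) / self.delay_step_s)) + 1
        return self.delay_min_s + self.delay_step_s * np.arange(n)

    @property
    def k2_grid_per_min(self) -> np.ndarray:
        return np.geomspace(self.k2_min_per_min, self.k2_max_per_min, self.n_k2)


@dataclass(frozen=True)
class KineticResult:
    """Fitted 1TCM parameters for one (tissue TAC, input function) pair.

    ``k1`` is in mL/100 cm^3/min (display units), ``k2`` in 1/min,
    ``delay_s`` in seconds. ``wrss`` is the weighted residual sum of
    squares at the optimum; ``model_values`` the fitted frame-averaged
    model curve.
    """

    k1: float
    k2_per_min: float
    delay_s: float
    wrss: float
    model_values: np.ndarray = field(repr=False)
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "k1_mL_per_100cm3_min": self.k1,
            "k2_per_min": self.k2_per_min,
            "delay_s": self.delay_s,
            "wrss": self.wrss,
            "converged": self.converged,
            "model_values_kBq_per_mL": [float(v) for v in self.model_values],
        }


def _weights(framing_durations: np.ndarray, scheme: str) -> np.ndarray:
    if scheme == "uniform":
        w = np.ones_like(framing_durations)
    else:
        w = framing_durations.astype(float)
    return w / w.sum()


def fit_1tcm(
    tissue: TimeActivityCurve,
    input_fn: TimeActivityCurve,
    cfg: FitConfig | None = None,
) -> KineticResult:
    """Fit the 1TCM with delay to a tissue TAC given an input function.

    Grid-searches delay and k2 (basis-function method, closed-form K1 >= 0
    per basis), then optionally polishes (K1, k2) continuously at the best
    delay. Returns K1 in mL/100 cm^3/min.
    """
    cfg = cfg or FitConfig()
    if tissue.n_frames != input_fn.n_frames or not np.allclose(
        tissue.mid_times_s, input_fn.mid_times_s
    ):
        raise ValueError("tissue and input curves must share the framing")
    if not np.any(input_fn.values > 0):
        raise ValueError("degenerate input: input function has no positive values")

    starts = tissue.mid_times_s - tissue.durations_s / 2.0
    framing = FramingScheme(groups=tuple((1, float(d)) for d in tissue.durations_s))
    if abs(starts[0]) > 1e-9:
        raise ValueError("non-overlapping time supports: tissue frames must start at t = 0")

    h = cfg.fine_step_s
    end = framing.total_duration_s
    _, fine_input = _input_on_fine_grid(input_fn, end, h)
    w = _weights(tissue.durations_s, cfg.weighting)
    ct = tissue.values
    sst = float(np.sum(w * ct * ct))

    delays = cfg.delay_grid_s
    k2s = cfg.k2_grid_per_min

    best = None  # (wrss, k1_per_s, k2_per_min, delay, model)
    for k2 in k2s:
        y_fine = _exp_conv_uniform(fine_input, k2 / 60.0, h)
        for delay in delays:
            basis = _frame_average_from_fine(y_fine, h, framing, shift_s=delay)
            denom = float(np.sum(w * basis * basis))
            if denom <= 0:
                k1_per_s = 0.0
            else:
                k1_per_s = max(0.0, float(np.sum(w * basis * ct)) / denom)
            resid = ct - k1_per_s * basis
            wrss = float(np.sum(w * resid * resid))
            if best is None or wrss < best[0]:
                best = (wrss, k1_per_s, float(k2), float(delay), k1_per_s * basis)

    wrss, k1_per_s, k2_best, delay_best, model = best
    converged = True

    if cfg.polish and sst > 0:
        sw = np.sqrt(w)

        def residuals(params):
            k1_s, k2_pm = params
            y = _exp_conv_uniform(fine_input, k2_pm / 60.0, h)
            b = _frame_average_from_fine(y, h, framing, shift_s=delay_best)
            return sw * (ct - k1_s * b)

        try:
            sol = optimize.least_squares(
                residuals,
                x0=[max(k1_per_s, 1e-12), k2_best],
                bounds=([0.0, cfg.k2_min_per_min * 1e-3], [np.inf, cfg.k2_max_per_min * 1e3]),
                xtol=1e-12,
                ftol=1e-12,
            )
            wrss_polished = float(np.sum(sol.fun**2))
            if sol.success and wrss_polished <= wrss:
                k1_per_s, k2_best = float(sol.x[0]), float(sol.x[1])
                wrss = wrss_polished
                y = _exp_conv_uniform(fine_input, k2_best / 60.0, h)
                model = k1_per_s * _frame_average_from_fine(y, h, framing, shift_s=delay_best)
            converged = bool(sol.success)
        except Exception:
            converged = False

    # k1_per_s carries units 1/s (per second of the convolution integral);
    # convert to mL/cm^3/min then to display units mL/100 cm^3/min.
    k1_display = convert_k1_units(k1_per_s * 60.0)
    return KineticResult(
        k1=k1_display,
        k2_per_min=k2_best,
        delay_s=delay_best,
        wrss=wrss,
        model_values=np.asarray(model, dtype=float),
        converged=converged,
    )
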