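"""Synthetic dynamic-PET lower-leg phantom with known ground-truth kinetics.

The phantom stands in for a patient scan: parametric axial cylinders for
the tibia, fibula, muscle compartments and a feeding artery on a metric
voxel grid, a bolus-shaped arterial input (gamma variate plus a
recirculation plateau), tissue curves following the one-tissue compartment
model, the 22-frame protocol framing, oxygen-15 decay applied before
frame-wise decay correction, and Poisson noise on pseudo-counts
proportional to frame duration. Because every curve and parameter is
known, each downstream analysis stage can be verified exactly.

Anatomical realism of the shapes is deliberately not attempted: the
analysis consumes label volumes, so cylinders keep the geometry exact and
testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .framing import DecaySpec, FramingScheme, decay_correction_factors, protocol_framing
from .image import DynamicImage
from .kinetics import _exp_conv_uniform, _frame_average_from_fine

__all__ = [
    "Cylinder",
    "LegPhantomConfig",
    "AIFModel",
    "TissueKinetics",
    "NoiseModel",
    "SimulationTruth",
    "gamma_variate_aif",
    "forward_1tcm",
    "simulate_dynamic_scan",
    "default_kinetics",
    "PARTITION_COEFFICIENT_ML_PER_CM3",
]

#: Conventional blood/tissue partition coefficient of water in muscle
#: (mL/cm^3); used only to derive default k2 = K1 / p for the phantom.
PARTITION_COEFFICIENT_ML_PER_CM3 = 0.9

#: Integer ids used in the label volume.
LABEL_IDS = {"tibia": 1, "fibula": 2, "posterior": 3, "anterior": 4, "artery": 5}
BONE_LABELS = ("tibia", "fibula")


@dataclass(frozen=True)
class Cylinder:
    """Axial cylinder: in-plane center offset from the grid center, in mm."""

    center_xy_mm: tuple[float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if not (self.radius_mm > 0):
            raise ValueError("cylinder radius must be positive")


@dataclass(frozen=True)
class LegPhantomConfig:
    """Geometry of the synthetic lower leg.

    The default grid uses the protocol voxel size 1.65 x 1.65 x 1.5 mm and
    spans the lower leg from the medial malleolus (z = 0) past the knee
    joint space, with the arterial bifurcation landmark near the top so
    the input-function start plane (3 cm distal to it) lies in-volume.
    """

    shape: tuple[int, int, int] = (64, 64, 272)
    voxel_size_mm: tuple[float, float, float] = (1.65, 1.65, 1.5)
    cylinders: dict = field(
        default_factory=lambda: {
            "tibia": Cylinder((-14.0, -14.0), 11.0),
            "fibula": Cylinder((20.0, -10.0), 6.0),
            "posterior": Cylinder((2.0, 20.0), 22.0),
            "anterior": Cylinder((0.0, -34.0), 10.0),
            "artery": Cylinder((-16.0, 40.0), 3.0),
        }
    )
    malleolus_z_mm: float = 0.0
    knee_z_mm: float = 380.0
    artery_bifurcation_z_mm: float = 395.0

    def __post_init__(self) -> None:
        if not (self.malleolus_z_mm < self.knee_z_mm):
            raise ValueError("malleolus must be distal to (below) the knee")

    def build_labels(self) -> np.ndarray:
        """Rasterize the cylinders into an integer label volume.

        Raises if any two structures overlap (labels must be disjoint; in
        particular the artery may not intersect bone).
        """
        nx, ny, nz = self.shape
        dx, dy, _ = self.voxel_size_mm
        cx = (nx - 1) / 2.0 * dx
        cy = (ny - 1) / 2.0 * dy
        x = np.arange(nx) * dx - cx
        y = np.arange(ny) * dy - cy
        xx, yy = np.meshgrid(x, y, indexing="ij")
        labels = np.zeros(self.shape, dtype=np.uint8)
        for name, cyl in self.cylinders.items():
            if name not in LABEL_IDS:
                raise ValueError(f"unknown structure {name!r}")
            inplane = (xx - cyl.center_xy_mm[0]) ** 2 + (
                yy - cyl.center_xy_mm[1]
            ) ** 2 <= cyl.radius_mm**2
            if not inplane.any():
                raise ValueError(f"cylinder {name!r} lies outside the grid")
            region = np.repeat(inplane[:, :, None], nz, axis=2)
            if (labels[region] != 0).any():
                raise ValueError(f"structure {name!r} overlaps another label")
            labels[region] = LABEL_IDS[name]
        return labels


@dataclass(frozen=True)
class AIFModel:
    """Bolus-shaped arterial input: peak-normalized gamma variate plus a
    recirculation plateau.

    ``amplitude_kBq_mL`` is the first-pass peak height; ``t0_s`` the
    appearance time; ``alpha`` (shape) and ``beta_s`` (scale) set the bolus
    width, with the peak at t0 + alpha*beta; ``recirc_fraction`` the
    plateau level as a fraction of the peak, approached with time constant
    ``recirc_tau_s``.
    """

    amplitude_kBq_mL: float = 60.0
    t0_s: float = 12.0
    alpha: float = 2.5
    beta_s: float = 4.0
    recirc_fraction: float = 0.15
    recirc_tau_s: float = 40.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta_s <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0 <= self.recirc_fraction < 1):
            raise ValueError("recirculation fraction must lie in [0, 1)")
        if self.recirc_tau_s <= 0:
            raise ValueError("recirculation time constant must be positive")

    def __call__(self, t) -> np.ndarray:
        return gamma_variate_aif(self, t)


def gamma_variate_aif(model: AIFModel, t) -> np.ndarray:
    """Evaluate the arterial input model; zero for t <= t0.

    C_a(t) = A (1-r) ((t-t0)/(alpha beta))^alpha exp(alpha - (t-t0)/beta)
             + A r (1 - exp(-(t-t0)/tau))
    """
    t = np.asarray(t, dtype=float)
    x = t - model.t0_s
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    a, b = model.alpha, model.beta_s
    gamma = (xp / (a * b)) ** a * np.exp(a - xp / b)
    plateau = 1.0 - np.exp(-xp / model.recirc_tau_s)
    out[pos] = model.amplitude_kBq_mL * (
        (1.0 - model.recirc_fraction) * gamma + model.recirc_fraction * plateau
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TissueKinetics:
    """Ground-truth 1TCM parameters of one tissue label.

    ``k1`` in the display unit mL/100 cm^3/min; ``k2_per_min`` in 1/min;
    ``delay_s`` the arterial-to-tissue blood delay in seconds.
    """

    k1: float
    k2_per_min: float
    delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError("K1 must be non-negative")
        if not (self.k2_per_min > 0):
            raise ValueError("k2 must be positive")
        if self.delay_s < 0:
            raise ValueError("delay must be non-negative")


def default_kinetics(k1: float, delay_s: float = 4.0) -> TissueKinetics:
    """Kinetics with k2 tied to K1 via the water partition coefficient."""
    k2 = (k1 / 100.0) / PARTITION_COEFFICIENT_ML_PER_CM3  # 1/min
    return TissueKinetics(k1=k1, k2_per_min=k2, delay_s=delay_s)


@dataclass(frozen=True)
class NoiseModel:
    """Poisson noise on pseudo-counts.

    Expected counts per voxel and frame are kappa * C * dt * V with C the
    (decayed) concentration in kBq/mL, dt the frame duration in s and V
    the voxel volume in mL; kappa = 0 gives exactly noiseless output.
    """

    kappa: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


def forward_1tcm(
    k1: float,
    k2_per_min: float,
    delay_s: float,
    aif,
    times_s,
    fine_step_s: float = 0.01,
) -> np.ndarray:
    """Tissue concentration of the 1TCM at the requested time points.

    C_T(t) = K1 int_0^t C_a(s - delay) exp(-k2 (t - s)) ds, with ``k1`` in
    mL/100 cm^3/min and ``aif`` a callable returning kBq/mL.
    """
    times = np.asarray(times_s, dtype=float)
    if times.ndim and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if not (k2_per_min > 0):
        raise ValueError("k2 must be positive")
    end = float(np.max(times))
    n = int(math.ceil(end / fine_step_s)) + 1
    t_fine = np.arange(n + 1) * fine_step_s
    ca = np.asarray(aif(t_fine - delay_s), dtype=float)
    conv = _exp_conv_uniform(ca, k2_per_min / 60.0, fine_step_s)
    k1_per_s = k1 / 100.0 / 60.0
    return np.interp(times, t_fine, k1_per_s * conv)


def _frame_average(fine_values: np.ndarray, fine_step_s: float, framing: FramingScheme):
    return _frame_average_from_fine(fine_values, fine_step_s, framing)


def kappa_for_frame_cv(
    target_cv: float, values: np.ndarray, framing: FramingScheme, volume_mL: float
) -> float:
    """Pseudo-count scale giving the requested Poisson CV on a TAC.

    The CV of a frame value under the pseudo-count model is
    1 / sqrt(kappa * C * dt * V); kappa is set so the frame with the
    highest concentration has CV ``target_cv``.
    """
    if not (0 < target_cv):
        raise ValueError("target CV must be positive")
    values = np.asarray(values, dtype=float)
    j = int(np.argmax(values))
    ref = values[j] * framing.durations_s[j] * volume_mL
    if ref <= 0:
        raise ValueError("curve has no positive frame to calibrate on")
    return 1.0 / (target_cv**2 * ref)


def poisson_noisy_tac(
    values: np.ndarray,
    framing: FramingScheme,
    kappa: float,
    volume_mL: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson pseudo-count noise applied to a VOI-mean curve.

    Counts pooled over the whole VOI volume are drawn with expectation
    kappa * C * dt * V per frame and converted back to concentration —
    the curve-level equivalent of voxelwise simulation noise followed by
    VOI averaging.
    """
    values = np.asarray(values, dtype=float)
    lam = kappa * values * framing.durations_s * volume_mL
    return rng.poisson(lam) / (kappa * framing.durations_s * volume_mL)


@dataclass
class SimulationTruth:
    """Ground truth returned beside a simulated scan.

    ``tac_ideal`` holds the frame-averaged decay-free curve per label;
    ``tac_image`` the expected voxel value in the output image (after
    decay and, if enabled, frame-wise decay correction). They differ only
    by the small within-frame mismatch between exact decay and the
    constant-activity correction factor.
    """

    labels: np.ndarray
    aif: AIFModel
    kinetics: dict
    tac_ideal: dict
    tac_image: dict
    framing: FramingScheme
    voxel_size_mm: tuple[float, float, float]
    seed: int | None


def simulate_dynamic_scan(
    phantom: LegPhantomConfig | None = None,
    aif: AIFModel | None = None,
    kinetics: dict | None = None,
    framing: FramingScheme | None = None,
    decay: DecaySpec | None = None,
    noise: NoiseModel | None = None,
    *,
    apply_decay: bool = True,
    decay_correct: bool = True,
    fine_step_s: float = 0.02,
    dtype=np.float64,
) -> tuple[DynamicImage, SimulationTruth]:
    """Simulate a dynamic lower-leg scan with known kinetics.

    Artery voxels carry the frame-averaged arterial input; each tissue
    label carries its forward-model curve. Frames hold frame-averaged
    decayed concentrations with Poisson pseudo-count noise, converted back
    to concentration and decay-corrected if requested. Identical seeds
    give bit-identical output.
    """
    phantom = phantom or LegPhantomConfig()
    aif = aif or AIFModel()
    if kinetics is None:
        kinetics = {"posterior": default_kinetics(3.0), "anterior": default_kinetics(2.2)}
    framing = framing or protocol_framing()
    decay = decay or DecaySpec()
    noise = noise or NoiseModel(kappa=0.0)

    labels = phantom.build_labels()
    present = {name for name, lid in LABEL_IDS.items() if (labels == lid).any()}
    for name in kinetics:
        if name not in present:
            raise ValueError(f"kinetics given for label {name!r} absent from the phantom")
    if "artery" not in present:
        raise ValueError("phantom has no artery to carry the input function")

    end = framing.total_duration_s
    n_fine = int(math.ceil(end / fine_step_s))
    t_fine = np.arange(n_fine + 1) * fine_step_s

    fine_curves = {"artery": np.asarray(aif(t_fine), dtype=float)}
    for name, kin in kinetics.items():
        ca = np.asarray(aif(t_fine - kin.delay_s), dtype=float)
        conv = _exp_conv_uniform(ca, kin.k2_per_min / 60.0, fine_step_s)
        fine_curves[name] = (kin.k1 / 100.0 / 60.0) * conv

    decay_fine = np.exp(-decay.lambda_per_s * t_fine) if apply_decay else 1.0
    factors = decay_correction_factors(framing, decay) if (apply_decay and decay_correct) else None

    tac_ideal, tac_measured, tac_image = {}, {}, {}
    for name, fine in fine_curves.items():
        ideal = _frame_average(fine, fine_step_s, framing)
        measured = _frame_average(fine * decay_fine, fine_step_s, framing) if apply_decay else ideal
        tac_ideal[name] = ideal
        tac_measured[name] = measured
        tac_image[name] = measured * factors if factors is not None else measured

    data = np.zeros((*phantom.shape, framing.n_frames), dtype=dtype)
    rng = np.random.default_rng(noise.seed)
    vox_mL = float(np.prod(phantom.voxel_size_mm)) / 1000.0
    durations = framing.durations_s
    for name in fine_curves:
        mask = labels == LABEL_IDS[name]
        n_vox = int(mask.sum())
        if noise.kappa > 0:
            lam = noise.kappa * tac_measured[name] * durations * vox_mL  # (n_frames,)
            counts = rng.poisson(np.broadcast_to(lam, (n_vox, framing.n_frames)))
            conc = counts / (noise.kappa * durations * vox_mL)
            if factors is not None:
                conc = conc * factors
            data[mask] = conc
        else:
            data[mask] = tac_image[name]

    dyn = DynamicImage(
        data=data,
        voxel_size_mm=phantom.voxel_size_mm,
        framing=framing,
        decay_corrected=not apply_decay or decay_correct,
        half_life_s=decay.half_life_s,
        meta={"seed": noise.seed, "kappa": noise.kappa},
    )
    truth = SimulationTruth(
        labels=labels,
        aif=aif,
        kinetics=dict(kinetics),
        tac_ideal=tac_ideal,
        tac_image=tac_image,
        framing=framing,
        voxel_size_mm=phantom.voxel_size_mm,
        seed=noise.seed,
    )
    return dyn, truth
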