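# waterpet

Quantification of skeletal-muscle perfusion from dynamic [¹⁵O]H₂O PET of the
lower leg, with a synthetic digital phantom that makes every stage of the
analysis verifiable against known ground truth.

[¹⁵O]H₂O is a freely diffusible, metabolically inert perfusion tracer: in the
one-tissue compartment model (1TCM)

```
C_T(t) = K1 · C_a(t − Δ) ⊗ e^(−k2·t)
```

the influx rate constant K1 (mL blood · cm⁻³ tissue · min⁻¹, reported per
100 cm³) *is* tissue perfusion. `C_a` is the arterial input function, read
from the image itself (an IDIF from the superficial femoral artery), `k2` the
washout rate, and Δ the blood delay between artery and muscle. The blood
volume fraction is fixed at zero, appropriate for the high extraction of
water in muscle.

The package is aimed at researchers evaluating calf-muscle perfusion
protocols — e.g. for peripheral arterial occlusive disease — who need a
tested, reproducible implementation of:

* **framing & decay** — the 22-frame dynamic protocol (8×5, 3×10, 4×15,
  6×30, 1×60 s; 370 s) and frame-averaged ¹⁵O decay correction;
* **synthetic phantom** — a parametric lower-leg (bones, muscle
  compartments, feeding artery) on a 1.65×1.65×1.5 mm grid, gamma-variate
  bolus input, 1TCM tissue curves, Poisson pseudo-count noise;
* **IDIF extraction** — four highest-intensity voxels per plane over ten
  consecutive planes, starting 3 cm distal to the common femoral
  bifurcation, fixed at the first-pass peak frame;
* **VOI construction** — the posterior-compartment muscle contour in ten
  axial slices at 60% of the lower-leg length with a 20-mm bone exclusion
  zone, and the dual 7.5-mm-sphere VOI (3.5 mL);
* **kinetic fitting** — basis-function 1TCM fit with delay grid search and
  frame-duration weighting;
* **agreement statistics** — ICC(2,1) (two-way random effects, absolute
  agreement, single measures) with F-based CIs, Bland–Altman limits of
  agreement (±1.96 SD), and an in-silico two-rater × two-session
  reproducibility study.

## Worked example

Simulate a noisy leg scan with known kinetics, extract the IDIF and the
muscle-contour VOI, and fit the 1TCM:

```python
import numpy as np
import waterpet as wp
from waterpet.phantom import LABEL_IDS

phantom = wp.LegPhantomConfig()
dyn, truth = wp.simulate_dynamic_scan(
    phantom=phantom,
    kinetics={"posterior": wp.default_kinetics(3.0), "anterior": wp.default_kinetics(2.2)},
    noise=wp.NoiseModel(kappa=10.0, seed=42),
)

artery = wp.VOIMask(truth.labels == LABEL_IDS["artery"], dyn.voxel_size_mm, provenance="search")
start = wp.locate_start_plane(phantom.artery_bifurcation_z_mm, dyn.grid_shape, dyn.voxel_size_mm)
selection, idif = wp.extract_idif(dyn, artery, start_plane=start)

level = wp.lower_leg_level(phantom.malleolus_z_mm, phantom.knee_z_mm)
bone = np.isin(truth.labels, [LABEL_IDS["tibia"], LABEL_IDS["fibula"]])
zone = wp.bone_exclusion_zone(wp.VOIMask(bone, dyn.voxel_size_mm, provenance="label"))
contour = wp.muscle_contour_voi(truth.labels, dyn.voxel_size_mm, level, zone)

result = wp.fit_1tcm(wp.extract_tac(dyn, contour), idif)
```

which prints (via the obvious `print` statements):

```
IDIF: 40 voxels, peak frame 4 (20-25 s), peak 63.3 kBq/mL
contour VOI: 3600 voxels, 14.70 mL at the 60% level (228 mm)
K1 = 2.90 mL/100cm3/min, k2 = 0.0211/min, delay = 4.5 s  (truth: K1 = 3.00, k2 = 0.0333, delay = 4.0)
```

The fitted K1 sits within ~3% of the simulated truth under this noise
level; the delay lands within one 0.5-s grid step. (k2 of water in resting
muscle is small, so its relative error is larger — it barely shapes the
370-s curve.)

The same pipeline is available from the shell:

```sh
waterpet simulate --seed 42 --out sim/
waterpet extract-idif --dyn sim/dynamic.nii.gz --region artery.nii.gz --bifurcation-z 395 --out idif.csv
waterpet make-vois --labels sim/labels.nii.gz --malleolus-z 0 --knee-z 380 --out vois/
waterpet fit --tissue tac.csv --input idif.csv --out result.json
waterpet virtual-study --seed 1 --n-legs 10 --out report/
```

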