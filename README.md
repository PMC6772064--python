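# opmarray

Empirical-Bayes scoring and optimisation of magnetometer-array geometries
for MEG source reconstruction.

Optically pumped magnetometers (OPMs) can be placed directly on the scalp,
but unlike fixed cryogenic arrays their positions and orientations are not
known precisely a priori. This package implements a model-comparison
framework that treats the sensor geometry itself as part of the generative
model of the measured fields: every candidate geometry gets a forward model,
an empirical-Bayes source inversion and a variational free energy, so
geometries can be compared, systems can be characterised by how quickly
their evidence degrades under geometric error, and the pose of a rigid
array can be recovered from the field data alone — no fiducials, no scalp
digitisation, only the cortical geometry as spatial support.

It is intended for people simulating or designing wearable MEG arrays and
for methodologists studying co-registration-free source reconstruction.

## Model

Measured fields follow the general linear model `Y = LJ + ε` with
`Y ∈ R^(Nc×Nt)` the sensor data, `L` the lead field of a candidate geometry
(Sarvas conducting sphere or a corrected-sphere "single shell"), `J` the
cortical currents and white sensor noise `ε ~ N(0, λ₁I)`. The source prior
is the Empirical Bayes Beamformer (EBB) prior `J ~ N(0, λ₂ diag(Γ))` with
per-source beamformer power `Γ_d = 1 / (l_dᵀ C_Y⁻¹ l_d)`. Restricted
maximum likelihood (Fisher scoring on log hyperparameters) maximises the
free energy of the implied sensor covariance `C = λ₁I + λ₂ L diag(Γ) Lᵀ`:

    F = accuracy − complexity
      = −N/2 [tr(C_Y C⁻¹) + log|C|] − (Nc N/2) log 2π
        − ½(λ̂−ν)ᵀΠ(λ̂−ν) + ½ log|Σ_λ Π|

Free-energy differences are log evidence ratios: `ΔF = −3` marks a geometry
about `exp(3) ≈ 20` times less likely than the best one. A *perturbation
curve* scores the same data under increasingly wrong geometries; its
half-width at `ΔF = −3` quantifies how much geometric error a system can
hide. A Metropolis sampler over the rigid-array pose (acceptance
`min(1, exp(ΔF))`) turns the same score into a posterior over array
positions, and Bayesian model averaging combines the source estimates of
the sampled geometries with weights `∝ exp(F − max F)`.

## Worked example

Everything needed is generated synthetically: a spherical inner skull, a
cortex-like source surface 10 mm inside it (with a sulcus-like fold so the
simulated somatosensory dipole is tangential, as the real N20m generator
is), a 13-sensor scanner-cast-like patch 6.5 mm above the scalp, and a
single 10 nAm, 10 Hz dipole in 100 fT RMS white noise:

```python
import numpy as np
from opmarray import (standard_setup, score_geometry, perturb_orientations,
                      perturbation_curve, width_at_threshold)

setup = standard_setup(seed=0)          # 13-channel OPM patch, 10 nAm @ 10 Hz
data, array = setup["data"], setup["array"]
sources, head = setup["sources"], setup["head"]

true_fit = score_geometry(data, array, sources, head)
wrong = perturb_orientations(array, 10.0, rng_seed=1)
wrong_fit = score_geometry(data, wrong, sources, head)
print(f"F(true geometry)      = {true_fit.F:10.2f} nats")
print(f"F(10 deg orient err)  = {wrong_fit.F:10.2f} nats")
print(f"log evidence ratio    = {true_fit.F - wrong_fit.F:10.2f}")

offsets = np.arange(-20.0, 20.1, 2.5)
curve = perturbation_curve(data, array, sources, head, "orientation",
                           offsets, n_repeats=30, rng_seed=1)
width = width_at_threshold(curve, delta_F=-3.0)
print(f"dF=-3 half-width      = {width.half_width:10.2f} degrees")
```

prints

```
F(true geometry)      =    5890.33 nats
F(10 deg orient err)  =    5871.11 nats
log evidence ratio    =      19.22
dF=-3 half-width      =       4.22 degrees
```

The true geometry beats the 10°-perturbed one by ~19 nats (an evidence
ratio of `e^19`), and on average the evidence drops below the 20-fold
rejection threshold once more than ~4° of orientation error is injected —
i.e. this simulated system's geometry is constrained by its own data to a
few degrees. `metropolis_pose_search` and `bma_sources` extend this to
recovering the array position (typically to well under a millimetre on
these simulations, with posterior confidence volumes thousands of times
smaller than a 4×4×4 cm³ prior box).

The inversion core follows the Model/Results pattern:
`EmpiricalBayesBeamformer(data, leadfield).fit()` returns an `EBBResults`
with `params` (λ̂), `cov_params` (posterior covariance of log λ),
`free_energy`, `accuracy`, `complexity`, `source_estimate()` and a
`summary()` table.

A CLI mirrors the library: `opmarray simulate|score|curve|search|bma
--config cfg.yaml --seed N --out DIR`.

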