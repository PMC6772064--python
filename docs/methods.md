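# Methods

This note documents the models, the synthetic-data generator and the
numerical decisions behind `opmarray`, in the spirit of a package manual:
what is computed, under which assumptions, and what the simulations can and
cannot show about real recordings.

## Generative model and inversion

Sensor data are modelled as `Y = LJ + ε` with Gaussian sensor noise
`ε ~ N(0, Q_ε)`, `Q_ε = λ₁ I` (homogeneous, independent channels) and a
Gaussian source prior `J ~ N(0, Q)`. Sources are current dipoles at fixed
cortical locations with fixed orientations (the surface normals), one
lead-field column per source; free-orientation (three-column) sources are
out of scope. The source prior is the Empirical Bayes Beamformer (EBB)
prior `Q = λ₂ diag(Γ)`, `Γ_d = 1/(l_dᵀ C_Y⁻¹ l_d)`, the per-source
beamformer power estimate, valid under the assumption of no zero-lag
correlated sources. `Γ` is rescaled to unit mean (the scale is absorbed by
`λ₂`; unit trace is available via `normalize="trace"`). The sample
covariance is `C_Y = Y Yᵀ / Nt` (a `normalizer="Nc"` switch exists; a
global scale shifts every F equally and cancels from all comparisons). By
default no diagonal loading is applied when inverting `C_Y` for the prior
(`regularization=0`); a fraction of `tr(C_Y)/Nc` can be added for
rank-deficient data.

The conditional source estimate is the posterior mean
`Ĵ = Q Lᵀ (Q_ε + L Q Lᵀ)⁻¹ Y`, computed with Cholesky solves rather than
explicit inverses.

### Hyperparameter optimisation

`(λ₁, λ₂)` are estimated by restricted maximum likelihood on
`η = log λ` (positivity by construction), maximising

    L(η) = −N/2 [tr(C_Y C(η)⁻¹) + log|C(η)|] − (Nc N/2) log 2π
           − ½(η−ν)ᵀ Π (η−ν),

with vague Gaussian priors on the log hyperparameters (`ν = 0`,
`Π = 10⁻⁶ I`). Updates are Fisher-scoring steps `Δη = H⁻¹ g` with the
expected information `H_ij = N/2 tr(C⁻¹ λᵢQᵢ C⁻¹ λⱼQⱼ) + Π_ij`, damped by
step-halving so the objective never decreases, steps clipped to ±8 log
units, at most 128 iterations. Convergence is declared when the objective
changes by less than 10⁻⁴ nats or the gradient is below 10⁻⁴ nats per log
unit; non-convergence returns the best iterate with a warning and a flag.
The hyperparameter posterior is the Laplace approximation
`Σ_η = H⁻¹` at the optimum. Initialisation splits the data power evenly
across components: `λᵢ = tr(C_Y) / (k · tr(Qᵢ))`.

### Free energy

    F = accuracy − complexity
    accuracy   = −N/2 [tr(C_Y C⁻¹) + log|C|] − (Nc N/2) log 2π
    complexity = ½(η̂−ν)ᵀΠ(η̂−ν) − ½ log|Σ_η Π|

Accuracy is the Gaussian log likelihood of the data under the implied
covariance (verified in the tests against a brute-force multivariate-normal
log density); complexity is the variational-Laplace Occam term, which is
non-negative whenever the posterior is tighter than the prior. All
experiments use F *differences*, so any fixed normalisation convention
cancels.

### Effective temporal degrees of freedom

Band-limited evoked data carry far fewer independent temporal observations
than raw samples, and the evidence should count observations, not samples:
with the raw `Nt = 1000` of the default protocol, free-energy differences
are dominated by the sampling fluctuations of `C_Y` (±tens of nats between
equivalent geometries) and the perturbation curves are meaningless.
Standard practice in this family of inversions projects the data onto a
small set of dominant temporal modes and passes that count to the ReML
objective. `EmpiricalBayesBeamformer` exposes this as `n_eff`
(default `min(Nt, 16)`; `None` uses the raw count). Hyperparameter
*estimates* are invariant to this scale — only the nats scale of F (and the
width of hyperparameter posteriors) depends on it. With the default cap,
one nat of free energy corresponds to one `e`-fold of evidence at 16
effective observations, and the `ΔF = −3` threshold sits at a sensible
rejection level for the simulated protocol.

## Forward models

**Sphere (Sarvas).** Closed-form external field of a current dipole in a
homogeneous conducting sphere. Radial dipole moments and sources at the
centre are externally silent; the implementation zeroes the `q × r₀` term
when the moment is numerically parallel to the source radius (relative sine
below 10⁻¹⁰) or the source sits within 1 nm of the centre, so these exact
silences are not polluted by floating-point cross-product noise. Sphere
parameters come from a least-squares geometric fit (algebraic Kåsa
initialisation, Levenberg–Marquardt refinement of `Σ(‖v−c‖−r)²`); a
`region` argument restricts the fit to a patch for local spheres (the
choice of patch is the caller's; there is no canonical anatomical default).

**Corrected-sphere single shell.** The Sarvas field of the sphere fitted to
the shell mesh, plus a curl-free correction `∇ψ`, where `ψ` is expanded in
exterior real solid harmonics `r^{−(l+1)} S_lm` (degrees 1..`sh_order`,
default 8) about the fitted centre. Coefficients are fitted per source by
least squares at the mesh face centres so that the *normal* component of
the total field on the shell equals that of the primary (infinite-medium)
dipole field — the boundary condition that the volume currents leave the
surface-normal field unchanged. The collocation matrix is factored once
per (head, array) pair (SVD with relative truncation at 10⁻¹⁰ and a
conditioning warning), so repeated lead fields during curves and searches
are cheap. On an exactly spherical shell the residual vanishes and the
model reduces to the sphere analytically (tested to 0.5%); on a ±5%
ellipsoid the order-6 and order-10 expansions agree to <1% for sources at
~60% of the shell radius. Basis gradients use central finite differences
(step 1 µm, relative truncation error ~10⁻¹⁰ at head scale). Convergence
degrades for sources close to the shell or for strongly aspherical
surfaces; `sh_order` is the dial.

Sensors are point magnetometers: one sample of the field along one axis,
scaled by a gain. Vapour-cell volume integration, cross-talk and
gradiometer baselines are not modelled.

## Geometry perturbations

* **Orientation error**: each sensor independently rotated by exactly the
  requested angle about one of the three head-frame axes (roll/pitch/yaw)
  chosen uniformly at random per sensor and model. A uniformly random
  rotation axis would be the natural alternative; the frame-axis convention
  is kept deliberately and documented.
* **Arc displacement**: the whole array rotated rigidly about an axis
  through the fitted head-sphere centre (default: the left–right axis,
  configurable) by `θ = arc / r̄`, `r̄` the mean sensor distance from the
  centre, so the stated offset is the mean arc length in mm. Rigidity
  (pairwise distances and relative orientations) is preserved to 10⁻¹².
* **Gain error**: each gain multiplied by an independent
  `Normal(1, p²)` draw — a symmetric model of un-modelled calibration and
  cross-talk error; `p ≥ 1` is rejected (sign flips are not modelled).

In `perturbation_curve`, gain-error draws are *paired across offsets*
(repeat r reuses the same gain realisation at every offset, orientation
draws stay fresh per model). Unpaired draws add independent per-offset
noise to the curve mean, which inflates the curve maximum (an extreme-value
effect over 17 offsets) and spuriously *narrows* the measured width;
pairing cancels the constant part of the gain penalty and exposes the
physical effect — gain error genuinely flattens the orientation dependence
and broadens the curve. Curves are reported relative to the maximum of the
per-offset mean; per-repeat values are retained for dispersion. Width at a
threshold interpolates the mean relative curve linearly on each side of the
argmax and flags sides that never reach the threshold as open-ended.

## Synthetic data

The generator replaces the unavailable subject anatomy with parametric
surfaces carrying the protocol's stated scalars: an 80 mm inner-skull
sphere, a source surface 10 mm interior, a scalp 10 mm exterior, 13 sensors
at 6.5 mm standoff above the scalp with ≥25 mm spacing in concentric rings
over the sensorimotor target, one 10 Hz sinusoidal dipole of 10 nAm at the
(scaled) somatosensory coordinate, 1 s at 1000 Hz, and white sensor noise
of 100 fT RMS per channel and sample (divided by √n_trials for averaged
trials, default single trial). Scoring uses a 2–80 Hz zero-phase
fourth-order Butterworth band-pass. MNI-like coordinates are mapped by a
linear rescale that puts the nominal cortical shell onto the model's source
surface.

Head kinds: `sphere` (concentric spheres; source normals radial — useful
for forward-model oracles but *externally silent* under a spherical
conductor, so useless for simulation), `ellipsoid`, and the default
`two_surface`: a spherical skull with a corrugated source surface —
seeded band-limited spherical-harmonic corrugation (degrees 4–9, 3 mm RMS)
plus a deterministic sulcus-like fold through the target (5 mm amplitude,
16 mm wavelength, one fold across, ~5 cm along). The fold gives the
simulated dipole the tangential orientation of a real sulcal-wall source
(~50–55° from radial here; a real N20m generator is closer to fully
tangential, so the simulated fields of ~340 fT peak are conservative). The
fold is a *single* sulcus by construction: a periodic fold would alias —
displacing the array by one wavelength would find an identical wall, a
degeneracy real aperiodic cortex does not have. Surface radii are clamped
2 mm inside the skull. The default source space has 10242 vertices
(~4 mm spacing); the simulated recording and geometry of the standard
protocol are fixed study conditions, with run-time seeds driving noise and
perturbation draws.

What the generator does **not** emulate: realistic cortical folding beyond
one sulcus (so any result that depends on the spatial homogeneity of the
cortex — most notably the arc-displacement curve width, which measures how
well a displaced array can re-explain the data with shifted sources — is
narrower here than over a fully folded cortex), correlated neural
background noise, environmental interference, cross-talk, and gain
inhomogeneity of real arrays. Passing tests therefore demonstrate the
machinery and its scaling, not system-level performance on real data.

## Pose search and model averaging

The Metropolis sampler works on a box-bounded parameter space: by default
the 3 translation parameters of the rigid array (a flat ±20 mm box,
64 cm³), optionally a single-axis (1D) or full 6-parameter rigid mode
(rotations bounded at ±0.35 rad). Proposals are Gaussian with
per-parameter steps initialised at a tenth of the box width and adapted
multiplicatively toward ~30% acceptance during the first 40% of iterations
(then frozen, so the retained chain satisfies detailed balance);
out-of-bounds proposals are rejected; forward-model failures score −∞ with
a warning. Acceptance is `min(1, exp(F_prop − F_curr))` — F differences
*are* log posterior ratios under the flat prior. Defaults follow the
experiments: 4 chains × 600 iterations.

BMA draws 30 models from the post-burn-in (last 60%) chain states with
weights `∝ exp(F − max F)`, inverts each drawn geometry once (weighted by
its multiplicity) and averages the current estimates. The posterior
summary uses the full weighted post-burn-in cloud: evidence-weighted mean
pose, and the 95% confidence ellipsoid of the central sensor's position
(semi-axes `√(χ²₃(0.95) · eigenvalues)` of the weighted covariance; volume
`4/3 π ∏ semi-axes`). A posterior whose weighted spread is numerically
zero is flagged collapsed and returns the single dominant model. Note the
averaged current estimate inherits the beamformer's noise bias: sources
the patch barely sees get large prior variance `Γ` and thus inflated
posterior power, so the global power argmax is only meaningful within the
array's field of view (or after averaging enough trials).

## Numerical conventions

SI units internally (metres, teslas, radians); millimetres, degrees and fT
at file and CLI boundaries only. One seeded `numpy` generator per
stochastic operation, spawned from `SeedSequence` so sub-streams are
independent and reproducible; every artifact records its seed. Degenerate
inputs fail loudly: coplanar sphere fits, open shell meshes, non-positive-
definite covariances, zero rotation axes and out-of-range gain fractions
all raise with actionable messages.

## Known limitations

Single-axis point magnetometers only; one-shell conductors (no three-shell,
BEM or FEM); fixed-orientation sources; no trial-level statistics or
induced-response inversion; the pose search assumes a rigid array of known
internal geometry. The arc-displacement width and the absolute nats scale
of F depend on modelling choices (`n_eff`, cortical homogeneity) that are
documented above and exposed as parameters rather than hidden.
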