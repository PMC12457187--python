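# Methods

This note documents the models, the synthetic study conditions, and the
numerical and design choices behind `vbtstim`. Everything stated here is
computed by the package itself (the test suite and
`scripts/acceptance.py` exercise each claim); nothing is quoted from
external results.

## The Epileptor-Stimulation field model

Seizure dynamics on the cortical mesh follow a 4-state extension of the
phenomenological Epileptor. At every node *i* (a mesh vertex, or a
single node for a subcortical structure):

```
x' = y - f1(x, z, m) - z + I_ext + I_stim
     + γ_lc Σ_j S(g_ij) H(x_j, θ_lc) + γ_gc Σ_l W_kl H(X_l, θ_gc)
y' = c - d x² - y
z' = r (4 (x - x0 + n H(m - m_thresh)) - z) + f2(z)
m' = r (I_stim - m)
```

with `f1 = a x³ - b x²` for `x < 0` and `-(m + 0.6 (z - 4)²) x` for
`x ≥ 0`; `f2 = -0.1 z⁷` for `z < 0`, else 0; `H(v, θ) = 1` iff `v ≥ θ`;
`S(g) = e^{-|g|}/2` over geodesic distances `g_ij` (mm); `X_l` is the
mean of `x` over the vertices of region *l*, and `W` is the
max-normalized structural connectome.

`x, y` are the fast discharge variables; `z` is the slow permittivity
that carries the node between interictal and ictal states; `m` low-pass
filters the stimulation input with rate `r` and, once it crosses
`m_thresh`, flips a Heaviside term in `z'` that can push the node over
the seizure threshold. Defaults: `I_ext = 3.1, c = 1, d = 5, r = 1,
a = 1, n = 1, m_thresh = 1.8, γ_gc = 0.1, γ_lc = 0.8, θ_gc = θ_lc = -1`.
`b = 2` follows the original Epileptor (it does not appear in the
stimulation variant's published defaults and is exposed as a parameter).

**Sign of the Heaviside drive.** As written, a positive `n` *raises*
`z`, which stabilizes the node: single-node sweeps with the defaults
put the unstimulated seizure threshold near `x0 ≈ -1.2`, and with the
Heaviside term active at `n = +1` the threshold moves *up* to
`≈ -0.2`. The seizure-promoting direction is `n` negative: with
`n = -1` the active-Heaviside threshold moves down to `≈ -2.2`, so the
canonical excitabilities behave exactly as intended — `x0 = -1.6`
(epileptogenic) is quiescent alone but seizes when stimulation drives
`m` past threshold, while `x0 = -2.5` (healthy) never seizes. The
package implements the equation verbatim with `n` exposed and uses
`n = -1` (`N_SEIZURE_PROMOTING`) in all stimulation studies. The
clamped-`m` bifurcation (grid 1.0–2.5, step 0.1) then sits exactly at
the smallest grid value ≥ `m_thresh = 1.8`, verified for `dt ∈ {0.05,
0.02, 0.01}`.

**Integrator.** Fixed-step Heun, default `dt = 0.01` model-time units;
stochastic Heun (additive noise on `x, y` only) when `noise_sd > 0`.
The closed-form relaxation `m(t) = s + (m₀ - s) e^{-rt}` for constant
input is reproduced to < 1e-4 at `dt = 0.01`. A non-finite state aborts
the run with the first offending node and time; the `x ≥ 0` branch of
`f1` grows like `+0.6 (z-4)² x`, so trajectories entering the up-state
with large `m` can genuinely diverge — this is a property of the model
as written, not of the integrator, and constrains usable stimulation
amplitudes (below).

**Initial condition.** Nodes start at the numerically located
interictal fixed point (root finding on the `x < 0` branch with
`m = 0`), not at zeros.

**Time calibration.** One model-time unit corresponds to 0.05 s
(`SECONDS_PER_TIME_UNIT`), chosen so the fast Epileptor discharges land
in the tens-of-Hz band of ictal recordings; simulated sensor series at
`dt = 0.01` therefore have an effective 2 kHz sampling rate.

## The reduced 2D Epileptor (generative model of the inversion)

Timescale separation reduces the Epileptor per region to

```
x' = I1 - x³ - 2x² - z
z' = (1/τ0) (4 (x - x0) - z + K Σ_j C_ij (x_j - x_i))
```

with `I1 = 3.1`; `τ0` scales seizure length and `K` the network
coupling through the connectome `C`. Excitability `x0` is the parameter
of clinical interest: `-2.5` healthy, `-1.6` epileptogenic on this
scale.

## Synthetic anatomy

`make_toy_brain` generates two deformed spherical lobes of human extent
(radius 40 mm), triangulated on the unit sphere (so every generated
vertex is kept) and radially deformed afterwards. Regions are contiguous
patches from farthest-point seeding per lobe; the connectome is a sparse
symmetric gamma-weighted matrix with zero diagonal, max-normalized to
one; SEEG shafts are collinear 8-contact runs (3.5 mm spacing) aimed at
region centroids; scalp electrodes sit on an enclosing sphere 15 mm
outside the head.

The toy keeps realistic *extent* and reduces vertex *density*: at the
default 400 vertices the per-vertex area is ~100 mm², versus ~10 mm²
for clinical-resolution meshes (reachable here by raising `n_vertices`
to ~4×10⁴). Sensor-to-source distance contrasts — what the forward
models and the inversion actually rely on — are therefore realistic,
while the local-coupling kernel `e^{-g}` (unit length 1 mm) is
negligible across ~9 mm vertex spacing; local seizure spread is
correspondingly under-expressed relative to a dense mesh. What passing
tests show about real data is hence the *network-level* logic (fields,
thresholds, envelopes, inversion), not fine surface propagation.
Geodesics are Dijkstra over the mesh edge graph (cutoff 20 mm); the
edge-graph overestimate of exact polyhedral geodesics is second-order
under the fast-decaying kernel.

## Stimulation

**SEEG.** A charge-balanced biphasic pulse train (clinical defaults
50 Hz, 3 mA, 2 ms pulses, 3.5 s) drives every vertex through the
bipolar field map `|κ(i, anode) - κ(i, cathode)|` with
`κ(i, s) = a_i / d_{i,s}²`; the per-region maximum is broadcast
uniformly to the region's vertices and the map is normalized to max 1.
`I_stim(i, t) = amplitude_scale · field(i) · ψ(t)`. Because ψ is
charge-balanced, `m` cannot integrate it on average; accumulation works
through the per-pulse ripple of `m` (amplitude ≈ `(1 - e^{-r·pw/2}) ·
peak`), which crosses `m_thresh` intermittently. The physical-to-model
conversion is deliberately free: `amplitude_scale = 40` is the
calibrated operating point at which a directly stimulated epileptogenic
region seizes (single-node threshold ≈ 32) while a directly stimulated
healthy region stays subthreshold (crosses only ≥ ~56).

**TI.** Two scalp pairs at 1000 and 1005 Hz, synthesized at 30 kHz for
1 s, linearly summed; the 5 Hz beat envelope is extracted by cubic-spline
interpolation through successive local maxima of the absolute signal (a
Hilbert-transform alternative is available for cross-checking). Only
the envelope enters the neural model — the kHz carrier never does. The
per-vertex field stand-in is a quasi-static two-point-source model per
pair projected on vertex normals (the published workflow computes these
with a finite-element head model; real maps can be loaded from file),
combined as `2·min(E1, E2)` — the classic TI effective-field amplitude.
The default montage pairs the four scalp electrodes nearest the target
region crosswise. The usable TI amplitude window is narrow
(`amplitude_scale ≈ 2.05–2.1`): the sustained nonnegative envelope
drives `m` high, and seizures that onset with large `m` diverge through
the `f1` up-state branch. This is a real limitation of the model
variant and is documented rather than patched.

## Forward models

- Distance gain (region level): `g_{j,k} = Σ_{i∈j} a_i / d_{i,k}²`,
  nonnegative; distances floored at 0.5 mm with a warning.
- Dipole gain (vertex level): `g_{i,k} = a_i/(4πσ) · Q·(r_k - r_i)/|r_k
  - r_i|³` with unit normal-constrained moments per unit area and
  `σ = 1` (unbounded homogeneous medium). Scalp-EEG uses the same
  formula as a stand-in for a boundary-element head model; the
  unbounded approximation errs little for deep sources near electrodes
  but ignores skull attenuation at the scalp, so external lead fields
  can be loaded to override it.

Simulated recordings project *vertex* activity through the dipole gain
(orientation-aware, high-fidelity); the inversion consumes the
*region-summed* dipole gain — the same physics aggregated to the
reduced model's resolution — with bipolar column differences for SEEG.
The distance gain remains available and carries the same tests.

## Data features

Per channel, in order: slice `[onset - pad_before, offset +
pad_after]`; replace outliers at or beyond 2 SD by the trace mean;
zero-phase 4th-order Butterworth high-pass (10 Hz); non-overlapping
100-sample windows → square, mean, natural log (ε = 1e-12 guard);
despike again; zero-phase low-pass; subtract the mean over the first
`baseline_s` seconds. Zero-phase filtering preserves onset timing,
which the epileptogenicity values depend on. Window stride and filter
family are unspecified in the clinical recipe and exposed as config.

Toy runs compress time 20× (0.05 s per model unit), so the toy feature
configuration shrinks the clinical constants accordingly: pads 0.4/0.5 s,
envelope low-pass 1 Hz (vs 0.05 Hz), baseline 0.5 s; the 10 Hz
high-pass and 100-sample window are unchanged at the 2 kHz effective
rate. Simulations add fast-variable noise (sd 0.05) so every channel
has a finite pre-ictal baseline, as in real SEEG; envelope rises then
scale with each channel's gain toward the discharging tissue rather
than with the log-ε floor.

## Bayesian inversion

The generative model Euler-integrates the 2D Epileptor on the feature
grid (`dt = 0.1` per feature sample, `τ0 = 10` by default) and maps
`x(t)` through each modality's gain with an affine observation
`pred = α (G x) + β` and iid Gaussian noise `σ`; EEG uses the
elementwise-absolute gain. The multimodal likelihood is the sum over
modalities of the same source trajectory. The published workflow never
states the observation equation linking the reduced states to the
envelope; linear-in-`x` with free `α, β` is the minimal choice
consistent with fitting the envelope.

Free parameters: `x0` (per region), `x(t0)`, `z(t0)`, `K`, per-modality
`α, β`, `σ`, and — for stimulated seizures — one gain `c` on a known
stimulation pattern (per-region field strength gated to the stimulation
window) added to `x'`. Without this term, subthreshold stimulation
responses in healthy regions are mis-attributed to elevated
excitability; with it, the stimulus explains them and `x0` explains the
seizure. A config switch removes the term.

Priors are identical across regions (the prior belief is that every
region is healthy): `x0 ~ N(-2.5, 1)`; `x(t0) ~ N(-1.8, 0.5)`,
`z(t0) ~ N(3.5, 0.5)` around the healthy fixed point; `K` and `σ`
half-normal, sampled on the log scale with exact Jacobians; `β ~ N(0,
10)`. `α` and `c` are *positive* (lognormal): envelope power rises with
source activity, and with unconstrained sign the posterior grows a
mirror mode (negative `α`, suppressed-EZ `x0`) that breaks
localization.

`x0` and `z(t0)` are sampled in the eigenbasis `V` of `GᵀG`
(channels-stacked `G`), ascending eigenvalues, signs fixed by the
largest-magnitude component; `V` is orthonormal, so the identical
per-region priors transform without Jacobian corrections and region
permutations commute with inference.

**Gradients** of the log posterior are exact: reverse-mode (adjoint)
accumulation through the Euler recursion, hand-written and verified
against central finite differences to ~1e-6 relative error. The two
sequential time loops are numba-compiled with a NumPy fallback.

**Optimization and sampling.** MAP: multi-start L-BFGS (reference
policy 50 restarts, keep the best 8; scaled-down runs use fewer) from
prior-centered random inits. Sampling: an in-house No-U-Turn sampler
(slice variant, recursive doubling, dual-averaging step size, max tree
depth 7–8), 16 chains cycled over the 8 MAP inits (2 per init) in the
reference policy. Each chain's diagonal mass matrix is fixed from the
Hessian diagonal of the log posterior at its MAP init (central
differences of the exact gradient, clipped positive); warmup variance
re-estimation is disabled because it is unreliable on this multimodal
posterior and empirically destroys the preconditioning. Target
acceptance 0.9. Divergences (energy error > 1000) are counted and
reported; runs are returned with a warning when they exceed 10% of
transitions.

**Diagnostics.** Split-chain potential scale reduction factor (exact
copies of a chain return exactly 1) and Geyer initial-positive-sequence
effective sample size, implemented in-house and cross-checked against
`arviz` in the tests. On the seizure posterior, chains seeded at
different MAP modes legitimately disagree (the likelihood is
multimodal); the epileptogenicity ranking is the quantity of interest
and is stable across chains.

## Epileptogenicity values

For each posterior sample the 2D model is re-integrated (vectorized
across draws); a region's onset `t_i` is the first sample with `x`
strictly above 0 (literal reading of "above": the boundary does not
count), sentinel 200 when it never crosses, both in feature-grid units.
With `t0 = min_i t_i`,

```
EV_i = -log(((t_i - t0) + 1) / 20)
```

(natural log), strictly decreasing in onset delay, then min-max
normalized to [0, 1] per sample; an all-equal vector maps to zeros (no
seizure anywhere ⇒ no epileptogenic evidence). Per-region summaries
report the 25th/50th/75th percentiles and rank regions by median.

## Study conditions and problem sizes

The standard recovery study: toy brain with 400 vertices, 12 regions,
one epileptogenic region (the one best sampled by the first shaft),
SEEG stimulation at the pair nearest the EZ (50 Hz / 3 mA / 2 ms /
3.5 s, `amplitude_scale 40`), 100 model-time units (5 s) of simulation,
dynamics noise sd 0.05; features at the toy configuration; inversion
with 12 MAP restarts (keep 4), 4 chains × 500 draws after 250 warmup;
EVs from 400 posterior draws. Under these conditions the epileptogenic
region ranks first by median EV in 5/5 seeded replicates of the test
suite's acceptance run. The stimulation sweep stimulates the 12 pairs
with the weakest field coupling into the EZ plus the pair nearest the
EZ: the near pair induces a seizure in the EZ only; the weak-coupling
pairs induce none.

## Known limitations

- The printed model's up-state branch diverges when seizures onset at
  large `m`; TI amplitudes have a narrow usable window and SEEG
  amplitudes an upper bound (~55 in scale units).
- With `r = 1` both `z` and `m` relax within one time unit, so induced
  discharges are stimulation-locked and end with the stimulus; slow
  afterdischarge dynamics require a smaller `r` (runnable, but then the
  charge-balanced pulse ripple no longer reaches `m_thresh` at clinical
  amplitudes).
- Scalp-EEG gains use the unbounded-medium dipole formula; no skull
  attenuation.
- The toy mesh under-expresses local (geodesic-kernel) seizure spread
  relative to clinical-resolution meshes.
- The seizure posterior is multimodal; between-chain scale-reduction
  factors can exceed classical thresholds even when the EV ranking is
  stable. Diagnostics are reported, not hidden.
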