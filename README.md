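# vbtstim — virtual brain twins for stimulation-induced seizures

`vbtstim` is a toolkit for the model-based localization of the
epileptogenic zone network (EZN) from *stimulation-induced* seizures.
It targets the presurgical-epilepsy setting where spontaneous seizures
are scarce and clinicians provoke them instead — invasively through
SEEG depth-electrode pulses, or non-invasively through temporal
interference (TI) stimulation, whose kilohertz carriers at frequencies
f and f + Δf beat at the low difference frequency that actually
stimulates tissue.

The package covers the whole workflow on a synthetic, patient-free
scaffold (real meshes, connectomes, sensors and lead fields can be
supplied through standard formats):

1. **Anatomy** — a two-lobe cortical mesh with per-vertex areas and
   normals, a contiguous parcellation, a max-normalized structural
   connectome, SEEG shafts and scalp electrodes.
2. **Dynamics** — the 4-state Epileptor-Stimulation neural field: the
   classic fast discharge variables (x, y) and slow permittivity z,
   plus an accumulation variable m that integrates the stimulus and,
   past the threshold m_thresh = 1.8, flips a Heaviside term in ż that
   can push tissue into the seizing state. Excitability x0 separates
   healthy (−2.5, never seizes) from epileptogenic tissue (−1.6,
   quiescent alone, seizes under clinical-range stimulation).
3. **Stimulation** — charge-balanced biphasic SEEG pulse trains
   (50 Hz / 3 mA / 2 ms) with inverse-square bipolar field maps, and TI
   carrier synthesis with peak-spline beat-envelope extraction.
4. **Forward models** — region-level distance gains
   g_jk = Σ a_i/d² and vertex-level dipole gains
   g_ik = a_i/(4πσ) · Q·(r_k−r_i)/|r_k−r_i|³, bipolar SEEG montages,
   linear projection to sensors.
5. **Features** — the seizure log-power envelope: despike → 10 Hz
   high-pass → windowed square/mean/log → despike → low-pass →
   baseline subtraction.
6. **Inversion** — Bayesian estimation of per-region excitabilities
   with the reduced 2D Epileptor
   (ẋ = I₁ − x³ − 2x² − z, ż = (4(x−x0) − z + K ΣC(x_j−x_i))/τ0),
   MAP-seeded No-U-Turn HMC sampling in the eigenbasis of GᵀG, with
   exact hand-written adjoint gradients, multimodal (SEEG + EEG)
   likelihoods, and split-R̂ / ESS diagnostics.
7. **EZN mapping** — per-sample epileptogenicity values
   EV_i = −log(((t_i − t₀) + 1)/20) from first-crossing onsets
   (sentinel 200 for non-seizing regions), min-max normalized, ranked
   by posterior median.

See `docs/methods.md` for the models, calibrated study conditions, and
numerical choices.

## Worked example

```python
from vbtstim import pipeline

study = pipeline.build_study(n_vertices=400, n_regions=12, seed=7)
print(f"epileptogenic region: region-{study.ez_region:02d}")

sim = pipeline.run_seeg_stim_simulation(study, seed=7)
print(f"stimulated pair: {sim.stim_target}, seized: {sim.seized_regions}")

feat, gain = pipeline.extract_study_features(study, sim, "seeg")
post, diag, summary = pipeline.invert_study(
    study, [(feat, gain)], sim=sim, n_restarts=12, n_keep=4,
    n_chains=4, draws=500, warmup=250, seed=7)
print(summary.head(5).to_string(index=False))
```

prints

```
epileptogenic region: region-10
stimulated pair: ("A'4", "A'5"), seized: [10]
   region  p25  median      p75  rank
region-10  0.0     1.0 1.000000     1
region-00  0.0     0.0 0.000000     2
region-01  0.0     0.0 0.000000     2
region-02  0.0     0.0 0.256782     2
region-03  0.0     0.0 0.000000     2
```

The designated epileptogenic region (region-10) is the only one that
seizes under bipolar pulse stimulation at the nearest contact pair, and
the inversion of the resulting SEEG envelope ranks it first by median
epileptogenicity value, with all other regions near zero.

The same pipeline runs from the shell:

```sh
vbtstim make-anatomy --config run.toml --out out/anatomy --seed 7
vbtstim simulate     --config run.toml --out out/sim     --seed 7 --stim seeg
vbtstim invert       --config run.toml --out out/inv     --seed 7 --modality seeg
vbtstim sweep        --config run.toml --out out/sweep   --seed 7
```

with a TOML config (all blocks optional; unknown keys rejected):

```toml
[anatomy]
n_vertices = 400
n_regions  = 12

[stimulation]
kind = "seeg"

[inversion]
chains = 4
draws  = 500
```

Every command writes a `manifest.json` with the config snapshot, seeds
and artifact checksums; deterministic stages reproduce bit-for-bit.

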