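# dimerforce

Mechanics and kinetics of multi-domain protein dimers under force, for
single-molecule magnetic-tweezers experiments.

Anti-parallel dimers of multi-domain proteins — the spectrin-repeat (SR) rod
dimers of α-actinins are the motivating case — carry mechanical load in the
actin cytoskeleton. In a magnetic-tweezers assay the dimer is tethered
between a coverslip and a bead, force is applied in shear or unzip geometry,
and every structural transition (domain unfolding, dimer rupture,
re-dimerization) appears as a step in the bead-height record. `dimerforce`
implements the full computational chain for such experiments:

* **Polymer mechanics** — folded bodies as single-segment freely-jointed
  chains, `x(f) = b (coth(fb/kBT) − kBT/fb)`; unfolded peptides as
  Marko–Siggia worm-like chains, `fA/kBT = 1/[4(1−x/L)²] − 1/4 + x/L` with
  `L = N·l0`. The predicted step of a transition at force `f` is
  `Δx(f) = x_after(f) − x_before(f)` for the corresponding mechanical series.
* **Construct model** — declarative descriptions of tether constructs
  (domains, rods, looped linker, shear/unzip geometry) with built-in presets,
  mapping conformational states to mechanical series and producing
  force-dependent step-size tables.
* **Rupture kinetics** — Bell slip-bond rates `k(f) = k0·exp(Δf/kBT)`, a
  multivalent dimer model in which only boundary domain pairs un-pair,
  un-paired folded domains can rapidly re-pair, and unfolding gates
  re-pairing; exact mean first-passage lifetimes from the Markov chain, a
  Gillespie simulator at constant force, ramp simulation, and the
  Evans–Ritchie modal rupture force `F* = (kBT/Δ)·ln(rΔ/k0 kBT)`.
* **Trace analysis** — FFT low-pass smoothing, change-point / HMM step
  detection, dwell-time extraction from force-jump cycles (right-censored
  when no rupture occurs), rupture forces from linear ramps.
* **Inference** — censored-exponential lifetime fits
  (`P(t) = 1 − exp(−t/τ)`), the M = 20 bootstrap for rate uncertainties,
  weighted Bell-model fits of `ln k` vs `f`, Gaussian rupture-force peaks,
  and the re-dimerization sigmoid `P(F) = 1/(exp((F−Fc)Δx/kBT)+1)`.
* **Synthetic data** — dwell samples, clustered (multi-state) dwell
  populations, and full 200 Hz bead-height traces with 2–5 nm Gaussian noise
  and ground-truth annotations, so the whole pipeline is testable end to end.

## Worked example

Predict the step sizes of the full-rod shear dimer, then run a complete
simulate → detect → extract → fit round trip:

```python
import dimerforce as df

c = df.get_preset("actn1_shear_full")
unfold = (df.TetherState(dimerized=True, open_pairs=1),
          df.TetherState(dimerized=True, open_pairs=1, unfolded=1))
rupture = (df.TetherState(dimerized=True, open_pairs=1, unfolded=1),
           df.TetherState(dimerized=False, unfolded=4))
print(df.predicted_step_table(c, [unfold, rupture], [45.0, 56.0]))
```

```
                        transition  force_pN    step_nm
dimer+1open+0unf->dimer+1open+1unf      45.0  29.617787
dimer+1open+0unf->dimer+1open+1unf      56.0  30.391615
   dimer+1open+1unf->ruptured+4unf      45.0 145.587874
   dimer+1open+1unf->ruptured+4unf      56.0 149.456201
```

Unfolding one 110-residue SR domain (5 nm folded span) yields a ~30 nm step
at 45 pN; rupture of the dimer with concurrent unfolding of the remaining
domains releases the looped 170-residue linker and the 480-residue rod chain,
a ~146 nm step.

```python
true = df.BellParams(k0=1e-3, delta=0.8)      # zero-force rate, transition distance
model = df.single_bond_model(true)
pts = []
for i, f in enumerate((25.0, 30.0, 35.0)):
    proto = df.ForceProtocol(kind="jump_cycle", high_force=f, n_cycles=25,
                             max_hold_s=120.0, low_duration_s=1.0)
    trace, _ = df.generate_trace(c, proto, df.NoiseModel(height_sd=3.0),
                                 model=model, rng_seed=101 + i)
    records = df.extract_dwell_times([trace], min_step=20.0)
    est = df.bootstrap_rates(records, df.BootstrapConfig(rng_seed=7))
    print(f"F = {f:4.1f} pN   tau = {est.tau:6.2f} +/- {est.tau_sd:.2f} s")
    pts.append((f, est.k_rupture, est.k_sd))
fit = df.fit_bell(pts)
print(f"Bell fit: k0 = {fit.params.k0:.2e} 1/s, delta = {fit.params.delta:.2f} +/- {fit.delta_se:.2f} nm")
```

```
F = 25.0 pN   tau =   9.99 +/- 1.98 s
F = 30.0 pN   tau =   3.56 +/- 0.84 s
F = 35.0 pN   tau =   0.92 +/- 0.17 s
Bell fit: k0 = 2.54e-04 1/s, delta = 0.97 +/- 0.12 nm
```

The fitted transition distance (0.97 ± 0.12 nm) recovers the generating
value (0.8 nm) within two standard errors; the lifetimes fall from ~10 s to
~1 s over 10 pN, the Bell-model signature of a slip bond.

A CLI wraps the same pipeline (`dimerforce predict-steps | generate |
simulate | analyze | fit`); every output embeds the seed and a config hash.

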