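# Methods

## Polymer models and the step-size calculator

A stretched tether is a mechanical series of segments sharing one tension;
its extension is the sum of member extensions.

* **Rigid bodies** (folded domains, the dimerized rod pair) follow the
  single-segment freely-jointed chain: `x(f) = b·L(fb/kBT)` with `L` the
  Langevin function and `b` the span between force-attachment points.
  Below argument 1e-4 the Langevin function is evaluated by its series
  `y/3 − y³/45` to avoid catastrophic cancellation.
* **Unfolded peptides** follow the Marko–Siggia worm-like chain with
  persistence length `A = 0.8 nm` and contour `L = N·l0`, `l0 = 0.38 nm`.
  The force→extension inversion is a bracketed Brent solve on
  `[0, L(1−1e−9)]` (xtol 1e-12); deterministic, no randomness.
* `kBT = 4.075 pN·nm`, the thermal energy at 22 °C, the experimental
  temperature; all constants are overridable through `PolymerEnvironment`.
  Units are pN / nm / s throughout; nothing converts units internally.

The predicted bead-height step of a transition is the extension difference
of the after- and before-series at the transition force. Standard
parameters: an SR domain is 110 residues with a 5 nm folded span; a full
four-SR rod (helical inter-repeat linkers included) is 480 residues with a
24 nm span; the looped flexible linker is 170 residues (shear geometry) or
218 residues (unzip).

**Loop bookkeeping.** While the dimer is intact the looped linker is off the
force path. Two conventions exist for the rupture step:

1. *Default*: the unreleased loop contributes nothing and the released loop
   contributes its full WLC extension. Under this convention the composite
   rupture-plus-unfolding steps for the full-rod shear dimer evaluate to
   145.6 / 149.5 nm at 45 / 56 pN (the corresponding published predictions,
   138 / 142 nm, use an unstated residue bookkeeping; the agreement is
   within ~5%). One-SR unfolding evaluates to 29.6 / 30.4 nm, matching the
   published 30 / 31 nm.
2. *Loop-geometry accounting* (`include_loop_geometry=True`, or
   `loop_release_step`): the loop's dimer-imposed end-to-end distance
   (24 / 18 / 12 nm for full-rod / three-SR / two-SR shear, ~2 nm unzip)
   enters the dimerized series as a fixed span, so a pure release step is
   the linker's extension *difference* — the natural choice for
   rupture-without-unfolding and re-dimerization curves.

The naive WLC evaluation of the looped-linker force gives 0.19 pN for the
unzip linker (218 residues at 2 nm) and 1.59 pN for the two-SR shear dimer
(12 nm); the corresponding published bounds are "<0.1 pN" and "<1.5 pN".
The package reports the naive values and does not force agreement — the
exact assumption behind those bounds is unstated.

## Multivalent rupture kinetics

All transitions are Bell: `k(f) = k0·exp(Δf/kBT)`, with Δ > 0 for
force-accelerated channels (un-pairing, unfolding) and Δ ≤ 0 for
force-suppressed ones (re-pairing, refolding). Exponents are capped at 700
and rates at 1e12 s⁻¹ — numerical safety with no physical consequence.

The dimer is a continuous-time Markov chain over per-pair states
{paired, open-folded, open-unfolded}:

* only **boundary** pairs un-pair (terminal, or all pairs toward one
  force-bearing terminus already open) — dissociation unzips inward from the
  loaded ends, so the intact block stays contiguous;
* an open, folded pair adjacent to the intact block may re-pair (held in
  proximity by the remaining pairs); open domains may unfold; unfolded
  domains cannot re-pair until they refold;
* full rupture (no intact pair) is absorbing. Detailed balance is not
  assumed; only rate positivity and reachability of the absorbing state.

Mean lifetimes come from the exact first-passage linear system over the
reachable states (≤ 3ⁿ, enumerable for n ≤ 5). The Gillespie simulator
draws trajectories at constant force; under linear ramps the force axis is
discretized in ≤ 0.01 pN steps (rates constant within a step, event
probability `1 − exp(−R dt)` per step), which reproduces the
inhomogeneous-Poisson closed form for a single bond to well under 2% in the
modal rupture force. One seeded `numpy` generator drives each simulation;
seeds are recorded in results.

The paper-level model fixes the *structure* of this chain but not its
rates: re-pairing and interconversion kinetics are not quantified
experimentally, and fitted (k0, Δ) values appear only on figure panels.
All kinetic parameters are therefore free, config-driven inputs; the demo
values used in tests (un-pair k0 = 0.5 s⁻¹, Δ = 1 nm; re-pair k0 = 20 s⁻¹,
Δ = −0.5 nm; unfold k0 = 0.05 s⁻¹, Δ = 1.5 nm; refold k0 = 5 s⁻¹,
Δ = −2 nm) were chosen once to give lifetimes of seconds-to-minutes in the
5–40 pN range with visible multivalent amplification, and are never
presented as measured values.

## Trace analysis

Traces are uniform 200 Hz (time, force, bead-height) records. "w-point FFT
smoothing" is implemented as a low-pass filter zeroing Fourier components
at or above `f_s/(2w)`; a centred moving average is available as a fallback
(`method="boxcar"`).

Step detection fits a piecewise-constant level sequence by greedy binary
segmentation on the residual sum of squares with a BIC-style stop
(penalty `2σ²ln n`, σ estimated robustly from first differences), then
collapses change points closer than 5 samples (noise can split one sharp
edge) and reports steps whose level change exceeds `min_step`
(default 10 nm for rupture/unfolding; ~2 nm suits hopping records).
Sub-threshold boundaries stay in the fit so neighbouring level estimates
are uncontaminated, but produce no events. A Gaussian-emission HMM
(`method="hmm"`, user-set state count) serves two-state hopping traces.
Step time is the midpoint of the fitted transition; the force at a step is
read from the force channel at that sample. Detection is invariant to
constant height offsets.

Dwell extraction requires hold-phase annotations
(`metadata["hold_phases"]`); the first qualifying step inside a hold window
sets the dwell, and windows without one yield *right-censored* records at
the hold duration rather than being discarded (discarding long survivors
would bias τ downward; censored records enter the likelihood as survival
probability). Classifying a measured step as rupture versus unfolding in
mixed cascades uses a nearest-prediction rule against the construct's
step-size table — a package convention, since no acceptance threshold is
published.

## Inference

The per-force lifetime estimator is the censored-exponential MLE
`τ = (Σ dwells, censored included) / (# ruptures)`; an empirical-curve mode
(least squares of `P(t) = 1 − exp(−kt)` against the ECDF, or one minus the
Kaplan–Meier survival curve when censoring is present) is selectable.
The bootstrap draws M = 20 resamples of size N with replacement, re-fits
each, and summarizes the pools of k and τ = 1/k separately; degenerate
(all-censored) resamples are redrawn and logged. **Uncertainty
convention**: the pool *sd* is the bootstrap estimate of the estimator's
standard error and is what recovery checks use; the pool sd/√M (the
Monte-Carlo error of the pool mean) is also reported as `tau_se` / `k_se`.
Coverage of `Δ ± 2·se` in the full pipeline was verified at ~92% over 200
simulated replicates.

The Bell fit is linear in log space (`ln k` vs `f`), weighted by the
propagated `se(ln k) = se_k/k` when uncertainties are supplied; the
parameter covariance is then the unscaled `(XᵀWX)⁻¹` appropriate for known
per-point variances (a residual-rescaled covariance would rest on ~3
degrees of freedom and materially under-cover). Gaussian force-histogram
fits use the exact normal MLE (one component) or a seeded EM mixture (two
components, sorted-sample initialization). The re-dimerization sigmoid is
fitted by least squares and satisfies `P(Fc) = 0.5` exactly. A
two-component exponential-mixture EM is provided for automatic clustering
of dwell sub-populations; the primary clustered-lifetime workflow is manual
per-cluster assignment.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:
exponential force-dependent dwells (with optional censoring), hidden
sub-states persisting over blocks of cycles (slow interconversion), and
full traces in which the bead height is the series extension of the
current tether state at the instantaneous force, relative to the initial
state, plus Gaussian noise (default σ = 3 nm, range 2–5 nm, 200 Hz).
Protocols: constant force, linear ramps (±0.1–5 pN/s regime, validated to
±10), and jump cycles (low-force re-formation, instantaneous jump, clamped
hold). Jumps add a configurable constant offset during the hold — a bead
re-orientation artifact excluded from the ground-truth events, which the
extraction stage must ignore. Re-formation at low force is treated as
instantaneous between cycles; refolding/re-dimerization *during* slow
down-ramps can instead be generated from the same kinetic engine with
force-suppressed rates. Traces are byte-identical across runs with the same
seed.

What the generator does **not** emulate: Brownian bead fluctuation spectra,
camera/tracking artifacts beyond Gaussian noise, drift, force-calibration
error (the ~10% calibration uncertainty is metadata only), and bead
re-orientation torque during jumps beyond the constant-offset artifact.
Passing round-trip tests therefore shows the analysis is self-consistent
under the stated noise model, not that it is robust to every instrumental
artifact of real recordings.

## Problem sizes used in tests

Statistical checks run at sizes chosen to make sampling error the binding
tolerance: 1000–1500 Gillespie runs for simulator/oracle equivalence (3 SE
criterion), 1000 ramp trajectories for the modal-force check (2%),
20 replicates × 5 forces × 50 dwells for Bell-parameter recovery (≥ 90%
of replicates within 2 se), and 3 forces × 25 jump cycles at σ = 3 nm for
the full round trip (τ within 2 bootstrap se per force, ≥ 95% step recall).

## Known limitations

* Residue bookkeeping for composite rupture steps approximates the
  published prediction curves within ~5% (their exact convention —
  helical-linker and tag residues — is unstated).
* Partially unfolded post-rupture rods mix per-domain spans and chains,
  leaving helical-linker residues unaccounted in mixed states.
* The multivalent model tracks one effective force-bearing domain per pair
  (state space 3ⁿ), not both monomers independently, and does not model
  the rigid-pair re-orientation cooperativity discussed qualitatively for
  clustered mechanical states.
* Extensible WLC, twist/torque mechanics and temperature-dependent
  persistence length are out of scope, as is deriving spans from actual
  PDB structures (stated spans are accepted as numbers).
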