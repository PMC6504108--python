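# Methods

## Model structure and assumptions

The otic vesicle's medial edge is abstracted to a one-dimensional axis of
independent cells, position 0 (anterior) to 1 (posterior); there is no cell
movement, growth, diffusion, or cell–cell signalling other than through the
two extrinsic inputs.  Each cell runs the same ordinary-differential-
equation network (see the README for the equations); spatial pattern arises
solely from two static sources of positional information:

1. **Extrinsic Fgf gradient** `Fgf_e(x)`: constant at the plateau level for
   x ≤ 0.30 (the rhombomere 4/5 boundary projects to about 30% of vesicle
   length) and declining beyond.  The default decline is exponential —
   the generic far-field shape for a secreted ligand — with the length
   constant chosen so that the excess over baseline has decayed to 5% of
   its plateau value at the posterior end; a linear decline is available in
   the config.  Baseline is 5% of the plateau, so posterior cells receive a
   small but non-zero input and become inducible when thresholds fall.
   The gradient is held constant in time over the modelled window
   (11.5–36 hpf); this is a simplification — reporter data suggest the
   hindbrain source weakens by 24 hpf — but none of the modelled readouts
   depend on late extrinsic input, because pole maintenance is taken over
   by the intrinsic-fgf loop.

2. **Pole competence** `C(x)` for intrinsic *fgf* induction: 1 within 0.15
   of either pole, 0 in the centre (hard mask by default; a cosine-ramp
   soft mask is config-selectable).  The width matches the terminal
   domains where duplicate intrinsic-fgf expression appears; it is exposed
   in the config, not hard-coded.

**Hedgehog input** is spatially uniform.  Cells track it with an
intracellular effector `G` relaxing at rate `delta_G` (half-life ≈ 4 h,
motivated by the persistence of Gli activator proteins), and `G` raises the
Fgf-response threshold of each anterior gene linearly:
`theta_eff = theta0 · (1 + alpha · G)`.  Linear-in-G is the simplest
monotone form consistent with threshold antagonism.  The effector is
initialised at equilibrium with the extracellular level at the start of
simulation (Hh signalling is active well before otic stages); mRNAs and
proteins start at zero, so the wild-type anterior pre-pattern emerges from
the equations rather than being imposed.

**Regulatory logic.**  *hmx3a* sums Fgf and autoregulatory input (OR-like),
which makes its subsystem bistable: once induced, autoregulation alone
holds it on.  *pax5* and intrinsic *fgf* use AND logic (product of Hill
terms in Fgf and Hmx3a activity) because both are lost when Hmx3a protein
is absent.  Intrinsic *fgf* is additionally gated by `C(x)`; its product
feeds the local Fgf protein pool, closing a cell-autonomous positive
feedback loop that maintains anterior identity at a pole after the
inducing signal has gone.  Under the *hmx3a* loss-of-function allele the
truncated protein lacks its DNA-binding domain, so Hmx3a *activity* is set
to zero while mRNA dynamics continue unchanged.

**Units.**  Concentrations are in arbitrary units normalised so that
`beta/delta = 1` for each mRNA (saturation level 1); time is hours post
fertilisation (hpf).  The wild-type extracellular Hh level is 1.

## Scenarios

Heat-shock transgene induction is a rectangular production pulse of
amplitude 20 a.u./h for 1.0 h (30 min at 39 °C plus the 30 min step-down at
33 °C, which is thought to extend transgene activation), then first-order
decay at `delta_x = 0.7/h`.  The amplitude is calibrated so that total Fgf
exceeds every effective threshold axis-wide during the pulse.  Cyclopamine
is a timed reduction of extracellular Hh to 20% of baseline (the drug
down-regulates but does not abolish pathway activity) over 14–22.5 hpf;
wash-out restores Hh instantaneously and the cellular lag is carried
entirely by `G`.  The *smoothened* mutant sets Hh to zero throughout.
Simulations run 11.5–36 hpf, sampled every 0.25 h plus the assay stages
{16, 22.5, 25.5, 30, 36} hpf; integration restarts at every pulse edge and
Hh interval boundary so the solver (LSODA, rtol 1e-7, atol 1e-10) never
steps across a discontinuity.  Simulation is fully deterministic.

## Default kinetic parameters and how they were fixed

The system's data are staged qualitative expression patterns, not
time-series concentrations, so parameters were calibrated once against the
shipped concordance suite (24 staged observations across six regimes) and
then frozen; they are conventions of this implementation, not measured
quantities.  The load-bearing choices:

- `n_hill = 2`: moderate cooperativity, so the graded Fgf input under
  lowered thresholds produces a graded (not all-or-none) *hmx3a* response
  at intermediate stages, as seen under Hh inhibition.
- `theta_h0 = 0.2`, `alpha_h = 9`: wild-type effective threshold 2.0,
  placing the *hmx3a* ignition boundary near mid-axis; strong Hh
  sensitivity lets the boundary sweep posteriorly during Hh inhibition.
- `w_auto = 4.4` (= 2.2 × the wild-type effective threshold): just above
  the bistability margin, so autoregulation maintains *hmx3a* at ~70% of
  saturation with no Fgf input, but cannot self-ignite from baseline.
- `theta_f0 = 0.10`, `alpha_f = 7`, `k_translate = 1.8`, `delta_P = 1.0`:
  the pole fgf loop self-sustains once ignited, ignites at the poles
  whenever thresholds are lowered (Hh inhibition) or Fgf is supplied
  (heat shock), but possesses a stable off state at wild-type Hh levels.
  This margin is deliberately tight: it is what lets the model reproduce
  the experimental negative result that uniform *hmx3a* mis-expression
  alone does **not** duplicate the ear, while Hh inhibition does — the
  only discriminator between those two regimes is the threshold state.
- `theta_p0 = 0.17`, `alpha_p = 4`: wild-type *pax5* occupies roughly the
  anterior 40–50% (inside the *hmx3a* domain), and the posterior pole's
  Fgf loop output clears the recovered threshold after wash-out, giving
  the late, weaker posterior *pax5* domain.
- mRNA half-lives ~1–1.4 h (`delta` 0.5–0.7/h): fast enough that a marker
  crosses the 20% detection level within ~2 h of induction (the observed
  rapid *hmx3a* response to heat shock) and decays from the centre between
  22.5 and 25.5 hpf (the observed *pax5* resolution into two domains).

## Pattern measurement conventions

A profile "expresses" where it exceeds 20% of the species' saturation
level; the mapping from in-situ stain visibility to a model threshold is a
convention and the value is exposed in the config and echoed in outputs.
Domain calling takes maximal above-threshold runs, closes single-point
dips (discretisation robustness), and discards runs narrower than 5% of
the axis.  Extent is the above-threshold length with linear interpolation
of crossings, as a percentage of axis length — the in-silico analogue of
measuring stain extent along the medial edge.  The asymmetry index is
(A − P)/(A + P) over anterior- and posterior-half means.

## Synthetic cohorts

The cohort generator emulates per-ear extent measurements: per embryo, one
multiplicative log-normal jitter (CV 0.1, mean 1) on production rates and
base thresholds — shared by both ears, so ears within an embryo are
correlated — then an independent Gaussian measurement error (SD 3
percentage points) per ear, clipped to [0, 100] (clipping is logged and
never activates under defaults).  The noise magnitudes are conventions
chosen to give between-group separations visually comparable to real
per-ear stain measurements; the raw data they emulate are not available.
All embryos of a cohort are integrated as one stacked ODE system (cells
are independent, so embryos are just extra columns with their own
parameters), which makes thousand-replicate calibration runs cheap.

What the generator deliberately does not emulate: left/right ear
asymmetries within an embryo beyond measurement noise, staging error,
batch effects, and any spatial correlation of measurement error — so
passing statistical checks here demonstrates the correctness and
calibration of the resampling machinery, not robustness to every artefact
of real in-situ data.

Group comparison resamples embryos, not ears: percentile bootstrap (95%
CI) and label permutation (p-value), both deterministic given a seed.
Ear-level resampling is available as an option for comparison with
analyses that treat ears as independent data points.

## Numerical choices

- LSODA with rtol 1e-7 / atol 1e-10 (defaults; config-exposed).  Halving
  tolerances changes kymographs by < 0.1% relative at values above 1% of
  each species' maximum (checked in the acceptance tests).
- Event-aware integration: piecewise integration between breakpoints;
  within a segment the Hh level and pulse rates are constants evaluated at
  the segment midpoint.
- Non-negativity: the right-hand side clamps its input state at zero (any
  production at zero concentration is non-negative), and the integrator
  rejects any trajectory dipping below −1e-9 before clipping round-off to
  zero.
- The single-cell fixed-point oracle uses damped fixed-point iteration
  (damping 0.25, residual < 1e-10); `h_init` selects the branch where the
  *hmx3a* equation is bistable.
- Cohort simulations default to a coarser grid (positions are independent,
  so a coarser axis only coarsens the extent readout by its grid spacing).

## Known limitations

- *hmx2* is tracked only qualitatively (its observed behaviour parallels
  *hmx3a*); retinoic acid is outside the model; expression is
  deterministic (no transcriptional noise).
- Under *hmx3a* loss of function the model's *hmx3a* mRNA becomes a pure
  Fgf readout (autoregulation acts through the protein, which the
  truncation kills) and falls below the detection threshold anteriorly,
  whereas embryos show reduced-but-present stain with unchanged extent.
  The shipped suite therefore asserts the loss of *pax5* and intrinsic
  *fgf* (the robust observations) and reports, rather than asserts,
  *hmx3a* levels in this regime.
- In the constitutive Hh-loss mutant the simulated *hmx3a* profile is
  near-saturated (essentially flat) by 22.5 hpf, whereas stained embryos
  still show a graded pattern at that stage; the graded-profile assertion
  is made for the cyclopamine regime, where the model genuinely shows it.
- After *hmx3a* mis-expression the model keeps ectopic *hmx3a* on
  indefinitely through autoregulation; embryos largely restore the normal
  pattern.  The scenario's headline outcome — no duplication of *pax5* /
  intrinsic *fgf*, no double-anterior ear — is reproduced and reported.
- Late heat shock (18 hpf) reproduces the broad marker expansion at
  22.5 hpf; the downstream loss of competence to form a fully duplicated
  ear involves mechanisms outside this network and is not modelled.
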