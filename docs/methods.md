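# Methods

## The model

`ampktoggle` models the regulatory triangle that decides whether a cell
runs protein synthesis or autophagy: AMPK (the energy sensor, active
when phosphorylated at Thr-172), mTORC1 (the nutrient sensor, written
`mTOR` throughout), ULK1 (the autophagy-initiating kinase, active when
phosphorylated at Ser-555), and a lumped autophagy activator ATG whose
level stands in for autophagic activity (experimentally: LC3-II
accumulation and p62 degradation).

Each species is a covalent-modification (Goldbeter–Koshland) cycle with
constant total (one dimensionless unit): a Michaelis–Menten activation
flux on the inactive pool balances a Michaelis–Menten inactivation flux
on the active pool.  Writing `A`, `M`, `U`, `G` for the active levels,

```
dA/dt = kaA·S·(AT−A)/(JaA+AT−A) − (kiA + kiAU·U + kiAM·M)·A/(JiA+A)
dM/dt = kamtor·(MT−M)/(JaM+MT−M) − (kiM + kiMA·A + kiMU·U)·M/(JiM+M)
dU/dt = kaUA·A·(UT−U)/(JaU+UT−U) − (kiU + kiUM·M)·U/(JiU+U)
dG/dt = (kaG0 + kaGU·U)·(GT−G)/(JaG+GT−G) − (kiG + kiGM·M)·G/(JiG+G)
```

Rate constants are min⁻¹; Michaelis constants and totals are
dimensionless.  Inhibitory edges of the wiring diagram catalyse
inactivation, activating edges catalyse activation.  Three design
commitments are structural, not fitted:

* **ULK1 has no basal activation term** — its activation strictly
  requires AMPK.  This is what makes AMPK necessary (but not
  sufficient) for autophagy induction.
* **kiAM is the new edge.**  mTOR-catalysed AMPK inactivation closes the
  AMPK ┤ mTOR ┤ AMPK double-negative loop.  `ModelVariant` can switch
  it off, reducing the system bitwise-exactly to the template network
  without that edge; every other edge has an ablation switch too.
* **kaG0 > 0 but small** — cells keep residual autophagic activity at
  rest; it never approaches the ULK1-driven flux.

No phosphosite-resolved states are modelled (Ser-757 vs Ser-555 are not
separate variables), and TSC1/2 and Raptor act only through the
effective rate constants.

## Calibrated defaults

`kamtor = 0.025` and unit totals are fixed conventions (hyper-activated
mTOR is `kamtor = 0.05`, a 2-fold increase, so the baseline is half
that).  Everything else is this package's calibration, shipped in
`data/default_parameters.yaml` and verifiable at zero violations with
`ampktoggle calibrate`.  The qualitative constraints the defaults
satisfy simultaneously:

* resting state at S = 1: mTOR active (M ≈ 0.67), AMPK/ULK1/ATG off,
  and this is the *only* attractor at S = 1 (no coexisting state, no
  limit cycle);
* the full 16-scenario phenotype matrix (below) at zero mismatches;
* a bistable window in the stress input S (≈ [1.1, 1.95]) with clean
  hysteresis;
* mTOR hyper-activation (kamtor 0.05) raises M enough (≈ 0.93) that
  the AMPK activation threshold moves beyond the starvation stimulus.

Numerically load-bearing choices, found during calibration:

* **A's cycle is ultrasensitive** (JaA = 0.01, JiA = 0.005): AMPK
  behaves as a sharp switch, which the phenotype contrasts need.
* **M's cycle is graded** (JaM = JiM = 0.1): p70S6K-P declines
  progressively rather than all-or-none, and the M level transmits the
  2-fold kamtor difference into a usable gap (0.67 vs 0.93).
* **U's cycle is graded** (JaU = 0.05, JiU = 0.2).  With zero-order
  (small-J) ULK1 kinetics the slow AMPK→ULK1→AMPK negative feedback
  supports a stable limit cycle near the lower fold of the autophagy
  branch — an oscillation the biology of this switch does not show.
  Graded ULK1 kinetics damp that mode; the toggle then terminates in
  plain saddle-node folds.  The damping also bounds how slow the
  AMPK/ULK1 cycles may be relative to mTOR's: the shipped rates are the
  slowest (most blot-like) setting that keeps the induced branch free
  of oscillations.
* **The AMPK/ULK1 timescale is set to the blot sampling.**  All seven
  AMPK/ULK1 rate constants share a common scale chosen so the
  rapamycin-induced AMPK-P transient spans the 30–60 min samples
  (threshold crossings at ≈ 12 and ≈ 36 min) instead of collapsing
  between two sampling points; rescaling them jointly changes no
  steady state, only the clock.
* **kiM = 0.022 just below kamtor = 0.025**: the small headroom makes
  the mTOR cycle flippable by modest AMPK/ULK1 input while keeping the
  resting state robust.
* ULK1-P decays slowly (kiU = 3·10⁻⁴ min⁻¹): after rapamycin-induced
  AMPK-P has been switched off by ULK1-dependent feedback, ULK1-P and
  autophagy persist through the 2-h experimental window.

## Treatments and protocols

Wet-lab manipulations map to parameter overrides (package conventions;
no pharmacokinetics — printed doses correspond to fixed magnitudes):

| treatment    | override             | rationale                          |
|--------------|----------------------|------------------------------------|
| si_ulk1      | UT → 0.001           | siRNA depletion of total ULK1      |
| si_tsc12     | kamtor → 0.05        | loss of the upstream mTOR brake    |
| mtor_hyper   | kamtor × 2           | same magnitude, stated as 2-fold   |
| rapamycin    | MT → 0.01            | active-capable mTOR pool collapses |
| compound_c   | kaA × 0.05           | AMPK activation blocked            |
| starvation   | S → 2.6              | energy stress through the input    |
| resveratrol  | S → 2.6              | treated as an AMPK activator       |
| ampk_hyper   | S → 6                | strong direct AMPK activation      |

Protocols are staged: pre-treatments (siRNA, Compound C) start at t = 0
and the main treatment at t = 30 min; overrides accumulate across
stages.  State is carried continuously across stage boundaries except
that a reduced total forces the conservation clamp (active mTOR cannot
exceed the new MT at rapamycin onset).  Integration is LSODA (BDF
fallback) at rtol 1e-8 / atol 1e-10 on a 1-min output grid.

The starvation magnitude S = 2.6 sits above the bistable window's upper
fold (so starvation flips the toggle) and below the AMPK activation
threshold of the hyper-activated-mTOR state (so siTSC1/2 blocks it);
these two constraints bracket it to roughly [2.3, 3.0].

## Phenotype classification

Band densitometry in the mirrored experiments is reported as
significant/non-significant changes, so calls are made on declared
thresholds over the protocol window: θ_high = 0.5 and θ_low = 0.25 of
the nominal (untreated) totals.  HIGH: final ≥ θ_high.  TRANSIENT:
peak ≥ θ_high and final ≤ θ_low.  LOW: peak < θ_high.  The leftover
case (peak high, final between thresholds) is PARTIAL and never matches
an expectation.  Expectations are *sets* of acceptable levels;
"mTOR off at the end" is {LOW, TRANSIENT} because M starts at its high
baseline (a pre-staged protocol shows it high for 30 min before the
drug removes it), and "AMPK significantly phosphorylated" without a
persistence claim is {HIGH, TRANSIENT}.

The 16 scenarios: control; rapamycin; starvation; resveratrol;
Compound C; siULK1; siTSC1/2; mTOR-hyper; AMPK-hyper; siULK1 + each of
rapamycin/starvation/resveratrol; siTSC1/2 + each of
rapamycin/starvation/resveratrol; CompoundC+rapamycin.  Variant
comparisons and matrix evaluation always start from the reference
resting state of the *extended* model, so an ablated variant is scored
on how its response differs, not on a different baseline — the template
network has no stable mTOR-active rest state at these parameters, which
is itself the observation motivating the extra edge.

## Steady states, scans, nullclines

Steady states come from multi-start bounded least-squares root finding
(Latin-hypercube starts plus a deterministic lattice that includes the
box faces, where ultrasensitive cycles park their roots), de-duplicated
at 1e-5 and classified by the eigenvalues of a central-difference
Jacobian (step 1e-6).  Scans seed each column with the neighbouring
column's roots; bistable intervals are reported as grid brackets, not
polished fold points.  Hysteresis sweeps integrate to steady state
(rate tolerance 1e-7) carrying the previous state — a quasi-static
parameter ramp.  Nullclines live in the (A, M) plane with U and G at
quasi-steady state (each is a monotone 1-D root, solved by Brent);
the reduction is for visualisation and cross-checks only.

## Synthetic densitometry

The generator emulates loading-control-normalised immunoblot
quantification at 30-min sampling over the 2-h drug window, three
replicates.  Read-outs: AMPK-Thr172-P → A, p70S6K-P → M, ULK1-Ser555-P
→ U, LC3-II → G, p62 → `1·(1−G) + 0.1` (p62 is degraded by autophagy;
the floor keeps residual signal, as blots show).  Noise is
multiplicative lognormal, mean-corrected (E[noisy cell] = clean cell),
with a per-lane loading factor shared by all read-outs of one replicate
at one time point — one gel lane, one GAPDH band.  Defaults: 10% band
CV, 5% loading CV, n = 3.

What the generator does *not* emulate: saturation/nonlinearity of film
exposure, band overlap, batch effects between blots, or biological
replicate variability beyond the lognormal cell noise.  Passing
recovery tests on these tables therefore shows the fitting machinery is
sound under the declared noise model, not that the parameters are
identifiable from real blots.

## Calibration and fitting

`calibrate` scores a parameter set by a weighted count of violated
qualitative constraints plus margin shortfalls, optionally including
existence of a bistable S window; the search is Latin-hypercube
screening over log-uniform ranges, then coordinate-wise multiplicative
refinement with a shrinking step.  Accepted-step scores are monotone
non-increasing.  `kamtor`, the totals, and the structural zero (no
basal ULK1 activation) are never searched.

`fit_time_course` is multi-start trust-region least squares in
log-parameter space against replicate-mean table values, re-simulating
the table's own protocol per evaluation (rtol 1e-6 inside the loop).
More than three simultaneous free parameters triggers an
identifiability warning.  The shipped recovery experiment fits
(kaUA, kiAU) to rapamycin tables: exact (< 1% relative error) at zero
noise; median-over-20-seeds error well under 20% at 10% noise.

## Degenerate inputs and tie-breaks

All-zero rate constants make every point a fixed point; steady-state
search raises a dedicated degenerate-model error.  The physiological
initial state is the stable steady state with the largest M (ties:
largest M, then smallest A).  A scan over a zero-width range is valid
with one point but requires ≥ 3 points otherwise.  Conflicting replace
overrides on the same field are an error; replace beats multiply within
a stage; applying a replace treatment twice equals applying it once.

## Known limitations

* Parameters are a qualitative-constraint calibration, not a fit to
  quantitative kinetics; absolute time scales (e.g. the ~12-min AMPK-P
  rise under rapamycin) are order-of-magnitude choices consistent with
  the 0–120 min observation window.
* The bistable window in S is a calibration outcome (≈ [1.1, 1.95]);
  no claim is made about its physiological width.
* The phase-plane reduction treats U and G as fast, which is only
  qualitatively true; all quantitative results use the full 4-D system.
* Problem sizes in the shipped tests (grid densities, 100-draw
  robustness sweeps, 20-seed recovery) are desk-scale choices; the
  machinery accepts larger settings unchanged.
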