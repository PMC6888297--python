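# ampktoggle

An ODE model of the AMPK–mTORC1–ULK1 regulatory triangle that decides
between cell growth and autophagy, including the mTOR ┤ AMPK arm that
closes a double-negative feedback loop (AMPK ┤ mTOR ┤ AMPK) and turns
the network into a bistable toggle switch.  The package is for systems
biologists who want to re-run, perturb, or extend the in-silico
counterparts of the classic autophagy-induction experiments: rapamycin
and starvation time courses, siRNA silencing of ULK1 or TSC1/2,
Compound C inhibition of AMPK, and their staged combinations.

## The model

Four dimensionless variables track active fractions: `A` (AMPK-Thr172-P),
`M` (active mTORC1), `U` (ULK1-Ser555-P), `G` (the lumped autophagy
activator ATG).  Each is a Goldbeter–Koshland covalent-modification
cycle; inhibitory edges catalyse inactivation, activating edges catalyse
activation:

```
dA/dt = kaA·S·(AT−A)/(JaA+AT−A) − (kiA + kiAU·U + kiAM·M)·A/(JiA+A)
dM/dt = kamtor·(MT−M)/(JaM+MT−M) − (kiM + kiMA·A + kiMU·U)·M/(JiM+M)
dU/dt = kaUA·A·(UT−U)/(JaU+UT−U) − (kiU + kiUM·M)·U/(JiU+U)
dG/dt = (kaG0 + kaGU·U)·(GT−G)/(JaG+GT−G) − (kiG + kiGM·M)·G/(JiG+G)
```

Rate constants are min⁻¹; totals are one unit each; `S` is the
stress/energy input (1 = physiological).  `kiAM·M` is the newly proposed
mTOR ┤ AMPK edge; `ModelVariant(mtor_inhibits_ampk=False)` removes it,
giving the template network for ablation contrasts.  See
`docs/methods.md` for the full scientific account.

## Worked example

Score the 16-scenario qualitative phenotype matrix (every single and
combined treatment, simulated from the physiological resting state and
classified against the transcribed expectations):

```
$ ampktoggle evaluate-matrix
matched 16 of 16 scenarios
  ok   control                  A=LOW M=HIGH U=LOW G=LOW
  ok   rapamycin                A=TRANSIENT M=LOW U=HIGH G=HIGH
  ok   si_ulk1                  A=LOW M=HIGH U=LOW G=LOW
  ok   si_tsc12                 A=LOW M=HIGH U=LOW G=LOW
  ok   si_ulk1+rapamycin        A=HIGH M=TRANSIENT U=LOW G=LOW
  ok   compound_c+rapamycin     A=LOW M=TRANSIENT U=LOW G=LOW
  ...
```

Reading the calls: at rest only mTOR is active.  Rapamycin inactivates
mTOR; AMPK-P then surges but is later switched off by ULK1-dependent
feedback (TRANSIENT) while ULK1-P and autophagy stay on (HIGH).
Silencing ULK1 leaves AMPK-P LOW — mTOR alone now holds it down, which
is the signature of the mTOR ┤ AMPK edge.  With both mTOR inhibited and
ULK1 silenced, AMPK-P is permanently HIGH yet autophagy stays LOW
(AMPK is not sufficient); with AMPK inhibited instead, everything stays
LOW (AMPK is necessary).

The edge-ablation contrast directly:

```
$ ampktoggle compare-variants --scenario si_ulk1
extended  A=LOW M=HIGH U=LOW G=LOW
template  A=HIGH M=TRANSIENT U=LOW G=LOW
final AMPK-P difference (template - extended): +0.993
```

Without the mTOR ┤ AMPK edge the model predicts a large AMPK-P surge
under ULK1 depletion that the silencing experiments do not show; with
it, AMPK-P stays down.

The toggle itself — scanning the stress input finds the hysteresis
window:

```
$ ampktoggle scan --param S --lo 1.0 --hi 2.2 --n-points 25
bistable interval: [1.1, 1.9]
wrote results/scan_S.csv
```

Inside the window a growth state (M high) and an autophagy state
(U, G high) coexist, separated by a saddle; starvation (S = 2.6) lies
above the upper fold and flips the switch.

From Python, the rapamycin cascade with its event ordering
(mTOR falls at onset, AMPK-P crosses the activation threshold at
12 min, ULK1-P at 36 min, autophagy active at the end):

```python
from ampktoggle import (default_parameters, standard_protocol,
                        integrate, event_ordering,
                        physiological_steady_state)

p = default_parameters()
rest = physiological_steady_state(p)       # A=0.004, M=0.669, U≈0, G≈0
traj = integrate(standard_protocol(["rapamycin"], [], 120), p,
                 initial_state=rest)
ev = event_ordering(traj, baseline=rest)
ev.fall["M"], ev.rise["A"], ev.rise["U"]   # (0.0, 12.0, 36.0)
traj.series("G")[-1]                       # 0.995
```

Other entry points: `ampktoggle simulate` (trajectory CSV/JSON + plot),
`steady-states`, `nullclines`, `calibrate` (verify or refine the
shipped defaults against the qualitative constraints), and
`generate-fixtures` (synthetic immunoblot densitometry tables with
lognormal noise, for fitting experiments).

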