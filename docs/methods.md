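# Methods

## Model and assumptions

The gastrointestinal tract is modelled as `n_p` discrete fluid plugs.  Each
plug `j` is a well-mixed pocket of volume `V_j` that leaves the stomach at a
scheduled onset time and thereafter moves through the intestine
independently of every other plug: there is no mass transfer between plugs,
and suspended and dissolved drug are homogeneously mixed within a plug.
Only dissolved drug can cross the intestinal wall.

Within plug `j`, the dose is divided into particle-size fractions `i`, each
a monodisperse population of spheres with initial radius `r0_i` and initial
solid mass `X0_ij`.  Four masses per (i, j) pair evolve jointly:

* solid mass `Xs_ij`, by Noyes–Whitney dissolution for shrinking spheres —
  the remaining mass enters as `X0^(1/3) Xs^(2/3)` (surface area of a
  shrinking sphere), the driving force is `Cs_j − Xd_j/V_j` with `Xd_j` the
  plug-total dissolved mass shared across fractions;
* dissolved mass `Xd_ij`, fed by dissolution and depleted by first-order
  absorption `ka_j(t) · Xd_ij`;
* plasma mass `Xp_ij` and tissue mass `Xt_ij`, a linear two-compartment
  disposition with central elimination.

Absorption is attenuated by a presystemic bioavailability factor `F_j`; the
complementary flux `(1−F_j) ka_j Xd_ij` is accumulated in a first-pass
ledger, and cleared drug `(cl/Vd) ΣXp` in an elimination ledger, so that at
every instant

```
Σ_ij (Xs + Xd + Xp + Xt) + eliminated + firstpass = dose.
```

The ledgers are not part of the physiological model; they exist so that
mass conservation is a measurable property of every run rather than an
assumption.

Gastric emptying of plug `j` is the transition of `ka_j` from 0 (no gastric
absorption) to its intestinal value over a short window, by a cosine
smoothstep that is exact at both anchor points, monotone and continuously
differentiable.  Chaining segments through common end points builds
arbitrary piecewise profiles (e.g. region-dependent permeability), and the
same schedule machinery drives plug volume and solubility if a scenario
makes them time-dependent.  Schedules are re-evaluated at every RK4
sub-step, including the half-step.

### Elimination site and conventions

Clearance acts on the central compartment as the first-order rate
`ke = cl/Vd` (units cancel: (mL/min/kg)/(mL/kg) = min⁻¹; 4/600 ≈ 0.00667
min⁻¹ for the default parameters).  This is the standard two-compartment
convention; gut-wall or portal-vein metabolism would require an extra
compartment and is out of scope.

"Particle size" in scenario files is a radius by default
(`options.particle_size_interpretation: diameter` halves it), since the
radius is the dissolution law's only geometric parameter.

## Parameters that matter

| parameter | units | default | role |
|---|---|---|---|
| `D` | cm²/min | 3e-4 | aqueous diffusion coefficient; scales dissolution rate |
| `ρ` | mg/cm³ | 1300 | solid density; inversely scales dissolution rate |
| `Cs` | mg/mL | 0.01 | solubility; driving force and saturation ceiling |
| `h_max` | cm | 3e-3 | diffusion-layer cap; `h = min(r, h_max)` |
| `r0` | cm | 1e-4 | particle radius; complete-dissolution time scales as `r0²` |
| `ka` (intestine) | min⁻¹ | 0.07 | first-order absorption; 0 in the stomach |
| transition | min | 1 | emptying-transition window |
| `F` | — | 0.5 | presystemic bioavailability |
| `cl`, `Vd`, `mb` | mL/min/kg, mL/kg, kg | 4, 600, 70 | clearance and distribution; `ke = cl/Vd` |
| `k12`, `k21` | min⁻¹ | 0.03, 0.01 | plasma–tissue exchange |

The default drug is a nifedipine-like hypothetical compound; the default
plug layouts (three 80-mL plugs at 0/15/30 min; one 240-mL plug; seven
240/7-mL plugs at 0,5,…,30 min; a variant with the first plug drug-free)
are the bundled presets.  A note on two preset choices that the source
material leaves open: the seven-plug onsets are spaced evenly over the same
0–30 min span as the three-plug layout, preserving the emptying-time
centroid (15 min); and the single-plug reference empties with the first
plug's 0→1 min transition.

With the default dose and volumes, each plug's dose-to-volume ratio equals
`Cs` exactly (0.8 mg / 80 mL = 0.01 mg/mL), so dissolution in a closed plug
approaches saturation asymptotically and finishes only once absorption
begins draining the dissolved pool — the stomach plugs sit near saturation
until they empty.

## Numerical scheme

Classical fourth-order Runge–Kutta at a fixed step of 0.001 min, the step
at which the published demonstration runs of this model were computed.
This is far below every time scale in the system (the fastest default rate
constant is 0.07 min⁻¹), and halving the step changes Cmax of the
three-plug preset by ~7e-13 relative, so the scheme is fully converged.
Output is thinned to a 0.5-min grid by default (Tmax resolution equals the
output interval; no interpolation is applied).  The final time point is
always recorded, via a shortened last step when the duration is not a step
multiple.  Summation over plugs is in fixed ascending order, so repeated
runs are bit-identical.

Two engines share the arithmetic expression for expression: a
numba-compiled kernel (default; ~1 s per 720-min three-plug run) and a
pure-Python reference path assembled from the model-module rate laws,
retained for transparency and asserted to agree with the kernel in the test
suite.

### The cube-root extinction point

Near complete dissolution the solid-mass rate behaves as `Xs^(1/3)`
(radius-dependent diffusion layer), which reaches zero in finite time with
unbounded curvature.  The final RK4 step of a fraction's life therefore
overshoots slightly below zero — up to ~1e-6 mg at the default step, well
below any dose of interest but far above machine epsilon.  The overshoot is
mass that left the solid within that step, so it is folded into the
dissolved pool and the solid set to zero; the ledger stays exact to machine
precision and recorded states are non-negative.  Solids below 1e-12 mg are
snapped the same way, avoiding fractional powers of vanishing numbers.
Negative excursions beyond a configurable instability threshold (default
1e-4 mg) abort the run — that magnitude indicates a genuinely unstable
step, not the extinction artefact.

Other numerical conventions: the dissolution driving force uses only the
positive part of each dissolved mass; a supersaturated plug (`Xd/V > Cs`)
drives the rate positive (precipitation back onto particles), capped so the
solid never exceeds its initial mass, with a config flag to clamp it to
zero instead; the abrupt-transition variant (`transition_mode: step`)
switches at the transition-window midpoint, preserving the centroid of the
smooth transition it replaces — switching at the window start would
systematically turn absorption on early by half a window and biases the
comparison.

## Stochastic emptying generator

`EmptyingDistribution` describes fasted-state emptying of a 240-mL water
dose: plug count uniform on 2–6, onsets uniform over the first 30 min
(sorted), Dirichlet(α=2) volume splits, and dose allocated proportionally
to volume (a well-stirred stomach).  These ranges are motivated by MRI
observations that post-dose intestinal fluid is fragmented into a handful
of drug-relevant pockets, and by the 0–30 min emptying span of the
deterministic presets; each choice is overridable per scenario.  Sampled
volumes and doses close exactly on the declared totals, and every draw is
seeded — identical seed, identical scenario, bit for bit.

What the generator does *not* emulate: correlation between plug volume and
emptying time, secretion/reabsorption of fluid during transit (plug volumes
are constant unless scheduled), plug convergence or break-up, and
inter-subject variability in drug disposition.  Passing tests on sampled
scenarios therefore demonstrate the machinery (reproducibility, closure,
the direction of the Cmax effect), not calibrated population predictions.

## Verification strategy

The simulator is checked against independent closed forms rather than
against itself:

* pre-dissolved drug with constant `ka` reduces the system to ODEs with
  known solutions — the Bateman function (one compartment) and the
  three-exponential solution (two compartments); the simulated profiles
  match both to ~1e-14 relative, with Tmax on the grid next to the analytic
  `ln(ka/ke)/(ka−ke)` and AUC within 0.001 % of `F·dose/(cl·mb)`;
* forced-sink dissolution of a monodisperse fraction has the closed-form
  completion time `ρ r0²/(2 D Cs)` (2.17 min at 1 µm, 216.7 min at 10 µm);
* n identical plugs must reproduce one plug of the pooled dose and volume
  (linearity), observed to ~1e-14;
* the mass-balance ledger must return the dose at every output time
  (~1e-13 relative in practice).

## Known limitations

* No portal-vein compartment: gut-wall/hepatic first-pass is a static
  factor `F`, not a saturable process.
* Solubility schedules are user-supplied curves; there is no buffer
  chemistry or pH titration model behind them.
* Plug volumes do not respond to water secretion/absorption unless
  explicitly scheduled.
* Tmax is grid-resolved (default 0.5 min); AUC extrapolation to infinity
  uses the terminal log-linear slope and is flagged as absent when no
  credible terminal phase exists.
* The plug-count robustness comparison (7 vs 3 plugs over the same span)
  shows up to ~12 % of Cmax pointwise difference during the absorption
  phase even though Cmax itself agrees within ~3 % — merging or splitting
  plugs is a faithful approximation for exposure metrics, less so for the
  instantaneous profile while emptying is in progress.
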