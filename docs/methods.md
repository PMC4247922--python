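# Methods

## Model

Two cell populations in a tissue region — healthy cells `x1(t)` and cancer
cells `x2(t)`, dimensionless concentrations — compete Lotka–Volterra style
and are harvested by periodic radiotherapy:

    dx1/dt = α1 x1 (1 − x1/K1) − β1 x1 x2 − ε D(t) x1
    dx2/dt = α2 x2 (1 − x2/K2) − β2 x1 x2 −   D(t) x2

`D(t)` is piecewise constant and ω-periodic: equal to the dose rate `γ ≥ 0`
on the half-open treatment window `[nω, nω+L)` (so the dose at a period
start is `γ` and at `t = nω+L` it is `0`) and zero on the recovery window.
Time is in hours; `α_i` are proliferation rates (per hour), `K_i` carrying
capacities, `β_i` competition coefficients (per concentration per hour) and
`ε > 0` the fraction of the dose felt by healthy cells.  All seven model
constants are required strictly positive, and `0 < L < ω`.

The model assumes well-mixed populations (no spatial structure, no
cell-cycle phases) and a linear kill term — dose rate times concentration —
rather than a linear-quadratic radiobiology response.  The analysis is
organised around the untreated *cancer-wins baseline* `K1 < α2/β2`,
`K2 > α1/β1`, under which the untreated system has the globally stable
equilibrium `(0, K2)`: treatment is what creates any other outcome.

## Closed forms on the axes

Both axes are invariant.  On each, the model reduces to a logistic equation
whose linear rate switches once per period: `r_on = α1 − εγ` (healthy) or
`α2 − γ` (cancer) during treatment, `r_off = α1` or `α2` during recovery,
with self-limitation `a = α_i/K_i`.  The reciprocal `y = 1/x` satisfies a
linear ODE in each phase, `y(t) = a/r + (y0 − a/r) e^{−rt}`, so the
one-period map on `y` is affine, `y ↦ A y + B` with
`A = exp(−r_on L − r_off (ω−L))` and `B > 0`.  A unique positive ω-periodic
solution exists iff the mean linear rate `r_on L + r_off (ω−L)` is positive
(then `A < 1`), with initial value `x*(0) = (1−A)/B`.  This affine-map
construction is used instead of transcribing the equivalent single closed
formula, because it composes phase maps that are individually trivial to
verify; it is cross-checked against numerical shooting to below 1e−10
relative in the tests.  Rates with `|r| < 1e−12` use the exact limit
`1/x(t) = 1/x0 + a t` (the eradication reference set has `r_on = 0.005`, so
near-degenerate rates are a practical concern, not a corner case).

Each phase of the switched logistic is monotone toward its phase
equilibrium, so the per-period minimum `σ` is attained at a phase endpoint;
the implementation evaluates `t ∈ {0, L, ω}` and confirms against a
2001-point grid, raising if the grid undercuts the endpoint minimum by more
than 1e−6.

## Numerical integration and Poincaré machinery

`D(t)` is piecewise constant, so the system is smooth between switch
times.  The simulator splits the time span at every `nω` and `nω+L` and
integrates each segment with DOP853 at `rtol 1e−10 / atol 1e−12` (defaults;
chosen so closed-form cross-checks hold to 1e−8 relative).  No event
detection is ever attempted across a discontinuity.  Axis starts are
integrated on the reduced one-species system so the zero component stays
exactly zero.  States in `(−1e−6, 0)` arising from round-off are clipped to
zero; anything below `−1e−6` is an integrity failure, since the nonnegative
quadrant is invariant for the exact flow.

Periodic orbits of the full system are fixed points of the time-ω return
map started at a treatment-phase start.  The finder iterates the period map
plainly (the global-stability results make this convergent on the regimes
of interest) and falls back to a quasi-Newton root solve on the 2-D
residual if the residual has not reached `1e−10` after 200 iterations.
Orbits are classified by extinction threshold: a component whose orbit
maximum is below `1e−8` is extinct (fixed-point iteration reaches axis
orbits only asymptotically, so exact zeros cannot be demanded).  The
`contraction` field is the spectral radius of a central finite-difference
Jacobian of the period map (step `1e−6`, scaled by component magnitude).

The stability probe launches seeded uniform perturbations of magnitude
`m` (default 0.1), integrates 50 periods and reports the fraction ending
within `1e−4` of the fixed point.  Two deliberate choices here: components
that are positive on the orbit are floored at `1e−6` rather than clipped to
exactly zero — the axes are invariant, so a start clipped onto an axis is
outside the positive cone the global-stability statements concern and could
never return to an interior orbit — and the 50-period horizon is what a
near-axis start needs to re-invade (growth from `1e−6` back to an interior
orbit at the slow rates of the coexistence set takes ≈ 45 periods).

## Condition checkers

Every sufficient condition of the analysis is a checker returning the
verdict plus all intermediates.  All inequalities are strict; an optional
margin can demand extra slack, and slacks are always reported so borderline
cases are visible.  Notable points:

* The μ-coefficient dose window (`μ1 = (α1−K2β1) + ε(α2−K1β2)`,
  `μ2 = α2(α1−K2β1) + α1(α2−K1β2)`, three sign cases) is a *necessary*
  bound: it is derived by summing the two coexistence inequalities, which
  loses sharpness.  For the coexistence reference set it gives `(0, 0.45)`,
  while the ratio-chain condition itself holds exactly on
  `(0.05143, 0.37057)`.  `coexistence_window_exact` solves the chain in
  closed form (the middle ratio is a monotone Möbius function of γ, so each
  inequality cuts a half-line); the property tests verify it against a
  brute-force γ-grid scan of the checker.  An empty window and the
  "neither" classification of the comparison system are ordinary results,
  never exceptions.
* The eradication-stability decay condition `γ(ω−L) < ηω` with
  `−η = max{α1 − εγ − α1σ1/K1, α2 − γ}` takes `σ1` from the caller, because
  the value is convention-sensitive.  Under this package's convention
  (treatment first) the eradication reference schedule (γ=0.65, 8 h on)
  gives `σ1 = 0.122733` and the condition fails (`ηω = 0.3276 < 1.3`).
  Exchanging the on/off durations (treatment 2 h, recovery 8 h) gives
  `σ1 = 0.437710`, for which the condition *still* fails by 0.0032
  (`ηω = 1.2968 < 1.3`); it passes only for `σ1 = 0.44` (`ηω = 1.30385`).
  The scenario runner computes and reports both readings side by side and
  adopts neither as ground truth; the `swap_phases` option exposes the
  alternative convention throughout the closed-form layer.  The dynamical
  conclusion itself — perturbed trajectories return to the eradication
  orbit — holds empirically in the probe regardless, which is consistent
  with the condition being sufficient, not necessary.
* The reversed ratio chain (comparison equilibrium a saddle) is detected
  and flagged as an open regime; no dynamical conclusion is drawn from it.

## Scenarios, sampler, problem sizes

Three reference parameter sets ship as fixtures, all started from
`(x1, x2) = (0.5, 0.8)`:

| family | parameters | schedule | outcome |
|---|---|---|---|
| set1 | α=(0.1, 0.45), β=(0.11, 0.15), K=(0.65, 1), ε=0.05 | γ=0.35, ω=50, L∈{15,30,45} | interior orbit |
| set2 | α=(0.2, 0.5), β=(0.5, 0.55), K=(0.65, 1), ε=0.3 | ω=10, (γ,L)∈{(0.65,8),(0.65,9),(0.75,8),(0.8,8)} | eradication |
| set3 | α=(0.2, 0.5), β=(0.48, 0.05), K=(0.65, 1), ε=0.3 | ω=10, (γ,L)∈{(0.4,2),(0.6,1)} | cancer win |

The random-parameter sampler draws rates in (0.01, 1), capacities in
(0.1, 2), ε in (0, 0.5), ω in (5, 100) h and L uniform in (0, ω), with
optional rejection to the cancer-wins baseline; these ranges bracket the
reference sets by roughly an order of magnitude each way and keep
time scales resolvable at the default tolerances.  The sampler emulates
parameter heterogeneity only — it does not model measurement noise,
non-logistic growth or dose-response saturation, so passing property tests
demonstrate internal consistency of the solver and closed forms across the
parameter space, not fidelity to any real cell population (the reference
values themselves are illustrative, not fitted).

Test and probe sizes are chosen for quick desk-scale runs: invariance and
ultimate boundedness (`x_i ≤ K_i + 1` eventually) are checked on 100
sampled sets over 12 periods each; untreated convergence to `(0, K2)` on
8 baseline-filtered sets with the horizon scaled by the slowest linear rate
`min(β1K2 − α1, α1, α2)`; perturbation-return on the three reference
regimes with 20 seeded perturbations each.

## Known limitations

* The comparison-theorem step behind the coexistence result asserts
  componentwise lower bounds by the auxiliary system for a competitive
  (non-quasimonotone) system; the package verifies the *conclusion*
  (permanence) behaviourally rather than assuming the bound pointwise.
* Orbit classification by the `1e−8` extinction threshold cannot
  distinguish true extinction from decay slower than the iteration budget;
  the residual and contraction fields are reported so such cases are
  diagnosable.
* The saddle regime and any medication/recovery-stage extensions are out of
  scope; the checkers only detect the former.
* Stability evidence for the full system is numerical (contraction estimate
  plus perturbation probe), not a proof; the probe's return tolerance and
  horizon are reported parameters.
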