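# Methods

This note documents the models, algorithms and numerical choices behind
`mmpc`, in the order a run executes them: prediction models and bolus
semantics, synthetic training data, Akaike weight maps, sparse-grid
surrogates, the per-interval multiobjective solve, adaptive input
selection, and the benchmark harness.

## Prediction models and bolus semantics

A prediction model is an ODE system `dx/dt = f(x, u, t, θ)` with a
measured-output map `y = g(x, u, t, θ)` and a controlled-output map
`z = h(x, u, t, θ)`.  The control input `u` is a vector of reagent
concentrations confined to a box Ω (case-study default
`[0, 50] µM × [0, 10] µM`).

**Boluses are persistent.**  A dose administered at time `t_d` raises a
standing input concentration that remains in effect afterwards; later
doses add to it.  This models reagents that are not washed out of the
culture.  Inputs enter the rate laws only through saturating Hill factors
`u/(u + K)`, so the standing concentration can be carried as a piecewise-
constant parameter rather than an extra state.  Dose times are integration
breakpoints: each constant-input segment is integrated separately
(`scipy.integrate.solve_ivp`, LSODA, `rtol 1e-7`, `atol 1e-9`), so boluses
are resolved exactly and trajectories before the first nonzero dose are
bitwise identical to the uncontrolled run on the same grid.

**Normalization.**  Structurally different models produce outputs on
different raw scales.  Each model's controlled output is divided by the
peak of its *uncontrolled* response (computed on a 301-point grid over
[0, 30] min) so that the uncontrolled peak is 1.  Calibration is
idempotent and invariant to rescaling the raw output map.

### The miniature three-member bank

The bank members are three deliberately different descriptions of the same
physiology — a stimulus-driven three-tier phosphorylation cascade whose
terminal phosphoprotein (a pErk analogue) is the controlled output:

* `cascade_ma` — pure mass-action with explicit phospho/unphospho pairs
  per tier (7 states; tier totals conserved by construction),
* `cascade_fb` — mass-action with an output-driven negative feedback on
  receptor desensitization and a positive feedback on tier-2 activation
  (4 states),
* `cascade_hill` — normalized Hill-type dynamics with states on [0, 1],
  the continuous homologue of a logical-model description (4 states).

The stimulus is a unit step at t = 0.  The receptor-proximal signal decays
toward a small nonzero plateau (exponential desensitization), which makes
the late response a flux balance: inhibiting the terminal *phosphatase*
(input 1) re-elevates and sustains the output even when dosed late, while
inhibiting the terminal *kinase* (input 2) cuts the phosphorylation rate
immediately, even at low doses, and overpowers simultaneous phosphatase
inhibition.  These three phenotypes are asserted by the test suite for
every member, for the dose ladders of the training design.

**Where the members agree and disagree.**  The members' cascade kinetics
are calibrated so that all three uncontrolled trajectories coincide (to
0.03 sup-norm on the normalized scale) — they describe the same
stimulation biology, exactly as a bank of published models fitted to the
same stimulation data would.  The mismatch is concentrated in the input
couplings (`phi = 1 − I_max·u/(u + K)`):

| member | I1max | K1 (µM) | I2max | K2 (µM) |
|---|---|---|---|---|
| `cascade_ma` | 0.85 | 5 | 0.95 | 3.0 |
| `cascade_fb` | 0.88 | 7 | 0.99 | 0.6 |
| `cascade_hill` | 0.85 | 6 | 0.98 | 1.2 |

The members nearly agree on the phosphatase inhibitor but disagree
five-fold on the kinase inhibitor's potency: `cascade_ma` believes large
terminal boluses are needed while `cascade_fb` expects small doses to
suffice, with the Hill member (the designated plant) in between.  A
single-model controller built on the wrong member therefore
systematically over- or under-doses the termination phase — the mismatch
axis on which dosing errors remain correctable by later boluses, unlike a
spurious kinase-inhibitor dose during a hold phase, which no later bolus
can undo under persistent-bolus semantics.  All rate constants are fixed
documented constants in `toy_bank.py`: the calibration to the common
uncontrolled phenotype was performed once while constructing the bank and
the resulting values are frozen as part of the fixture contract.

## Synthetic training experiments

The training design emulates a 14-experiment screening protocol: one
unperturbed control, five doses of input 1 (0.5, 2, 5, 20, 50 µM) at
15 min, five doses of input 2 (0.5, 1, 2, 5, 10 µM) at 6 min, and three
combinations ((0.5, 1), (50, 1), (50, 10) µM) at 6 min.

The generator simulates the designated plant through each protocol,
samples 8 raw time points per experiment by default (112 points total) —
the raw per-experiment count of the emulated protocol is not recoverable,
so it is exposed as `n_timepoints` — and adds i.i.d. Gaussian noise with
standard deviation `noise_sd × peak` of that experiment's noiseless
trajectory (error bars roughly uniform on the normalized scale; benchmark
default `noise_sd = 0.05`).

Raw time courses are smoothed with a penalized cubic smoothing spline
minimizing `p·Σ(yᵢ − s(tᵢ))² + (1 − p)·∫ s″²`, the convention under which
the default smoothing weight is `p = 0.6`, and resampled at 31 evenly
spaced times spanning the raw range.  The implementation delegates to
`scipy.interpolate.make_smoothing_spline` with `lam = (1 − p)/p`
(identical penalty); `p = 1` interpolates, `p = 0` fits the least-squares
line.  The spline requires at least five raw points.

## Akaike weight maps

For a least-squares fit with `n_j` points on output j,

    AICc = Σ_j n_j ln(RSS_j / n_j) + 2k + 2k(k+1)/(n − k − 1),  n = Σ_j n_j,

and the Akaike weights are `w_i = exp(−Δ_i/2) / Σ_r exp(−Δ_r/2)` with
`Δ_i = AICc_i − min AICc` (computed in log space; an infinite AICc maps to
weight zero).  `k` counts each member's *uncertain* parameters: for the
toy bank these are the four input-coupling constants (I1max, K1, I2max,
K2) per member — the dose-response hypotheses the maps discriminate —
while the cascade kinetics, calibrated to the common uncontrolled
phenotype, are treated as fixed.  Equal k across the bank keeps the
no-information limit flat: where the data cannot distinguish the members,
the complexity penalty does not manufacture a digital winner.

A *weight map* makes the weights queryable at any `u ∈ Ω`, not only at
tested doses.  Both the smoothed data and each model's predictions under
the 14 training protocols are extended over the (dose₁, dose₂, time) space
by piecewise-linear interpolation on a Delaunay triangulation
(`scipy.interpolate.LinearNDInterpolator`), with coordinates scaled to the
unit cube so dose and time axes are commensurate.  Simulating each model
under the experiments' own protocols (rather than on a fresh lattice)
keeps the model counterpart exactly comparable to the interpolated data —
the training design doses at 6 or 15 min depending on the reagent, so a
lattice simulation would need an arbitrary dose-time convention.  Model
predictions also pass through the identical smoothing pipeline as the
data (sampled at the raw experiment times, smoothed with the same spline,
resampled on the same grid): the spline's systematic rounding of
post-bolus transients then cancels in the residuals, so with noise-free
plant-generated data the plant member's residuals vanish and its weight
reaches 1 at every training dose — the model-identification property the
construction is required to have.  Queries
outside the convex hull of the support clamp to the nearest support point
(flagged internally as extrapolation), so the map is total on Ω; queries
that land exactly on a hull facet are nudged toward the support centroid
before clamping.

At a query `u` the per-model residual sum of squares is computed between
the data surface and the model surface along the 31-point time grid,
converted to a mean squared residual, and scaled by the dataset's raw
point count `n_total` before entering the AICc: the criterion's sharpness
then grows with the amount of training data (the "digital map" large-n
regime), and the expression reduces to the standard least-squares AICc
when the comparison grid equals the raw grid.

Recalibration during control queries the map at the proposed dose over
the **whole time course** by default: the "portion of the training data
corresponding to the input" is local in input space (that is what the
interpolation at u provides), not in time.  A time-windowed mode —
restricting the comparison to grid times inside `[t_k, t_k + Δt]` and
scaling `n_total` by the window fraction — is also implemented
(`RunConfig.windowed_weights`); it makes the effective sample size per
query small enough (~20 points for a 5-min window) that the AICc
small-sample penalty, rather than fit, can decide near-tie regions, so it
is not the default.

Two limits anchor the construction and are asserted in the tests: with no
informative data (identical models) the weight surface is flat at 1/n_M,
and with noise-free plant-generated data the plant member's weight exceeds
0.99 at every training dose.

## Sparse-grid surrogates

Objective surfaces are interpolated on nested, boundary-including sparse
grids with piecewise-multilinear hierarchical basis functions.  In one
dimension, level 0 contributes the midpoint with a constant basis, level 1
the two boundary points, and level l ≥ 2 the odd multiples of `2^−l`;
every basis function is `max(1 − w·|x − node|, 0)` with `w = 0, 2, 2^l`
respectively.  The d-dimensional grid at depth n is the union of tensor
products over level vectors with total level ≤ n.  Hierarchical surpluses
(function value minus coarser-interpolant value at the new node) are the
coefficients; the maximum absolute surplus on the newest level is the
error estimate, taken relative to the observed function range for the
relative criterion.  Refinement stops when the estimate meets the absolute
(default 0.01) or relative (default 1%) tolerance or the depth limit
(default 6) is reached — the classical surplus heuristic; linear functions
are reproduced exactly by depth 2 and constants stop at depth 1 with zero
estimated error.

Surrogate use is optional: the controller accepts direct-evaluation
callables with the identical contract, and the tests assert that the
surrogate's lattice argmin agrees with direct ODE evaluation to one
lattice cell on the toy bank.

## The tracking objective

For model i, interval `[t_k, t_k + H_p·Δt]` and candidate doses `U_k`,

    J_i = Σ_m (ẑ(t_m) − r(t_m))ᵀ Q (ẑ(t_m) − r(t_m)) + Σ (u/u_scale)ᵀ R (u/u_scale),

summed over 1-min samples of the horizon, returned as `ln(J + ε)` with
`ε = 1e-2` — log-space compression flattens the cost surface, and the
offset both keeps perfect tracking finite and sets the resolution floor
of the compression: ε equals the squared error that 5% observation noise
induces over a 5-sample horizon, so predicted improvements smaller than
the training data's own noise floor are flattened rather than amplified.
(With a tiny offset the log transform magnifies sub-noise differences and
controllers chase them with small persistent kinase-inhibitor doses that
are irreversible on hold-type targets.)  `Q = R = I` and `H_u = H_p = 1` interval
(a longer horizon makes the controllers overly conservative; boluses
persist anyway, so a committed dose keeps acting).  `u_scale` defaults to
ones in the library function; the controller sets it to the input-space
upper bounds so that a full dose of either reagent carries unit effort —
with raw µM inputs, a 50 µM dose would otherwise cost 2500 error units and
no dosing would ever be worthwhile on the unit-normalized output scale.

Target trajectories follow
`r(t) = (1 − e^{−t/τ_r}) · [p_ss + (1 − p_ss)/(1 + e^{(t − t_off)/τ_f})]`
with `τ_r = τ_f = 1` min: rapid activation, hold near 1, settle to the
fraction `p_ss` beginning at `t_off`.  The ten case-study pairs
{(8, 0), (15, 0), (22, 0), (8, .25), (15, .25), (22, .25), (8, .5),
(15, .5), (22, .5), (30, 1)} ship as a preset.

## Pareto set generation (normalized normal constraint)

Each interval poses one objective per model.  Anchor points are found by
bound-constrained multistart minimization (box center and corners, 5
starts, L-BFGS-B); the objective space is normalized so each anchor maps
its own objective to 0 and the worst anchor value per objective to 1.
Evenly distributed points on the utopia hyperplane (convex combinations of
the normalized anchors; 15 per interval by default) each define a scalar
subproblem: minimize the last normalized objective subject to Ω and
half-space constraints normal to the utopia-plane directions (SLSQP, warm
started from the previous front point, the anchors, and a 7×7 lattice
prescreen).  A Pareto filter removes dominated points and duplicates
(tolerance 1e-6 in normalized space).

Degenerate fronts are handled explicitly: when the per-model objectives
are nearly identical (late intervals of settled targets) the normalization
magnifies a sliver-thin front and every subproblem may fail; the anchors
themselves are then returned as the (single-point or near-single-point)
Pareto set.  Subproblem feasibility is judged on the constraint values at
the returned point rather than the optimizer's success flag, which SLSQP
under-reports on kinked piecewise-linear surrogate surfaces.

## Adaptive input selection

The interval's dose is the Pareto point minimizing `ωᵀJ` (log-space
objective vector, Akaike weight vector; deterministic lexicographic
tie-break on the input vector).  Because ω depends on the proposed input,
selection iterates: rank under the current weights, recalibrate
`ω ← ω(u)` from the weight map at the winner, and repeat until neither the input (tolerance
Ω-range/100) nor the weights (tolerance 1e-3) move, up to 10 iterations.
An input revisited from an earlier iteration indicates a limit cycle; the
weight vectors over one cycle period are averaged and the ranking is
recomputed once as the tie-break.  At the first interval the initial
weights come from the entire training set (per-model RSS against all 14
smoothed experiments, no interpolation); later intervals start from the
previous interval's final weights.

The equal-weight controller (`M_eq`) is the same machinery with ω fixed at
1/n_M and adaptation disabled.  Single-model controllers (`S_i`) minimize
that model's objective directly over Ω (no Pareto stage).

## The open-loop control loop and benchmark

Five dosing intervals at {3, 8, 13, 18, 23} min span the 30-min
experiment; the final interval's prediction horizon extends to 30 min so
the whole experiment is scored.  Per interval: build per-model objective
surrogates from each
model's own current state, run the NNC sweep, select the dose, advance
*every* model's state under the chosen bolus, append to U*.  The finished
U* is applied to the plant (1-min evaluation grid; squared error against
the target; observation noise off by default, as the in silico studies
use deterministic plants).

The benchmark rotates the plant over the three members.  For each plant,
training data are generated from that plant (noise 5%, 8 raw points per
experiment) and a weight map is trained for the remaining two members;
each of the ten targets is then controlled by `S_matched` (the plant
itself — unrealizable in practice, kept for reference), both
`S_mismatched` members, `M_eq` and `M_aw`, giving 30/60/30/30
scenario-runs per class.  Summaries report mean ± standard error per
class and percent reductions of `M_aw` against each comparator; ANOVA-
style group testing is deliberately left to the user's statistics tooling.
The weight-map sensitivity analysis retrains maps on a full (31 raw
points/experiment) and a limited (10/experiment) dataset and reports the
fraction of an 11×11 input lattice at which the model *ranking* agrees,
plus dose differences of the regimens designed under either map.

## Problem sizes and runtimes

The full sweep (3 plants × 10 targets × 5 controller runs, 5 intervals
each, NNC with 15 points) completes in roughly 8–12 minutes on one CPU;
a single adaptive run takes a few seconds.  These sizes — 8 raw points
per training experiment, depth-6 objective grids, 15 Pareto points — are
the package defaults chosen to keep a full comparison interactive while
leaving every algorithmic setting at its documented value.

## Known limitations

* The generator emulates protocol structure and noise scale, not real
  Western-blot artifacts (saturation, loading normalization, replicate
  correlation); passing tests show the machinery identifies and exploits
  model-fit structure, not that it would rank real models correctly.
* With abundant data the weight maps are nearly digital (winner-take-all),
  so `M_aw` mostly *switches* between members rather than blending them;
  smoother blending appears only with scarcer data.
* The one-interval horizon is myopic: when a plant's output can only be
  prevented from decaying (not re-elevated), a truthful model can be
  out-scored by an alarmist one that doses earlier.  The receptor plateau
  in the toy bank keeps control bidirectional precisely to avoid rewarding
  model error systematically.
* Open-loop by design: no measurement feedback during execution; weight
  adaptation uses only pre-existing training data.
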