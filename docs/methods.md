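# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data tests do and do not establish.

## Coordinate conventions

All positions live in a fixed right-handed *site frame*: X is the horizontal
projection of the mean downhill (fall-line) direction, Y across the slope,
Z up. Time is seconds from run start. The *lean plane* at a sample is the
vertical plane containing the horizontal left-of-travel direction
n̂ = ẑ × v̂_h; the signed lean angle θ is positive when the body axis tilts
toward +n̂ (a left turn leans left). Radial acceleration a_r is the
component of horizontal acceleration along n̂, so its sign alternates across
linked turns.

## Inverted-pendulum model

The skier is one rigid bar pivoting at the snow contact G, with the COM at
k·l and the antenna at l along the bar (k = COM height fraction, default
0.56, 0.57 female / 0.55 male; l is found from terrain intersection, not
assumed). The bar is unactuated (driving torque zero) with a point mass at
the COM, so mass cancels and dynamic balance reads

    l_g·θ̈ + a_r·cos θ − (a_z + g)·sin θ = 0,      l_g = k·l.

**Closed-form solution.** Substituting t = tan(θ/2) gives the quadratic
(l_g·θ̈ − a_r)·t² − 2(a_z+g)·t + (l_g·θ̈ + a_r) = 0. Both roots solve the
balance equation; the physical branch is the one with |θ| < π/2. Roots are
computed with the numerically stable quadratic formula; a guaranteed upright
root exists whenever |l_g·θ̈| < a_z + g (sign change of the residual over
the upright range). Outside that region the estimator substitutes the
quasi-static lean atan2(a_r, a_z+g), clipped to ±(π/2 − 0.05) — such samples
only occur on data that violate the balanced-bar model.

**Antenna→COM acceleration transfer.** With COM = antenna − (1−k)·l·u(θ),
differentiating twice in the lean plane gives

    a_com = a_antenna − (1−k)·[(l̈ − l·θ̇²)·u + (l·θ̈ + 2·l̇·θ̇)·w],

u = (sin θ, cos θ), w = (cos θ, −sin θ). The radial (−θ̇²), tangential (θ̈)
and extension/Coriolis (l̈, 2·l̇·θ̇) terms are validated against central
second finite differences of exactly placed antenna/COM points (< 1e-3 m/s²
at 120 Hz). Rotation of the lean plane itself (heading rate ~0.6 rad/s)
contributes ~0.2 m/s² and is neglected; on balanced synthetic runs this
costs under a centimetre of COM accuracy.

**Kalman smoothing of θ.** State [θ, θ̇, θ̈] with a white-jerk process
(spectral density q) and position-only measurements (variance r); forward
filter plus Rauch–Tung–Striebel backward pass (offline smoothing, matching
the batch setting). Estimator defaults q = 10, r = 1e-2 put the smoother
bandwidth (q/r)^{1/6} ≈ 3.2 rad/s just below the pendulum's natural
frequency √(g/l_g) ≈ 3.5 rad/s: faster lean modes cannot be balanced and
only destabilize the fixed point. Both θ and the length series l get the
same smoother. Before smoothing, series are extended by quadratic
extrapolation (the smoother's own constant-acceleration continuation) so
the edges carry no one-sided bias.

**Band-limited differentiation.** All second derivatives that either feed
the balance equation or feed back on itself pass through a shared zero-phase
Butterworth low-pass (order 2, 0.9 Hz cutoff, quadratic-extrapolation
padding; `skipose.filtering`). Sample-scale error modes otherwise see a
feedback gain of order l_g/(g·dt²) ≈ 10³ per iteration at 120 Hz — the
fixed point is unconditionally unstable without a band limit. The cutoff
sits 3–4× above the turn rhythm (~0.25 Hz), keeping the bias on the
physical signal below one percent. A side benefit: the estimator needs no
separate pre-smoothing for RTK-level GNSS noise (an optional Savitzky–Golay
window remains available via `smooth_window_s`).

**Fixed-point loop.** (i) antenna accelerations and n̂ from the
(band-limited) track, outermost 4 samples held at the nearest interior
value; (ii) COM accelerations initialised to antenna accelerations; then
repeat (iii) closed-form θ (θ̈ damped into the solvable region, lean capped
at 65°), (iv) pendulum length from the lean-ray/mesh intersection,
(v) Kalman θ̇/θ̈, (vi) acceleration transfer — until max|Δθ| < 1e-3 rad
(default) or 20 iterations. Convergence takes 4–9 iterations on synthetic
runs; non-convergence is reported, not raised, with the residual history.

## Query features

The learned models consume (a_r, v, α): radial acceleration v_h²/r with r
the circumradius of three adjacent horizontally projected samples (collinear
→ ∞, a_r → 0) and the sign of (v⃗_h × a⃗_h)_z; absolute speed |dp/dt|; and
the skiing angle α = atan2(v·e_y, v·e_x) of the tangent-plane-projected
velocity, measured from the projected fall-line axis. a_r is computed as
v²/r — the product of angular velocity and radius alone would be a
velocity, not an acceleration.

## Learned pose models

Both map the query to the 9-D relative pose (COM, left ski, right ski
offsets from the antenna); adding the antenna track back gives absolute
trajectories. Inputs and outputs are z-scored internally.

**Locally weighted regression.** Gaussian receptive fields
w(x) = exp(−½(x−c)ᵀD(x−c)) with a *fixed* metric D (no online metric
adaptation, no PLS projections — with a 3-D query, projections add
nothing). Field centers are created in one deterministic temporal-order
pass wherever no existing field activates above w_gen = 0.2; each local
ridge-regularised linear model then accumulates the full training set
(identical, via sufficient statistics, to running the weighted recursive
least-squares update over every point — and immune to the data starvation
a strictly single-pass update inflicts on late-created fields). Default
D = 10·I in standardized units ≈ 0.1·I on raw query scales (features are
O(10) in their natural units); on a default synthetic run this yields ~55
local models. Ridge λ = 1e-9 is a numerical guard only — λ = 1e-6 already
biases local slopes visibly (~1e-4 relative). Prediction is the
activation-weighted convex blend of local models (cutoff 1e-4); queries
activating nothing fall back to the nearest field and are flagged as
extrapolation.

**Backprop network.** tanh hidden layers (default one layer of 30 units),
identity output, MSE loss, seeded uniform ±1/√fan_in initialisation,
mini-batch (32) gradient descent at lr = 1e-2, default 300 epochs.
Gradients are verified against central finite differences (< 1e-5 relative
error). Plain SGD on tanh nets plateaus a few percent of output SD above
the representational optimum for quasi-linear targets; this is accepted in
favour of a simple, fully deterministic trainer.

## Synthetic world

The generator builds a world in which the pendulum's assumptions hold
exactly, so estimators are validated by parameter recovery.

* **Course**: inclined plane with pitch atan(drop/length) (defaults
  350 m / 99 m ≈ 15.8°), 12 gates at equal along-slope intervals with
  alternating ±4 m lateral offsets. The ground path through uniformly
  spaced alternating gates is the cosine interpolant — the C^∞ choice;
  piecewise-polynomial paths put jerk jumps at the gates that the balance
  equation cannot absorb. Speed follows a smooth exponential saturation
  from 8 toward 16 m/s with initial slope 1.2 m/s² (a hard clip would kink
  the acceleration). Peak turn values: radius ≈ 26 m, a_r ≈ 9–10 m/s²,
  lean ≈ 35°.
* **Balanced skier**: the lean series is the fixed point of the balance
  equation evaluated with the COM path's own accelerations, iterated with
  relaxation 0.4 through the shared band-limited differentiator to
  max|Δθ| < 1e-10. The residual invariant (< 1e-8 at interior samples) is
  *operator-consistent*: `run_balance_residual` recomputes θ, l from the
  emitted geometry and differentiates with the same operator. Any honest
  independent discretization agrees to ~1e-4 at 120 Hz, which is the
  level at which the estimator (with its own operators) can exploit it.
* **Geometry**: antenna = G + l·u, COM = G + k·l·u (defaults l = 1.40 m,
  k = 0.56 — a crouched skier's along-axis neck-antenna distance), skis at
  ±stance/2 (0.30 m) across the direction of travel on the mesh.
* **Styles** (unbalanced subjects): constant lean bias (|bias| ∈
  [0.03, 0.08] rad), fore-aft COM offset along travel ([0.05, 0.12] m) and
  lean-synchronised flexion of l ([0.08, 0.20] m). Draws are bounded away
  from zero because the cross-validation experiments presume visibly
  distinct techniques; runs of one skier differ by small speed-profile
  jitter (σ ≈ 0.3–0.5 m/s).
* **GNSS degradation**: decimation to 20 Hz plus i.i.d. Gaussian noise,
  σ_h = 3.5 mm per horizontal axis and σ_v = 8 mm (95 % error bounds of
  7/16 mm read as ≈ 2σ).

**What a green test does not establish.** The synthetic world is noiseless
at 120 Hz, rigidly geometric, planar-sloped, and its "subjects" differ by
three constant style parameters. Real skiers flex dynamically, terrain is
rough, and GNSS drops out; cross-subject error levels measured here
(diagonal cells of a few millimetres) are therefore much smaller than
field-campaign values and only the *structure* of the comparison — COM
easier than skis, own-subject models best, learned models beating the
style-blind pendulum — transfers.

## Evaluation protocol

Errors are per-sample 3-D Euclidean distances; the pendulum's single ground
point is scored against the mid-point of the two reference skis (weight
equally distributed). For aggregation, each run is resampled by linear
interpolation onto 200 equally spaced values of the path fraction
s ∈ [0, 1], defined by cumulative *horizontal arc length* (a duration-based
grid is available; the two coincide at constant speed), then averaged
pointwise across runs. Cross-validation trains one model per skier on all
of that skier's runs and scores every model on every run; cells report mean
(SD) over all samples of the run. The paired t-test on method comparisons
uses only the off-diagonal cells (models applied to other skiers' runs; 72
cases for 18 runs × 5 models), t = mean(d)/(sd(d)/√n) with df = n−1,
two-sided p; degenerate inputs: all-equal pairs → t = 0, p = 1;
zero-variance nonzero-mean differences → p = 0.

## Known limitations

* The pendulum transfer neglects lean-plane rotation terms (~2 % of a_r).
* The estimator's outermost ~0.5 s carries mildly elevated error (one-sided
  information); padding mitigates but cannot remove it.
* The LWPR variant has no metric adaptation, forgetting, or confidence
  bounds; the network has no regularisation or architecture search.
* Upper-body pose is out of scope throughout; the models output COM and ski
  points only.
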