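# Methods

## The circular resetting model

The clock is a phase point on the unit circle. A stimulus is a rigid
displacement F·e^{iΦ} of the complex state; the post-stimulus phase is
the argument of the displaced state and the PRC is the wrapped
difference g(θ₁) = θ₂ − θ₁. The model's assumptions are: (i) the limit
cycle is circular with radius 1, (ii) relaxation back to the cycle is
instantaneous and radial, so only the angle of the displaced state
matters, and (iii) the displacement is phase-independent in magnitude
and direction. Under these assumptions the map θ₁ → θ₂ winds once
around the circle for F < 1 (continuous, type-1 PRC) and zero times for
F > 1 (discontinuous, type-0 PRC); at F = 1 the state antipodal to Φ
lands on the origin, where phase is undefined (the singular point).

Conventions: phases live on [0, 2π) (two-argument arctangent, branch
mapped up), shifts on (−π, π] — a half-cycle shift is reported as the
maximal advance +π, consistent with advance/delay symmetry. Circadian
time is CT = θ·24/2π. A post-stimulus state with magnitude below
`tol_singular` = 1e−9 limit-cycle radii raises a singularity error; the
threshold is an implementation choice (the singular input is
measure-zero, so any small tolerance only catches deliberate hits).

PRC type is decided by the winding number — the sum of wrapped
successive differences of θ₂ around the closed phase circle, divided by
2π — rather than by jump detection, because winding is a topological
quantity robust to sampling density. A winding sum farther than 0.25
from every integer signals aliasing (undersampling) and is rejected
rather than rounded.

## SR estimation

Three estimators of the order parameter R·e^{iΘ}:

1. **Quadrature over a PRC** — equal-weight mean of e^{i(θ+g(θ))} at
   uniform phase nodes. The integrand is smooth and periodic for F ≠ 1,
   so the trapezoid-type rule converges spectrally; the historical
   100-node choice is already accurate away from F ≈ 1, but the package
   defaults to 10⁴ nodes in the forward/inverse amplitude maps, where
   the F ≈ 1 region matters. Fewer than 16 nodes emits an
   undersampling warning.
2. **Complex mean over single-cell records** — valid when pre-stimulus
   phases are approximately uniform (the measurement condition for SR);
   the resultant length of N unit vectors has standard error ≲ 1/√N.
3. **Bulk time series** — detrend, cosine-fit, read off amplitude and
   acrophase (below).

When the resultant length falls below `theta_report_floor` = 0.02 the
phase is reported as undefined: the argument of a near-zero mean is
noise.

### Detrending and cosine fitting

Raw luminescence l_j is converted to relative deviation from its
centered 24-h moving average, L_j = (l_j − l̄_j)/l̄_j, with l̄ the boxcar
mean over 2n+1 samples (n = 72 at 10-min sampling — the count of
samples in a 12-h half-window). Points without a complete window are
dropped, not computed from shrunken windows; this costs 12 h at each
end but removes boundary bias, and the post-stimulus fit window is
interior by construction. The 24-h boxcar annihilates the 24-h harmonic
exactly, so the rhythm of interest passes through to L undistorted.

The post-stimulus window (default 24–48 h after the stimulus;
slower tissues may use 24–96 h) is fitted with
baseline + A·cos(2π(t−t_stim)/T + φ) by least squares. With T fixed at
24 h the fit is linear in a cos/sin basis and solved exactly; with T
free (bounded to [20, 28] h) a bounded nonlinear fit (lmfit) is
initialized from the fixed-period solution. Negative amplitudes are
folded into the phase. The SR phase Θ is the acrophase φ referenced to
the stimulus time — i.e. the fitted cosine back-extrapolated to the
moment of stimulation at its own period — and is also reported in CT
hours. A window whose variance is below the noise floor is rejected as
degenerate rather than fitted.

### Same-plate corrections

Bulk amplitudes are on an arbitrary reporter scale and a plate that is
not perfectly desynchronized carries residual collective rhythm through
the stimulus. `measure_sr`/`measure_plate_sr` therefore support two
corrections, both standard practice and both optional: vector
subtraction of a vehicle-control well's fitted cosine (removes the
residual-synchrony component, which otherwise inflates or distorts weak
responses), and division by a maximal-response reference amplitude
(places R on the [0, 1] SR scale, the same role the normalization of
dose-response curves by their maximum plays). Raw amplitude, control
difference and reference ratio are all emitted.

## Forward map and PRC reconstruction

R(F) is strictly increasing, zero at F = 0, and approaches 1
asymptotically (every post-stimulus phase collapses onto Φ), so the map
is invertible on [0, R(F_max)). Inversion is by Brent bracketing on
[0, F_max = 10³] — the monotone map makes the root unique, and
bracketing is derivative-free and deterministic; the squared-error
objective at the solution is available for comparison with
gradient-descent style fits. A measured (R, Θ) reconstructs a full PRC
as generate_prc(invert(R), Θ); the round trip PRC → SR → PRC is
identity up to quadrature error (< 10⁻² rad across F ∈ [0.2, 3] in the
test suite). Requested amplitudes at or above the ceiling R(F_max)
raise an out-of-range error carrying the achievable ceiling.

## Dose response

SR amplitude vs. concentration is fitted with the Hill function
H(x) = xⁿ/(xⁿ + EC₅₀ⁿ). EC₅₀ is fitted in log₁₀ space (bounds: the
observed dose range widened 100-fold each way) and n on (0, 10], by
bounded trust-region least squares from a multi-start grid — a
single-start descent on this surface is fragile when n is small.
Zero-dose rows are excluded from the least squares (H(0) = 0 exactly;
vehicle controls are for comparison) and an explicit per-row exclusion
mask mirrors the manual exclusion of cytotoxic doses. A mean response
that drops more than 20% below its running maximum at higher dose sets
a non-monotone flag (the Hill model is then suspect, e.g. oxidative
stimuli that kill cells at high dose). Tables on an arbitrary scale are
first normalized by the largest per-concentration mean — means, not raw
replicates, so one noisy point cannot set the ceiling — and the ceiling
r_max is retained to map predictions back. Goodness of fit is the
ordinary coefficient of determination. By default the fit uses raw
replicate points; a per-concentration-mean option exists because
published fits do not always say which was used.

The SR phase is modeled as a straight line Θ = a + b·R over the
amplitude range where phase is defined. Phases are unwrapped around
their circular mean before ordinary least squares — a cluster
straddling 0/2π must not produce an artificial 2π jump — and a spread
exceeding π after unwrapping is rejected as wrap-ambiguous instead of
silently fitted. Circular regression was deliberately not used: the
empirical relationship is a straight line over a modest arc, and the
wrap guard catches the failure mode.

`predict_sr_at_dose` composes the two fits (R = r_max·H(x),
Θ = a + b·R) and chains into PRC reconstruction, so four parameters
(EC₅₀, n, a, b) predict the complete phase response at any dose.

## Combination rules

* **Different pathways**: complex sum of the SRs. The reported
  amplitude is capped at 1 (an order parameter cannot exceed 1) with a
  flag; the phase always comes from the uncapped sum, and the uncapped
  sum is retained for later subtraction, with a cap-bias warning when
  it matters.
* **Same pathway**: each amplitude is converted to its equivalent
  concentration x_eq = EC₅₀·(R/(1−R))^{1/n} (closed-form Hill inverse;
  amplitudes within 10⁻⁶ of saturation raise a saturated error), the
  doses add, and the combined amplitude is H(x_eq,A + x_eq,B). This is
  strictly subadditive, unlike the vector sum, and is exact when the
  two stimuli genuinely share one saturating pathway.
* **Background (pre-treatment), same pathway**:
  R_ADD = H(d·x_BK + x_ADD) − H(d·x_BK), where d ∈ (0, 1] is a
  multiplicative decay of the background concentration between the two
  treatments (presets: 1, 1/2, 1/3; the factor is stimulus-specific and
  defaults to no decay). The attenuation is monotone in x_BK for
  n ≤ 1 — the experimentally observed slope range; for n > 1 the model
  itself predicts a facilitation regime below the EC₅₀, so the
  monotonicity property is only asserted on n ≤ 1.
* **Background, different pathway**: vector subtraction of the
  background SR from the final SR returns the added stimulus's own SR
  unchanged — a different-pathway background has no effect.
* **Antagonist**: when the final response falls below the background
  response, the added compound's SR amplitude is the drop
  R_BK − R_final and its phase is opposite (+π) the reset phase of the
  inhibited target.

Phase prediction for same-pathway and background combinations requires
an explicit phase-amplitude line argument; lines are fitted per
stimulus and tissue, and silently reusing one across conditions would
be wrong, so there is no default.

## Stuart-Landau simulator

Each oscillator follows dR/dt = α(A − R²)R, dθ/dt = σ_i, i.e. the
zero-shear normal form of a Hopf bifurcation: radial relaxation to the
circular cycle of radius √A at rate α plus uniform rotation. Defaults
A = 1, σ_i = 2π/24 rad/h. The radial equation is logistic in u = R² and
is propagated by its closed form (written with decaying exponentials so
it is stable for arbitrarily large α·t); trajectories carry no
integrator error, and R = 0 — the unstable fixed point — propagates
exactly. Only this zero-shear branch is implemented; the general form
with radial-angular coupling is out of scope.

α is not fixed by the underlying experiments; the default is 1 h⁻¹
(relaxation fast relative to the 24-h cycle but not instantaneous), and
it is a visible knob because relaxation speed is the model's key
caveat: in the fast-relaxation limit the simulated SR reproduces the
circular-model quadrature to < 0.02, while slow relaxation (α ≲ 0.05)
biases the measured amplitude — both regimes are exercised in the
tests. Note the limit-cycle radius is √A (the fixed point of the radial
equation); descriptions of A itself as the cycle amplitude only
coincide with this at A = 1, which is the configuration used
throughout.

A stimulus displaces every oscillator's complex state by F·e^{iΦ}; an
oscillator landing exactly at the origin has no defined angle and is
re-randomized with a warning (at radius zero the angle is
inconsequential until the next perturbation). The collective output is
mean_j R_j·cos θ_j, the in-silico analogue of bulk bioluminescence.
`simulate_sr` applies the stimulus to 100 uniformly phased on-cycle
oscillators, samples the collective output every 10 min, and
cosine-fits the 24–48 h window — the same measurement applied to real
traces.

### Synthetic plate generator

`generate_plate` emulates a one-week plate recording: per-well
luminescence

    l(t) = b₀·e^{−kt} · (1 + c·mean_j R_j cos θ_j) + ε,

with an exponentially decaying baseline (b₀ = 1000 counts,
k = 0.005 h⁻¹), relative rhythm amplitude c = 0.5, additive Gaussian
counting noise (σ = 5 counts), 10-min sampling, 168-h duration and the
stimulus at 96 h. Wells start fully synchronized and desynchronize
spontaneously through per-oscillator period heterogeneity: periods are
drawn once per well from a normal law with SD 2 h around 24 h (clipped
to [12, 48] h against absurd tails). Under Gaussian dephasing the
collective envelope is exp(−σ_ω²t²/2) with σ_ω = 2πσ_T/T²; SD = 2 h
puts the envelope at ≈ 11% of its initial value at the 96-h stimulus —
a genuinely desynchronized plate — and sits within the measured
single-cell period dispersion of cultured fibroblasts (≈ 1.5–2.5 h).
An SD of 1 h would leave ≈ 58% of the initial coherence at
stimulation, which contradicts the desynchronized-state premise of the
SR measurement. All randomness derives from the protocol seed
(per-well child seeds), identical protocols are bit-reproducible, and
a ground-truth record (programmed F, Φ, forward-map-predicted R) is
emitted beside every plate.

What the generator does *not* emulate: stochastic phase diffusion
(desynchronization here is purely deterministic frequency dispersion),
cell division and death, multiplicative/photon-counting noise
statistics, spatial coupling (SCN-like networks), and drifts in the
baseline other than a single exponential. Consequences observed while
validating: frequency heterogeneity correlates each oscillator's phase
at stimulation with its frequency, so a weakly stimulated well retains
an echo of its pre-stimulus order that decays differently from freshly
imprinted synchrony. Pure maximum-normalization then underestimates
weak responses by ≈ 15% (infinite-N calculation); vector subtraction of
the vehicle-control well reduces the residual bias to ≈ 5%. Passing
recovery tests therefore demonstrate the estimator pipeline under this
specific nuisance model, not robustness to every noise structure in
real recordings.

## Numerical choices and degenerate inputs

* Quadrature nodes on the singular point (possible only at F = 1 on an
  even grid antipodal to Φ): the grid is shifted by half a step and a
  warning is logged; the perturbed curve represents the same stimulus.
* Inversion tolerance 10⁻⁶ on R; forward-map ceiling reported when a
  target is unreachable.
* Cosine-fit degenerate window: variance below 10⁻⁸ raises rather than
  returning a meaningless zero-amplitude fit.
* Detrending rejects a series when more than 5% of moving-average
  points are nonpositive; isolated nonpositive points become NaN and
  are excluded from fits.
* Hill fit: multi-start over a 5×4 (log EC₅₀ × n) grid; ties broken by
  lowest residual cost.
* Plate-generator luminescence is clipped at zero (with a warning) —
  photon counts cannot be negative.

## Problem sizes used in the validation suite

Model-level checks run at 10⁴ quadrature nodes and 200–1000 phase
samples. Simulation-based recovery studies use 200–2000 oscillators per
well, 3–20 seeded replicates, and single plates of 3–6 wells; these
sizes keep the full suite in the tens of seconds while leaving
Monte-Carlo error well below the tolerances being asserted. The
acceptance script runs only deterministic model-level computations and
completes in seconds.

## Known limitations

* The circular, instantaneous-relaxation PRC model is specific to
  circadian-like oscillators; systems with strongly non-sinusoidal PRCs
  (integrate-and-fire neurons) have well-defined SRs but would need a
  different forward model for PRC reconstruction.
* The phase-amplitude line is an empirical local model; extrapolating
  it beyond the fitted amplitude range is unguarded beyond a recorded
  validity range.
* Equivalent-concentration combination assumes a single shared
  saturating pathway; partially overlapping pathways fall between the
  two rules and are not modeled.
* The cap at 1 on vector-sum amplitudes, followed by subtraction,
  is order-dependent; the package subtracts on the uncapped sum and
  warns, but chained capped combinations remain approximate.
* Non-competitive antagonism and pharmacokinetics beyond a single
  multiplicative background decay are out of scope.
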