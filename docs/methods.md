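# Methods

## Model

Each brain region is an exact macroscopic reduction of an infinite
network of all-to-all pulse-coupled quadratic integrate-and-fire (QIF)
neurons whose excitabilities follow a Lorentzian distribution of centre
eta_bar and half-width-at-half-maximum Delta. The reduction (an
Ott-Antonsen-type low-dimensional ansatz) closes exactly on two
variables per region — the instantaneous population rate r_k and the
mean membrane potential v_k:

    tau_m dr_k/dt = Delta / (tau_m * pi) + 2 r_k v_k
    tau_m dv_k/dt = v_k^2 + eta_bar(k) + I_B + I_S^(k)(t)
                    - (pi tau_m r_k)^2 + tau_m sum_l J_kl r_l

Internal units are milliseconds for time and 1/ms for rates; voltages
and currents are dimensionless. Rates are converted to Hz only at I/O
boundaries, which keeps the equations literal with tau_m = 20 ms and
puts spectrogram frequency axes in Hz.

The coupling matrix is built from a structural connectome Jt normalized
to [0, 1] with zero diagonal (diagonal zeroed first, then division by
the maximal remaining entry — the only reading consistent with imposing
Jt_kk = 0): J_kk = 20 sigma (recurrent intra-region synapses) and
J_kl = 5 sigma Jt_kl between regions. Two presets mirror the cohorts
the pipeline is designed around: `healthy` (90 regions, sigma = 1) and
`patient` (88 regions, sigma = 1.25, default eta_bar = -7.5).

A single region with J_self = 20, Delta = 1 has one to three equilibria,
found as the positive real roots of

    -pi^2 tau^2 r^4 + J_self tau r^3 + (eta_bar + I) r^2
        + Delta^2/(4 pi^2 tau^2) = 0

(companion-matrix roots; |imag| < 1e-9 and r > 1e-12 accepted;
near-double roots carry a degeneracy flag). The window of bistability
for these parameters is eta_bar in (-10.16, -3.90): a low-activity (LA)
stable node, a saddle, and a high-activity (HA) stable focus approached
through damped oscillations. Stability is read off the 2x2 Jacobian;
eigenvalues with zero real part are labelled "degenerate" rather than
guessed. In the phase diagram a single equilibrium counts as
high-activity only when it is an *underdamped* focus
(|Im lambda| > |Re lambda|): at weak coupling the low-rate equilibrium
is formally a focus with a negligible imaginary part and belongs to the
LA region.

The model has only fixed points as attractors: a "seizure-like event"
is a stimulus-triggered transition of one or more regions from LA to HA
with damped macroscopic ringing, not a limit cycle. Synaptic kinetics,
delays, gap junctions, plasticity and noise terms are out of scope.

## Numerics

**Network integration** is explicit fixed-step RK4 with default
dt = 0.01 ms. The HA focus rings at several hundred Hz; this step keeps
at least ~40 steps per fastest period, and halving dt changes LA-regime
endpoints by < 1e-8 (tested). The rectangular stimulus is constant
within a step; pulse edges land on the step grid. Divergence raises an
error naming the blow-up time. Rate positivity is automatic
(dr/dt = Delta/(pi tau^2) > 0 at r = 0).

**Microscopic QIF oracle.** The finite-N simulator advances each
membrane with the closed-form solution of tau dV/dt = V^2 + c between
synaptic kicks (c constant per step): for c > 0 the phase
atan(V/sqrt(c)) advances linearly and every wrap through pi/2 is a
spike with the ideal infinite threshold and reset; for c < 0 the
corresponding hyperbolic quantity decays linearly. Each presynaptic
spike increments every *other* membrane by J/N (no autapses) once per
step, so dt only discretises kick timing, not the membrane flow. A
plain Euler scheme with finite threshold V_p = 100, two-phase hold
(+V_p then -V_p for tau/V_p each, restoring the ideal neuron's travel
time beyond the threshold) is retained as an independent cross-check;
it needs far smaller dt for the same accuracy, which is why the exact
map is the default.

Population measures: the rate is the spike count per 1-ms bin / (N x
bin), smoothed with a 10-ms rectangular kernel. The mean voltage is
estimated two ways — the mean of V clipped to [-V_p, V_p] (a
principal-value surrogate for the heavy-tailed Lorentzian voltage
distribution) and the per-bin sample median, which estimates the
distribution's centre directly and is the default: the clipped mean
carries an O(width/V_p) truncation bias plus large finite-N noise.

Excitabilities are sampled either as deterministic Lorentzian quantiles
(eta_i = eta_bar + Delta tan(pi (2i - N - 1)/(2(N + 1)))) or i.i.d.
Cauchy with a seed; microscopic runs are initialised on a chosen
macroscopic branch by Lorentzian-quantile voltage samples (centre v*,
width pi tau r*), shuffled to decorrelate them from the sorted
excitability samples.

**Exactness, and one honest caveat.** With N = 10,000 neurons and
deterministic sampling the time-averaged rate matches the mean-field
fixed point to 0.3-4% in every regime, and the voltage to 0-3% at LA
states and at weakly coupled foci; errors shrink as N grows. At a
*strongly coupled* HA focus (J_self = 20) the time-averaged voltage
retains a ~10% relative bias at N = 10,000: delta-spike shot noise
(common input of variance ~ J^2 r / N) continuously re-excites the
weakly damped focus (Re lambda = 2 v*/tau with v* ~ -0.1), and the r*v
nonlinearity rectifies the fluctuations. The simulation satisfies the
stationarity identity <v> = -Delta/(2 pi tau <r>) - cov(r, v)/<r> to
3e-4, confirming this is a property of the finite network, not an
integration artefact; |v*| ~ 0.1 makes the *relative* error look large.
The exactness tests therefore assert (r, v) at the LA node, the
weakly-coupled HA focus and the bistable LA branch, and the *rate* on
the bistable HA branch.

## Protocols

**Sweeps.** The up-sweep starts all regions at (r, v) = (0, 0) at
eta_bar = -50 and raises eta_bar in steps of 1.5 to +10, relaxing 2 s
per step and carrying the final state forward; the down-sweep retraces
from the top. The LA -> HA jump (up) and HA -> LA collapse (down) occur
at different eta_bar — the hysteretic multistable band. At sigma = 0
both branches coincide with the single-region equilibria to 1e-4.
Maps of regimes repeat the sweep pair over a sigma grid.

**Recruitment criterion.** The transition of an area from LA to HA
needs a numeric threshold the model itself supplies: the rate of the
*saddle* of the single-region system at the run's eta_bar(k) with that
region's own recurrent coupling J_kk — the separatrix between the LA
and HA basins. Outside the bistable window the geometric mean of the LA
and HA rates at the nearest bistable eta_bar is used; a fixed
user-supplied threshold is also accepted. An area is recruited iff its
rate exceeds r_c at the trajectory end, and its recruitment time is the
first post-onset crossing of r_c that is *sustained* to the end —
transient stimulus-driven excursions of non-recruited areas do not
count. Times are grid values of the 1-ms recording grid, measured from
stimulus onset; the evaluation window is 2 s after pulse offset.

**Stimulation and thresholds.** Runs start from a prepared all-LA state
(relax 2 s from (0, 0); preparation fails, and the grid point is
flagged saturated, when some region lands in HA — this happens at the
top of the scan range where only the network-HA state survives). The
default pulse is amplitude 10 for 400 ms; multi-region EZs are
stimulated simultaneously. A threshold scan varies eta_bar over
[-15, -4] and reports eta_asy(k) (smallest grid eta_bar with at least
one recruited area — the stimulated one) and eta_gen(k) (smallest with
all areas recruited; undefined when never attained). Thresholds are
grid values, not interpolated. Scans across areas share the per-eta LA
preparation. Heterogeneous-excitability runs draw eta_bar(k) ~
Normal(eta_G, 0.1) per repetition (10 by default, seeded) and average
the recruitment counts; sd = 0 reproduces the homogeneous scan exactly.

**Graph measures.** Node strength is the row sum. Weighted clustering
is Barrat's coefficient, implemented vectorised (the installed graph
libraries expose either no Barrat form or only an undirected one; the
implementation is cross-checked in the tests against brute-force triple
enumeration and igraph's weighted local transitivity). Distances use
reciprocal edge lengths 1/w with Dijkstra — the printed average-path
formula in the source material is dimensionally inconsistent with its
own statement that doubling a weight halves the path, so the reciprocal
-length reading is used; it reproduces that halving property exactly.
Betweenness is the raw Brandes pair-fraction sum, endpoints excluded,
unnormalised; pairs are unordered on symmetric matrices and ordered on
asymmetric ones. Disconnected pairs are reported, not raised; per-node
path lengths average over reachable targets only.

**Spectrograms** use a Hann window of 0.2 s with 95% overlap (hop
0.01 s), one-sided spectrum, no detrending; slice k covers samples
[k*hop, k*hop + window). Power is averaged across regions first in
population-average mode, then divided by its global maximum,
log10-transformed and clipped at -2 (the clipping is applied after
normalisation: the 1e-2 floor is read as relative power). The time axis
is shifted right by half a window (0.1 s) so onset-locked features
appear causally. Input scaling cancels, so the FFT normalisation
constant is irrelevant.

**Clinical evaluation.** The SEEG-style PZ rule band-passes each
simulated area voltage at 1-50 Hz (order-4 Butterworth, zero-phase),
sums squared samples from stimulus onset to trajectory end, and selects
non-EZ areas with at least 30% of the maximal energy; the EZ is
excluded even when it holds the maximum. The rule operates on simulated
area signals directly — a stated substitution for electrode contacts
mapped to areas, not an equivalence. Recruitment reports use
linear-interpolation (type-7) quartiles and whiskers capped at 1.5 x
IQR beyond the quartiles. The PZ-earlier comparison is a one-sided
Mann-Whitney U test, exact when both groups have <= 8 untied
observations and tie-corrected asymptotic otherwise; unrecruited areas
are excluded by default (an optional mode ranks them beyond the largest
observation). Cohort summaries sort connectomes by the median
reciprocal-weight distance of all areas to the EZ.

## Synthetic study conditions

The generator replaces diffusion-MRI tractography data. It emulates:
square nonnegative matrices with zero diagonal normalized to [0, 1],
~90 regions (healthy preset; 88 for the patient preset), sparse
connectivity (default density 0.3) guaranteed connected by seeding the
edge set with a random spanning tree, and approximately log-normal
nonzero weights. The log-weight standard deviation defaults to 1.0
(natural log): probability-coefficient tractography matrices are
moderately heavy-tailed, and this value reproduces the macroscopic
regime the method is known to operate in — node strengths of order
1-3 on 90 regions, an asymptomatic band near eta_bar ~ -8..-6.5, a
generalized threshold near -6, and first-recruited-area weights a
sizeable fraction of the maximum. An optional `hub_bias` exponent
concentrates extra edges on a few regions.

What the generator does **not** emulate: hemispheric symmetry and
homotopic connections, distance-dependent weight decay, community
structure of real parcellations, and subject-to-subject covariance.
Passing tests therefore demonstrate the pipeline's correctness and the
model's qualitative phenomenology (bistability, hysteresis, cascade
recruitment, topology-recruitment relations) on realistic weight
statistics — not quantitative reproduction of any individual subject's
connectome.

EZ/PZ fixtures pick a seeded EZ and define the PZ as the top non-EZ
regions by total weight to the EZ (or by shortest path), which makes
the evaluation stage testable without patient data; both PZ variants
(clinician-style and SEEG-style) are set to the same set in fixtures.

## Problem sizes and determinism

The shipped tests and the acceptance script run at desk scale: QIF
exactness at N = 10,000 for 2 s per point; sweeps on a 90-region
synthetic connectome at the full protocol grid (eta step 1.5, 2 s
settle); threshold maps on 20 regions with a 0.5 grid step plus a
single-area scan at 90 regions; a two-region scan validated against a
continuous bisection oracle. All protocol code is deterministic given
the configuration — rerunning any experiment reproduces trajectories
bit-identically — and every random choice (generator, fixtures,
heterogeneous draws) takes an explicit seed.

## Known limitations

- No synaptic kinetics, conduction delays, gap junctions, plasticity or
  stochastic input terms; events are damped-oscillation transients, and
  self-sustained seizure oscillations are outside the model class.
- The time-averaged voltage of a strongly coupled finite-N HA focus is
  biased by fluctuation rectification (see above); comparisons there
  should use the rate or larger N.
- The saddle-rate recruitment criterion is parameter-consistent but not
  the only possible reading of an LA->HA "pass"; a fixed threshold can
  be supplied where a different convention is wanted.
- On small heavy-tailed networks the recruitment order is sensitive to
  the oscillation phase of the drive; per-position monotonicity of
  recruitment times in the stimulus amplitude is a cohort-scale
  (~90-region) property.
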