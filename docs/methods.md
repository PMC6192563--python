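# Methods

## The model

Each brain region `i` of a parcellated structural connectome carries a
Wilson–Cowan neural-mass oscillator. The fractions of active excitatory and
inhibitory neurons, `E_i(t)` and `I_i(t)`, evolve as

    τ dE_i/dt = −E_i + (S_E^max − E_i) · S_E( c1·E_i − c2·I_i
                 + c5·Σ_j A_ij·E_j(t − d_ij/t_d) + P_i(t) ) + σ·w_i(t)
    τ dI_i/dt = −I_i + (S_I^max − I_i) · S_I( c3·E_i − c4·I_i
                 + c6·Σ_j A_ij·I_j(t − d_ij/t_d) )            + σ·v_i(t)

with the shifted logistic `S(x) = 1/(1+e^{−a(x−θ)}) − 1/(1+e^{aθ})`, which is
pinned to `S(0) = 0` so the origin is an equilibrium of the unforced system.
`A` is the subject's weighted structural connectivity matrix (streamline
counts normalized by the summed endpoint volumes), `c5` a global excitatory
coupling gain with `c6 = c5/4`, `d_ij` the Euclidean distance between region
centroids and `t_d = 10 mm/ms` the conduction velocity, so signals arrive
with heterogeneous delays. `P_i(t)` is an external stimulation input to the
excitatory population only.

Constants (`c1=16, c2=12, c3=15, c4=3, a_E=1.3, a_I=2, θ_E=4, θ_I=3.7, τ=8,
σ=1e−5`) are the standard biologically derived set for this model family.
The sigmoid ceilings `S^max = 1 − 1/(1+e^{aθ})` are the sigmoid's asymptotic
maxima — the conventional choice; they are derived, not free parameters.

**Units.** Time is in milliseconds throughout. The integration step of 0.1
is read as 0.1 ms — the only unit consistent with `τ = 8` (ms) and delays
`d[mm] / 10[mm/ms]`.

## Integration

Stochastic midpoint Runge–Kutta (RK2) at fixed step `h = 0.1 ms` from
`E_i(0) = I_i(0) = 0.1`; pre-history for the delayed coupling terms is held
at the initial condition. Delays are rounded to the nearest integer step
(delays under half a step become zero-lag coupling). The delayed coupling
input is evaluated once per step from the history buffer and held across
both RK2 stages; with delays resolved at 0.1 ms this sub-step freezing is
far below every tolerance used here, and with coupling absent the integrator
is a clean second-order midpoint method (the test suite verifies observed
order ≥ 1.8 on a smooth trajectory). Noise enters as one additive
`σ·N(0,1)` increment per state variable per step, applied after the
deterministic update; the governing equations write the noise inside the ODE
without specifying a discretization, and at `σ = 1e−5` the distinction
between per-step and per-stage injection is far below all tolerances. Noise
streams are keyed per region (`SeedSequence(seed).spawn`), so a region's
stream does not depend on how many regions are simulated — decoupled
subnetworks reproduce exactly. A guard aborts integration (with the step
number) if any state exceeds magnitude 10; the states are population
fractions and never legitimately leave `[0, S^max]` by more than noise.

Analysis windows start after a 1 s stabilization period that is always
discarded.

## Excitability transition (c5T)

With `P = 0`, the network is swept over the global coupling grid
`0.05 ≤ c5 ≤ 0.25`; each grid point runs an independent simulation and
records mean excitatory activity over all regions and retained samples. At a
subject-specific coupling the activity jumps abruptly from the quiescent
fixed point to a high-amplitude oscillatory state. The transition value c5T
is read at the **left edge** of the curve's maximal forward difference — the
largest coupling before the excited state — provided that jump exceeds
`jump_factor = 5` times the median absolute forward difference (otherwise a
"no transition" error is raised; a flat or smoothly rising curve has no
transition). Ties break toward smaller c5. Reading the left edge makes
"just below c5T" well defined as c5T minus one grid step, the finest
subthreshold state the grid resolves, which is where stimulation experiments
hold the coupling.

The reference grid step is 0.001; desk-scale runs (analysis scripts, tests,
acceptance) coarsen it to 0.005 and use 0.5 s of recorded activity per grid
point over the same range — transition detection is insensitive to both
choices because the jump is orders of magnitude above the noise floor
(measured jump / median-difference ratios are ~50–100).

## Stimulation, functional connectivity, functional effect

Protocol per subject: hold `c5 = c5T − one grid step`, integrate one
continuous run — 1 s stabilization, 1 s quiet (`P = 0`), 1 s with
`P = 1.15` applied to the 4-region stimulation site. `P = 1.15` pushes an
isolated unit into a limit cycle, and near the transition the response
propagates along strong structural pathways.

Functional connectivity between regions `i, j` is the **signed maximum**
over integer lags `ℓ ∈ [−250, +250] ms` of the Pearson correlation between
`E_i(t)` and `E_j(t+ℓ)` computed on the overlapping samples of a 1 s window
(no padding). The lag scan is two-sided, so FC is exactly symmetric; pairs
whose signals are constant are flagged undefined (NaN) rather than zero. FC
is computed separately for the quiet and stimulated segments; their
difference ΔFC summarizes the stimulation's effect, averaged over all
unordered region pairs (global), pairs with both endpoints in a task
circuit (within), or both endpoints outside it (outside). Cross pairs (one
endpoint in, one out) belong to neither restricted scope. Signals are
sampled at a 1 ms stride for the FC scan (configurable down to the 0.1 ms
integration grid; at these smooth oscillation frequencies the stride changes
nothing at the tolerances used).

Cross-subject variability maps (structural, functional activity, FC) are
coefficients of variation: sample standard deviation (ddof = 1) across
subjects divided by the cross-subject mean, with zero-mean entries flagged
missing (NaN) rather than set to zero — a 0/0 is an absence of evidence,
not zero variability.

## Network statistics

Weighted degree `k_i = Σ_j A_ij` and its mean; spectral radius
`λ_max(A)` (its inverse bounds the coupling at which network-wide
synchronization can onset) and Laplacian synchronizability
`λ_2(L)/λ_max(L)`, `L = D − A`, which is 0 for disconnected graphs and 1
for the complete graph. Eigenvalues come from a dense symmetric solver —
the matrices are at most a few hundred nodes. Note that at 15 % density a
50-region synthetic network often has an isolated low-degree node, so
synchronizability is frequently exactly 0 across a synthetic cohort.

## Statistics

Associations between per-subject features (c5T, functional effects, graph
statistics) and median response times are Pearson correlations with
two-sided p-values from the standard t reference distribution (the sidedness
is a package choice; nothing in the protocol fixes it). 90 % confidence
intervals are percentile bootstrap: resample subject pairs with replacement
5,000 times and take the 0.05/0.95 quantiles of the resampled r; degenerate
resamples (zero variance) are redrawn, not dropped. Multiple comparisons
are controlled per feature and condition across the task family with
Benjamini–Hochberg FDR at 0.05.

**Known limitation.** The percentile bootstrap CI undercovers for
correlations at n = 10: measured coverage of the nominal 90 % interval is
≈ 84–85 % on bivariate-normal data (3,000 replicates, several true
correlations). This is a property of the method at small n, reported as-is;
the acceptance suite records the measured coverage.

Randomization controls:

* **Weight shuffling** — the full upper-triangle weight multiset (zeros
  included, so topology is also randomized) is permuted uniformly and
  mirrored. This preserves the weight distribution, total weight and mean
  degree exactly while destroying organization.
* **Random subnetworks** — region subsets of the true circuit's size are
  drawn uniformly (reference count 10,000; desk runs use 500–2,000); each
  draw re-averages the already-computed ΔFC matrices (no re-simulation) and
  the fraction of draws reaching `r > 0.5 and p < 0.05` against behavior is
  reported, along with each draw's overlap with the true circuit.
* **Alternate stimulation sites** — spatially contiguous 4-region groups
  inside the task circuit, enumerated under a symmetric 3-nearest-neighbor
  adjacency on region centroids (the protocol's "continuous volume" has no
  stated adjacency; kNN on centroids is the package's definition), each run
  through the full stimulation pipeline.

## The synthetic cohort generator

No cohort data are distributable, so the generator manufactures cohorts
with the statistical structure the analysis assumes — and, critically, with
individual differences of the *kind the shuffle control can falsify*.

Design: all subjects share the region atlas (labels, centroids in two
hemisphere-like Gaussian clouds separated along one axis, volumes) **and one
edge-weight multiset** — a log-normal sample (shape σ = 1) drawn once per
cohort, zero-padded to the target density (15 %), and rescaled so every
subject's mean weighted degree is exactly 70. What differs between subjects
is *placement*: weights are assigned to region pairs by the rank of a noisy
hub-affinity score `γ_s·(g_i + g_j)/√2 + ε`, with subject-specific hub
scores `g` and hub-affinity strength `γ_s` spread evenly over a cohort
range. Large `γ_s` concentrates the big weights on a few hubs, raising the
spectral radius and lowering c5T; small `γ_s` spreads them uniformly. Since
the multiset is identical across subjects, weight-shuffled subjects are
statistically exchangeable — any feature ordering that survives shuffling
cannot be attributed to network organization, which is precisely the logic
the shuffling control needs. (With independently drawn weights per subject,
c5T would track each subject's mean degree, which shuffling preserves, and
the control could never fire.)

The planted task circuit is **densely connected**: every within-circuit
pair carries an edge. Circuit pairs receive a fixed mid-band of the shared
weight list (the contiguous run of the sorted nonzero weights whose mean is
closest to the overall nonzero mean), permuted within the circuit per
subject, and then scaled by `circuit_bonus`. Giving the circuit mid-band
weights rather than letting it compete in the hub-rank game keeps its
internal coupling controlled by the bonus alone; when circuit weights were
instead allowed to align with hubs, the circuit's baseline (pre-stimulation)
coherence varied wildly between cohorts and the stimulation contrast was
unstable. A within-hemisphere weight factor (default 1.2) adds block
structure.

Two canonical study conditions are frozen in `conndyn.synth`:

* `excitability_cohort_spec()` — 12 subjects, hub-affinity range (0, 1.2),
  circuit bonus 1.0 (the circuit exists topologically but does not dominate
  the dynamics). Used for c5T mapping and behavior association: c5T spans
  ≈ 0.07–0.12 across the cohort with a detection repeatability of ±1 grid
  step over noise seeds.
* `circuit_cohort_spec()` — 5 subjects, fixed mid-range hub affinity (0.5),
  circuit bonus 2.5. Used for stimulation experiments: the bonus makes the
  circuit the preferred propagation pathway without saturating its members
  at a high fixed point (stronger bonuses overdrive circuit members into
  non-oscillatory saturation, which *decorrelates* them).

The mean weighted degree of 70 places the transition comfortably inside the
standard sweep range for 50-region networks; it is a scale choice of the
generator, as is everything the weight normalization of real streamline
counts would otherwise set.

Synthetic response times are `RT = intercept + slope · z(feature) + noise`
per task and condition, with the driving feature z-scored so the slope is in
ms per standard deviation regardless of the feature's units; defaults
(intercept 900 ms, slope 80 ms/SD, noise 15–20 ms) give response times and
effect sizes in the range typical of timed language tasks. A
feature-independent mode generates pure-null behavior for false-positive
calibration.

**What passing tests on synthetic cohorts do and do not show.** They show
the machinery is correct: transitions are detected where they exist, planted
linear structure–behavior relationships are recovered and their shuffling
control behaves, stimulation effects localize to strongly coupled circuits.
They do not show that real DSI connectomes have hub-placement individual
differences of this geometry, that real task circuits are dense cliques, or
that empirical response times are linear in any model feature — those are
substantive claims about brains that only real cohort data can test.

## Problem sizes in this repository

Analysis scripts, tests and the acceptance script run 50-region networks,
coupling grids at step 0.005, 0.5 s sweep windows, 12-subject cohorts,
500–2,000 subnetwork draws and 500–5,000 bootstrap resamples. These are the
package's desk-scale defaults; every size is a parameter, and the reference
values (0.001 grid, 1 s windows, 10,000 draws, 5,000 resamples) are a
function argument away.

## Degenerate inputs and tie-breaks

* Asymmetry in a connectome file: relative asymmetry ≤ 1e−9 is averaged
  away; anything larger is an error, never silently fixed.
* Variability maps: edges/regions with zero cross-subject mean are NaN.
* FC: constant signals give NaN pairs; defined values are clipped to
  [−1, 1] against round-off.
* Transition detection: ties go to the smaller c5; downward jumps never
  qualify.
* Shuffling 1- or 2-region networks returns the input.
* Bootstrap degenerate resamples are redrawn (bounded retries).
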