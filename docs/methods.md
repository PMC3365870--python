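# Methods

This note records the modelling assumptions, numerical choices and
known limitations behind `escapenet`, at the level of detail a user
needs to judge what a passing test suite does and does not establish.

## Model and escape problem

A node is the subcritical-Hopf normal form with quintic saturation,
`dz = [(λ−1+iω)z + 2z|z|² − z|z|⁴] dt + α dw`, with `w` a complex
Wiener process whose real and imaginary parts are independent standard
Wiener processes (so each real coordinate receives variance `α² dt`
per unit time). For `0 < λ < 1` the origin (rest) and the outer limit
cycle (oscillation) are both attracting, separated by the unstable
cycle at `|z|² = 1 − √λ`. The limit-cycle radii are the roots of
`r⁴ − 2r² + (1−λ) = 0`, i.e. `1 ± √λ`; any appearance of `1 ± λ` in
informal descriptions is a typographical shorthand that neither solves
the quartic nor matches the barrier formula, and is not used here.

The escape problem starts every trajectory at `z = 0` and asks for the
first time the trajectory leaves the rest basin. Two boundaries play
distinct roles:

* the **separatrix** `|z|² = 1 − √λ` — the mathematically exact basin
  boundary, and the absorbing boundary of the Dynkin boundary-value
  oracle and the Schuss formula;
* the **detection boundary** `|z|² = 1 − λ` (the package default) —
  slightly outside the separatrix, so a detected crossing is a
  committed transition rather than a grazing touch that falls back
  with probability ~1/2.

The reference escape statistics of the model (e.g. the γ ≈ 0.007
exponential rate of the fully connected 3-node network at λ=0.9,
α=0.05, β=1) are reproduced with the detection boundary; comparisons
against the boundary-value oracle always re-set the threshold to the
separatrix so both sides answer the same question. In the asymptotic
regime `E[τ] ≥ 100` the relative difference between the two
definitions vanishes (the post-barrier commit time is O(1) seconds
against an exponentially large waiting time).

## Escape-time theory

The closed form is the n = 2 Schuss singular-perturbation result for
gradient systems, assembled from the radial potential
`ψ(r) = (1−λ)r²/2 − r⁴/2 + r⁶/6` (gauge `ψ(0)=0`; the rotational part
of the field is divergence-free along level sets and does not enter):
barrier `ψ̂ = 1/6 − λ/2 + λ^{3/2}/3`, Hessian `H(0) = (1−λ)I`,
boundary curvature `c = |ψ''(r_u)|/2 = 2√λ(1−√λ)`, and boundary
integral `2π r_u √c` over the full escape circle (the barrier is
constant on it, so the whole circle contributes — the reason the
discrete-saddle Eyring–Kramers formalism is not applicable here and is
not implemented). This yields

```
E[τ] = α √π exp(2ψ̂/α²) / (2√2 λ^{1/4} (1−λ)(1−√λ)).
```

The prefactor's `√π` follows from the n = 2 assembly
(`α^{n−1} π^{(n+1)/2}` over the Hessian and boundary terms) and is
confirmed empirically by the boundary-value oracle: agreement is 0.4–9%
across the validity region, which a `π`-prefactor (a factor 1.77) could
not produce.

**Validity flag.** The formula is flagged reliable when `E[τ] ≥ 100`
*and* `2ψ̂/α² ≥ 2`. The first is the empirical agreement region; the
second is the asymptotic premise itself (barrier ≫ noise) and is what
catches the spurious divergence as λ → 1, where the formula prints
large numbers while the true exit time collapses to zero. The formula
also turns upward in α beyond `α* = 2√ψ̂` (`alpha_turning_point`);
below `α*` it is monotone decreasing, as the physics requires.

**Dynkin oracle.** For the rotationally symmetric node the expected
exit time depends only on radius and satisfies
`(α²/2)(u'' + u'/r) + g(r) u' = −1` on `(0, r_u)`, `u'(0)=0`,
`u(r_u)=0`, with `g` the radial drift. Discretisation: second-order
central differences on a uniform grid (default 2000 points; doubling
changes `u(0)` by < 0.1%), a one-sided symmetric closure at `r = 0`
(`u'' + u'/r → 2u''(0)`), solved as a tridiagonal system. This oracle
carries no small-α assumption and adjudicates every question about the
closed form.

## Network simulation

**Integrator.** Euler–Maruyama in the co-rotating frame: per step the
slow drift, diffusive coupling and noise are advanced by Euler and the
rigid rotation is applied as the exact phase factor `e^{iω dt}`.
Because the vector field is rotation-equivariant, the coupling is
linear and the noise isotropic, this is *in law* the Euler scheme for
the ω = 0 system rotated back — it preserves exactly the model's
property that ω has no effect on the exit problem. Naive Euler on the
full complex drift does not: `|1 + iω dt| ≈ 1 + ω²dt²/2` inflates the
modulus at rate `ω²dt/2` per unit time (= 1.0 at ω=20, dt=0.005),
which would dwarf the true radial drift `(λ−1)r` and collapse escape
times by an order of magnitude. With additive noise the scheme is
strong order 1.0.

Step sizes: dt = 0.005 model-seconds by default; 0.001 when β > 10 so
the coupling eigenvalues (up to β·N) stay well inside the stability
region. Halving dt at the reference point moves ensemble means by less
than one Monte-Carlo standard error (asserted in the suite). A safety
bound `|z|² > 10⁶` aborts with diagnostics rather than silently
overflowing.

**Escape detection.** Per-node first crossing of the detection
boundary, linearly interpolated in `|z|²` within the step; the network
has escaped when `ceil(fraction × N)` nodes have crossed (default
fraction 1/2: "at least half", so exactly half suffices for even N).
First crossing counts — no debounce — matching the exit-problem
definition; a sustained-crossing option (k consecutive steps) exists
but is off by default. Coupling shifts the true network separatrix,
but transition is deliberately defined against the node-level boundary.

**Ensembles and censoring.** Each trial consumes its own noise stream
keyed by `(master seed, trial index)` through NumPy's seed-sequence
splitting, so trial k is bit-reproducible in isolation and results are
independent of batch composition (asserted). Trials that reach `t_max`
are censored and enter the mean through the exponential
censored-likelihood estimator, total exposure / number of events,
which reduces to the sample mean when nothing is censored; the rate CI
is a nonparametric bootstrap over (duration, event) pairs. When numba
is importable the stepping loop runs as a compiled kernel (identical
streams and scheme; agreement with the pure-numpy path is ~1e-15
relative); otherwise the numpy path is used.

**Exponentiality screen.** The headline rate γ is the reciprocal
censored-MLE mean. The Kolmogorov–Smirnov screen asks whether the
*tail* is exponential: the shortest 2% of times are discarded (a trial
started exactly at the rest state cannot cross immediately, so the
density is suppressed at short times), the remainder re-based at the
trim point, and compared against the rate refit on that tail. Refitting
matters: the short-time deficit inflates the full-sample mean by a few
percent, and testing the tail against the full-sample rate builds in a
systematic mismatch that a large ensemble always detects. With the
tail-refit the screen passes at the 1% level across seeds at n = 1000.

**Transitions per hour.** A renewal construction: simulate from rest,
record the escape, reset all nodes to zero, repeat until the requested
simulated time is covered; rate = escapes per simulated hour (with ω
in rad/s, one model-second is one second). Resetting rather than
waiting for spontaneous return is a modelling choice: for λ > 1/4 the
limit cycle attracts more strongly than the rest state and returns are
too rare to simulate.

## Graphs

Topologies are directed, unweighted, unlabelled graphs without
self-loops; `M[i][j] = 1` means i influences j, and node i receives
input along column i of M ("normalised adjacency" is interpreted as
binary 0/1 by default; an in-degree-normalised mode exists for
sensitivity analysis, but every quantitative result here uses binary).
Isomorphism is decided by brute force over all ≤ 4! node permutations
(the canonical key is the lexicographically minimal adjacency
bit-string) — at this scale correctness is self-evident and no
heuristic canonicaliser is needed. Exhaustive enumeration gives 3
classes on 2 nodes, 16 (13 at least weakly connected) on 3, and on 4
nodes 218 / 199 (weakly+) / 83 (strongly) — the sometimes-quoted figure
of 216 four-node networks matches none of the standard connectivity
filters, so the package reports all three counts rather than forcing
agreement.

The first transitive component is computed as the union of source
components of the SCC condensation (networkx); it is strongly
connected iff there is exactly one source component and disconnected
otherwise — never merely weakly connected (asserted exhaustively for
n ≤ 4). The strong-coupling score `(N − |u|)/N_e` is computed over the
FTC subgraph by default (escape at strong coupling depends only on the
FTC), with a whole-graph scope available; `|u|` is Euclidean by default
(u enters the centre-of-mass dynamics through a dot product), with L1
available. The score is `nan` when the scoped subgraph has no edges
(single-node or edgeless FTC) — the scaling law is about strongly
connected cores. The acceptance check of the law is a rank correlation
(Spearman > 0.8 of log mean escape time against the score) on one
representative per distinct score value among the 83 strongly connected
4-node graphs, subsampled to 12 evenly spaced score levels at 400
trials each: representatives remove the within-score degeneracy (all
balanced graphs share one asymptotic escape time while their scores
spread with edge count — a real flat-top in the relationship, visible
in the full 83-graph scan as ρ ≈ 0.69), and the trial count keeps the
log-mean noise (~0.05) below the between-level spacing.

## EEG pipeline

Preprocessing follows standard clinical practice: drop the earlobe
channels (A1/A2), re-reference to the common average, zero-phase
(forward–backward) 4th-order Butterworth band-pass [0.5, 70] Hz and
2nd-order IIR notch at 50 Hz. Zero-phase filtering is essential — any
phase-skewing filter would contaminate the Hilbert phases downstream.
Band splitting uses the same zero-phase Butterworth design per band
(δ 1–3, θ 4–8, α 9–14, β 15–30, γ 31–70 Hz). Hilbert-transform edge
transients are trimmed (0.5 s per end) before phase extraction; the
transform is applied to the full epoch (windowing choices are not
standardised in the field; the trim is a pragmatic default).

The PLF matrix is treated as a correlation matrix to obtain directed
β-weights `−R_ij/R_ii`, `R = P⁻¹` — entry (i, j) read as the influence
of channel i in predicting channel j, matching the adjacency
convention. A PLF matrix need not be positive semidefinite, so the
inversion is ridge-guarded (default 10⁻⁶) and the condition number
logged; a matrix still singular after the ridge raises. Thresholding
retains exactly `round(d·n)` off-diagonal entries of largest absolute
value, ties broken by (|value| desc, row-major asc) for determinism;
d is restricted to integers 1..n−1, matching its use at d = 11–14.
Cohort rates are simulated at λ = 0.9 (the operating point used for
every network experiment; the cohort analysis leaves it unstated) with
coupling β = α = 0.1. The group comparison is the one-sided Wilcoxon
rank-sum with normal approximation and midrank tie correction,
cross-checked against an exact permutation oracle (agreement < 0.02 at
n = 10 per group); an all-tied input returns p = 0.5.

## Synthetic signal generator

A Kuramoto-type coupled-phase-oscillator generator
(`dθ_i = [2π f_c + κ Σ_j A_ji sin(θ_j − θ_i)] dt + σ dW_i`,
`x_i = sin θ_i` + measurement noise) produces 19-channel, 256 Hz, 20 s
epochs with graph-structured phase locking. Since the PLF is a pure
phase statistic, amplitude realism would be invisible to every
pipeline stage — which is exactly why this generator and not a
filtered-noise mixture. The phases are integrated with internal
oversampling (substep ≤ 0.2/κ) so arbitrarily strong locking stays
resolved. Defaults: phase diffusion σ = 12 rad/√s — deliberately less
coherent than a real alpha rhythm, so that 20 s contains many phase
coherence times and uncoupled pairs sit at a clean < 0.1 PLF null;
κ ≈ 100–300 gives intermediate locking and κ ≳ 1000 near-complete
locking (stationary concentration `2κ/σ²`). Directionality is planted
through the asymmetric coupling matrix, but recovery of *direction* by
β-weights is measured, not asserted — the β-weight construction is a
practical device for building a digraph, not a validated causal
estimator.

What passing tests show, and what they do not: the pipeline recovers
planted coupling structure (edge ranking beats chance, cliques elevate
PLF, group differences in coupling arrangement propagate to simulated
rate differences at n = 10 per group), and the group comparison is
calibrated on null cohorts. None of this bears on real EEG features the
generator omits — 1/f background, artifacts, nonstationarity, volume
conduction — so performance on clinical recordings is out of scope
(the clinical cohort of the original study is not publicly deposited).

## Problem sizes

The stochastic checks are sized for a single CPU: 1000-trial ensembles
for the reference-rate check, 120–400 trials per topology for the
structure scans (with `t_max` capped and censoring handled by the
exposure estimator), 12 score levels for the scaling law, and
10-channel, 20-subject cohorts for the pipeline checks. These sizes
leave Monte-Carlo error comfortably inside every asserted tolerance;
full-scale reruns are a matter of raising `n_trials`/`total_hours` in
the workflow calls.

## Known limitations

* The escape-time machinery addresses initiation only; seizure
  termination, ictal waveform morphology and spike-wave structure are
  not modelled (the limit cycle is a featureless sinusoid).
* The closed form exists for the single node only; network escape
  times come from Monte Carlo (no coupled-network Dynkin solver).
* Enumeration stops at 4 nodes by design (combinatorial growth).
* The default escape threshold is the node-level boundary even in
  networks, where coupling deforms the true separatrix; the threshold
  is configurable and the rank-based structure results are insensitive
  to the choice.
* `scaling_score` is undefined (nan) for graphs whose FTC has no edges.
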