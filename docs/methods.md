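# Methods

This note documents the models, estimators and design choices behind
`popglass`, and what the synthetic benchmarks do and do not establish.

## Data representation

Spike trains are discretized into fixed timebins (default 20 ms, the
timescale at which retinal population words are usually read out), with more
than one spike per bin truncated to 1.  Bins are half-open `[t·Δt, (t+1)·Δt)`
with 0-based indices; a recording of duration `D` yields `floor(D/Δt)` bins.
The empirical statistics kept for modeling are the per-neuron rates
`p_i = ⟨r_i⟩` and the second moments `m_ij = ⟨r_i r_j⟩`; both the covariance
and the Pearson matrix are stored, and the correlation-scaling manipulation
acts on covariances with rates held fixed (this keeps the rescaled second
moments well-defined when the model is refit).  Neurons with `p_i ∈ {0, 1}`
carry no pairwise constraint; they are kept in rasters but dropped from
model fits with a logged warning.

## Pairwise maximum-entropy model

The model over binary patterns `R` is

    P(R) = Z⁻¹ exp( Σᵢ hᵢ rᵢ + Σ_{i<j} J_ij rᵢ rⱼ ),

the maximum-entropy distribution matching rates and pairwise moments.
Identifying the exponent with `−E(R)` makes this a Boltzmann distribution at
effective temperature `T = 1`; the one-parameter family
`P(R;T) ∝ exp(−E/T)` is a diagnostic knob, not a physical temperature.

**Exact fitting (N ≤ 20).**  The log-likelihood is concave, so the fit is the
unique solution of moment matching.  We minimize `log Z − θ·μ_data` with the
analytic gradient (model minus data moments) by L-BFGS over the full
enumeration of 2^N patterns; convergence is declared when every moment
residual is below `tol` (default 1e-6).  When a moment sits within 1e-3 of
its Fréchet bound, a small L2 damping (1e-6) on J is switched on for
numerical stability and reported in the diagnostics.  Infeasible moments
raise an error naming the offending pair.

**Boltzmann learning (N > 20).**  Gradient matching with model moments
estimated by Gibbs sampling: single-site heat-bath updates in a fixed sweep
order (bit-reproducible given a seed), a persistent chain across learning
iterations, Robbins-Monro step decay `η_t = η₀/(1+t/τ)`, and Polyak
averaging of the last 100 iterates.  Convergence is checked on a long fresh
run: every moment residual must fall below 3× the Monte-Carlo standard error
at the training sampling effort (blocked standard errors).  An optional
warm start initializes J at half the independent-pair log-odds ratio, which
substantially accelerates convergence on sparse rasters.

**Pseudo-likelihood (large N, used by the size scan).**  Maximizing the
product of per-site conditional likelihoods (logistic regressions with a
shared symmetric J) is consistent for this model class, deterministic and
fast.  The specific-heat size scan uses it for subsets beyond the
enumeration limit because stochastic moment matching leaves residual
shrinkage in weakly constrained coupling directions — directions that barely
move any single moment but add up to a systematic upward bias of the peak
temperature.  Boltzmann learning remains the general-purpose large-N fitter
and the two agree closely on recoverable couplings (tested).

**Interaction and correlation scaling.**  `scale_couplings` sets
`J → factor·J` and refits only the fields so rates match the data
(closed-form logit at factor 0).  `scale_correlations` sets
`C_ij → γ·C_ij` at fixed rates and verifies Fréchet feasibility of the
rebuilt second moments.

## Thermodynamic diagnostics

The heat capacity is computed as `C(T) = Var_T(E)/T²`, by enumeration when
possible and otherwise from Gibbs samples at temperature T with a blocked
standard error; the equivalent derivative form `∂⟨E⟩/∂T` is used as a
cross-check (the two agree within 1% on enumerable models).  For an
independent model `C(T) = Σᵢ hᵢ² pᵢ(T)(1−pᵢ(T))/T²` with
`pᵢ(T) = σ(hᵢ/T)` — the closed form used to pin scan endpoints.

**Size scan.**  Random neuron subsets are drawn *nested* (each draw is a
random ordering; the size-10 subset is contained in the size-20 subset), the
subset's marginal statistics are measured on a long raster sampled from the
full model (default here: 120,000 bins), a pairwise model is refit per
subset, and C(T)/N curves are averaged per size.  Nesting pairs the size
comparison and cancels much of the subset-composition variability, which
otherwise dominates (different subsets of a frustrated model genuinely
differ in their peak temperature by several hundredths).  The peak T* is
located by 3-point parabolic interpolation in log T, making it insensitive
to the grid resolution.  The default grid is log-spaced over [0.3, 3].

The frustrated benchmark ensemble uses zero-mean Gaussian couplings
(J_std = 0.45 at N = 40) and fields near −3 (rates ≈ 5% per bin, a typical
sparse retinal rate at 20 ms).  This places the full population just below
its specific-heat peak (T* slightly above 1) — the marginally sub-critical,
frustrated ("glassy") regime — while small subsets are field-dominated with
higher-temperature peaks, so T* falls and the peak grows with N.  Problem
sizes (N = 40, 120k bins, 17-point T grid, 3 nested subset draws) were
chosen so the whole scan completes in a couple of minutes on one core while
keeping the size trend well clear of subset and Monte-Carlo noise.

**Correlation-scaling scan.**  For each γ in a grid containing 0 and 1 the
covariances are scaled, the model refit, and C(T=1)/N recorded; a
4-parameter logistic is least-squares fit over γ and its midpoint reported
as γ*.  Individual fit failures flag points (the sigmoid fit proceeds with
≥ 5 valid points); a curve whose amplitude is under 5% of its level is
flagged degenerate (no transition), which is what rate-matched shuffled
controls produce.  Whether the y-axis is C or C/N is a display choice; both
are reported.

**Cluster-distribution temperature transform.**
`P_T(α) ∝ P(α)^{1/T}` with zero-probability clusters excluded; its entropy
in bits is non-decreasing in T (property-tested), interpolating between the
argmax cluster (T→0) and uniform (T→∞).

## Tree-emission hidden Markov model

The latent-variable model is `P(R) = Σ_α w_α Q_α(R)` with a first-order
Markov chain over modes and per-mode tree emissions
`Q_α(R) = P_α(r_root) Π_{⟨ij⟩} P_α(r_i|r_j)` over an acyclic spanning graph.
EM alternates forward–backward over the mode chain with an M-step that
re-learns each mode's tree as the maximum-weight spanning tree on
posterior-weighted pairwise mutual information (Chow–Liu — the
maximum-likelihood tree) and refills the conditional tables from
posterior-weighted counts with Laplace smoothing (pseudo-count 0.5, so no
emission is ever impossible).  Initialization is k-means-style seeding in
Hamming distance with 5 restarts (best final likelihood kept); the training
log-likelihood is asserted non-decreasing up to a 1e-6 relative slack (the
smoothing technically breaks the exact EM guarantee).  A mode whose
posterior mass drops below 1 bin is reseeded once, then dropped with a
warning.  Edgeless (independent-Bernoulli) emissions are supported as
degenerate trees, and the synthetic generator plants them by default with an
optional chain-tree mode so structure recovery is testable.

**Model selection.**  Contiguous 2/3 train / 1/3 test split (interleaving
would leak temporal dependence).  The per-bin test log-likelihood gets a
blocked standard error (10 contiguous blocks), and the selected M* is the
smallest M within one standard error of the best — a parsimony rule that
returns the planted M when structure is real and M* = 1 on structureless
data, where the likelihood is flat within noise.

**Assignment.**  Static MAP (default): `α* = argmax_α w_α Q_α(R)`.
Dynamic: a greedy one-step filter `argmax_α P(α_t|R_t, α_{t−1})` using the
transition row of the previous assignment.  The two coincide whenever the
transition rows equal the stationary weights (a memoryless chain).  Ties
break to the lowest mode index.

**Cluster metrics.**  Reliability is the per-bin modal agreement across
repeat trials.  Separation uses a two-class linear discriminant with
shrinkage-regularized within-class covariance (Ledoit–Wolf, never singular)
and `d′ = |μ₁−μ₂|/(σ₁+σ₂)` on the projections.  The shuffle control permutes
which neuron carries which within-cluster firing rate and re-emits the
cluster's bins from the permuted profile before recomputing d′ — an
interpretation of "rearranging firing rates within a cluster" chosen so that
a cluster with a symmetric rate profile is exactly unchanged.  Cluster
information uses the plug-in estimator of I(cluster; bin index) across
repeats, with a logged warning below 10 repeats where its upward bias is
material.

## Landscape geometry

All searches use only local energy differences, so they scale to any N.
Single-flip ascent accepts strictly improving flips in random order until a
full pass accepts nothing; fixed-K ascent uses single (active, silent)
swaps.  "Strictly improving" means ΔE < −1e-10: on degenerate (symmetric)
landscapes exact ties would otherwise round to ±1e-16 and cycle.  A fixed-K
endpoint is labeled robust when all n_paths (default 10) independent
proposal orderings agree.  Ridgelines are traced by switching on one silent
neuron at a time and re-ascending at K+1, keeping endpoints that contain the
current pattern (locality by initialization — the search is anchored by
where it starts, since no metric is otherwise defined); two or more distinct
robust superset endpoints within a log-probability window (default ln 10)
constitute a split and every branch is traced.  The active set is the union
of spiking neurons along the chain; membership in the cluster is the rule
"all spikes in the active set and K_min ≤ K ≤ K_max".  The trace stops at
K_limit (default: the largest spike count observed in the data, capping the
search to data-supported counts).

## Winner-take-all readout

Readout units receive the pattern through non-negative weights; the winner
of a bin is the unit with the largest drive that exceeds both its threshold
and zero (all-silent bins have no winner).  Only the ingredients of the
circuit are fixed by the biology (Hebbian feedforward plasticity, global
inhibition, homeostatic excitability); the update rules here are one
concrete choice: winner-only potentiation `ΔW = η₊ r_i` on spiking inputs,
multiplicative decay `ΔW = −η₋ W` on its silent inputs, weights clipped to
[0, w_max], and for every unit a threshold step `θ ← θ + η_θ(won − target)`
toward a target winning rate (default: active-bin fraction divided by the
number of readouts).  Thresholds act as activity clamps: a unit that wins
too often prices itself out, letting starved units capture patterns, which
is what yields full cluster coverage at 2× redundancy.  The ideal readout
implements the membership rule directly — fire iff at least K_min active-set
inputs spike and no silent-set input spikes (veto weights stand in for the
disynaptic inhibition).

## Synthetic data: what it emulates, what it does not

The generators provide exactly the structures the analyses target: Gibbs
rasters from a known frustrated pairwise model; latent-mode rasters from a
sticky Markov chain (default self-transition 0.75, mean dwell 4 bins —
matching the few-bin cluster persistence reported for retinal populations)
with disjoint active sets (default M = 5 sets of 8 neurons among N = 40,
emission 0.5 inside / 0.01 outside); rate-matched independent controls by
per-neuron time permutation; repeat ensembles sharing one latent sequence
with fresh emission noise; and a ±1 checkerboard whose frames drive mode
probabilities through planted spatial filters.  Real recordings differ in
ways these generators deliberately ignore: overlapping and graded cell
assemblies, rate nonstationarity and adaptation, higher-order correlations
beyond pairwise or tree structure, and stimulus-locked temporal kernels.
Passing tests therefore establish correctness of the estimators and the
internal consistency of the pipeline on data obeying the model assumptions,
not that any particular biological population is glassy.  The emission noise
of real clusters is not a quantity we presume to know; it is a free
generator parameter.

## Numerical conventions

- All randomness flows from one integer seed through
  `numpy.random.SeedSequence` spawning (named sub-seeds in the pipeline
  manifest); kernels receive 31-bit seeds.
- HDF5 artifacts are written with `track_times=False` so identical runs are
  byte-identical (checksummed in the pipeline manifest).
- Peak localization: 3-point parabolic interpolation in log T; boundary
  maxima return the grid point.
- The pattern census and every exact computation refuse N beyond their
  enumeration limits rather than silently approximating.

## Known limitations

- The Markov chain over modes is first-order; multi-timebin spike words and
  dwell-time (semi-Markov) structure are out of scope.
- Boltzmann-learning convergence is certified by moment residuals; in very
  sparse regimes weakly constrained coupling combinations remain slow, which
  is why the size scan prefers the pseudo-likelihood backend.
- The plug-in cluster-information estimator is biased upward for few
  repeats; no bias correction is applied beyond the warning.
- Ridge tracing explores upward in K only; basin volumes and the
  Gaussian-like peaks that dominate under heavily repeated stimuli are not
  modeled.
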