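# Methods

`bindkin` implements the kinetic and thermodynamic inference chain used to
characterize reversible small-molecule binding to a buried protein cavity
(the benzene / T4 lysozyme L99A system is the motivating example): Markov
state modelling of featurized trajectories, transition path theory,
umbrella-sampling/WHAM free-energy profiles, and infrequent-metadynamics
off-rate recovery. Because the raw molecular-dynamics data behind such
studies are rarely available, the package ships a synthetic-data layer with
exactly solvable ground truth so that every estimator can be validated
end to end.

## Unit system

Internally everything is ns (time), nm (length), kcal/mol (energy), with
k_B = 0.0019872041 kcal/mol/K and 1 kcal = 4.184 kJ. The default
temperature is 303 K (the simulation temperature of the motivating study).
Quantities quoted in kJ/mol by convention (umbrella force constants,
metadynamics hill heights) are accepted in kJ/mol at the API surface and
converted on entry. Rates cross to 1/s and 1/(M·s) only in user-facing
summaries.

## Synthetic ground truth

**Kinetic networks.** A `KineticNetwork` is an irreducible continuous-time
Markov chain with generator Q (1/ns). Stationary distributions solve
πQ = 0; pairwise mean first-passage times (MFPTs) solve the standard linear
system on the complement of the target; committors solve the Q-restricted
harmonic system with 0/1 boundary values. Trajectories are drawn with the
Gillespie algorithm and discretized by *point sampling* on the frame grid
(the state occupied at each grid time), matching how MD frames are saved.
Point sampling matters for validation: a grid-sampled chain detects
arrivals only at grid times and can miss visits shorter than the lag, so
discrete-chain MFPTs carry a positive O(lag) bias relative to the CTMC
values (about 2% for the benchmark's 8.7 ns unbound state at a 0.2 ns lag).
Tests compare estimators against the exactly discretized reference
(expm(Q·lag)) where this matters.

**The bundled four-state benchmark.** The default network reproduces the
population/lifetime hierarchy of a cavity-binding macrostate model exactly:
populations (0.11%, 6.4e-3%, 4.7e-2%, 99.83%) and lifetimes (2.6e3, 69,
742, 9e5 ns) for unbound (MS0), two gateway intermediates (MS1, MS2) and
bound (MS3). Under detailed balance these constraints pin the per-state
exit fluxes; a consistent non-negative symmetric flux matrix requires both
a direct MS0–MS3 channel and a small MS1–MS2 exchange. The chosen
allocation (code: `synthetic._BENCHMARK_FLUXES`) satisfies populations and
lifetimes to four digits; the split between the direct and gateway channels
is a package choice, and the resulting committors (≈0.67/0.83 for the
intermediates) are a consequence of it, not a constrained target. The
network's own MFPT_off comes out at 3.3e6 ns, the same order as the
motivating system. `benchmark_network(time_scale=s)` multiplies all rates
by `s` (populations unchanged), which is how desk-scale studies compress
the native microsecond-to-millisecond hierarchy; the validation studies use
s = 300 with 0.1 ns frames.

**Emissions.** Features are drawn per frame from each state's spherical
Gaussian. The benchmark emits 4 informative dimensions (unit-axis centers,
spread 0.15, i.e. well-separated but overlapping at the ~5σ level) plus 2
pure-noise dimensions to exercise the dimensionality-reduction stage. Real
contact features are binary, autocorrelated within states and
non-spherical; passing tests on the Gaussian benchmark demonstrates
correctness of the estimators, not robustness to every real-data pathology.

**Langevin sampler.** Overdamped Euler–Maruyama,
x ← x − (dt/γ)∇U + sqrt(2 kT dt/γ) ξ, on analytic potentials (harmonic,
quartic double well, and a four-basin 2D "binding landscape" with a deep
cavity, two gateways and a broad bulk basin). γ plays the role of a drag
coefficient (energy·time/length²). A heuristic guard rejects time steps
whose deterministic drift per step exceeds half the potential's length
scale, and the umbrella sampler additionally enforces dt·k/γ < 0.5 for the
restraint stiffness (Euler stability).

**Seeding.** Every stochastic routine takes an integer seed; ensembles
derive per-trajectory seeds from a master seed through
`numpy.random.SeedSequence(master).generate_state(n) % 2^31`, so runs are
reproducible trajectory by trajectory.

## Model building

**tICA.** Covariances are estimated with ensemble mean removal and
symmetrization (C_τ ← (C_τ + C_τᵀ)/2, C_0 averaged over both window ends),
guaranteeing a real spectrum bounded by 1. A ridge ε = 1e-10·tr(C_0)/d on
the C_0 diagonal handles rank-deficient (e.g. binary-contact) features.
Components are ordered by eigenvalue; the kinetic variance fraction of
component i is λ_i²/Σλ_j². Both selection rules are supported: fixed n and
smallest n with cumulative kinetic variance ≥ threshold. Note that for
processes carried by very-low-population states the tICA eigenvalue is
suppressed by the variance ratio (autocorrelation × signal/total variance),
so aggressive truncation can silently drop rare-state directions; the
benchmark study therefore keeps the full (6-component) whitened space.

**k-means.** In-package Lloyd iteration, deterministic per seed, ties
broken toward the lowest center index, emptied clusters re-seeded from the
farthest point. The default initialization is farthest-point (maximin)
seeding rather than k-means++ D² sampling: D² sampling allocates centers by
population mass and reliably misses metastable states whose stationary
weight is orders of magnitude below the rest (the benchmark's 6.4e-5
intermediate occupies ~50 frames in 10⁶ and never received a center in
repeated k-means++ runs), whereas maximin covers any geometrically
separated cluster regardless of population. Classic seeded k-means++
remains available (`init="kmeans++"`).

**Reversible MSM.** Sliding-window counts at the lag; the active set is the
largest connected component of the symmetrized count graph. The
maximum-likelihood transition matrix under detailed balance is found by the
standard self-consistent fixed point on symmetric pair weights
x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j), converged when the max change of
T falls below 1e-10. Invariants (row sums, πT = π, detailed balance) are
asserted on construction; the spectrum is computed on the symmetrized
matrix so it is real by construction. Implied timescales
t_i = −τ/ln λ_i(τ) are tabulated across lags with a plateau diagnostic
(relative change of t_2); non-positive eigenvalues yield NaN rather than an
exception.

**Macrostates.** Memberships are initialized by PCCA+ (inner-simplex
vertex selection on the top right eigenvectors with a feasibility
projection) and refined by Baum–Welch estimation of a discrete-emission
HMM (hmmlearn backend) at the same lag, using all lag-phase-shifted
subsequences. EM starts from the *crisp* PCCA+ partition with count-based
macro transition estimates: fuzzy-membership projection proved fragile when
one state dominates (eigenvector noise leaks dominant-state weight into
rare macrostates and poisons EM). Likelihood monotonicity is checked as a
bug guard. Macro populations come from the stationary distribution of the
HMM transition matrix; lifetimes are lag/(1 − T̃_ii); memberships are the
Bayes posteriors π_a B_a,i normalized over macrostates. The EM iteration
cap (default 100; 30 in the benchmark studies) is the binding control in
practice: the nominal 1e-8 log-likelihood tolerance is an absolute change and
is rarely reached on long sequences.

**Kinetics.** MFPT over state sets solves (I − T_CC)m = τ1 on the
complement of the target set, with the source average weighted by the
stationary distribution restricted to the source (uniform weighting
available). The pipeline computes MFPT_on/off on the *microstate* MSM
between macrostate core sets (crisp memberships); the 4×4 HMM matrix is the
alternative route. The micro-MSM route pools transition statistics over all
cells and was measurably more accurate on the benchmark. Rates follow
k_on = 1/(MFPT_on·C), k_off = 1/MFPT_off; binding free energy
ΔG_sim = −k_B T ln(π_bound/π_unbound) at the simulated ligand concentration
C, with the 1 M standard state recovered as ΔG⁰ = ΔG_sim + RT ln(C/1 M)
(this convention reproduces the motivating study's −6.9 kcal/mol from its
printed populations and 9.55 mM). Activation barriers use the
transition-path-time relation k_off = (1/τ_TPT) e^{−ΔG*_unb/RT} and the
cycle ΔG_binding = ΔG*_binding − ΔG*_unbinding. Uncertainties are
trajectory-level bootstrap (default 100 replicates, seeded; replicates
where the estimator fails — e.g. a rare state lost from the resample — are
dropped and counted, erroring above 20%).

**Transition path theory.** Forward committors by linear solve with exact
boundary values; backward committors on the time-reversed chain (equal to
1 − q⁺ for reversible models). Gross flux f_ij = π_i q⁻_i T_ij q⁺_j, net
flux f⁺ = max(f − fᵀ, 0); conservation at intermediates is verified to
1e-8 as a bug guard. Pathways are extracted greedily: repeatedly find the
max-bottleneck A→B path (widest-path Dijkstra), subtract its bottleneck
flux, stop when the remaining flux drops below 1% of the total. Greedy
subtraction order is part of the definition; near-degenerate paths can
re-partition under other orders.

## Free-energy and rate recovery on biased simulations

**Umbrella/WHAM.** Windows restrain the 1D CV with U + ½k(x−c)²
(k in kJ/mol/nm², default 8000; default spacing 0.05 nm; each window
started at its center with 10% equilibration discarded). WHAM's
self-consistency equations are solved by minimizing the equivalent convex
likelihood in the window shifts (L-BFGS) and then certifying the
self-consistent fixed point to the requested tolerance (default 1e-8 on
the relative shift change) — plain fixed-point iteration alone stalls on
weakly coupled window sets. The default bin width is half the window
spacing; with stiff restraints (σ ≈ 0.018 nm at 8000 kJ/mol/nm²) accurate
profiles need explicit finer bins (the validation study uses ~7 bins per
window σ), since bias factors are evaluated at bin centers. Profiles are
reported on bins with nonzero counts, pinned to min 0. The PMF is
invariant under duplicating the whole window set exactly; duplicating a
*single* window reweights it against its neighbours and perturbs the
profile at the statistical-noise level.

**Infrequent metadynamics.** Well-tempered hills
(h_k = h₀ e^{−V(s_k)/((Γ−1)kT)}, Γ > 1) are deposited every `pace` ns along
the 1D CV; the bias and its gradient are accumulated analytically on a
grid (1200 nodes, linear interpolation). Runs stop at the first frame past
the escape threshold; runs that never escape raise a censored-run error
and are excluded-but-counted by the ensemble driver. The acceleration
factor α = ⟨e^{V(s_t,t)/kT}⟩_t is accumulated per step with the bias
evaluated *before* any hill deposited at that step (keeping transition
states bias-free in expectation); rescaled time = simulated time × α.
Escape-time ensembles are checked against the Poisson law: MLE mean, KS
statistic against 1 − e^{−t/mean}, p-value from the asymptotic Kolmogorov
distribution. Estimating the mean from the same sample inflates the
p-value somewhat; the test is a consistency check, as is conventional.
The validation protocol on the 8 kT double well uses pace 0.2 ns (≈8 well
relaxation times, so deposition is genuinely infrequent), hill width
0.1 nm (about the thermal well width) and initial height 0.6 kJ/mol
(≈0.25 kT), chosen against the unbiased first-passage oracle so the
rescaled times are unbiased within the Poisson scatter; the API defaults
(pace 10 ps, 1.2 kJ/mol, Γ = 6) mirror the conventions used for solvated
protein–ligand CVs. The printed-convention hill width of 0.025 Å is
implausibly narrow for a nm-scale CV; width is therefore a required,
explicitly-chosen argument.

## Validation studies and their problem sizes

The test suite validates each stage against independent oracles
(brute-force Monte Carlo, analytic solutions, exhaustive enumeration) and
then the whole chain against the benchmark network:

* oracle equivalence (5-state network, 16 × 20 000 frames, MC with 10⁵
  chains/state);
* benchmark recovery: 3 master seeds × 25 trajectories × 40 000 frames
  (10⁶ frames/seed at 0.1 ns), tICA lag 0.5 ns, 100 clusters, MSM/HMM lag
  0.2 ns. Macro populations are required to match the analytic stationary
  distribution within 3 trajectory-bootstrap standard errors; k_on/k_off
  within a factor 1.5 of the oracle rates, aggregated as the geometric
  mean over seeds. At these sizes the ensemble contains only ~10 complete
  binding/unbinding events per seed — the factor-1.5 band and the
  seed aggregation reflect that intrinsic Poisson limit, and the slowest
  implied timescale is likewise only determined to ~25–30% there (the 10%
  t₂-recovery property is demonstrated on a moderate, well-sampled 4-state
  network instead);
* WHAM: 57 windows × 20 ns on the 8 kT double well, 0.2 kT RMSD bound on
  well-sampled bins;
* metadynamics: 15 escape runs vs a 20-run unbiased first-passage oracle,
  factor-2 bound on the median rescaled time; KS calibration on 100
  exponential-null seeds.

## Known limitations

* The HMM emission model is categorical over microstates (not a projected
  continuous-emission variant); adequate at these scales, and recorded in
  the model metadata.
* Umbrella sampling and metadynamics operate on 1D CVs only; the 2D
  landscape is analyzed through its radial coordinate.
* Rigid-body superposition RMSDs carry a float64 noise floor of ~1e-8 nm
  (square root of an O(machine-eps) residual).
* The pipeline's bound/unbound identification uses the benchmark's
  population ordering (bound = most populated macrostate); systems where
  the ligand is mostly unbound need the roles assigned explicitly.
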