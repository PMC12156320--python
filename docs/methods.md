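# Methods

## The model

A conformational ensemble is a set of N conformers with statistical
weights w, nonnegative and summing to one.  Experimental observables are
population averages, ⟨O_i⟩ = Σ_t w_t O_i(t), with NOE-derived distances
averaged as ⟨r⟩_eff = (Σ_t w_t r_t⁻⁶)^(−1/6) instead (signal intensity
falls off as r⁻⁶, so close conformers dominate).

Given prior weights w⁰ (from a force-field free-energy surface, from
trajectory counts, or uniform when no prior information exists), the
refinement corrects the prior toward agreement with M experimental
values O_iᵉˣᵖ ± σ_i.  Rather than optimizing all N weights, the package
optimizes a vector k of M per-observable force constants of an
umbrella-sampling-style bias potential,

    V(k, t) = Σ_i ½ k_i ((O_iᵉˣᵖ − O_i(t)) / σ_i)²  ,

and maps k to weights through the umbrella-reweighting identity

    w_t(k) = w⁰_t exp(−V(k, t)) / Z ,   Z = Σ_t w⁰_t exp(−V(k, t)) .

Reduced units are used throughout: k_BT ≡ 1, so k_i absorbs temperature
(only k/k_BT is identifiable).  k = 0 reproduces the prior exactly;
weights stay strictly positive on the prior's support for any finite k;
a zero-prior conformer stays at zero.  The normalization is log-sum-exp
stabilized, so large biases cannot overflow.

k is chosen by minimizing the regularized cost

    cost(k) = θ · D_KL(k) + χ²(k) ,
    χ²(w)  = (1/M) Σ_i ((O_iᵉˣᵖ − ⟨O_i⟩_w) / σ_i)² ,

where D_KL is the Kullback–Leibler divergence between prior and
reweighted ensemble.  The *forward* direction D_KL(w⁰‖w) is the default:
it is mode-covering, diverging wherever the proposal abandons mass the
prior holds, so refined ensembles retain every region the prior
populates.  The reverse (mode-seeking) direction is available as a
configuration choice.  Natural logarithms are used; divergences are in
nats.

## Optimization

`optimize_k` minimizes cost(k) with L-BFGS-B and analytic gradients,
initialized at k = 0, which guarantees cost(k_opt) ≤ χ²_init and makes
runs deterministic.  The gradient follows from
∂w_t/∂k_j = w_t (⟨d²_j⟩_w − d²[t,j]) / 2 with d²[t,j] the squared
normalized deviation; the forward-KL term has the closed form
D = ⟨V⟩_{w⁰} + ln Z, convex in k.  Default tolerances are tight
(ftol = gtol = 1e-12): cost and gradient evaluations are O(N·M), and at
small θ the cost valley is flat enough that looser tolerances leave
visibly under-converged iterates.  A line search that stalls at machine
precision is accepted as converged when a small gradient step cannot
improve the iterate.

k is unconstrained in sign by default.  Negative entries are admissible
minimizers but physically suspect as umbrella force constants (they
*amplify* deviations of one observable to compensate others); results
flag them, and `nonnegative=True` enforces k ≥ 0.

The χ² term makes cost(k) non-convex, and at small θ independent
optimizations can land in different local basins.  `regularization_path`
computes a whole θ grid robustly: it pools candidate k-vectors from a
cold start at every θ plus descending and ascending warm-start
continuation sweeps, then assigns each θ the pool candidate with the
lowest cost.  Because every θ selects from the same candidate set, the
exchange argument guarantees D_KL non-increasing and χ² non-decreasing
in θ — the expected shape of a regularization path — while each solution
is at least as good as its cold-start optimum.

## Observable classes and NOE handling

Chemical shifts (ppm) and ³J couplings (Hz) enter χ² and the bias
two-sidedly.  NOE upper distance bounds (Å) are linearized before
optimization: distances r ↦ r⁻⁶, bound b ↦ b⁻⁶, and σ′ = 6 b⁻⁷ σ by
first-order propagation, so the steeply weighted NOE average becomes a
linear average.  Bounds are one-sided by default (`noe_one_sided=True`):
an ensemble violates a bound only when its averaged distance exceeds it,
i.e. ⟨r⁻⁶⟩ < b⁻⁶ in linearized space, and only violating conformers
(r_t > b) contribute to the bias potential.  Satisfying an upper bound —
being closer than the detection limit requires — is not a disagreement
and is never penalized.  Two-sided treatment is available as
configuration for sensitivity checks.

Observables constant across all conformers add a constant to V that
cancels in Z; they are retained in χ² but produce a warning, since they
cannot steer the reweighting.

σ in the experimental file is the *total* uncertainty (experimental and
back-calculation error combined upstream); the reader performs no error
combination, and σ is mandatory for every observable.

## Choosing θ

θ sets the refinement strength: large θ pins the ensemble to the prior
(underfitting), small θ chases the data (overfitting, collapsing weight
onto few conformers).  `cross_validate_theta` estimates θ by k-fold
cross-validation over *observables* (default 5 folds; a 75/25
train/validation fraction is supported for very small observable sets):
for each θ and fold the k-vector is optimized on training observables
only, and the held-out fold is scored with

    validation score = sigmoid(ln(χ²/χ²_init)) = ratio / (1 + ratio) ,

which is scale-free, 0.5 for no change, below 0.5 when refinement
improves observables it never saw.  `select_theta` returns the θ at the
minimum of the fold-mean curve, preferring the largest θ within 1%
(relative) of the minimum — the conservative, least-reweighting choice.
A minimum on the *upper* grid boundary yields "no recommendation" (the
curve never turned up; nothing distinguishes θ values that all do
nothing); a minimum at the lower boundary is a genuine recommendation
for the strongest refinement on offer.  The default grid is 40 points,
log-spaced over [1e-3, 1e2].

As an overfitting diagnostic complementing the score, the ensemble
preservation

    e.p. = 100 · exp(−D_KL(w‖w⁰))   (reverse direction)

is the percent-scale effective fraction of the prior ensemble that
survives reweighting: 100 iff unchanged, 100/n when the weights collapse
onto one of n equally weighted prior conformers, near 0 under severe
collapse.  This exponential-of-relative-entropy definition satisfies
every property required of the diagnostic and is continuous; it is
isolated in a single function so an alternative convention can be
swapped in without touching anything else.

## Synthetic systems

`make_grid_system` emulates a blocked-dipeptide-like molecule whose
conformational space reduces to the backbone dihedrals (φ, ψ),
discretized into 10° bins on a 36 × 36 grid (1296 conformers, bin
centers −175°, …, +175°).  The free-energy surface is minus a sum of
Gaussian wells on the torus (defaults: a dominant β-sheet-like well, a
weaker α-region well, a weak left-handed well); the prior follows the
Boltzmann distribution, and depth-0 wells give the equipotential
(uniform) prior.  Observables (default 12, as in a dipeptide refinement
with ten shifts and two couplings): Karplus ³J couplings of φ and ψ,
J = A cos²(θ+Δ) + B cos(θ+Δ) + C with literature-style HN–Hα
coefficient sets, σ = 0.7 Hz; and shift-like observables built as
periodic first- plus second-harmonic surfaces of (φ, ψ) with seeded
random phases, amplitudes bounded away from zero, σ = 0.4 ppm.
Periodicity is required of any function of a dihedral, and the bounded
amplitude mirrors the curation step of real refinements, where
conformation-insensitive observables are discarded as non-representative.

`make_recovery_fixture` produces inputs with known ground truth.  The
true weights are w(k_true) biased toward a seeded shifted reference
(prior averages + N(0, 2σ) by default — a force field whose averages
genuinely disagree with experiment); experimental values are the
ensemble averages under those true weights plus seeded Gaussian noise of
0.2 σ by default.  Initial χ² then falls around 0.5–6 depending on the
seed, bracketing the 1.3–2.2 range typical of real refinement inputs.
k_true = 2.0 by default.  All randomness sits behind one seeded
generator per fixture.

What these fixtures do *not* emulate: correlated back-calculation errors
across observables, model error outside the bias family (except through
the additive noise), conformer clustering artifacts, and the
high-dimensional conformational spaces of real peptides where the
observable-to-degree-of-freedom ratio is far less favorable.  Passing
tests on these fixtures demonstrate correctness of the machinery and
sane statistical behavior, not accuracy on any particular molecule.

The three-state classifier for fast-folding hairpin peptides
(`classify_chignolin_state`) labels a conformer unfolded iff radius of
gyration > 6.3 Å AND RMSD to the reference structure > 3.0 Å; otherwise
native or misfolded according to the backbone region adopted by the
turn glycine (β_PR or α_L).  The region-to-state assignment is
convention-dependent and therefore a configurable mapping (default:
β_PR → native, α_L → misfolded).

## Numerical choices and degenerate inputs

* Weight vectors are validated to sum to one within 1e-9 and renormalized
  exactly on construction; downstream exponentials amplify drift.
* A perfect prior (χ²_init = 0) short-circuits to the k = 0 identity.
* χ² = 0 on a validation fold is floored at ratio 1e-12 inside the
  sigmoid score, keeping scores strictly inside (0, 1).
* Ties in `select_theta` resolve toward larger θ (less reweighting).
* The optimizer never returns an iterate worse than k = 0.
* Units: Å for distances and bounds, ppm for shifts, Hz for couplings,
  k_BT for energies, nats for divergences, percent for preservation.

## Cross-method comparison and its limits

The classical alternative optimizes the N weights directly under the
reverse-KL-regularized cost.  On fixtures that emulate realistic inputs
— substantial, partly irreducible disagreement between experiment and
back-calculation (initial χ² ≈ 2 with a σ-scale inconsistent component),
uniform prior — the k-vector refinement and a direct-weight optimizer
tuned to the same ensemble preservation agree in χ² to within ~5% across
strengths from under- to overfitting, and the test suite pins that
agreement.  The agreement is regime-dependent, however, and this is a
known limitation: when the experimental values are nearly exactly
reachable (low noise, truth inside the bias family), the free-weight
optimum — a convex problem solved globally — can undercut the k-family's
χ² by 20–30% at matched preservation.  In that regime the two
parameterizations genuinely differ; the k-vector method buys its M-
parameter economy and mode-covering regularization at some χ²
efficiency.  Desk-scale problem sizes used throughout the tests and the
reproduction script: N = 1296 conformers, M = 12 observables, θ grids of
12–40 points.
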