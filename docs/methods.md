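# Methods

This note documents the models, estimators, conventions and limitations of
`msmbind`, in the order the pipeline applies them.

## The physical picture and the synthetic generators

The analysis targets systems where a receptor exchanges slowly between
several metastable conformations while a small ligand binds and unbinds
quickly relative to those conformational changes. The kinetic network then
has a product structure: (conformation) × (bound / associated / unbound),
with binding transitions inside each conformation much faster than
transitions between conformations, and with conformational exchange routed
through one well-connected "hub" conformation.

### Ground-truth Markov chain

`GroundTruthSpec`/`build_ground_truth_model` construct a microstate chain
with exactly this structure, and with *exact* reversibility: the chain is a
random walk on a symmetric weight matrix S,

    T_ij = S_ij / Σ_k S_ik,   π_i ∝ Σ_k S_ik,

which satisfies detailed balance identically (no post-hoc symmetrization),
so estimator-recovery tests have a machine-precision reference. Off-diagonal
couplings are g·√(w_i w_j) with g = `binding_exchange_weight` between
adjacent substates of one conformation (bound–associated–unbound chain,
skipping absent classes) and g = `conformational_exchange_weight` between
like substate classes of a conformation and the hub. The diagonal absorbs
the remainder w_i − Σ_j S_ij, which makes the stationary distribution equal
the requested weights exactly; specs whose couplings exceed a state's
weight are rejected rather than renormalized.

Defaults: `binding_exchange_weight` 0.1, `conformational_exchange_weight`
1e-3 (ratio 100). At a ratio ≥ 50 the (n_conformations − 1) conformational
relaxation timescales separate from the binding timescales by a factor ≥ 5,
which is the regime the analysis assumes; this separation is asserted by a
property test. The default preset has seven conformations, one of them
bound-only (a conformation that exists only with the ligand bound — it
exchanges with the hub through its bound substate), star (hub) topology,
and unequal stationary weights. These values are qualitative presets
chosen to produce a clearly metastable, fully connected network, not fits
to any particular receptor. Associated substates are given small weights
(shallow, short-lived intermediates); no quantitative lifetime is claimed
for them.

Each microstate carries a representative ligand distance (bound 4 Å,
associated 10 Å, unbound 20 Å). `ligand_distance_series` turns a sampled
state sequence into a per-frame distance series by adding truncated
Gaussian noise (σ = 0.5 Å) that keeps every frame on the correct side of
the 6 Å cutoff, so the frame-level split machinery can be exercised
without relabeling ambiguity.

### Toy binder

`ToyBinderSpec`/`simulate_toy_binder` provide a continuous analogue for
exercising TICA and clustering: overdamped Langevin dynamics on

    U(x, r) = U_x(x) + ½ k_r (r − r_u)² − A·gate(x)·exp(−(r − r_b)²/2σ_b²)

with x a conformational coordinate (harmonic for one well, quartic
double-well otherwise), r ≥ 0 a binding distance (reflected at zero), and a
sigmoidal gate that opens the bound well only near the designated x-well.
Integration is fixed-step Euler–Maruyama,
z ← z − (D/kT) ∇U dt + √(2 D dt) ξ — the simplest scheme with known weak
convergence, adequate for a test system; a non-finite or out-of-box
coordinate aborts with the step index. Observables are a fixed linear mix
of (x, r) into d ≥ 2 channels plus Gaussian noise, with the raw r appended
as the ligand-distance column.

What the generators deliberately do *not* emulate: continuous-time memory
(the chain is Markovian at the frame level by construction), force-field
detail, solvent, or any specific receptor's landscape. Passing
recovery tests therefore demonstrates the correctness of the estimators on
data satisfying their assumptions, not the validity of those assumptions
for any particular MD dataset — for real data the implied-timescale and
Chapman–Kolmogorov diagnostics are the check.

## Featurization

`group_min_distances` computes per-frame minimum Euclidean distances
between named groups of 3-D points (Å); `site_ligand_distance` is the same
computation for the (recognition site, ligand) pair. Group construction —
which atoms belong to a group, heavy-atom filtering — is the caller's
responsibility: the package computes distances only and performs no
topology parsing.

## TICA

Covariances are pooled over trajectories and computed mean-free with the
symmetrized (reversible) estimator: C₀ averages both ends of each lagged
pair and C_τ is symmetrized as (C + Cᵀ)/2, consistent with the reversible
MSM downstream and guaranteeing real eigenvalues. The generalized
eigenproblem C_τ v = λ C₀ v is solved with a ridge term (default 1e-10) on
the diagonal of C₀, guarding against the rank deficiency of strongly
correlated distance features; components are normalized to unit C₀-norm,
so projections have unit instantaneous variance. Projections are plain
eigenvector projections — no kinetic-map or eigenvalue scaling — a
convention, flagged here because whitening choices change cluster
geometries. The designated ligand-distance column is excluded from the
linear map and carried through projection unchanged as a passthrough
column, because the split stage needs the physical distance, not a mixed
coordinate. Default number of components: 5. The TICA lag is a free
parameter defaulting to the MSM preprocessing lag.

## Discretization

Regular-space clustering makes one pass over the frames in input order
(trajectory file order, then frame order — the result is order-dependent
and the order is part of the contract): a frame becomes a center iff it is
≥ dmin from every existing center, so pairwise center distances are ≥ dmin
by construction. Assignment is nearest-center Euclidean with ties to the
lowest center index. `dmin` is a free parameter; the defaults in the
bundled configurations give tens to a few hundred microstates on the
synthetic presets.

The bound-state split uses the *per-frame* ligand distance at the cutoff
(default 6 Å, strict `<` for bound): each parent microstate with frames on
both sides becomes two children (bound child first), parents with frames
on one side only are kept as a single child, so the new state count is the
old count plus the number of parents actually split, and no
zero-population microstate is ever created. Downstream classification into
bound/associated/unbound instead uses each microstate's *mean* ligand
distance — two deliberately distinct criteria (frame-level for state
definition, state-level for class labels).

## Reversible MSM

Counting is sliding-window (every (s_t, s_{t+τ}) pair counts); the
uncertainty mechanism is the bootstrap, so no effective-count correction
is applied. Estimation restricts to the largest strongly connected
component of the count graph (largest by state count, ties by total
counts). The maximum-likelihood reversible transition matrix is obtained
by the self-consistent fixed-point iteration on symmetric unnormalized
flux variables,

    x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j),

initialized from the symmetrized counts, with a *relative* convergence
criterion (max change / max x, default 1e-10) since x is defined only up
to scale. The likelihood is non-decreasing across iterations (asserted in
tests), detailed balance holds to near machine precision at the fixed
point, and the attained likelihood is verified in the test suite against
an independent general-purpose constrained optimizer. Non-convergence at
`maxiter` returns the model with a flag and residual rather than raising.

Spectra of reversible matrices are computed via the symmetric similarity
transform D^{1/2} T D^{−1/2} (real eigenvalues by construction). Implied
timescales are t_k(τ) = −τ/ln|λ_k(τ)|; negative eigenvalues are handled
via |λ| and flagged with a warning. Uncertainties come from a moving-block
bootstrap: overlapping blocks of length (block size + 1) frames — block
size defaults to the lag, the +1 makes a block hold at least one
transition — are drawn with replacement up to the original total length
and treated as independent short trajectories; the mean and 1σ spread over
replicates are reported.

The Chapman–Kolmogorov test compares, for each metastable set A, the
prediction [T(τ)^k]_AA aggregated with π-weights over A against the same
quantity from a model re-estimated at lag kτ, with bootstrap bands;
multiples exceeding the data length are dropped with a warning.

## Metastable decomposition and thermodynamics

PCCA++ builds the first m right eigenvectors (π-orthonormal, the
stationary eigenvector fixed to the constant 1), locates m simplex
vertices by the spread-maximizing inner-simplex search, computes fuzzy
memberships as barycentric coordinates (clipped to ≥ 0 and row-
normalized), and assigns crisply by argmax. Eigenvalue near-degeneracy at
the cut (|λ_m − λ_{m+1}| < 1e-8) triggers an instability warning. The
number of sets defaults to the spectral-gap heuristic (largest ratio of
consecutive timescales), with explicit override.

Classification boundaries: bound d < 6 Å, associated 6 ≤ d ≤ 15 Å, unbound
d > 15 Å — boundary values fall in the associated class, a documented
convention since the source ranges state no boundary rule.

Coarse-graining: p_IJ = Σ_{i∈I,j∈J} π_i p_ij / π_I. This inherits
stationarity and detailed balance of π_I exactly (asserted at 1e-10) and
illustrates connectivity and kinetics; it is not a transferable
coarse-grained model.

Binding free energies: ΔG = −kT ln(Σ_bound π_i / Σ_unbound π_i), per
conformation (restricting both sums to the set) and overall. Associated
microstates belong to neither side of the ratio, an adopted convention.
Conformations lacking a bound or unbound substate get `None` rather than
±∞. kT defaults to 0.5962 kcal/mol (300 K). The standard-state correction
is −kT ln(c°/c_sim) with c° = 1 mol/l; with the 3.7 mM default this is
−3.34 kcal/mol, i.e. the correction makes binding more favorable when the
simulated concentration is below the reference.

## Kinetics

MFPTs solve the linear system m = τ·1 + T m off the target (zero on it),
in physical units via lag × frame interval; the residual is checked.
Coarse MFPTs are π-weighted averages over the source set. The global
binding time starts from the π-weighted *unbound* ensemble (associated
states are intermediates, not sources — an adopted convention), and
k_on = 1/(t_bind·c_sim), k_off = 1/t_unbind. For systems that are
effectively two-state (timescale separation ≥ 100×), k_off/(k_on·c°)
agrees with exp(ΔG°/kT) within 10% — asserted on a single-conformation
preset.

## Transition path theory

Forward committors solve the harmonic boundary-value problem; for
reversible models q⁻ = 1 − q⁺ (the general backward committor via the
reversed chain is implemented for completeness). Gross flux
f_ij = π_i q⁻_i T_ij q⁺_j (zero diagonal), net flux max(0, f_ij − f_ji),
total flux = net flux out of the source, rate = F / (τ Σ_i π_i q⁻_i).
Conservation at intermediates, boundary-flux equality and A↔B symmetry are
asserted at 1e-10 on every construction. Coarse fluxes sum net fluxes
between sets and require the partition not to mix source and sink states
in one set. Pathway decomposition repeatedly extracts the widest
(maximum-bottleneck) path — modified Dijkstra, ties broken toward smaller
state indices for determinism — subtracts its bottleneck flux, and stops
at k paths, at a flux fraction, or on disconnection (remainder implicit).
Displayed/aggregated fluxes are net fluxes, and the MFPT-based and
TPT-based rates are both reported when they differ (they do in general;
no reconciliation is attempted).

## Pipeline, configuration, reproducibility

`run_pipeline` chains the stages for four input modes (synthetic chain,
synthetic binder, feature CSVs, pre-discretized trajectories), writes each
stage's serialized artifact plus `manifest.json` and `summary.json` into a
run directory, and halts on the failing stage with upstream artifacts
preserved. All randomness flows from explicit per-call seeds derived from
the config seed — there is no global RNG state — so a rerun with the same
config is bit-identical. Serialization uses plain text (one-integer-per-
line discrete trajectories with `#` headers, CSV features, versioned JSON
models with full-precision floats); format versions are checked on read.

## Problem sizes in the test suite

The suite uses deliberately small systems with exact ground truth: 10⁶
sampled steps (20 states) for estimator recovery, 10⁵ walkers for hitting-
time oracles, 10⁷ steps for reactive-flux counting on a 6-state binder,
10⁵ frames for TICA source recovery, and 20 replicates for
Chapman–Kolmogorov coverage. These sizes give the statistical power the
3σ-style assertions need while keeping the default run to a couple of
minutes on one CPU.

Statistical conventions adopted in the validation suite: vector-valued
"within 3σ" checks (e.g. a 20-component stationary distribution against a
replicate-estimated SEM) use a Bonferroni-corrected t quantile for the
family-wise comparison, since the maximum of many standardized errors
exceeds 3 with high probability even for a perfect estimator;
Chapman–Kolmogorov "passes within 2σ" is a coverage statement (≥ 95% of
set/multiple points across replicates), not an every-point requirement.

## Known limitations

- PCCA++ uses the inner-simplex initial guess without the subsequent
  constrained optimization refinement; for well-separated metastable
  systems (the intended regime) the crisp assignments coincide, and the
  block-recovery and preset-recovery tests pin this behavior.
- The moving-block bootstrap treats blocks as independent; for quantities
  whose correlation time exceeds the block length (e.g. stationary
  probabilities under strong metastability) its σ is an underestimate —
  validation of such quantities uses across-trajectory spreads instead.
- No Bayesian transition-matrix sampling, hidden Markov models, TRAM,
  k-means/density clustering, VAMP scoring, or kinetic-map scaling.
- Rates and times are reported in the time unit of the input frame
  interval (default 1.0, i.e. lag units); converting k_on to
  per-molar-per-second requires the caller to supply frame intervals in
  seconds.
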