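# msmbind

Markov state model (MSM) analysis of coupled protein conformational dynamics
and ligand binding.

## What problem this solves

Receptors such as the serine protease trypsin do not bind their ligands as
rigid locks: the protein exchanges between several metastable conformations
on slow timescales, each with its own binding pocket geometry, affinity and
kinetics, while ligand association and dissociation are comparatively fast.
Characterizing this coupled system from simulation data requires more than
a two-state (bound/unbound) picture — it requires the full kinetic network
of (conformation × binding-status) states.

`msmbind` implements the complete analysis chain for this problem, for
computational chemists and structural bioinformaticians working with long
molecular-dynamics datasets:

1. **Featurization** — minimum distances between residue groups, and the
   ligand–recognition-site minimum distance (`msmbind.featurize`).
2. **TICA** — time-lagged independent component analysis finds the slowest
   linear collective coordinates by solving the generalized eigenproblem
   C(τ) v = λ C(0) v with symmetrized covariances (`msmbind.tica`).
3. **Discretization** — regular-space (uniform-distance) clustering of the
   projected coordinates, Voronoi assignment, and a frame-level split of
   every microstate at a 6 Å ligand-distance cutoff into bound/other
   children (`msmbind.discretize`).
4. **Reversible MSM** — sliding-window transition counts, largest strongly
   connected set, and the maximum-likelihood transition matrix constrained
   to detailed balance π_i T_ij = π_j T_ji, estimated by the standard
   self-consistent fixed-point iteration; validated by implied timescales
   t_k(τ) = −τ/ln λ_k(τ) with moving-block bootstrap uncertainties and the
   Chapman–Kolmogorov test (`msmbind.msm`).
5. **Metastable decomposition** — PCCA++ assigns microstates to metastable
   conformations from the simplex structure of the dominant eigenvectors;
   each microstate is classified bound (<6 Å), associated (6–15 Å) or
   unbound (>15 Å) by its mean ligand distance (`msmbind.metastable`).
6. **Thermodynamics** — per-conformation and overall binding free energies
   ΔG = −kT ln(P_bound/P_unbound), with the standard-state volume
   correction −kT ln(c°/c_sim) (`msmbind.metastable`).
7. **Kinetics** — mean first passage times by linear solve, per-conformation
   binding/unbinding times, and rate constants k_on = 1/(t_bind·c_sim),
   k_off = 1/t_unbind (`msmbind.kinetics`).
8. **Transition path theory** — forward committors, reactive fluxes
   f_ij = π_i q⁻_i T_ij q⁺_j, coarse-grained fluxes between conformations,
   and dominant pathway decomposition by iterative bottleneck (widest-path)
   removal (`msmbind.tpt`).

Because datasets of the required scale (hundreds of microseconds of MD) are
rarely shareable, the package ships a first-class synthetic-data module
(`msmbind.synthetic`): an exactly reversible ground-truth Markov chain over
(conformation × {bound, associated, unbound}) states with a hub topology and
fast binding / slow conformational exchange, plus a continuous toy binder
(overdamped Langevin dynamics on a gated 2-D binding landscape, mixed into
noisy observables). Every downstream stage is verified by parameter-recovery
tests against these generators.

## Worked example

Recover the thermodynamics and kinetics of the default seven-conformation
network from sampled trajectories:

```python
import numpy as np
from msmbind import (build_ground_truth_model, sample_markov_chain, estimate_msm,
                     pcca, classify_microstates, binding_thermodynamics,
                     binding_kinetics, flux, dominant_pathways)
from msmbind.synthetic import default_ground_truth_spec, ligand_distance_series
from msmbind.discretize import split_by_distance

truth = build_ground_truth_model(default_ground_truth_spec(seed=0))
dtrajs = [sample_markov_chain(truth, 50_000, seed=1 + k) for k in range(8)]
dists = [ligand_distance_series(truth, d, seed=101 + k) for k, d in enumerate(dtrajs)]
dtrajs, disc = split_by_distance(dtrajs, dists, cutoff=6.0)

model = estimate_msm(dtrajs, lag=5)
part = pcca(model, n_sets=7)
part.classes = classify_microstates(np.asarray(disc.mean_ligand_distances)[model.active_set])

thermo = binding_thermodynamics(model, part, kT=0.5962, c_sim=3.7e-3)
kin = binding_kinetics(model, part, c_sim=3.7e-3)
print(f"microstates: {model.n_states}, metastable sets: {part.n_sets}")
print(f"dG(sim) = {thermo.overall_sim:+.2f} kcal/mol, "
      f"volume correction = {thermo.correction:+.2f} kcal/mol, "
      f"dG(standard) = {thermo.overall_standard:+.2f} kcal/mol")
print(f"t_bind = {kin.t_bind_global:.0f} steps, t_unbind = {kin.t_unbind_global:.0f} steps")
print(f"k_on = {kin.k_on:.2f} / (M step), k_off = {kin.k_off:.4f} / step")
fn = flux(model, part.class_members("unbound"), part.class_members("bound"))
paths = dominant_pathways(fn, k=3)
print(f"total reactive flux = {fn.total_flux:.4f} / step; "
      f"top pathway carries {paths[0][1] / fn.total_flux:.0%}")
```

Output:

```
microstates: 16, metastable sets: 7
dG(sim) = -0.22 kcal/mol, volume correction = -3.34 kcal/mol, dG(standard) = -3.56 kcal/mol
t_bind = 68 steps, t_unbind = 101 steps
k_on = 3.99 / (M step), k_off = 0.0099 / step
total reactive flux = 0.0747 / step; top pathway carries 36%
```

Reading the numbers: the estimated MSM keeps all 16 microstates of the
generator, PCCA++ recovers its 7 conformations exactly, and the overall
binding free energy at the simulated ligand concentration (−0.22 kcal/mol)
plus the standard-state correction gives ΔG° ≈ −3.6 kcal/mol, within the
sampling error of the analytic ground-truth value. Binding is roughly 1.5×
faster than unbinding here, and about a third of the reactive
unbound → bound flux travels along a single conformational channel — the
behavior built into the generator.

A command-line interface mirrors the library:
`msmbind generate | tica | cluster | estimate | its | cktest | pcca |
thermo | kinetics | tpt | run`; `msmbind run --config cfg.yaml --out rundir`
executes the whole pipeline and writes per-stage artifacts plus
`summary.json`. `configs/trypsin_benzamidine_settings.yaml` records the
published study settings (6 Å split, 6/15 Å classes, τ = 30 ns, 7 sets,
3.7 mM, 5 TICA components) for reference.

## Scope

No MD engine integration: the package consumes feature matrices (CSV) or
discrete trajectories (plain text), not trajectory formats of MD engines,
and performs no structural analysis beyond distances. Details of the
models, conventions and limitations are in `docs/methods.md`.
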