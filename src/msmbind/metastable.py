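"""Metastable decomposition (PCCA++), binding classification, coarse-graining
and binding thermodynamics.

PCCA++ assigns microstates to metastable sets using the simplex structure of
the dominant eigenvectors of a reversible transition matrix: the rows of the
first m eigenvectors lie (approximately) in an (m-1)-simplex whose vertices
correspond to the most metastable microstates. Vertices are located by the
spread-maximizing inner-simplex search, memberships are the barycentric
coordinates with respect to those vertices, and the crisp assignment is the
argmax membership.

Each microstate additionally carries a ligand class from its mean
site--ligand distance: bound (< 6 A), associated (6--15 A), unbound
(> 15 A); boundary values fall in the associated class. Per-conformation
binding free energies compare the stationary probability of a set's bound
microstates with its unbound microstates,

    dG_b = -kT ln( sum_{i in bound} pi_i / sum_{i in unbound} pi_i ),

and the standard-state (volume) correction -kT ln(c_ref / c_sim) converts a
free energy at the simulated ligand concentration to the 1 mol/l reference
state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .msm import TransitionModel

__all__ = [
    "MacrostatePartition",
    "BindingThermodynamics",
    "pcca",
    "pcca_memberships",
    "classify_microstates",
    "coarse_grain",
    "binding_free_energy",
    "volume_correction",
    "binding_thermodynamics",
    "suggest_n_sets",
    "DEFAULT_KT",
]

DEFAULT_KT = 0.5962  # kcal/mol at 300 K
BOUND_CUTOFF = 6.0
ASSOCIATED_CUTOFF = 15.0


@dataclass
class MacrostatePartition:
    """Assignment of microstates to metastable sets and ligand classes."""

    assignments: np.ndarray  # microstate -> set index
    memberships: np.ndarray  # (n_micro, n_sets) fuzzy memberships
    classes: np.ndarray | None = None  # per-microstate ligand class strings
    pi_macro: np.ndarray | None = None
    coarse_transition_matrix: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        self.n_sets = int(self.assignments.max()) + 1
        counts = np.bincount(self.assignments, minlength=self.n_sets)
        if np.any(counts == 0):
            raise ValueError("every metastable set must be non-empty")
        if not self.labels:
            self.labels = [f"conf{i}" for i in range(self.n_sets)]

    def members(self, set_index: int, ligand_class: str | None = None) -> np.ndarray:
        sel = self.assignments == set_index
        if ligand_class is not None:
            if self.classes is None:
                raise ValueError("partition has no ligand classes")
            sel &= self.classes == ligand_class
        return np.where(sel)[0]

    def class_members(self, ligand_class: str) -> np.ndarray:
        if self.classes is None:
            raise ValueError("partition has no ligand classes")
        return np.where(self.classes == ligand_class)[0]


def _dominant_eigenvectors(model: TransitionModel, m: int) -> tuple[np.ndarray, np.ndarray]:
    """First m right eigenvectors (pi-orthonormal, real) of a reversible T."""
    T, pi = model.transition_matrix, model.stationary_distribution
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * T / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)
    ev, U = scipy.linalg.eigh(S)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    psi = U / sqrt_pi[:, None]
    # fix the stationary eigenvector to be exactly the constant 1
    psi[:, 0] = 1.0
    return ev, psi


def _inner_simplex_vertices(X: np.ndarray) -> np.ndarray:
    """Spread-maximizing vertex states of the eigenvector simplex."""
    n, m = X.shape
    idx = np.empty(m, dtype=np.int64)
    ortho = X.copy()
    norms = np.linalg.norm(ortho, axis=1)
    idx[0] = int(np.argmax(norms))
    ortho = ortho - ortho[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = int(np.argmax(norms))
        v = ortho[idx[j]]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("degenerate eigenvector simplex: too many sets requested")
        v = v / nv
        ortho = ortho - np.outer(ortho @ v, v)
    return idx


def pcca_memberships(model: TransitionModel, n_sets: int) -> np.ndarray:
    """Fuzzy PCCA++ memberships (rows sum to 1, entries >= 0)."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    n = model.n_states
    if n_sets > n:
        raise ValueError("n_sets exceeds number of microstates")
    if n_sets == 1:
        return np.ones((n, 1))
    ev, psi = _dominant_eigenvectors(model, n_sets)
    if n_sets < n and abs(ev[n_sets - 1] - ev[n_sets]) < 1e-8:
        warnings.warn(
            "eigenvalue near-degeneracy at the metastability cut: "
            "decomposition may be unstable"
        )
    if ev[n_sets - 1] <= 0:
        raise ValueError("n_sets exceeds the number of positive eigenvalues")
    X = psi[:, :n_sets]
    verts = _inner_simplex_vertices(X)
    A = np.linalg.inv(X[verts])
    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    rs = chi.sum(axis=1)
    chi = chi / rs[:, None]
    return chi


def pcca(model: TransitionModel, n_sets: int = 7) -> MacrostatePartition:
    """Crisp PCCA++ decomposition into metastable sets.

    Sets are relabeled densely in order of first appearance so the result
    is deterministic for a fixed model.
    """
    chi = pcca_memberships(model, n_sets)
    crisp = np.argmax(chi, axis=1)
    # dense relabel by first appearance
    seen: dict[int, int] = {}
    out = np.empty_like(crisp)
    for i, c in enumerate(crisp):
        if int(c) not in seen:
            seen[int(c)] = len(seen)
        out[i] = seen[int(c)]
    if len(seen) < n_sets:
        warnings.warn(
            f"only {len(seen)} of {n_sets} requested sets are non-empty after "
            "crisp assignment"
        )
    chi = chi[:, sorted(seen, key=seen.__getitem__)]
    return MacrostatePartition(assignments=out, memberships=chi)


def suggest_n_sets(timescales: np.ndarray, max_sets: int = 12) -> int:
    """Spectral-gap heuristic: cut after the largest timescale ratio.

    With timescales t_2 >= t_3 >= ... the number of metastable sets is k+1
    where t_{k+1}/t_{k+2} is maximal (a gap after the k-th relaxation
    timescale separates k+1 metastable sets).
    """
    ts = np.asarray(timescales, dtype=float)
    ts = ts[np.isfinite(ts) & (ts > 0)][: max_sets - 1]
    if ts.size < 2:
        return 2
    ratios = ts[:-1] / ts[1:]
    return int(np.argmax(ratios)) + 2


def classify_microstates(
    mean_distances: np.ndarray,
    bound_cutoff: float = BOUND_CUTOFF,
    associated_cutoff: float = ASSOCIATED_CUTOFF,
) -> np.ndarray:
    """Ligand class per microstate from its mean site--ligand distance (A).

    bound: d < bound_cutoff; associated: bound_cutoff <= d <= associated
    cutoff; unbound: d > associated_cutoff.
    """
    d = np.asarray(mean_distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.full(d.shape, "associated", dtype=object)
    out[d < bound_cutoff] = "bound"
    out[d > associated_cutoff] = "unbound"
    return out.astype(str)


def coarse_grain(
    model: TransitionModel, partition: MacrostatePartition
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse-grained transition matrix p_IJ and macrostate probabilities pi_I.

    p_IJ = sum_{i in I, j in J} pi_i p_ij / pi_I. The result is
    row-stochastic and inherits stationarity and detailed balance of pi_I
    exactly; it illustrates connectivity and kinetics but is not a
    transferable coarse model.
    """
    if partition.assignments.size != model.n_states:
        raise ValueError("partition does not cover the model's active set")
    n_sets = partition.n_sets
    pi = model.stationary_distribution
    T = model.transition_matrix
    M = np.zeros((model.n_states, n_sets))
    M[np.arange(model.n_states), partition.assignments] = 1.0
    pi_macro = M.T @ pi
    if np.any(pi_macro <= 0):
        raise ValueError("empty macrostate")
    flux = M.T @ (pi[:, None] * T) @ M
    P = flux / pi_macro[:, None]
    return P, pi_macro


def binding_free_energy(
    pi: np.ndarray,
    bound_set: np.ndarray,
    unbound_set: np.ndarray,
    kT: float = DEFAULT_KT,
) -> float:
    """dG = -kT ln(P_bound / P_unbound) in the units of kT (kcal/mol).

    Raises when either side has zero probability (e.g. a bound-only
    conformation has no defined binding free energy).
    """
    pi = np.asarray(pi, dtype=float)
    bound_set = np.asarray(bound_set, dtype=np.int64)
    unbound_set = np.asarray(unbound_set, dtype=np.int64)
    pb = pi[bound_set].sum() if bound_set.size else 0.0
    pu = pi[unbound_set].sum() if unbound_set.size else 0.0
    if pb <= 0 or pu <= 0:
        side = "bound" if pb <= 0 else "unbound"
        raise ValueError(f"{side} set has zero probability: free energy unbounded")
    return float(-kT * np.log(pb / pu))


def volume_correction(
    c_sim: float, c_ref: float = 1.0, kT: float = DEFAULT_KT
) -> float:
    """Standard-state correction dG_corr = -kT ln(c_ref / c_sim) (kcal/mol).

    For c_sim < c_ref the correction is negative: binding is more favorable
    at the reference concentration than at the dilute simulated one; the
    standard-state free energy is dG_sim + dG_corr.
    """
    if c_sim <= 0 or c_ref <= 0:
        raise ValueError("concentrations must be positive")
    return float(-kT * np.log(c_ref / c_sim))


@dataclass
class BindingThermodynamics:
    """Per-conformation and overall binding free energies (kcal/mol)."""

    kT: float
    c_sim: float
    c_ref: float
    per_set: dict[int, float | None]
    overall_sim: float
    correction: float

    @property
    def overall_standard(self) -> float:
        return self.overall_sim + self.correction


def binding_thermodynamics(
    model: TransitionModel,
    partition: MacrostatePartition,
    kT: float = DEFAULT_KT,
    c_sim: float = 3.7e-3,
    c_ref: float = 1.0,
) -> BindingThermodynamics:
    """Binding free energy per metastable set and overall.

    The overall value compares all bound against all unbound microstates
    (associated microstates belong to neither side); sets lacking a bound or
    an unbound microstate get None instead of +-infinity.
    """
    if partition.classes is None:
        raise ValueError("partition must carry ligand classes")
    pi = model.stationary_distribution
    per_set: dict[int, float | None] = {}
    for I in range(partition.n_sets):
        b = partition.members(I, "bound")
        u = partition.members(I, "unbound")
        if b.size == 0 or u.size == 0:
            per_set[I] = None
            continue
        per_set[I] = binding_free_energy(pi, b, u, kT=kT)
    overall = binding_free_energy(
        pi, partition.class_members("bound"), partition.class_members("unbound"), kT=kT
    )
    corr = volume_correction(c_sim, c_ref, kT=kT)
    return BindingThermodynamics(
        kT=kT, c_sim=c_sim, c_ref=c_ref, per_set=per_set,
        overall_sim=overall, correction=corr,
    )
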