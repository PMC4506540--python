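"""Mean first passage times and binding/unbinding rate constants.

The MFPT vector m to a target set J solves the linear system

    m_i = 0                        for i in J
    m_i = tau + sum_j T_ij m_j     otherwise,

in physical units via tau = lag x frame_interval. A coarse-grained MFPT
from set I to set J is the stationary-weighted average of the microstate
MFPTs over I. Rate constants follow the two-state reduction: the
association rate k_on = 1 / (t_bind c_sim) normalizes the global binding
MFPT (from the pi-weighted unbound ensemble to the bound set) by the
simulated ligand concentration; the dissociation rate is k_off =
1 / t_unbind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .metastable import MacrostatePartition
from .msm import TransitionModel

__all__ = ["KineticsReport", "mfpt", "coarse_mfpt", "rate_constants", "binding_kinetics"]


def mfpt(model: TransitionModel, target: np.ndarray) -> np.ndarray:
    """Mean first passage time from every microstate to the target set.

    Returns times in physical units (lag x frame_interval per step); zero on
    target states. Raises if the target is unreachable from some state.
    """
    target = np.asarray(target, dtype=np.int64)
    if target.size == 0:
        raise ValueError("target set is empty")
    n = model.n_states
    if np.any((target < 0) | (target >= n)):
        raise ValueError("target contains invalid state indices")
    tau = model.lag_time
    m = np.zeros(n)
    rest = np.setdiff1d(np.arange(n), target)
    if rest.size == 0:
        return m  # target covers the whole space
    T = model.transition_matrix
    A = np.eye(rest.size) - T[np.ix_(rest, rest)]
    try:
        sol = np.linalg.solve(A, np.full(rest.size, tau))
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular MFPT system (unreachable target?): {e}") from None
    resid = np.max(np.abs(A @ sol - tau))
    if not np.all(np.isfinite(sol)) or np.any(sol < -1e-9 * tau):
        raise ValueError("MFPT system ill-conditioned (unreachable target?)")
    if resid > 1e-8 * tau * max(1.0, np.abs(sol).max() / tau):
        warnings.warn(f"MFPT linear-system residual {resid:.2e}")
    m[rest] = sol
    return m


def coarse_mfpt(
    model: TransitionModel,
    source: np.ndarray,
    target: np.ndarray,
    pi: np.ndarray | None = None,
) -> float:
    """Stationary-weighted MFPT from set I to set J.

    sum_{i in I} (pi_i / pi_I) m_i(J); source and target must be disjoint
    and non-empty.
    """
    source = np.asarray(source, dtype=np.int64)
    target = np.asarray(target, dtype=np.int64)
    if source.size == 0 or target.size == 0:
        raise ValueError("source and target must be non-empty")
    if np.intersect1d(source, target).size:
        raise ValueError("source and target must be disjoint")
    if pi is None:
        pi = model.stationary_distribution
    m = mfpt(model, target)
    w = pi[source]
    return float(w @ m[source] / w.sum())


def rate_constants(
    t_bind_global: float, t_unbind_global: float, c_sim: float
) -> tuple[float, float]:
    """(k_on, k_off) from global binding/unbinding MFPTs.

    k_on = 1 / (t_bind c_sim) in 1/(concentration x time); k_off =
    1 / t_unbind. Times must be in the desired output time unit already.
    """
    if t_bind_global <= 0 or t_unbind_global <= 0:
        raise ValueError("passage times must be positive")
    if c_sim <= 0:
        raise ValueError("concentration must be positive")
    return 1.0 / (t_bind_global * c_sim), 1.0 / t_unbind_global


@dataclass
class KineticsReport:
    """Binding/unbinding kinetics of a classified partition."""

    t_bind_global: float
    t_unbind_global: float
    k_on: float
    k_off: float
    c_sim: float
    t_bind_per_set: dict[int, float | None] = field(default_factory=dict)
    t_unbind_per_set: dict[int, float | None] = field(default_factory=dict)
    time_unit_warning: bool = False


def binding_kinetics(
    model: TransitionModel,
    partition: MacrostatePartition,
    c_sim: float = 3.7e-3,
) -> KineticsReport:
    """Global and per-conformation binding and unbinding kinetics.

    t_bind is the pi-weighted MFPT from all unbound microstates to the bound
    set (associated states are intermediates, not sources); t_unbind is the
    reverse. Per-conformation times restrict the source to the
    conformation's own unbound (resp. bound) microstates while keeping the
    global target, so they answer "starting unbound in conformation I, how
    long to bind anywhere" -- and None when the conformation lacks that
    substate.
    """
    if partition.classes is None:
        raise ValueError("partition must carry ligand classes")
    bound = partition.class_members("bound")
    unbound = partition.class_members("unbound")
    if bound.size == 0 or unbound.size == 0:
        raise ValueError("need both bound and unbound microstates")
    t_bind = coarse_mfpt(model, unbound, bound)
    t_unbind = coarse_mfpt(model, bound, unbound)
    k_on, k_off = rate_constants(t_bind, t_unbind, c_sim)
    tb: dict[int, float | None] = {}
    tu: dict[int, float | None] = {}
    for I in range(partition.n_sets):
        u = partition.members(I, "unbound")
        b = partition.members(I, "bound")
        tb[I] = coarse_mfpt(model, u, bound) if u.size else None
        tu[I] = coarse_mfpt(model, b, unbound) if b.size else None
    return KineticsReport(
        t_bind_global=t_bind, t_unbind_global=t_unbind,
        k_on=k_on, k_off=k_off, c_sim=c_sim,
        t_bind_per_set=tb, t_unbind_per_set=tu,
    )
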