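"""Transition path theory: committors, reactive fluxes, and pathways.

For a source set A and sink set B, the forward committor q+ solves the
boundary-value problem (0 on A, 1 on B, harmonic elsewhere); for reversible
dynamics the backward committor is q- = 1 - q+. The gross reactive flux of
A -> B transitions through edge i -> j is

    f_ij = pi_i q-_i T_ij q+_j      (i != j),

the net flux is f+_ij = max(0, f_ij - f_ji), and the total reactive flux F
is the net flux out of A (equivalently into B). The TPT rate is
F / (tau sum_i pi_i q-_i). Dominant pathways are extracted by iterative
bottleneck (widest-path) decomposition of the net-flux graph.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .metastable import MacrostatePartition
from .msm import TransitionModel

__all__ = ["FluxNetwork", "committor", "flux", "coarse_flux", "dominant_pathways"]


def committor(
    model: TransitionModel, A: np.ndarray, B: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward committors for source A and sink B.

    Returns (q_plus, q_minus); the backward committor uses the
    time-reversed chain, which for a reversible model reduces to
    q- = 1 - q+.
    """
    A = np.unique(np.asarray(A, dtype=np.int64))
    B = np.unique(np.asarray(B, dtype=np.int64))
    if A.size == 0 or B.size == 0:
        raise ValueError("A and B must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("A and B must be disjoint")
    n = model.n_states
    T = model.transition_matrix
    q = np.zeros(n)
    q[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if inter.size:
        M = np.eye(inter.size) - T[np.ix_(inter, inter)]
        rhs = T[np.ix_(inter, B)].sum(axis=1)
        try:
            q[inter] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as e:
            raise ValueError(f"singular committor system: {e}") from None
    q = np.clip(q, 0.0, 1.0)
    if model.is_reversible():
        qm = 1.0 - q
    else:  # general backward committor via the reversed chain
        pi = model.stationary_distribution
        Tb = (pi[None, :] * T.T) / pi[:, None]
        qm = np.zeros(n)
        qm[A] = 1.0
        if inter.size:
            M = np.eye(inter.size) - Tb[np.ix_(inter, inter)]
            rhs = Tb[np.ix_(inter, A)].sum(axis=1)
            qm[inter] = np.linalg.solve(M, rhs)
        qm = np.clip(qm, 0.0, 1.0)
    return q, qm


@dataclass
class FluxNetwork:
    """Reactive flux network between a source set A and sink set B."""

    A: np.ndarray
    B: np.ndarray
    q_plus: np.ndarray
    q_minus: np.ndarray
    gross_flux: np.ndarray
    net_flux: np.ndarray
    total_flux: float
    rate: float
    lag_time: float = 1.0
    pathways: list[tuple[list[int], float]] = field(default_factory=list)

    def check(self, tol: float = 1e-10) -> None:
        """Assert flux conservation and boundary conditions."""
        n = self.q_plus.size
        inter = np.setdiff1d(np.arange(n), np.concatenate([self.A, self.B]))
        F = self.net_flux
        imbalance = F.sum(axis=1) - F.sum(axis=0)
        scale = max(self.total_flux, 1e-300)
        assert np.all(np.abs(imbalance[inter]) <= tol * max(1.0, scale)), "flux not conserved"
        out_A = F[self.A, :].sum() - F[:, self.A].sum()
        into_B = F[:, self.B].sum() - F[self.B, :].sum()
        assert abs(out_A - self.total_flux) <= tol * max(1.0, scale)
        assert abs(into_B - self.total_flux) <= tol * max(1.0, scale)


def flux(
    model: TransitionModel,
    A: np.ndarray,
    B: np.ndarray,
    q_plus: np.ndarray | None = None,
    q_minus: np.ndarray | None = None,
) -> FluxNetwork:
    """Reactive flux network for the transition A -> B.

    Committors are computed if not supplied. Fluxes are probabilities per
    step of the model's lag; the rate is per physical time unit.
    """
    A = np.unique(np.asarray(A, dtype=np.int64))
    B = np.unique(np.asarray(B, dtype=np.int64))
    if q_plus is None or q_minus is None:
        q_plus, q_minus = committor(model, A, B)
    pi = model.stationary_distribution
    T = model.transition_matrix
    G = (pi * q_minus)[:, None] * T * q_plus[None, :]
    np.fill_diagonal(G, 0.0)
    net = np.clip(G - G.T, 0.0, None)
    total = float(net[A, :].sum() - net[:, A].sum())
    denom = model.lag_time * float(pi @ q_minus)
    rate = total / denom if denom > 0 else np.nan
    fn = FluxNetwork(
        A=A, B=B, q_plus=q_plus, q_minus=q_minus,
        gross_flux=G, net_flux=net, total_flux=total, rate=rate,
        lag_time=model.lag_time,
    )
    fn.check()
    return fn


def coarse_flux(fluxnet: FluxNetwork, partition: MacrostatePartition) -> np.ndarray:
    """Net reactive flux aggregated between macrostates.

    F_IJ = sum_{i in I, j in J} f+_ij for I != J. The partition must not
    place source and sink states in the same set as intermediates would make
    the aggregation ill-defined.
    """
    assign = partition.assignments
    n_sets = partition.n_sets
    inter = np.setdiff1d(
        np.arange(assign.size), np.concatenate([fluxnet.A, fluxnet.B])
    )
    a_sets = set(assign[fluxnet.A].tolist())
    b_sets = set(assign[fluxnet.B].tolist())
    if a_sets & b_sets:
        raise ValueError("partition mixes source and sink states in one set")
    M = np.zeros((assign.size, n_sets))
    M[np.arange(assign.size), assign] = 1.0
    F = M.T @ fluxnet.net_flux @ M
    np.fill_diagonal(F, 0.0)
    return F


def _widest_path(
    cap: np.ndarray, A: np.ndarray, B: np.ndarray
) -> tuple[list[int], float] | None:
    """Maximum-bottleneck path from any state in A to any in B.

    Modified Dijkstra maximizing the minimum edge capacity; ties among
    equal-capacity paths break toward lexicographically smaller state order
    (determinism contract).
    """
    n = cap.shape[0]
    best = np.zeros(n)
    prev = np.full(n, -1, dtype=np.int64)
    visited = np.zeros(n, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for a in sorted(A.tolist()):
        best[a] = np.inf
        heapq.heappush(heap, (-np.inf, a, -1))
    Bset = set(B.tolist())
    while heap:
        negw, u, p = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        prev[u] = p
        if u in Bset:
            path = [u]
            while prev[path[-1]] != -1:
                path.append(int(prev[path[-1]]))
            path.reverse()
            return path, float(-negw)
        w_u = -negw
        for v in np.nonzero(cap[u] > 0)[0]:
            if visited[v]:
                continue
            w = min(w_u, cap[u, v])
            if w > best[v]:
                best[v] = w
                heapq.heappush(heap, (-w, int(v), u))
    return None


def dominant_pathways(
    fluxnet: FluxNetwork,
    k: int | None = None,
    flux_fraction: float | None = None,
) -> list[tuple[list[int], float]]:
    """Decompose the net flux into dominant A -> B pathways.

    Repeatedly extracts the widest (highest minimum-capacity) path on the
    net-flux graph, records it with its bottleneck flux, and subtracts that
    flux along the path. Stops after ``k`` paths, when the cumulative flux
    reaches ``flux_fraction`` of the total, or when A and B disconnect (the
    unassigned remainder is then implicit).
    """
    if k is None and flux_fraction is None:
        flux_fraction = 1.0 - 1e-10
    cap = fluxnet.net_flux.copy()
    paths: list[tuple[list[int], float]] = []
    carried = 0.0
    while True:
        if k is not None and len(paths) >= k:
            break
        if flux_fraction is not None and fluxnet.total_flux > 0 and carried >= flux_fraction * fluxnet.total_flux:
            break
        found = _widest_path(cap, fluxnet.A, fluxnet.B)
        if found is None:
            break
        path, bottleneck = found
        if bottleneck <= 1e-16 * max(fluxnet.total_flux, 1.0):
            break
        for u, v in zip(path[:-1], path[1:]):
            cap[u, v] -= bottleneck
        carried += bottleneck
        paths.append((path, bottleneck))
    fluxnet.pathways = paths
    return paths
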