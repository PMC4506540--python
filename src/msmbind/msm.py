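"""Reversible Markov state model estimation and validation.

Workflow: sliding-window transition counting at a lag time, restriction to
the largest strongly connected set, maximum-likelihood estimation of a
transition matrix constrained to detailed balance, and the two standard
validation diagnostics -- implied timescales as a function of lag (with
moving-block bootstrap uncertainties) and the Chapman-Kolmogorov test.

The reversible maximum-likelihood estimator maximizes

    L(T) = prod_ij T_ij ** c_ij

subject to row-stochasticity and detailed balance pi_i T_ij = pi_j T_ji.
It is solved by the standard self-consistent fixed-point iteration on the
unnormalized symmetric variables x_ij = pi_i T_ij:

    x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j)

with x_i = sum_j x_ij and c_i = sum_j c_ij, which increases the likelihood
monotonically and converges to the constrained maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import networkx as nx

from .trajectories import DiscreteTrajectory

__all__ = [
    "CountMatrix",
    "TransitionModel",
    "TimescaleTable",
    "CKTestResult",
    "count_transitions",
    "largest_connected_set",
    "estimate_reversible",
    "stationary_distribution",
    "transition_matrix_eigenvalues",
    "implied_timescales",
    "ck_test",
    "estimate_msm",
]


@dataclass
class CountMatrix:
    """Transition counts c_ij at a fixed lag, sliding-window mode."""

    counts: np.ndarray
    lag: int
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix T(tau) with stationary distribution.

    ``active_set`` maps row/column indices of ``transition_matrix`` back to
    the microstate labels of the original discretization (identity when the
    model was built directly).
    """

    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    lag: int = 1
    frame_interval: float = 1.0
    active_set: np.ndarray | None = None
    converged: bool = True
    n_iter: int = 0
    residual: float = 0.0

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.stationary_distribution, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows must sum to 1")
        if np.any(T < -1e-15) or np.any(T > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if pi.shape != (T.shape[0],):
            raise ValueError("stationary distribution shape mismatch")
        self.transition_matrix = T
        self.stationary_distribution = pi / pi.sum()
        if self.active_set is None:
            self.active_set = np.arange(T.shape[0])
        else:
            self.active_set = np.asarray(self.active_set, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def lag_time(self) -> float:
        """Lag in physical units (lag frames x frame interval)."""
        return self.lag * self.frame_interval

    def is_reversible(self, tol: float = 1e-8) -> bool:
        T, pi = self.transition_matrix, self.stationary_distribution
        flux = pi[:, None] * T
        return bool(np.max(np.abs(flux - flux.T)) < tol)

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        return transition_matrix_eigenvalues(
            self.transition_matrix, self.stationary_distribution, k=k
        )

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied relaxation timescales -tau/ln|lambda| in physical units.

        The unit eigenvalue is dropped; negative eigenvalues are handled via
        their magnitude (flagged by a warning elsewhere).
        """
        ev = self.eigenvalues(None if k is None else k + 1)[1:]
        with np.errstate(divide="ignore"):
            ts = -self.lag_time / np.log(np.abs(ev))
        return ts if k is None else ts[:k]


def count_transitions(
    dtrajs: list[DiscreteTrajectory], lag: int, n_states: int | None = None
) -> CountMatrix:
    """Sliding-window transition counts at the given lag (frames).

    Every pair (s_t, s_{t+lag}) in every trajectory increments c, so the
    total count equals sum over trajectories of (length - lag).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    usable = [d for d in dtrajs if len(d) > lag]
    if not usable:
        raise ValueError(f"no trajectory longer than lag={lag}")
    if n_states is None:
        n_states = int(max(d.states.max() for d in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    for d in usable:
        s = d.states
        np.add.at(C, (s[:-lag], s[lag:]), 1.0)
    return CountMatrix(C, lag=lag, frame_interval=usable[0].frame_interval)


def largest_connected_set(C: CountMatrix) -> tuple[np.ndarray, CountMatrix]:
    """Largest strongly connected component of the count graph.

    Edges are directed i -> j wherever c_ij > 0. The largest component by
    state count is kept (ties broken by total counts within the component);
    the restricted count matrix preserves all counts among kept states.
    """
    n = C.n_states
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(C.counts > 0)
    G.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = list(nx.strongly_connected_components(G))
    comps.sort(key=lambda c: (len(c), C.counts[np.ix_(sorted(c), sorted(c))].sum()))
    keep = np.array(sorted(comps[-1]), dtype=np.int64)
    dropped = n - keep.size
    if dropped:
        warnings.warn(f"{dropped} state(s) outside the largest connected set dropped")
    sub = CountMatrix(C.counts[np.ix_(keep, keep)], lag=C.lag, frame_interval=C.frame_interval)
    return keep, sub


def _loglik(C: np.ndarray, T: np.ndarray) -> float:
    mask = C > 0
    with np.errstate(divide="ignore"):
        return float(np.sum(C[mask] * np.log(T[mask])))


def estimate_reversible(
    C: CountMatrix,
    tol: float = 1e-10,
    maxiter: int = 100_000,
    return_loglik_trace: bool = False,
) -> TransitionModel:
    """Maximum-likelihood reversible transition matrix from counts.

    Requires an irreducible count matrix (restrict with
    :func:`largest_connected_set` first). Detailed balance holds by
    construction of the symmetric fixed point; the log-likelihood increases
    monotonically across iterations.
    """
    Cm = C.counts
    n = C.n_states
    # irreducibility check on the symmetrized sparsity pattern is not enough:
    # the MLE needs the directed graph strongly connected
    G = nx.DiGraph((int(i), int(j)) for i, j in zip(*np.nonzero(Cm > 0)))
    G.add_nodes_from(range(n))
    if not nx.is_strongly_connected(G):
        raise ValueError(
            "count matrix is reducible; restrict to the largest connected set first"
        )
    c_row = Cm.sum(axis=1)
    Csym = Cm + Cm.T
    x = Csym.copy()  # init: symmetrized counts
    sym_mask = Csym > 0
    trace: list[float] = []
    residual = np.inf
    it = 0
    for it in range(1, maxiter + 1):
        x_row = x.sum(axis=1)
        q = c_row / x_row  # c_i / x_i
        denom = q[:, None] + q[None, :]
        x_new = np.where(sym_mask, Csym / np.where(denom > 0, denom, 1.0), 0.0)
        # relative residual: x is only defined up to overall scale
        residual = float(np.max(np.abs(x_new - x)) / np.max(x_new))
        x = x_new
        if return_loglik_trace:
            xr = x.sum(axis=1)
            trace.append(_loglik(Cm, x / xr[:, None]))
        if residual < tol:
            break
    x_row = x.sum(axis=1)
    T = x / x_row[:, None]
    pi = x_row / x_row.sum()
    model = TransitionModel(
        T, pi, lag=C.lag, frame_interval=C.frame_interval,
        converged=residual < tol, n_iter=it, residual=residual,
    )
    if not model.converged:
        warnings.warn(
            f"reversible MLE not converged after {maxiter} iterations "
            f"(residual {residual:.2e})"
        )
    if return_loglik_trace:
        model.loglik_trace = np.array(trace)  # type: ignore[attr-defined]
    return model


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix.

    Left eigenvector of eigenvalue 1, normalized to sum 1, all entries > 0.
    """
    T = np.asarray(T, dtype=float)
    G = nx.DiGraph((int(i), int(j)) for i, j in zip(*np.nonzero(T > 0)))
    G.add_nodes_from(range(T.shape[0]))
    if not nx.is_strongly_connected(G):
        raise ValueError("transition matrix is reducible")
    w, vl = scipy.linalg.eig(T.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(vl[:, k])
    pi = np.abs(pi)
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise ValueError("non-positive stationary probability (reducible input?)")
    return pi


def transition_matrix_eigenvalues(
    T: np.ndarray, pi: np.ndarray | None = None, k: int | None = None
) -> np.ndarray:
    """Real sorted (descending) eigenvalues of a reversible transition matrix.

    Uses the similarity transform D^{1/2} T D^{-1/2} (symmetric for matrices
    in detailed balance with pi) so the spectrum is computed by a symmetric
    eigensolver and is exactly real.
    """
    T = np.asarray(T, dtype=float)
    if pi is None:
        pi = stationary_distribution(T)
    sqrt_pi = np.sqrt(pi)
    S = sqrt_pi[:, None] * T / sqrt_pi[None, :]
    S = 0.5 * (S + S.T)  # symmetrize away round-off
    ev = scipy.linalg.eigvalsh(S)[::-1]
    return ev if k is None else ev[:k]


@dataclass
class TimescaleTable:
    """Implied timescales per lag, with moving-block bootstrap intervals.

    ``timescales[l, k]`` is the point estimate of the (k+2)-th slowest
    relaxation timescale at ``lags[l]`` (the stationary process is dropped).
    Bootstrap mean and 1-sigma intervals have the same layout; NaN when
    n_boot = 0.
    """

    lags: np.ndarray
    timescales: np.ndarray
    boot_mean: np.ndarray
    boot_std: np.ndarray
    frame_interval: float = 1.0
    negative_eigenvalue_flag: bool = False

    def to_frame(self):
        import pandas as pd

        rows = []
        for li, lag in enumerate(self.lags):
            for k in range(self.timescales.shape[1]):
                rows.append(
                    {
                        "lag": lag,
                        "index": k + 2,
                        "value": self.timescales[li, k],
                        "lo": self.boot_mean[li, k] - self.boot_std[li, k],
                        "hi": self.boot_mean[li, k] + self.boot_std[li, k],
                    }
                )
        return pd.DataFrame(rows)


def _moving_block_starts(
    dtrajs: list[DiscreteTrajectory], block: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw moving blocks with replacement to the original total length.

    Returns (traj_index, start) arrays; every admissible overlapping block
    of ``block`` frames across all trajectories is a candidate. Each block
    is treated as an independent short trajectory downstream (no artificial
    transitions across block boundaries).
    """
    cand_t: list[np.ndarray] = []
    cand_s: list[np.ndarray] = []
    for ti, d in enumerate(dtrajs):
        if len(d) >= block:
            n = len(d) - block + 1
            cand_t.append(np.full(n, ti, dtype=np.int64))
            cand_s.append(np.arange(n, dtype=np.int64))
    if not cand_t:
        raise ValueError(f"no trajectory provides a block of {block} frames")
    ct = np.concatenate(cand_t)
    cs = np.concatenate(cand_s)
    total = sum(len(d) for d in dtrajs)
    n_blocks = int(np.ceil(total / block))
    pick = rng.integers(ct.size, size=n_blocks)
    return ct[pick], cs[pick]


def _counts_from_blocks(
    dtrajs: list[DiscreteTrajectory],
    traj_idx: np.ndarray,
    starts: np.ndarray,
    block: int,
    lag: int,
    n_states: int,
) -> CountMatrix:
    """Sliding-window counts at ``lag`` restricted to the sampled blocks."""
    if block <= lag:
        raise ValueError("block must exceed the lag to hold a transition")
    C = np.zeros((n_states, n_states))
    offs = np.arange(block - lag, dtype=np.int64)
    for ti in np.unique(traj_idx):
        s = starts[traj_idx == ti]
        pos = (s[:, None] + offs[None, :]).ravel()
        states = dtrajs[ti].states
        np.add.at(C, (states[pos], states[pos + lag]), 1.0)
    if C.sum() == 0:
        raise ValueError("no transitions in resampled blocks")
    return CountMatrix(C, lag=lag, frame_interval=dtrajs[0].frame_interval)


def implied_timescales(
    dtrajs: list[DiscreteTrajectory],
    lags: list[int],
    n_timescales: int = 5,
    n_boot: int = 0,
    block_size: int | None = None,
    seed: int | None = None,
) -> TimescaleTable:
    """Implied timescales t_k(tau) = -tau/ln|lambda_k(tau)| over lags.

    For each lag a reversible MSM is estimated on the largest connected set
    and the slowest ``n_timescales`` relaxation timescales are reported in
    physical units. With ``n_boot`` > 0, trajectories are resampled as moving
    blocks of ``block_size`` frames (default: the lag, plus one frame so each
    block holds at least one transition) and the bootstrap mean and 1-sigma
    spread are attached.
    """
    n_states = int(max(d.states.max() for d in dtrajs)) + 1
    lags_arr = np.asarray(lags, dtype=int)
    nts = n_timescales
    ts = np.full((len(lags_arr), nts), np.nan)
    bmean = np.full_like(ts, np.nan)
    bstd = np.full_like(ts, np.nan)
    neg_flag = False
    rng = np.random.default_rng(seed)

    def _ts_from_counts(C: CountMatrix) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, Cr = largest_connected_set(C)
            m = estimate_reversible(Cr)
        k = min(nts, m.n_states - 1)
        out = np.full(nts, np.nan)
        out[:k] = m.timescales(k)
        return out

    for li, lag in enumerate(lags_arr):
        C = count_transitions(dtrajs, int(lag), n_states=n_states)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, Cr = largest_connected_set(C)
            model = estimate_reversible(Cr)
        k = min(nts, model.n_states - 1)
        ev = model.eigenvalues(k + 1)[1:]
        if np.any(ev < 0):
            neg_flag = True
        ts[li, :k] = model.timescales(k)
        if n_boot > 0:
            block = (block_size if block_size is not None else int(lag)) + 1
            reps = np.full((n_boot, nts), np.nan)
            for b in range(n_boot):
                ti_b, s_b = _moving_block_starts(dtrajs, block, rng)
                try:
                    Cb = _counts_from_blocks(dtrajs, ti_b, s_b, block, int(lag), n_states)
                    reps[b] = _ts_from_counts(Cb)
                except ValueError:
                    continue
            bmean[li] = np.nanmean(reps, axis=0)
            bstd[li] = np.nanstd(reps, axis=0, ddof=1)
    if neg_flag:
        warnings.warn(
            "negative eigenvalue(s) encountered; timescales use |lambda|"
        )
    return TimescaleTable(
        lags_arr, ts, bmean, bstd,
        frame_interval=dtrajs[0].frame_interval,
        negative_eigenvalue_flag=neg_flag,
    )


@dataclass
class CKTestResult:
    """Chapman-Kolmogorov test: predicted vs re-estimated set probabilities.

    For each metastable set A and lag multiple k the model estimated at the
    base lag predicts p_pred(k tau) = [T(tau)^k]_AA (pi-weighted set-to-set
    probability) which is compared with p_est from a model estimated directly
    at k tau.
    """

    multiples: np.ndarray
    set_labels: list[int]
    predicted: np.ndarray  # (n_sets, n_multiples)
    estimated: np.ndarray
    predicted_std: np.ndarray
    estimated_std: np.ndarray
    lag: int = 1

    def to_frame(self):
        import pandas as pd

        rows = []
        for si, s in enumerate(self.set_labels):
            for ki, k in enumerate(self.multiples):
                rows.append(
                    {
                        "set": s,
                        "multiple": int(k),
                        "predicted": self.predicted[si, ki],
                        "predicted_std": self.predicted_std[si, ki],
                        "estimated": self.estimated[si, ki],
                        "estimated_std": self.estimated_std[si, ki],
                    }
                )
        return pd.DataFrame(rows)


def _set_probability(model: TransitionModel, members: np.ndarray, power: int = 1) -> float:
    """pi-weighted probability of remaining in the member set after `power` steps."""
    T = np.linalg.matrix_power(model.transition_matrix, power) if power > 1 else model.transition_matrix
    pi = model.stationary_distribution
    sel = np.isin(model.active_set, members)
    if not sel.any():
        return np.nan
    w = pi[sel] / pi[sel].sum()
    return float(w @ T[np.ix_(sel, sel)].sum(axis=1))


def ck_test(
    dtrajs: list[DiscreteTrajectory],
    lag: int,
    multiples: list[int],
    sets: list[np.ndarray],
    n_boot: int = 0,
    seed: int | None = None,
) -> CKTestResult:
    """Chapman-Kolmogorov test for metastable-set self-transition probabilities.

    ``sets`` is a list of microstate index arrays. Multiples whose lag k*tau
    leaves no usable trajectory are dropped with a warning.
    """
    n_states = int(max(d.states.max() for d in dtrajs)) + 1
    max_len = max(len(d) for d in dtrajs)
    usable = [k for k in multiples if k * lag < max_len]
    for k in set(multiples) - set(usable):
        warnings.warn(f"multiple {k}: lag {k * lag} exceeds all trajectories; dropped")
    if not usable:
        raise ValueError("no usable lag multiple")
    rng = np.random.default_rng(seed)

    def _models(counts_at):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            keep, Cr = largest_connected_set(counts_at(lag))
            base = estimate_reversible(Cr)
            base.active_set = keep
            per_k = {}
            for k in usable:
                kk, Crk = largest_connected_set(counts_at(k * lag))
                mk = estimate_reversible(Crk)
                mk.active_set = kk
                per_k[k] = mk
        return base, per_k

    def _curves(counts_at) -> tuple[np.ndarray, np.ndarray]:
        base, per_k = _models(counts_at)
        pred = np.full((len(sets), len(usable)), np.nan)
        est = np.full_like(pred, np.nan)
        for si, members in enumerate(sets):
            for ki, k in enumerate(usable):
                pred[si, ki] = _set_probability(base, members, power=k)
                est[si, ki] = _set_probability(per_k[k], members, power=1)
        return pred, est

    pred, est = _curves(lambda L: count_transitions(dtrajs, L, n_states=n_states))
    pred_std = np.zeros_like(pred)
    est_std = np.zeros_like(est)
    if n_boot > 0:
        block = max(usable) * lag + 1
        preds = np.full((n_boot,) + pred.shape, np.nan)
        ests = np.full((n_boot,) + est.shape, np.nan)
        for b in range(n_boot):
            ti_b, s_b = _moving_block_starts(dtrajs, block, rng)
            try:
                preds[b], ests[b] = _curves(
                    lambda L: _counts_from_blocks(dtrajs, ti_b, s_b, block, L, n_states)
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
        pred_std = np.nanstd(preds, axis=0, ddof=1)
        est_std = np.nanstd(ests, axis=0, ddof=1)
    return CKTestResult(
        np.asarray(usable), list(range(len(sets))), pred, est, pred_std, est_std, lag=lag
    )


def estimate_msm(
    dtrajs: list[DiscreteTrajectory], lag: int, tol: float = 1e-10, maxiter: int = 100_000
) -> TransitionModel:
    """Count, restrict to the largest connected set, and estimate reversibly."""
    C = count_transitions(dtrajs, lag)
    keep, Cr = largest_connected_set(C)
    model = estimate_reversible(Cr, tol=tol, maxiter=maxiter)
    model.active_set = keep
    return model
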