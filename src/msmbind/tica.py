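"""Time-lagged independent component analysis (TICA).

TICA finds the slowest linear collective coordinates of a set of feature
trajectories: the generalized eigenproblem

    C_tau v = lambda C_0 v

where C_0 is the instantaneous covariance and C_tau the time-lagged
covariance at lag tau, symmetrized as (C + C^T)/2 -- the reversible
estimator, consistent with the reversible Markov model estimated
downstream. Eigenvalues approximate autocorrelations of the components at
the lag; components are ordered by decreasing eigenvalue and normalized to
unit C_0-weighted norm, so projections have unit instantaneous variance.

A small ridge term on the diagonal of C_0 guards against the numerical rank
deficiency typical of strongly correlated distance features. Projections
are plain eigenvector projections (no kinetic-map scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .trajectories import FeatureTrajectory

__all__ = ["TicaModel", "estimate_tica", "project"]

FORMAT_VERSION = 1


@dataclass
class TicaModel:
    """Fitted TICA transform."""

    lag: int
    mean: np.ndarray
    c0: np.ndarray
    ctau: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray  # columns are component vectors
    n_components: int
    feature_names: list[str] | None = None

    @property
    def n_features(self) -> int:
        return self.mean.size


def _lagged_pairs(trajs: list[FeatureTrajectory], lag: int, exclude: np.ndarray | None):
    for ft in trajs:
        X = ft.values if exclude is None else np.delete(ft.values, exclude, axis=1)
        if ft.n_frames > lag:
            yield X[:-lag], X[lag:]


def estimate_tica(
    trajs: list[FeatureTrajectory],
    lag: int,
    regularization: float = 1e-10,
    n_components: int = 5,
    include_ligand_column: bool = False,
) -> TicaModel:
    """Estimate the TICA transform from pooled trajectories.

    The designated ligand-distance column, if present, is excluded from the
    estimation by default (it is carried through projection separately as a
    passthrough column). Trajectories shorter than the lag are excluded with
    a warning; constant features are rejected by name.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    exclude = None
    names = list(trajs[0].feature_names)
    lig = trajs[0].ligand_distance_column
    if lig is not None and not include_ligand_column:
        exclude = np.array([lig])
        names = [nm for i, nm in enumerate(names) if i != lig]
    short = [i for i, ft in enumerate(trajs) if ft.n_frames <= lag]
    if short:
        warnings.warn(f"trajectories {short} shorter than lag {lag} excluded")
        if len(short) == len(trajs):
            raise ValueError("no trajectory longer than the lag")
    pairs = list(_lagged_pairs(trajs, lag, exclude))
    n_pairs = sum(a.shape[0] for a, _ in pairs)
    if n_pairs < 2:
        raise ValueError("fewer than two lagged pairs")
    d = pairs[0][0].shape[1]
    s = np.zeros(d)
    for a, b in pairs:
        s += a.sum(axis=0) + b.sum(axis=0)
    mean = s / (2 * n_pairs)
    C0 = np.zeros((d, d))
    Ct = np.zeros((d, d))
    for a, b in pairs:
        a = a - mean
        b = b - mean
        C0 += a.T @ a + b.T @ b
        Ct += a.T @ b
    C0 /= 2 * n_pairs
    Ct = (Ct + Ct.T) / (2 * n_pairs)
    var = np.diag(C0)
    const = np.where(var < 1e-12 * max(var.max(), 1.0))[0]
    if const.size:
        bad = [names[i] for i in const]
        raise ValueError(f"constant feature(s) make C0 singular: {bad}")
    C0r = C0 + regularization * np.eye(d)
    ev, V = scipy.linalg.eigh(Ct, C0r)
    order = np.argsort(ev)[::-1]
    ev, V = ev[order], V[:, order]
    # eigh(B-normalized): v^T C0 v = 1 already; renormalize defensively
    nrm = np.sqrt(np.einsum("ij,jk,ki->i", V.T, C0r, V))
    V = V / nrm[None, :]
    return TicaModel(
        lag=lag, mean=mean, c0=C0, ctau=Ct, eigenvalues=ev,
        components=V, n_components=min(n_components, d), feature_names=names,
    )


def project(
    trajs: list[FeatureTrajectory],
    model: TicaModel,
    n_components: int | None = None,
) -> list[FeatureTrajectory]:
    """Project trajectories onto the leading TICA components.

    The ligand-distance column is not part of the linear map; it is appended
    unchanged as a passthrough column (needed downstream for the bound-state
    split) and re-designated on the output.
    """
    k = model.n_components if n_components is None else n_components
    if k < 1 or k > model.components.shape[1]:
        raise ValueError(f"n_components must be in [1, {model.components.shape[1]}]")
    out = []
    for ft in trajs:
        lig = ft.ligand_distance_column
        X = ft.values if lig is None else np.delete(ft.values, lig, axis=1)
        if X.shape[1] != model.n_features:
            raise ValueError(
                f"feature count mismatch: model has {model.n_features}, data {X.shape[1]}"
            )
        Y = (X - model.mean) @ model.components[:, :k]
        names = [f"tic{i + 1}" for i in range(k)]
        lig_col = None
        if lig is not None:
            Y = np.column_stack([Y, ft.values[:, lig]])
            names.append("site_ligand_distance")
            lig_col = k
        out.append(
            FeatureTrajectory(
                Y, feature_names=names, ligand_distance_column=lig_col,
                frame_interval=ft.frame_interval,
            )
        )
    return out
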