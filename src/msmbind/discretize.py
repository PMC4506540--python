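"""Microstate definition: regular-space clustering, Voronoi assignment, and
the bound-state split.

Regular-space (uniform-distance) clustering makes a single pass over the
frames in input order: a frame becomes a new cluster center iff it lies at
least ``dmin`` from every existing center, so pairwise center distances are
guaranteed >= dmin. Frames are then assigned to their nearest center
(Euclidean, ties to the lowest center index).

Because ligand binding is faster than the conformational changes that
dominate the slow subspace, clusters in the projected space do not separate
bound from unbound frames; every microstate is therefore split by the
per-frame site--ligand distance at a cutoff (default 6 A) into a bound and
a remaining child state. Downstream classification into
bound/associated/unbound uses the per-microstate *mean* distance -- a
distinct criterion recorded here per microstate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .trajectories import DiscreteTrajectory, FeatureTrajectory

__all__ = [
    "Discretization",
    "regular_space_cluster",
    "assign",
    "split_by_distance",
    "discretize_pipeline",
]

DEFAULT_SPLIT_CUTOFF = 6.0


@dataclass
class Discretization:
    """Cluster centers plus the bound-split bookkeeping.

    ``labels[m] = (parent_center, bound_flag)`` maps each final microstate
    to its regular-space parent center and whether its frames lie below the
    split cutoff; without a split, bound_flag is None.
    """

    centers: np.ndarray
    dmin: float
    split_cutoff: float | None = None
    labels: list[tuple[int, bool | None]] = field(default_factory=list)
    mean_ligand_distances: np.ndarray | None = None

    @property
    def n_microstates(self) -> int:
        return len(self.labels) if self.labels else self.centers.shape[0]


def regular_space_cluster(
    trajs: list[FeatureTrajectory] | list[np.ndarray], dmin: float
) -> np.ndarray:
    """Single-pass regular-space cluster centers (frames x dims -> centers).

    Pass order is trajectory file order, then frame order; the first frame
    is always a center. Order matters and is part of the contract.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    arrays = [t.values if isinstance(t, FeatureTrajectory) else np.asarray(t, float) for t in trajs]
    if not arrays or all(a.shape[0] == 0 for a in arrays):
        raise ValueError("no data")
    X = np.vstack(arrays)
    if not np.all(np.isfinite(X)):
        bad = int(np.argwhere(~np.isfinite(X).all(axis=1))[0][0])
        raise ValueError(f"non-finite coordinates at concatenated frame {bad}")
    centers: list[np.ndarray] = [X[0]]
    # blocked pass: distances to pre-block centers are vectorized; only
    # centers born inside the current block need a per-frame check
    block = 4096
    for start in range(0, X.shape[0], block):
        chunk = X[start : start + block]
        dmin_old = cdist(chunk, np.asarray(centers)).min(axis=1)
        fresh: list[np.ndarray] = []
        for i in range(chunk.shape[0]):
            if dmin_old[i] < dmin:
                continue
            if fresh and np.linalg.norm(np.asarray(fresh) - chunk[i], axis=1).min() < dmin:
                continue
            fresh.append(chunk[i])
        centers.extend(fresh)
    return np.asarray(centers)


def assign(
    trajs: list[FeatureTrajectory] | list[np.ndarray], centers: np.ndarray
) -> list[DiscreteTrajectory]:
    """Voronoi assignment of frames to nearest centers (ties: lowest index)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if centers.shape[0] < 1:
        raise ValueError("need at least one center")
    out = []
    for t in trajs:
        fi = t.frame_interval if isinstance(t, FeatureTrajectory) else 1.0
        X = t.values if isinstance(t, FeatureTrajectory) else np.asarray(t, float)
        if X.shape[1] != centers.shape[1]:
            raise ValueError(
                f"dimension mismatch: data {X.shape[1]}, centers {centers.shape[1]}"
            )
        idx = np.argmin(cdist(X, centers), axis=1)  # argmin takes the lowest index on ties
        out.append(DiscreteTrajectory(idx, frame_interval=fi))
    return out


def split_by_distance(
    dtrajs: list[DiscreteTrajectory],
    distance_series: list[np.ndarray],
    cutoff: float = DEFAULT_SPLIT_CUTOFF,
    centers: np.ndarray | None = None,
    dmin: float = np.nan,
) -> tuple[list[DiscreteTrajectory], Discretization]:
    """Split every microstate by the per-frame ligand distance at ``cutoff``.

    A parent state with frames strictly below and at-or-above the cutoff
    becomes two child states (bound first); a parent with frames on one side
    only keeps a single child, so the new state count is the old count plus
    the number of parents split. Relabeling is dense, recorded in the
    returned :class:`Discretization` together with each child's mean ligand
    distance.
    """
    if len(dtrajs) != len(distance_series):
        raise ValueError("dtrajs and distance_series length mismatch")
    for k, (d, s) in enumerate(zip(dtrajs, distance_series)):
        if len(d) != len(np.asarray(s)):
            raise ValueError(f"trajectory {k}: frame count mismatch with distances")
    states = np.concatenate([d.states for d in dtrajs])
    dist = np.concatenate([np.asarray(s, dtype=float) for s in distance_series])
    bound = dist < cutoff
    parents = np.unique(states)
    label_map: dict[tuple[int, bool], int] = {}
    labels: list[tuple[int, bool | None]] = []
    for p in parents:
        sel = states == p
        has_bound = bool(np.any(bound[sel]))
        has_other = bool(np.any(~bound[sel]))
        if has_bound:
            label_map[(int(p), True)] = len(labels)
            labels.append((int(p), True))
        if has_other:
            label_map[(int(p), False)] = len(labels)
            labels.append((int(p), False))
    new_flat = np.array(
        [label_map[(int(s), bool(b))] for s, b in zip(states, bound)], dtype=np.int64
    )
    means = np.zeros(len(labels))
    for m in range(len(labels)):
        means[m] = dist[new_flat == m].mean()
    out = []
    pos = 0
    for d in dtrajs:
        out.append(
            DiscreteTrajectory(new_flat[pos : pos + len(d)], frame_interval=d.frame_interval)
        )
        pos += len(d)
    disc = Discretization(
        centers=centers if centers is not None else np.empty((0, 0)),
        dmin=dmin,
        split_cutoff=cutoff,
        labels=labels,
        mean_ligand_distances=means,
    )
    return out, disc


def discretize_pipeline(
    projected: list[FeatureTrajectory],
    dmin: float,
    split_cutoff: float | None = DEFAULT_SPLIT_CUTOFF,
) -> tuple[list[DiscreteTrajectory], Discretization]:
    """Cluster the projected coordinates, assign, and (optionally) split.

    Clustering runs on all columns except the passthrough ligand-distance
    column; the split consumes that column.
    """
    coords = []
    dists = []
    for ft in projected:
        if ft.ligand_distance_column is not None:
            coords.append(np.delete(ft.values, ft.ligand_distance_column, axis=1))
            dists.append(ft.ligand_distances)
        else:
            coords.append(ft.values)
    centers = regular_space_cluster(coords, dmin)
    fi = projected[0].frame_interval
    dtrajs = assign(coords, centers)
    dtrajs = [DiscreteTrajectory(d.states, frame_interval=fi) for d in dtrajs]
    if split_cutoff is None or not dists:
        disc = Discretization(centers=centers, dmin=dmin, labels=[(i, None) for i in range(centers.shape[0])])
        return dtrajs, disc
    return split_by_distance(dtrajs, dists, cutoff=split_cutoff, centers=centers, dmin=dmin)
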