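"""Distance features from grouped 3-D point trajectories.

The conformational input coordinates are minimum distances between named
groups of points (e.g. heavy atoms of two consecutive residues), and the
binding coordinate is the minimum heavy-atom distance between the ligand
group and the recognition-site group. Group construction (which atoms form
a group, heavy-atom filtering) is the caller's responsibility; this module
only computes distances, in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .trajectories import FeatureTrajectory

__all__ = ["GroupedPointTrajectory", "group_min_distances", "site_ligand_distance"]


@dataclass
class GroupedPointTrajectory:
    """Per-frame coordinates of named point groups.

    ``groups[label]`` is an array of shape (n_frames, n_points, 3) in
    Angstrom; group membership (n_points) is constant across frames.
    """

    groups: dict[str, np.ndarray]
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        n_frames = None
        for label, arr in self.groups.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[2] != 3:
                raise ValueError(f"group '{label}' must have shape (frames, points, 3)")
            if arr.shape[1] == 0:
                raise ValueError(f"group '{label}' is empty")
            if n_frames is None:
                n_frames = arr.shape[0]
            elif arr.shape[0] != n_frames:
                raise ValueError(f"group '{label}' frame count mismatch")
            self.groups[label] = arr
        self.n_frames = int(n_frames)  # type: ignore[arg-type]


def _min_dist_series(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [cdist(a[t], b[t]).min() for t in range(a.shape[0])]
    )


def group_min_distances(
    traj: GroupedPointTrajectory, pairs: list[tuple[str, str]]
) -> FeatureTrajectory:
    """Per-frame minimum inter-group Euclidean distances, one feature per pair.

    Features are named ``<A>-<B>``. The minimum runs over all point pairs
    (one from each group), so identical groups give 0.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    for a, b in pairs:
        for label in (a, b):
            if label not in traj.groups:
                raise KeyError(f"unknown group '{label}'")
    cols = [
        _min_dist_series(traj.groups[a], traj.groups[b]) for a, b in pairs
    ]
    return FeatureTrajectory(
        np.column_stack(cols),
        feature_names=[f"{a}-{b}" for a, b in pairs],
        frame_interval=traj.frame_interval,
    )


def site_ligand_distance(
    traj: GroupedPointTrajectory, site_group: str, ligand_group: str
) -> np.ndarray:
    """Per-frame minimum distance between recognition site and ligand (A)."""
    ft = group_min_distances(traj, [(site_group, ligand_group)])
    return ft.values[:, 0]
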