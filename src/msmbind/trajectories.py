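"""Core trajectory containers shared by all analysis stages.

Two in-memory forms are used throughout:

* :class:`FeatureTrajectory` -- a frames x features real matrix, optionally
  carrying a designated ligand--recognition-site distance column (Angstrom),
  the input to TICA and clustering.
* :class:`DiscreteTrajectory` -- a sequence of microstate indices, the input
  to Markov state model estimation.

Both carry ``frame_interval``, the physical time between successive frames,
used to convert lag times and mean first passage times to physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureTrajectory", "DiscreteTrajectory"]


@dataclass
class FeatureTrajectory:
    """Continuous observables for one trajectory.

    Parameters
    ----------
    values : ndarray, shape (n_frames, n_features)
        Feature matrix; must be finite.
    feature_names : list of str
        One label per column.
    ligand_distance_column : int or None
        Index of the column holding the site--ligand minimum distance in
        Angstrom (non-negative), or None if no such column is designated.
    frame_interval : float
        Time between frames, in arbitrary but consistent units.
    """

    values: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    ligand_distance_column: int | None = None
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x features)")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at frame {bad[0]}, feature {bad[1]}")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length does not match n_features")
        if self.ligand_distance_column is not None:
            c = self.ligand_distance_column
            if not 0 <= c < self.values.shape[1]:
                raise ValueError(f"ligand_distance_column {c} out of range")
            if np.any(self.values[:, c] < 0):
                raise ValueError("ligand distances must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def ligand_distances(self) -> np.ndarray:
        if self.ligand_distance_column is None:
            raise ValueError("no ligand_distance_column designated")
        return self.values[:, self.ligand_distance_column]


@dataclass
class DiscreteTrajectory:
    """Microstate index sequence for one trajectory."""

    states: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be 1-D")
        if self.states.size == 0:
            raise ValueError("empty trajectory")
        if np.any(self.states < 0):
            raise ValueError("state indices must be non-negative")

    def __len__(self) -> int:
        return self.states.size

    @property
    def n_frames(self) -> int:
        return self.states.size
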