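"""Serialization of trajectories, models and analysis results.

Formats are deliberately plain: discrete trajectories as one integer per
line with ``#`` header comments, feature trajectories as CSV with a header
row (ligand-distance column named ``site_ligand_distance``), and models /
partitions / flux networks as versioned JSON with full-precision decimal
floats so round-trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .discretize import Discretization
from .metastable import MacrostatePartition
from .msm import TransitionModel
from .tica import TicaModel
from .tpt import FluxNetwork
from .trajectories import DiscreteTrajectory, FeatureTrajectory

__all__ = [
    "read_dtraj", "write_dtraj",
    "read_feature_trajectory", "write_feature_trajectory",
    "read_transition_model", "write_transition_model",
    "read_tica_model", "write_tica_model",
    "read_discretization", "write_discretization",
    "read_partition", "write_partition",
    "write_flux_network",
]

FORMAT_VERSION = 1
LIGAND_COLUMN_NAME = "site_ligand_distance"


def _check_version(doc: dict, path: Path) -> None:
    v = doc.get("format_version")
    if v != FORMAT_VERSION:
        raise ValueError(f"{path}: format version {v!r} != {FORMAT_VERSION}")


# -- discrete trajectories -------------------------------------------------

def write_dtraj(dtraj: DiscreteTrajectory, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_interval: {dtraj.frame_interval!r}\n")
        fh.write("\n".join(str(int(s)) for s in dtraj.states))
        fh.write("\n")


def read_dtraj(path: str | Path) -> DiscreteTrajectory:
    path = Path(path)
    frame_interval = 1.0
    states: list[int] = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("frame_interval:"):
                frame_interval = float(body.split(":", 1)[1])
            continue
        try:
            states.append(int(line))
        except ValueError:
            raise ValueError(f"{path}:{ln}: not an integer state index: {line!r}") from None
    return DiscreteTrajectory(np.asarray(states), frame_interval=frame_interval)


# -- feature trajectories --------------------------------------------------

def write_feature_trajectory(ft: FeatureTrajectory, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# frame_interval: {ft.frame_interval!r}; distance units: Angstrom\n")
        pd.DataFrame(ft.values, columns=ft.feature_names).to_csv(fh, index=False)


def read_feature_trajectory(
    path: str | Path, require_ligand_column: bool = False
) -> FeatureTrajectory:
    path = Path(path)
    frame_interval = 1.0
    with path.open() as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("#"):
            body = first[1:].strip()
            for part in body.split(";"):
                part = part.strip()
                if part.startswith("frame_interval:"):
                    frame_interval = float(part.split(":", 1)[1])
        else:
            fh.seek(pos)
        df = pd.read_csv(fh)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in feature CSV")
    lig = None
    if LIGAND_COLUMN_NAME in df.columns:
        lig = int(df.columns.get_loc(LIGAND_COLUMN_NAME))
    elif require_ligand_column:
        raise ValueError(
            f"{path}: required column '{LIGAND_COLUMN_NAME}' not found"
        )
    return FeatureTrajectory(
        df.to_numpy(dtype=float), feature_names=list(df.columns),
        ligand_distance_column=lig, frame_interval=frame_interval,
    )


# -- transition models -----------------------------------------------------

def write_transition_model(model: TransitionModel, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "transition_matrix": model.transition_matrix.tolist(),
        "stationary_distribution": model.stationary_distribution.tolist(),
        "lag": int(model.lag),
        "frame_interval": model.frame_interval,
        "active_set": model.active_set.tolist(),
        "converged": bool(model.converged),
        "n_iter": int(model.n_iter),
        "residual": float(model.residual),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_transition_model(path: str | Path) -> TransitionModel:
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_version(doc, path)
    return TransitionModel(
        np.asarray(doc["transition_matrix"]),
        np.asarray(doc["stationary_distribution"]),
        lag=doc["lag"],
        frame_interval=doc["frame_interval"],
        active_set=np.asarray(doc["active_set"], dtype=np.int64),
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        residual=doc["residual"],
    )


# -- TICA models -----------------------------------------------------------

def write_tica_model(model: TicaModel, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "lag": int(model.lag),
        "mean": model.mean.tolist(),
        "c0": model.c0.tolist(),
        "ctau": model.ctau.tolist(),
        "eigenvalues": model.eigenvalues.tolist(),
        "components": model.components.tolist(),
        "n_components": int(model.n_components),
        "feature_names": model.feature_names,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_tica_model(path: str | Path) -> TicaModel:
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_version(doc, path)
    return TicaModel(
        lag=doc["lag"], mean=np.asarray(doc["mean"]), c0=np.asarray(doc["c0"]),
        ctau=np.asarray(doc["ctau"]), eigenvalues=np.asarray(doc["eigenvalues"]),
        components=np.asarray(doc["components"]),
        n_components=doc["n_components"], feature_names=doc["feature_names"],
    )


# -- discretizations ---------------------------------------------------------

def write_discretization(disc: Discretization, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "centers": np.asarray(disc.centers).tolist(),
        "dmin": None if np.isnan(disc.dmin) else disc.dmin,
        "split_cutoff": disc.split_cutoff,
        "labels": [[p, f] for p, f in disc.labels],
        "mean_ligand_distances": (
            None if disc.mean_ligand_distances is None
            else np.asarray(disc.mean_ligand_distances).tolist()
        ),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_discretization(path: str | Path) -> Discretization:
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_version(doc, path)
    return Discretization(
        centers=np.asarray(doc["centers"]),
        dmin=np.nan if doc["dmin"] is None else doc["dmin"],
        split_cutoff=doc["split_cutoff"],
        labels=[(int(p), None if f is None else bool(f)) for p, f in doc["labels"]],
        mean_ligand_distances=(
            None if doc["mean_ligand_distances"] is None
            else np.asarray(doc["mean_ligand_distances"])
        ),
    )


# -- partitions --------------------------------------------------------------

def write_partition(part: MacrostatePartition, path: str | Path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "assignments": part.assignments.tolist(),
        "memberships": part.memberships.tolist(),
        "classes": None if part.classes is None else part.classes.tolist(),
        "pi_macro": None if part.pi_macro is None else np.asarray(part.pi_macro).tolist(),
        "coarse_transition_matrix": (
            None if part.coarse_transition_matrix is None
            else np.asarray(part.coarse_transition_matrix).tolist()
        ),
        "labels": part.labels,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_partition(path: str | Path) -> MacrostatePartition:
    path = Path(path)
    doc = json.loads(path.read_text())
    _check_version(doc, path)
    return MacrostatePartition(
        assignments=np.asarray(doc["assignments"], dtype=np.int64),
        memberships=np.asarray(doc["memberships"]),
        classes=None if doc["classes"] is None else np.asarray(doc["classes"], dtype=str),
        pi_macro=None if doc["pi_macro"] is None else np.asarray(doc["pi_macro"]),
        coarse_transition_matrix=(
            None if doc["coarse_transition_matrix"] is None
            else np.asarray(doc["coarse_transition_matrix"])
        ),
        labels=doc["labels"],
    )


# -- flux networks -----------------------------------------------------------

def write_flux_network(fn: FluxNetwork, path: str | Path) -> None:
    """JSON document plus an adjacent edge-list CSV (i, j, gross, net)."""
    path = Path(path)
    doc = {
        "format_version": FORMAT_VERSION,
        "A": fn.A.tolist(), "B": fn.B.tolist(),
        "q_plus": fn.q_plus.tolist(), "q_minus": fn.q_minus.tolist(),
        "total_flux": fn.total_flux, "rate": fn.rate, "lag_time": fn.lag_time,
        "pathways": [{"states": p, "flux": f} for p, f in fn.pathways],
    }
    path.write_text(json.dumps(doc, sort_keys=True))
    ii, jj = np.nonzero(fn.gross_flux)
    pd.DataFrame(
        {"i": ii, "j": jj, "gross": fn.gross_flux[ii, jj], "net": fn.net_flux[ii, jj]}
    ).to_csv(path.with_suffix(".edges.csv"), index=False)
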