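"""Ground-truth kinetic systems and trajectories for validation.

Two generators mimic the statistical structure of a protein--ligand system
whose slow degrees of freedom are conformational exchange and whose fast
degrees of freedom are ligand binding/unbinding:

1. A reversible microstate Markov chain over (conformation, substate) pairs,
   where substates are ligand classes {bound, associated, unbound}. Binding
   exchange within a conformation is fast; conformational exchange is slow
   and routed exclusively through one "hub" conformation, so the macrostate
   topology is a star. Reversibility is exact by construction: the chain is
   a random walk on a symmetric weight matrix S, T_ij = S_ij / sum_k S_ik,
   which satisfies detailed balance with pi_i proportional to sum_k S_ik.
   The diagonal of S is chosen so that pi matches the requested stationary
   weights exactly.

2. A continuous "toy binder": overdamped Langevin dynamics on a 2-D
   landscape U(x, r) with a conformational coordinate x (multi-well) and a
   binding-distance coordinate r >= 0 (Angstrom) whose bound well near small
   r is only accessible from designated x wells. The two coordinates are
   linearly mixed into d >= 2 noisy observables, with the raw r appended as
   the designated ligand-distance column -- the input TICA and clustering
   expect.

All randomness flows from an explicit per-call seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msm import TransitionModel
from .trajectories import DiscreteTrajectory, FeatureTrajectory

__all__ = [
    "GroundTruthSpec",
    "GroundTruthModel",
    "ToyBinderSpec",
    "build_ground_truth_model",
    "sample_markov_chain",
    "simulate_toy_binder",
    "default_ground_truth_spec",
    "default_toy_binder_spec",
]

CLASSES = ("bound", "associated", "unbound")


@dataclass
class GroundTruthSpec:
    """Blueprint of a (conformation x binding-substate) kinetic network.

    ``substates_per_conformation[c]`` lists the ligand classes of
    conformation ``c`` in the fixed order bound < associated < unbound;
    every conformation needs a bound substate (a bound-only conformation is
    allowed -- it exchanges with the hub through its bound substate) and at
    least one conformation must have an unbound substate.

    ``binding_exchange_weight`` couples adjacent substates within one
    conformation and must exceed ``conformational_exchange_weight`` (binding
    is fast relative to conformational change). Inter-conformation coupling
    exists only between each conformation and the hub, matching like
    substate classes.

    ``substate_stationary_weights[c]`` gives the target stationary weight of
    each substate; the constructed chain reproduces them exactly (up to
    normalization).
    """

    n_conformations: int = 7
    substates_per_conformation: list[list[str]] = field(default_factory=list)
    conformational_exchange_weight: float = 1e-3
    binding_exchange_weight: float = 0.1
    hub_index: int = 0
    substate_stationary_weights: list[list[float]] = field(default_factory=list)
    frame_interval: float = 1.0
    representative_distances: dict[str, float] = field(
        default_factory=lambda: {"bound": 4.0, "associated": 10.0, "unbound": 20.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformations < 1:
            raise ValueError("need at least one conformation")
        if not self.substates_per_conformation:
            self.substates_per_conformation = [
                ["bound", "unbound"] for _ in range(self.n_conformations)
            ]
        if len(self.substates_per_conformation) != self.n_conformations:
            raise ValueError("substates_per_conformation length mismatch")
        order = {c: i for i, c in enumerate(CLASSES)}
        for c, subs in enumerate(self.substates_per_conformation):
            if not subs:
                raise ValueError(f"conformation {c} has no substates")
            bad = set(subs) - set(CLASSES)
            if bad:
                raise ValueError(f"unknown substate class(es) {bad}")
            if len(set(subs)) != len(subs):
                raise ValueError(f"conformation {c} repeats a substate class")
            if "bound" not in subs:
                raise ValueError(f"conformation {c} lacks a bound substate")
            self.substates_per_conformation[c] = sorted(subs, key=order.__getitem__)
        if not any("unbound" in s for s in self.substates_per_conformation):
            raise ValueError("no conformation has an unbound substate")
        if not 0 <= self.hub_index < self.n_conformations:
            raise ValueError("hub_index out of range")
        if self.conformational_exchange_weight <= 0 or self.binding_exchange_weight <= 0:
            raise ValueError("exchange weights must be positive")
        if self.binding_exchange_weight <= self.conformational_exchange_weight:
            raise ValueError(
                "binding_exchange_weight must exceed conformational_exchange_weight "
                "(binding is fast relative to conformational change)"
            )
        if not self.substate_stationary_weights:
            self.substate_stationary_weights = [
                [1.0] * len(s) for s in self.substates_per_conformation
            ]
        if [len(w) for w in self.substate_stationary_weights] != [
            len(s) for s in self.substates_per_conformation
        ]:
            raise ValueError("substate_stationary_weights shape mismatch")
        if any(w <= 0 for ws in self.substate_stationary_weights for w in ws):
            raise ValueError("stationary weights must be positive")

    @property
    def n_microstates(self) -> int:
        return sum(len(s) for s in self.substates_per_conformation)


@dataclass
class GroundTruthModel(TransitionModel):
    """Transition model annotated with its generating macrostate structure."""

    conformation_labels: np.ndarray = None  # type: ignore[assignment]
    substate_classes: list[str] = field(default_factory=list)
    hub_index: int = 0
    mean_ligand_distances: np.ndarray = None  # type: ignore[assignment]
    spec: GroundTruthSpec | None = None


def build_ground_truth_model(spec: GroundTruthSpec) -> GroundTruthModel:
    """Construct the exact reversible microstate chain of a spec.

    The chain is a random walk on a symmetric weight matrix S: within each
    conformation, adjacent substates (bound--associated--unbound, skipping
    absent classes) are coupled with weight b * sqrt(w_i w_j); each non-hub
    conformation couples to the hub through every substate class both share
    with weight g * sqrt(w_i w_j). The diagonal S_ii absorbs the remainder
    w_i - sum_j S_ij so that pi_i = w_i / sum(w) holds exactly; weights for
    which the remainder would be non-positive are rejected.
    """
    subs = spec.substates_per_conformation
    weights = spec.substate_stationary_weights
    index: dict[tuple[int, str], int] = {}
    conf_of: list[int] = []
    class_of: list[str] = []
    w: list[float] = []
    for c, classes in enumerate(subs):
        for k, cls in enumerate(classes):
            index[(c, cls)] = len(conf_of)
            conf_of.append(c)
            class_of.append(cls)
            w.append(weights[c][k])
    n = len(conf_of)
    wv = np.asarray(w, dtype=float)
    S = np.zeros((n, n))

    def couple(i: int, j: int, g: float) -> None:
        S[i, j] = S[j, i] = g * np.sqrt(wv[i] * wv[j])

    b, g = spec.binding_exchange_weight, spec.conformational_exchange_weight
    for c, classes in enumerate(subs):
        for a, bb in zip(classes[:-1], classes[1:]):
            couple(index[(c, a)], index[(c, bb)], b)
    hub = spec.hub_index
    for c in range(spec.n_conformations):
        if c == hub:
            continue
        shared = set(subs[c]) & set(subs[hub])
        if not shared:
            raise ValueError(
                f"conformation {c} shares no substate class with hub {hub}: "
                "isolated block"
            )
        for cls in sorted(shared):
            couple(index[(c, cls)], index[(hub, cls)], g)
    off = S.sum(axis=1)
    diag = wv - off
    if np.any(diag <= 0):
        bad = int(np.argmin(diag))
        raise ValueError(
            f"exchange weights too large for stationary weight of microstate {bad} "
            f"(conformation {conf_of[bad]}, {class_of[bad]}): reduce couplings"
        )
    S[np.diag_indices(n)] = diag
    row = S.sum(axis=1)  # == wv by construction
    T = S / row[:, None]
    pi = row / row.sum()
    dist = np.array([spec.representative_distances[c] for c in class_of])
    return GroundTruthModel(
        transition_matrix=T,
        stationary_distribution=pi,
        lag=1,
        frame_interval=spec.frame_interval,
        conformation_labels=np.asarray(conf_of, dtype=np.int64),
        substate_classes=class_of,
        hub_index=hub,
        mean_ligand_distances=dist,
        spec=spec,
    )


def default_ground_truth_spec(seed: int = 0) -> GroundTruthSpec:
    """Preset mirroring the qualitative published network: seven
    conformations, one of them bound-only (a conformation induced by the
    ligand), a hub connecting all others, fast binding and slow
    conformational exchange. Values are presets, not fits.
    """
    subs = [
        ["bound", "associated", "unbound"],  # hub (conformation 0)
        ["bound", "unbound"],
        ["bound", "associated", "unbound"],
        ["bound", "unbound"],
        ["bound"],                            # bound-only conformation
        ["bound", "associated", "unbound"],
        ["bound", "unbound"],
    ]
    weights = [
        [2.0, 0.3, 3.0],
        [1.5, 1.0],
        [1.0, 0.2, 1.2],
        [4.0, 0.8],
        [1.2],
        [0.8, 0.15, 2.2],
        [2.5, 0.6],
    ]
    return GroundTruthSpec(
        n_conformations=7,
        substates_per_conformation=subs,
        conformational_exchange_weight=1e-3,
        binding_exchange_weight=0.1,
        hub_index=0,
        substate_stationary_weights=weights,
        seed=seed,
    )


def _sample_chain_python(cum_rows: np.ndarray, start: int, u: np.ndarray) -> np.ndarray:
    out = np.empty(u.size + 1, dtype=np.int64)
    out[0] = start
    s = start
    for t in range(u.size):
        s = int(np.searchsorted(cum_rows[s], u[t], side="right"))
        out[t + 1] = s
    return out


try:  # optional acceleration of the inherently sequential sampling loop
    from numba import njit

    @njit(cache=False)
    def _sample_chain_numba(cum_rows, start, u):  # pragma: no cover - jitted
        out = np.empty(u.size + 1, dtype=np.int64)
        out[0] = start
        s = start
        n = cum_rows.shape[1]
        for t in range(u.size):
            row = cum_rows[s]
            lo, hi = 0, n
            x = u[t]
            while lo < hi:
                mid = (lo + hi) // 2
                if row[mid] <= x:
                    lo = mid + 1
                else:
                    hi = mid
            s = lo
            out[t + 1] = s
        return out

    _sample_chain = _sample_chain_numba
except ImportError:  # pragma: no cover
    _sample_chain = _sample_chain_python


def sample_markov_chain(
    model: TransitionModel,
    n_steps: int,
    start_state: int | str = "stationary",
    seed: int = 0,
) -> DiscreteTrajectory:
    """Sample a trajectory of ``n_steps`` transitions (n_steps+1 frames).

    ``start_state`` is a microstate index or ``"stationary"`` to draw the
    initial state from pi. Reproducible for a fixed seed.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    T = model.transition_matrix
    rng = np.random.default_rng(seed)
    if start_state == "stationary":
        start = int(
            rng.choice(model.n_states, p=model.stationary_distribution)
        )
    else:
        start = int(start_state)
        if not 0 <= start < model.n_states:
            raise ValueError(f"start_state {start} out of range")
    if n_steps == 0:
        import warnings

        warnings.warn("single-frame trajectory: unusable for counting at any lag")
        return DiscreteTrajectory(np.array([start]), frame_interval=model.frame_interval)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0 + 1e-12  # guard against round-off at the right edge
    u = rng.random(n_steps)
    states = _sample_chain(cum, start, u)
    return DiscreteTrajectory(states, frame_interval=model.frame_interval)


def ligand_distance_series(
    model: GroundTruthModel,
    dtraj: DiscreteTrajectory,
    noise: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Per-frame site--ligand distances consistent with the microstate classes.

    Each frame gets its microstate's representative class distance plus
    truncated Gaussian noise (distances stay non-negative and on the correct
    side of the 6 A bound cutoff), emulating the continuous distance series
    the frame-level bound/unbound split consumes.
    """
    rng = np.random.default_rng(seed)
    base = model.mean_ligand_distances[dtraj.states]
    d = base + noise * rng.standard_normal(dtraj.n_frames)
    bound = np.array([c == "bound" for c in model.substate_classes])[dtraj.states]
    d = np.where(bound, np.clip(d, 0.5, 5.9), np.clip(d, 6.1, None))
    return d


@dataclass
class ToyBinderSpec:
    """Overdamped Langevin dynamics on a 2-D binding landscape.

    The potential is

        U(x, r) = U_x(x) + 0.5 k_r (r - r_unbound)^2
                  - depth * gate(x) * exp(-(r - r_bound)^2 / (2 sigma_b^2))

    where U_x is harmonic (one well) or quartic (two wells at
    ``x_well_positions`` with barrier ``x_barrier_height``), and ``gate`` is
    a smooth switch that opens the bound well only near the designated
    ``gate_x_well``. r is reflected at 0 so it remains a valid distance.
    Observables are ``mixing_matrix @ (x, r)`` plus Gaussian noise, with the
    raw r appended as the ligand-distance column.
    """

    x_well_positions: tuple[float, ...] = (-1.0, 1.0)
    x_barrier_height: float = 4.0
    x_spring: float = 4.0  # used only for a single-well (harmonic) landscape
    r_unbound: float = 15.0
    r_bound: float = 3.0
    r_spring: float = 0.05
    bound_depth: float = 3.0
    bound_width: float = 1.5
    gate_x_well: int = 1  # index into x_well_positions; <0 disables gating
    gate_sharpness: float = 4.0
    diffusion: float = 1.0
    timestep: float = 1e-3
    kT: float = 1.0
    mixing_matrix: np.ndarray | None = None
    noise_amplitude: float = 0.05
    box_bound: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.x_well_positions) < 1:
            raise ValueError("need at least one x well")
        if self.timestep <= 0 or self.diffusion <= 0 or self.kT <= 0:
            raise ValueError("timestep, diffusion and kT must be positive")
        if self.mixing_matrix is None:
            rng = np.random.default_rng(1234)  # fixed structural mixing
            self.mixing_matrix = rng.standard_normal((5, 2))
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if self.mixing_matrix.ndim != 2 or self.mixing_matrix.shape[1] != 2:
            raise ValueError("mixing_matrix must map 2 coordinates to d observables")

    # -- potential ---------------------------------------------------------
    def _ux_grad(self, x: float) -> tuple[float, float]:
        p = self.x_well_positions
        if len(p) == 1:
            u = 0.5 * self.x_spring * (x - p[0]) ** 2
            return u, self.x_spring * (x - p[0])
        c = 0.5 * (p[0] + p[-1])
        a = 0.5 * (p[-1] - p[0])
        z = ((x - c) / a) ** 2 - 1.0
        u = self.x_barrier_height * z**2
        du = self.x_barrier_height * 4.0 * z * (x - c) / a**2
        return u, du

    def _gate(self, x: float) -> tuple[float, float]:
        if self.gate_x_well < 0 or len(self.x_well_positions) == 1:
            return 1.0, 0.0
        p = self.x_well_positions
        x0 = p[self.gate_x_well]
        center = 0.5 * (min(p) + max(p))
        sgn = 1.0 if x0 >= center else -1.0
        z = self.gate_sharpness * sgn * (x - center)
        g = 1.0 / (1.0 + np.exp(-z))
        dg = self.gate_sharpness * sgn * g * (1.0 - g)
        return g, dg

    def potential(self, x: float, r: float) -> float:
        ux, _ = self._ux_grad(x)
        g, _ = self._gate(x)
        well = np.exp(-((r - self.r_bound) ** 2) / (2 * self.bound_width**2))
        return (
            ux
            + 0.5 * self.r_spring * (r - self.r_unbound) ** 2
            - self.bound_depth * g * well
        )

    def gradient(self, x: float, r: float) -> tuple[float, float]:
        _, dux = self._ux_grad(x)
        g, dg = self._gate(x)
        dr = r - self.r_bound
        well = np.exp(-(dr**2) / (2 * self.bound_width**2))
        du_dx = dux - self.bound_depth * dg * well
        du_dr = self.r_spring * (r - self.r_unbound) + self.bound_depth * g * well * dr / self.bound_width**2
        return du_dx, du_dr


def simulate_toy_binder(
    spec: ToyBinderSpec, n_steps: int, start: tuple[float, float] | None = None
) -> FeatureTrajectory:
    """Euler-Maruyama integration of the toy binder, returning observables.

    The update is z <- z - (D/kT) grad U dt + sqrt(2 D dt) xi with xi
    standard normal; r is reflected at zero. A non-finite or out-of-box
    coordinate aborts with the offending step index (unstable integration).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(spec.seed)
    dt, D, kT = spec.timestep, spec.diffusion, spec.kT
    amp = np.sqrt(2.0 * D * dt)
    if start is None:
        start = (spec.x_well_positions[0], spec.r_unbound)
    x, r = float(start[0]), float(start[1])
    xr = np.empty((n_steps + 1, 2))
    xr[0] = (x, r)
    noise = rng.standard_normal((n_steps, 2))
    for t in range(n_steps):
        gx, gr = spec.gradient(x, r)
        x = x - (D / kT) * gx * dt + amp * noise[t, 0]
        r = r - (D / kT) * gr * dt + amp * noise[t, 1]
        r = abs(r)  # reflecting wall: r is a distance
        if not (np.isfinite(x) and np.isfinite(r)) or max(abs(x), abs(r)) > spec.box_bound:
            raise FloatingPointError(
                f"unstable integration at step {t + 1}: coordinate left the box"
            )
        xr[t + 1] = (x, r)
    obs = xr @ spec.mixing_matrix.T
    if spec.noise_amplitude > 0:
        obs = obs + spec.noise_amplitude * rng.standard_normal(obs.shape)
    values = np.column_stack([obs, xr[:, 1]])
    names = [f"obs{i}" for i in range(obs.shape[1])] + ["site_ligand_distance"]
    return FeatureTrajectory(
        values,
        feature_names=names,
        ligand_distance_column=values.shape[1] - 1,
        frame_interval=dt,
    )


def default_toy_binder_spec(seed: int = 0) -> ToyBinderSpec:
    """Two conformational wells; binding gated by the x > 0 well."""
    return ToyBinderSpec(seed=seed)
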