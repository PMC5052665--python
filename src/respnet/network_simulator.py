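"""Full-network Heun integration with instantaneous short-range and delayed
long-range coupling.

Per node ``i`` the drive entering the first state variable is

    eta * [ (1 - alpha) * sum_j W_ij psi1_j(t)
            + alpha * sum_b c_{area(i), b} <psi1>_b(t - tau_{area(i), b}) ]
    + stimulus_i(t)

where ``W`` is the node-level Gaussian connectivity, ``c``/``tau`` the
area-level weights and delays, and ``<psi1>_b`` the arithmetic mean over the
member nodes of area ``b``.  Delayed area means are kept in a ring buffer;
delays are rounded to the nearest integer step.  History before t=0 is zero
(the network is silent at rest).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .exceptions import DivergenceError, InvalidArgumentError
from .node_dynamics import NodeParams, StimulusSpec, simulate_isolated_node
from .synthetic_brain import BrainGeometry, HeterogeneousSC, HomogeneousSC, Parcellation

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "subtract_isolated_response",
    "area_mean_field",
    "save_result",
    "load_result",
]


@dataclass
class SimulationConfig:
    """Integration settings for one stimulation run."""

    alpha: float = 0.6  # heterogeneous share in [0, 1]
    dt: float = 4e-5  # s
    duration: float = 1.0  # s
    record_stride: int = 25  # steps between recorded samples (25 -> 1 ms)
    speed_override: float | None = None  # m/s

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidArgumentError("alpha must be in [0, 1]")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.record_stride < 1:
            raise InvalidArgumentError("record_stride must be >= 1")


@dataclass
class SimulationResult:
    """Recorded node time series of both state variables."""

    psi1: np.ndarray  # (n_nodes, n_recorded)
    psi2: np.ndarray  # (n_nodes, n_recorded)
    dt_recorded: float  # s between recorded samples
    stimulus: StimulusSpec
    condition: dict = field(default_factory=dict)  # site, alpha, sigma, ...

    @property
    def n_nodes(self) -> int:
        return self.psi1.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.psi1.shape[1]) * self.dt_recorded


def _area_averaging_matrix(parcellation: Parcellation, n_nodes: int) -> sp.csr_matrix:
    """Sparse (n_areas x n_nodes) matrix mapping node values to area means."""
    rows, cols, vals = [], [], []
    for a in range(parcellation.n_areas):
        mem = parcellation.members(a)
        if mem.size == 0:
            continue
        rows.extend([a] * mem.size)
        cols.extend(mem.tolist())
        vals.extend([1.0 / mem.size] * mem.size)
    return sp.csr_matrix(
        (vals, (rows, cols)), shape=(parcellation.n_areas, n_nodes)
    )


def simulate(
    geometry: BrainGeometry,
    parcellation: Parcellation,
    hom: HomogeneousSC,
    het: HeterogeneousSC,
    params: NodeParams,
    stim: StimulusSpec | None,
    cfg: SimulationConfig,
) -> SimulationResult:
    """Integrate the full network with Heun's method.

    All nodes of the stimulated area receive the stimulus simultaneously.
    The integrator is deterministic: identical inputs give bit-identical
    outputs.
    """
    n_nodes = geometry.n_nodes
    n_areas = parcellation.n_areas
    if het.n_areas != n_areas:
        raise InvalidArgumentError("heterogeneous SC does not match parcellation")
    if hom.weights.shape != (n_nodes, n_nodes):
        raise InvalidArgumentError("homogeneous SC does not match geometry")
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    speed = cfg.speed_override if cfg.speed_override is not None else het.speed
    het_eff = het if speed == het.speed else replace(het, speed=speed)

    # delayed-edge bookkeeping: target row convention, delays in integer steps
    tgt, src = np.nonzero(het_eff.weights)
    w_edge = het_eff.weights[tgt, src]
    d_edge = np.rint(het_eff.delays[tgt, src] / dt).astype(np.int64)
    buf_len = int(d_edge.max()) + 2 if d_edge.size else 2
    if buf_len > n_steps + 2:
        buf_len = max(buf_len, 2)  # buffer may exceed run length; harmless

    avg = _area_averaging_matrix(parcellation, n_nodes)
    W = hom.weights.tocsr()
    eta, gamma, eps = params.eta, params.gamma, params.epsilon
    one_minus_a, a = 1.0 - cfg.alpha, cfg.alpha

    stim_nodes = None
    if stim is not None:
        stim_nodes = parcellation.members(stim.target_area)
        if stim_nodes.size == 0:
            raise InvalidArgumentError(f"stimulated area {stim.target_area} is empty")

    psi1 = np.zeros(n_nodes)
    psi2 = np.zeros(n_nodes)
    buf = np.zeros((n_areas, buf_len))  # ring buffer of area means of psi1

    n_rec = n_steps // cfg.record_stride + 1
    rec1 = np.zeros((n_nodes, n_rec))
    rec2 = np.zeros((n_nodes, n_rec))
    rec_i = 1  # sample 0 is the zero initial state

    def het_drive(step_index: int) -> np.ndarray:
        out = np.zeros(n_areas)
        if d_edge.size:
            vals = buf[src, (step_index - d_edge) % buf_len]
            np.add.at(out, tgt, w_edge * vals)
        return out

    def stim_vec(t0: float, t1: float) -> np.ndarray | float:
        # step-averaged drive, matching the isolated-node integrator exactly
        if stim_nodes is None:
            return 0.0
        s = stim.step_drive(t0, t1, params)
        if s == 0.0:
            return 0.0
        v = np.zeros(n_nodes)
        v[stim_nodes] = s
        return v

    for k in range(n_steps):
        t = k * dt
        cur = k % buf_len
        nxt = (k + 1) % buf_len
        buf[:, cur] = avg @ psi1
        sv = stim_vec(t, t + dt)

        drive1 = eta * (one_minus_a * (W @ psi1) + a * het_drive(k)[parcellation.node_area])
        drive1 = drive1 + sv
        d1a = eta * (psi2 - gamma * psi1 - psi1**3) + drive1
        d2a = -eta * eps * psi1
        p1 = psi1 + dt * d1a
        p2 = psi2 + dt * d2a

        # predictor estimate of the t+dt area means, for zero-delay edges
        buf[:, nxt] = avg @ p1
        drive2 = eta * (one_minus_a * (W @ p1) + a * het_drive(k + 1)[parcellation.node_area])
        drive2 = drive2 + sv
        d1b = eta * (p2 - gamma * p1 - p1**3) + drive2
        d2b = -eta * eps * p1

        psi1 = psi1 + 0.5 * dt * (d1a + d1b)
        psi2 = psi2 + 0.5 * dt * (d2a + d2b)
        buf[:, nxt] = avg @ psi1

        if (k + 1) % cfg.record_stride == 0 and rec_i < n_rec:
            rec1[:, rec_i] = psi1
            rec2[:, rec_i] = psi2
            rec_i += 1
            if not np.isfinite(psi1[0]) or not np.all(np.isfinite(psi1)):
                raise DivergenceError(k + 1)

    if not (np.all(np.isfinite(psi1)) and np.all(np.isfinite(psi2))):
        raise DivergenceError(n_steps)

    condition = {
        "site": stim.target_area if stim is not None else None,
        "alpha": cfg.alpha,
        "sigma": hom.sigma,
    }
    return SimulationResult(
        psi1=rec1[:, :rec_i],
        psi2=rec2[:, :rec_i],
        dt_recorded=dt * cfg.record_stride,
        stimulus=stim if stim is not None else StimulusSpec(amplitude=0.0),
        condition=condition,
    )


def isolated_reference(
    params: NodeParams, stim: StimulusSpec, cfg: SimulationConfig
) -> np.ndarray:
    """Isolated-node trajectory on the recorded time grid, shape (2, n_recorded)."""
    traj = simulate_isolated_node(params, stim, cfg.dt, cfg.duration)
    return traj[:, :: cfg.record_stride]


def subtract_isolated_response(
    result: SimulationResult,
    parcellation: Parcellation,
    params: NodeParams,
    stim: StimulusSpec,
    cfg: SimulationConfig,
) -> SimulationResult:
    """Remove the isolated-node stimulation response from the stimulated area.

    Only nodes of the stimulated area are modified; what remains there is the
    network-mediated re-entrant activity.
    """
    if abs(cfg.dt * cfg.record_stride - result.dt_recorded) > 1e-15:
        raise InvalidArgumentError("config grid does not match the result grid")
    ref = isolated_reference(params, stim, cfg)
    n_t = result.psi1.shape[1]
    if ref.shape[1] < n_t:
        raise InvalidArgumentError("reference trajectory shorter than the result")
    nodes = parcellation.members(stim.target_area)
    psi1 = result.psi1.copy()
    psi2 = result.psi2.copy()
    psi1[nodes] -= ref[0, :n_t]
    psi2[nodes] -= ref[1, :n_t]
    return SimulationResult(
        psi1=psi1,
        psi2=psi2,
        dt_recorded=result.dt_recorded,
        stimulus=result.stimulus,
        condition={**result.condition, "isolated_subtracted": True},
    )


def area_mean_field(result: SimulationResult, parcellation: Parcellation) -> np.ndarray:
    """Per-area arithmetic mean of psi1 at each recorded time, (n_areas x n_t)."""
    for a in range(parcellation.n_areas):
        if parcellation.members(a).size == 0:
            raise InvalidArgumentError(f"area {a} has no member nodes")
    avg = _area_averaging_matrix(parcellation, result.n_nodes)
    return avg @ result.psi1


def save_result(result: SimulationResult, path) -> None:
    """Store a simulation result in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("psi1", data=result.psi1, compression="gzip")
        f.create_dataset("psi2", data=result.psi2, compression="gzip")
        f.attrs["dt_recorded"] = result.dt_recorded
        f.attrs["stim_target_area"] = result.stimulus.target_area
        f.attrs["stim_amplitude"] = result.stimulus.amplitude
        f.attrs["stim_onset"] = result.stimulus.onset
        if result.stimulus.duration is not None:
            f.attrs["stim_duration"] = result.stimulus.duration
        for k, v in result.condition.items():
            if v is not None:
                f.attrs[f"condition_{k}"] = v


def load_result(path) -> SimulationResult:
    import h5py

    with h5py.File(path, "r") as f:
        stim = StimulusSpec(
            target_area=int(f.attrs["stim_target_area"]),
            amplitude=float(f.attrs["stim_amplitude"]),
            onset=float(f.attrs["stim_onset"]),
            duration=float(f.attrs["stim_duration"]) if "stim_duration" in f.attrs else None,
        )
        condition = {
            k[len("condition_"):]: f.attrs[k]
            for k in f.attrs
            if k.startswith("condition_")
        }
        return SimulationResult(
            psi1=f["psi1"][()],
            psi2=f["psi2"][()],
            dt_recorded=float(f.attrs["dt_recorded"]),
            stimulus=stim,
            condition=condition,
        )
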