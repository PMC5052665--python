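"""Isolated two-variable oscillator node: flow, linearization, stimulus calibration.

Each network node is a planar flow

    d psi1 / dt = eta * (psi2 - gamma * psi1 - psi1**3) + drive
    d psi2 / dt = -eta * epsilon * psi1

parameterized just below a supercritical Andronov-Hopf bifurcation, so an
isolated node responds to input with a damped oscillation and is silent
otherwise.  The default parameterization (gamma=1.21, epsilon=12.3083,
eta=76.74 1/s) gives a natural frequency of ~42 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import CalibrationError, IntegrationStepError, InvalidArgumentError

__all__ = [
    "NodeParams",
    "StimulusSpec",
    "node_flow",
    "node_eigenfrequency",
    "critical_coupling",
    "simulate_isolated_node",
    "calibrate_stimulus_amplitude",
]

#: Impulse scaling written for the delta-function stimulus protocol; kept as a
#: documented constant but not used — the calibrated constant-drive protocol is
#: authoritative (see calibrate_stimulus_amplitude).
DELTA_IMPULSE_FACTOR = -5.0


@dataclass
class NodeParams:
    """Parameters of the two-variable node flow.

    The coupling vectors ``a_input``, ``a_local``, ``a_longrange`` project
    input and both connectivity types onto the first state variable; their
    first entry defaults to ``eta`` and the second to 0.
    """

    gamma: float = 1.21
    epsilon: float = 12.3083
    eta: float = 76.74  # 1/s
    a_input: tuple[float, float] | None = None
    a_local: tuple[float, float] | None = None
    a_longrange: tuple[float, float] | None = None

    def __post_init__(self):
        if self.eta <= 0:
            raise InvalidArgumentError("eta must be positive")
        default = (self.eta, 0.0)
        self.a_input = tuple(self.a_input) if self.a_input is not None else default
        self.a_local = tuple(self.a_local) if self.a_local is not None else default
        self.a_longrange = (
            tuple(self.a_longrange) if self.a_longrange is not None else default
        )

    @property
    def is_oscillatory(self) -> bool:
        return self.epsilon > self.gamma**2 / 4


@dataclass
class StimulusSpec:
    """Constant-drive stimulation of one area.

    ``duration`` defaults to the characteristic node time ``1/eta``;
    ``amplitude`` is the pre-scaled drive magnitude added to dpsi1/dt during
    the stimulus window (already signed; see calibrate_stimulus_amplitude).
    """

    target_area: int = 0
    amplitude: float = 1.0
    onset: float = 0.0
    duration: float | None = None

    def resolved_duration(self, params: NodeParams) -> float:
        d = self.duration if self.duration is not None else 1.0 / params.eta
        if d <= 0:
            raise InvalidArgumentError("stimulus duration must be positive")
        return d

    def drive_at(self, t: float, params: NodeParams) -> float:
        d = self.resolved_duration(params)
        return self.amplitude if self.onset <= t < self.onset + d else 0.0

    def step_drive(self, t0: float, t1: float, params: NodeParams) -> float:
        """Exact average drive over the integration step [t0, t1].

        Using the step average in both Heun stages integrates the piecewise-
        constant input exactly, so the stimulus on/offset discontinuities do
        not degrade the second-order convergence of the integrator.
        """
        d = self.resolved_duration(params)
        overlap = min(t1, self.onset + d) - max(t0, self.onset)
        if overlap <= 0:
            return 0.0
        return self.amplitude * overlap / (t1 - t0)


def node_flow(state, params: NodeParams, drive: float = 0.0):
    """Evaluate the node vector field; ``drive`` is added raw to dpsi1/dt.

    Works elementwise on array-valued states, which is what the network
    integrator relies on.
    """
    psi1, psi2 = state
    dpsi1 = params.eta * (psi2 - params.gamma * psi1 - psi1**3) + drive
    dpsi2 = -params.eta * params.epsilon * psi1
    return dpsi1, dpsi2


def node_eigenfrequency(params: NodeParams) -> tuple[float, float]:
    """Natural frequency (Hz) and decay rate (1/s) of the linearized node.

    The Jacobian at the origin is ``[[-eta*gamma, eta], [-eta*epsilon, 0]]``
    with eigenvalues ``eta * (-gamma/2 +- sqrt(gamma^2/4 - epsilon))``.
    Returns frequency 0 in the overdamped/critically damped case.
    """
    disc = params.epsilon - params.gamma**2 / 4
    decay = params.eta * params.gamma / 2
    if disc <= 0:
        return 0.0, decay
    return params.eta * np.sqrt(disc) / (2 * np.pi), decay


def critical_coupling(params: NodeParams) -> float:
    """Constant self-input weight at which the linearized node loses stability.

    A self-connection of weight ``w`` feeds ``eta * w * psi1`` into dpsi1/dt,
    turning the effective damping into ``gamma - w``; the real part of the
    eigenvalues crosses zero at ``w = gamma``.  With both connectivities
    normalized to unity maximum in-strength, the total weight onto any node is
    at most 1 < gamma, so every node stays subcritical.
    """
    return params.gamma


def simulate_isolated_node(
    params: NodeParams,
    stim: StimulusSpec | None,
    dt: float,
    T: float,
    self_weight: float = 0.0,
    initial_state: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Heun-integrate a single node; returns array of shape (2, n_steps+1).

    ``self_weight`` adds an instantaneous self-connection (used to probe the
    criticality threshold).
    """
    freq, _ = node_eigenfrequency(params)
    if freq > 0 and dt >= 1.0 / (10 * freq):
        raise IntegrationStepError(
            f"dt={dt} too coarse for oscillation at {freq:.1f} Hz"
        )
    n = int(round(T / dt))
    out = np.empty((2, n + 1))
    state = np.array(initial_state, dtype=float)
    out[:, 0] = state
    w = self_weight * params.eta

    for k in range(n):
        t = k * dt
        s = stim.step_drive(t, t + dt, params) if stim is not None else 0.0
        d1, d2 = node_flow(state, params, s + w * state[0])
        pred = state + dt * np.array([d1, d2])
        e1, e2 = node_flow(pred, params, s + w * pred[0])
        state = state + 0.5 * dt * np.array([d1 + e1, d2 + e2])
        out[:, k + 1] = state
    return out


def calibrate_stimulus_amplitude(
    params: NodeParams,
    dt: float = 4e-5,
    target_peak: float = 1.0,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> float:
    """Amplitude of a constant drive over ``1/eta`` giving peak |psi1| = 1.

    Found by bisection on the (monotone) peak response of the isolated node.
    """
    duration = 1.0 / params.eta
    # simulate long enough to capture the first few oscillation cycles
    freq, _ = node_eigenfrequency(params)
    T = duration + (3.0 / freq if freq > 0 else 20 * duration)

    def peak(amp: float) -> float:
        stim = StimulusSpec(amplitude=amp, onset=0.0, duration=duration)
        traj = simulate_isolated_node(params, stim, dt, T)
        return float(np.abs(traj[0]).max())

    lo, hi = 0.0, params.eta
    p_hi = peak(hi)
    grow = 0
    while p_hi < target_peak:
        lo, hi = hi, hi * 2
        p_hi = peak(hi)
        grow += 1
        if grow > 60:
            raise CalibrationError("could not bracket the target peak amplitude")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        p = peak(mid)
        if abs(p - target_peak) <= tol:
            return mid
        if p < target_peak:
            lo = mid
        else:
            hi = mid
    raise CalibrationError("bisection did not converge to the target peak")
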