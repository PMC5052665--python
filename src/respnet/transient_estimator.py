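"""Binary activation cascade over areas, used to bound the post-stimulus transient.

Each area is a cell that is either active or inactive.  Activating the seed cell
at t=0 activates every cell ``i`` with a positive incoming weight from an active
cell ``j`` at the sender's activation time plus the transmission delay; activation
is permanent.  The settling time of the cascade, maximized over seed areas,
estimates how long delayed long-range transmission keeps recruiting new areas —
the decomposition window is placed after it.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError
from .synthetic_brain import HeterogeneousSC

__all__ = ["ActivationSchedule", "run_cellular_automaton", "estimate_transient"]


@dataclass
class ActivationSchedule:
    """Activation time per area for one seed; +inf marks unreachable cells."""

    activation_times: np.ndarray  # (n_areas,) seconds
    seed_area: int

    @property
    def settling_time(self) -> float:
        """Largest finite activation time (0 if only the seed fires)."""
        finite = self.activation_times[np.isfinite(self.activation_times)]
        return float(finite.max()) if finite.size else 0.0

    @property
    def unreachable(self) -> np.ndarray:
        return np.where(~np.isfinite(self.activation_times))[0]


def run_cellular_automaton(het: HeterogeneousSC, seed_area: int) -> ActivationSchedule:
    """Run the activation cascade from one seed area.

    Implemented as an event queue: each activation event schedules candidate
    activations of all downstream cells at (current time + delay); a cell
    activates the first time it is reached.
    """
    n = het.n_areas
    if not 0 <= seed_area < n:
        raise InvalidArgumentError(f"seed area {seed_area} out of range")
    tau = het.delays
    out_edges: list[np.ndarray] = [np.nonzero(het.weights[:, j] > 0)[0] for j in range(n)]
    times = np.full(n, np.inf)
    times[seed_area] = 0.0
    queue: list[tuple[float, int]] = [(0.0, seed_area)]
    while queue:
        t, j = heapq.heappop(queue)
        if t > times[j]:
            continue  # superseded event
        for i in out_edges[j]:
            t_new = t + tau[i, j]
            if t_new < times[i]:
                times[i] = t_new
                heapq.heappush(queue, (t_new, int(i)))
    return ActivationSchedule(activation_times=times, seed_area=seed_area)


def estimate_transient(
    het: HeterogeneousSC, return_schedules: bool = False
) -> float | tuple[float, list[ActivationSchedule]]:
    """Maximum settling time of the cascade over all seed areas (seconds).

    Unreachable cells are excluded from the maximum; they are reported on the
    per-seed schedules rather than making the estimate infinite.
    """
    schedules = [run_cellular_automaton(het, s) for s in range(het.n_areas)]
    settle = max((sch.settling_time for sch in schedules), default=0.0)
    if return_schedules:
        return settle, schedules
    return settle
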