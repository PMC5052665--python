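"""PCA of the post-transient stimulation response, plus envelope utilities."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .exceptions import InvalidArgumentError
from .network_simulator import SimulationResult

__all__ = ["ResponseEigenspace", "envelope", "decompose_response"]

log = logging.getLogger(__name__)

VARIANCE_RETENTION = 0.99
MAX_COMPONENTS = 3


@dataclass
class ResponseEigenspace:
    """Up to three orthonormal spatial patterns of one stimulation condition."""

    eigenvectors: np.ndarray  # (n_nodes, k), orthonormal columns
    variance_fractions: np.ndarray  # (k,), descending, in [0, 1]
    all_fractions: np.ndarray  # full spectrum fractions (for diagnostics)
    condition: dict = field(default_factory=dict)
    window: tuple[float, float] = (0.0, 0.0)  # (start s, length s)

    @property
    def k(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def retained_variance(self) -> float:
        return float(self.variance_fractions.sum())

    def validate(self) -> None:
        g = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(g, np.eye(self.k), atol=1e-10):
            raise InvalidArgumentError("eigenvectors are not orthonormal")
        if (np.diff(self.variance_fractions) > 1e-12).any():
            raise InvalidArgumentError("variance fractions must be descending")


def envelope(timeseries: np.ndarray, min_samples: int = 8) -> np.ndarray:
    """Analytic-signal amplitude of each row (Hilbert-transform envelope)."""
    ts = np.atleast_2d(np.asarray(timeseries, dtype=float))
    if ts.shape[1] < min_samples:
        raise InvalidArgumentError(
            f"need at least {min_samples} samples, got {ts.shape[1]}"
        )
    env = np.abs(hilbert(ts, axis=1))
    return env if np.asarray(timeseries).ndim > 1 else env[0]


def canonical_sign(vectors: np.ndarray) -> np.ndarray:
    """Flip columns so the largest-magnitude element of each is positive."""
    v = vectors.copy()
    idx = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[idx, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    return v * signs


def decompose_response(
    result: SimulationResult, window: tuple[float, float]
) -> ResponseEigenspace:
    """Principal spatial patterns of psi1 over the analysis window.

    The covariance is taken across nodes over the window samples (each node
    mean-centered over time); eigenvectors come from an SVD of the centered
    data matrix, sorted by eigenvalue.  The smallest ``k <= 3`` components
    whose cumulative variance fraction first exceeds 0.99 are retained; if
    three never suffice, all three are kept and a warning is logged.
    """
    start, length = window
    if length <= 0:
        raise InvalidArgumentError("window length must be positive")
    t = result.times
    sel = (t >= start) & (t < start + length)
    if not sel.any():
        raise InvalidArgumentError("window lies outside the recorded range")
    x = result.psi1[:, sel]
    x = x - x.mean(axis=1, keepdims=True)
    # economy SVD of the centered data: covariance eigenvectors are the left
    # singular vectors, eigenvalues are s^2 / (T - 1)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    total = var.sum()
    if total == 0:
        fractions = np.zeros_like(var)
        k = 1
    else:
        fractions = var / total
        cum = np.cumsum(fractions[:MAX_COMPONENTS])
        above = np.nonzero(cum >= VARIANCE_RETENTION)[0]
        if above.size:
            k = int(above[0]) + 1
        else:
            k = min(MAX_COMPONENTS, fractions.size)
            log.warning(
                "top-%d components cover only %.4f of variance (condition %s)",
                k, cum[-1], result.condition,
            )
    k = min(k, u.shape[1])
    return ResponseEigenspace(
        eigenvectors=canonical_sign(u[:, :k]),
        variance_fractions=fractions[:k].copy(),
        all_fractions=fractions,
        condition=dict(result.condition),
        window=(float(start), float(length)),
    )
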