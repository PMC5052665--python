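"""Shared fixtures: synthetic brains, node parameters, toy point-area networks."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from respnet.node_dynamics import NodeParams, calibrate_stimulus_amplitude
from respnet.pipeline_cli import make_fixture
from respnet.synthetic_brain import (
    BrainGeometry,
    HeterogeneousSC,
    HomogeneousSC,
    Parcellation,
    normalize_heterogeneous,
)
from respnet.transient_estimator import estimate_transient


@pytest.fixture(scope="session")
def params():
    return NodeParams()


@pytest.fixture(scope="session")
def amplitude(params):
    return calibrate_stimulus_amplitude(params)


@pytest.fixture(scope="session")
def tiny_bundle():
    return make_fixture("tiny", seed=0)


@pytest.fixture(scope="session")
def tiny_transient(tiny_bundle):
    return estimate_transient(tiny_bundle.het)


def make_point_brain(n_areas: int, weights: np.ndarray, lengths: np.ndarray,
                     speed: float = 6.0, positions: np.ndarray | None = None,
                     normalize: bool = True):
    """A brain of point-like areas only: zero short-range SC, custom long-range SC.

    Convenient for hand-checkable delay and coupling scenarios.
    """
    if positions is None:
        positions = np.column_stack(
            [np.arange(n_areas, dtype=float) * 10.0, np.zeros(n_areas), np.zeros(n_areas)]
        )
    geom = BrainGeometry(
        cortical_vertices=np.empty((0, 3)),
        triangles=np.empty((0, 3), dtype=int),
        hemisphere_label=np.empty(0, dtype=int),
        subcortical_positions=positions,
    )
    areas = pd.DataFrame(
        dict(
            id=range(n_areas),
            name=[f"SUB{i}" for i in range(n_areas)],
            kind="subcortical",
            hemisphere="none",
            is_callosal=False,
        )
    )
    parc = Parcellation(
        node_area=np.arange(n_areas),
        areas=areas,
        area_centroids=positions,
    )
    hom = HomogeneousSC(weights=sp.csr_matrix((n_areas, n_areas)), sigma=1.0)
    w = normalize_heterogeneous(weights) if normalize else np.asarray(weights, float)
    het = HeterogeneousSC(weights=w, tract_lengths=np.asarray(lengths, float),
                          speed=speed)
    return geom, parc, hom, het
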