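import numpy as np
import pandas as pd
import pytest

from immunet.graph import AGGREGATE_NODES, SignedWeightedDigraph
from immunet.panel import CYTOKINES, NOMINAL_MINUTES, TIMEPOINT_LABELS, CytokinePanel


def make_panel(subjects=(("S1", "HC"), ("S2", "GWI")), base=10.0):
    """Small well-formed pg/ml panel: every cytokine at all 8 draws."""
    rows = []
    for k, (sid, group) in enumerate(subjects):
        for c_i, cyt in enumerate(CYTOKINES):
            for t_i, label in enumerate(TIMEPOINT_LABELS):
                conc = base + k + 0.5 * c_i + 0.25 * t_i
                rows.append(
                    (sid, group, cyt, label, NOMINAL_MINUTES[label], conc)
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "group", "cytokine", "timepoint_label",
            "minutes_from_T1", "concentration",
        ],
    )
    return CytokinePanel(df, units="pg_ml")


@pytest.fixture
def small_panel():
    return make_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_signed_graph(n_nodes, density, rng, names=None, weight_scale=1.0):
    names = tuple(names) if names else tuple(f"n{i}" for i in range(n_nodes))
    A = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i != j and rng.random() < density:
                A[i, j] = rng.choice([-1, 1]) * rng.uniform(0.2, 1.0) * weight_scale
    return SignedWeightedDigraph(names, A)


@pytest.fixture
def aggregate_names():
    return AGGREGATE_NODES
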