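import networkx as nx
import numpy as np
import pytest

from dysnet import CoverInstance, ExpressionStudy


@pytest.fixture
def path_instance():
    """Path a-b-c; S_a={u1,u2}, S_b={}, S_c={u2,u3}; k=1, l=0."""
    g = nx.path_graph(["a", "b", "c"])
    return CoverInstance(
        g, {"a": {"u1", "u2"}, "b": set(), "c": {"u2", "u3"}},
        ["u1", "u2", "u3"], k=1, l=0,
    )


@pytest.fixture
def triangle_instance():
    """Three mutually linked genes, three cases: genes 1 and 2 dysregulated in
    cases 1 and 3, gene 3 only in case 1; with k=2, l=1 the trio is a valid
    cover with case 2 as the outlier."""
    g = nx.complete_graph(["g1", "g2", "g3"])
    sets = {"g1": {"c1", "c3"}, "g2": {"c1", "c3"}, "g3": {"c1"}}
    return CoverInstance(g, sets, ["c1", "c2", "c3"], k=2, l=1)


@pytest.fixture
def unit_controls_study():
    """Two genes with control mean 0 and control sd exactly 1 and 0.1."""
    genes = ["gA", "gB"]
    samples = ["s_case", "c1", "c2", "c3"]
    values = np.array([
        [2.0, -1.0, 0.0, 1.0],   # gA: controls sd 1
        [0.3, -0.1, 0.0, 0.1],   # gB: controls sd 0.1
    ])
    labels = {"s_case": "case", "c1": "control", "c2": "control", "c3": "control"}
    return ExpressionStudy(genes, samples, values, labels)
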