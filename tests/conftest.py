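import pytest
from hypothesis import settings

from complexevo import ComplexDataset
from complexevo.ontology import GOResource

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture()
def chain_go() -> GOResource:
    """Three-term chain root→a→b with four annotated proteins.

    Propagated counts: root 4, a 3 (p1, p2 via b; p3 direct), b 2 —
    so IC(a) = −ln(3/4) and IC(b) = −ln(2/4).
    """
    return GOResource(
        parents={"root": set(), "a": {"root"}, "b": {"a"}},
        annotations={
            "p1": {"b"},
            "p2": {"b"},
            "p3": {"a"},
            "p4": {"root"},
        },
    )


@pytest.fixture()
def worked_benchmark():
    """Gold {A,B,C},{D,E}; clusters {A,B,D,E},{C,F} — the hand-scored case."""
    gold = ComplexDataset.from_lists([{"A", "B", "C"}, {"D", "E"}], provenance="gold")
    predicted = ComplexDataset.from_lists([{"A", "B", "D", "E"}, {"C", "F"}])
    return predicted, gold
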