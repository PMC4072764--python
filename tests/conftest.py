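from __future__ import annotations

import pytest
from hypothesis import settings

from blisterome.go_enrichment import AnnotationSet
from blisterome.go_semantics import GoDag

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: hand-built five-term DAG used across the semantic-similarity tests
#:
#:        R
#:       / \
#:      A   B
#:     / \ / \
#:    C   D   E
TOY_PARENTS = {
    "R": set(),
    "A": {"R"},
    "B": {"R"},
    "C": {"A"},
    "D": {"A", "B"},
    "E": {"B"},
}
TOY_NAMESPACE = {t: "biological_process" for t in TOY_PARENTS}

#: direct annotations of an 8-gene corpus over the toy DAG; propagated
#: counts are C:2, D:2, E:1, A:5, B:4, R:8 (g8 reaches only the root)
TOY_DIRECT = {
    "g1": {"C"},
    "g2": {"C"},
    "g3": {"D"},
    "g4": {"D"},
    "g5": {"E"},
    "g6": {"A"},
    "g7": {"B"},
    "g8": set(),
}


@pytest.fixture
def toy_dag() -> GoDag:
    return GoDag(parents={k: set(v) for k, v in TOY_PARENTS.items()},
                 namespace=dict(TOY_NAMESPACE))


@pytest.fixture
def toy_annotations(toy_dag) -> AnnotationSet:
    from blisterome.synthetic_data import propagate_annotations

    direct = {g: set(ts) for g, ts in TOY_DIRECT.items()}
    propagated = {g: propagate_annotations(ts, toy_dag) | {"R"}
                  for g, ts in direct.items()}
    return AnnotationSet(direct=direct, propagated=propagated)
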