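"""Shared fixtures: small hand-built pathways and one default simulated study."""

from __future__ import annotations

import pytest

from dmspn.pathway_model import GeneAnnotationMap, PathwayDefinition, Reaction
from dmspn.pipeline import run_simulated_study
from dmspn.synthetic import SimulationDesign


@pytest.fixture
def chain_pathway() -> PathwayDefinition:
    """Linear chain: S1 -(E1)-> C1 -(E2)-> C2 -(E3)-> P."""
    return PathwayDefinition(
        pathway_id="path:chain",
        reactions=[
            Reaction("R1", ("S1",), ("C1",), ("E1",)),
            Reaction("R2", ("C1",), ("C2",), ("E2",)),
            Reaction("R3", ("C2",), ("P",), ("E3",)),
        ],
    )


@pytest.fixture
def simple_annotations() -> GeneAnnotationMap:
    return GeneAnnotationMap(
        [("g1", "E1"), ("g2", "E1"), ("g3", "E2"), ("g4", "E3"), ("g4", "E1")]
    )


@pytest.fixture(scope="session")
def default_study():
    """The default simulated study, shared across tests (seed fixed)."""
    return run_simulated_study(SimulationDesign(seed=1))
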