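from __future__ import annotations

import pytest

from pathalign import (
    CompoundSimilarityProvider,
    build_hypergraph,
)


def chain_records(n: int = 3, compounds: str = "ABCDEFGHIJ"):
    """Raw records for a linear chain A -R1-> B -R2-> C ..."""
    ecs = ["1.1.1.1", "2.2.2.2", "3.3.3.3", "4.4.4.4", "5.5.5.5",
           "6.6.6.6", "1.2.3.4", "2.3.4.5", "3.4.5.6", "4.5.6.7"]
    return [
        {
            "id": f"R{i + 1}",
            "inputs": [compounds[i]],
            "outputs": [compounds[i + 1]],
            "ec": [ecs[i % len(ecs)]],
        }
        for i in range(n)
    ]


@pytest.fixture
def chain3():
    return build_hypergraph(chain_records(3), pathway_id="chain3")


@pytest.fixture
def identity_provider():
    return CompoundSimilarityProvider.identity()
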