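from __future__ import annotations

import pytest

from derepkit.io_formats import GenomeRecord, SimilarityEdge
from derepkit.similarity import (
    DereplicationParams,
    build_similarity_graph,
    compute_scores,
)


def make_roster(n50s: dict[str, int]) -> list[GenomeRecord]:
    """Single-contig genomes whose N50 equals the given length."""
    return [
        GenomeRecord(gid, (n,), n, "<test>") for gid, n in n50s.items()
    ]


def edge(
    a: str,
    b: str,
    ani: float = 99.5,
    af_a: float = 95.0,
    af_b: float = 95.0,
) -> SimilarityEdge:
    return SimilarityEdge(a, b, ani, af_a, af_b)


def graph_and_scores(edges, n50s, params: DereplicationParams | None = None):
    params = params or DereplicationParams()
    roster = make_roster(n50s)
    graph = build_similarity_graph(edges, roster, params)
    return graph, compute_scores(graph, roster)


@pytest.fixture
def default_params() -> DereplicationParams:
    return DereplicationParams()
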