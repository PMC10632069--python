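"""Shared fixtures: a literal OBO fragment, random-DAG builders with
brute-force closure oracles, and a small synthetic cohort."""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from ontomet.ontology import OntologyGraph, OntologyTerm
from ontomet.simulate import (
    SimulationDesign,
    make_env_ontology,
    make_go_like_ontology,
    make_taxonomy,
    simulate_dataset,
)
from ontomet.store import Store

# A hand-written OBO fragment around the worked subclass-query example:
# photosynthesis and methanogenesis are recursive subclasses of cellular
# metabolic process; cation binding sits under binding.  Includes an
# obsolete term and a dangling parent on purpose.
GO_FIXTURE_OBO = """format-version: 1.2
ontology: fixture

[Term]
id: GO:0044237
name: cellular metabolic process

[Term]
id: GO:0015979
name: photosynthesis
is_a: GO:0044237 ! cellular metabolic process

[Term]
id: GO:0015947
name: methane metabolic process
is_a: GO:0044237

[Term]
id: GO:0015948
name: methanogenesis
is_a: GO:0015947

[Term]
id: GO:0005488
name: binding

[Term]
id: GO:0043169
name: cation binding
is_a: GO:0005488

[Term]
id: GO:0016151
name: nickel cation binding
is_a: GO:0043169

[Term]
id: GO:0000001
name: retired process
is_a: GO:0044237
is_obsolete: true

[Term]
id: GO:0000002
name: orphan process
is_a: GO:0099999
"""


@pytest.fixture(scope="session")
def go_graph():
    from ontomet.ontology import parse_obo

    return parse_obo(GO_FIXTURE_OBO)


def build_graph(parent_map: dict[str, set[str]], ranks=None) -> OntologyGraph:
    ranks = ranks or {}
    terms = {
        t: OntologyTerm(
            id=t,
            label=f"term {t}",
            parent_ids=frozenset(ps),
            rank=ranks.get(t, "no rank"),
        )
        for t, ps in parent_map.items()
    }
    g = OntologyGraph(terms=terms)
    g.validate_acyclic()
    return g


def random_dag(rng: np.random.Generator, n: int) -> dict[str, set[str]]:
    """Random DAG as a parent map; parents always precede children."""
    ids = [f"T:{i:04d}" for i in range(n)]
    parents: dict[str, set[str]] = {ids[0]: set()}
    for i in range(1, n):
        k = int(rng.integers(0, min(3, i) + 1))
        chosen = rng.choice(ids[:i], size=k, replace=False) if k else []
        parents[ids[i]] = set(map(str, chosen))
    return parents


def bfs_reachable(adj: dict[str, set[str]], start: str) -> set[str]:
    """Plain BFS over an adjacency map — the independent closure oracle."""
    seen = {start}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nxt in adj.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)
    return seen


def children_map(parent_map: dict[str, set[str]]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {t: set() for t in parent_map}
    for child, parents in parent_map.items():
        for p in parents:
            adj[p].add(child)
    return adj


@pytest.fixture(scope="session")
def cohort():
    """64-sample HOT-like cohort at reduced sequencing depth, in memory."""
    design = SimulationDesign(seed=11, n_samples=64, scale=1e-3)
    records, stats, func, taxa, ledger = simulate_dataset(design)
    store = Store(
        records={r.sample_id: r for r in records},
        stats=stats,
        tables={"function": func, "taxon": taxa},
    )
    ontologies = {
        "function": make_go_like_ontology(design.seed, design.n_function_terms),
        "taxon": make_taxonomy(design.seed, design.n_taxon_terms),
        "env": make_env_ontology(),
    }
    return store, ontologies, ledger, design
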