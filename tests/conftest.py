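"""Shared builders and independent oracles for the test suite."""

from __future__ import annotations

import random

import pytest

from gocongruence import parse_obo


def make_obo(terms, header: str = "format-version: 1.2\nontology: test\n") -> str:
    """Assemble OBO text from term dicts.

    Each term dict: ``id`` (required), optional ``name``, ``namespace``
    (default biological_process), ``is_a``/``part_of`` parent lists,
    ``obsolete`` flag, ``alt_ids``, ``replaced_by``.
    """
    chunks = [header]
    for t in terms:
        lines = ["[Term]", f"id: {t['id']}"]
        if "name" in t:
            lines.append(f"name: {t['name']}")
        if t.get("namespace", "biological_process") is not None:
            lines.append(f"namespace: {t.get('namespace', 'biological_process')}")
        for p in t.get("is_a", ()):
            lines.append(f"is_a: {p}")
        for p in t.get("part_of", ()):
            lines.append(f"relationship: part_of {p}")
        for a in t.get("alt_ids", ()):
            lines.append(f"alt_id: {a}")
        if t.get("obsolete"):
            lines.append("is_obsolete: true")
        for r in t.get("replaced_by", ()):
            lines.append(f"replaced_by: {r}")
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def gid(i: int) -> str:
    return f"GO:{i:07d}"


@pytest.fixture
def chain_graph():
    """a is_a b is_a root (GO:3 -> GO:2 -> GO:1)."""
    return parse_obo(
        make_obo(
            [
                {"id": gid(1), "name": "root"},
                {"id": gid(2), "name": "b", "is_a": [gid(1)]},
                {"id": gid(3), "name": "a", "is_a": [gid(2)]},
            ]
        )
    )


@pytest.fixture
def diamond_graph():
    """a is_a b, a is_a c, b is_a root, c is_a root."""
    return parse_obo(
        make_obo(
            [
                {"id": gid(1), "name": "root"},
                {"id": gid(2), "name": "b", "is_a": [gid(1)]},
                {"id": gid(3), "name": "c", "is_a": [gid(1)]},
                {"id": gid(4), "name": "a", "is_a": [gid(2), gid(3)]},
            ]
        )
    )


def random_dag(rng: random.Random, n_terms: int):
    """A random rooted DAG as (term ids, edge list (child, parent, relation)).

    Node 1 is the root; every node i > 1 picks 1-3 parents among
    lower-numbered nodes, so the graph is acyclic by construction.
    """
    ids = [gid(i) for i in range(1, n_terms + 1)]
    edges = []
    for i in range(2, n_terms + 1):
        n_parents = rng.randint(1, min(3, i - 1))
        for p in rng.sample(range(1, i), n_parents):
            edges.append((gid(i), gid(p), rng.choice(["is_a", "part_of"])))
    return ids, edges


def dag_to_obo(ids, edges) -> str:
    terms = []
    for tid in ids:
        is_a = [p for c, p, rel in edges if c == tid and rel == "is_a"]
        part_of = [p for c, p, rel in edges if c == tid and rel == "part_of"]
        terms.append({"id": tid, "name": tid, "is_a": is_a, "part_of": part_of})
    return make_obo(terms)


def reachability_oracle(edges, start: str, relations=("is_a", "part_of")) -> set[str]:
    """Reflexive transitive closure by plain recursive DFS on the edge list.

    Independent of the package's breadth-first implementation: works on the
    raw generated edges, never on a parsed graph.
    """
    adjacency: dict[str, list[str]] = {}
    for c, p, rel in edges:
        if rel in relations:
            adjacency.setdefault(c, []).append(p)
    seen: set[str] = set()

    def visit(node: str) -> None:
        if node in seen:
            return
        seen.add(node)
        for parent in adjacency.get(node, ()):
            visit(parent)

    visit(start)
    return seen


GAF_HEADER = "!gaf-version: 2.1\n"


def gaf_row(
    gene: str,
    term: str,
    evidence: str = "IDA",
    aspect: str = "P",
    qualifier: str = "",
    taxon: str = "taxon:9606",
    symbol: str | None = None,
) -> str:
    cols = [
        "TESTDB",
        gene,
        symbol or gene,
        qualifier,
        term,
        "PMID:1",
        evidence,
        "",
        aspect,
        "",
        "",
        "protein",
        taxon,
        "20110910",
        "TEST",
        "",
        "",
    ]
    return "\t".join(cols) + "\n"
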