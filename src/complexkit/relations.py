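"""Sub-assembly / super-assembly detection among unique compositions.

A composition *a* is a sub-assembly of *b* when every component of *a* also
occurs in *b* and *b* has at least one additional component; *b* is then a
super-assembly of *a*.  Components compare by canonical identity (accession
for mapped components, full type/entry/entity label for unmapped ones), so an
unmapped component only ever matches itself.  Two stoichiometry regimes are
supported: ``strict`` requires shared components to keep identical copy
numbers; ``relaxed`` only requires the sub-assembly's copy numbers not to
exceed the super-assembly's.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx

from .identity import label_identity
from .models import UniqueAssembly

MODES = ("strict", "relaxed")


def _identity_counts(unique: UniqueAssembly) -> dict[str, int]:
    out: dict[str, int] = {}
    for label in unique.key.labels:
        identity = label_identity(label)
        stoich = int(label.rsplit("_", 1)[1])
        out[identity] = out.get(identity, 0) + stoich
    return out


def is_subassembly(a: UniqueAssembly, b: UniqueAssembly, mode: str = "strict") -> bool:
    """True iff a's components form a strict subset of b's.

    In strict mode every shared component must have equal stoichiometry; in
    relaxed mode the sub-assembly's stoichiometry may be lower.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    ca, cb = _identity_counts(a), _identity_counts(b)
    if not set(ca) < set(cb):
        return False
    if mode == "strict":
        return all(cb[k] == v for k, v in ca.items())
    return all(cb[k] >= v for k, v in ca.items())


def build_relation_graph(
    uniques: Sequence[UniqueAssembly], mode: str = "strict"
) -> nx.DiGraph:
    """All-pairs sub/super relation graph over unique compositions.

    Nodes are composition md5 digests; an edge (a, b) means a is a
    sub-assembly of b.  Node attributes carry per-composition counts of
    super- and sub-assemblies.
    """
    graph = nx.DiGraph(mode=mode)
    counts = [(u.md5_hex, _identity_counts(u), u) for u in uniques]
    for md5, _, u in counts:
        graph.add_node(md5, accession=u.accession)
    for i, (md5_a, ca, _) in enumerate(counts):
        for j, (md5_b, cb, _) in enumerate(counts):
            if i == j or md5_a == md5_b:
                continue
            if not set(ca) < set(cb):
                continue
            if mode == "strict":
                ok = all(cb[k] == v for k, v in ca.items())
            else:
                ok = all(cb[k] >= v for k, v in ca.items())
            if ok:
                added = sorted(set(cb) - set(ca))
                graph.add_edge(md5_a, md5_b, added_components=added)
    for node in graph.nodes:
        graph.nodes[node]["n_super"] = graph.out_degree(node)
        graph.nodes[node]["n_sub"] = graph.in_degree(node)
    return graph


def transitive_reduction_view(graph: nx.DiGraph) -> nx.DiGraph:
    """Direct-containment view of the relation graph (derived, not stored)."""
    reduced = nx.transitive_reduction(graph)
    reduced.add_nodes_from(graph.nodes(data=True))
    return reduced


def relation_rows(
    graph: nx.DiGraph, accession_of: dict[str, str]
) -> list[dict[str, str]]:
    """Flatten the graph to stable TSV-ready rows (sub, super, added)."""
    rows = []
    for sub_md5, super_md5, data in graph.edges(data=True):
        rows.append(
            {
                "sub_accession": accession_of.get(sub_md5, sub_md5),
                "super_accession": accession_of.get(super_md5, super_md5),
                "sub_md5": sub_md5,
                "super_md5": super_md5,
                "added_components": "|".join(data.get("added_components", [])),
            }
        )
    rows.sort(key=lambda r: (r["sub_accession"], r["super_accession"]))
    return rows


def summarize(graph: nx.DiGraph) -> dict[str, float]:
    n = graph.number_of_nodes()
    n_sub = sum(1 for _, deg in graph.out_degree() if deg > 0)
    n_super = sum(1 for _, deg in graph.in_degree() if deg > 0)
    return {
        "n_compositions": n,
        "n_subassemblies": n_sub,
        "n_superassemblies": n_super,
        "fraction_subassemblies": (n_sub / n) if n else 0.0,
        "fraction_superassemblies": (n_super / n) if n else 0.0,
    }


def brute_force_edges(
    uniques: Iterable[UniqueAssembly], mode: str = "strict"
) -> set[tuple[str, str]]:
    """Quadratic oracle: re-derive the edge set directly from is_subassembly."""
    us = list(uniques)
    return {
        (a.md5_hex, b.md5_hex)
        for a in us
        for b in us
        if a.md5_hex != b.md5_hex and is_subassembly(a, b, mode=mode)
    }
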