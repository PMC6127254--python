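"""Association networks over significant concept pairs.

Nodes are enriched concepts (tagged with their dictionary); an edge
carries the number of publications linking the pair (the pair's
co-occurrence document count) and the pair's FDR. Networks are grown
explicitly from a seed concept by expanding one node at a time, with a
hard cap on children per expansion so that dense hubs stay readable.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .enrichment import PairAssociation

__all__ = [
    "AssociationNetwork",
    "build_network",
    "expand_from_term",
    "prune",
    "export_network",
    "import_network",
    "collapse_levels",
    "MAX_CHILDREN",
]

#: a node can be expanded by at most this many sub-nodes per call
MAX_CHILDREN = 10


@dataclass
class AssociationNetwork:
    graph: nx.Graph = field(default_factory=nx.Graph)
    seed: str = ""
    # pair table and concept->dictionary lookup captured at build time so
    # expansion calls need not re-supply them
    pairs: list[PairAssociation] = field(default_factory=list, repr=False)
    dictionaries: dict[str, str] = field(default_factory=dict, repr=False)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def node_dictionary(self, concept_id: str) -> str:
        return self.graph.nodes[concept_id].get("dictionary", "")

    def edges(self) -> list[tuple[str, str, int, float]]:
        return [
            (a, b, d["publication_count"], d["fdr"])
            for a, b, d in self.graph.edges(data=True)
        ]


def _pair_lookup(pairs: Iterable[PairAssociation]) -> dict[str, list[PairAssociation]]:
    by_concept: dict[str, list[PairAssociation]] = {}
    for p in pairs:
        by_concept.setdefault(p.concept_a, []).append(p)
        by_concept.setdefault(p.concept_b, []).append(p)
    return by_concept


def build_network(
    seed_concept: str,
    pairs: Iterable[PairAssociation],
    dictionaries: Mapping[str, str] | None = None,
) -> AssociationNetwork:
    """Start a network: the seed node alone; expansion is explicit."""
    pairs = list(pairs)
    known = {c for p in pairs for c in (p.concept_a, p.concept_b)}
    if dictionaries:
        known |= set(dictionaries)
    if seed_concept not in known:
        raise KeyError(f"unknown concept {seed_concept!r}")
    net = AssociationNetwork(seed=seed_concept, pairs=pairs,
                             dictionaries=dict(dictionaries or {}))
    dname = net.dictionaries.get(seed_concept, "")
    net.graph.add_node(seed_concept, dictionary=dname)
    return net


def expand_from_term(
    net: AssociationNetwork,
    node: str,
    allowed_dictionaries: set[str] | None = None,
    max_children: int = MAX_CHILDREN,
    pairs: Iterable[PairAssociation] | None = None,
    dictionaries: Mapping[str, str] | None = None,
    rank_by: str = "publications",
) -> AssociationNetwork:
    """Expand ``node`` with up to ``max_children`` partners from the
    significant pairs.

    Partners are ranked by publication count descending, FDR ascending,
    then concept id (``rank_by="fdr"`` swaps the first two keys). Partners
    whose dictionary is not in ``allowed_dictionaries`` (when given) are
    skipped. Nodes already present gain the edge but are not duplicated;
    expanding the same node twice is a no-op.
    """
    if node not in net.graph:
        raise KeyError(f"node {node!r} not in network")
    if pairs is None:
        pairs = net.pairs
    dictionaries = dict(dictionaries or net.dictionaries)
    partners: list[tuple[PairAssociation, str]] = []
    for p in pairs:
        if node == p.concept_a:
            other = p.concept_b
        elif node == p.concept_b:
            other = p.concept_a
        else:
            continue
        if other == node:
            continue
        dname = dictionaries.get(other, "")
        if allowed_dictionaries is not None and dname not in allowed_dictionaries:
            continue
        partners.append((p, other))
    if rank_by == "fdr":
        partners.sort(key=lambda t: (t[0].fdr, -t[0].co_doc_count, t[1]))
    else:
        partners.sort(key=lambda t: (-t[0].co_doc_count, t[0].fdr, t[1]))
    for p, other in partners[:max_children]:
        if other not in net.graph:
            net.graph.add_node(other, dictionary=dictionaries.get(other, ""))
        net.graph.add_edge(node, other, publication_count=p.co_doc_count, fdr=p.fdr)
    return net


def prune(net: AssociationNetwork, min_links: int) -> AssociationNetwork:
    """Iteratively drop non-seed nodes of degree < min_links until stable."""
    if min_links < 1:
        raise ValueError("min_links must be >= 1")
    g = net.graph
    while True:
        victims = [n for n in g.nodes if n != net.seed and g.degree(n) < min_links]
        if not victims:
            break
        g.remove_nodes_from(victims)
    return net


def export_network(net: AssociationNetwork, path: str | Path, format: str = "edge-list") -> None:
    """Write the network: ``graph-markup`` (GraphML), ``structured-records``
    (line-delimited JSON node/edge records), or ``edge-list`` (TSV
    a, b, publication_count, fdr)."""
    path = Path(path)
    if format == "graph-markup":
        g = net.graph.copy()
        g.graph["seed"] = net.seed
        nx.write_graphml(g, path)
    elif format == "structured-records":
        with path.open("w") as fh:
            fh.write(json.dumps({"record": "meta", "seed": net.seed}) + "\n")
            for n, d in net.graph.nodes(data=True):
                fh.write(json.dumps({"record": "node", "id": n,
                                     "dictionary": d.get("dictionary", "")}) + "\n")
            for a, b, d in net.graph.edges(data=True):
                fh.write(json.dumps({"record": "edge", "a": a, "b": b,
                                     "publication_count": d["publication_count"],
                                     "fdr": d["fdr"]}) + "\n")
    elif format == "edge-list":
        with path.open("w") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for a, b, count, fdr in sorted(net.edges()):
                w.writerow([a, b, count, repr(fdr)])
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path: str | Path, format: str = "structured-records") -> AssociationNetwork:
    path = Path(path)
    if format == "graph-markup":
        g = nx.read_graphml(path)
        seed = g.graph.pop("seed", "")
        net = AssociationNetwork(seed=seed)
        for n, d in g.nodes(data=True):
            net.graph.add_node(n, dictionary=d.get("dictionary", ""))
        for a, b, d in g.edges(data=True):
            net.graph.add_edge(a, b, publication_count=int(d["publication_count"]),
                               fdr=float(d["fdr"]))
        return net
    if format == "structured-records":
        net = AssociationNetwork()
        with path.open() as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                if rec["record"] == "meta":
                    net.seed = rec.get("seed", "")
                elif rec["record"] == "node":
                    net.graph.add_node(rec["id"], dictionary=rec.get("dictionary", ""))
                else:
                    net.graph.add_edge(rec["a"], rec["b"],
                                       publication_count=int(rec["publication_count"]),
                                       fdr=float(rec["fdr"]))
        return net
    raise ValueError(f"unknown format {format!r}")


def collapse_levels(net: AssociationNetwork) -> AssociationNetwork:
    """Merge DNA- and protein-level nodes describing the same variant.

    Nodes whose ids are pipe-form variants sharing (wild, position, mutant)
    collapse into one node (the protein-level id wins); edges are merged
    keeping the larger publication count, smaller FDR.
    """
    groups: dict[tuple, list[str]] = {}
    for n in net.graph.nodes:
        parts = n.split("|")
        if len(parts) == 5:
            key = (parts[1], parts[2].upper(), parts[3], parts[4].upper())
            groups.setdefault(key, []).append(n)
    merged = AssociationNetwork(seed=net.seed)
    rename: dict[str, str] = {}
    for key, members in groups.items():
        if len(members) > 1:
            keep = sorted(members, key=lambda m: (not m.startswith("p|"), m))[0]
            for m in members:
                rename[m] = keep
    for n, d in net.graph.nodes(data=True):
        merged.graph.add_node(rename.get(n, n), **d)
    for a, b, d in net.graph.edges(data=True):
        a2, b2 = rename.get(a, a), rename.get(b, b)
        if a2 == b2:
            continue
        if merged.graph.has_edge(a2, b2):
            prev = merged.graph.edges[a2, b2]
            prev["publication_count"] = max(prev["publication_count"], d["publication_count"])
            prev["fdr"] = min(prev["fdr"], d["fdr"])
        else:
            merged.graph.add_edge(a2, b2, **d)
    merged.seed = rename.get(net.seed, net.seed)
    return merged
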