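"""Haplotype networks and their temporal decomposition.

Distances between haplotypes count mutational steps column by column,
optionally treating the alignment gap as a fifth character state so that
each deleted position contributes one step (a 64-bp deletion is 64 steps).
The network itself is a minimum-spanning network (MSN): the union of every
edge that occurs in at least one minimum spanning tree of the complete
distance graph.  The MSN is deterministic, keeps all equally-short
alternative connections as tie edges, and replaces statistical-parsimony
construction for descriptive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import networkx as nx
import pandas as pd

from haplochron.seqio import (
    AMBIGUITY_CODES,
    HaplotypeCatalog,
    HaplotypeTable,
    InputError,
)

Edge = tuple[str, str, int]


def pairwise_distance(
    a: str,
    b: str,
    gap_mode: Literal["fifth_state", "ignore"] = "fifth_state",
) -> int:
    """Number of mutational steps between two aligned haplotype sequences.

    ``fifth_state``: '-' is a distinct character, so every column of a
    deletion counts as one step.  ``ignore``: columns where either
    sequence has '-' are skipped.
    """
    if len(a) != len(b):
        raise InputError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if gap_mode == "fifth_state":
        return sum(x != y for x, y in zip(a, b))
    if gap_mode == "ignore":
        return sum(x != y for x, y in zip(a, b) if x != "-" and y != "-")
    raise InputError(f"unknown gap_mode {gap_mode!r}")


@dataclass
class HaplotypeNetwork:
    """Nodes = haplotypes (with sample frequency), edges = mutational steps.

    ``tie_edges`` are edges kept only because they tie an alternative
    minimum-spanning connection; removing any one of them still leaves a
    minimum spanning tree inside the network.
    """

    nodes: dict[str, dict]
    edges: set[Edge]
    tie_edges: set[Edge] = field(default_factory=set)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for label, attrs in self.nodes.items():
            g.add_node(label, **attrs)
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w, tie=(a, b, w) in self.tie_edges)
        return g

    def to_graphml(self, path: str | Path) -> None:
        g = self.graph()
        # GraphML attribute values must be scalars
        for _, attrs in g.nodes(data=True):
            comp = attrs.pop("composition", None)
            if comp is not None:
                for key, cnt in comp.items():
                    attrs[f"count_{key}"] = cnt
        nx.write_graphml(g, str(path))

    def to_edgelist_tsv(self, path: str | Path) -> None:
        rows = [
            {"a": a, "b": b, "weight": w, "tie": (a, b, w) in self.tie_edges}
            for a, b, w in sorted(self.edges)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _canon(a: str, b: str, w: int) -> Edge:
    return (a, b, w) if a <= b else (b, a, w)


def build_msn(
    catalog: HaplotypeCatalog,
    gap_mode: Literal["fifth_state", "ignore"] = "fifth_state",
    max_connection: int | None = None,
) -> HaplotypeNetwork:
    """Build the minimum-spanning network over a haplotype catalog.

    An edge (u, v) of weight w belongs to some minimum spanning tree of
    the complete distance graph iff u and v lie in different components of
    the subgraph made of all strictly lighter edges (cycle property).  The
    MSN retains exactly those edges, so it is the union of all MSTs and is
    independent of input order.

    ``max_connection`` optionally drops MSN edges heavier than the given
    number of steps, emulating a network connection limit; the result may
    then be disconnected.
    """
    labels = sorted(catalog.labels)
    if not labels:
        raise InputError("empty catalog")
    seq = {lab: catalog.sequence(lab) for lab in labels}
    freq = {lab: len(catalog.members(lab)) for lab in labels}

    all_edges: list[Edge] = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            all_edges.append(_canon(a, b, pairwise_distance(seq[a], seq[b], gap_mode)))
    all_edges.sort(key=lambda e: e[2])

    msn: set[Edge] = set()
    lighter = nx.Graph()
    lighter.add_nodes_from(labels)
    i = 0
    while i < len(all_edges):
        # process all edges of equal weight against the strictly-lighter graph
        j = i
        w = all_edges[i][2]
        comp = {n: c for c, nodes in enumerate(nx.connected_components(lighter))
                for n in nodes}
        while j < len(all_edges) and all_edges[j][2] == w:
            a, b, _ = all_edges[j]
            if comp[a] != comp[b]:
                msn.add(all_edges[j])
            j += 1
        for e in all_edges[i:j]:
            lighter.add_edge(e[0], e[1])
        i = j

    if max_connection is not None:
        msn = {e for e in msn if e[2] <= max_connection}

    # tie edges: MSN edges beyond the |V|-1 needed for a single MST, i.e.
    # edges whose removal leaves the MST weight unchanged
    g = nx.Graph()
    g.add_nodes_from(labels)
    for a, b, w in msn:
        g.add_edge(a, b, weight=w)
    tie: set[Edge] = set()
    if nx.is_connected(g) and len(labels) > 1:
        mst_w = nx.minimum_spanning_tree(g).size(weight="weight")
        for a, b, w in msn:
            g.remove_edge(a, b)
            if nx.is_connected(g):
                alt = nx.minimum_spanning_tree(g).size(weight="weight")
                if alt == mst_w:
                    tie.add((a, b, w))
            g.add_edge(a, b, weight=w)

    nodes = {
        lab: {"frequency": freq[lab], "composition": {}} for lab in labels
    }
    return HaplotypeNetwork(nodes=nodes, edges=msn, tie_edges=tie)


@dataclass
class TemporalLayers:
    """Per-period slices of a haplotype network.

    ``layers`` maps each period label to the haplotype counts present in
    that period; ``persistence`` maps each haplotype to the set of periods
    in which it was observed.
    """

    layers: list[tuple[str, dict[str, int]]]
    persistence: dict[str, set[str]]

    def to_tsv(self, path: str | Path) -> None:
        periods = [p for p, _ in self.layers]
        haps = sorted(self.persistence)
        df = pd.DataFrame(0, index=haps, columns=periods, dtype=int)
        for period, counts in self.layers:
            for hap, n in counts.items():
                df.loc[hap, period] = n
        df.to_csv(path, sep="\t", index_label="haplotype")


def temporal_layers(
    network: HaplotypeNetwork, table: HaplotypeTable
) -> TemporalLayers:
    """Decompose a network into one layer per temporal period."""
    unknown = set(table.labels) - set(network.nodes)
    if unknown:
        raise InputError(f"table haplotypes absent from network: {sorted(unknown)}")
    layers: list[tuple[str, dict[str, int]]] = []
    persistence: dict[str, set[str]] = {}
    for period in table.period_labels:
        col = table.column(period)
        present = {h: int(n) for h, n in col.items() if n > 0}
        layers.append((period, present))
        for h in present:
            persistence.setdefault(h, set()).add(period)
    for label, attrs in network.nodes.items():
        if label in table.labels:
            attrs["composition"] = {
                p: int(table.counts.loc[label, p]) for p in table.period_labels
            }
    return TemporalLayers(layers=layers, persistence=persistence)
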