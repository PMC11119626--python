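"""Pathway signal flow: propagate expression through signed pathway graphs.

Each pathway node receives a fold-change-like positive value derived from a
spot cluster's expression (the exponential of the mean centralized log
expression of the node's genes over the cluster's spots; unmatched nodes
are neutral at 1). Signals then flow from source to sink nodes in
topological order: a node's signal is its own value multiplied by the
combined input, where an activating edge contributes the parent's signal,
an inhibiting edge the reciprocal of the parent's signal, and multiple
inputs combine by their geometric mean. On a linear activation chain the
sink signal is therefore exactly the product of node values, and
all-neutral input yields all-neutral signals.

Cycles, when permitted, are condensed: each strongly connected component
collapses to one node valued at the geometric mean of its members (a
documented approximation); all members inherit the component's signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .types import DataError, ExpressionMatrix, PathwayGraph, SpotLabels


@dataclass
class PsfResult:
    cluster_label: str
    node_signals: dict[str, float] = field(default_factory=dict)
    sink_signals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for n, s in self.node_signals.items():
            if not (np.isfinite(s) and s > 0):
                raise DataError(f"node {n!r} has non-positive or non-finite signal {s}")


def node_values_from_cluster(
    matrix: ExpressionMatrix,
    labels: SpotLabels,
    cluster_label: str,
    pathway: PathwayGraph,
    node_genes: dict[str, list[str]] | None = None,
    base: float = 2.0,
) -> dict[str, float]:
    """Fold-change-like node values for one spot cluster.

    ``node_genes`` maps pathway nodes to gene ids (e.g. for process nodes or
    gene families); nodes not in the map fall back to their own identifier.
    ``base`` is the logarithm base of the preprocessing (default log2), used
    to undo the log scale.
    """
    if matrix.stage != "centralized":
        raise DataError(f"node values need centralized data, got stage {matrix.stage!r}")
    member_spots = [b for b in labels.barcodes_for(cluster_label) if b in set(matrix.spot_barcodes)]
    if not member_spots:
        raise DataError(f"cluster {cluster_label!r} has no spots in the matrix")
    col_idx = [matrix.spot_index(b) for b in member_spots]
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    values: dict[str, float] = {}
    for node in pathway.nodes:
        genes = (node_genes or {}).get(node, [node])
        rows = [gene_pos[g] for g in genes if g in gene_pos]
        if not rows:
            values[node] = 1.0
            continue
        mean_log = float(matrix.values[np.ix_(rows, col_idx)].mean())
        values[node] = float(base ** mean_log)
    return values


def _combined_input(signals: dict[str, float], parents: list[tuple[str, int]]) -> float:
    logs = [sign * np.log(signals[p]) for p, sign in parents]
    return float(np.exp(np.mean(logs)))


def propagate(
    pathway: PathwayGraph,
    node_values: dict[str, float],
    cluster_label: str = "",
    condense_cycles: bool = True,
) -> PsfResult:
    """Evaluate signals from sources to sinks in topological order."""
    g = pathway.graph
    missing = [n for n in g.nodes if n not in node_values]
    if missing:
        raise DataError(f"missing node values for {missing[:5]}")
    for n, v in node_values.items():
        if not (np.isfinite(v) and v > 0):
            raise DataError(f"node {n!r} has non-positive value {v}; PSF needs positive values")

    member_of: dict[str, int] = {}
    if nx.is_directed_acyclic_graph(g):
        dag = g
        value_of = {n: float(node_values[n]) for n in g.nodes}
    elif not condense_cycles:
        cycle = nx.find_cycle(g)
        raise DataError(f"pathway graph contains a cycle: {cycle}")
    else:
        cond = nx.condensation(g)  # nodes are SCC ids with 'members'
        dag = nx.DiGraph()
        value_of = {}
        for scc_id, data in cond.nodes(data=True):
            members = sorted(data["members"])
            for m in members:
                member_of[m] = scc_id
            value_of[scc_id] = float(
                np.exp(np.mean([np.log(node_values[m]) for m in members]))
            )
            dag.add_node(scc_id)
        for u, v, d in g.edges(data=True):
            cu, cv = member_of[u], member_of[v]
            if cu != cv:
                # keep the first sign seen for parallel condensed edges
                if not dag.has_edge(cu, cv):
                    dag.add_edge(cu, cv, sign=d["sign"])

    signals: dict = {}
    for node in nx.topological_sort(dag):
        parents = [(p, dag.edges[p, node]["sign"]) for p in dag.predecessors(node)]
        if not parents:
            signals[node] = value_of[node]
        else:
            signals[node] = value_of[node] * _combined_input(signals, parents)

    if member_of:
        node_signals = {n: signals[member_of[n]] for n in g.nodes}
    else:
        node_signals = {n: signals[n] for n in g.nodes}
    sink_signals = {s: node_signals[s] for s in pathway.sinks}
    return PsfResult(cluster_label=cluster_label, node_signals=node_signals,
                     sink_signals=sink_signals)


def cluster_psf(
    matrix: ExpressionMatrix,
    labels: SpotLabels,
    pathway: PathwayGraph,
    node_genes: dict[str, list[str]] | None = None,
    base: float = 2.0,
    clusters: list[str] | None = None,
) -> list[PsfResult]:
    """PSF for every (or selected) cluster label: values then propagation."""
    results = []
    for cl in clusters or labels.unique_labels:
        values = node_values_from_cluster(matrix, labels, cl, pathway, node_genes, base)
        results.append(propagate(pathway, values, cluster_label=cl))
    return results
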