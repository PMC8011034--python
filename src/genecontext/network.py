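"""Directed 5'->3' domain co-occurrence network around anchor genes.

Within each anchor window (half-width 3 by convention) genes are taken in
raw contig 5'->3' order; each gene is labeled by its domain families (or its
OG label when it has none), and consecutive labels yield directed edges.
Edge weight is the number of distinct genera in which the adjacency occurs.
Only nodes with at least one R-M-classified node in their immediate
neighborhood are retained.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .errors import ValidationError
from .model import (
    DomainHit,
    NeighborhoodWindow,
    OrthologGroupMap,
    RMReference,
    TaxonRecord,
)
from .neighborhood import gene_labels

logger = logging.getLogger(__name__)


def _labels_for_gene(gene, domains, ogmap, aliases, multi_domain) -> list[str] | None:
    labels = gene_labels(gene, domains, ogmap)
    if labels == ["na"]:
        return None  # no domain and no OG label: nothing to draw
    if multi_domain == "first":
        labels = labels[:1]
    if aliases:
        labels = [aliases.get(l, l) for l in labels]
    # a gene may carry several families; dedupe after aliasing
    out: list[str] = []
    for l in labels:
        if l not in out:
            out.append(l)
    return out


def build_network(
    windows: Iterable[NeighborhoodWindow],
    domains: Mapping[str, Sequence[DomainHit]],
    ogmap: Optional[OrthologGroupMap],
    rmref: RMReference,
    taxonomy: Mapping[str, TaxonRecord],
    aliases: Optional[Mapping[str, str]] = None,
    multi_domain: str = "all",
    bridge_gaps: bool = True,
    rm_filter: bool = True,
) -> nx.DiGraph:
    """Build the genus-weighted 5'->3' adjacency network over anchor windows.

    ``aliases`` relabels nodes (e.g. the anchor OG label to a role alias such
    as ``RR-like``). ``multi_domain`` "all" draws every family of a
    multi-domain gene (each connected to every label of the adjacent gene);
    "first" keeps only the N-terminal-most family. With ``bridge_gaps``
    label-less genes are skipped so adjacency bridges over them. Windows of
    genomes without a genus in ``taxonomy`` are skipped with a warning.
    ``rm_filter`` applies :func:`filter_rm_neighborhood` before returning.
    """
    if multi_domain not in ("all", "first"):
        raise ValidationError(f"unknown multi_domain mode {multi_domain!r}")
    g = nx.DiGraph()
    for w in windows:
        genome = w.anchor.genome_id
        taxon = taxonomy.get(genome)
        genus = taxon.genus if taxon else None
        if genus is None:
            logger.warning("genome %s lacks a genus; skipping its windows", genome)
            continue
        gene_seq = w.genes_in_contig_order(include_anchor=True)
        label_seq: list[list[str]] = []
        for gene in gene_seq:
            labels = _labels_for_gene(gene, domains, ogmap, aliases, multi_domain)
            if labels is None:
                if bridge_gaps:
                    continue
                labels = []
            label_seq.append(labels)
        for labels in label_seq:
            for l in labels:
                if l not in g:
                    g.add_node(l, rm_types=rmref.rm_types(l))
        for left, right in zip(label_seq, label_seq[1:]):
            for a in left:
                for b in right:
                    if g.has_edge(a, b):
                        g[a][b]["genera"].add(genus)
                    else:
                        g.add_edge(a, b, genera={genus})
    for _, _, attrs in g.edges(data=True):
        attrs["weight"] = len(attrs["genera"])
    return filter_rm_neighborhood(g, rmref) if rm_filter else g


def filter_rm_neighborhood(g: nx.DiGraph, rmref: RMReference) -> nx.DiGraph:
    """Retain nodes that are R-M-classified or adjacent to an R-M node.

    Idempotent: R-M nodes are always kept, so their neighbors keep their
    qualifying adjacency in the induced subgraph.
    """
    def is_rm(n) -> bool:
        return bool(g.nodes[n].get("rm_types")) or rmref.is_rm(n)

    keep = {
        n
        for n in g
        if is_rm(n)
        or any(is_rm(m) for m in set(g.predecessors(n)) | set(g.successors(n)))
    }
    sub = g.subgraph(keep).copy()
    for _, _, attrs in sub.edges(data=True):
        attrs["weight"] = len(attrs["genera"])
    return sub


def collapse_nonrm_neighbors(
    g: nx.DiGraph, hub_label: str, aggregate_label: Optional[str] = None
) -> nx.DiGraph:
    """Merge the hub's non-R-M leaf neighbors into one aggregate node.

    A leaf neighbor is a non-R-M node whose only connection (in either
    direction) is the hub. The aggregate node records ``merged_count`` and
    the merged labels; edge genera are unioned per direction.
    """
    if hub_label not in g:
        raise KeyError(f"hub {hub_label!r} not present in network")
    out = g.copy()
    neighbors = set(out.predecessors(hub_label)) | set(out.successors(hub_label))
    leaves = [
        n
        for n in sorted(neighbors)
        if not out.nodes[n].get("rm_types")
        and (set(out.predecessors(n)) | set(out.successors(n))) == {hub_label}
    ]
    if not leaves:
        return out
    agg = aggregate_label or f"non-RM neighbors of {hub_label} (n={len(leaves)})"
    out.add_node(agg, rm_types=frozenset(), merged_count=len(leaves), merged_labels=tuple(leaves))
    to_hub: set[str] = set()
    from_hub: set[str] = set()
    for n in leaves:
        if out.has_edge(n, hub_label):
            to_hub |= out[n][hub_label]["genera"]
        if out.has_edge(hub_label, n):
            from_hub |= out[hub_label][n]["genera"]
        out.remove_node(n)
    if to_hub:
        out.add_edge(agg, hub_label, genera=to_hub, weight=len(to_hub))
    if from_hub:
        out.add_edge(hub_label, agg, genera=from_hub, weight=len(from_hub))
    return out
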