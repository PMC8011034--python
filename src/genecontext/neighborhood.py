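"""Anchor-centered gene windows and co-localization statistics.

Distances are gene-rank distances on a single contig (the adjacent gene is
at distance 1), strand-agnostic. Upstream/downstream sides of a window are
oriented by the anchor's strand by default — "upstream" is a biological
statement — with a flag to keep raw contig order instead.
"""
from __future__ import annotations

import math
from collections import Counter
from typing import Callable, Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .model import (
    DomainHit,
    GeneRecord,
    LinkageResult,
    NeighborhoodWindow,
    OrthologGroupMap,
)

#: Label used for window genes with neither a domain hit nor an OG label.
NA_LABEL = "na"


class GeneIndex:
    """Lookup structure over a cohort's GeneRecords: per-contig ranked lists
    and a protein_id index."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self._contigs: dict[tuple[str, str], list[GeneRecord]] = {}
        self._by_protein: dict[str, GeneRecord] = {}
        for g in genes:
            self._contigs.setdefault((g.genome_id, g.contig_id), []).append(g)
            if g.protein_id is not None:
                self._by_protein[g.protein_id] = g
        for key, recs in self._contigs.items():
            recs.sort(key=lambda g: g.rank)
            ranks = [g.rank for g in recs]
            if ranks != list(range(len(recs))):
                raise ValidationError(
                    f"contig {key}: ranks are not consecutive 0..n-1"
                )

    def contig_genes(self, genome_id: str, contig_id: str) -> list[GeneRecord]:
        return self._contigs[(genome_id, contig_id)]

    def gene_of(self, protein_id: str) -> GeneRecord:
        try:
            return self._by_protein[protein_id]
        except KeyError:
            raise KeyError(f"protein {protein_id!r} not found in gene index") from None

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_protein

    def contigs(self) -> list[tuple[str, str]]:
        return sorted(self._contigs)


def extract_window(
    contig_genes: Sequence[GeneRecord],
    anchor: GeneRecord,
    k: int,
    orient_by_strand: bool = True,
) -> NeighborhoodWindow:
    """Extract the ordered +/-k gene window around ``anchor``.

    ``contig_genes`` must be the anchor's contig, ranked 0..n-1. Sides are
    nearest-first; for a minus-strand anchor (with ``orient_by_strand``)
    upstream/downstream are swapped relative to contig order. Genes beyond a
    contig end are omitted and the corresponding side flagged truncated.
    """
    if k < 0:
        raise ValidationError("window half-width k must be >= 0")
    r = anchor.rank
    if r >= len(contig_genes) or contig_genes[r] != anchor:
        raise KeyError(f"anchor {anchor.protein_id!r} not found at rank {r} of its contig")
    left = tuple(contig_genes[max(0, r - k): r][::-1])   # nearest first
    right = tuple(contig_genes[r + 1: r + 1 + k])
    trunc_left = len(left) < k
    trunc_right = len(right) < k
    flip = orient_by_strand and anchor.strand == "-"
    upstream, downstream = (right, left) if flip else (left, right)
    trunc_up, trunc_down = (trunc_right, trunc_left) if flip else (trunc_left, trunc_right)
    return NeighborhoodWindow(
        anchor=anchor,
        upstream=upstream,
        downstream=downstream,
        k=k,
        truncated_up=trunc_up,
        truncated_down=trunc_down,
    )


def windows_for_anchors(
    index: GeneIndex,
    anchors: Iterable[GeneRecord],
    k: int,
    orient_by_strand: bool = True,
) -> list[NeighborhoodWindow]:
    return [
        extract_window(
            index.contig_genes(a.genome_id, a.contig_id), a, k, orient_by_strand
        )
        for a in anchors
    ]


def resolve_anchors(
    index: GeneIndex,
    anchor_set: Iterable[str] | str,
    ogmap: Optional[OrthologGroupMap] = None,
) -> list[GeneRecord]:
    """Resolve an anchor specification (an OG label, or protein ids) to genes.

    Each paralog anchors its own region, so a genome with multiple members
    contributes multiple anchors.
    """
    if isinstance(anchor_set, str):
        if ogmap is None or anchor_set not in ogmap:
            raise ValidationError(f"anchor OG label {anchor_set!r} not in ortholog groups")
        ids: Iterable[str] = ogmap.members(anchor_set)
    else:
        ids = anchor_set
    anchors = [index.gene_of(pid) for pid in ids if pid in index]
    return sorted(anchors, key=lambda g: (g.genome_id, g.contig_id, g.rank))


def og_partner_predicate(
    ogmap: OrthologGroupMap, og_label: str
) -> Callable[[GeneRecord], bool]:
    """Predicate: gene's product belongs to ortholog group ``og_label``."""
    members = set(ogmap.members(og_label))
    return lambda g: g.protein_id in members


def domain_partner_predicate(
    domains: Mapping[str, Sequence[DomainHit]], families: Iterable[str]
) -> Callable[[GeneRecord], bool]:
    """Predicate: gene's product carries a hit from any of ``families``."""
    fams = set(families)
    return lambda g: g.protein_id is not None and any(
        h.domain_name in fams for h in domains.get(g.protein_id, ())
    )


def compute_linkage(
    index: GeneIndex,
    anchors: Sequence[GeneRecord],
    partner: Callable[[GeneRecord], bool],
    d: int,
    min_neighbors: int = 1,
) -> LinkageResult:
    """Fraction of anchor regions with >=1 partner within ``d`` gene ranks.

    A region counts as linked iff at least one gene at rank distance <= d on
    the anchor's contig satisfies the partner predicate. Regions with fewer
    than ``min_neighbors`` genes in the +/-d window are excluded (tallied in
    ``n_excluded``) — the analog of regions unsuitable because the assembly
    ends too close to the anchor.
    """
    anchors = list(anchors)
    if not anchors:
        raise ValidationError("empty anchor set")
    if d < 1:
        raise ValidationError("distance d must be >= 1")
    n_linked = n_regions = n_excluded = 0
    for a in anchors:
        w = extract_window(
            index.contig_genes(a.genome_id, a.contig_id), a, d, orient_by_strand=False
        )
        neigh = w.neighbors
        if len(neigh) < min_neighbors:
            n_excluded += 1
            continue
        n_regions += 1
        if any(partner(g) for g in neigh):
            n_linked += 1
    return LinkageResult(d=d, n_regions=n_regions, n_linked=n_linked, n_excluded=n_excluded)


def gene_labels(
    gene: GeneRecord,
    domains: Mapping[str, Sequence[DomainHit]],
    ogmap: Optional[OrthologGroupMap],
) -> list[str]:
    """Labels contributed by one gene: its distinct domain families (each
    once, in order of first appearance along the protein), else its OG label,
    else ``na``."""
    if gene.protein_id is not None:
        hits = sorted(
            domains.get(gene.protein_id, ()), key=lambda h: (h.env_start, h.env_end)
        )
        fams: list[str] = []
        for h in hits:
            if h.domain_name not in fams:
                fams.append(h.domain_name)
        if fams:
            return fams
        og = ogmap.og_of(gene.protein_id) if ogmap is not None else None
        if og is not None:
            return [og]
    return [NA_LABEL]


def tabulate_neighborhood_domains(
    windows: Iterable[NeighborhoodWindow],
    domains: Mapping[str, Sequence[DomainHit]],
    ogmap: Optional[OrthologGroupMap] = None,
    include_anchor: bool = False,
) -> Counter:
    """Count domain families encoded around anchors, summed over windows.

    Per window gene each distinct family on its product counts once; a gene
    without domain hits contributes its OG label; a gene with neither
    contributes ``na``.
    """
    counts: Counter = Counter()
    for w in windows:
        genes = w.genes_in_contig_order(include_anchor=include_anchor)
        for g in genes:
            counts.update(gene_labels(g, domains, ogmap))
    return counts


def top_fraction_domains(counts: Mapping[str, int], fraction: float) -> list[tuple[str, int]]:
    """The best-represented ceil(fraction * n_labels) labels.

    Ordered by count descending, then label ascending; ties at the cutoff are
    resolved by that same ordering.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must be in (0, 1]")
    if not counts:
        return []
    n = math.ceil(fraction * len(counts))
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ordered[:n]


def counts_frame(counts: Mapping[str, int]) -> pd.DataFrame:
    """Tabular report: label, count, rank (1 = most frequent)."""
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [
            {"label": label, "count": cnt, "rank": i}
            for i, (label, cnt) in enumerate(ordered, start=1)
        ],
        columns=["label", "count", "rank"],
    )


def linkage_sweep(
    index: GeneIndex,
    anchors: Sequence[GeneRecord],
    partner: Callable[[GeneRecord], bool],
    d_max: int,
    min_neighbors: int = 1,
) -> pd.DataFrame:
    """LinkageResult rows for d = 1..d_max (linkage is monotone in d)."""
    rows = []
    for d in range(1, d_max + 1):
        r = compute_linkage(index, anchors, partner, d, min_neighbors)
        rows.append(
            {
                "d": r.d,
                "n_regions": r.n_regions,
                "n_linked": r.n_linked,
                "linkage": r.linkage,
                "n_excluded": r.n_excluded,
            }
        )
    return pd.DataFrame(rows, columns=["d", "n_regions", "n_linked", "linkage", "n_excluded"])
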