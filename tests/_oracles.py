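"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: naive double loops over
gene lists, so that agreement with the fast paths is meaningful.
"""
from collections import Counter


def brute_linkage(genes, anchors, partner_ids, d, min_neighbors=1):
    """All-pairs distance scan: (n_regions, n_linked, n_excluded)."""
    n_regions = n_linked = n_excluded = 0
    for a in anchors:
        neighbors = [
            g
            for g in genes
            if g.genome_id == a.genome_id
            and g.contig_id == a.contig_id
            and g is not a
            and abs(g.rank - a.rank) <= d
        ]
        if len(neighbors) < min_neighbors:
            n_excluded += 1
            continue
        n_regions += 1
        if any(g.protein_id in partner_ids for g in neighbors):
            n_linked += 1
    return n_regions, n_linked, n_excluded


def brute_tabulate(genes, anchors, k, domains, og_of):
    """Naive double-loop recount of window domain labels."""
    counts = Counter()
    for a in anchors:
        for g in genes:
            if g.genome_id != a.genome_id or g.contig_id != a.contig_id:
                continue
            if g is a or abs(g.rank - a.rank) > k:
                continue
            fams = []
            for h in sorted(domains.get(g.protein_id, []) if g.protein_id else [],
                            key=lambda h: (h.env_start, h.env_end)):
                if h.domain_name not in fams:
                    fams.append(h.domain_name)
            if fams:
                counts.update(fams)
            elif g.protein_id and og_of(g.protein_id):
                counts[og_of(g.protein_id)] += 1
            else:
                counts["na"] += 1
    return counts


def brute_rm_count(genes, anchors, k, domains, rm_families, mode):
    """Naive windowed R-M count over all anchor windows."""
    total = 0
    for a in anchors:
        for g in genes:
            if g.genome_id != a.genome_id or g.contig_id != a.contig_id:
                continue
            if g is a or abs(g.rank - a.rank) > k:
                continue
            fams = {
                h.domain_name
                for h in (domains.get(g.protein_id, []) if g.protein_id else [])
                if h.domain_name in rm_families
            }
            total += len(fams) if mode == "families_per_gene" else int(bool(fams))
    return total


def brute_edge_weights(windows, domains, og_of, genus_of, aliases=None):
    """Exhaustive adjacency enumeration: {(src, tgt): set of genera}.

    Mirrors the documented rules: per-window genes in contig order (anchor
    included), each gene labeled by its distinct families in order of first
    appearance else its OG label, label-less genes bridged over, all-pairs
    edges between consecutive genes' label lists.
    """
    aliases = aliases or {}
    edges = {}
    for w in windows:
        genus = genus_of(w.anchor.genome_id)
        if genus is None:
            continue
        ordered = sorted(list(w.upstream) + [w.anchor] + list(w.downstream),
                         key=lambda g: g.rank)
        labelled = []
        for g in ordered:
            fams = []
            for h in sorted(domains.get(g.protein_id, []) if g.protein_id else [],
                            key=lambda h: (h.env_start, h.env_end)):
                if h.domain_name not in fams:
                    fams.append(h.domain_name)
            if not fams and g.protein_id and og_of(g.protein_id):
                fams = [og_of(g.protein_id)]
            fams = [aliases.get(f, f) for f in fams]
            dedup = []
            for f in fams:
                if f not in dedup:
                    dedup.append(f)
            if dedup:
                labelled.append(dedup)
        for left, right in zip(labelled, labelled[1:]):
            for a in left:
                for b in right:
                    edges.setdefault((a, b), set()).add(genus)
    return edges
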