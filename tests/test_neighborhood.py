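import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from genecontext import (
    CohortSpec,
    GeneIndex,
    GeneRecord,
    OrthologGroupMap,
    ValidationError,
    compute_linkage,
    extract_window,
    generate_cohort,
    og_partner_predicate,
    resolve_anchors,
    tabulate_neighborhood_domains,
    top_fraction_domains,
    windows_for_anchors,
)
from _oracles import brute_linkage, brute_tabulate
from conftest import make_contig, hit


class TestExtractWindow:
    def test_lone_anchor_has_empty_truncated_sides(self):
        contig = make_contig(1)
        w = extract_window(contig, contig[0], k=10)
        assert w.upstream == () and w.downstream == ()
        assert w.truncated_up and w.truncated_down

    def test_k_zero_is_empty_without_truncation(self):
        contig = make_contig(5)
        w = extract_window(contig, contig[2], k=0)
        assert w.neighbors == ()
        assert not w.truncated_up and not w.truncated_down

    def test_full_window_matches_list_slicing(self):
        contig = make_contig(21)
        w = extract_window(contig, contig[10], k=10)
        assert list(w.upstream) == contig[0:10][::-1]   # nearest first
        assert list(w.downstream) == contig[11:21]
        assert not w.truncated_up and not w.truncated_down

    def test_minus_strand_anchor_swaps_sides(self):
        contig = make_contig(5, strands=["+", "+", "-", "+", "+"])
        w = extract_window(contig, contig[2], k=2)
        # biological upstream of a minus-strand gene lies at higher ranks
        assert [g.rank for g in w.upstream] == [3, 4]
        assert [g.rank for g in w.downstream] == [1, 0]
        raw = extract_window(contig, contig[2], k=2, orient_by_strand=False)
        assert [g.rank for g in raw.upstream] == [1, 0]

    @given(n=st.integers(1, 30), anchor=st.integers(0, 29), k=st.integers(0, 12))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_window_bounds_and_anchor_exclusion(self, n, anchor, k):
        anchor = anchor % n
        contig = make_contig(n)
        w = extract_window(contig, contig[anchor], k)
        assert len(w.neighbors) <= 2 * k
        assert contig[anchor] not in w.neighbors
        assert len(w.upstream) <= k and len(w.downstream) <= k
        assert all(g.contig_id == contig[anchor].contig_id for g in w.neighbors)


def flip_cohort(genes):
    """Reverse every contig's gene order and flip every strand."""
    by_contig = {}
    for g in genes:
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)
    flipped = []
    for recs in by_contig.values():
        n = len(recs)
        for g in recs:
            flipped.append(
                GeneRecord(
                    genome_id=g.genome_id,
                    contig_id=g.contig_id,
                    rank=n - 1 - g.rank,
                    start=1 + 1000 * (n - 1 - g.rank),
                    end=900 + 1000 * (n - 1 - g.rank),
                    strand="-" if g.strand == "+" else "+",
                    protein_id=g.protein_id,
                )
            )
    return flipped


class TestLinkage:
    def test_every_anchor_with_adjacent_partner_gives_one(self):
        genes = make_contig(10)
        idx = GeneIndex(genes)
        anchors = [genes[3], genes[7]]
        partners = {genes[4].protein_id, genes[6].protein_id}
        r = compute_linkage(idx, anchors, lambda g: g.protein_id in partners, d=1)
        assert r.linkage == 1.0 and r.n_regions == 2

    def test_no_partners_gives_zero(self):
        genes = make_contig(10)
        idx = GeneIndex(genes)
        r = compute_linkage(idx, [genes[5]], lambda g: False, d=3)
        assert r.linkage == 0.0 and r.n_linked == 0

    def test_empty_anchor_set_rejected(self):
        idx = GeneIndex(make_contig(5))
        with pytest.raises(ValidationError, match="empty anchor"):
            compute_linkage(idx, [], lambda g: True, d=3)

    def test_min_neighbors_excludes_short_regions(self):
        genes = make_contig(1)  # anchor alone on its contig
        idx = GeneIndex(genes)
        r = compute_linkage(idx, [genes[0]], lambda g: True, d=3, min_neighbors=1)
        assert r.n_excluded == 1 and r.n_regions == 0

    def test_planted_linkage_recovers_rate_and_truth(self):
        spec = CohortSpec(n_genomes=500, genes_per_contig=40, p_link=0.9,
                          paralog_prob=0.0, seed=42)
        cohort, truth = generate_cohort(spec)
        idx = GeneIndex(cohort.genes)
        anchors = resolve_anchors(idx, "OG_A", cohort.ogmap)
        assert len(anchors) == 500
        r = compute_linkage(idx, anchors,
                            og_partner_predicate(cohort.ogmap, "OG_B"), d=3)
        # exactly the generator's bookkeeping ...
        assert r.linkage == pytest.approx(truth.realized_linkage(3))
        # ... and within 3 binomial SEs of the planted rate
        se = math.sqrt(0.9 * 0.1 / 500)
        assert abs(r.linkage - 0.9) <= 3 * se

    def test_monotone_in_d(self, small_cohort):
        cohort, _ = small_cohort
        idx = GeneIndex(cohort.genes)
        anchors = resolve_anchors(idx, "OG_A", cohort.ogmap)
        partner = og_partner_predicate(cohort.ogmap, "OG_B")
        vals = [compute_linkage(idx, anchors, partner, d).linkage for d in range(1, 8)]
        assert vals == sorted(vals)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_scan_on_small_cohorts(self, seed):
        spec = CohortSpec(n_genomes=1, genes_per_contig=25 + seed, p_link=0.7,
                          rm_window=5, link_d=3, seed=seed)
        cohort, _ = generate_cohort(spec)
        idx = GeneIndex(cohort.genes)
        anchors = resolve_anchors(idx, "OG_A", cohort.ogmap)
        partner_ids = set(cohort.ogmap.members("OG_B")) if "OG_B" in cohort.ogmap else set()
        for d in (1, 2, 3, 5):
            r = compute_linkage(idx, anchors, lambda g: g.protein_id in partner_ids, d)
            assert (r.n_regions, r.n_linked, r.n_excluded) == brute_linkage(
                cohort.genes, anchors, partner_ids, d
            )

    def test_strand_and_order_flip_invariance(self, small_cohort):
        cohort, _ = small_cohort
        flipped = flip_cohort(cohort.genes)
        partner = og_partner_predicate(cohort.ogmap, "OG_B")
        for genes in (cohort.genes, flipped):
            idx = GeneIndex(genes)
            anchors = resolve_anchors(idx, "OG_A", cohort.ogmap)
            res = compute_linkage(idx, anchors, partner, d=3)
            counts = tabulate_neighborhood_domains(
                windows_for_anchors(idx, anchors, 10), cohort.domains, cohort.ogmap
            )
            if genes is cohort.genes:
                base = (res, counts)
        assert res.n_linked == base[0].n_linked and res.n_regions == base[0].n_regions
        assert counts == base[1]


class TestTabulate:
    def test_domain_og_and_na_rules(self):
        genes = make_contig(4)
        idx = GeneIndex(genes)
        domains = {
            genes[0].protein_id: [hit(genes[0].protein_id, "A")],
            genes[2].protein_id: [hit(genes[2].protein_id, "A", env=(5, 60)),
                                  hit(genes[2].protein_id, "B", env=(80, 150))],
        }
        og = OrthologGroupMap({"OG_7": [genes[3].protein_id, "other"]})
        w = extract_window(genes, genes[1], k=3)
        counts = tabulate_neighborhood_domains([w], domains, og)
        assert counts == Counter({"A": 2, "B": 1, "OG_7": 1})

    def test_repeated_family_counts_once_per_gene(self):
        genes = make_contig(2)
        pid = genes[1].protein_id
        domains = {pid: [hit(pid, "A", env=(5, 60)), hit(pid, "A", env=(100, 160))]}
        w = extract_window(genes, genes[0], k=1)
        counts = tabulate_neighborhood_domains([w], domains, None)
        assert counts == Counter({"A": 1})

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_double_loop_recount(self, seed):
        spec = CohortSpec(n_genomes=2, genes_per_contig=40, seed=100 + seed)
        cohort, _ = generate_cohort(spec)
        idx = GeneIndex(cohort.genes)
        anchors = resolve_anchors(idx, "OG_A", cohort.ogmap)
        windows = windows_for_anchors(idx, anchors, 10)
        counts = tabulate_neighborhood_domains(windows, cohort.domains, cohort.ogmap)
        assert counts == brute_tabulate(
            cohort.genes, anchors, 10, cohort.domains, cohort.ogmap.og_of
        )


class TestTopFraction:
    def test_all_tied_picks_lexicographically_smallest(self):
        counts = {f"lab{i:03d}": 1 for i in range(100)}
        assert top_fraction_domains(counts, 0.01) == [("lab000", 1)]

    def test_fraction_one_returns_everything(self):
        counts = {"a": 3, "b": 1, "c": 2}
        top = top_fraction_domains(counts, 1.0)
        assert top == [("a", 3), ("c", 2), ("b", 1)]

    def test_ceiling_arithmetic(self):
        counts = {f"l{i}": i for i in range(250)}
        assert len(top_fraction_domains(counts, 0.01)) == 3  # ceil(2.5)

    def test_empty_counts_give_empty_subset(self):
        assert top_fraction_domains({}, 0.5) == []
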