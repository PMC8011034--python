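import random

import pytest

from genecontext import (
    ArchitectureCall,
    TaxonRecord,
    ValidationError,
    classify_all,
    classify_architecture,
    collapse_redundant,
    filter_bona_fide,
    make_architecture_fixtures,
    phyletic_distribution,
    summarize_architectures,
)
from genecontext.architecture import ProteinMeta, merge_overlapping_hits
from conftest import hit


def focal(pid, evalue=1e-20, env=(200, 260)):
    return hit(pid, "HEF_HK", evalue=evalue, env=env, plen=450)


class TestBonaFide:
    def test_threshold_is_strict(self):
        hits = [focal("keep", 1e-07), focal("drop", 1e-04), focal("edge", 1e-05)]
        assert filter_bona_fide(hits) == {"keep"}

    def test_best_hit_decides(self):
        hits = [focal("p", 1e-03), focal("p", 1e-09)]
        assert filter_bona_fide(hits) == {"p"}


class TestClassify:
    def test_full_sandwich_is_group_one(self):
        hits = [
            hit("p", "HATPase_c_3", env=(5, 160), plen=450),
            focal("p"),
            hit("p", "HATPase_c", env=(300, 420), plen=450),
        ]
        call = classify_architecture(hits)
        assert call.group == 1
        assert call.has_nterm_hatpase_c3 and call.has_cterm_hatpase_c

    def test_focal_only_is_group_four(self):
        call = classify_architecture([focal("p")])
        assert call.group == 4 and call.extra_domains == ()

    def test_midpoint_inside_focal_does_not_set_flag(self):
        # companion envelope overlaps the focal hit, midpoint not N-terminal
        hits = [hit("p", "HATPase_c_3", env=(180, 260), plen=450),
                focal("p", env=(170, 280))]
        call = classify_architecture(hits)
        assert not call.has_nterm_hatpase_c3 and call.group == 4

    def test_companion_over_threshold_ignored(self):
        hits = [hit("p", "HATPase_c", evalue=1e-4, env=(300, 420)), focal("p")]
        assert classify_architecture(hits).group == 4

    def test_extra_domains_do_not_change_group(self):
        hits = [focal("p"), hit("p", "HNH_2", env=(300, 380))]
        call = classify_architecture(hits)
        assert call.group == 4 and call.extra_domains == ("HNH_2",)

    def test_hit_order_invariance(self):
        hits = [
            hit("p", "HATPase_c_3", env=(5, 160), plen=450),
            focal("p"),
            hit("p", "HATPase_c", env=(300, 420), plen=450),
            hit("p", "HNH_2", env=(430, 445), plen=450),
        ]
        calls = set()
        rng = random.Random(0)
        for _ in range(10):
            rng.shuffle(hits)
            calls.add(classify_architecture(list(hits)))
        assert len(calls) == 1

    def test_overlapping_same_family_merged_to_best(self):
        hits = [hit("p", "HEF_HK", evalue=1e-12, env=(195, 255)),
                hit("p", "HEF_HK", evalue=1e-22, env=(200, 260))]
        merged = merge_overlapping_hits(hits)
        assert len(merged) == 1 and merged[0].evalue == 1e-22
        # disjoint hits of one family stay separate
        apart = merge_overlapping_hits(
            [hit("p", "X", env=(5, 60)), hit("p", "X", env=(100, 160))])
        assert len(apart) == 2

    def test_no_bona_fide_focal_raises(self):
        with pytest.raises(ValidationError, match="no bona fide"):
            classify_architecture([focal("p", evalue=1e-4)])


class TestCollapseRedundant:
    def meta(self, pid, species, ev=1e-20, length=400, genome=None):
        return ProteinMeta(protein_id=pid, species=species, focal_evalue=ev,
                           length=length, genome_id=genome)

    def test_three_strains_one_species_keep_one(self):
        metas = [self.meta(f"p{i}", "Pectobacterium brasiliense", ev=10.0 ** -(20 + i))
                 for i in range(3)]
        assert collapse_redundant(metas) == {"p2"}  # best e-value

    def test_evalue_tie_broken_by_length_then_id(self):
        metas = [self.meta("pA", "sp1", length=300), self.meta("pB", "sp1", length=420)]
        assert collapse_redundant(metas) == {"pB"}
        metas = [self.meta("pB", "sp1"), self.meta("pA", "sp1")]
        assert collapse_redundant(metas) == {"pA"}

    def test_missing_species_buckets_by_genome(self):
        metas = [self.meta("p1", None, genome="gX"), self.meta("p2", None, genome="gY"),
                 self.meta("p3", None, genome="gX", ev=1e-30)]
        assert collapse_redundant(metas) == {"p2", "p3"}

    def test_idempotent_and_never_grows(self):
        metas = [self.meta(f"p{i}", f"sp{i % 4}", ev=10.0 ** -(10 + i))
                 for i in range(12)]
        once = collapse_redundant(metas)
        twice = collapse_redundant([m for m in metas if m.protein_id in once])
        assert twice == once and len(once) <= len(metas)


class TestSummaries:
    def make_calls(self, counts):
        flags = {1: (True, True), 2: (False, True), 3: (True, False), 4: (False, False)}
        calls = []
        for group, n in counts.items():
            for i in range(n):
                calls.append(ArchitectureCall(
                    protein_id=f"g{group}_{i}", group=group,
                    has_nterm_hatpase_c3=flags[group][0],
                    has_cterm_hatpase_c=flags[group][1],
                    focal_evalue=1e-20, length=400))
        return calls

    def test_companion_shares(self):
        s = summarize_architectures(self.make_calls({1: 174, 2: 34, 3: 11, 4: 3}))
        assert s.total == 222
        assert s.nterm_percent == 83.3 and s.cterm_percent == 93.7

    def test_all_group_four(self):
        s = summarize_architectures(self.make_calls({4: 5}))
        assert s.nterm_percent == 0.0 and s.cterm_percent == 0.0

    def test_shares_partition_total(self):
        rng = random.Random(1)
        counts = {g: rng.randint(0, 50) for g in (1, 2, 3, 4)}
        counts[1] += 1  # non-empty
        s = summarize_architectures(self.make_calls(counts))
        assert (s.count(1) + s.count(3)) + (s.count(2) + s.count(4)) == s.total
        assert (s.count(1) + s.count(2)) + (s.count(3) + s.count(4)) == s.total
        # shares recomputed from a direct flag census
        calls = self.make_calls(counts)
        n_share = sum(c.has_nterm_hatpase_c3 for c in calls) / len(calls)
        c_share = sum(c.has_cterm_hatpase_c for c in calls) / len(calls)
        assert s.nterm_share == pytest.approx(n_share)
        assert s.cterm_share == pytest.approx(c_share)

    def test_phyletic_single_phylum_row_equals_group_counts(self):
        calls = [
            ArchitectureCall(protein_id=f"p{i}", group=g,
                             has_nterm_hatpase_c3=(g in (1, 3)),
                             has_cterm_hatpase_c=(g in (1, 2)),
                             focal_evalue=1e-20, length=400, genome_id=f"g{i}")
            for i, g in enumerate([1, 1, 2, 3])
        ]
        taxa = {f"g{i}": TaxonRecord(genome_id=f"g{i}", phylum="Proteobacteria")
                for i in range(4)}
        table = phyletic_distribution(calls, taxa, "phylum")
        assert table.loc["Proteobacteria", 1] == 2
        assert table.loc["All", "All"] == 4

    def test_phyletic_margins_and_unclassified(self):
        calls = [
            ArchitectureCall(protein_id=f"p{i}", group=4,
                             has_nterm_hatpase_c3=False, has_cterm_hatpase_c=False,
                             focal_evalue=1e-20, length=100, genome_id=g)
            for i, g in enumerate(["gA", "gB", None])
        ]
        taxa = {"gA": TaxonRecord(genome_id="gA", phylum="Firmicutes")}
        table = phyletic_distribution(calls, taxa, "phylum")
        assert table.loc["All", "All"] == len(calls)
        assert table.loc["unclassified", 4] == 2


class TestFixtures:
    def test_requested_group_counts_are_recovered(self):
        hits, expected = make_architecture_fixtures({1: 20, 2: 6, 3: 4, 4: 2}, seed=5)
        calls = classify_all(hits)
        got = {g: sum(1 for c in calls.values() if c.group == g) for g in (1, 2, 3, 4)}
        assert got == {1: 20, 2: 6, 3: 4, 4: 2}
        for pid, call in calls.items():
            assert call.group == expected[pid]

    def test_boundary_cases_follow_documented_rules(self):
        hits, expected = make_architecture_fixtures({}, seed=1, boundary_cases=True)
        calls = classify_all(hits)
        for pid, exp in expected.items():
            if exp is None:
                assert pid not in calls  # sub-threshold focal hit excluded
            else:
                assert calls[pid].group == exp

    def test_shuffled_hit_order_gives_identical_calls(self):
        hits, _ = make_architecture_fixtures({1: 5, 2: 3}, seed=2)
        calls = classify_all(hits)
        rng = random.Random(3)
        shuffled = {}
        for pid, phits in hits.items():
            phits = list(phits)
            rng.shuffle(phits)
            shuffled[pid] = phits
        assert classify_all(shuffled) == calls

    def test_written_fixture_round_trips_through_domtblout(self, tmp_path):
        from genecontext import io as gcio

        hits, expected = make_architecture_fixtures({1: 3, 4: 2}, seed=7,
                                                    outdir=tmp_path)
        back = gcio.read_domtblout(tmp_path / "architectures.domtblout")
        by_protein = {}
        for h in back:
            by_protein.setdefault(h.protein_id, []).append(h)
        calls = classify_all(by_protein)
        assert {pid: c.group for pid, c in calls.items()} == {
            pid: g for pid, g in expected.items() if g is not None
        }
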