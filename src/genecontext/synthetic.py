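"""Synthetic annotated genome cohorts with planted statistical structure.

The generator emulates the cohorts the pipeline is built for: ordered genes
on contigs, anchor genes (RR-like, grouped as ``OG_A``) whose partners
(GHKL-carrying, ``OG_B``) are planted within a configurable gene distance at
a configurable linkage rate, R-M-domain genes planted at an elevated rate
near anchors versus background, and a small taxonomy. It emits exactly the
file formats the readers consume, plus a machine-readable truth record, so
every pipeline stage is testable without downloads. No nucleotide or amino
acid sequences are generated — only ordering matters to the statistics.

Coordinates are synthesized as non-overlapping fixed-width intervals (width
900, spacing 1000) since only gene order enters any statistic; strands are
sampled uniformly.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import io as gcio
from .errors import ValidationError
from .model import Cohort, DomainHit, GeneRecord, OrthologGroupMap, RMReference, TaxonRecord

ANCHOR_OG = "OG_A"
PARTNER_OG = "OG_B"

#: R-M families planted by the generator, with REBASE-style type assignments
#: (families assigned to more than one type are the "multi" cases).
DEFAULT_RM_TYPES: dict[str, tuple[str, ...]] = {
    "Vsr": ("V-gene",),
    "HNH_2": ("II",),
    "MvaI_BcnI": ("II",),
    "EcoRII-C": ("II",),
    "ParBc": ("II",),
    "HSDR": ("I",),
    "ResIII": ("I", "III"),
    "DNA_methylase": ("II",),
    "N6_N4_Mtase": ("I", "II", "III"),
}

#: Background (non-R-M) families sprinkled over the cohort.
DEFAULT_BG_FAMILIES = (
    "HATPase_c",
    "HATPase_c_3",
    "HiskA",
    "Response_reg",
    "CdiI_3",
    "Ntox28",
    "ABC_tran",
    "Helicase_C",
    "GntR",
    "LysR_substr_bind",
)

DEFAULT_TAXONOMY_SPEC: dict = {
    "Proteobacteria": {
        "Gammaproteobacteria": {
            "Enterobacterales": {
                "Pectobacteriaceae": ["Pectobacterium", "Dickeya"],
                "Yersiniaceae": ["Yersinia", "Serratia"],
            },
            "Pseudomonadales": {"Moraxellaceae": ["Acinetobacter"]},
        },
        "Alphaproteobacteria": {
            "Rhizobiales": {"Rhizobiaceae": ["Rhizobium", "Agrobacterium"]},
            "Rhodobacterales": {"Rhodobacteraceae": ["Rhodovulum"]},
        },
    },
    "Bacteroidetes": {
        "Flavobacteriia": {
            "Flavobacteriales": {"Flavobacteriaceae": ["Flavobacterium", "Chryseobacterium"]}
        },
        "Bacteroidia": {"Bacteroidales": {"Bacteroidaceae": ["Bacteroides"]}},
    },
}


def default_rm_reference() -> RMReference:
    return RMReference(DEFAULT_RM_TYPES)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the cohort structure the statistics were designed for:
    25 genomes (the permutation-test cohort size), one 400-gene contig per
    genome (a scaled-down bacterial chromosome), one anchor per genome with
    occasional 2-3 paralogs, partners planted within 3 genes at rate 0.916,
    and R-M families planted at 0.25 per locus within 10 genes of an anchor
    against a 0.10 background — rates that reproduce realistic windowed R-M
    counts (typically 5-7 near anchors, 2-3 expected by chance).
    """

    n_genomes: int = 25
    contigs_per_genome: int = 1
    genes_per_contig: int = 400
    anchor_prob: float = 1.0
    paralog_prob: float = 0.048  # chance an anchored genome carries 2-3 paralogs
    p_link: float = 0.916
    link_d: int = 3
    lambda_near: float = 0.25
    lambda_bg: float = 0.10
    rm_window: int = 10
    noncoding_prob: float = 0.02
    bg_domain_prob: float = 0.40
    og_prob: float = 0.30
    n_bg_ogs: int = 30
    rm_types: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_RM_TYPES)
    )
    bg_families: Sequence[str] = DEFAULT_BG_FAMILIES
    taxonomy_spec: Mapping = field(default_factory=lambda: DEFAULT_TAXONOMY_SPEC)
    seed: int = 0

    def __post_init__(self):
        for name in ("anchor_prob", "paralog_prob", "p_link", "noncoding_prob",
                     "bg_domain_prob", "og_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.lambda_near < 0 or self.lambda_bg < 0:
            raise ValidationError("lambda_near and lambda_bg must be >= 0")
        if not (0 <= self.lambda_near <= 1 and 0 <= self.lambda_bg <= 1):
            raise ValidationError("per-locus R-M probabilities must be in [0, 1]")
        if self.link_d < 1:
            raise ValidationError("link_d must be >= 1")
        if self.link_d >= self.genes_per_contig:
            raise ValidationError("partner distance exceeds contig length")
        if self.genes_per_contig < 2 * self.rm_window + 1:
            raise ValidationError("contig too short for the R-M window")


@dataclass
class PartnerTruth:
    anchor_protein_id: str
    protein_id: str
    distance: int


@dataclass
class RMLocusTruth:
    protein_id: str
    family: str
    provenance: str  # "near" or "background"


@dataclass
class GenomeTruth:
    anchors: list[str]
    anchor_loci: dict[str, list]  # protein_id -> [contig_id, rank]
    partners: list[PartnerTruth]
    rm_loci: list[RMLocusTruth]
    linked: dict[str, bool]  # anchor protein_id -> partner planted within link_d


@dataclass
class TruthRecord:
    """Planting bookkeeping for a generated cohort."""

    genomes: dict[str, GenomeTruth]

    def n_anchors(self) -> int:
        return sum(len(g.anchors) for g in self.genomes.values())

    def realized_linkage(self, d: Optional[int] = None) -> float:
        """Fraction of planted anchors with a partner within ``d`` genes
        (all planted partners when ``d`` is None)."""
        linked = total = 0
        for g in self.genomes.values():
            dist = {p.anchor_protein_id: p.distance for p in g.partners}
            for a in g.anchors:
                total += 1
                if a in dist and (d is None or dist[a] <= d):
                    linked += 1
        return linked / total if total else 0.0

    def to_json(self) -> dict:
        return {
            "genomes": {
                gid: {
                    "anchors": g.anchors,
                    "anchor_loci": g.anchor_loci,
                    "partners": [asdict(p) for p in g.partners],
                    "rm_loci": [asdict(r) for r in g.rm_loci],
                    "linked": g.linked,
                }
                for gid, g in self.genomes.items()
            }
        }

    @classmethod
    def from_json(cls, data: dict) -> "TruthRecord":
        genomes = {}
        for gid, g in data["genomes"].items():
            genomes[gid] = GenomeTruth(
                anchors=list(g["anchors"]),
                anchor_loci={k: list(v) for k, v in g["anchor_loci"].items()},
                partners=[PartnerTruth(**p) for p in g["partners"]],
                rm_loci=[RMLocusTruth(**r) for r in g["rm_loci"]],
                linked=dict(g["linked"]),
            )
        return cls(genomes=genomes)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "TruthRecord":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _pick_lineages(spec: CohortSpec):
    lineages = []
    for phylum, classes in spec.taxonomy_spec.items():
        for class_, orders in classes.items():
            for order, families in orders.items():
                for family, genera in families.items():
                    for genus in genera:
                        lineages.append((phylum, class_, order, family, genus))
    return lineages


def _place_anchors(rng, spec: CohortSpec, n: int, count: int) -> list[int]:
    """Anchor ranks with full R-M windows, spaced so windows never overlap."""
    spacing = 2 * spec.rm_window + 1
    eligible = list(range(spec.rm_window, n - spec.rm_window))
    for _ in range(20):  # greedy random placement can dead-end; retry
        rng.shuffle(eligible)
        chosen: list[int] = []
        for r in eligible:
            if all(abs(r - c) >= spacing for c in chosen):
                chosen.append(r)
            if len(chosen) == count:
                return sorted(chosen)
    fallback = list(range(spec.rm_window, n - spec.rm_window, spacing))[:count]
    if len(fallback) == count:
        return fallback
    raise ValidationError(
        f"cannot place {count} non-overlapping anchor windows on a {n}-gene contig"
    )


def plant_rm_clusters(
    genome_loci: Sequence[GeneRecord],
    anchor_ranks: Mapping[str, Sequence[int]],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, str], dict[str, str]]:
    """Assign R-M families to a genome's loci with near-anchor elevation.

    Every coding, non-anchor locus within ``rm_window`` gene ranks of an
    anchor (same contig) carries an R-M family with probability
    ``lambda_near``; all other coding loci with ``lambda_bg``. Returns
    (protein_id -> family, protein_id -> "near"/"background").
    """
    rm_families = sorted(spec.rm_types)
    anchor_set = {
        (contig, r) for contig, ranks in anchor_ranks.items() for r in ranks
    }
    families: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for g in genome_loci:
        if g.protein_id is None or (g.contig_id, g.rank) in anchor_set:
            continue
        near = any(
            abs(g.rank - r) <= spec.rm_window
            for r in anchor_ranks.get(g.contig_id, ())
        )
        lam = spec.lambda_near if near else spec.lambda_bg
        if rng.random() < lam:
            fam = rm_families[rng.integers(len(rm_families))]
            families[g.protein_id] = fam
            provenance[g.protein_id] = "near" if near else "background"
    return families, provenance


def _domain_hits_for(pid: str, fams: Sequence[str], rng) -> list[DomainHit]:
    hits = []
    for i, fam in enumerate(fams):
        start = 5 + 150 * i
        end = start + 115
        hits.append(
            DomainHit(
                protein_id=pid,
                domain_name=fam,
                evalue=float(10.0 ** rng.uniform(-30, -8)),
                env_start=start,
                env_end=end,
                protein_len=150 * len(fams) + 30,
            )
        )
    return hits


def generate_cohort(
    spec: CohortSpec, outdir=None, write_gff3: bool = False
) -> tuple[Cohort, TruthRecord]:
    """Generate a cohort per ``spec``; all randomness flows from ``spec.seed``.

    When ``outdir`` is given, emits ``genes.tsv`` (plus per-genome GFF3 when
    requested), ``domains.domtblout``, ``groups.txt``, ``taxonomy.tsv``,
    ``rm_reference.tsv`` and ``truth.json``.
    """
    rng = np.random.default_rng(spec.seed)
    lineages = _pick_lineages(spec)
    rmref = RMReference(spec.rm_types)

    genes: list[GeneRecord] = []
    domains: dict[str, list[DomainHit]] = {}
    og_members: dict[str, list[str]] = {ANCHOR_OG: [], PARTNER_OG: []}
    taxonomy: dict[str, TaxonRecord] = {}
    truth_genomes: dict[str, GenomeTruth] = {}

    for gi in range(spec.n_genomes):
        gid = f"g{gi + 1:03d}"
        lineage = lineages[rng.integers(len(lineages))]
        phylum, class_, order, family, genus = lineage
        species = f"{genus} sp{int(rng.integers(1, max(2, spec.n_genomes // 2 + 1)))}"
        taxonomy[gid] = TaxonRecord(
            genome_id=gid, phylum=phylum, class_=class_, order=order,
            family=family, genus=genus, species=species,
        )

        pc = 0  # per-genome protein counter
        genome_loci: list[GeneRecord] = []
        fams_of: dict[str, list[str]] = {}
        for ci in range(spec.contigs_per_genome):
            contig = f"{gid}_c{ci + 1}"
            for rank in range(spec.genes_per_contig):
                coding = rng.random() >= spec.noncoding_prob
                pid = None
                if coding:
                    pc += 1
                    pid = f"{gid}_p{pc:05d}"
                    fams_of[pid] = []
                genome_loci.append(
                    GeneRecord(
                        genome_id=gid,
                        contig_id=contig,
                        rank=rank,
                        start=1 + 1000 * rank,
                        end=900 + 1000 * rank,
                        strand="+" if rng.random() < 0.5 else "-",
                        protein_id=pid,
                    )
                )

        by_contig: dict[str, list[GeneRecord]] = {}
        for g in genome_loci:
            by_contig.setdefault(g.contig_id, []).append(g)

        # --- anchors (each paralog anchors its own region)
        n_anchors = 0
        if rng.random() < spec.anchor_prob:
            n_anchors = 1
            if rng.random() < spec.paralog_prob:
                n_anchors = int(rng.integers(2, 4))
        anchors: list[GeneRecord] = []
        anchor_ranks: dict[str, list[int]] = {}
        if n_anchors:
            contig_ids = sorted(by_contig)
            per_contig: dict[str, int] = {}
            for _ in range(n_anchors):
                c = contig_ids[rng.integers(len(contig_ids))]
                per_contig[c] = per_contig.get(c, 0) + 1
            for c, cnt in sorted(per_contig.items()):
                ranks = _place_anchors(rng, spec, len(by_contig[c]), cnt)
                for r in ranks:
                    gene = by_contig[c][r]
                    if gene.protein_id is None:  # promote to coding
                        pc += 1
                        gene = GeneRecord(
                            genome_id=gid, contig_id=c, rank=r, start=gene.start,
                            end=gene.end, strand=gene.strand,
                            protein_id=f"{gid}_p{pc:05d}",
                        )
                        by_contig[c][r] = gene
                        fams_of[gene.protein_id] = []
                    anchors.append(gene)
                    anchor_ranks.setdefault(c, []).append(r)
        genome_loci = [g for c in sorted(by_contig) for g in by_contig[c]]
        for a in anchors:
            og_members[ANCHOR_OG].append(a.protein_id)

        # --- partners within link_d of their anchor
        partners: list[PartnerTruth] = []
        linked: dict[str, bool] = {}
        taken = {(a.contig_id, a.rank) for a in anchors}
        for a in anchors:
            linked[a.protein_id] = False
            if rng.random() >= spec.p_link:
                continue
            contig_genes = by_contig[a.contig_id]
            offsets = [
                o
                for o in list(range(-spec.link_d, 0)) + list(range(1, spec.link_d + 1))
                if 0 <= a.rank + o < len(contig_genes)
                and (a.contig_id, a.rank + o) not in taken
            ]
            if not offsets:
                raise ValidationError("no room to plant a partner next to an anchor")
            off = offsets[rng.integers(len(offsets))]
            r = a.rank + off
            gene = contig_genes[r]
            if gene.protein_id is None:
                pc += 1
                gene = GeneRecord(
                    genome_id=gid, contig_id=a.contig_id, rank=r, start=gene.start,
                    end=gene.end, strand=gene.strand, protein_id=f"{gid}_p{pc:05d}",
                )
                contig_genes[r] = gene
                fams_of[gene.protein_id] = []
            taken.add((a.contig_id, r))
            fams_of[gene.protein_id].append("HATPase_c")
            og_members[PARTNER_OG].append(gene.protein_id)
            partners.append(
                PartnerTruth(
                    anchor_protein_id=a.protein_id,
                    protein_id=gene.protein_id,
                    distance=abs(off),
                )
            )
            linked[a.protein_id] = True
        genome_loci = [g for c in sorted(by_contig) for g in by_contig[c]]

        # --- R-M planting (near-anchor elevation)
        rm_fams, rm_prov = plant_rm_clusters(genome_loci, anchor_ranks, spec, rng)
        for pid, fam in rm_fams.items():
            fams_of[pid].append(fam)

        # --- background domains and OG labels
        partner_ids = {p.protein_id for p in partners}
        anchor_ids = {a.protein_id for a in anchors}
        bg = list(spec.bg_families)
        for g in genome_loci:
            pid = g.protein_id
            if pid is None or pid in anchor_ids or pid in partner_ids:
                continue
            if rng.random() < spec.bg_domain_prob:
                fams_of[pid].append(bg[rng.integers(len(bg))])
            elif not fams_of[pid] and rng.random() < spec.og_prob:
                og = f"OG_{100 + int(rng.integers(spec.n_bg_ogs))}"
                og_members.setdefault(og, []).append(pid)

        for pid, fams in fams_of.items():
            if fams:
                domains[pid] = _domain_hits_for(pid, fams, rng)

        genes.extend(genome_loci)
        truth_genomes[gid] = GenomeTruth(
            anchors=sorted(anchor_ids),
            anchor_loci={a.protein_id: [a.contig_id, a.rank] for a in anchors},
            partners=partners,
            rm_loci=[
                RMLocusTruth(protein_id=pid, family=fam, provenance=rm_prov[pid])
                for pid, fam in sorted(rm_fams.items())
            ],
            linked=linked,
        )

    # prune background OGs with < 2 members (would be singleton groups)
    og_members = {
        label: members
        for label, members in og_members.items()
        if len(members) >= 2 or label in (ANCHOR_OG, PARTNER_OG)
    }
    og_members = {k: v for k, v in og_members.items() if v}
    ogmap = OrthologGroupMap(og_members)
    cohort = Cohort(genes=genes, domains=domains, ogmap=ogmap, rmref=rmref, taxonomy=taxonomy)
    truth = TruthRecord(genomes=truth_genomes)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gcio.write_gene_table(genes, outdir / "genes.tsv")
        gcio.write_domtblout(
            (h for pid in sorted(domains) for h in domains[pid]),
            outdir / "domains.domtblout",
        )
        gcio.write_groups(ogmap, outdir / "groups.txt")
        gcio.write_taxonomy(taxonomy, outdir / "taxonomy.tsv")
        gcio.write_rm_reference(rmref, outdir / "rm_reference.tsv")
        truth.save(outdir / "truth.json")
        if write_gff3:
            gff = outdir / "gff3"
            gff.mkdir(exist_ok=True)
            for gid in sorted({g.genome_id for g in genes}):
                _write_gff3([g for g in genes if g.genome_id == gid], gff / f"{gid}.gff3")
    return cohort, truth


def _write_gff3(records: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(records, key=lambda g: (g.contig_id, g.rank)):
            ftype = "CDS" if g.protein_id else "ncRNA"
            attrs = f"ID={g.protein_id}" if g.protein_id else f"ID={g.contig_id}_r{g.rank}"
            if g.protein_id:
                attrs += f";protein_id={g.protein_id}"
            fh.write(
                f"{g.contig_id}\tgenecontext\t{ftype}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ------------------------------------------------- architecture fixtures

_GROUP_LAYOUTS: dict[int, tuple[tuple[str, int, int], ...]] = {
    1: (("HATPase_c_3", 5, 160), ("HEF_HK", 200, 260), ("HATPase_c", 300, 420)),
    2: (("HEF_HK", 20, 90), ("HATPase_c", 150, 300)),
    3: (("HATPase_c_3", 5, 160), ("HEF_HK", 200, 260)),
    4: (("HEF_HK", 30, 120),),
}
_GROUP_LENGTHS = {1: 450, 2: 330, 3: 290, 4: 150}


def make_architecture_fixtures(
    n_per_group: Mapping[int, int],
    seed: int = 0,
    boundary_cases: bool = False,
    outdir=None,
) -> tuple[dict[str, list[DomainHit]], dict[str, Optional[int]]]:
    """Synthetic focal-domain proteins with known architecture groups.

    Returns (hits per protein, expected call per protein). An expected value
    of ``None`` marks a protein the classifier must exclude (sub-threshold
    focal hit). ``boundary_cases`` adds overlap/threshold edge cases whose
    expected outcomes follow the documented midpoint and merge rules. When
    ``outdir`` is given, writes ``architectures.domtblout`` and
    ``expected_calls.tsv``.
    """
    rng = np.random.default_rng(seed)
    hits: dict[str, list[DomainHit]] = {}
    expected: dict[str, Optional[int]] = {}

    def jitter(lo: int, hi: int) -> tuple[int, int]:
        d = int(rng.integers(0, 5))
        return lo + d, hi + d

    for group in sorted(n_per_group):
        if group not in _GROUP_LAYOUTS:
            raise ValidationError(f"unknown architecture group {group}")
        for i in range(n_per_group[group]):
            pid = f"arch_g{group}_{i + 1:04d}"
            plen = _GROUP_LENGTHS[group] + int(rng.integers(0, 40))
            phits = []
            for fam, lo, hi in _GROUP_LAYOUTS[group]:
                lo, hi = jitter(lo, hi)
                phits.append(
                    DomainHit(
                        protein_id=pid,
                        domain_name=fam,
                        evalue=float(10.0 ** rng.uniform(-30, -10)),
                        env_start=lo,
                        env_end=hi,
                        protein_len=plen,
                    )
                )
            hits[pid] = phits
            expected[pid] = group

    if boundary_cases:
        # N-companion overlapping the focal hit, midpoint inside it: no N flag.
        pid = "arch_b_overlap"
        hits[pid] = [
            DomainHit(pid, "HATPase_c_3", 1e-20, 180, 260, protein_len=300),
            DomainHit(pid, "HEF_HK", 1e-20, 170, 280, protein_len=300),
        ]
        expected[pid] = 4
        # Companion above the e-value threshold is invisible.
        pid = "arch_b_weak_companion"
        hits[pid] = [
            DomainHit(pid, "HATPase_c_3", 1e-4, 5, 160, protein_len=300),
            DomainHit(pid, "HEF_HK", 1e-20, 200, 260, protein_len=300),
        ]
        expected[pid] = 4
        # Sub-threshold focal hit: protein excluded outright.
        pid = "arch_b_weak_focal"
        hits[pid] = [
            DomainHit(pid, "HEF_HK", 1e-4, 200, 260, protein_len=300),
            DomainHit(pid, "HATPase_c", 1e-20, 300, 420, protein_len=450),
        ]
        expected[pid] = None
        # Two overlapping focal hits merge to the better one.
        pid = "arch_b_dup_focal"
        hits[pid] = [
            DomainHit(pid, "HEF_HK", 1e-12, 195, 255, protein_len=450),
            DomainHit(pid, "HEF_HK", 1e-22, 200, 260, protein_len=450),
            DomainHit(pid, "HATPase_c", 1e-20, 300, 420, protein_len=450),
        ]
        expected[pid] = 2

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        gcio.write_domtblout(
            (h for pid in sorted(hits) for h in hits[pid]),
            outdir / "architectures.domtblout",
        )
        import pandas as pd

        pd.DataFrame(
            [
                {"protein_id": pid, "expected_group": "" if g is None else g}
                for pid, g in sorted(expected.items())
            ]
        ).to_csv(outdir / "expected_calls.tsv", sep="\t", index=False)
    return hits, expected
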