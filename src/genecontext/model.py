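"""Core data model for gene-neighborhood context analysis.

All genomic coordinates are 1-based inclusive (GenBank/GFF3 convention);
gene ranks are 0-based indices within a contig, ordered by start coordinate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError

#: R-M system type labels: types I-IV plus very-short-patch-repair ("V") genes.
RM_TYPE_LABELS = frozenset({"I", "II", "III", "IV", "V-gene"})

STRANDS = ("+", "-")


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One gene locus on a contig.

    ``protein_id`` is ``None`` for non-coding loci; such loci still occupy a
    rank (they count as window occupants) but carry no domain annotation.
    """

    genome_id: str
    contig_id: str
    rank: int
    start: int
    end: int
    strand: str
    protein_id: Optional[str] = None

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.protein_id or '?'}: start {self.start} > end {self.end}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"gene {self.protein_id or '?'}: bad strand {self.strand!r}")


@dataclass(frozen=True, slots=True)
class DomainHit:
    """A single domain-family hit on a protein (one domtblout domain line).

    ``evalue`` is the per-domain independent e-value; ``env_start``/``env_end``
    are 1-based envelope residue coordinates. ``protein_len`` is the query
    length when the source format provides it.
    """

    protein_id: str
    domain_name: str
    evalue: float
    env_start: int
    env_end: int
    accession: Optional[str] = None
    protein_len: Optional[int] = None

    def __post_init__(self):
        if self.env_start > self.env_end:
            raise ValidationError(
                f"{self.protein_id}/{self.domain_name}: env_start > env_end"
            )
        if self.evalue < 0:
            raise ValidationError(f"{self.protein_id}/{self.domain_name}: negative e-value")

    @property
    def midpoint(self) -> float:
        return (self.env_start + self.env_end) / 2.0


class OrthologGroupMap:
    """Assignment of proteins to ortholog groups (OrthoMCL-style labels).

    Each protein belongs to at most one group; group membership lists are
    retained so group sizes can be reported.
    """

    def __init__(self, groups: Mapping[str, Sequence[str]]):
        self.groups: dict[str, tuple[str, ...]] = {}
        self._og_of: dict[str, str] = {}
        for label, members in groups.items():
            members = tuple(members)
            self.groups[label] = members
            for m in members:
                if m in self._og_of and self._og_of[m] != label:
                    raise ValidationError(
                        f"protein {m!r} assigned to both {self._og_of[m]} and {label}"
                    )
                self._og_of[m] = label

    def og_of(self, protein_id: Optional[str]) -> Optional[str]:
        if protein_id is None:
            return None
        return self._og_of.get(protein_id)

    def members(self, og_label: str) -> tuple[str, ...]:
        return self.groups[og_label]

    def sizes(self) -> dict[str, int]:
        return {label: len(m) for label, m in self.groups.items()}

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, og_label: str) -> bool:
        return og_label in self.groups


class RMReference:
    """Mapping from domain-family names to restriction-modification types.

    Emulates a REBASE-derived "gold standard" table: every listed family has
    at least one type from types I-IV or the V (Vsr repair) gene class; a
    family with more than one type is flagged multi-type.
    """

    def __init__(self, types: Mapping[str, Iterable[str]]):
        self.types: dict[str, frozenset[str]] = {}
        for name, labels in types.items():
            labels = frozenset(labels)
            if not labels:
                raise ValidationError(f"R-M family {name!r} has no type label")
            unknown = labels - RM_TYPE_LABELS
            if unknown:
                raise ValidationError(
                    f"R-M family {name!r}: unknown type label(s) {sorted(unknown)}"
                )
            self.types[name] = labels

    def is_rm(self, domain_name: str) -> bool:
        return domain_name in self.types

    def rm_types(self, domain_name: str) -> frozenset[str]:
        return self.types.get(domain_name, frozenset())

    def is_multi(self, domain_name: str) -> bool:
        return len(self.types.get(domain_name, ())) > 1

    def __len__(self) -> int:
        return len(self.types)

    def __contains__(self, domain_name: str) -> bool:
        return domain_name in self.types


@dataclass(frozen=True, slots=True)
class TaxonRecord:
    """Taxonomic lineage of one genome assembly. Any level may be absent."""

    genome_id: str
    phylum: Optional[str] = None
    class_: Optional[str] = None
    order: Optional[str] = None
    family: Optional[str] = None
    genus: Optional[str] = None
    species: Optional[str] = None

    def level(self, name: str) -> Optional[str]:
        key = "class_" if name == "class" else name
        return getattr(self, key)


@dataclass(frozen=True, slots=True)
class NeighborhoodWindow:
    """Ordered genes within +/-k gene ranks of an anchor.

    ``upstream``/``downstream`` are nearest-first and oriented by the anchor's
    strand when extracted with strand orientation (the default); the anchor
    itself is never a member of either side. ``truncated_up``/``truncated_down``
    flag sides cut short by a contig end.
    """

    anchor: GeneRecord
    upstream: tuple[GeneRecord, ...]
    downstream: tuple[GeneRecord, ...]
    k: int
    truncated_up: bool
    truncated_down: bool

    @property
    def neighbors(self) -> tuple[GeneRecord, ...]:
        """All window genes (both sides), anchor excluded."""
        return self.upstream + self.downstream

    def genes_in_contig_order(self, include_anchor: bool = True) -> list[GeneRecord]:
        genes = list(self.neighbors) + ([self.anchor] if include_anchor else [])
        return sorted(genes, key=lambda g: g.rank)


@dataclass(frozen=True, slots=True)
class LinkageResult:
    """Co-localization bookkeeping: of ``n_regions`` analyzable anchor regions,
    ``n_linked`` have at least one partner within ``d`` gene ranks;
    ``n_excluded`` regions were unsuitable (too few window neighbors)."""

    d: int
    n_regions: int
    n_linked: int
    n_excluded: int = 0

    def __post_init__(self):
        if not (0 <= self.n_linked <= self.n_regions):
            raise ValidationError("n_linked must lie in [0, n_regions]")

    @property
    def linkage(self) -> float:
        """Linked fraction in [0, 1]; 0.0 for an empty region set."""
        return self.n_linked / self.n_regions if self.n_regions else 0.0


@dataclass(frozen=True, slots=True)
class PseudoGenome:
    """A genome with its gene identities permuted across its loci.

    ``loci`` are the genome's gene records in canonical order (contigs sorted
    lexicographically, ranks ascending); ``identities[i]`` is the protein
    identity assigned to locus ``loci[i]`` after shuffling. The multiset of
    identities equals the original genome's exactly; coordinates and contig
    structure are untouched.
    """

    genome_id: str
    seed: int
    loci: tuple[GeneRecord, ...]
    identities: tuple[Optional[str], ...]

    def __post_init__(self):
        if len(self.loci) != len(self.identities):
            raise ValidationError("identities must map one-to-one onto loci")


@dataclass(slots=True)
class NullDistribution:
    """Per-genome empirical null of windowed R-M counts over pseudogenomes."""

    genome_id: str
    n_sims: int
    counts: np.ndarray
    observed: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.n_sims:
            raise ValidationError("counts length must equal n_sims")
        if (self.counts < 0).any() or self.observed < 0:
            raise ValidationError("R-M counts must be non-negative")

    def empirical_p(self) -> float:
        """(1 + #{null >= observed}) / (1 + n_sims): add-one upper-tail p."""
        return (1 + int((self.counts >= self.observed).sum())) / (1 + self.n_sims)

    def summary(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "n_sims": self.n_sims,
            "observed": self.observed,
            "null_mean": float(self.counts.mean()) if self.n_sims else float("nan"),
            "null_q95": float(np.quantile(self.counts, 0.95)) if self.n_sims else float("nan"),
            "empirical_p": self.empirical_p(),
        }


def stars_for(p: float) -> str:
    """Significance band for a p-value: ns / * / ** / *** / ****."""
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One-tailed enrichment test of observed windowed R-M counts vs a null."""

    label: str
    t_statistic: float
    p_one_tailed: float
    empirical_p: float
    stars: str
    flagged: bool = False

    def __post_init__(self):
        if not (0.0 <= self.empirical_p <= 1.0):
            raise ValidationError("empirical_p out of [0, 1]")


@dataclass(frozen=True, slots=True)
class ArchitectureCall:
    """Architecture group of a focal-domain protein.

    Group 1: N-terminal HATPase_c_3 and C-terminal HATPase_c companions both
    present; group 2: C-terminal only; group 3: N-terminal only; group 4:
    neither.
    """

    protein_id: str
    group: int
    has_nterm_hatpase_c3: bool
    has_cterm_hatpase_c: bool
    focal_evalue: float
    length: int
    extra_domains: tuple[str, ...] = ()
    genome_id: Optional[str] = None

    def __post_init__(self):
        expected = {(True, True): 1, (False, True): 2, (True, False): 3, (False, False): 4}[
            (self.has_nterm_hatpase_c3, self.has_cterm_hatpase_c)
        ]
        if self.group != expected:
            raise ValidationError(
                f"{self.protein_id}: group {self.group} inconsistent with companion flags"
            )


@dataclass(slots=True)
class Cohort:
    """In-memory bundle of one analysis cohort: gene tables, domain hits per
    protein, ortholog groups, the R-M reference and taxonomy."""

    genes: list[GeneRecord]
    domains: dict[str, list[DomainHit]] = field(default_factory=dict)
    ogmap: Optional[OrthologGroupMap] = None
    rmref: Optional[RMReference] = None
    taxonomy: dict[str, TaxonRecord] = field(default_factory=dict)

    def genome_ids(self) -> list[str]:
        return sorted({g.genome_id for g in self.genes})

    def genes_of(self, genome_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.genome_id == genome_id]
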