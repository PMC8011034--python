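"""Domain-architecture classification of focal-domain proteins.

Proteins carrying the focal transmitter-like domain (default ``HEF_HK``) are
classified by the presence of GHKL-superfamily companions: an N-terminal
``HATPase_c_3`` and/or a C-terminal ``HATPase_c``. Group 1 has both,
group 2 only the C-terminal companion, group 3 only the N-terminal one, and
group 4 neither. "N-terminal"/"C-terminal" are decided by envelope midpoints
relative to the focal hit's envelope bounds, which is robust to partial
overlaps.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .model import ArchitectureCall, DomainHit, TaxonRecord

FOCAL_DOMAIN = "HEF_HK"
NTERM_COMPANION = "HATPase_c_3"
CTERM_COMPANION = "HATPase_c"
DEFAULT_EVALUE_MAX = 1e-5

_GROUP_OF_FLAGS = {(True, True): 1, (False, True): 2, (True, False): 3, (False, False): 4}


def filter_bona_fide(
    hits: Iterable[DomainHit],
    focal: str = FOCAL_DOMAIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> set[str]:
    """Proteins whose best focal-domain hit is strictly below ``evalue_max``."""
    if evalue_max <= 0:
        raise ValidationError("evalue_max must be > 0")
    best: dict[str, float] = {}
    for h in hits:
        if h.domain_name == focal:
            best[h.protein_id] = min(best.get(h.protein_id, float("inf")), h.evalue)
    return {pid for pid, e in best.items() if e < evalue_max}


def merge_overlapping_hits(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Collapse overlapping same-family hits to the best-e-value hit.

    Hits of one family whose envelopes overlap (transitively) form a cluster;
    the cluster is represented by its lowest-e-value hit.
    """
    by_family: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_family.setdefault(h.domain_name, []).append(h)
    merged: list[DomainHit] = []
    for fam_hits in by_family.values():
        fam_hits = sorted(fam_hits, key=lambda h: (h.env_start, h.env_end))
        cluster: list[DomainHit] = []
        cluster_end = -1
        for h in fam_hits:
            if cluster and h.env_start > cluster_end:
                merged.append(min(cluster, key=lambda x: (x.evalue, x.env_start)))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.env_end)
        if cluster:
            merged.append(min(cluster, key=lambda x: (x.evalue, x.env_start)))
    return sorted(merged, key=lambda h: (h.env_start, h.env_end, h.domain_name))


def classify_architecture(
    hits: Sequence[DomainHit],
    focal: str = FOCAL_DOMAIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    genome_id: Optional[str] = None,
) -> ArchitectureCall:
    """Classify one protein's hits into architecture group 1-4.

    Requires at least one bona fide focal hit (e-value < ``evalue_max``).
    Companion hits use the same e-value threshold. The result is invariant
    to the order of ``hits``.
    """
    if not hits:
        raise ValidationError("no domain hits supplied")
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValidationError("classify_architecture expects hits of a single protein")
    protein_id = pids.pop()
    sig = [h for h in merge_overlapping_hits(hits) if h.evalue < evalue_max]
    focal_hits = [h for h in sig if h.domain_name == focal]
    if not focal_hits:
        raise ValidationError(f"{protein_id}: no bona fide {focal} hit below {evalue_max:g}")
    best = min(focal_hits, key=lambda h: h.evalue)
    has_n = any(
        h.domain_name == NTERM_COMPANION and h.midpoint < best.env_start for h in sig
    )
    has_c = any(
        h.domain_name == CTERM_COMPANION and h.midpoint > best.env_end for h in sig
    )
    extra = tuple(
        sorted(
            {
                h.domain_name
                for h in sig
                if h.domain_name not in (focal, NTERM_COMPANION, CTERM_COMPANION)
            }
        )
    )
    length = next((h.protein_len for h in hits if h.protein_len), None)
    if length is None:
        length = max(h.env_end for h in hits)
    return ArchitectureCall(
        protein_id=protein_id,
        group=_GROUP_OF_FLAGS[(has_n, has_c)],
        has_nterm_hatpase_c3=has_n,
        has_cterm_hatpase_c=has_c,
        focal_evalue=best.evalue,
        length=int(length),
        extra_domains=extra,
        genome_id=genome_id,
    )


def classify_all(
    hits_by_protein: Mapping[str, Sequence[DomainHit]],
    focal: str = FOCAL_DOMAIN,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    genome_of: Optional[Mapping[str, str]] = None,
    strict_group4: bool = False,
) -> dict[str, ArchitectureCall]:
    """Classify every bona fide focal protein in a hit collection.

    With ``strict_group4`` proteins that would fall in group 4 but carry other
    known domains are dropped (group 4 then means "no other known domain").
    """
    keep = filter_bona_fide(
        (h for hits in hits_by_protein.values() for h in hits), focal, evalue_max
    )
    calls: dict[str, ArchitectureCall] = {}
    for pid in sorted(keep):
        call = classify_architecture(
            hits_by_protein[pid],
            focal=focal,
            evalue_max=evalue_max,
            genome_id=genome_of.get(pid) if genome_of else None,
        )
        if strict_group4 and call.group == 4 and call.extra_domains:
            continue
        calls[pid] = call
    return calls


@dataclass(frozen=True, slots=True)
class ProteinMeta:
    """Redundancy-collapse key data for one focal protein."""

    protein_id: str
    species: Optional[str]
    focal_evalue: float
    length: int
    genome_id: Optional[str] = None


def collapse_redundant(metas: Iterable[ProteinMeta]) -> set[str]:
    """One protein per species: best focal e-value, then greatest length,
    then lexicographically smallest id.

    Proteins without a species fall into per-genome "species-unknown"
    buckets. Idempotent, and never increases the set.
    """
    buckets: dict[object, list[ProteinMeta]] = {}
    for m in metas:
        key = m.species if m.species else ("species-unknown", m.genome_id or m.protein_id)
        buckets.setdefault(key, []).append(m)
    return {
        min(ms, key=lambda m: (m.focal_evalue, -m.length, m.protein_id)).protein_id
        for ms in buckets.values()
    }


def metas_from_calls(
    calls: Mapping[str, ArchitectureCall],
    taxonomy: Mapping[str, TaxonRecord],
) -> list[ProteinMeta]:
    out = []
    for pid, call in sorted(calls.items()):
        taxon = taxonomy.get(call.genome_id) if call.genome_id else None
        out.append(
            ProteinMeta(
                protein_id=pid,
                species=taxon.species if taxon else None,
                focal_evalue=call.focal_evalue,
                length=call.length,
                genome_id=call.genome_id,
            )
        )
    return out


@dataclass(frozen=True, slots=True)
class ArchitectureSummary:
    """Group counts with the derived companion-domain shares."""

    counts: tuple[tuple[int, int], ...]  # (group, count), groups 1..4
    total: int
    nterm_share: float  # (g1 + g3) / total
    cterm_share: float  # (g1 + g2) / total

    @property
    def nterm_percent(self) -> float:
        return round(100.0 * self.nterm_share, 1)

    @property
    def cterm_percent(self) -> float:
        return round(100.0 * self.cterm_share, 1)

    def count(self, group: int) -> int:
        return dict(self.counts).get(group, 0)


def summarize_architectures(calls: Iterable[ArchitectureCall]) -> ArchitectureSummary:
    """Counts per group plus the shares of proteins with each companion."""
    calls = list(calls)
    if not calls:
        raise ValidationError("no architecture calls to summarize")
    counts = {g: 0 for g in (1, 2, 3, 4)}
    for c in calls:
        counts[c.group] += 1
    total = len(calls)
    return ArchitectureSummary(
        counts=tuple(sorted(counts.items())),
        total=total,
        nterm_share=(counts[1] + counts[3]) / total,
        cterm_share=(counts[1] + counts[2]) / total,
    )


def phyletic_distribution(
    calls: Iterable[ArchitectureCall],
    taxonomy: Mapping[str, TaxonRecord],
    level: str = "phylum",
) -> pd.DataFrame:
    """Contingency table taxon x architecture group with margins.

    Calls whose genome lacks taxonomy at ``level`` fall under "unclassified".
    Margins sum to the number of calls.
    """
    if level not in ("phylum", "class", "order", "family"):
        raise ValidationError(f"unsupported taxonomic level {level!r}")
    rows = []
    for c in calls:
        taxon = taxonomy.get(c.genome_id) if c.genome_id else None
        name = taxon.level(level) if taxon else None
        rows.append({"taxon": name or "unclassified", "group": c.group})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    table = pd.crosstab(df["taxon"], df["group"], margins=True, margins_name="All")
    return table


def calls_frame(calls: Mapping[str, ArchitectureCall]) -> pd.DataFrame:
    rows = [
        {
            "protein_id": c.protein_id,
            "group": c.group,
            "has_nterm_hatpase_c3": c.has_nterm_hatpase_c3,
            "has_cterm_hatpase_c": c.has_cterm_hatpase_c,
            "focal_evalue": c.focal_evalue,
            "length": c.length,
            "extra_domains": ",".join(c.extra_domains),
            "genome_id": c.genome_id or "",
        }
        for c in calls.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "group", "has_nterm_hatpase_c3", "has_cterm_hatpase_c",
            "focal_evalue", "length", "extra_domains", "genome_id",
        ],
    ).sort_values("protein_id").reset_index(drop=True)
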