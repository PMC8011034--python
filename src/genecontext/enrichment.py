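"""Pseudogenome permutation null and enrichment statistics.

A pseudogenome is the genome with its gene identities uniformly permuted
across all its loci (all contigs jointly, anchors included); coordinates and
contig structure stay fixed, and domain/OG annotations travel with the gene
identity. Re-extracting the anchor windows at the anchors' new loci and
counting windowed R-M domains over many pseudogenomes yields an empirical
null for the observed count.

Counting modes for "number of R-M domains" in a window:

* ``families_per_gene`` (default): sum over window genes of the number of
  distinct R-M-classified families on each product;
* ``genes``: number of window genes carrying at least one R-M family.
"""
from __future__ import annotations

from itertools import permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .model import (
    DomainHit,
    EnrichmentResult,
    GeneRecord,
    NeighborhoodWindow,
    NullDistribution,
    PseudoGenome,
    RMReference,
    stars_for,
)

COUNT_MODES = ("families_per_gene", "genes")


def rm_family_count(
    protein_id: Optional[str],
    domains: Mapping[str, Sequence[DomainHit]],
    rmref: RMReference,
) -> int:
    """Number of distinct R-M-classified families on a protein (0 if none)."""
    if protein_id is None:
        return 0
    return len({h.domain_name for h in domains.get(protein_id, ()) if rmref.is_rm(h.domain_name)})


def _locus_value(pid, domains, rmref, mode: str) -> int:
    n = rm_family_count(pid, domains, rmref)
    return n if mode == "families_per_gene" else int(n > 0)


def count_rm_in_windows(
    windows: Iterable[NeighborhoodWindow],
    domains: Mapping[str, Sequence[DomainHit]],
    rmref: RMReference,
    mode: str = "families_per_gene",
) -> int:
    """Total windowed R-M count, summed over all given windows."""
    if mode not in COUNT_MODES:
        raise ValidationError(f"unknown counting mode {mode!r}")
    total = 0
    for w in windows:
        for g in w.neighbors:
            total += _locus_value(g.protein_id, domains, rmref, mode)
    return total


def canonical_loci(genes: Iterable[GeneRecord]) -> list[GeneRecord]:
    """A genome's loci in canonical order: contigs lexicographic, ranks ascending."""
    return sorted(genes, key=lambda g: (g.contig_id, g.rank))


def shuffle_genome(genes: Sequence[GeneRecord], rng_seed: int) -> PseudoGenome:
    """Uniform random permutation of a genome's gene identities across its loci.

    Deterministic for a fixed seed. ``genes`` must belong to one genome.
    """
    if not genes:
        raise ValidationError("cannot shuffle an empty genome")
    genomes = {g.genome_id for g in genes}
    if len(genomes) != 1:
        raise ValidationError("shuffle_genome expects loci of a single genome")
    loci = tuple(canonical_loci(genes))
    perm = np.random.default_rng(rng_seed).permutation(len(loci))
    identities = tuple(loci[j].protein_id for j in perm)
    return PseudoGenome(
        genome_id=loci[0].genome_id, seed=rng_seed, loci=loci, identities=identities
    )


def _genome_arrays(
    loci: Sequence[GeneRecord],
    domains: Mapping[str, Sequence[DomainHit]],
    rmref: RMReference,
    mode: str,
):
    """Per-locus identity values plus per-position contig bounds."""
    values = np.array(
        [_locus_value(g.protein_id, domains, rmref, mode) for g in loci], dtype=np.int64
    )
    n = len(loci)
    contig_lo = np.empty(n, dtype=np.int64)
    contig_hi = np.empty(n, dtype=np.int64)
    i = 0
    while i < n:
        j = i
        while j < n and loci[j].contig_id == loci[i].contig_id:
            j += 1
        contig_lo[i:j] = i
        contig_hi[i:j] = j - 1
        i = j
    return values, contig_lo, contig_hi


def _windowed_count(perm, values, anchor_idx, k, contig_lo, contig_hi) -> int:
    """Windowed R-M count for one identity->locus assignment.

    ``perm[p]`` is the original locus index whose identity occupies position
    ``p``. Windows exclude the anchor locus itself; overlapping windows of
    different anchors each count their occupants.
    """
    v_pos = values[perm]
    cs = np.concatenate(([0], np.cumsum(v_pos)))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    total = 0
    for a in anchor_idx:
        q = inv[a]
        lo = max(q - k, contig_lo[q])
        hi = min(q + k, contig_hi[q])
        total += int(cs[hi + 1] - cs[lo] - v_pos[q])
    return total


def count_rm_for_assignment(
    pg: PseudoGenome,
    domains: Mapping[str, Sequence[DomainHit]],
    rmref: RMReference,
    anchor_ids: Sequence[str],
    k: int,
    mode: str = "families_per_gene",
) -> int:
    """Object-level windowed R-M recount on a PseudoGenome (used as the slow
    reference path; equals the vectorized path for the same permutation)."""
    pos_of = {pid: p for p, pid in enumerate(pg.identities) if pid is not None}
    total = 0
    for aid in anchor_ids:
        if aid not in pos_of:
            raise ValidationError(f"anchor {aid!r} absent from pseudogenome")
        q = pos_of[aid]
        contig = pg.loci[q].contig_id
        for p in range(q - k, q + k + 1):
            if p == q or not (0 <= p < len(pg.loci)):
                continue
            if pg.loci[p].contig_id != contig:
                continue
            total += _locus_value(pg.identities[p], domains, rmref, mode)
    return total


def simulate_null(
    genes: Sequence[GeneRecord],
    domains: Mapping[str, Sequence[DomainHit]],
    rmref: RMReference,
    anchor_ids: Sequence[str],
    k: int,
    n_sims: int,
    base_seed: int,
    mode: str = "families_per_gene",
) -> NullDistribution:
    """Empirical null of windowed R-M counts over ``n_sims`` pseudogenomes.

    The observed count comes from the unshuffled genome. Per-simulation seeds
    are ``base_seed + i`` so any single pseudogenome can be reproduced with
    :func:`shuffle_genome`.
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    if mode not in COUNT_MODES:
        raise ValidationError(f"unknown counting mode {mode!r}")
    loci = canonical_loci(genes)
    if not loci:
        raise ValidationError("empty genome")
    idx_of = {g.protein_id: i for i, g in enumerate(loci) if g.protein_id is not None}
    anchor_idx = []
    for aid in anchor_ids:
        if aid not in idx_of:
            raise ValidationError(f"anchor {aid!r} not found in genome")
        anchor_idx.append(idx_of[aid])
    values, contig_lo, contig_hi = _genome_arrays(loci, domains, rmref, mode)
    n = len(loci)
    identity = np.arange(n)
    observed = _windowed_count(identity, values, anchor_idx, k, contig_lo, contig_hi)
    counts = np.empty(n_sims, dtype=np.int64)
    for s in range(n_sims):
        perm = np.random.default_rng(base_seed + s).permutation(n)
        counts[s] = _windowed_count(perm, values, anchor_idx, k, contig_lo, contig_hi)
    return NullDistribution(
        genome_id=loci[0].genome_id, n_sims=n_sims, counts=counts, observed=observed
    )


def exact_null_counts(
    genes: Sequence[GeneRecord],
    domains: Mapping[str, Sequence[DomainHit]],
    rmref: RMReference,
    anchor_ids: Sequence[str],
    k: int,
    mode: str = "families_per_gene",
    max_loci: int = 8,
) -> np.ndarray:
    """Windowed R-M count under every one of the n! permutations (tiny genomes).

    The full enumeration is the exact permutation null that pseudogenome
    sampling approximates.
    """
    loci = canonical_loci(genes)
    if len(loci) > max_loci:
        raise ValidationError(f"exact enumeration limited to {max_loci} loci")
    idx_of = {g.protein_id: i for i, g in enumerate(loci) if g.protein_id is not None}
    anchor_idx = [idx_of[a] for a in anchor_ids]
    values, contig_lo, contig_hi = _genome_arrays(loci, domains, rmref, mode)
    out = [
        _windowed_count(np.array(perm), values, anchor_idx, k, contig_lo, contig_hi)
        for perm in permutations(range(len(loci)))
    ]
    return np.array(out, dtype=np.int64)


def enrichment_test(
    real_counts: Sequence[float],
    null_counts: Sequence[float],
    label: str = "",
    alternative: str = "greater",
    flavor: str = "student",
) -> EnrichmentResult:
    """One-tailed two-sample t-test of observed counts against a pooled null.

    ``flavor`` "student" is the pooled-variance Student test; "welch" drops
    the equal-variance assumption. Also reports the add-one empirical
    p-value ``(1 + #{null >= mean(real)}) / (1 + |null|)`` and the
    significance band of the t-test p-value.
    """
    real = np.asarray(real_counts, dtype=float)
    null = np.asarray(null_counts, dtype=float)
    if real.size < 2 or null.size < 2:
        raise ValidationError("t-test requires >= 2 values in each sample")
    flagged = False
    if real.std() == 0.0 and null.std() == 0.0 and real.mean() == null.mean():
        t, p = 0.0, 0.5  # degenerate: identical constant samples
        flagged = True
    else:
        t, p = stats.ttest_ind(
            real, null, equal_var=(flavor == "student"), alternative=alternative
        )
        t, p = float(t), float(p)
    emp = (1 + int((null >= real.mean()).sum())) / (1 + null.size)
    return EnrichmentResult(
        label=label,
        t_statistic=t,
        p_one_tailed=p,
        empirical_p=emp,
        stars=stars_for(p),
        flagged=flagged,
    )


def round_robin_mixes(genome_ids: Sequence[str], mix_size: int = 5) -> dict[str, str]:
    """Assign genomes to consecutive mixes of ``mix_size`` (mix1, mix2, ...)."""
    return {
        gid: f"mix{i // mix_size + 1}" for i, gid in enumerate(sorted(genome_ids))
    }


def pool_mixes(
    null_dists: Sequence[NullDistribution] | Mapping[str, NullDistribution],
    mix_assignment: Mapping[str, str] | Mapping[str, Sequence[str]],
) -> dict[str, np.ndarray]:
    """Concatenate member genomes' null counts per mix.

    ``mix_assignment`` maps genome_id -> mix_id, or mix_id -> genome list;
    every genome with a null distribution must belong to exactly one mix.
    """
    if isinstance(null_dists, Mapping):
        dists = dict(null_dists)
    else:
        dists = {nd.genome_id: nd for nd in null_dists}
    # normalize to genome -> mix
    g2m: dict[str, str] = {}
    values = list(mix_assignment.values())
    if values and isinstance(values[0], (list, tuple)):
        for mix, members in mix_assignment.items():
            for gid in members:
                if gid in g2m:
                    raise ValidationError(f"genome {gid!r} assigned to two mixes")
                g2m[gid] = mix
    else:
        g2m = dict(mix_assignment)  # type: ignore[arg-type]
    missing = sorted(set(dists) - set(g2m))
    if missing:
        raise ValidationError(f"genomes not assigned to any mix: {missing}")
    pooled: dict[str, list[np.ndarray]] = {}
    for gid in sorted(dists):
        pooled.setdefault(g2m[gid], []).append(dists[gid].counts)
    return {mix: np.concatenate(chunks) for mix, chunks in sorted(pooled.items())}
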