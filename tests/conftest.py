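import pytest

from genecontext import CohortSpec, DomainHit, GeneRecord, generate_cohort


def make_gene(genome="g1", contig="c1", rank=0, strand="+", protein_id="auto"):
    if protein_id == "auto":
        protein_id = f"{genome}_{contig}_p{rank}"
    return GeneRecord(
        genome_id=genome,
        contig_id=contig,
        rank=rank,
        start=1 + 1000 * rank,
        end=900 + 1000 * rank,
        strand=strand,
        protein_id=protein_id,
    )


def make_contig(n, genome="g1", contig="c1", strands=None):
    return [
        make_gene(genome, contig, r, (strands[r] if strands else "+"))
        for r in range(n)
    ]


def hit(pid, family, evalue=1e-20, env=(5, 120), plen=None):
    return DomainHit(
        protein_id=pid,
        domain_name=family,
        evalue=evalue,
        env_start=env[0],
        env_end=env[1],
        protein_len=plen,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-genome cohort with planted anchors/partners/R-M clusters."""
    spec = CohortSpec(n_genomes=6, genes_per_contig=80, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_files(tmp_path_factory):
    """The same kind of cohort, written to disk in all external formats."""
    outdir = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_genomes=6, genes_per_contig=80, seed=11)
    cohort, truth = generate_cohort(spec, outdir=outdir)
    return outdir, cohort, truth
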