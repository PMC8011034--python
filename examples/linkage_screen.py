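"""Gene-neighborhood linkage screen on a synthetic cohort.

Generates 50 annotated genomes in which a partner gene (GHKL-labelled,
ortholog group OG_B) is planted within 3 genes of each anchor (OG_A) with
probability 0.916, then re-estimates that co-localization rate by scanning
anchor neighborhoods over a distance sweep.
"""
from genecontext import (
    CohortSpec,
    GeneIndex,
    generate_cohort,
    linkage_sweep,
    og_partner_predicate,
    resolve_anchors,
)

spec = CohortSpec(n_genomes=50, genes_per_contig=120, p_link=0.916, seed=7)
cohort, truth = generate_cohort(spec)

index = GeneIndex(cohort.genes)
anchors = resolve_anchors(index, "OG_A", cohort.ogmap)
partner = og_partner_predicate(cohort.ogmap, "OG_B")
report = linkage_sweep(index, anchors, partner, d_max=5)

print(report.to_string(index=False))
print(f"\nplanted linkage within d=3: {truth.realized_linkage(3):.3f}")
# Each row gives the fraction of anchor regions with >=1 partner within d
# gene ranks; the column is monotone in d, and at d=3 the estimate recovers
# the planted rate up to binomial noise.
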