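# Methods

`genecontext` implements a comparative-genomics workflow for characterizing
an uncharacterized gene family by the company it keeps: gene-neighborhood
linkage between ortholog groups, a permutation ("pseudogenome") null for
restriction–modification (R–M) domain enrichment around anchor genes, a
directed 5′→3′ domain co-occurrence network, and rule-based protein
domain-architecture classification with phyletic summaries. This note
records the models, conventions and design choices, and what the synthetic
cohorts do and do not establish about real data.

## Data model and conventions

Coordinates are 1-based inclusive throughout (the GFF3/GenBank convention);
gene ranks are 0-based indices within a contig, assigned by sorting on start
coordinate with ties broken by end coordinate, then identifier. Distances
between genes are **gene-rank distances** (the adjacent gene is at distance
1), strand-agnostic, and never cross a contig boundary. We use rank rather
than base-pair distance because the neighborhood statements being tested
("within three genes", "ten genes up- and downstream") are counts of loci.
Non-coding loci occupy a rank — they count as window occupants — but carry
no protein, hence no domains.

Domain annotations come from HMMER3 per-domain tables (domtblout). We use
the **independent per-domain e-value** (not the full-sequence e-value)
because positional architecture decisions need per-domain significance, and
the envelope coordinates as the domain's location. All e-value thresholds
are strict less-than; the default cutoff is 1e-05.

## Neighborhood windows and linkage

A window is the ordered set of genes within ±k ranks of an anchor, the
anchor excluded, sides truncated at contig ends (and flagged). Upstream and
downstream are oriented by the anchor's strand by default, since "upstream
of the anchor" is a biological statement; a flag restores raw contig order.

The linkage statistic is the fraction of anchor regions with at least one
partner gene (an ortholog-group or domain predicate) within distance d.
Regions whose ±d window contains fewer than `min_neighbors` genes (default
1) are excluded and tallied separately — the analog of regions unusable
because an assembly ends too close to the anchor. When a genome carries
anchor paralogs, each paralog anchors its own region. Linkage is monotone
non-decreasing in d by construction.

The domain-frequency table counts, per window gene, each distinct family on
its product once; a gene with no domain hits contributes its ortholog-group
label instead, and a gene with neither contributes "na". The top-fraction
report keeps the `ceil(fraction × #labels)` most frequent labels, ordered by
count descending then label ascending (the same ordering resolves ties at
the cutoff).

## Pseudogenome permutation null

A pseudogenome is the genome with its gene identities uniformly permuted
across all loci of all contigs jointly — anchors included in the shuffle —
with coordinates and contig structure fixed; domain and ortholog annotations
travel with the identity. (A per-contig shuffle mode exists behind a flag.)
For each pseudogenome the anchor windows are re-extracted at the anchors'
new loci and the windowed R–M count is computed; summed over a genome's
anchors this yields one null draw. The observed count comes from the
unshuffled genome.

"Number of R–M domains" is ambiguous, so both readings are implemented:
`families_per_gene` (default) sums distinct R–M-classified families per
window gene; `genes` counts window genes carrying at least one such family.
Reports name the mode.

Tests use three independent checks of the sampler: (i) object-level
recounts on explicitly materialized pseudogenomes equal the vectorized
prefix-sum path permutation-by-permutation; (ii) on a 100-locus genome the
null mean matches the closed-form sampling-without-replacement expectation
E[w]·m/(N−1), where E[w] averages the window size over the shuffled
anchor's landing position (window truncation at contig ends makes E[w]
slightly less than 2k — for N=100, k=10, E[w]=18.9, not 20); (iii) on
genomes of ≤7 loci the sampled null matches exact enumeration of all n!
permutations.

The enrichment test is the pooled-variance (Student) two-sample t-test,
one-tailed with alternative observed > null, applied to the observed counts
against null counts pooled over mixes of five genomes (Welch is available
as an option); significance bands are ns/*/**/***/**** at
0.05/0.01/0.001/0.0001. An add-one empirical p-value,
(1 + #{null ≥ observed})/(1 + n_sims), is reported alongside. If both
samples are constant and equal the t-test p is set to 0.5 and flagged.
Per-simulation seeds are `base_seed + simulation index`, so any single
pseudogenome is reproducible in isolation.

**Calibration caveat (anchor edge-avoidance).** The permutation test is
exactly calibrated only when anchors are exchangeable with other loci. If
anchors systematically avoid contig ends (as curated "analyzable regions"
do in real assemblies), the observed windows are never truncated while
shuffled-anchor windows sometimes are, deflating the null mean by roughly
k(k+1)/(2kN) per anchor and making the test slightly anti-conservative
(about a 1% mean shift at k=50, N=2000). The calibration experiment
therefore places anchors near-uniformly; for real data the effect is a
small liberal bias that grows with k/N and should be kept in mind for
marginal calls.

## Co-occurrence network

Windows of half-width 3 are walked in raw contig 5′→3′ order (not
anchor-strand order, since the drawn arrows represent order of appearance).
Every gene contributes all its domain-family labels (first-domain-only mode
available), or its ortholog-group label when it has none; label-less genes
are bridged over by default (a strict-adjacency flag disables bridging).
Consecutive genes' labels are connected all-against-all with directed
edges. An edge's weight is the number of **distinct genera** in which the
adjacency occurs — repeated observations within a genus do not thicken an
edge — so adjacencies are deduplicated at the genus level. Only nodes that
are R–M-classified or adjacent to an R–M-classified node are retained (the
filter is idempotent). A hub's non-R–M leaf neighbors can be collapsed into
one aggregate node recording the merged-label census.

## Architecture classification

Proteins with a bona fide focal-domain hit (default `HEF_HK`, e-value
< 1e-05) are classified by two flags: an N-terminal `HATPase_c_3` companion
(any bona fide hit whose envelope midpoint lies before the focal envelope
start) and a C-terminal `HATPase_c` companion (midpoint after the focal
envelope end). Group 1 has both, group 2 only C-terminal, group 3 only
N-terminal, group 4 neither — a total, mutually exclusive function of the
flags. Midpoints were chosen over strict envelope bounds because they are
robust to partial overlaps; a hit straddling the focal domain with its
midpoint inside it sets no flag. Overlapping same-family hits are merged to
the best-e-value hit before evaluation, which also makes classification
invariant to hit order. Companion hits reuse the focal threshold. Proteins
with additional domains keep their flag-based group; a strict mode drops
such proteins from group 4 (where "no other known domain" is the intended
reading).

Redundancy collapse keeps one protein per species — best focal e-value,
then greatest length, then smallest identifier — with species-less proteins
bucketed per genome; the operation is idempotent. Summaries report group
counts, the N-terminal companion share (groups 1+3 over total) and the
C-terminal share (groups 1+2), to one decimal; phyletic tables are
taxon × group contingency tables with margins, "unclassified" rows for
genomes without taxonomy at the requested level.

## Synthetic cohorts

The generator emits the exact formats the readers consume (gene-table TSV
or GFF3, domtblout, OrthoMCL-style groups, taxonomy TSV, R–M reference TSV)
plus a truth record of everything planted. Defaults are the study
conditions the statistics were designed around: 25 genomes of one 400-gene
contig (a scaled-down chromosome; only gene order matters to any statistic,
so coordinates are fixed-width 900 bp intervals on a 1 kb grid and strands
uniform); one anchor per genome with a 4.8% chance of 2–3 paralogs;
partners planted within `link_d`=3 ranks at rate `p_link`=0.916; R–M
families planted per locus at `lambda_near`=0.25 within 10 ranks of an
anchor versus `lambda_bg`=0.10 elsewhere. Those rates put 5–7 R–M domains
in a typical anchor window (about 48% of genomes) with 2–3 expected by
chance — realistic windowed counts for enriched neighborhoods. The planted
R–M reference covers Vsr (V-gene), HNH_2, MvaI_BcnI, EcoRII-C, ParBc and
C5 DNA_methylase (type II), HSDR (type I), and the multi-type ResIII
(I,III) and N6_N4_Mtase (I,II,III), following standard REBASE usage.
Background ortholog groups with a single member are pruned so emitted
cohorts re-read without warnings.

What the cohorts do **not** emulate: sequence content (no nucleotides or
residues), operonic strand structure, gene-length variation, assembly
fragmentation, or HMM score distributions; passing tests demonstrate the
statistics and their calibration, not annotation-pipeline robustness.
Architecture fixtures lay out envelope coordinates per group (with jitter)
plus boundary cases — overlapping companions, sub-threshold e-values,
duplicate focal hits — with expected calls recorded at generation time.

## Problem sizes and numerics

The test suite and the acceptance script run everything at desk scale,
chosen to keep statistical properties measurable: oracle-equivalence checks
use 20 random cohorts of ≤50 genes against naive double-loop recounts;
linkage recovery uses 500 planted anchors (three binomial standard errors);
the power experiment uses 25 genomes × 2,000 pseudogenomes at a five-fold
near/background rate ratio; the null-calibration experiment uses 1,000
replicate 3,000-gene genomes with 2–3 near-uniformly placed anchors, k=75
and 1,000 pseudogenomes each, sized from an exact hypergeometric model of
the windowed count so that the discrete p-value grid is fine enough for the
uniformity check. All randomness flows through named integer seeds
(`numpy.random.default_rng`); equal seeds reproduce every file byte for
byte. Windowed counts use prefix sums over the permuted per-locus values,
so a genome's null of S simulations costs O(S·N).

## Known limitations

- The pseudogenome null conditions on the observed gene content; it tests
  positional association only.
- Overlapping windows of paralogous anchors double-count shared loci (in
  both observed and null counts, so the test remains internally consistent).
- Pooling raw null counts across the genomes of a mix (rather than testing
  per-genome means) follows the figure-level analysis it mirrors; both
  observed and null are counts, but genomes of very different sizes
  contribute unequal null spreads.
- The genus-weighted network treats taxonomy as given; genomes lacking a
  genus are skipped with a warning rather than guessed.
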