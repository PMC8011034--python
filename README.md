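# genecontext

Gene-neighborhood context analysis for bacterial genome cohorts.

When a gene family has no characterized domain, its genomic company is often
the best evidence for its role. `genecontext` quantifies that company four
ways:

- **Linkage** — the fraction of anchor-gene regions with a partner gene
  (another ortholog group, or a domain set) within *d* gene ranks:
  `linkage(d) = n_linked / n_regions`, with unsuitable regions excluded and
  tallied. Windows of ±k genes around each anchor also feed a
  domain-frequency table (top-fraction report).
- **Pseudogenome enrichment** — an empirical null for the number of
  restriction–modification (R–M) domains within ±k genes of the anchors,
  built by uniformly permuting each genome's gene identities across its loci
  ("pseudogenomes"), re-extracting anchor windows, and recounting. Observed
  versus pooled null counts are compared with a one-tailed pooled-variance
  t-test (bands ns/*/**/***/**** at 0.05/0.01/0.001/0.0001) plus an add-one
  empirical p-value `(1 + #{null ≥ obs}) / (1 + n_sims)`.
- **Co-occurrence network** — a directed graph of domain labels in 5′→3′
  order within ±3-gene windows, edges weighted by the number of distinct
  genera exhibiting the adjacency, restricted to the R–M neighborhood.
- **Architecture groups** — rule-based classification of focal-domain
  (HEF_HK) proteins by GHKL companions: group 1 = N-terminal HATPase_c_3 +
  focal + C-terminal HATPase_c, group 2 = C-terminal only, group 3 =
  N-terminal only, group 4 = focal alone; with per-species redundancy
  collapse and taxon × group contingency tables.

A synthetic-cohort generator (`genecontext.synthetic`) plants all of this
structure — anchors, partners at a configurable linkage rate, R–M domains at
elevated near-anchor rates, a small taxonomy — and emits the same file
formats the readers consume (gene-table TSV/GFF3, HMMER3 domtblout,
OrthoMCL-style groups, taxonomy and R–M reference TSV) plus a truth record,
so the whole pipeline is testable without downloads.

## Worked example

`examples/linkage_screen.py` plants partners within 3 genes of each anchor
at rate 0.916 across 50 genomes and re-estimates the rate:

```
 d  n_regions  n_linked  linkage  n_excluded
 1         52        13 0.250000           0
 2         52        27 0.519231           0
 3         52        44 0.846154           0
 4         52        44 0.846154           0
 5         52        44 0.846154           0

planted linkage within d=3: 0.846
```

The linkage column is monotone in *d*; at the planting distance it equals
the generator's own bookkeeping (0.846) and recovers the planted 0.916 up to
binomial noise at 52 regions. `examples/rm_enrichment.py` runs the
permutation test on an enriched cohort (near-anchor R–M rate 5× background):

```
g001: observed= 7  null_mean=1.22  empirical_p=0.002
g002: observed= 5  null_mean=0.86  empirical_p=0.00399
...
mix1: t=12.00  p=1.37e-32  ****
mix2: t=10.95  p=1.32e-27  ****
```

Each genome's observed windowed R–M count sits far in the upper tail of its
2,000-pseudogenome null, and every 5-genome mix rejects at the **** band.
The other examples build the genus-weighted domain network and the
architecture-group summary (174/34/11/3 proteins in groups 1–4 → N-terminal
companion share 83.3%, C-terminal 93.7%).

There is also a thin CLI over the same functions:

```sh
genecontext simulate --n-genomes 10 --seed 1 --outdir cohort/
genecontext linkage --genes cohort/genes.tsv --groups cohort/groups.txt --d 3 --outdir out/
genecontext enrich --genes cohort/genes.tsv --domains cohort/domains.domtblout \
    --groups cohort/groups.txt --rm-reference cohort/rm_reference.tsv --outdir out/
```

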