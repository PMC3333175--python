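# Methods

## The analysis model

The pipeline treats protein percent identity between paralogs as a proxy
for duplication age: the more a pair has diverged, the older the
duplication.  Sweeping an identity criterion *t* therefore produces a
nested series of duplicate sets — at *t* = 90 only near-identical (young)
pairs qualify, while at *t* = 10 nearly every detectable paralog pair does.
Qualification uses the *maximum* of the two directional identities
(identity of the alignment relative to each gene's own length), with a
strict ">" comparison; the asymmetric pair is kept in the input because
Ensembl-style exports provide both directions and the shorter gene's
identity is systematically higher.

Families are single-linkage clusters (connected components) of qualified
pairs.  A consequence worth stating: two genes whose direct pair falls
below the criterion can still end up in one family through a chain of
qualifying pairs.  That is the intended "at least one gene in common"
clustering; complete-linkage is not implemented.

AS status is deliberately crude — more than one *known* peptide — because
it is the definition the underlying gene annotations support at scale.  It
is a gene-level property independent of the criterion; only the family
context around a gene changes across the sweep.  Genes with zero counted
peptides have undefined AS status and are excluded from the analysis
universe up front (and counted in the report warnings); paralog pairs that
touch excluded genes are dropped, also with a warning.  The alternative
`all` peptide mode (novel peptides included) reproduces the more permissive
protocol used for cross-species comparisons.

## Statistics

* **2×2 chi-squared.**  `scipy.stats.chi2_contingency` with the Yates
  continuity correction on by default, matching R's `chisq.test` behaviour
  for 2×2 tables; the uncorrected statistic is available for exact
  comparison against the textbook Σ(O−E)²/E formula (the test suite checks
  agreement to 1e-10).  Degenerate margins raise instead of returning
  nonsense.
* **Quantiles.**  Linear interpolation between order statistics (numpy's
  default, the classic "type 7"), used consistently in every boxplot-style
  export (lengths, Ka/Ks).
* **Ka/Ks.**  The ratio is formed per gene; genes missing Ka or Ks or with
  Ks ≤ 0 are excluded and reported in `excluded_kaks_count`, never silently
  dropped.
* **Mean isoform count** averages over *all* genes of a stratum (a no-AS
  gene contributes its single isoform), so strata of different AS
  proportion remain comparable on a common per-gene basis; an
  `over="as_only"` mode restricts to AS genes for sensitivity analyses.
* **GO shares** count gene–category incidences (a gene annotated with k
  categories contributes k), so a group's row is the share of annotations,
  not of genes; per-gene counting is exposed as an option.  Categories at
  or below 1% are merged into "others" (strictly-larger-than-1% survive).
  MIXED_F families are excluded from all four-group comparisons (Ka/Ks,
  length, domains, GO) but included in duplicate-level AS statistics.
* **EST profile.**  Filters are inclusive at both bounds (length ≥ 100 bp,
  aligned-region identity = matches/(matches+mismatches) ≥ 0.95).  Ties for
  best match are broken deterministically (identity, then matched bases,
  then smallest isoform id); a truly arbitrary choice would make runs
  irreproducible for no benefit.  The profile's denominator counts every
  transcript of a group's genes, hit or not.

## The synthetic generator

`synthetic_data.generate` plants the structure the statistics are meant to
detect.  Units (singletons or families) are drawn from a unit-size
distribution (default: 55% singletons, a decreasing tail over family sizes
2–12); each family gets an age *a* uniform on (0.02, 0.88], mapped to a
mean pair identity 100·(1−a) with per-pair Gaussian jitter (sd 2 identity
points).  Jitter is per pair, so a family near a threshold can be only
partially visible — deliberately exercising single-linkage on ragged
similarity.  Directional identities are emitted so their maximum equals the
single planted draw, keeping criterion visibility analytically tractable.

AS probability is p_s = 0.65 for singletons (the round figure for a
well-annotated mammalian genome) and logistic(−0.405 + 4·a − 2·1[k ≥ 8])
for a gene in a family of size k — i.e. ~40% at age 0, rising past 90% for
the oldest families, with a constant large-family penalty.  These defaults
encode the qualitative regime the pipeline is meant to resolve: AS depleted
among young duplicates, enriched among ancient ones, and uniformly rare in
large families.  AS genes carry 2 + Poisson(1.3) known peptides; every gene
also gains Poisson(0.4) novel peptides so the two peptide-status modes
differ.  Ka/Ks, protein length, domain count (negative binomial), GO
category weights and per-transcript EST rates are drawn per
(duplicate?, AS?) class with defaults ordered as the group comparisons
expect (e.g. no-AS families get the lowest EST rate, so the expression
profile can flag them as under-sampled).

`planted_expectations` returns the exact expected AS proportion per
*observed* family-size stratum: given the age, pairs of a size-k clique
qualify independently with probability q(a,t), so a gene's observed family
is its connected component in an Erdős–Rényi graph G(k, q); the
component-size law follows from the standard connected-graph recursion and
is integrated over a 400-point age grid.  Fragmentation near thresholds —
including family genes that appear as singletons — is therefore handled
exactly.

What the generator does **not** emulate: real identity distributions are
not Gaussian slices of a uniform age mixture; real families are not
cliques with i.i.d. pair identities; AS status is not independent across
family members given age; GO labels ignore the ontology DAG; EST library
biases and repeat contamination are absent.  Passing recovery tests shows
the pipeline's bookkeeping and statistics are correct under a known model,
not that the biological conclusions transfer to any particular genome.

## Sampling-noise conventions in the tests

Recovery tests compare observed AS proportions against
`planted_expectations` in units of binomial standard error.  Because genes
arrive in families that share a single age draw, per-stratum counts are
cluster-sampled and their true spread slightly exceeds the binomial SE,
noticeably so for small cohorts.  The end-to-end recovery test therefore
runs at the preset scale of 10,000 genes with the generator's default seed,
where every criterion × stratum cell is required to sit within 3 binomial
SE; the small-cohort consistency test (3 × 3,000 genes) allows a minority
of cells between 3 and 4.5 SE to absorb the design effect.  Determinism is
checked by running simulate + analyze twice at 3,000 genes and comparing
every output file byte for byte.  Cross-checks of the clustering use a
brute-force transitive-closure oracle on 200 random graphs of up to 50
nodes, and the chi-squared path is compared against the explicit formula on
1,000 random tables.

## Degenerate inputs and tie-breaks

* Family ids are the lexicographically smallest member gene id — stable
  under any input row ordering.
* Empty strata produce rows with n = 0 and null statistics rather than
  vanishing, so downstream joins stay rectangular.
* A chi-squared table with a zero margin (e.g. no duplicates at a very
  high criterion) yields null statistic and p-value in the sweep table.
* PSL records with zero aligned columns are skipped with a warning; a
  malformed PSL line fails loudly with its line number.
* Report JSON and all TSVs are written with sorted keys/rows and no
  timestamps, so identical inputs give bit-identical outputs.

## Known limitations

* One species per run; cross-species tables are assembled from per-species
  reports with `dupsplice compare`.
* No GO hierarchy traversal: categories are consumed as flat labels.
* Domain counts are consumed precomputed; no domain identification is
  performed.
* The EST identity formula ignores indel columns (matches over
  matches+mismatches); an alternative including gap columns would be
  slightly stricter and can be emulated by pre-adjusting the input PSL.
* Complete-linkage family construction is not offered.
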