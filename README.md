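# dupsplice

Gene duplication and alternative splicing (AS) are the two main routes by
which genomes diversify their protein repertoire: duplication multiplies
loci, AS multiplies isoforms per locus.  Whether the two are substitutes
(newly duplicated genes rarely splice alternatively) or companions (ancient
duplicates accumulate isoforms) depends on *when* after duplication you
look.  `dupsplice` is a toolkit for asking that question systematically: it
stratifies duplications by age using a sweep of protein percent-identity
criteria, builds paralog gene families, classifies genes by AS status, and
compares the resulting groups on every axis where duplicates and singletons
are expected to differ.

It is aimed at comparative genomicists working from Ensembl-style paralog
exports (gene pairs with directional protein identities, peptide
inventories with known/novel status, Ka/Ks from ortholog comparison, domain
counts, flat GO categories, and BLAT PSL alignments of ESTs to transcript
isoforms).

## Method

For each identity criterion *t* in a sweep (default *t* ∈ {10, 20, 30, 50,
70, 90}):

1. **Pair qualification.** A paralog pair (*a*, *b*) with directional
   identities (*i_a*, *i_b*) qualifies iff max(*i_a*, *i_b*) > *t* — at
   least one gene aligns to the other above the criterion, strict
   inequality.  High *t* keeps only young duplications; lowering *t*
   progressively admits older ones.
2. **Family construction.** Qualified pairs are clustered single-linkage:
   families are the connected components of the qualified-pair graph
   (components of size ≥ 2); all remaining genes are singletons at *t*.
3. **AS status.** A gene has AS iff it carries more than one peptide
   counted under the configured status mode (known peptides by default).
4. **Group labels.** Families whose members all have AS are A_F, families
   with none are N_F, mixed families are MIXED_F; singletons split into
   A_S / N_S.
5. **Statistics.** Per criterion: AS proportion and mean isoform count per
   family-size stratum (singleton, 2–4, 5–7, 8+); duplicate-vs-singleton
   2×2 Pearson chi-squared (Yates-corrected by default); per-group Ka/Ks
   ratio, protein length and domain-count summaries (MIXED_F excluded from
   four-group comparisons); GO category shares with categories ≤ 1% merged
   into "others".
6. **Expression profile.** ESTs ≥ 100 bp whose aligned region reaches ≥ 95%
   identity are each assigned to their best-matching isoform; the per-group
   average of EST hits per transcript flags groups whose apparent lack of
   AS may just be shallow expression sampling.

A synthetic-data generator (`dupsplice.synthetic_data`) plants this entire
structure — family sizes, family ages mapped to pair identities, an
age-dependent logistic AS model with a large-family penalty, group-specific
Ka/Ks, length, domain and EST-rate models — and provides *exact*
closed-form expectations for the AS proportion of every observed
family-size stratum at every criterion, so the whole pipeline is testable
without any downloads.

## Worked example

```sh
dupsplice simulate --n 2000 --seed 42 --out demo/data
dupsplice run \
    --genes demo/data/genes.tsv --peptides demo/data/peptides.tsv \
    --pairs demo/data/pairs.tsv --kaks demo/data/kaks.tsv \
    --est demo/data/est.psl --isoform-map demo/data/isoform_map.tsv \
    --out demo/report
```

prints

```
synthetic dataset (2000 genes, seed 42) written to demo/data
report written to demo/report (2000 genes)
```

and `demo/report/report.json` then contains, among others:

```
criterion >90: 173 duplicates (40.5% AS) vs 1827 singletons (70.9% AS),
               chi-squared 66.09, p = 4.3e-16
criterion >10: 1506 duplicates (70.3% AS) vs 494 singletons (62.1% AS),
               chi-squared 10.91, p = 9.6e-4
```

This is the planted age-dependent pattern recovered end to end: at a high
identity criterion (young duplicates only) AS is significantly *depleted*
among duplicates, while once ancient duplicates are included (criterion
>10) the association reverses and duplicates are significantly *enriched*
for AS.  The accompanying TSVs (`proportions.tsv`, `chisq.tsv`, `kaks.tsv`,
`lengths.tsv`, `go_mf.tsv`, `go_bp.tsv`, `est_profile.tsv`, …) hold the
full stratified tables; `--plots` adds PNG figures.  Multi-species runs can
be merged with `dupsplice compare report1.json report2.json --out table.tsv`.

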