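# duonorm

Dual-normalization consensus analysis for two-group microarray designs.

Probe-level intensity data is pushed through two independent
normalization routes — an MAS5-like route (trimmed-mean array scaling +
one-step Tukey-biweight summarization) and an RMA route (normexp
background correction + quantile normalization + median-polish
summarization).  Each route gets empirical-Bayes moderated t-statistics
and a pareto-scaled two-class OPLS-DA model with jack-knifed VIP
confidence intervals.  A probeset becomes a *candidate* only when it
behaves consistently under both routes:

1. its correlation loadings Cor(T_P, x) share the same sign in both models,
2. the loading pair lies within radius r = 0.75 of the shared corner of
   the [-1, 1]&sup2; loading square,
3. VIP > 1.0 in both models, and
4. the jack-knifed lower VIP confidence bound is >= 0 in both models.

Candidates are ranked by the sum of the two moderated-t p-values and
split into direction-specific top-200 subsets.  Downstream stages:

- **enrich** — EASE-score overrepresentation with Cohen-kappa term
  clustering (EASE < 0.01, kappa 0.7, >= 3 terms/cluster, >= 5 genes/term)
  and complete-linkage heat-map ordering;
- **profiles** — k-means clustering (k = 6, 1000 restarts) of
  cross-experiment log2 fold-change profiles per normalization with
  exact one-to-one cluster matching by Jaccard overlap and
  up/down/unchanged sign patterns (|log2fc| < 0.10 = unchanged);
- **footprint** — conserved PWM hits in 2000-base upstream promoter
  windows via global affine-gap alignment against an ortholog, with
  one-sided Fisher enrichment (significant at p < 0.0005);
- **pcrstats** — 2^-ddCt relative expression and ChIP percent-input
  statistics with seeded Monte-Carlo Dunnett many-to-one comparisons.

A fully seeded synthetic-data module (`duonorm.synthdata`) generates
every input with planted ground truth (differential probesets, enriched
annotation modules, conserved promoter motifs, qPCR fold changes), so
the whole pipeline is testable for parameter recovery.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria.  One test
(`test_supplementary_bookkeeping_targets`) requires the article's
supplementary candidate tables, which are journal supplements and are not
redistributed here; place them under `data/supplementary/` (S1/S2/S3/S10
as `.tsv` or `.xlsx`) to evaluate it — without them it fails with a
diagnostic explaining the missing inputs.

## CLI

```sh
duonorm synth --seed 1 --n-probesets 2000 --outdir out        # probe-level TSV + truth
duonorm normalize out/probes.tsv --outdir out                 # both expression matrices
duonorm destats out/expr_rma.tsv --outdir out                 # moderated t statistics
duonorm oplsda out/expr_rma.tsv --outdir out                  # VIP + jack-knife CIs
duonorm select --mas mas.tsv --rma rma.tsv --outdir out       # consensus candidates
duonorm profiles profiles.tsv --outdir out                    # k-means fold-change profiles
duonorm enrich genes.txt terms.gmt --outdir out               # EASE/kappa clusters
duonorm footprint promoters.fasta motifs.jaspar --candidates cand.txt --outdir out
duonorm pcr ct.tsv GeneX --outdir out                         # ddCt + Dunnett
duonorm run-all --seed 1 --outdir out                         # full 3-experiment workflow
```

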