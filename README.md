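# cerna-moml

Regulator-mediated competing endogenous RNA (ceRNA) network inference
from multi-omics tumour cohorts.

## The problem

The ceRNA hypothesis holds that mRNAs and lncRNAs sharing miRNA response
elements compete for a common pool of miRNAs and thereby co-regulate each
other: when two transcripts are repressed by the same miRNAs, their
expression is positively correlated, and that correlation collapses once
the shared miRNA pool is accounted for. Classical ceRNA screens treat
miRNAs as the only regulator of expression; this package additionally
conditions each gene's expression on its copy-number alteration (CNA),
DNA-methylation β value (DM), and candidate transcription factors (TFs),
so that only miRNA effects surviving those covariates feed the network.

It is written for computational biologists who have per-cohort expression
counts, gene-level CNA/DM matrices, and candidate interaction tables
(miRNA→mRNA, miRNA→lncRNA, TF→gene) and want tested, scriptable building
blocks rather than a monolithic web tool.

## The method

Per cohort, four stages:

1. **Differential expression** — low-count filter (log₂-CPM < 1 in more
   than half the samples), TMM library normalization, voom-style log-CPM
   with mean–variance precision weights, empirical-Bayes moderated
   t-statistics; features pass at |log₂FC| > 1 and BH FDR < 0.01.
2. **Regulator selection** — for each DE mRNA, a LASSO model

   `mRNA ~ CNA + DM + miRNA expression + TF expression`

   (lncRNAs: miRNA terms only), minimizing
   `(1/2n)‖y − Xβ‖² + λ‖β‖₁` with λ chosen by 10-fold cross-validation.
   Each model is refit 100 times with reshuffled folds; predictors
   non-zero in more than 75 runs are retained and then confirmed by a
   case-resampling bootstrap (percentile CI excluding zero). The
   significant miRNA predictors of each target define its miRNA set.
3. **ceRNA pair calling** — every pair of targets sharing at least one
   miRNA is scored with three conjunctive filters: Pearson r > 0.40,
   hypergeometric shared-miRNA p < 0.05, and multiple sensitivity
   correlation `mscor = cor(x,y) − pcor(x,y | shared miRNAs)` with a
   one-sided permutation p, BH-adjusted across pairs, < 0.05.
4. **Cross-cohort analysis** — passed pairs are keyed as
   `idA_idB` (lexicographic) and intersected across cohorts via a one-way
   frequency table; genes shared by a cohort combination are screened for
   prognosis (median-dichotomized expression, Kaplan–Meier/log-rank,
   Cox hazard ratios) and for gene-set enrichment (hypergeometric test
   against user GMT sets).

A synthetic-cohort generator (`cerna_moml.synthetic_data`) plants a known
ceRNA architecture — negative-binomial counts with group effects,
tumour-sample CNA/DM matrices, decoy interaction wiring, shared-miRNA
sponge pairs with negative coefficients, expression-linked survival — so
the whole pipeline is testable end to end without any download.

## Worked example

Recover a planted network from a simulated cohort (200 tumour samples,
50 mRNAs, 30 miRNAs, 10 planted pairs):

```python
import numpy as np
from cerna_moml import (SimulationConfig, simulate_cohort,
                        truth_recovery_report, infer_network,
                        build_mirna_maps)
from cerna_moml.pipeline import DEFAULT_PARAMS, select_regulators_for_cohort

cfg = SimulationConfig(seed=1, n_tumour=200, n_mrna=50, n_mirna=30,
                       n_cerna_pairs=10)
cohort = simulate_cohort(cfg)

de = {"mRNA":  {f for f in cohort.expression.index if f.startswith(("ENSG", "TF"))},
      "lncRNA": {f for f in cohort.expression.index if f.startswith("ENSL")},
      "miRNA": {f for f in cohort.expression.index if f.startswith("MIR")}}
models = select_regulators_for_cohort(cohort.expression, cohort.regulators,
                                      de, dict(DEFAULT_PARAMS),
                                      np.random.default_rng(1))
net = infer_network(cohort.expression, build_mirna_maps(models),
                    cohort.counts.feature_class, n_perm=500,
                    rng=np.random.default_rng(51))

pairs, unique = net.summary()
print(f"passed pairs: {pairs}  unique RNAs: {unique}")
print(net.to_frame().head(3).to_string(index=False))
print(truth_recovery_report(net, cohort.truth))
```

prints

```
passed pairs: 10  unique RNAs: 20
         pair_key    rna_a    rna_b  shared_mirna_count  pearson_r  hypergeom_p    mscor  mscor_p_adj
ENSG0001_ENSG0002 ENSG0001 ENSG0002                   3   0.579788     0.000246 0.579002     0.001996
ENSG0003_ENSG0004 ENSG0003 ENSG0004                   3   0.510088     0.000246 0.720140     0.001996
ENSG0005_ENSL0001 ENSG0005 ENSL0001                   3   0.715763     0.000246 0.696327     0.001996
{'sensitivity': 1.0, 'observed_fdr': 0.0}
```

All ten planted pairs pass all three filters (sensitivity 1.0) with no
false pairs (observed FDR 0.0). Each pair shares its three planted
miRNAs; the mscor column shows how much of the partners' correlation is
explained by the shared pool.

The same run is available from the shell:

```bash
cerna-moml simulate --seed 1 --out cohort1/
cerna-moml run-all --config config.yaml     # diffexpr → models → network → intersect → survival
```

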