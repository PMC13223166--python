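# lymphmap

Probabilistic mapping of lymph-node metastasis (LNM) patterns in epithelial
ovarian cancer.

Systematic lymphadenectomy removes nodes from many anatomical stations, but
which stations are involved — and in what order disease tends to spread
between them — is not random. `lymphmap` implements a reusable pipeline for
analysing patient-level lymphadenectomy data over a 14-zone pelvic /
para-aortic atlas (paired common / external / internal iliac, obturator,
superficial inguinal and para-aortic stations, presacral, and distant
nodes):

* **Cohort statistics** — Youden-index dichotomization of continuous
  predictors (J = sensitivity + specificity − 1), χ² and Mann–Whitney group
  comparisons, odds ratios with Woolf confidence intervals
  (exp(ln OR ± 1.96·√Σ 1/nᵢ)) and the Haldane–Anscombe +0.5 correction for
  zero cells, and forward-stepwise logistic regression with
  likelihood-ratio entry tests.
* **Regional mapping** — per-zone shares of positive nodes and of
  node-positive patients, the overall node positivity rate, resection
  summaries, and laterality stratification.
* **Bayesian-network engine** — discrete DAGs scored by BIC
  (log-likelihood − (ln n)/2 per free parameter), steepest-ascent
  hill-climbing structure search with add/delete/reverse operators,
  maximum-likelihood conditional probability tables, and exact inference
  by variable elimination.
* **Consensus + pathway rule** — bootstrap edge strength (the fraction of
  resampled structure-learning runs containing each edge), pairwise zone
  co-occurrence probabilities, and the dual-criterion rule: a connection is
  a high-probability metastatic route iff its edge strength ≥ τ (default
  0.6), its co-occurrence ranks in the top q (default 30%) of all 91 zone
  pairs, **and** the pair is anatomically plausible per an explicit,
  editable adjacency list. Highlighted graphs are labelled into hubs,
  terminals and intermediates and reported as ordered chains.
* **Synthetic cohorts** — a generator that samples zone involvement
  ancestrally from a known truth DAG (with planted routes, clinical
  covariate effects, laterality mixtures and negative-binomial resection
  counts), so every downstream stage can be validated against ground truth.

The estimators follow scikit-learn conventions (`fit`, fitted attributes
with trailing underscores, `get_params`/`set_params`): see
`DiscreteBayesianNetwork`, `BootstrapEdgeConsensus`, `YoudenBinarizer`,
`ForwardStepwiseLogistic` and the end-to-end `MetastasisPathwayModel`.

## Worked example

```python
from lymphmap import datasets, odds_ratio_2x2
from lymphmap.simulate import default_config, plant_pathway, generate_lnm_cohort, ZONE_COLS
from lymphmap.pathways import MetastasisPathwayModel

# association statistics from published aggregate 2x2 counts
res = odds_ratio_2x2(datasets.RISK_FACTOR_TABLES["tumor_lateralization"])
print(f"bilateral-tumour OR: {res.odds_ratio:.2f} (95% CI {res.ci_low:.2f}-{res.ci_high:.2f})")

# synthetic cohort with a planted external->internal->common iliac route
cfg = plant_pathway(default_config(n_patients=400, seed=1), [3, 5, 1], 0.9)
cohort = generate_lnm_cohort(cfg, 300)
model = MetastasisPathwayModel(B=100, tau=0.6, q=0.3, random_state=1).fit(cohort[ZONE_COLS])
for (u, v), (strength, cooc) in sorted(model.pathway_.highlighted_edges.items()):
    print(f"route {u} -> {v}: strength {strength:.2f}, co-occurrence {cooc:.2f}")
print("chains:", model.chains_)
```

prints

```
bilateral-tumour OR: 3.83 (95% CI 2.77-5.31)
route 2 -> 6: strength 1.00, co-occurrence 0.29
route 3 -> 5: strength 1.00, co-occurrence 0.33
route 5 -> 1: strength 1.00, co-occurrence 0.31
route 6 -> 4: strength 1.00, co-occurrence 0.32
route 8 -> 10: strength 1.00, co-occurrence 0.24
route 11 -> 12: strength 1.00, co-occurrence 0.48
chains: [(2, 6, 4), (3, 5, 1), (8, 10), (11, 12)]
```

The odds ratio says bilateral primary tumours carry ~3.8-fold higher odds of
nodal metastasis than unilateral ones in the reference cohort. The route
lines are the planted chain 3→5→1 plus the other edges of the default truth
structure, each recovered in every bootstrap resample (strength 1.00) with
its co-occurrence probability among node-positive patients; the chains join
highlighted edges into maximal directed paths.

A `lymphmap` command-line tool wraps the same stages
(`simulate`, `table1`, `regress`, `map`, `learn`, `bootstrap`, `cooccur`,
`pathways`, `augment`, `query`, `run-all`); `lymphmap run-all cohort.csv
--out-dir reports/` writes the full TSV/JSON/DOT report bundle,
reproducibly for a given config and seed.

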