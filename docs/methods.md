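# Methods

This note documents the models, estimators and numerical choices behind
`lymphmap`, and what the synthetic-cohort experiments do and do not show.

## Data model

A cohort is a table with one row per patient: clinical covariates (age,
menopausal status, parity, CA125, HE4, ascites volume, tumour size, grade,
histological subtype, FIGO stage, tumour laterality, neoadjuvant
chemotherapy), binary involvement of 14 anatomical nodal zones, and
per-zone counts of resected and histologically positive nodes. Row
invariants are enforced on read: `positive ≤ resected` per zone,
involvement ⇔ `positive ≥ 1`, and the structural zero that stage I–II
patients have no involved zone (nodal involvement upstages to III by
definition). Analyses are complete-case.

The 14 zones are: 1/2 left/right common iliac, 3/4 external iliac, 5/6
internal iliac, 7/8 obturator, 9/10 superficial inguinal, 11/12
para-aortic, 13 presacral, 14 distant.

## Cohort statistics

* **Dichotomization.** Continuous predictors are cut at the observed value
  maximizing the Youden index J = sensitivity + specificity − 1, with the
  rule "positive iff value ≥ threshold" and ties broken toward the
  smallest threshold; candidates are restricted to observed values so the
  cut is data-determined. Fixed clinical cut-offs ship as defaults: CA125
  264.5 U/mL, HE4 148.5 (postmenopausal) / 122.2 (premenopausal), ascites
  90 mL, age 50 years, tumour size 100 mm.
* **2×2 measures.** OR = (n₁₁n₀₀)/(n₁₀n₀₁) with the Woolf log-normal 95%
  interval; zero cells use Haldane–Anscombe +0.5 with a flag rather than
  reporting an unbounded estimate (relevant to structural-zero tables such
  as FIGO stage vs nodal status). χ² is Pearson without continuity
  correction (a flag enables the Yates variant); Mann–Whitney uses midrank
  ties with exact enumeration for small tie-free samples and the
  tie-corrected normal approximation otherwise (via scipy).
* **Logistic regression.** Newton/IRLS, convergence at score norm < 1e-8,
  at most 100 iterations; monotone likelihood (separation) is declared
  when any |β| exceeds 15 and flagged instead of iterating to infinity.
  Forward stepwise selection is entry-only: at each step the candidate
  with the smallest likelihood-ratio p-value enters if p < α_in (default
  0.05). The per-candidate entry probability under the null is ≈ α_in, so
  the chance of a spurious entry compounds with the candidate count — the
  procedure controls per-test, not family-wise, error, which is why it is
  treated as exploratory. A separated binary candidate falls back to the
  Haldane-corrected 2×2 estimate; other separated candidates are skipped
  with a warning.

## Regional mapping

Two distributions summarize zone involvement: the node-level share
(positive nodes in a zone / all positive nodes, summing to 1) and the
patient-level share (node-positive patients with the zone involved /
node-positive patients — deliberately **not** the whole cohort; a
whole-cohort variant is available for sensitivity analysis). The overall
positivity rate is total positive / total resected nodes. Resection
summaries report per-zone totals, patients with any node removed, and
median (min, max) per patient, with empty zones reported as median 0.
Patients treated with neoadjuvant chemotherapy are excluded before mapping
and network stages by default, since chemotherapy can sterilize nodes and
distort the spread pattern; a flag retains them.

## Bayesian-network engine

Zone involvement indicators are modelled as a discrete Bayesian network.
Scoring is BIC in the higher-is-better convention: the maximized
log-likelihood minus (ln n)/2 per free parameter, with 0·ln 0 = 0. The
score decomposes over nodes; local scores are cached by (node, parent set)
and a cache entry always equals recomputation.

Structure search is steepest-ascent hill climbing over add / delete /
reverse operators, acyclicity-preserving, applying the single best
strictly-improving operator per step (improvement tolerance 1e-10 to avoid
floating-point cycling). Tie-breaking is deterministic — operator type
add < delete < reverse, then (parent, child) position — so a seed fully
determines the result. Optional seeded random restarts perturb the
starting graph (random permutation order, edge probability 2/(k−1)) and
the best-scoring run wins. `max_indegree` is unlimited by default (14
binary nodes) and configurable for the clinical-augmented network.

Parameters are maximum-likelihood by default ((count + α)/(total + α·r)
with α = 0); unseen parent configurations yield uniform rows with a logged
flag, and α = 1 is available when inference must avoid zero-probability
evidence. Inference is exact variable elimination with a min-degree
ordering; a brute-force full-joint route (tractable at 2¹⁴ states) is kept
as an independent cross-check, and an exhaustive enumerator of all
labelled DAGs on ≤ 4 nodes (1, 3, 25, 543) serves as the oracle for the
search.

## Bootstrap consensus and the pathway rule

Edge strength is the fraction of B bootstrap resamples (rows resampled
with replacement, seeded) whose learned structure contains the edge.
B defaults to 200. Both the per-orientation (directed) frequency and the
appearance (undirected) frequency are recorded; appearance always
dominates either orientation.

Co-occurrence between two zones is the fraction of patients with both
involved, computed over node-positive patients by default (the mapping
denominator; an all-patients mode exists). The top-q rule ranks all
C(14,2) = 91 pairs and keeps ceil(q·91), including ties at the cut.

A connection is highlighted as a high-probability route iff (1) its
bootstrap strength ≥ τ (default 0.6), (2) its pair is in the top-q
co-occurrence set (default 0.3), and (3) the pair is in the atlas
adjacency list. Rejections are recorded with the first failing criterion
in the fixed order strength → co-occurrence → adjacency.

**Which frequency the τ threshold applies to is a real design choice.**
The τ threshold is applied to the *appearance* frequency, with the drawn
orientation being the majority direction — the strength/direction split
used in bootstrap model averaging. The reason is identifiability: a chain
A→B→C and its reorientations without new colliders are Markov-equivalent,
so the score cannot prefer one orientation and per-orientation frequencies
of a true chain edge can split roughly in half across resamples. In
simulation, thresholding per-orientation frequencies at τ = 0.6 lost
planted chain edges in 9 of 10 seeds while appearance-thresholding
recovered all planted connections in 10 of 10; the per-orientation
convention remains available (`strength_mode="directed"`), and directed
frequencies are always reported alongside. For the same reason, reported
edge directions are consensus orientations, not causal claims.

Node labels on the highlighted graph: hub (total degree ≥ 3 — the
threshold is a package choice, configurable), terminal (incoming but no
outgoing highlighted edge), intermediate (any other connected node),
isolated; precedence hub > terminal > intermediate > isolated. Chains are
all maximal simple directed paths, longest first; a cycle (possible after
aggregating edges across resamples) is broken by dropping the
lowest-strength edge with a logged note.

The anatomical adjacency list is explicit and editable: chain neighbours
along the iliac vessels, the contralateral common-iliac, obturator,
inguinal and para-aortic pairs, obturator links to the iliac chains and to
inguinal/presacral stations, the common-iliac → para-aortic continuation,
and para-aortic / common-iliac access to the distant station. "Distant" is
operationally "not in the adjacency list".

## Clinical augmentation

Eight covariates join the network by default — age, menopausal status,
CA125, HE4, FIGO stage, grade, tumour size, histological subtype —
discretized at the fixed clinical cut-offs above (grade keeps its three
levels; subtype and stage are binary). Structure learning and
bootstrapping run exactly as for the zone-only network, with
clinical↔zone edges permitted in both directions unless a blacklist is
configured; single-state variables are dropped with a warning (FIGO stage
is always single-state among node-positive patients because of the
structural zero). Conditional-probability reports answer exact posterior
queries row by row, flagging inconsistent evidence instead of failing.

## Synthetic cohorts

The generator emulates the cohort the analysis expects. Zone involvement
is sampled ancestrally, in topological order with ties broken by zone id,
from a configurable truth DAG and CPTs, so a seed fully determines a
cohort. The default truth has six strong, anatomically adjacent edges
(3→5, 5→1, 4→6, 6→2, 11→12, 8→10) with P(child involved | parent
involved) = 0.85 and baseline 0.05, and root marginals between 0.08 and
0.5 (highest for the left para-aortic zone, the most frequently involved
station). `plant_pathway` adds a route with chosen strength;
covariate-to-zone effects are additive log-odds shifts applied during
sampling, which makes planted conditional probabilities exact by
construction (e.g. baseline 0.5 plus a shift of ln(0.875/0.125) for
grade-3 cases plants P = 0.875 exactly).

Clinical covariates are marginally independent unless effects are planted
(no joint covariate distribution is assumed): age ~ Normal(53, 10),
biomarkers and tumour size log-normal with location/scale chosen so the
fraction above each clinical cut-off matches a surgical EOC cohort
(~60% CA125-high, ~62% HE4-high, ~60% ascites-high, median size ~90 mm),
grade mix 6/10/84%, ~34% serous, laterality mixture (0.18 left, 0.24
right, 0.58 bilateral) echoing a node-positive mapping cohort, and a 19%
neoadjuvant-treatment rate. Ascites volume is treated as a generic
positive continuous variable. Resected counts are negative-binomial per
zone (means 1.7–5.3, dispersion 1.2, echoing observed per-patient medians
of 0–4 with para-aortic stations yielding the most nodes); positives are
one plus a Binomial(resected − 1, 0.25) thinning when a zone is involved.
FIGO is assigned after zone sampling — any involvement forces III–IV,
uninvolved patients are advanced with probability 0.36 — preserving the
structural zero.

**What passing tests show.** Synthetic cohorts reproduce the marginal and
conditional structures named in the configuration and nothing else: no
spatial correlation beyond the truth DAG, no covariate co-dependence, no
informative missingness, no inter-rater variation in pathology. Recovery
results on them validate the machinery (search, bootstrap, rule), not any
claim about real lymphatic anatomy.

## Problem sizes and numerical choices

The shipped experiments use: 20 random 4-variable datasets (n = 300,
20 restarts) against the 543-DAG oracle; 50 random networks of ≤ 6 binary
nodes for inference cross-checks (agreement within 1e-9); 10 seeds at
n = 2000 for skeleton-F1 recovery of the 6-edge truth (median F1 observed
at 1.0, threshold 0.8); n = 2000 for planted-conditional recovery
(±0.05); and 10 seeds × 300 node-positive patients × B = 100 for
end-to-end route recovery. These sizes make the whole validation run in
tens of seconds while leaving the statistical margins wide.

Probabilities are clipped to [1e-9, 1 − 1e-9] only where a log-odds shift
is applied to a degenerate CPT entry; CPT rows must sum to 1 within 1e-9;
Woolf intervals use 1.96 exactly. Bootstrap resampling, restarts and the
cohort generator all draw from `numpy.random.default_rng` seeded
explicitly; the pipeline derives stable per-stage seeds from one global
seed so stages can be rerun independently.

## Known limitations

* Orientation of highlighted edges within a Markov-equivalence class is a
  consensus of tie-breaks, not evidence of direction of spread.
* Bootstrap CPTs are not model-averaged; only edge presence is
  aggregated.
* The engine is discrete-only (no continuous or hybrid nodes, no CPDAG
  search, no approximate inference) and the atlas adjacency list, while
  editable, is a modelling assumption rather than measured anatomy.
* Stepwise selection and data-derived Youden cut-offs both overfit the
  cohort they are computed on; results are exploratory by design.
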