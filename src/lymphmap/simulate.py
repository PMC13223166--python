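"""Synthetic patient cohorts with known lymphatic-spread structure.

The generator emulates the data layout of a retrospective epithelial
ovarian cancer lymphadenectomy cohort: per-patient clinical covariates,
binary involvement of the 14 nodal zones, and per-zone resected / positive
node counts.  Zone involvement is sampled ancestrally from a known truth
DAG with explicit conditional probability tables, so structure-learning and
pathway-extraction stages can be validated against planted ground truth.

Key mechanics
-------------
* Ancestral sampling in a fixed topological order (ties broken by zone id),
  so a seed fully determines the cohort.
* Clinical covariates are drawn marginally independent by default; planted
  covariate -> zone effects act as additive log-odds shifts on the child
  zone's conditional probability.
* Resected node counts per zone follow a negative-binomial-shaped integer
  distribution; positives are allocated by thinning when a zone is involved
  (at least one positive node, never more than resected).
* FIGO stage is assigned after zone sampling: any nodal involvement forces
  stage III-IV; uninvolved patients are advanced-stage with a configurable
  probability, preserving the structural zero (no stage I-II patient is
  node-positive).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ZoneAtlas, default_atlas
from .bayesnet import Cpt, Dag

__all__ = [
    "ClinicalEffect",
    "CovariateModel",
    "SimulationConfig",
    "default_config",
    "make_zone_cpts",
    "plant_pathway",
    "generate_cohort",
    "generate_lnm_cohort",
]

ZONE_COLS = [f"zone_{i:02d}" for i in range(1, 15)]
RESECTED_COLS = [f"resected_{i:02d}" for i in range(1, 15)]
POSITIVE_COLS = [f"positive_{i:02d}" for i in range(1, 15)]

#: Per-zone mean resected-node counts, echoing observed per-patient medians
#: of 0-4 nodes per station (para-aortic stations yield the most nodes).
DEFAULT_RESECTED_MEANS = {
    1: 2.0, 2: 2.1, 3: 2.1, 4: 2.0, 5: 2.0, 6: 1.9, 7: 2.8,
    8: 3.1, 9: 1.7, 10: 1.8, 11: 5.3, 12: 4.6, 13: 1.9, 14: 1.9,
}


@dataclass(frozen=True)
class ClinicalEffect:
    """A planted covariate -> zone effect.

    The indicator is 1 when the (raw) covariate satisfies the condition:
    ``value >= threshold`` for numeric covariates, ``value == level`` for
    categorical ones.  While sampling the target zone, ``log_odds`` is added
    to the logit of its conditional involvement probability for patients
    with indicator 1.
    """

    covariate: str
    zone: int
    log_odds: float
    threshold: float | None = None
    level: str | None = None

    def indicator(self, values: pd.Series) -> np.ndarray:
        if self.level is not None:
            return (values == self.level).to_numpy()
        if self.threshold is not None:
            return (values.astype(float) >= self.threshold).to_numpy()
        return values.astype(float).to_numpy() > 0


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions for the clinical covariates.

    Continuous biomarkers are log-normal (location/scale on the log scale);
    categorical covariates carry explicit class probabilities.  Defaults
    echo the marginal frequencies of a surgical EOC cohort: median age 53,
    ~46% postmenopausal ("menopause" = menstruation ceased), CA125/HE4
    predominantly elevated, median tumour size ~90 mm.
    """

    age_mean: float = 53.0
    age_sd: float = 10.0
    menopause_prob: float = 0.465
    parity_probs: tuple[float, float, float] = (0.077, 0.676, 0.247)  # 0, 1-3, >3
    ca125_log_mu: float = 5.96
    ca125_log_sigma: float = 1.5
    he4_log_mu: float = 5.2
    he4_log_sigma: float = 1.0
    ascites_log_mu: float = 4.79
    ascites_log_sigma: float = 1.3
    tumor_size_log_mu: float = 4.52
    tumor_size_log_sigma: float = 0.60
    grade_probs: tuple[float, float, float] = (0.06, 0.10, 0.84)  # G1, G2, G3
    serous_prob: float = 0.344


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one synthetic cohort.

    Parameters
    ----------
    n_patients
        Cohort size.
    seed
        Global seed; a config plus a seed fully determines the cohort.
    truth_dag, truth_cpts
        Ground-truth spread structure over the 14 zone variables.
    laterality_probs
        (left, right, bilateral) mixture for the primary tumour; defaults
        echo a node-positive mapping cohort (38/50/122 of 210).
    clinical_model
        Marginal covariate distributions.
    clinical_effects
        Planted covariate -> zone log-odds shifts (empty by default).
    resected_means, resected_dispersion
        Negative-binomial resected-count model per zone (dispersion is the
        NB size parameter; smaller = more overdispersed).
    positive_thinning
        Extra positives beyond the first follow Binomial(resected-1, p).
    nact_prob
        Probability of neoadjuvant chemotherapy.
    advanced_if_negative_prob
        P(FIGO III-IV) for patients without nodal involvement (involved
        patients are always III-IV).
    """

    n_patients: int = 500
    seed: int = 0
    truth_dag: Dag = None  # type: ignore[assignment]
    truth_cpts: dict[str, Cpt] = None  # type: ignore[assignment]
    laterality_probs: tuple[float, float, float] = (38 / 210, 50 / 210, 122 / 210)
    clinical_model: CovariateModel = field(default_factory=CovariateModel)
    clinical_effects: tuple[ClinicalEffect, ...] = ()
    resected_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RESECTED_MEANS)
    )
    resected_dispersion: float = 1.2
    positive_thinning: float = 0.25
    nact_prob: float = 0.193
    advanced_if_negative_prob: float = 0.36
    atlas: ZoneAtlas = field(default_factory=default_atlas)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if abs(sum(self.laterality_probs) - 1.0) > 1e-9:
            raise ValueError(
                f"laterality_probs must sum to 1, got {self.laterality_probs}"
            )
        if self.truth_dag is None or self.truth_cpts is None:
            raise ValueError("config is missing truth_dag / truth_cpts")
        try:
            self.truth_dag.topological_order()
        except ValueError as exc:
            raise ValueError(f"truth_dag is not acyclic: {exc}") from exc
        for v in self.truth_dag.nodes:
            if v not in self.truth_cpts:
                raise ValueError(f"truth_cpts missing node {v!r}")
            cpt = self.truth_cpts[v]
            if tuple(cpt.parents) != self.truth_dag.parents(v):
                raise ValueError(f"CPT parents of {v!r} do not match truth_dag")
            if not np.allclose(cpt.table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {v!r} do not sum to 1")
        if not (0.0 <= self.nact_prob <= 1.0):
            raise ValueError("nact_prob must be in [0, 1]")


# ---------------------------------------------------------------------------
# Truth-structure construction helpers


def make_zone_cpts(dag: Dag, root_probs: dict[str, float],
                   strength: float = 0.85, baseline: float = 0.05) -> dict[str, Cpt]:
    """Noisy-OR-style binary CPTs for a zone DAG.

    Roots get their marginal from ``root_probs`` (default ``baseline``).
    A child is involved with probability ``strength`` if any parent is
    involved and ``baseline`` otherwise.
    """
    cpts: dict[str, Cpt] = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        if not parents:
            p1 = float(root_probs.get(v, baseline))
            table = np.array([[1 - p1, p1]])
        else:
            q = 2 ** len(parents)
            table = np.empty((q, 2))
            for row in range(q):
                bits = [(row >> (len(parents) - 1 - k)) & 1 for k in range(len(parents))]
                p1 = strength if any(bits) else baseline
                table[row] = [1 - p1, p1]
        cpts[v] = Cpt(v, parents, 2, (2,) * len(parents), table)
    return cpts


#: Default planted spread structure: six strong chain edges that are all
#: anatomically adjacent (external iliac -> internal iliac -> common iliac on
#: the left, external -> internal -> common on the right, the para-aortic
#: cross-over, and obturator -> inguinal).
DEFAULT_TRUTH_EDGES: tuple[tuple[int, int], ...] = (
    (3, 5), (5, 1), (4, 6), (6, 2), (11, 12), (8, 10),
)

DEFAULT_ROOT_PROBS: dict[str, float] = {
    "zone_03": 0.35, "zone_04": 0.35, "zone_08": 0.30, "zone_11": 0.50,
    "zone_07": 0.25, "zone_09": 0.10, "zone_13": 0.10, "zone_14": 0.08,
}


def default_truth_dag(edges=DEFAULT_TRUTH_EDGES) -> Dag:
    return Dag(ZONE_COLS, [(f"zone_{u:02d}", f"zone_{v:02d}") for u, v in edges])


def default_config(n_patients: int = 500, seed: int = 0, strength: float = 0.85,
                   baseline: float = 0.05, **overrides) -> SimulationConfig:
    """The standard study conditions: 6-strong-edge truth DAG over 14 zones."""
    dag = default_truth_dag()
    cpts = make_zone_cpts(dag, DEFAULT_ROOT_PROBS, strength=strength, baseline=baseline)
    cfg = SimulationConfig(
        n_patients=n_patients, seed=seed, truth_dag=dag, truth_cpts=cpts, **overrides
    )
    cfg.validate()
    return cfg


def plant_pathway(config: SimulationConfig, route, strength: float,
                  baseline: float = 0.05) -> SimulationConfig:
    """Return a config whose truth contains the consecutive edges of ``route``.

    ``route`` is an ordered list of zone ids (length >= 2).  For each edge
    the child's CPT is rebuilt with ``P(child=1 | any parent=1) = strength``
    and ``P(child=1 | all parents=0) = baseline``.  A route edge that would
    close a directed cycle raises, naming the offending edge.
    """
    if len(route) < 2:
        raise ValueError("route must contain at least 2 zones")
    for z in route:
        if not 1 <= int(z) <= 14:
            raise ValueError(f"invalid zone id {z}")
    dag = config.truth_dag.copy()
    touched: set[str] = set()
    for u, v in zip(route, route[1:]):
        pu, pv = f"zone_{u:02d}", f"zone_{v:02d}"
        if not dag.has_edge(pu, pv):
            try:
                dag.add_edge(pu, pv)
            except ValueError as exc:
                raise ValueError(
                    f"route edge {u}->{v} would close a directed cycle"
                ) from exc
        touched.add(pv)
    cpts = dict(config.truth_cpts)
    root_probs = {
        v: c.table[0, 1] for v, c in cpts.items() if not c.parents
    }
    for v in dag.nodes:
        if dag.parents(v) != config.truth_dag.parents(v) or v in touched:
            sub = Dag(dag.nodes, [(p, v) for p in dag.parents(v)])
            cpts[v] = make_zone_cpts(sub, root_probs, strength, baseline)[v]
    cfg = replace(config, truth_dag=dag, truth_cpts=cpts)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Cohort generation


def _sample_covariates(cm: CovariateModel, n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(cm.age_mean, cm.age_sd, n), 20, 90).round(1)
    menopause = (rng.random(n) < cm.menopause_prob).astype(int)
    parity = rng.choice(["0", "1-3", ">3"], size=n, p=cm.parity_probs)
    ca125 = np.exp(rng.normal(cm.ca125_log_mu, cm.ca125_log_sigma, n)).round(1)
    he4 = np.exp(rng.normal(cm.he4_log_mu, cm.he4_log_sigma, n)).round(1)
    ascites = np.exp(rng.normal(cm.ascites_log_mu, cm.ascites_log_sigma, n)).round(0)
    size = np.exp(rng.normal(cm.tumor_size_log_mu, cm.tumor_size_log_sigma, n)).round(0)
    grade = rng.choice(["G1", "G2", "G3"], size=n, p=cm.grade_probs)
    histology = np.where(rng.random(n) < cm.serous_prob, "serous", "non-serous")
    return pd.DataFrame(
        {
            "age": age,
            "menopause": menopause,
            "parity": parity,
            "ca125": ca125,
            "he4": he4,
            "ascites_ml": ascites,
            "tumor_size_mm": size,
            "grade": grade,
            "histology": histology,
        }
    )


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a synthetic patient cohort as a DataFrame (one row/patient).

    Columns follow the cohort CSV schema: identifiers and clinical
    covariates, then ``zone_01..zone_14`` (binary involvement),
    ``resected_01..resected_14`` and ``positive_01..positive_14`` counts.
    Deterministic given ``config.seed``.
    """
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    covs = _sample_covariates(config.clinical_model, n, rng)
    laterality = rng.choice(
        ["left", "right", "bilateral"], size=n, p=config.laterality_probs
    )
    nact = (rng.random(n) < config.nact_prob).astype(int)

    # planted covariate indicators, per effect
    shifts: dict[str, np.ndarray] = {}
    for eff in config.clinical_effects:
        node = f"zone_{eff.zone:02d}"
        ind = eff.indicator(covs[eff.covariate]).astype(float)
        shifts[node] = shifts.get(node, np.zeros(n)) + eff.log_odds * ind

    # ancestral zone sampling: topological order, ties broken by zone id
    dag = config.truth_dag
    order = sorted_topological(dag)
    zones = np.zeros((n, 14), dtype=np.int64)
    col_of = {v: j for j, v in enumerate(ZONE_COLS)}
    for v in order:
        cpt = config.truth_cpts[v]
        if cpt.parents:
            cfg_idx = np.zeros(n, dtype=np.int64)
            for p in cpt.parents:
                cfg_idx = cfg_idx * 2 + zones[:, col_of[p]]
            p1 = cpt.table[cfg_idx, 1]
        else:
            p1 = np.full(n, cpt.table[0, 1])
        if v in shifts:
            pc = np.clip(p1, 1e-9, 1 - 1e-9)
            p1 = 1.0 / (1.0 + np.exp(-(np.log(pc / (1 - pc)) + shifts[v])))
        zones[:, col_of[v]] = rng.random(n) < p1

    # resected counts (negative binomial) and positives (thinning)
    resected = np.zeros((n, 14), dtype=np.int64)
    positive = np.zeros((n, 14), dtype=np.int64)
    size_param = config.resected_dispersion
    for j, zid in enumerate(range(1, 15)):
        mean = float(config.resected_means.get(zid, 2.0))
        p_nb = size_param / (size_param + mean)
        resected[:, j] = rng.negative_binomial(size_param, p_nb, n)
        involved = zones[:, j] == 1
        resected[involved, j] = np.maximum(resected[involved, j], 1)
        extra = rng.binomial(
            np.maximum(resected[:, j] - 1, 0), config.positive_thinning
        )
        positive[involved, j] = 1 + extra[involved]

    any_involved = zones.any(axis=1)
    figo = np.where(
        any_involved,
        "III-IV",
        np.where(rng.random(n) < config.advanced_if_negative_prob, "III-IV", "I-II"),
    )

    out = pd.DataFrame({"patient_id": [f"P{i + 1:05d}" for i in range(n)]})
    out = pd.concat([out, covs], axis=1)
    out["figo"] = figo
    out["laterality"] = laterality
    out["nact"] = nact
    for j, c in enumerate(ZONE_COLS):
        out[c] = zones[:, j]
    for j, c in enumerate(RESECTED_COLS):
        out[c] = resected[:, j]
    for j, c in enumerate(POSITIVE_COLS):
        out[c] = positive[:, j]
    return out


def sorted_topological(dag: Dag) -> list[str]:
    """Topological order with ties broken by zone id (node-name order)."""
    indeg = {v: len(dag.parents(v)) for v in dag.nodes}
    ready = sorted(v for v in dag.nodes if indeg[v] == 0)
    order: list[str] = []
    while ready:
        v = ready.pop(0)
        order.append(v)
        changed = False
        for c in dag.children(v):
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
                changed = True
        if changed:
            ready.sort()
    if len(order) != len(dag.nodes):
        raise ValueError("truth_dag contains a cycle")
    return order


def generate_lnm_cohort(config: SimulationConfig, n_lnm: int,
                        max_batches: int = 200) -> pd.DataFrame:
    """Generate exactly ``n_lnm`` node-positive patients (deterministic).

    Repeatedly draws cohorts of ``config.n_patients`` (advancing the seed
    each batch) and keeps node-positive, NACT-free patients until the target
    count is reached.
    """
    kept: list[pd.DataFrame] = []
    total = 0
    for b in range(max_batches):
        batch = generate_cohort(replace(config, seed=(config.seed + 7919 * b) % (2**31)))
        pos = batch[(batch[ZONE_COLS].sum(axis=1) > 0) & (batch["nact"] == 0)]
        kept.append(pos)
        total += len(pos)
        if total >= n_lnm:
            break
    else:
        raise RuntimeError(f"could not collect {n_lnm} node-positive patients")
    out = pd.concat(kept, ignore_index=True).head(n_lnm).copy()
    out["patient_id"] = [f"P{i + 1:05d}" for i in range(len(out))]
    return out
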