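"""End-to-end report pipeline.

Runs the full analysis in cohort order: descriptive group comparisons,
univariate odds ratios, forward-stepwise multivariable model, exclusion of
neoadjuvant-treated patients, laterality stratification, regional mapping
metrics, Bayesian-network structure learning, bootstrap edge confidence,
co-occurrence ranking, pathway extraction, clinical augmentation, and
conditional-probability reports.  Every emitted file carries the producing
stage, config hash, and seed in a header comment; identical config + cohort
yield a byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import mapping, stats
from .atlas import default_atlas
from .io import (
    RunConfig,
    cpts_to_json,
    dag_to_edge_tsv,
    pathway_to_dot,
    stage_seed,
    validate_cohort,
)
from .pathways import (
    ClinicalBnSpec,
    MetastasisPathwayModel,
    augment_with_clinical,
    conditional_probability_report,
    discretize_clinical,
)
from .simulate import ZONE_COLS

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

CONTINUOUS_VARS = ["age", "ca125", "he4", "ascites_ml", "tumor_size_mm"]
BINARY_FACTORS = {
    "age_ge_50": lambda df: (df["age"] >= 50).astype(int),
    "menopause": lambda df: df["menopause"].astype(int),
    "ca125_high": lambda df: (df["ca125"] >= 264.5).astype(int),
    "he4_high": lambda df: (
        df["he4"].to_numpy(dtype=float)
        >= np.where(df["menopause"].astype(int) == 1, 148.5, 122.2)
    ).astype(int),
    "ascites_high": lambda df: (df["ascites_ml"] >= 90).astype(int),
    "size_ge_100": lambda df: (df["tumor_size_mm"] >= 100).astype(int),
    "bilateral": lambda df: (df["laterality"] == "bilateral").astype(int),
    "non_serous": lambda df: (df["histology"] == "non-serous").astype(int),
    "grade_g3": lambda df: (df["grade"] == "G3").astype(int),
    "nact": lambda df: df["nact"].astype(int),
}


def _write(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig) -> None:
    header = f"# stage={stage} config={cfg.config_hash()} seed={cfg.seed}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=True, float_format="%.6g", lineterminator="\n")


def run_pipeline(config: RunConfig, cohort: pd.DataFrame, out_dir) -> dict:
    """Execute all stages and write the report bundle to ``out_dir``.

    Returns a dict of in-memory stage results.  Any stage error aborts with
    the stage name; files already written are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "validate"
    try:
        validate_cohort(cohort)
        outcome = (cohort[ZONE_COLS].sum(axis=1) > 0).astype(int)
        if int(outcome.sum()) == 0:
            raise ValueError(
                "cohort has zero node-positive patients; group comparisons, "
                "mapping and network stages are undefined"
            )

        # -- descriptive comparison (group tests) --------------------------
        stage = "table1"
        rows = []
        for var in CONTINUOUS_VARS:
            a = cohort.loc[outcome == 0, var].to_numpy(dtype=float)
            b = cohort.loc[outcome == 1, var].to_numpy(dtype=float)
            u, p = stats.mann_whitney_u(a, b)
            rows.append({"variable": var, "test": "mann-whitney",
                         "median_negative": float(np.median(a)),
                         "median_positive": float(np.median(b)), "p_value": p})
        factors = {k: f(cohort) for k, f in BINARY_FACTORS.items()}
        for name, ind in factors.items():
            tab = stats.ContingencyTable2x2.from_arrays(ind, outcome)
            try:
                chi2, p = stats.chi_square_2x2(tab)
            except ValueError:
                chi2, p = float("nan"), float("nan")
            rows.append({"variable": name, "test": "chi-square",
                         "n_exposed": int(ind.sum()), "p_value": p})
        table1 = pd.DataFrame(rows).set_index("variable")
        _write(table1, out / "table1_summary.tsv", stage, config)
        results["table1"] = table1

        # -- univariate odds ratios ----------------------------------------
        stage = "univariate"
        rows = []
        for name, ind in factors.items():
            tab = stats.ContingencyTable2x2.from_arrays(ind, outcome)
            res = stats.odds_ratio_2x2(tab, correction=True)
            rows.append({"variable": name, "odds_ratio": res.odds_ratio,
                         "ci_low": res.ci_low, "ci_high": res.ci_high,
                         "zero_cell_corrected": res.corrected})
        univariate = pd.DataFrame(rows).set_index("variable")
        _write(univariate, out / "univariate_or.tsv", stage, config)
        results["univariate"] = univariate

        # -- multivariable forward stepwise --------------------------------
        stage = "stepwise"
        candidates = pd.DataFrame(factors)
        sw = stats.forward_stepwise(candidates, outcome, alpha_in=config.alpha_in)
        payload = {
            "stage": stage, "config": config.config_hash(), "seed": config.seed,
            "selected": sw.selected, "entry_pvalues": sw.entry_pvalues,
            "skipped": sw.skipped,
        }
        if sw.fit is not None:
            payload["coefficients"] = dict(
                zip(sw.fit.term_names, [float(b) for b in sw.fit.coefficients])
            )
        (out / "stepwise_model.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        results["stepwise"] = sw

        # -- NACT exclusion and laterality strata --------------------------
        stage = "strata"
        analysis = cohort[cohort["nact"] == 0] if config.exclude_nact else cohort
        strata = mapping.stratify_by_laterality(analysis)
        results["strata_sizes"] = {k: len(v) for k, v in strata.items()}

        # -- regional mapping ----------------------------------------------
        stage = "mapping"
        lnm = mapping.lnm_patients(analysis)
        if len(lnm) == 0:
            raise ValueError("cohort has zero node-positive patients after filtering")
        node_dist = mapping.node_level_distribution(lnm)
        pat_dist = mapping.patient_level_distribution(lnm)
        dist = pd.DataFrame({
            "node_share": node_dist.node_share,
            "patient_share": pat_dist.patient_share,
        })
        _write(dist, out / "zone_distribution.tsv", stage, config)
        _write(mapping.resection_summary(analysis), out / "resection_summary.tsv",
               stage, config)
        results["positivity_rate"] = mapping.overall_positivity_rate(analysis)
        results["distribution"] = dist
        for side, sub in strata.items():
            sub_lnm = mapping.lnm_patients(sub)
            if len(sub_lnm):
                d = mapping.patient_level_distribution(sub_lnm)
                _write(d.patient_share.to_frame(),
                       out / f"zone_distribution_{side}.tsv", stage, config)

        # -- network, bootstrap, co-occurrence, pathways -------------------
        stage = "pathways"
        model = MetastasisPathwayModel(
            B=config.bootstrap_B, tau=config.tau, q=config.q,
            hub_min=config.hub_min, denominator_mode=config.denominator_mode,
            restarts=config.restarts, max_indegree=config.max_indegree,
            atlas=default_atlas().with_extra_links(config.extra_adjacency),
            random_state=stage_seed(config.seed, "pathways"),
        )
        model.fit(lnm[ZONE_COLS])
        results["model"] = model
        edge_rows = [
            {"parent": u, "child": v, "directed_freq": f,
             "undirected_freq": model.edge_summary_.undirected(u, v)}
            for (u, v), f in sorted(model.edge_summary_.directed_freq.items())
        ]
        _write(pd.DataFrame(edge_rows).set_index("parent"),
               out / "bootstrap_edges.tsv", stage, config)
        _write(model.cooccurrence_.matrix, out / "cooccurrence.tsv", stage, config)
        hi = [
            {"parent": u, "child": v, "strength": s, "cooccurrence": c}
            for (u, v), (s, c) in sorted(model.pathway_.highlighted_edges.items())
        ]
        _write(pd.DataFrame(hi, columns=["parent", "child", "strength", "cooccurrence"])
               .set_index("parent"),
               out / "pathways.tsv", stage, config)
        pathway_to_dot(model.pathway_, out / "pathways.dot")
        (out / "chains.json").write_text(json.dumps(
            {"stage": stage, "config": config.config_hash(), "seed": config.seed,
             "chains": [list(c) for c in model.chains_],
             "node_labels": {str(k): v for k, v in sorted(model.node_labels_.items())}},
            indent=2, sort_keys=True))

        # -- clinical augmentation -----------------------------------------
        stage = "augment"
        spec = ClinicalBnSpec(clinical_variables=tuple(config.clinical_variables))
        dag, cpts, summary = augment_with_clinical(
            lnm, spec, B=config.bootstrap_B, seed=stage_seed(config.seed, "augment"),
            restarts=config.restarts, max_indegree=config.max_indegree,
            alpha=config.alpha,
        )
        dag_to_edge_tsv(dag, out / "augmented_edges.tsv", summary)
        cpts_to_json(cpts, out / "augmented_cpts.json")
        results["augmented"] = (dag, cpts, summary)

        # -- conditional probability report --------------------------------
        stage = "conditional"
        clin = discretize_clinical(lnm, spec)
        queries = []
        for (u, v) in sorted(model.pathway_.highlighted_edges):
            child = f"zone_{v:02d}"
            parent = f"zone_{u:02d}"
            if child in dag.nodes and parent in dag.nodes:
                queries.append((child, {parent: 1}))
                for var in ("grade", "tumor_size_mm", "age"):
                    if var in dag.nodes:
                        hi_state = int(clin[var].max())
                        queries.append((child, {parent: 1, var: hi_state}))
        report = conditional_probability_report(dag, cpts, queries)
        _write(report.set_index("target"), out / "conditional_probabilities.tsv",
               stage, config)
        results["conditional"] = report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return results
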