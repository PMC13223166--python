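"""Pathway extraction: dual-criterion rule, labels, chains, clinical nodes."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from lymphmap.atlas import default_atlas
from lymphmap.bayesnet import Cpt, Dag, fit_cpts, posterior_query
from lymphmap.consensus import BootstrapEdgeSummary, cooccurrence_matrix, top_quantile_pairs
from lymphmap.pathways import (
    ClinicalBnSpec,
    MetastasisPathwayModel,
    PathwayGraph,
    augment_with_clinical,
    chain_report,
    classify_nodes,
    conditional_probability_report,
    discretize_clinical,
    extract_routes,
)
from lymphmap.simulate import (
    ZONE_COLS,
    ClinicalEffect,
    SimulationConfig,
    generate_cohort,
    generate_lnm_cohort,
    make_zone_cpts,
    plant_pathway,
)


def summary_from(directed: dict) -> BootstrapEdgeSummary:
    """Build a BootstrapEdgeSummary from {(u, v): freq} by hand."""
    und: dict = {}
    for (u, v), f in directed.items():
        key = frozenset((u, v))
        und[key] = min(1.0, und.get(key, 0.0) + f)
    return BootstrapEdgeSummary(B=100, seed=0, directed_freq=dict(directed),
                                undirected_freq=und)


ALL_PAIRS = {frozenset((a, b)) for a in range(1, 15) for b in range(a + 1, 15)}


class TestExtractRoutes:
    def test_edge_meeting_all_criteria_highlighted(self):
        s = summary_from({("zone_03", "zone_05"): 0.8})
        g = extract_routes(s, {frozenset((3, 5))}, default_atlas(), tau=0.6)
        assert (3, 5) in g.highlighted_edges

    def test_distant_pair_excluded_even_when_strong(self):
        s = summary_from({("zone_03", "zone_09"): 0.9})
        g = extract_routes(s, {frozenset((3, 9))}, default_atlas(), tau=0.6)
        assert g.excluded_edges[(3, 9)] == "anatomically_distant"
        assert not g.highlighted_edges

    def test_exclusion_reason_precedence(self):
        atlas = default_atlas()
        weak = summary_from({("zone_03", "zone_09"): 0.3})
        g = extract_routes(weak, set(), atlas, tau=0.6)
        assert g.excluded_edges[(3, 9)] == "below_strength"  # strength checked first
        strong = summary_from({("zone_03", "zone_09"): 0.9})
        g = extract_routes(strong, set(), atlas, tau=0.6)
        assert g.excluded_edges[(3, 9)] == "below_cooccurrence"

    def test_empty_summary_gives_empty_graph(self):
        g = extract_routes(summary_from({}), ALL_PAIRS, default_atlas())
        assert not g.highlighted_edges and not g.excluded_edges

    def test_directed_mode_thresholds_each_orientation(self):
        s = summary_from({("zone_03", "zone_05"): 0.4, ("zone_05", "zone_03"): 0.45})
        g = extract_routes(s, ALL_PAIRS, default_atlas(), tau=0.6,
                           strength_mode="directed")
        assert not g.highlighted_edges
        g = extract_routes(s, ALL_PAIRS, default_atlas(), tau=0.6)  # undirected: 0.85
        assert (5, 3) in g.highlighted_edges  # majority orientation

    def test_monotone_in_tau_and_q(self, small_cohort):
        from lymphmap.consensus import bootstrap_edge_strength
        from lymphmap.mapping import lnm_patients
        Z = lnm_patients(small_cohort)[ZONE_COLS]
        s = bootstrap_edge_strength(Z, B=30, seed=1)
        cm = cooccurrence_matrix(Z)
        atlas = default_atlas()
        loose = extract_routes(s, top_quantile_pairs(cm, 0.6), atlas, tau=0.4)
        tight = extract_routes(s, top_quantile_pairs(cm, 0.3), atlas, tau=0.7)
        assert set(tight.highlighted_edges) <= set(loose.highlighted_edges)

    def test_every_highlighted_pair_is_adjacent(self, small_cohort):
        from lymphmap.consensus import bootstrap_edge_strength
        from lymphmap.mapping import lnm_patients
        Z = lnm_patients(small_cohort)[ZONE_COLS]
        s = bootstrap_edge_strength(Z, B=30, seed=2)
        cm = cooccurrence_matrix(Z)
        atlas = default_atlas()
        g = extract_routes(s, top_quantile_pairs(cm, 0.3), atlas, tau=0.5)
        assert all(atlas.adjacent(a, b) for (a, b) in g.highlighted_edges)


class TestClassifyNodes:
    def test_chain_labels(self):
        g = PathwayGraph(highlighted_edges={(3, 5): (0.9, 0.2), (5, 1): (0.8, 0.2)})
        labels = classify_nodes(g)
        assert labels[1] == "terminal"
        assert labels[3] == "intermediate" and labels[5] == "intermediate"
        assert labels[9] == "isolated"

    def test_star_center_is_hub(self):
        g = PathwayGraph(highlighted_edges={
            (5, 1): (0.9, 0.2), (5, 3): (0.9, 0.2), (5, 7): (0.9, 0.2), (2, 5): (0.9, 0.2),
        })
        assert classify_nodes(g)[5] == "hub"

    def test_labels_partition_all_zones(self):
        g = PathwayGraph(highlighted_edges={(11, 12): (0.9, 0.3)})
        labels = classify_nodes(g)
        assert set(labels) == set(range(1, 15))
        assert all(v in {"hub", "terminal", "intermediate", "isolated"}
                   for v in labels.values())


class TestChainReport:
    def test_two_edge_chain_joined(self):
        g = PathwayGraph(highlighted_edges={(4, 2): (0.9, 0.2), (2, 14): (0.8, 0.2)})
        assert chain_report(g) == [(4, 2, 14)]

    def test_single_edge_chain(self):
        g = PathwayGraph(highlighted_edges={(11, 12): (0.9, 0.2)})
        assert chain_report(g) == [(11, 12)]

    def test_cycle_broken_at_weakest_edge(self, caplog):
        import logging
        g = PathwayGraph(highlighted_edges={
            (3, 5): (0.9, 0.2), (5, 1): (0.8, 0.2), (1, 3): (0.65, 0.2),
        })
        with caplog.at_level(logging.WARNING, logger="lymphmap.pathways"):
            chains = chain_report(g)
        assert chains == [(3, 5, 1)]
        assert "cycle" in caplog.text

    def test_longest_first_then_lexicographic(self):
        g = PathwayGraph(highlighted_edges={
            (6, 4): (0.9, 0.2), (4, 2): (0.9, 0.2), (2, 1): (0.9, 0.2),
            (11, 12): (0.9, 0.2),
        })
        assert chain_report(g) == [(6, 4, 2, 1), (11, 12)]


class TestClinicalAugmentation:
    def test_discretization_uses_clinical_cutoffs(self, small_cohort):
        clin = discretize_clinical(small_cohort, ClinicalBnSpec())
        assert set(clin.columns) == set(ClinicalBnSpec().clinical_variables)
        assert set(clin["grade"].unique()) <= {0, 1, 2}
        manual = (small_cohort["ca125"] >= 264.5).astype(int)
        assert (clin["ca125"] == manual).all()
        # HE4 cutoff is menopause-dependent
        cut = np.where(small_cohort["menopause"] == 1, 148.5, 122.2)
        assert (clin["he4"] == (small_cohort["he4"].to_numpy() >= cut)).all()

    def test_augmented_node_count(self, small_cohort):
        from lymphmap.mapping import lnm_patients
        lnm = lnm_patients(small_cohort)
        dag, cpts, summary = augment_with_clinical(lnm, B=2, seed=0)
        # figo is single-state among node-positive patients and gets dropped
        assert 14 + 7 <= len(dag.nodes) <= 14 + 8

    def test_planted_grade_effect_recovered(self):
        dag0 = Dag(ZONE_COLS)
        cpts0 = make_zone_cpts(dag0, {"zone_05": 0.3, "zone_11": 0.4}, baseline=0.05)
        cfg = SimulationConfig(n_patients=1000, seed=13, truth_dag=dag0,
                               truth_cpts=cpts0,
                               clinical_effects=(ClinicalEffect("grade", 5, 2.0,
                                                                level="G3"),))
        coh = generate_cohort(cfg)
        spec = ClinicalBnSpec(clinical_variables=("grade", "age", "menopause"))
        dag, cpts, summary = augment_with_clinical(coh, spec, B=100, seed=3)
        assert summary.undirected("grade", "zone_05") >= 0.6


class TestConditionalReport:
    @staticmethod
    def _toy_network():
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": Cpt("A", (), 2, (), [[0.4, 0.6]]),
            "B": Cpt("B", ("A",), 2, (2,), [[0.8, 0.2], [0.3, 0.7]]),
        }
        return dag, cpts

    def test_sole_parent_evidence_returns_cpt_entry(self):
        dag, cpts = self._toy_network()
        rep = conditional_probability_report(dag, cpts, [("B", {"A": 1})])
        assert rep.loc[0, "posterior"] == pytest.approx(0.7, abs=1e-12)

    def test_inconsistent_evidence_flagged_not_fatal(self):
        dag = Dag("AB", [("A", "B")])
        cpts = {
            "A": Cpt("A", (), 2, (), [[0.0, 1.0]]),
            "B": Cpt("B", ("A",), 2, (2,), [[0.5, 0.5], [0.5, 0.5]]),
        }
        rep = conditional_probability_report(dag, cpts, [("B", {"A": 0}),
                                                         ("B", {"A": 1})])
        assert bool(rep.loc[0, "inconsistent_evidence"])
        assert not bool(rep.loc[1, "inconsistent_evidence"])

    def test_planted_087_conditional_recovered_from_learned_cpts(self):
        # generator plants P(zone5=1 | zone3=1, grade=G3) = 0.875 exactly
        shift = math.log(0.875 / 0.125)
        dag0 = Dag(ZONE_COLS)
        cpts0 = make_zone_cpts(dag0, {"zone_03": 0.5}, baseline=0.05)
        cfg = SimulationConfig(n_patients=2000, seed=17, truth_dag=dag0,
                               truth_cpts=cpts0)
        cfg = plant_pathway(cfg, [3, 5], 0.5)
        cfg = replace(cfg, clinical_effects=(
            ClinicalEffect("grade", 5, shift, level="G3"),
        ))
        coh = generate_cohort(cfg)
        clin = discretize_clinical(coh, ClinicalBnSpec(clinical_variables=("grade",)))
        data = pd.concat([coh[ZONE_COLS], clin], axis=1)
        fixed = Dag(list(data.columns), [("zone_03", "zone_05"), ("grade", "zone_05")])
        cpts = fit_cpts(fixed, data)
        post = posterior_query(fixed, cpts, "zone_05", 1, {"zone_03": 1, "grade": 2})
        assert abs(post - 0.875) < 0.05


class TestPathwayModel:
    def test_fit_recovers_planted_routes(self):
        dag = Dag(ZONE_COLS)
        cpts = make_zone_cpts(dag, {"zone_03": 0.5, "zone_11": 0.5}, baseline=0.05)
        cfg = SimulationConfig(n_patients=400, seed=23, truth_dag=dag, truth_cpts=cpts)
        cfg = plant_pathway(cfg, [3, 5, 1], 0.9)
        cfg = plant_pathway(cfg, [11, 12], 0.9)
        coh = generate_lnm_cohort(cfg, 300)
        model = MetastasisPathwayModel(B=60, random_state=1).fit(coh[ZONE_COLS])
        highlighted_pairs = {frozenset(e) for e in model.pathway_.highlighted_edges}
        for pair in [frozenset((3, 5)), frozenset((5, 1)), frozenset((11, 12))]:
            assert pair in highlighted_pairs
        assert model.chains_  # chain report produced
        assert set(model.node_labels_) == set(range(1, 15))

    def test_sklearn_params_roundtrip(self):
        m = MetastasisPathwayModel(B=10, tau=0.7)
        assert MetastasisPathwayModel().set_params(**m.get_params()).tau == 0.7
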