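"""Cohort CSV schema, validation, and graph/report serialization.

The patient CSV schema (one row per patient):

``patient_id, age, menopause, parity, ca125, he4, ascites_ml,
tumor_size_mm, grade, histology, figo, laterality, nact,
zone_01..zone_14, resected_01..resected_14, positive_01..positive_14``

Row invariants enforced on read: binary columns contain only 0/1, counts
are non-negative, ``positive <= resected`` per zone, involvement equals
``positive >= 1``, and stage I-II patients have no involved zone.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .atlas import ZONE_NAMES
from .bayesnet import Cpt, Dag
from .simulate import POSITIVE_COLS, RESECTED_COLS, ZONE_COLS

__all__ = [
    "COHORT_COLUMNS",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
    "dag_to_edge_tsv",
    "dag_to_dot",
    "cpts_to_json",
    "pathway_to_dot",
    "stage_seed",
]

CLINICAL_COLUMNS = [
    "patient_id", "age", "menopause", "parity", "ca125", "he4", "ascites_ml",
    "tumor_size_mm", "grade", "histology", "figo", "laterality", "nact",
]
COHORT_COLUMNS = CLINICAL_COLUMNS + ZONE_COLS + RESECTED_COLS + POSITIVE_COLS


@dataclass
class RunConfig:
    """Knobs for the full pipeline, with the stated defaults.

    ``tau`` (edge-strength threshold 0.6) and ``q`` (co-occurrence top
    fraction 0.3) are the pathway-rule defaults; ``bootstrap_B`` is the
    number of bootstrap structure-learning iterations.
    """

    seed: int = 0
    bootstrap_B: int = 200
    tau: float = 0.6
    q: float = 0.3
    alpha: float = 0.0
    hub_min: int = 3
    denominator_mode: str = "lnm_patients"
    restarts: int = 0
    max_indegree: int | None = None
    exclude_nact: bool = True
    alpha_in: float = 0.05
    extra_adjacency: list = field(default_factory=list)
    clinical_variables: list = field(
        default_factory=lambda: [
            "age", "menopause", "ca125", "he4", "figo", "grade",
            "tumor_size_mm", "histology",
        ]
    )

    def __post_init__(self) -> None:
        if not 0 < self.tau <= 1:
            raise ValueError("tau must be in (0, 1]")
        if not 0 < self.q <= 1:
            raise ValueError("q must be in (0, 1]")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if self.denominator_mode not in ("lnm_patients", "all_patients"):
            raise ValueError("denominator_mode must be lnm_patients or all_patients")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2^31)."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def validate_cohort(df: pd.DataFrame) -> None:
    """Raise with all schema/invariant violations collected together."""
    problems: list[str] = []
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if missing:
        problems.append(f"missing columns: {missing}")
    if extra:
        problems.append(f"unexpected columns: {extra}")
    if not missing:
        for c in ZONE_COLS + ["menopause", "nact"]:
            vals = set(pd.unique(df[c]))
            if not vals <= {0, 1}:
                problems.append(f"column {c} is not binary (values {sorted(vals)[:5]})")
        for c in RESECTED_COLS + POSITIVE_COLS:
            if (df[c] < 0).any():
                problems.append(f"column {c} has negative counts")
        pos = df[POSITIVE_COLS].to_numpy()
        res = df[RESECTED_COLS].to_numpy()
        zon = df[ZONE_COLS].to_numpy()
        bad = np.nonzero((pos > res).any(axis=1))[0]
        if bad.size:
            problems.append(f"positive > resected in rows {bad.tolist()[:10]}")
        bad = np.nonzero((zon != (pos >= 1)).any(axis=1))[0]
        if bad.size:
            problems.append(
                f"zone involvement inconsistent with positive counts in rows {bad.tolist()[:10]}"
            )
        early = df["figo"] == "I-II"
        bad = np.nonzero(early.to_numpy() & (zon.sum(axis=1) > 0))[0]
        if bad.size:
            problems.append(f"stage I-II patients with involved zones in rows {bad.tolist()[:10]}")
    if problems:
        raise ValueError("cohort validation failed:\n  " + "\n  ".join(problems))


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a patient cohort CSV."""
    df = pd.read_csv(path)
    validate_cohort(df)
    return df


# ---------------------------------------------------------------------------
# Graph serialization


def dag_to_edge_tsv(dag: Dag, path, summary=None) -> None:
    """Edge list TSV: parent, child (plus bootstrap frequencies if given)."""
    rows = []
    for (u, v) in sorted(dag.edges):
        row = {"parent": u, "child": v}
        if summary is not None:
            row["directed_freq"] = summary.directed(u, v)
            row["undirected_freq"] = summary.undirected(u, v)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _zone_label(node) -> str:
    try:
        zid = int(str(node).split("_")[1]) if str(node).startswith("zone_") else int(node)
        return f"{zid}: {ZONE_NAMES[zid]}"
    except (ValueError, KeyError, IndexError):
        return str(node)


def dag_to_dot(dag: Dag, path=None) -> str:
    lines = ["digraph bn {"]
    for v in dag.nodes:
        lines.append(f'  "{v}" [label="{_zone_label(v)}"];')
    for (u, v) in sorted(dag.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def pathway_to_dot(graph, path=None) -> str:
    """DOT export of a PathwayGraph; highlighted edges styled distinctly."""
    lines = ["digraph pathways {"]
    for z in graph.nodes:
        shape = {"hub": "doublecircle", "terminal": "box"}.get(
            graph.node_labels.get(z, ""), "circle"
        )
        lines.append(f'  "{z}" [label="{z}: {ZONE_NAMES[z]}", shape={shape}];')
    for (u, v), (freq, cooc) in sorted(graph.highlighted_edges.items()):
        lines.append(
            f'  "{u}" -> "{v}" [color=red, penwidth=2, '
            f'label="{freq:.2f}"];'
        )
    for (u, v), reason in sorted(graph.excluded_edges.items()):
        lines.append(f'  "{u}" -> "{v}" [style=dotted, color=gray, label="{reason}"];')
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def cpts_to_json(cpts: dict[str, Cpt], path=None) -> str:
    payload = {
        v: {
            "parents": list(c.parents),
            "card": c.card,
            "parent_cards": list(c.parent_cards),
            "alpha": c.alpha,
            "table": np.asarray(c.table).tolist(),
        }
        for v, c in cpts.items()
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text
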