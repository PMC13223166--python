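"""Regional distribution metrics for the 14 nodal zones.

Two complementary distributions are computed over a cohort:

* node-level: each zone's share of all positive lymph nodes,
  ``(positive nodes in zone) / (total positive nodes)``;
* patient-level: the fraction of node-positive patients with that zone
  involved, ``(patients with positive nodes in zone) / (patients with any
  nodal metastasis)``.

Plus the overall node positivity rate (positive / resected), per-zone
resection summaries (total removed, patients with any node removed, median
(min, max) removed per patient), and stratification of the cohort by
primary-tumour laterality with optional exclusion of patients treated with
neoadjuvant chemotherapy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ZONE_NAMES
from .simulate import POSITIVE_COLS, RESECTED_COLS, ZONE_COLS

logger = logging.getLogger(__name__)

__all__ = [
    "ZoneDistribution",
    "node_level_distribution",
    "patient_level_distribution",
    "overall_positivity_rate",
    "resection_summary",
    "stratify_by_laterality",
    "lnm_patients",
]


@dataclass
class ZoneDistribution:
    """Per-zone involvement distribution (indexed by zone id 1..14)."""

    node_share: pd.Series | None = None
    patient_share: pd.Series | None = None
    n_positive_nodes: int = 0
    n_lnm_patients: int = 0


def _zone_index() -> pd.Index:
    return pd.Index(range(1, 15), name="zone")


def lnm_patients(cohort: pd.DataFrame) -> pd.DataFrame:
    """Subset of patients with at least one involved zone."""
    return cohort[cohort[ZONE_COLS].sum(axis=1) > 0]


def node_level_distribution(cohort: pd.DataFrame) -> ZoneDistribution:
    """Each zone's share of all positive lymph nodes in the cohort."""
    positives = cohort[POSITIVE_COLS].sum(axis=0).to_numpy(dtype=float)
    total = positives.sum()
    if total <= 0:
        raise ValueError("no positive nodes in cohort: node-level distribution undefined")
    share = pd.Series(positives / total, index=_zone_index(), name="node_share")
    return ZoneDistribution(node_share=share, n_positive_nodes=int(total))


def patient_level_distribution(cohort: pd.DataFrame,
                               denominator: str = "lnm_patients") -> ZoneDistribution:
    """Fraction of node-positive patients with each zone involved.

    The denominator is the count of patients with any involved zone;
    ``denominator="all_patients"`` switches to the whole cohort for
    sensitivity analysis.
    """
    pos = lnm_patients(cohort)
    if len(pos) == 0:
        raise ValueError("no node-positive patients: patient-level distribution undefined")
    denom = len(pos) if denominator == "lnm_patients" else len(cohort)
    counts = pos[ZONE_COLS].sum(axis=0).to_numpy(dtype=float)
    share = pd.Series(counts / denom, index=_zone_index(), name="patient_share")
    return ZoneDistribution(patient_share=share, n_lnm_patients=len(pos))


def overall_positivity_rate(cohort: pd.DataFrame) -> float:
    """Total positive nodes / total resected nodes."""
    resected = float(cohort[RESECTED_COLS].to_numpy().sum())
    positive = float(cohort[POSITIVE_COLS].to_numpy().sum())
    if resected <= 0:
        raise ValueError("no resected nodes: positivity rate undefined")
    return positive / resected


def resection_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-zone resection summary table.

    Columns: zone name, total nodes removed, number of patients with >= 1
    node removed, and the median (min, max) removed per patient.  The
    median of a zone where no patient had nodes removed is reported as 0.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for zid, col in zip(range(1, 15), RESECTED_COLS):
        counts = cohort[col].to_numpy(dtype=int)
        if counts.max(initial=0) == 0:
            logger.info("zone %d: no nodes removed in any patient; median reported as 0", zid)
        rows.append(
            {
                "zone": zid,
                "name": ZONE_NAMES[zid],
                "total_removed": int(counts.sum()),
                "patients_with_removed": int((counts > 0).sum()),
                "median_removed": float(np.median(counts)),
                "min_removed": int(counts.min()),
                "max_removed": int(counts.max()),
            }
        )
    return pd.DataFrame(rows).set_index("zone")


def stratify_by_laterality(cohort: pd.DataFrame,
                           exclude_nact: bool = False) -> dict[str, pd.DataFrame]:
    """Partition the cohort into left / right / bilateral sub-cohorts.

    With ``exclude_nact``, patients treated with neoadjuvant chemotherapy
    are dropped before partitioning.  Unknown laterality values raise,
    naming the offending records.
    """
    df = cohort
    if exclude_nact:
        df = df[df["nact"] == 0]
    valid = {"left", "right", "bilateral"}
    bad = df[~df["laterality"].isin(valid)]
    if len(bad):
        raise ValueError(
            f"unknown laterality value(s) in records {bad['patient_id'].tolist()[:10]}"
        )
    return {side: df[df["laterality"] == side] for side in ("left", "right", "bilateral")}
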