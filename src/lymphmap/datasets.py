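"""Published summary tables from a retrospective epithelial ovarian cancer
lymphadenectomy cohort (654 patients, 14 nodal zones), used as worked-example
inputs.

Only aggregate counts are included: 2x2 tables of candidate risk factors
against nodal-metastasis status, cohort totals, and per-zone resection
counts.  These let the association statistics be recomputed exactly without
patient-level data.
"""

from __future__ import annotations

from .stats import ContingencyTable2x2

#: Cohort size and node-positive patient count.
N_PATIENTS = 654
N_LNM_PATIENTS = 291

#: Total nodes resected / metastatic in the mapping subcohort
#: (210 node-positive patients without neoadjuvant chemotherapy).
TOTAL_RESECTED_NODES = 18609
TOTAL_POSITIVE_NODES = 2015
N_MAPPING_PATIENTS = 210
N_MAPPING_COHORT = 528

#: 2x2 tables, exposure x outcome, outcome = nodal metastasis.
#: n00 = unexposed/negative, n01 = unexposed/positive,
#: n10 = exposed/negative, n11 = exposed/positive.
RISK_FACTOR_TABLES = {
    # bilateral (exposed) vs unilateral primary tumour
    "tumor_lateralization": ContingencyTable2x2(254, 110, 109, 181),
    # neoadjuvant chemotherapy given (exposed) vs not
    "nact": ContingencyTable2x2(318, 210, 45, 81),
    # age >= 50 years
    "age_ge_50": ContingencyTable2x2(150, 80, 212, 211),
    # CA125 >= 264.5 U/mL
    "ca125_high": ContingencyTable2x2(199, 54, 147, 232),
    # FIGO III-IV (structural zero: no stage I-II patient is node-positive)
    "figo_advanced": ContingencyTable2x2(232, 0, 129, 290),
}

#: Per-zone total resected-node counts in the mapping subcohort.
ZONE_RESECTED_TOTALS = {
    1: 1077, 2: 1131, 3: 1083, 4: 1069, 5: 1044, 6: 1000, 7: 1481,
    8: 1641, 9: 922, 10: 946, 11: 2821, 12: 2427, 13: 988, 14: 979,
}
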