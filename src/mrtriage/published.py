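"""Published summary results from a proteome-wide MR study of allergic disease.

Two reference tables transcribed from the study's printed results serve as
inputs here: the per-cohort replication odds ratios with 95% confidence
intervals (used to reconstruct log-OR/SE pairs and re-run the meta-analysis),
and the per-protein evidence flags feeding the tier-grading decision table.
Outcomes: AA allergic asthma, AD atopic dermatitis, AR allergic rhinitis.

Only summary-level printed numbers appear; no individual-level or full
genome-wide data.
"""

from __future__ import annotations

import pandas as pd

# protein, outcome, cohort (exposure panel / outcome GWAS), OR, lower, upper
_REPLICATION_ROWS = [
    # GALK1 / AA — two cohorts, fixed-effect; printed meta OR 0.7036, I2 18.43
    ("GALK1", "AA", "ARIC_UKB", 0.7228, 0.6363, 0.8211),
    ("GALK1", "AA", "ARIC_FinnGen", 0.5958, 0.4337, 0.8184),
    # IL6R / AA — four cohorts, fixed-effect; meta 0.9611, I2 27.47
    ("IL6R", "AA", "ARIC_UKB", 0.9632, 0.9459, 0.9807),
    ("IL6R", "AA", "ARIC_FinnGen", 0.9417, 0.9132, 0.9711),
    ("IL6R", "AA", "deCODE_UKB", 0.9683, 0.9243, 1.0145),
    ("IL6R", "AA", "deCODE_FinnGen", 1.0119, 0.9466, 1.0818),
    # PILRA / AA — four cohorts, fixed-effect; meta 1.0180, I2 0.00
    ("PILRA", "AA", "ARIC_UKB", 1.0231, 1.0110, 1.0354),
    ("PILRA", "AA", "ARIC_FinnGen", 1.0055, 0.9797, 1.0320),
    ("PILRA", "AA", "deCODE_UKB", 1.0110, 0.9906, 1.0319),
    ("PILRA", "AA", "deCODE_FinnGen", 1.0164, 0.9711, 1.0639),
    # PRSS8 / AA — four cohorts, fixed-effect; meta 0.7398, I2 16.93
    ("PRSS8", "AA", "ARIC_UKB", 0.7769, 0.6830, 0.8837),
    ("PRSS8", "AA", "ARIC_FinnGen", 0.7719, 0.6011, 0.9911),
    ("PRSS8", "AA", "deCODE_UKB", 0.5990, 0.4561, 0.7866),
    ("PRSS8", "AA", "deCODE_FinnGen", 0.5975, 0.3538, 1.0089),
    # CRAT / AD — two cohorts, fixed-effect; meta 0.8104, I2 0.00
    ("CRAT", "AD", "ARIC_UKB", 0.8147, 0.7455, 0.8903),
    ("CRAT", "AD", "ARIC_FinnGen", 0.8067, 0.7184, 0.9058),
    # ERBB3 / AD — four cohorts, fixed-effect; meta 1.3306, I2 39.45
    ("ERBB3", "AD", "ARIC_UKB", 1.2775, 1.1548, 1.4132),
    ("ERBB3", "AD", "ARIC_FinnGen", 1.2871, 1.1333, 1.4617),
    ("ERBB3", "AD", "deCODE_UKB", 1.5768, 1.3069, 1.9024),
    ("ERBB3", "AD", "deCODE_FinnGen", 1.5989, 1.2620, 2.0256),
    # IL6R / AD — four cohorts, fixed-effect; meta 0.9445, I2 0.00
    ("IL6R", "AD", "ARIC_UKB", 0.9430, 0.9239, 0.9625),
    ("IL6R", "AD", "ARIC_FinnGen", 0.9363, 0.8546, 1.0258),
    ("IL6R", "AD", "deCODE_UKB", 0.9494, 0.9261, 0.9732),
    ("IL6R", "AD", "deCODE_FinnGen", 0.9423, 0.9136, 0.9720),
    # MMP12 / AD — four cohorts, fixed-effect; meta 0.9083, I2 0.00
    ("MMP12", "AD", "ARIC_UKB", 0.9230, 0.8883, 0.9591),
    ("MMP12", "AD", "ARIC_FinnGen", 0.8911, 0.8539, 0.9300),
    ("MMP12", "AD", "deCODE_UKB", 0.9255, 0.8890, 0.9634),
    ("MMP12", "AD", "deCODE_FinnGen", 0.9051, 0.8636, 0.9485),
    # PILRA / AR — four cohorts, fixed-effect; meta 0.9984, I2 0.00
    ("PILRA", "AR", "ARIC_UKB", 0.9985, 0.9977, 0.9993),
    ("PILRA", "AR", "ARIC_FinnGen", 1.0053, 0.9799, 1.0315),
    ("PILRA", "AR", "deCODE_UKB", 0.9983, 0.9970, 0.9996),
    ("PILRA", "AR", "deCODE_FinnGen", 1.0092, 0.9673, 1.0530),
]

# protein, outcome, printed pooled OR, printed I2 (%), printed model
_PRINTED_META = [
    ("GALK1", "AA", 0.7036, 18.43, "fixed"),
    ("IL6R", "AA", 0.9611, 27.47, "fixed"),
    ("PILRA", "AA", 1.0180, 0.00, "fixed"),
    ("PRSS8", "AA", 0.7398, 16.93, "fixed"),
    ("CRAT", "AD", 0.8104, 0.00, "fixed"),
    ("ERBB3", "AD", 1.3306, 39.45, "fixed"),
    ("IL6R", "AD", 0.9445, 0.00, "fixed"),
    ("MMP12", "AD", 0.9083, 0.00, "fixed"),
    ("PILRA", "AR", 0.9984, 0.00, "fixed"),
]

# protein, outcome, steiger_keep, replication_pass, coloc PPH4 (fraction),
# external_pass, ppi_linked, printed tier label
_EVIDENCE_FLAGS = [
    # allergic asthma
    ("APOE", "AA", False, False, 0.015, False, True, "excluded"),
    ("STAT6", "AA", True, True, 1.000, True, True, "1"),
    ("TNFRSF6B", "AA", True, True, 0.994, False, True, "2"),
    ("IL1RL2", "AA", True, True, 0.000, True, True, "2"),
    ("IL6R", "AA", True, True, 1.000, False, True, "3"),
    ("GALK1", "AA", True, True, 0.999, False, False, "3"),
    ("NPNT", "AA", True, True, 1.000, False, False, "3"),
    ("PRSS8", "AA", True, True, 0.846, False, False, "3"),
    ("VTA1", "AA", True, True, 0.978, False, False, "3"),
    ("LRRC32", "AA", True, False, 0.954, False, False, "4"),
    ("MAX", "AA", True, True, 0.757, False, False, "4"),
    ("PILRA", "AA", True, True, 0.002, False, False, "4"),
    # atopic dermatitis — the internally consistent section of the table
    ("CRAT", "AD", True, True, 0.993, True, False, "1"),
    ("TNFRSF6B", "AD", True, True, 0.980, True, False, "1"),
    ("ERBB3", "AD", True, True, 0.997, False, True, "2"),
    ("IL6R", "AD", True, True, 1.000, False, True, "2"),
    ("MMP12", "AD", True, True, 0.970, False, True, "2"),
    ("LRRC32", "AD", True, False, 0.274, False, False, "4"),
]


def replication_table() -> pd.DataFrame:
    """Per-cohort printed OR (95% CI) cells for replicated proteins."""
    return pd.DataFrame(
        _REPLICATION_ROWS,
        columns=["protein", "outcome", "cohort", "or", "lower", "upper"])


def printed_meta_table() -> pd.DataFrame:
    """The printed pooled ORs, I² values and model labels."""
    return pd.DataFrame(
        _PRINTED_META,
        columns=["protein", "outcome", "pooled_or", "i2", "model"])


def evidence_flags() -> pd.DataFrame:
    """Printed per-protein evidence verdicts feeding the tier decision table."""
    return pd.DataFrame(
        _EVIDENCE_FLAGS,
        columns=["protein", "outcome", "steiger_keep", "replication_pass",
                 "coloc_pph4", "external_pass", "ppi_linked", "tier"])
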