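"""Cohort table schema: column groups, units, and validation.

A cohort table is a plain :class:`pandas.DataFrame`, one row per child.
Serum chemistry is in mg/dL, metabolites in μM, anthropometrics in the
units given in :data:`COLUMN_DICTIONARY`.
"""

from __future__ import annotations

import pandas as pd

ID_COLUMN = "child_id"
PHASE_COLUMN = "phase"
PHASES = ("baseline", "post", "mets")

#: free carnitine
CARNITINE = "c0"
#: acylcarnitines by acyl chain length (ac3/ac5 derive from amino acid catabolism)
ACYLCARNITINES = (
    "ac2", "ac3", "ac4", "ac5", "ac6", "ac8",
    "ac10", "ac12", "ac14", "ac16", "ac18",
)
AMINO_ACIDS = (
    "ala", "gly", "arg", "met", "pro", "val",
    "leu", "phe", "tyr", "cit", "orn",
)
METABOLITES = (CARNITINE,) + ACYLCARNITINES + AMINO_ACIDS

CHEMISTRY = ("glucose", "tag", "tc", "hdl")

ANTHROPOMETRICS = (
    "sex", "age", "weight", "height",
    "waist_circumference", "bmi_z", "sbp_pct", "dbp_pct",
)

#: every column a cohort CSV must carry
REQUIRED_COLUMNS = (ID_COLUMN, PHASE_COLUMN) + ANTHROPOMETRICS + CHEMISTRY + METABOLITES

#: numeric columns entering preprocessing / modelling
ANALYSIS_COLUMNS = CHEMISTRY + METABOLITES

#: amino acids entering the amino-acid index (the nine index members)
AAI_VARIABLES = ("gly", "ala", "met", "val", "pro", "leu", "phe", "tyr", "arg")
#: acylcarnitines entering the acylcarnitine index
ACI_VARIABLES = ("ac2", "ac4", "ac8", "ac10", "ac16")

#: fixed feature order consumed by the SOM classifier
SOM_FEATURES = ("glucose", "tag", "tc", "c0", "aci", "aai", "cit", "orn")

COLUMN_DICTIONARY = {
    ID_COLUMN: "unique child identifier within a phase",
    PHASE_COLUMN: "cohort phase: baseline | post | mets",
    "sex": "0 = girl, 1 = boy",
    "age": "years",
    "weight": "kg",
    "height": "cm",
    "waist_circumference": "cm",
    "bmi_z": "BMI-for-age z-score (precomputed input)",
    "sbp_pct": "systolic blood-pressure percentile for age/height (precomputed)",
    "dbp_pct": "diastolic blood-pressure percentile for age/height (precomputed)",
    "glucose": "fasting serum glucose, mg/dL",
    "tag": "serum triacylglycerols, mg/dL",
    "tc": "serum total cholesterol, mg/dL",
    "hdl": "serum HDL cholesterol, mg/dL",
    **{m: "serum concentration, μM" for m in METABOLITES},
}


class SchemaError(ValueError):
    """A cohort table violates the documented schema."""


def validate_cohort(table: pd.DataFrame, *, require_phase: str | None = None) -> pd.DataFrame:
    """Validate a cohort table against the schema.

    Checks required columns, numeric parsing of analysis columns,
    non-negative concentrations and uniqueness of ``child_id`` within phase.
    Returns the table with analysis columns coerced to float.

    Raises
    ------
    SchemaError
        naming every offending column.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")

    table = table.copy()
    bad_numeric = []
    for col in ANALYSIS_COLUMNS + ("age", "weight", "height", "waist_circumference",
                                   "bmi_z", "sbp_pct", "dbp_pct"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        if coerced.isna().sum() > pd.isna(table[col]).sum():
            bad_numeric.append(col)
        table[col] = coerced.astype(float)
    if bad_numeric:
        raise SchemaError(f"non-numeric values in columns: {bad_numeric}")

    negative = [c for c in ANALYSIS_COLUMNS if (table[c].dropna() < 0).any()]
    if negative:
        raise SchemaError(f"negative concentrations in columns: {negative}")

    bad_phase = set(table[PHASE_COLUMN].unique()) - set(PHASES)
    if bad_phase:
        raise SchemaError(f"unknown phase values: {sorted(bad_phase)}")
    if require_phase is not None and not (table[PHASE_COLUMN] == require_phase).all():
        raise SchemaError(f"expected all rows in phase {require_phase!r}")

    dup = table.duplicated(subset=[ID_COLUMN, PHASE_COLUMN])
    if dup.any():
        raise SchemaError(
            f"duplicate child_id within phase: {sorted(table.loc[dup, ID_COLUMN].unique())[:5]}"
        )
    return table
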