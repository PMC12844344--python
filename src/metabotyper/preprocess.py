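"""Eligibility screening, outlier exclusion and derived clinical indices.

Filtering is applied in a fixed order — completeness, metabolic-syndrome
screen, fasting rule, metabolite outliers — with full row accounting in
an :class:`ExclusionReport`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema

log = logging.getLogger(__name__)

#: triacylglycerol ceiling (mg/dL) above which the Friedewald formula is invalid
FRIEDEWALD_TAG_LIMIT = 400.0
#: fasting-violation proxy: fasting glucose at or above this is excluded
FASTING_GLUCOSE_LIMIT = 100.0


@dataclass(frozen=True)
class CookConfig:
    """Pediatric metabolic-syndrome screen: ≥3 abnormal components.

    Thresholds follow the standard pediatric definition; the waist
    criterion is evaluated against the empirical within-cohort percentile
    because the schema carries waist in cm, not as a reference percentile.
    """

    tag_mg_dl: float = 110.0
    hdl_mg_dl: float = 40.0
    glucose_mg_dl: float = 110.0
    bp_percentile: float = 90.0
    waist_percentile: float = 90.0
    min_components: int = 3


@dataclass
class ExclusionReport:
    """Per-rule counts and identifiers of removed children."""

    input_n: int = 0
    removed: dict[str, list[str]] = field(default_factory=dict)

    def record(self, rule: str, ids: list[str]) -> None:
        self.removed[rule] = list(ids)

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(ids) for rule, ids in self.removed.items()}

    @property
    def total_removed(self) -> int:
        return sum(self.counts.values())

    @property
    def retained_n(self) -> int:
        return self.input_n - self.total_removed

    def to_dict(self) -> dict:
        return {"input_n": self.input_n, "retained_n": self.retained_n,
                "counts": self.counts, "removed": self.removed}


def friedewald_ldl(tc, hdl, tag):
    """LDL cholesterol via the Friedewald formula, mg/dL.

    ``LDL = TC − HDL − TAG/5``; rows with TAG ≥ 400 mg/dL fall outside
    the formula's validity and return NaN rather than raising.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tag = np.asarray(tag, dtype=float)
    ldl = tc - hdl - tag / 5.0
    return np.where(tag >= FRIEDEWALD_TAG_LIMIT, np.nan, ldl)


def derived_panel(cohort: pd.DataFrame) -> pd.DataFrame:
    """Derived cardiometabolic and β-oxidation quantities per child.

    Returns columns ``ldl`` (mg/dL), ``athero_index`` (TC/HDL),
    ``tag_hdl``, ``ldl_hdl``, ``tyg`` = ln(TAG·glucose/2) in ln-units,
    ``betaox_init`` = AC16/C0 and ``betaox_rate`` = AC16/AC2. Quantities
    with a zero denominator (or non-positive TyG arguments) come back as
    NaN with a logged warning.
    """
    out = pd.DataFrame(index=cohort.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ldl"] = friedewald_ldl(cohort["tc"], cohort["hdl"], cohort["tag"])
        hdl = cohort["hdl"].to_numpy(dtype=float)
        out["athero_index"] = np.where(hdl > 0, cohort["tc"] / hdl, np.nan)
        out["tag_hdl"] = np.where(hdl > 0, cohort["tag"] / hdl, np.nan)
        out["ldl_hdl"] = np.where(hdl > 0, out["ldl"] / hdl, np.nan)
        prod = cohort["tag"].to_numpy(dtype=float) * cohort["glucose"].to_numpy(dtype=float)
        out["tyg"] = np.where(prod > 0, np.log(prod / 2.0), np.nan)
        c0 = cohort["c0"].to_numpy(dtype=float)
        ac2 = cohort["ac2"].to_numpy(dtype=float)
        out["betaox_init"] = np.where(c0 > 0, cohort["ac16"] / c0, np.nan)
        out["betaox_rate"] = np.where(ac2 > 0, cohort["ac16"] / ac2, np.nan)
    if out.isna().any().any():
        log.warning("derived_panel: %d rows have undefined derived quantities",
                    int(out.isna().any(axis=1).sum()))
    return out


def cook_positive(cohort: pd.DataFrame, config: CookConfig = CookConfig()) -> pd.Series:
    """Boolean mask of children meeting ≥3 metabolic-syndrome components."""
    waist_cut = np.nanpercentile(cohort["waist_circumference"], config.waist_percentile)
    components = (
        (cohort["tag"] >= config.tag_mg_dl).astype(int)
        + (cohort["hdl"] <= config.hdl_mg_dl).astype(int)
        + (cohort["glucose"] >= config.glucose_mg_dl).astype(int)
        + ((cohort["sbp_pct"] >= config.bp_percentile)
           | (cohort["dbp_pct"] >= config.bp_percentile)).astype(int)
        + (cohort["waist_circumference"] >= waist_cut).astype(int)
    )
    return components >= config.min_components


def screen_eligibility(cohort: pd.DataFrame,
                       config: CookConfig = CookConfig()
                       ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the healthy-development eligibility rules.

    In order: rows with incomplete analysis columns, then children
    screening positive for metabolic syndrome, then fasting violations
    (glucose ≥ 100 mg/dL). Rule sets are disjoint by application order.
    """
    missing_cols = [c for c in schema.REQUIRED_COLUMNS if c not in cohort.columns]
    if missing_cols:
        raise schema.SchemaError(f"cohort table missing required columns: {missing_cols}")

    report = ExclusionReport(input_n=len(cohort))
    kept = cohort

    incomplete = kept[list(schema.ANALYSIS_COLUMNS)].isna().any(axis=1)
    report.record("incomplete", kept.loc[incomplete, schema.ID_COLUMN].tolist())
    kept = kept.loc[~incomplete]

    mets = cook_positive(kept, config)
    report.record("metabolic_syndrome", kept.loc[mets, schema.ID_COLUMN].tolist())
    kept = kept.loc[~mets]

    fasting = kept["glucose"] >= FASTING_GLUCOSE_LIMIT
    report.record("fasting", kept.loc[fasting, schema.ID_COLUMN].tolist())
    kept = kept.loc[~fasting]

    log.info("eligibility screen: %d → %d (%s)", report.input_n, len(kept), report.counts)
    return kept.copy(), report


def robust_z(values: np.ndarray) -> np.ndarray:
    """Median-centred, scaled-MAD-standardized scores (MAD·1.4826)."""
    values = np.asarray(values, dtype=float)
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med)) * 1.4826
    if mad == 0:
        return np.full_like(values, np.nan)
    return (values - med) / mad


def flag_outliers(cohort: pd.DataFrame, threshold: float = 5.0
                  ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove children with an extreme robust z in any metabolite column.

    Child-level removal at |z| > ``threshold`` (default 5), z computed
    per metabolite as (x − median)/(1.4826·MAD). Columns with zero MAD
    are skipped with a warning. Deterministic.
    """
    if len(cohort) < 10:
        raise ValueError("outlier screen needs at least 10 rows")
    report = ExclusionReport(input_n=len(cohort))
    extreme = np.zeros(len(cohort), dtype=bool)
    for col in schema.METABOLITES:
        z = robust_z(cohort[col].to_numpy())
        if np.isnan(z).all():
            warnings.warn(f"flag_outliers: column {col!r} has zero MAD; skipped")
            continue
        extreme |= np.abs(z) > threshold
    report.record("metabolite_outlier", cohort.loc[extreme, schema.ID_COLUMN].tolist())
    return cohort.loc[~extreme].copy(), report
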