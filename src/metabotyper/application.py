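"""Phase-2 application of a frozen metabotype model.

Covers the paired pre/post transition analysis (counts, row percentages,
per-transition metabolite deltas, Bowker symmetry test) and descriptive
per-metabotype group comparisons with assumption-driven test selection
and covariate-adjusted linear models.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import schema

log = logging.getLogger(__name__)


def bowker_test(counts) -> tuple[float, int, float]:
    """McNemar–Bowker χ² test of symmetry for a k×k transition table.

    χ² = Σ_{i<j} (n_ij − n_ji)² / (n_ij + n_ji) with df = k(k−1)/2;
    off-diagonal pairs with n_ij + n_ji = 0 carry no information and are
    skipped, reducing df accordingly.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] != table.shape[1]:
        raise ValueError(f"Bowker test needs a square table, got shape {table.shape}")
    k = table.shape[0]
    if k < 2:
        raise ValueError("Bowker test needs k >= 2 categories")
    stat, df = 0.0, 0
    for i, j in itertools.combinations(range(k), 2):
        denom = table[i, j] + table[j, i]
        if denom == 0:
            continue
        stat += (table[i, j] - table[j, i]) ** 2 / denom
        df += 1
    if df == 0:
        return 0.0, 0, 1.0
    return float(stat), df, float(scipy.stats.chi2.sf(stat, df))


@dataclass
class TransitionTable:
    """Paired pre/post metabotype flows with per-transition deltas."""

    counts: pd.DataFrame                  # origin × destination
    row_percentages: pd.DataFrame
    percent_changed: float
    deltas: dict[tuple[str, str], pd.Series]   # mean post − pre per metabolite
    bowker_statistic: float
    bowker_df: int
    bowker_p: float

    def to_dict(self) -> dict:
        return {
            "counts": self.counts.to_dict(orient="split"),
            "row_percentages": self.row_percentages.to_dict(orient="split"),
            "percent_changed": self.percent_changed,
            "deltas": {f"{o}->{d}": s.to_dict() for (o, d), s in self.deltas.items()},
            "bowker": {"statistic": self.bowker_statistic, "df": self.bowker_df,
                       "p_value": self.bowker_p},
        }


def transition_table(pre_labels: pd.Series, post_labels: pd.Series,
                     pre_cohort: pd.DataFrame, post_cohort: pd.DataFrame,
                     metabolites=("tag", "tc", "glucose", "c0", "cit", "orn"),
                     alphabet=("METBA", "METLI", "METAA")) -> TransitionTable:
    """Cross-tabulate paired pre/post labels and summarize each flow.

    Children are paired by ``child_id``; unpaired children are excluded
    with a warning. Deltas are mean (post − pre) concentrations of the
    requested metabolites among the children taking each transition.
    """
    pre = pre_cohort.set_index(schema.ID_COLUMN)
    post = post_cohort.set_index(schema.ID_COLUMN)
    pre_lab = pd.Series(np.asarray(pre_labels), index=pre.index)
    post_lab = pd.Series(np.asarray(post_labels), index=post.index)
    shared = pre.index.intersection(post.index)
    unpaired = sorted(set(pre.index).symmetric_difference(post.index))
    if unpaired:
        warnings.warn(f"{len(unpaired)} unpaired children excluded: {unpaired[:5]}...")
    if len(shared) == 0:
        raise ValueError("no paired children")

    alphabet = list(alphabet)
    extra = (set(pre_lab.unique()) | set(post_lab.unique())) - set(alphabet)
    if extra:
        raise ValueError(f"labels outside the declared alphabet: {sorted(extra)}")

    o = pd.Categorical(pre_lab.loc[shared], categories=alphabet)
    d = pd.Categorical(post_lab.loc[shared], categories=alphabet)
    counts = pd.crosstab(o, d, dropna=False)
    counts.index = pd.Index(alphabet, name="origin")
    counts.columns = pd.Index(alphabet, name="destination")

    row_tot = counts.sum(axis=1).replace(0, np.nan)
    row_pct = counts.div(row_tot, axis=0) * 100.0

    total = counts.to_numpy().sum()
    changed = total - np.trace(counts.to_numpy())
    deltas = {}
    for origin in alphabet:
        for dest in alphabet:
            mask = (np.asarray(o) == origin) & (np.asarray(d) == dest)
            if not mask.any():
                continue
            ids = shared[mask]
            deltas[(origin, dest)] = (
                post.loc[ids, list(metabolites)].mean()
                - pre.loc[ids, list(metabolites)].mean())

    stat, df, p = bowker_test(counts.to_numpy())
    return TransitionTable(counts=counts, row_percentages=row_pct,
                           percent_changed=100.0 * changed / total,
                           deltas=deltas, bowker_statistic=stat,
                           bowker_df=df, bowker_p=p)


# ---------------------------------------------------------------------------
# per-metabotype group comparisons

AD_ALPHA = 0.05
DEFAULT_COVARIATES = ("age", "sex", "bmi_z", "waist_circumference")


def _groups_normal(groups) -> bool:
    from .normalize import anderson_normality

    return all(anderson_normality(g)[1] >= AD_ALPHA for g in groups)


def _dunn_bonferroni(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests after Kruskal–Wallis."""
    N = len(values)
    ranks = scipy.stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    groups = np.unique(labels)
    rows = []
    n_pairs = len(groups) * (len(groups) - 1) // 2
    for a, b in itertools.combinations(groups, 2):
        ra = ranks[labels == a].mean()
        rb = ranks[labels == b].mean()
        na = int((labels == a).sum())
        nb = int((labels == b).sum())
        z = (ra - rb) / np.sqrt(var_base * (1.0 / na + 1.0 / nb))
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": float(z),
                     "p_adjusted": float(min(1.0, p * n_pairs))})
    return pd.DataFrame(rows)


@dataclass
class GroupComparisonReport:
    summaries: pd.DataFrame            # variable × group descriptive stats
    tests: pd.DataFrame                # per-variable omnibus choice and p-values
    posthoc: dict[str, pd.DataFrame] = field(default_factory=dict)
    adjusted: dict[str, pd.DataFrame] = field(default_factory=dict)
    covariates: tuple = DEFAULT_COVARIATES

    def to_dict(self) -> dict:
        return {
            "summaries": self.summaries.reset_index().to_dict(orient="records"),
            "tests": self.tests.to_dict(orient="records"),
            "posthoc": {v: t.to_dict(orient="records") for v, t in self.posthoc.items()},
            "adjusted": {v: t.reset_index().to_dict(orient="records")
                         for v, t in self.adjusted.items()},
            "covariates": list(self.covariates),
        }


def group_comparison(cohort: pd.DataFrame, labels, variables,
                     covariates=DEFAULT_COVARIATES) -> GroupComparisonReport:
    """Compare variables across metabotypes with assumption-driven tests.

    Per variable: Anderson–Darling normality per group and Levene's
    homogeneity pick the omnibus test — ANOVA (normal, homoscedastic),
    Welch's ANOVA (normal, heteroscedastic) or Kruskal–Wallis — with the
    matching post hoc family (Tukey / Games–Howell / Dunn-Bonferroni).
    Omnibus p-values are Bonferroni-corrected across the variable list.
    Metabotype contrasts adjusted for the covariates come from an OLS
    fit per variable. Constant variables are skipped with a warning.
    """
    import pingouin as pg

    labels = pd.Series(np.asarray(labels), index=cohort.index, name="metabotype")
    groups = labels.unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 members")

    summaries = []
    test_rows = []
    posthoc: dict[str, pd.DataFrame] = {}
    adjusted: dict[str, pd.DataFrame] = {}
    n_vars = len(variables)

    for var in variables:
        values = cohort[var].to_numpy(dtype=float)
        if np.ptp(values[~np.isnan(values)]) == 0:
            warnings.warn(f"group_comparison: variable {var!r} is constant; skipped")
            continue
        by_group = [values[np.asarray(labels) == g] for g in groups]
        for g, vals in zip(groups, by_group):
            summaries.append({
                "variable": var, "metabotype": g, "n": len(vals),
                "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
                "median": float(np.median(vals)),
                "q1": float(np.percentile(vals, 25)), "q3": float(np.percentile(vals, 75)),
            })

        normal = _groups_normal(by_group)
        _, levene_p = scipy.stats.levene(*by_group, center="median")
        df = pd.DataFrame({"y": values, "metabotype": np.asarray(labels)})
        if normal and levene_p >= 0.05:
            test_name = "anova"
            _, p = scipy.stats.f_oneway(*by_group)
            tuk = pairwise_tukeyhsd(values, np.asarray(labels))
            posthoc[var] = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        elif normal:
            test_name = "welch_anova"
            p = float(pg.welch_anova(dv="y", between="metabotype", data=df)["p-unc"].iloc[0])
            posthoc[var] = pg.pairwise_gameshowell(dv="y", between="metabotype", data=df)
        else:
            test_name = "kruskal"
            _, p = scipy.stats.kruskal(*by_group)
            posthoc[var] = _dunn_bonferroni(values, np.asarray(labels))
        test_rows.append({"variable": var, "test": test_name, "normal": normal,
                          "levene_p": float(levene_p), "p_value": float(p),
                          "p_bonferroni": float(min(1.0, p * n_vars)),
                          "correction": f"bonferroni x{n_vars}"})

        model_df = cohort[list(covariates)].copy()
        model_df["y"] = values
        model_df["metabotype"] = np.asarray(labels)
        formula = "y ~ C(metabotype) + " + " + ".join(covariates)
        fit = smf.ols(formula, data=model_df).fit()
        keep = [ix for ix in fit.params.index if ix.startswith("C(metabotype)")]
        adjusted[var] = pd.DataFrame({
            "coef": fit.params[keep], "se": fit.bse[keep], "p_value": fit.pvalues[keep]})

    return GroupComparisonReport(
        summaries=pd.DataFrame(summaries).set_index(["variable", "metabotype"]),
        tests=pd.DataFrame(test_rows), posthoc=posthoc, adjusted=adjusted,
        covariates=tuple(covariates))
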