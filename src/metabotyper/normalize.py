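"""Per-variable normalization recipes, frozen for reuse on new cohorts.

For each variable the fitter evaluates a candidate set of strictly
monotone transforms and keeps the one with the smallest Anderson–Darling
normality statistic on the training values. The default candidates are
the smooth parametric maps — identity, natural log, Box–Cox,
Yeo–Johnson — with the ordered-quantile (rank → normal score) map held
back as a fallback for variables where no parametric candidate is
applicable. The rank map is deliberately not allowed to compete on the
AD statistic: it wins that contest by construction for *any* input, and
forcing a multimodal marginal onto an exact normal erases exactly the
between-cluster structure the downstream clustering is meant to find.
Smooth parametric transforms correct skew while preserving modes.

The fitted parameters, including the post-transform standardization and
the ordered-quantile reference table, are serializable and are reapplied
verbatim to new data: applying a recipe never refits anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

MIN_FIT_N = 20
PARAMETRIC_CANDIDATES = ("identity", "log", "boxcox", "yeojohnson")
CANDIDATES = PARAMETRIC_CANDIDATES + ("orderednorm",)


@dataclass
class VariableTransform:
    kind: str
    lmbda: float | None = None          # Box–Cox / Yeo–Johnson shape
    ref_x: np.ndarray | None = None     # ordered-quantile: sorted unique training values
    ref_score: np.ndarray | None = None  # ...and their normal scores
    mean: float = 0.0                    # post-transform standardization, frozen
    sd: float = 1.0
    ad_statistic: float = np.nan

    def raw(self, values: np.ndarray) -> np.ndarray:
        """Transform without standardization."""
        x = np.asarray(values, dtype=float)
        if self.kind == "identity":
            return x
        if self.kind == "log":
            return np.log(np.clip(x, 1e-12, None))
        if self.kind == "boxcox":
            return scipy.special.boxcox(np.clip(x, 1e-12, None), self.lmbda)
        if self.kind == "yeojohnson":
            return scipy.stats.yeojohnson(x, lmbda=self.lmbda)
        if self.kind == "orderednorm":
            return _interp_extrapolate(x, self.ref_x, self.ref_score)
        raise ValueError(f"unknown transform kind {self.kind!r}")

    def __call__(self, values: np.ndarray) -> np.ndarray:
        return (self.raw(values) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "lmbda": self.lmbda,
            "ref_x": None if self.ref_x is None else self.ref_x.tolist(),
            "ref_score": None if self.ref_score is None else self.ref_score.tolist(),
            "mean": self.mean, "sd": self.sd, "ad_statistic": self.ad_statistic,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VariableTransform":
        return cls(
            kind=d["kind"], lmbda=d["lmbda"],
            ref_x=None if d["ref_x"] is None else np.asarray(d["ref_x"], dtype=float),
            ref_score=None if d["ref_score"] is None else np.asarray(d["ref_score"], dtype=float),
            mean=d["mean"], sd=d["sd"], ad_statistic=d["ad_statistic"],
        )


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear tails (stays strictly monotone)."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        slope_lo = (fp[1] - fp[0]) / (xp[1] - xp[0])
        slope_hi = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(lo, fp[0] + (x - xp[0]) * slope_lo, y)
        y = np.where(hi, fp[-1] + (x - xp[-1]) * slope_hi, y)
    return y


def anderson_normality(values: np.ndarray) -> tuple[float, float]:
    """Anderson–Darling normality statistic and p-value (parameters estimated)."""
    res = scipy.stats.anderson(np.asarray(values, dtype=float), dist="norm",
                               method="interpolate")
    return float(res.statistic), float(res.pvalue)


def anderson_statistic(values: np.ndarray) -> float:
    return anderson_normality(values)[0]


def _fit_candidate(kind: str, x: np.ndarray) -> VariableTransform | None:
    if kind == "identity":
        return VariableTransform("identity")
    if kind == "log":
        if (x <= 0).any():
            return None
        return VariableTransform("log")
    if kind == "boxcox":
        if (x <= 0).any() or np.ptp(x) == 0:
            return None
        _, lmbda = scipy.stats.boxcox(x)
        return VariableTransform("boxcox", lmbda=float(lmbda))
    if kind == "yeojohnson":
        if np.ptp(x) == 0:
            return None
        _, lmbda = scipy.stats.yeojohnson(x)
        return VariableTransform("yeojohnson", lmbda=float(lmbda))
    if kind == "orderednorm":
        # Blom-style normal scores; ties share the mean score of their ranks
        n = len(x)
        ranks = scipy.stats.rankdata(x, method="average")
        scores = scipy.stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        order = np.argsort(x, kind="stable")
        xs, idx = np.unique(x[order], return_index=True)
        grouped = [scores[order][i:j].mean()
                   for i, j in zip(idx, list(idx[1:]) + [n])]
        if len(xs) < 2:
            return None
        return VariableTransform("orderednorm", ref_x=xs, ref_score=np.asarray(grouped))
    raise ValueError(kind)


def fit_variable(values: np.ndarray, candidates=PARAMETRIC_CANDIDATES,
                 fallback: str | None = "orderednorm") -> VariableTransform:
    """Select and freeze the best normalizing transform for one variable.

    Minimizes the AD statistic over ``candidates``; if none is
    applicable (non-positive values with only log-family candidates,
    degenerate inputs, ...) the ``fallback`` transform is fitted instead.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < MIN_FIT_N:
        raise ValueError(f"need at least {MIN_FIT_N} non-missing values to fit, got {len(x)}")
    best: VariableTransform | None = None
    for kind in candidates:
        cand = _fit_candidate(kind, x)
        if cand is None:
            continue
        t = cand.raw(x)
        if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
            continue
        cand.ad_statistic = anderson_statistic(t)
        if best is None or cand.ad_statistic < best.ad_statistic:
            best = cand
    if best is None and fallback is not None:
        best = _fit_candidate(fallback, x)
        if best is not None:
            best.ad_statistic = anderson_statistic(best.raw(x))
    if best is None:
        raise ValueError("no candidate transform is applicable")
    t = best.raw(x)
    best.mean = float(np.mean(t))
    best.sd = float(np.std(t, ddof=1))
    return best


@dataclass
class NormalizationRecipe:
    """Frozen per-variable transforms; reapplicable without refitting."""

    transforms: dict[str, VariableTransform]

    @classmethod
    def fit(cls, cohort: pd.DataFrame, variables) -> "NormalizationRecipe":
        return cls({v: fit_variable(cohort[v].to_numpy()) for v in variables})

    def apply(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """Return the cohort with recipe variables replaced by their
        standardized transformed values (row-wise independent)."""
        out = cohort.copy()
        for var, tr in self.transforms.items():
            out[var] = tr(cohort[var].to_numpy())
        return out

    @property
    def variables(self) -> list[str]:
        return list(self.transforms)

    def to_dict(self) -> dict:
        return {v: t.to_dict() for v, t in self.transforms.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationRecipe":
        return cls({v: VariableTransform.from_dict(t) for v, t in d.items()})
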