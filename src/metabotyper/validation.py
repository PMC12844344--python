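"""Internal validation of the metabotype partition.

Two complementary checks mirror the tool-development workflow:

* **stability** — retrain the SOM on bootstrap resamples of the children,
  reassign everyone, and measure agreement with the reference partition
  by the adjusted Rand index (chance-corrected, 1 = identical);
* **separability** — train a supervised Random Forest to predict the SOM
  labels from the same eight features and compare its held-out accuracy
  with a null distribution obtained by globally permuting the labels and
  retraining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.model_selection import train_test_split

from .som import SOMConfig, assign, train_som

log = logging.getLogger(__name__)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def silhouette_mean(features: np.ndarray, labels) -> float:
    """Mean silhouette s(i) = (b−a)/max(a,b) with Euclidean distances.

    Points in singleton clusters contribute s = 0.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    return float(silhouette_score(np.asarray(features, dtype=float), labels,
                                  metric="euclidean"))


@dataclass
class StabilityReport:
    B: int
    ari_values: np.ndarray        # NaN where a resample degenerated
    seed: int

    @property
    def valid(self) -> np.ndarray:
        return self.ari_values[~np.isnan(self.ari_values)]

    @property
    def mean_ari(self) -> float:
        return float(np.mean(self.valid))

    @property
    def percentile_interval(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.valid, [2.5, 97.5])
        return float(lo), float(hi)

    def to_dict(self) -> dict:
        lo, hi = self.percentile_interval
        return {"B": self.B, "mean_ari": self.mean_ari,
                "percentile_interval": [lo, hi], "seed": self.seed,
                "ari_values": [None if np.isnan(v) else float(v) for v in self.ari_values]}


def bootstrap_stability(features: np.ndarray, config: SOMConfig,
                        reference_labels, B: int = 50, seed: int = 0) -> StabilityReport:
    """Bootstrap cluster-stability assessment.

    For each of B resamples: draw n children with replacement, retrain
    the SOM (fresh child seed spawned from ``seed``), assign *all*
    original children to the retrained map, and compute the ARI against
    the reference partition. Resamples whose retrained map collapses
    below two occupied clusters are recorded as NaN and excluded from
    the mean.
    """
    X = np.asarray(features, dtype=float)
    reference = np.asarray(reference_labels)
    n = len(X)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    out = np.full(B, np.nan)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        som_seed = int(rng.integers(0, 2**31 - 1))
        idx = rng.integers(0, n, size=n)
        model = train_som(X[idx], SOMConfig(
            grid_length=config.grid_length, iterations=config.iterations,
            alpha_start=config.alpha_start, alpha_end=config.alpha_end,
            sigma_start=config.sigma_start, sigma_end=config.sigma_end,
            seed=som_seed))
        labels = assign(model, X)
        if len(np.unique(labels)) < 2:
            log.warning("bootstrap resample %d collapsed to one cluster; recorded as NA", b)
            continue
        out[b] = adjusted_rand_index(reference, labels)
    return StabilityReport(B=B, ari_values=out, seed=seed)


@dataclass
class SeparabilityReport:
    observed_accuracy: float
    null_accuracies: np.ndarray
    split: float
    seed: int
    rf_params: dict

    @property
    def n_perm(self) -> int:
        return len(self.null_accuracies)

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_accuracies))

    @property
    def p_value(self) -> float:
        return (1.0 + np.sum(self.null_accuracies >= self.observed_accuracy)) / (self.n_perm + 1.0)

    def to_dict(self) -> dict:
        return {"observed_accuracy": self.observed_accuracy,
                "null_mean": self.null_mean, "p_value": self.p_value,
                "n_perm": self.n_perm, "split": self.split, "seed": self.seed,
                "rf_params": self.rf_params,
                "null_accuracies": self.null_accuracies.tolist()}


RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


def _rf_accuracy(X, y, split, rng) -> float:
    rs = int(rng.integers(0, 2**31 - 1))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=rs)
    clf = RandomForestClassifier(random_state=rs, n_jobs=1, **RF_PARAMS)
    clf.fit(X_tr, y_tr)
    return float(clf.score(X_te, y_te))


def permutation_separability(features: np.ndarray, labels, n_perm: int = 250,
                             split: float = 0.8, seed: int = 0) -> SeparabilityReport:
    """Random-Forest separability of the partition against a permutation null.

    Observed accuracy is the overall proportion correct on the held-out
    20% of a stratified 80/20 split. Each permutation globally shuffles
    the labels, re-splits, retrains, and scores — so the null carries
    both the permutation and split variability.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 5:
        raise ValueError(f"every class needs at least 5 members to stratify; "
                         f"got {dict(zip(classes.tolist(), counts.tolist()))}")
    rng = np.random.default_rng(seed)
    observed = _rf_accuracy(X, y, split, rng)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = _rf_accuracy(X, rng.permutation(y), split, rng)
    return SeparabilityReport(observed_accuracy=observed, null_accuracies=null,
                              split=split, seed=seed, rf_params=dict(RF_PARAMS))
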