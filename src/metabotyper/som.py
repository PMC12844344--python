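"""Online Kohonen self-organizing map on a one-dimensional toroidal grid.

A 1×m rectangular grid with toroidal (wrap-around) topology is a ring of
m units. Training is the classic online rule: for each presented sample
the best-matching unit (BMU) is the codebook row nearest in Euclidean
distance, and every unit u moves toward the sample by

    w_u ← w_u + α(t) · exp(−d_ring(u, bmu)² / (2σ(t)²)) · (x − w_u)

with the learning rate α and neighborhood radius σ decaying linearly
over the total number of sample presentations. One "iteration" is a full
pass over the data in a freshly shuffled order; the default schedule is
100 passes with α: 0.05 → 0.01 and σ: m/2 → 0.3. The final radius is
kept below ~0.3 so late training decouples the units: on a 3-ring every
pair of units sits at ring distance 1, and a larger final radius keeps
dragging all codebook vectors toward the common mean. The codebook is
initialized from m distinct training rows drawn under the config seed,
so training is fully deterministic given (data, config).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sklearn.metrics import silhouette_score


@dataclass(frozen=True)
class SOMConfig:
    grid_length: int = 3
    iterations: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    sigma_start: float | None = None   # defaults to grid_length / 2
    sigma_end: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_length < 2:
            raise ValueError("grid_length must be at least 2")
        if self.iterations < 1:
            raise ValueError("iterations must be at least 1")
        if not (self.alpha_start >= self.alpha_end > 0):
            raise ValueError("need alpha_start >= alpha_end > 0")
        sigma0 = self.sigma_start if self.sigma_start is not None else self.grid_length / 2
        if not (sigma0 >= self.sigma_end > 0):
            raise ValueError("need sigma_start >= sigma_end > 0")

    @property
    def sigma0(self) -> float:
        return self.sigma_start if self.sigma_start is not None else self.grid_length / 2


@dataclass
class SOMModel:
    """Trained classifier: ring codebook plus frozen feature scaling context."""

    codebook: np.ndarray          # m × p
    feature_names: list[str]
    config: SOMConfig

    @property
    def m(self) -> int:
        return self.codebook.shape[0]

    def to_dict(self) -> dict:
        cfg = self.config
        return {"codebook": self.codebook.tolist(),
                "feature_names": self.feature_names,
                "config": {"grid_length": cfg.grid_length, "iterations": cfg.iterations,
                           "alpha_start": cfg.alpha_start, "alpha_end": cfg.alpha_end,
                           "sigma_start": cfg.sigma_start, "sigma_end": cfg.sigma_end,
                           "seed": cfg.seed}}

    @classmethod
    def from_dict(cls, d: dict) -> "SOMModel":
        return cls(codebook=np.asarray(d["codebook"], dtype=float),
                   feature_names=list(d["feature_names"]),
                   config=SOMConfig(**d["config"]))


def ring_distance(i: int, j: int, m: int) -> int:
    """Shortest path between units i and j on a ring of m units."""
    if not (0 <= i < m and 0 <= j < m):
        raise ValueError(f"unit indices must lie in [0, {m}), got ({i}, {j})")
    d = abs(i - j)
    return min(d, m - d)


def _ring_distance_matrix(m: int) -> np.ndarray:
    idx = np.arange(m)
    d = np.abs(idx[:, None] - idx[None, :])
    return np.minimum(d, m - d).astype(float)


def train_som(features: np.ndarray, config: SOMConfig,
              feature_names: list[str] | None = None) -> SOMModel:
    """Train the ring SOM; deterministic given features and config."""
    X = np.ascontiguousarray(features, dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature matrix contains NaN")
    n, p = X.shape
    m = config.grid_length
    if n < m:
        raise ValueError(f"need at least {m} samples to train a {m}-unit map")

    rng = np.random.default_rng(config.seed)
    codebook = X[rng.choice(n, size=m, replace=False)].copy()

    total = config.iterations * n
    t_frac = np.arange(total) / max(total - 1, 1)
    alphas = config.alpha_start + (config.alpha_end - config.alpha_start) * t_frac
    sigmas = config.sigma0 + (config.sigma_end - config.sigma0) * t_frac
    ring2 = _ring_distance_matrix(m) ** 2

    t = 0
    for _ in range(config.iterations):
        order = rng.permutation(n)
        for i in order:
            x = X[i]
            diff = x - codebook
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = alphas[t] * np.exp(ring2[bmu] / (-2.0 * sigmas[t] ** 2))
            codebook += h[:, None] * diff
            t += 1
    names = feature_names if feature_names is not None else [f"f{k}" for k in range(p)]
    return SOMModel(codebook=codebook, feature_names=list(names), config=config)


def assign(model: SOMModel, features: np.ndarray,
           feature_names: list[str] | None = None) -> np.ndarray:
    """Map each row to its BMU; ties break to the lowest unit index."""
    if feature_names is not None and list(feature_names) != list(model.feature_names):
        raise ValueError(
            f"feature columns {list(feature_names)} do not match the model's "
            f"{list(model.feature_names)}")
    X = np.asarray(features, dtype=float)
    if X.shape[1] != model.codebook.shape[1]:
        raise ValueError("feature dimension does not match the codebook")
    d2 = ((X[:, None, :] - model.codebook[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin takes the first minimum: the tie rule


def select_grid(features: np.ndarray, base_config: SOMConfig,
                grid_lengths=range(3, 7),
                feature_names: list[str] | None = None,
                ) -> tuple[SOMModel, dict[int, float]]:
    """Train one SOM per candidate ring length; pick the silhouette peak.

    Every candidate reuses ``base_config`` with its own ``grid_length``
    and the same seed. Rows are put in a canonical (lexicographic) order
    before training, so shuffling the input rows cannot change the
    outcome. Candidates that leave a unit empty, or that collapse to a
    single occupied unit, are ineligible. Returns the winning model and
    the silhouette score per eligible candidate.
    """
    canonical = np.asarray(features, dtype=float)[np.lexsort(np.asarray(features, dtype=float).T[::-1])]
    silhouettes: dict[int, float] = {}
    models: dict[int, SOMModel] = {}
    for m in grid_lengths:
        cfg = replace(base_config, grid_length=m, sigma_start=None)
        model = train_som(canonical, cfg, feature_names)
        labels = assign(model, canonical)
        occupied = np.unique(labels)
        if len(occupied) < m or len(occupied) < 2:
            continue  # empty unit: ineligible candidate
        silhouettes[m] = float(silhouette_score(canonical, labels, metric="euclidean"))
        models[m] = model
    if not silhouettes:
        raise RuntimeError("no eligible grid size: every candidate left units empty "
                           "or produced a single cluster")
    best = max(silhouettes, key=silhouettes.get)
    return models[best], silhouettes


@dataclass
class MetabotypeLabeling:
    """Characterization-based names for the units of a 3-ring SOM."""

    unit_names: dict[int, str]
    characterization: pd.DataFrame   # units × features, mean standardized values

    def to_dict(self) -> dict:
        return {"unit_names": {str(k): v for k, v in self.unit_names.items()},
                "characterization": self.characterization.to_dict(orient="split")}

    @classmethod
    def from_dict(cls, d: dict) -> "MetabotypeLabeling":
        char = pd.DataFrame(**{k: d["characterization"][k] for k in ("data", "index", "columns")})
        return cls({int(k): v for k, v in d["unit_names"].items()}, char)

    def names_for(self, unit_labels: np.ndarray) -> np.ndarray:
        return np.array([self.unit_names[int(u)] for u in unit_labels])


def name_clusters(model: SOMModel, features: np.ndarray,
                  unit_labels: np.ndarray) -> MetabotypeLabeling:
    """Name the three units by their standardized feature profile.

    METLI is the unit with the highest mean of the standardized glucose,
    TAG and TC features; METAA the remaining unit with the highest mean
    AAI; METBA the one left over. The rule reads the characterization
    table, not unit order, so relabeling units cannot change which
    children get which name. For m ≠ 3 units are named unit_0..unit_{m−1}.
    """
    names = model.feature_names
    char = pd.DataFrame(
        [features[unit_labels == u].mean(axis=0) if (unit_labels == u).any()
         else np.full(features.shape[1], np.nan)
         for u in range(model.m)],
        index=[f"unit_{u}" for u in range(model.m)], columns=names)

    if model.m != 3:
        return MetabotypeLabeling({u: f"unit_{u}" for u in range(model.m)}, char)

    lipid = char[["glucose", "tag", "tc"]].mean(axis=1).to_numpy()
    li = int(np.nanargmax(lipid))
    rest = [u for u in range(3) if u != li]
    aa = rest[int(np.nanargmax(char["aai"].to_numpy()[rest]))]
    ba = next(u for u in range(3) if u not in (li, aa))
    return MetabotypeLabeling({ba: "METBA", li: "METLI", aa: "METAA"}, char)
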