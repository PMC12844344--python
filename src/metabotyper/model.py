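"""Metabotype discovery model and its fitted results.

The public entry point mirrors the statsmodels idiom::

    model = MetabotypeModel(cohort, seed=42)
    res = model.fit()          # MetabotypeResults
    print(res.summary())
    res.bootstrap_stability(B=50)
    res.permutation_separability(n_perm=250)
    labels = res.classify(new_cohort)
    res.save("model.json")

``fit`` runs the full phase-1 pipeline: per-variable normalization, block
PCA on the amino-acid and acylcarnitine panels, construction of the AAI
and ACI composite indices, assembly of the eight-feature matrix
(glucose, TAG, TC, C0, ACI, AAI, Cit, Orn; z-scored), ring-SOM training
across candidate grid lengths with silhouette-based selection, and
characterization-based naming of the three metabotypes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import preprocess, schema
from .bundle import ModelBundle
from .normalize import NormalizationRecipe
from .pca import BlockPCA, assemble_features, build_index, fit_block_pca
from .som import (MetabotypeLabeling, SOMConfig, SOMModel, assign,
                  name_clusters, select_grid, train_som)
from .validation import (SeparabilityReport, StabilityReport,
                         bootstrap_stability, permutation_separability,
                         silhouette_mean)


class MetabotypeModel:
    """Unsupervised metabotype discovery on a baseline cohort table.

    Parameters
    ----------
    cohort
        Schema-conforming cohort table (see ``metabotyper.schema``).
    screen
        Apply the eligibility screen (completeness, metabolic-syndrome,
        fasting) and the metabolite outlier filter before fitting;
        exclusion reports end up on the fitted results.
    som_config
        Training schedule shared by all candidate grid lengths; its
        ``grid_length`` is overridden per candidate.
    seed
        Master seed; the SOM seed is derived from it.
    """

    def __init__(self, cohort: pd.DataFrame, *, screen: bool = False,
                 outlier_threshold: float = 5.0,
                 som_config: SOMConfig | None = None,
                 grid_lengths=range(3, 7), seed: int = 0):
        cohort = schema.validate_cohort(cohort)
        self.exclusions = []
        if screen:
            cohort, report = preprocess.screen_eligibility(cohort)
            self.exclusions.append(report)
            cohort, report = preprocess.flag_outliers(cohort, threshold=outlier_threshold)
            self.exclusions.append(report)
            cohort = cohort.reset_index(drop=True)
        self.cohort = cohort
        self.grid_lengths = list(grid_lengths)
        self.seed = seed
        som_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
        self.som_config = som_config if som_config is not None else SOMConfig(seed=som_seed)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MetabotypeModel":
        from .bundle import read_cohort
        return cls(read_cohort(path), **kwargs)

    def fit(self, grid_length: int | None = None) -> "MetabotypeResults":
        """Run the discovery pipeline; fix ``grid_length`` to skip selection."""
        cohort = self.cohort
        recipe = NormalizationRecipe.fit(cohort, schema.ANALYSIS_COLUMNS)
        normalized = recipe.apply(cohort)

        aa_pca = fit_block_pca(normalized[list(schema.AMINO_ACIDS)], "amino_acids")
        ac_pca = fit_block_pca(normalized[list(schema.ACYLCARNITINES)], "acylcarnitines")
        aai = build_index(aa_pca, normalized, "aai", selection=list(schema.AAI_VARIABLES))
        aci = build_index(ac_pca, normalized, "aci", selection=list(schema.ACI_VARIABLES))

        X, scaling = assemble_features(normalized, aai, aci)

        if grid_length is not None:
            som = train_som(X, replace(self.som_config, grid_length=grid_length,
                                       sigma_start=None),
                            feature_names=list(schema.SOM_FEATURES))
            unit_labels = assign(som, X)
            silhouettes = {grid_length: silhouette_mean(X, unit_labels)}
        else:
            som, silhouettes = select_grid(X, self.som_config, self.grid_lengths,
                                           feature_names=list(schema.SOM_FEATURES))
            unit_labels = assign(som, X)

        labeling = name_clusters(som, X, unit_labels)
        return MetabotypeResults(self, recipe, aa_pca, ac_pca, aai, aci,
                                 scaling, som, labeling, X, unit_labels, silhouettes)


class MetabotypeResults:
    """Fitted metabotype model: estimates, diagnostics and frozen artifacts.

    Attributes
    ----------
    labels_ : pandas.Series
        Named metabotype per training child (METBA/METLI/METAA).
    unit_labels_ : numpy.ndarray
        Raw BMU indices per training child.
    silhouette_by_grid_ : dict[int, float]
        Mean silhouette per candidate grid length (eligible candidates).
    features_ : numpy.ndarray
        The z-scored n×8 training feature matrix.
    """

    def __init__(self, model: MetabotypeModel, recipe: NormalizationRecipe,
                 aa_pca: BlockPCA, ac_pca: BlockPCA, aai, aci, scaling,
                 som: SOMModel, labeling: MetabotypeLabeling,
                 features: np.ndarray, unit_labels: np.ndarray,
                 silhouettes: dict[int, float]):
        self.model = model
        self.recipe = recipe
        self.aa_pca = aa_pca
        self.ac_pca = ac_pca
        self.aai = aai
        self.aci = aci
        self.scaling = scaling
        self.som = som
        self.labeling = labeling
        self.features_ = features
        self.unit_labels_ = unit_labels
        self.silhouette_by_grid_ = silhouettes
        self.labels_ = pd.Series(labeling.names_for(unit_labels),
                                 index=model.cohort.index, name="metabotype")

    # -- diagnostics -------------------------------------------------------

    @property
    def n_metabotypes(self) -> int:
        return self.som.m

    @property
    def silhouette_(self) -> float:
        return self.silhouette_by_grid_[self.som.m]

    @property
    def cluster_sizes_(self) -> pd.Series:
        return self.labels_.value_counts()

    def bootstrap_stability(self, B: int = 50, seed: int | None = None) -> StabilityReport:
        """Bootstrap ARI stability of the SOM partition (indices stay frozen)."""
        if seed is None:
            seed = self.model.seed + 1
        return bootstrap_stability(self.features_, self.som.config,
                                   self.unit_labels_, B=B, seed=seed)

    def permutation_separability(self, n_perm: int = 250, split: float = 0.8,
                                 seed: int | None = None) -> SeparabilityReport:
        """Random-Forest separability of the partition vs a permutation null."""
        if seed is None:
            seed = self.model.seed + 2
        return permutation_separability(self.features_, self.unit_labels_,
                                        n_perm=n_perm, split=split, seed=seed)

    # -- frozen-model application -----------------------------------------

    def to_bundle(self) -> ModelBundle:
        return ModelBundle(recipe=self.recipe, aai=self.aai, aci=self.aci,
                           scaling=self.scaling, som=self.som,
                           labeling=self.labeling, seed=self.model.seed)

    def classify(self, cohort: pd.DataFrame) -> pd.Series:
        """Classify a new cohort with the frozen pipeline (never refits)."""
        return self.to_bundle().classify(cohort)

    def save(self, path) -> None:
        from .bundle import save_bundle
        save_bundle(self.to_bundle(), path)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = []
        add = lines.append
        add("Metabotype discovery results")
        add("=" * 64)
        add(f"children (training)    {len(self.labels_)}")
        add(f"features               {', '.join(self.som.feature_names)}")
        add(f"selected grid          {self.som.m} x 1 (toroidal ring)")
        add(f"mean silhouette        {self.silhouette_: .3f}")
        add("")
        add("silhouette by grid length:")
        for m in sorted(self.silhouette_by_grid_):
            marker = "  <- selected" if m == self.som.m else ""
            add(f"  {m} x 1   {self.silhouette_by_grid_[m]: .4f}{marker}")
        add("")
        add("cluster sizes:")
        sizes = self.cluster_sizes_
        for name in sizes.index:
            add(f"  {name:6s} {sizes[name]:5d}  ({100 * sizes[name] / len(self.labels_):.0f}%)")
        add("")
        add("unit characterization (mean standardized feature values):")
        char = self.labeling.characterization.copy()
        char.index = [f"{u} [{self.labeling.unit_names[i]}]"
                      for i, u in enumerate(char.index)]
        add(char.round(2).to_string())
        add(f"\nrun id: {self.to_bundle().run_id}")
        return "\n".join(lines)

    def plot_codebook(self, ax=None):
        """Heatmap of the codebook: units × features, standardized scale."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 2 + 0.5 * self.som.m))
        im = ax.imshow(self.som.codebook, cmap="RdBu_r", aspect="auto",
                       vmin=-2.5, vmax=2.5)
        ax.set_xticks(range(len(self.som.feature_names)),
                      self.som.feature_names, rotation=45, ha="right")
        ax.set_yticks(range(self.som.m),
                      [self.labeling.unit_names[u] for u in range(self.som.m)])
        ax.figure.colorbar(im, ax=ax, label="standardized level")
        ax.set_title("SOM codebook vectors")
        return ax
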