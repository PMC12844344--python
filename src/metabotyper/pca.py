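"""Block PCA on metabolite panels and loading-weighted composite indices.

Separate PCAs are fitted on the correlation matrices of the amino-acid
and acylcarnitine blocks; components with eigenvalue > 1 are retained
(Kaiser criterion). A composite index (AAI for amino acids, ACI for
acylcarnitines) is a variance-fraction-weighted, loading-weighted linear
combination of the standardized member variables over the retained
components, with its sign oriented so the index correlates positively
with the mean of its members on the training data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BlockPCA:
    """Eigendecomposition of one metabolite block's correlation matrix."""

    block: str
    variables: list[str]
    eigenvalues: np.ndarray            # descending, all components
    loadings: np.ndarray               # p × k for the k retained components (eigvec·√λ)
    variance_fractions: np.ndarray     # length k
    n_retained: int


class CollinearityError(ValueError):
    pass


def fit_block_pca(block_table: pd.DataFrame, block: str) -> BlockPCA:
    """PCA of a standardized metabolite block via its correlation matrix.

    Zero eigenvalues (perfectly collinear inputs) are legal — they are
    simply never retained; degenerate inputs whose correlation matrix is
    undefined (constant columns, NaNs) raise :class:`CollinearityError`
    naming the offending columns. Eigenvalues within 0.1 of the Kaiser
    cutoff trigger an instability warning.
    """
    variables = list(block_table.columns)
    X = block_table.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("a block needs at least 2 variables")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than variables")
    sd = X.std(axis=0, ddof=1)
    constant = [v for v, s in zip(variables, sd) if s == 0 or not np.isfinite(s)]
    if constant:
        raise CollinearityError(f"correlation undefined for constant/NaN columns: {constant}")
    corr = np.corrcoef(X, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise CollinearityError("correlation matrix contains non-finite entries")

    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic sign: largest-|loading| element of each eigenvector positive
    for k in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[pivot, k] < 0:
            eigvecs[:, k] *= -1.0

    retained = int(np.sum(eigvals > 1.0))
    if np.any(np.abs(eigvals - 1.0) < 0.1):
        warnings.warn(
            f"block {block!r}: eigenvalues near 1 — the Kaiser-retained set is unstable")
    if retained == 0:
        retained = 1  # degenerate near-identity correlation: keep the top component
    loadings = eigvecs[:, :retained] * np.sqrt(eigvals[:retained])
    fractions = eigvals[:retained] / len(variables)
    return BlockPCA(block=block, variables=variables, eigenvalues=eigvals,
                    loadings=loadings, variance_fractions=fractions,
                    n_retained=retained)


@dataclass
class IndexDefinition:
    """A frozen composite metabolite index (AAI or ACI).

    ``weights`` already folds together the per-component variance
    fractions, the loadings of the selected variables and the
    orientation, so the index is a single dot product against the
    standardized member values; ``var_means``/``var_sds`` freeze the
    training-data standardization of the members (on the normalized
    scale).
    """

    name: str
    variables: list[str]
    weights: np.ndarray
    orientation: int
    var_means: np.ndarray
    var_sds: np.ndarray
    component_fractions: list[float]

    def to_dict(self) -> dict:
        return {"name": self.name, "variables": self.variables,
                "weights": self.weights.tolist(), "orientation": self.orientation,
                "var_means": self.var_means.tolist(), "var_sds": self.var_sds.tolist(),
                "component_fractions": list(self.component_fractions)}

    @classmethod
    def from_dict(cls, d: dict) -> "IndexDefinition":
        return cls(name=d["name"], variables=list(d["variables"]),
                   weights=np.asarray(d["weights"], dtype=float),
                   orientation=int(d["orientation"]),
                   var_means=np.asarray(d["var_means"], dtype=float),
                   var_sds=np.asarray(d["var_sds"], dtype=float),
                   component_fractions=list(d["component_fractions"]))


def build_index(pca: BlockPCA, training: pd.DataFrame, name: str,
                selection: list[str] | float | None = None) -> IndexDefinition:
    """Derive a composite index from a fitted block PCA.

    ``selection`` is either an explicit member-variable list, an absolute
    loading threshold (keep variables exceeding it on any retained
    component), or None to keep every block variable. The orientation is
    flipped, if needed, so the index rises with its members' mean.
    """
    if pca.n_retained < 1:
        raise ValueError("PCA has no retained components")
    if selection is None:
        members = list(pca.variables)
    elif isinstance(selection, float):
        keep = np.abs(pca.loadings).max(axis=1) > selection
        members = [v for v, k in zip(pca.variables, keep) if k]
    else:
        members = list(selection)
        unknown = [v for v in members if v not in pca.variables]
        if unknown:
            raise ValueError(f"selection names variables outside the block: {unknown}")
    if not members:
        raise ValueError("index selection is empty")

    rows = [pca.variables.index(v) for v in members]
    # fold variance-fraction component weights into one per-variable weight
    weights = (pca.loadings[rows, :] * pca.variance_fractions[None, :]).sum(axis=1)

    X = training[members].to_numpy(dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    z = (X - means) / sds
    raw_index = z @ weights
    member_mean = z.mean(axis=1)
    corr = np.corrcoef(raw_index, member_mean)[0, 1]
    orientation = -1 if corr < 0 else 1

    return IndexDefinition(name=name, variables=members,
                           weights=orientation * weights, orientation=orientation,
                           var_means=means, var_sds=sds,
                           component_fractions=pca.variance_fractions.tolist())


def compute_index(definition: IndexDefinition, cohort: pd.DataFrame) -> pd.Series:
    """Evaluate a frozen index on (normalized-scale) cohort values."""
    missing = [v for v in definition.variables if v not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks index variables: {missing}")
    X = cohort[definition.variables].to_numpy(dtype=float)
    z = (X - definition.var_means) / definition.var_sds
    return pd.Series(z @ definition.weights, index=cohort.index, name=definition.name)


@dataclass
class FeatureScaling:
    """Frozen z-scoring of the SOM feature matrix."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def to_dict(self) -> dict:
        return {"feature_names": self.feature_names,
                "means": self.means.tolist(), "sds": self.sds.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureScaling":
        return cls(list(d["feature_names"]),
                   np.asarray(d["means"], dtype=float),
                   np.asarray(d["sds"], dtype=float))


def assemble_features(cohort: pd.DataFrame, aai: IndexDefinition, aci: IndexDefinition,
                      scaling: FeatureScaling | None = None,
                      ) -> tuple[np.ndarray, FeatureScaling]:
    """Build the n×8 SOM feature matrix in fixed column order.

    Columns: glucose, TAG, TC, C0, ACI, AAI, Cit, Orn — the first four
    and the last two taken from the (normalized) cohort, the indices
    evaluated from their frozen definitions; all eight z-scored. Pass a
    frozen ``scaling`` to reuse training parameters on new data.
    """
    from .schema import SOM_FEATURES

    cols = {}
    for name in SOM_FEATURES:
        if name == "aai":
            cols[name] = compute_index(aai, cohort).to_numpy()
        elif name == "aci":
            cols[name] = compute_index(aci, cohort).to_numpy()
        else:
            if name not in cohort.columns:
                raise KeyError(f"cohort lacks feature column {name!r}")
            cols[name] = cohort[name].to_numpy(dtype=float)
    X = np.column_stack([cols[name] for name in SOM_FEATURES])
    if scaling is None:
        scaling = FeatureScaling(list(SOM_FEATURES), X.mean(axis=0), X.std(axis=0, ddof=1))
    return (X - scaling.means) / scaling.sds, scaling
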