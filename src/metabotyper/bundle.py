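"""Cohort CSV I/O and lossless serialization of trained model bundles.

A :class:`ModelBundle` ties together everything needed to classify a new
cohort with nothing refitted: the normalization recipe, both index
definitions, the frozen feature scaling, the SOM codebook and the
unit-naming map, stamped with a content-derived run ID so components
from different training runs cannot be silently mixed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import schema
from .normalize import NormalizationRecipe
from .pca import FeatureScaling, IndexDefinition, assemble_features
from .som import MetabotypeLabeling, SOMModel, assign

SCHEMA_VERSION = 1


def read_cohort(path) -> pd.DataFrame:
    """Read and schema-validate a cohort CSV."""
    table = pd.read_csv(path, float_precision="round_trip")
    return schema.validate_cohort(table)


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort CSV at full float precision (read's inverse)."""
    table.to_csv(path, index=False, float_format="%.17g")


class BundleError(ValueError):
    pass


@dataclass
class ModelBundle:
    recipe: NormalizationRecipe
    aai: IndexDefinition
    aci: IndexDefinition
    scaling: FeatureScaling
    som: SOMModel
    labeling: MetabotypeLabeling
    seed: int
    run_id: str = ""

    def content_hash(self) -> str:
        payload = json.dumps({
            "recipe": self.recipe.to_dict(), "aai": self.aai.to_dict(),
            "aci": self.aci.to_dict(), "scaling": self.scaling.to_dict(),
            "som": self.som.to_dict(), "labeling": self.labeling.to_dict(),
            "seed": self.seed}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def __post_init__(self) -> None:
        if not self.run_id:
            self.run_id = self.content_hash()

    def classify(self, cohort: pd.DataFrame, expected_run_id: str | None = None) -> pd.Series:
        """Classify a new cohort with the frozen pipeline.

        Applies, in order, the frozen normalization recipe, the frozen
        index definitions and feature scaling, BMU assignment, and the
        frozen unit naming. Nothing is refitted. ``expected_run_id``
        guards against mixing artifacts from different training runs.
        """
        if expected_run_id is not None and expected_run_id != self.run_id:
            raise BundleError(
                f"run ID mismatch: bundle is {self.run_id}, expected {expected_run_id}")
        cohort = schema.validate_cohort(cohort)
        normalized = self.recipe.apply(cohort)
        X, _ = assemble_features(normalized, self.aai, self.aci, scaling=self.scaling)
        units = assign(self.som, X)
        return pd.Series(self.labeling.names_for(units), index=cohort.index,
                         name="metabotype")

    def to_dict(self) -> dict:
        return {"schema_version": SCHEMA_VERSION, "run_id": self.run_id,
                "seed": self.seed, "recipe": self.recipe.to_dict(),
                "aai": self.aai.to_dict(), "aci": self.aci.to_dict(),
                "scaling": self.scaling.to_dict(), "som": self.som.to_dict(),
                "labeling": self.labeling.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelBundle":
        version = d.get("schema_version")
        if version != SCHEMA_VERSION:
            raise BundleError(
                f"bundle schema version {version!r} is not supported "
                f"(this build reads version {SCHEMA_VERSION}); re-fit or upgrade")
        required = ("recipe", "aai", "aci", "scaling", "som", "labeling", "seed", "run_id")
        missing = [k for k in required if k not in d]
        if missing:
            raise BundleError(f"bundle file incomplete; missing {missing}")
        bundle = cls(recipe=NormalizationRecipe.from_dict(d["recipe"]),
                     aai=IndexDefinition.from_dict(d["aai"]),
                     aci=IndexDefinition.from_dict(d["aci"]),
                     scaling=FeatureScaling.from_dict(d["scaling"]),
                     som=SOMModel.from_dict(d["som"]),
                     labeling=MetabotypeLabeling.from_dict(d["labeling"]),
                     seed=int(d["seed"]), run_id=d["run_id"])
        if bundle.content_hash() != d["run_id"]:
            raise BundleError("bundle content does not match its run ID (corrupt or edited file)")
        return bundle


def save_bundle(bundle: ModelBundle, path) -> None:
    Path(path).write_text(json.dumps(bundle.to_dict()))


def load_bundle(path) -> ModelBundle:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise BundleError(f"cannot parse bundle file {path}: {exc}") from exc
    return ModelBundle.from_dict(payload)


def classify_new(bundle: ModelBundle | str | Path, cohort: pd.DataFrame,
                 expected_run_id: str | None = None) -> pd.Series:
    """Classify a cohort with a frozen bundle (given in memory or as a path)."""
    if not isinstance(bundle, ModelBundle):
        bundle = load_bundle(bundle)
    return bundle.classify(cohort, expected_run_id=expected_run_id)
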