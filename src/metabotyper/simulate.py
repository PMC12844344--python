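"""Synthetic cohort generator with latent metabotype structure.

Emulates a targeted serum metabolomics panel (free carnitine, eleven
acylcarnitines, eleven amino acids), serum chemistry, and anthropometrics
for schoolchildren drawn from a three-component mixture:

* ``BA`` — balanced profile, the mixture baseline;
* ``LI`` — lipid/glucose-elevated profile (standardized upward shift on
  TAG, TC and fasting glucose);
* ``AA`` — amino-acid-elevated profile (upward shift on the nine
  index amino acids plus citrulline and ornithine, with palmitoyl-
  carnitine AC16 multiplicatively suppressed so the β-oxidation
  initiation proxy AC16/C0 is low).

Metabolites are log-normal within cluster (block-equicorrelated on the
log scale, which yields a dominant first principal component per block);
chemistry and anthropometrics are normal on the raw scale, truncated at
zero. Anthropometrics carry no cluster signal by default.

All randomness flows through :func:`numpy.random.default_rng`, so a given
spec + seed reproduces tables bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema

LABELS = ("BA", "LI", "AA")

#: metabolite marginals: median μM and SD of log-concentration
METABOLITE_MARGINALS: dict[str, tuple[float, float]] = {
    "c0": (30.0, 0.22),
    "ac2": (7.0, 0.25), "ac3": (0.35, 0.28), "ac4": (0.25, 0.30),
    "ac5": (0.15, 0.30), "ac6": (0.08, 0.32), "ac8": (0.10, 0.32),
    "ac10": (0.15, 0.32), "ac12": (0.10, 0.30), "ac14": (0.12, 0.28),
    "ac16": (1.0, 0.25), "ac18": (0.45, 0.25),
    "ala": (330.0, 0.20), "gly": (230.0, 0.22), "arg": (55.0, 0.25),
    "met": (24.0, 0.22), "pro": (170.0, 0.25), "val": (210.0, 0.18),
    "leu": (115.0, 0.18), "phe": (55.0, 0.15), "tyr": (58.0, 0.20),
    "cit": (28.0, 0.22), "orn": (55.0, 0.25),
}

#: chemistry marginals: mean and SD, mg/dL
CHEMISTRY_MARGINALS: dict[str, tuple[float, float]] = {
    "glucose": (85.0, 7.0),
    "tag": (80.0, 28.0),
    "tc": (158.0, 26.0),
    "hdl": (52.0, 11.0),
}


class GeneratorError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Configuration of the synthetic-cohort mixture.

    Default shift magnitudes are the package's calibrated study
    conditions: they place the mean silhouette of the three-unit SOM
    partition of the default n=658 cohort in the 0.30–0.40 band typical
    of healthy pediatric metabolomes (see docs/methods.md).
    """

    n_children: int = 658
    proportions: tuple[float, float, float] = (0.47, 0.29, 0.24)
    lipid_shift_sd: float = 4.5
    aa_shift_sd: float = 4.5
    betaox_suppression: float = 0.45
    block_correlation: tuple[float, float] = (0.6, 0.45)  # (amino acids, acylcarnitines)
    noise_sd: float = 1.0
    aa_age_offset: float = 0.0  # years subtracted from AA-group ages (off by default)
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if p.shape != (3,) or (p <= 0).any() or abs(p.sum() - 1.0) > 1e-8:
            raise GeneratorError(f"proportions must be 3 positive weights summing to 1, got {self.proportions}")
        for rho in self.block_correlation:
            if not 0.0 <= rho < 1.0:
                raise GeneratorError("block_correlation must lie in [0, 1)")
        if self.lipid_shift_sd < 0 or self.aa_shift_sd < 0:
            raise GeneratorError("shift magnitudes must be non-negative")
        if not 0.0 < self.betaox_suppression <= 1.0:
            raise GeneratorError("betaox_suppression must lie in (0, 1]")
        if self.noise_sd < 0:
            raise GeneratorError("noise_sd must be non-negative")


def cluster_shift(spec: GeneratorSpec, label: str) -> dict[str, float]:
    """Standardized per-variable mean shift of one latent metabotype.

    Keys are cohort columns; values are in within-cluster SD units
    (log-SD units for metabolites, raw-SD units for chemistry).
    """
    if label == "LI":
        return {"tag": spec.lipid_shift_sd, "tc": spec.lipid_shift_sd,
                "glucose": spec.lipid_shift_sd}
    if label == "AA":
        shift = {v: spec.aa_shift_sd for v in schema.AAI_VARIABLES}
        shift["cit"] = spec.aa_shift_sd
        shift["orn"] = spec.aa_shift_sd
        # multiplicative AC16 suppression expressed as a log-scale shift
        shift["ac16"] = np.log(spec.betaox_suppression) / METABOLITE_MARGINALS["ac16"][1]
        return shift
    if label == "BA":
        return {}
    raise GeneratorError(f"unknown latent label {label!r}")


def _latent_z(spec: GeneratorSpec, labels: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Standardized latent values for every analysis column."""
    n = len(labels)
    rho_aa, rho_ac = spec.block_correlation
    factor_aa = rng.standard_normal(n)
    factor_ac = rng.standard_normal(n)

    shifts = {lab: cluster_shift(spec, lab) for lab in LABELS}
    z = {}
    for col in schema.ANALYSIS_COLUMNS:
        eps = rng.standard_normal(n)
        if col in schema.AMINO_ACIDS:
            noise = np.sqrt(rho_aa) * factor_aa + np.sqrt(1.0 - rho_aa) * eps
        elif col == schema.CARNITINE or col in schema.ACYLCARNITINES:
            noise = np.sqrt(rho_ac) * factor_ac + np.sqrt(1.0 - rho_ac) * eps
        else:  # chemistry: independent residuals, shifts carry the structure
            noise = eps
        mean = np.array([shifts[lab].get(col, 0.0) for lab in labels])
        z[col] = mean + spec.noise_sd * noise
    return pd.DataFrame(z)


def _z_to_values(z: pd.DataFrame) -> pd.DataFrame:
    """Map standardized latents to concentrations in their units."""
    out = {}
    for col, (median, log_sd) in METABOLITE_MARGINALS.items():
        out[col] = median * np.exp(log_sd * z[col].to_numpy())
    for col, (mean, sd) in CHEMISTRY_MARGINALS.items():
        out[col] = np.clip(mean + sd * z[col].to_numpy(), 1.0, None)
    return pd.DataFrame(out)


def _anthropometrics(n: int, ages: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    height = 90.0 + 4.6 * ages + rng.normal(0.0, 5.5, n)
    bmi = np.clip(rng.normal(16.9, 2.5, n), 12.0, None)
    weight = bmi * (height / 100.0) ** 2
    waist = np.clip(0.47 * height + rng.normal(0.0, 4.0, n), 35.0, None)
    return pd.DataFrame({
        "sex": rng.integers(0, 2, n),
        "age": ages,
        "weight": weight,
        "height": height,
        "waist_circumference": waist,
        "bmi_z": rng.normal(0.25, 1.15, n),
        "sbp_pct": np.clip(rng.normal(68.0, 22.0, n), 1.0, 99.0),
        "dbp_pct": np.clip(rng.normal(62.0, 22.0, n), 1.0, 99.0),
    })


def _assemble(values: pd.DataFrame, anthro: pd.DataFrame, phase: str,
              start_id: int = 1) -> pd.DataFrame:
    n = len(values)
    table = pd.concat([anthro.reset_index(drop=True), values.reset_index(drop=True)], axis=1)
    table.insert(0, schema.PHASE_COLUMN, phase)
    table.insert(0, schema.ID_COLUMN, [f"C{start_id + i:06d}" for i in range(n)])
    return table[list(schema.REQUIRED_COLUMNS)]


def generate_cohort(spec: GeneratorSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Generate a baseline cohort table plus its latent metabotype labels.

    Returns
    -------
    (table, labels)
        ``table`` follows :data:`metabotyper.schema.REQUIRED_COLUMNS`;
        ``labels`` is a Series over {BA, LI, AA} aligned with the table.
    """
    if spec.n_children < 3:
        raise GeneratorError("need at least 3 children to populate three metabotypes")
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(LABELS, size=spec.n_children, p=list(spec.proportions))

    z = _latent_z(spec, labels, rng)
    values = _z_to_values(z)

    ages = np.clip(rng.normal(8.9, 1.25, spec.n_children), 6.0, 11.0)
    if spec.aa_age_offset:
        ages = np.clip(ages - spec.aa_age_offset * (labels == "AA"), 6.0, 11.0)
    anthro = _anthropometrics(spec.n_children, ages, rng)

    table = _assemble(values, anthro, "baseline")
    return table, pd.Series(labels, name="metabotype", index=table.index)


@dataclass(frozen=True)
class TransitionSpec:
    """Post-intervention transition kernel between latent metabotypes.

    ``matrix[origin][dest]`` is the probability of moving from ``origin``
    to ``dest``; ``shifts[(origin, dest)]`` maps cohort columns to
    standardized mean shifts applied to children taking that transition.
    """

    matrix: dict[str, dict[str, float]]
    shifts: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for origin in LABELS:
            row = self.matrix.get(origin)
            if row is None:
                raise GeneratorError(f"transition matrix missing origin {origin!r}")
            total = sum(row.get(d, 0.0) for d in LABELS)
            if abs(total - 1.0) > 1e-8 or any(row.get(d, 0.0) < 0 for d in LABELS):
                raise GeneratorError(f"transition row for {origin!r} must be a probability vector")
        for shift in self.shifts.values():
            if not all(np.isfinite(list(shift.values()))):
                raise GeneratorError("transition shifts must be finite")


def identity_transition_spec() -> TransitionSpec:
    return TransitionSpec(matrix={lab: {lab: 1.0} for lab in LABELS})


def default_transition_spec(spec: GeneratorSpec) -> TransitionSpec:
    """Transition kernel emulating the reported post-intervention flows.

    Roughly half of balanced children stay put, lipid-predominant
    children are the most stable, and almost all amino-acid-predominant
    children migrate. A child taking ``origin → dest`` receives the
    difference of the two cluster shift vectors, i.e. moves to the
    destination profile in expectation.
    """
    matrix = {
        "BA": {"BA": 0.53, "LI": 0.39, "AA": 0.08},
        "LI": {"BA": 0.32, "LI": 0.61, "AA": 0.07},
        "AA": {"BA": 0.44, "LI": 0.47, "AA": 0.09},
    }
    shifts = {}
    for origin in LABELS:
        s_o = cluster_shift(spec, origin)
        for dest in LABELS:
            if dest == origin:
                continue
            s_d = cluster_shift(spec, dest)
            delta = {v: s_d.get(v, 0.0) - s_o.get(v, 0.0)
                     for v in set(s_o) | set(s_d)}
            shifts[(origin, dest)] = {v: d for v, d in delta.items() if d != 0.0}
    return TransitionSpec(matrix=matrix, shifts=shifts)


def apply_intervention(cohort: pd.DataFrame, labels: pd.Series,
                       tspec: TransitionSpec, seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Produce a paired post-intervention table for the same children.

    Each child samples a destination metabotype from its origin row of
    ``tspec.matrix`` and receives that transition's standardized shift
    (log-scale multiplicative for metabolites, additive in raw-SD units
    for chemistry). Returns the shifted table (phase ``post``) and the
    sampled destination labels.
    """
    if len(cohort) != len(labels):
        raise GeneratorError("cohort and labels are not aligned")
    rng = np.random.default_rng(seed)
    post = cohort.copy()
    post[schema.PHASE_COLUMN] = "post"
    origins = np.asarray(labels)
    dests = np.empty(len(cohort), dtype=object)
    for origin in LABELS:
        idx = np.flatnonzero(origins == origin)
        if idx.size == 0:
            continue
        probs = [tspec.matrix[origin].get(d, 0.0) for d in LABELS]
        dests[idx] = rng.choice(LABELS, size=idx.size, p=probs)
    for origin in LABELS:
        for dest in LABELS:
            shift = tspec.shifts.get((origin, dest), {})
            if not shift:
                continue
            mask = (origins == origin) & (dests == dest)
            if not mask.any():
                continue
            for col, delta in shift.items():
                if col in METABOLITE_MARGINALS:
                    log_sd = METABOLITE_MARGINALS[col][1]
                    post.loc[mask, col] = post.loc[mask, col] * np.exp(log_sd * delta)
                elif col in CHEMISTRY_MARGINALS:
                    sd = CHEMISTRY_MARGINALS[col][1]
                    post.loc[mask, col] = np.clip(post.loc[mask, col] + sd * delta, 1.0, None)
                else:
                    raise GeneratorError(f"transition shift on unknown column {col!r}")
    return post, pd.Series(dests.astype(str), name="metabotype", index=cohort.index)


def marginal_z_moments(spec: GeneratorSpec, column: str) -> tuple[float, float]:
    """Marginal (pooled across metabotypes) mean and SD of a column's latent z.

    The healthy cohort is a mixture, so its marginal spread combines the
    within-cluster residual with the between-cluster shift variance, and
    its marginal mean carries the proportion-weighted cluster shifts.
    """
    p = np.asarray(spec.proportions, dtype=float)
    shifts = np.array([cluster_shift(spec, lab).get(column, 0.0) for lab in LABELS])
    mean = float(np.sum(p * shifts))
    between = np.sum(p * (shifts - mean) ** 2)
    return mean, float(np.sqrt(spec.noise_sd**2 + between))


def marginal_z_sd(spec: GeneratorSpec, column: str) -> float:
    return marginal_z_moments(spec, column)[1]


def generate_mets_group(n: int, base_spec: GeneratorSpec, mets_shift_sd: float,
                        seed: int) -> pd.DataFrame:
    """Generate a metabolic-syndrome-like group of ``n`` children.

    Relative to the healthy baseline marginals: TAG and fasting glucose
    are raised by ``mets_shift_sd`` pooled SDs (pooled = the healthy
    cohort's marginal SD, which includes the between-metabotype
    variance), HDL lowered, total cholesterol moderately raised
    (dyslipidemia), waist circumference and blood-pressure percentiles
    elevated. Phase tag is ``mets``.
    """
    if n < 1:
        raise GeneratorError("n must be at least 1")
    if mets_shift_sd <= 0:
        raise GeneratorError("mets_shift_sd must be positive")
    rng = np.random.default_rng(seed)
    labels = np.array(["BA"] * n)
    z = _latent_z(replace(base_spec, n_children=max(n, 3)), labels, rng)
    # shifts are relative to the healthy cohort's MARGINAL mean, in units of
    # its marginal SD; the base draw is the balanced cluster, so the marginal
    # mean offset is added alongside the requested shift
    for col, k in (("tag", mets_shift_sd), ("glucose", mets_shift_sd),
                   ("hdl", -0.8 * mets_shift_sd), ("tc", 0.5 * mets_shift_sd)):
        mean, sd = marginal_z_moments(base_spec, col)
        z[col] += mean + k * sd
    values = _z_to_values(z)
    values["hdl"] = np.clip(values["hdl"], 15.0, None)

    ages = np.clip(rng.normal(8.9, 1.25, n), 6.0, 11.0)
    anthro = _anthropometrics(n, ages, rng)
    anthro["waist_circumference"] += 4.0 * mets_shift_sd
    anthro["sbp_pct"] = np.clip(anthro["sbp_pct"] + 12.0 * mets_shift_sd, 1.0, 99.0)
    anthro["dbp_pct"] = np.clip(anthro["dbp_pct"] + 12.0 * mets_shift_sd, 1.0, 99.0)
    anthro["bmi_z"] = anthro["bmi_z"] + 0.5 * mets_shift_sd

    return _assemble(values, anthro, "mets", start_id=900001)
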