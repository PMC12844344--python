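"""Synthetic cohort generator: mixture structure, shifts, determinism."""

import numpy as np
import pandas as pd
import pytest

from metabotyper import (GeneratorSpec, TransitionSpec, adjusted_rand_index,
                         apply_intervention, default_transition_spec,
                         generate_cohort, generate_mets_group,
                         identity_transition_spec, silhouette_mean)
from metabotyper import schema
from metabotyper.simulate import (GeneratorError, METABOLITE_MARGINALS,
                                  CHEMISTRY_MARGINALS, cluster_shift,
                                  marginal_z_sd)


def standardized(table):
    """Standardize analysis columns on their generative scale
    (log for metabolites, raw for chemistry)."""
    cols = []
    for c in schema.ANALYSIS_COLUMNS:
        v = table[c].to_numpy(dtype=float)
        if c in schema.METABOLITES:
            v = np.log(v)
        cols.append(v)
    X = np.column_stack(cols)
    return (X - X.mean(0)) / X.std(0)


class TestGenerateCohort:
    def test_reported_scale_label_counts(self):
        cohort, labels = generate_cohort(GeneratorSpec(n_children=658, seed=1))
        counts = labels.value_counts()
        # multinomial 3·SE around (306, 192, 160)
        for lab, expect, p in [("BA", 306, 0.47), ("LI", 192, 0.29), ("AA", 160, 0.24)]:
            se = np.sqrt(658 * p * (1 - p))
            assert abs(counts[lab] - expect) < 3 * se
        assert len(cohort) == 658
        assert list(cohort.columns) == list(schema.REQUIRED_COLUMNS)

    def test_all_values_physiological(self):
        cohort, _ = generate_cohort(GeneratorSpec(n_children=500, seed=2))
        assert (cohort[list(schema.METABOLITES)] > 0).all().all()
        assert (cohort[list(schema.CHEMISTRY)] > 0).all().all()
        assert cohort["age"].between(6, 11).all()
        assert cohort[schema.ID_COLUMN].is_unique

    def test_seed_determinism(self):
        spec = GeneratorSpec(n_children=100, seed=7)
        a, la = generate_cohort(spec)
        b, lb = generate_cohort(spec)
        pd.testing.assert_frame_equal(a, b)
        assert (la == lb).all()

    def test_zero_shift_groups_share_distribution(self):
        spec = GeneratorSpec(n_children=900, lipid_shift_sd=0, aa_shift_sd=0,
                             betaox_suppression=1.0, seed=3)
        cohort, labels = generate_cohort(spec)
        X = standardized(cohort)
        # silhouette of the latent 3-way split is chance-level
        assert abs(silhouette_mean(X, labels)) < 0.02

    def test_extreme_separation_recovered_by_nearest_centroid(self):
        # brute-force oracle: centroid assignment on standardized columns
        spec = GeneratorSpec(n_children=658, lipid_shift_sd=5, aa_shift_sd=5,
                             noise_sd=1.0, seed=4)
        cohort, labels = generate_cohort(spec)
        X = standardized(cohort)
        cents = np.stack([X[np.asarray(labels) == g].mean(0) for g in ("BA", "LI", "AA")])
        d2 = ((X[:, None, :] - cents[None]) ** 2).sum(-1)
        recovered = np.array(["BA", "LI", "AA"])[d2.argmin(1)]
        assert adjusted_rand_index(recovered, labels) > 0.99

    def test_mixture_consistency_large_n(self):
        _, labels = generate_cohort(GeneratorSpec(n_children=10_000, seed=5))
        freqs = labels.value_counts(normalize=True)
        for lab, p in zip(("BA", "LI", "AA"), (0.47, 0.29, 0.24)):
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(freqs[lab] - p) < 3 * se

    @pytest.mark.parametrize("bad", [
        dict(proportions=(0.5, 0.5, 0.2)),
        dict(proportions=(1.0, 0.0, 0.0)),
        dict(betaox_suppression=0.0),
        dict(betaox_suppression=1.5),
        dict(block_correlation=(1.0, 0.4)),
        dict(lipid_shift_sd=-1),
    ])
    def test_invalid_spec_rejected(self, bad):
        with pytest.raises(GeneratorError):
            GeneratorSpec(**bad)

    def test_too_few_children(self):
        with pytest.raises(GeneratorError):
            generate_cohort(GeneratorSpec(n_children=2))

    def test_aa_group_suppresses_betaox_initiation(self):
        cohort, labels = generate_cohort(GeneratorSpec(n_children=2000, seed=6))
        ratio = cohort["ac16"] / cohort["c0"]
        assert ratio[np.asarray(labels) == "AA"].median() < 0.6 * ratio[np.asarray(labels) == "BA"].median()


class TestIntervention:
    def test_identity_kernel_is_noop(self):
        cohort, labels = generate_cohort(GeneratorSpec(n_children=120, seed=8))
        post, post_labels = apply_intervention(cohort, labels,
                                               identity_transition_spec(), seed=9)
        pd.testing.assert_frame_equal(
            post.drop(columns=["phase"]), cohort.drop(columns=["phase"]))
        assert (post_labels == labels).all()

    def test_forced_migration_shifts_every_aa_child(self):
        cohort, labels = generate_cohort(GeneratorSpec(n_children=400, seed=10))
        tspec = TransitionSpec(
            matrix={"BA": {"BA": 1.0}, "LI": {"LI": 1.0}, "AA": {"BA": 1.0}},
            shifts={("AA", "BA"): {"ala": -2.0}})
        post, post_labels = apply_intervention(cohort, labels, tspec, seed=11)
        aa = np.asarray(labels) == "AA"
        assert (post_labels[aa] == "BA").all()
        assert (post.loc[aa, "ala"] != cohort.loc[aa, "ala"]).all()
        assert (post.loc[~aa, "ala"] == cohort.loc[~aa, "ala"]).all()

    def test_known_shift_recovered_by_paired_differencing(self):
        cohort, labels = generate_cohort(GeneratorSpec(n_children=3000, seed=12))
        delta_z = 1.5
        tspec = TransitionSpec(
            matrix={"BA": {"LI": 1.0}, "LI": {"LI": 1.0}, "AA": {"AA": 1.0}},
            shifts={("BA", "LI"): {"glucose": delta_z}})
        post, _ = apply_intervention(cohort, labels, tspec, seed=13)
        ba = np.asarray(labels) == "BA"
        observed = (post.loc[ba, "glucose"] - cohort.loc[ba, "glucose"]).mean()
        expected = delta_z * CHEMISTRY_MARGINALS["glucose"][1]
        assert observed == pytest.approx(expected, abs=1e-9)  # deterministic additive shift

    def test_row_mismatch_rejected(self):
        cohort, labels = generate_cohort(GeneratorSpec(n_children=50, seed=14))
        with pytest.raises(GeneratorError):
            apply_intervention(cohort, labels.iloc[:-1], identity_transition_spec(), seed=0)

    def test_default_kernel_rows_are_probability_vectors(self):
        tspec = default_transition_spec(GeneratorSpec())
        for origin, row in tspec.matrix.items():
            assert sum(row.values()) == pytest.approx(1.0)


class TestMetsGroup:
    def test_requested_size(self):
        table = generate_mets_group(203, GeneratorSpec(), mets_shift_sd=2.0, seed=15)
        assert len(table) == 203
        assert (table["phase"] == "mets").all()

    def test_cook_direction_shifts(self):
        spec = GeneratorSpec(seed=16)
        healthy, labels = generate_cohort(spec)
        ba = healthy.loc[np.asarray(labels) == "BA"]
        mets = generate_mets_group(2000, spec, mets_shift_sd=2.0, seed=17)
        assert mets["tag"].mean() > ba["tag"].mean()
        assert mets["glucose"].mean() > ba["glucose"].mean()
        assert mets["hdl"].mean() < ba["hdl"].mean()
        assert mets["waist_circumference"].mean() > ba["waist_circumference"].mean()
        assert mets["sbp_pct"].mean() > ba["sbp_pct"].mean()

    def test_two_pooled_sd_elevation_over_healthy_mean(self):
        spec = GeneratorSpec(seed=18)
        healthy, _ = generate_cohort(GeneratorSpec(n_children=20_000, seed=18))
        mets = generate_mets_group(20_000, spec, mets_shift_sd=2.0, seed=19)
        for col in ("tag", "glucose"):
            shift_sd = (mets[col].mean() - healthy[col].mean()) / healthy[col].std()
            assert shift_sd == pytest.approx(2.0, abs=0.1)

    def test_vanishing_shift_converges_to_healthy_marginals(self):
        spec = GeneratorSpec(seed=20)
        healthy, labels = generate_cohort(GeneratorSpec(n_children=20_000, seed=20))
        ba = healthy.loc[np.asarray(labels) == "BA"]
        mets = generate_mets_group(20_000, spec, mets_shift_sd=1e-9, seed=21)
        # screened variables converge to the healthy marginal mean,
        # untouched variables to the balanced profile (= their marginal)
        for col in ("tag", "glucose", "hdl"):
            assert abs(mets[col].mean() - healthy[col].mean()) < 0.07 * healthy[col].std()
        for col in ("ala", "c0"):
            assert abs(mets[col].mean() - ba[col].mean()) < 0.07 * healthy[col].std()

    def test_marginal_sd_includes_between_cluster_variance(self):
        spec = GeneratorSpec()
        assert marginal_z_sd(spec, "tag") > 2.0       # lipid shift contributes
        assert marginal_z_sd(spec, "hdl") == pytest.approx(spec.noise_sd)

    def test_invalid_args(self):
        with pytest.raises(GeneratorError):
            generate_mets_group(0, GeneratorSpec(), 2.0, 1)
        with pytest.raises(GeneratorError):
            generate_mets_group(10, GeneratorSpec(), 0.0, 1)


def test_silhouette_monotone_in_separation():
    """Downstream 3-cluster silhouette is non-decreasing in the shift scale."""
    from sklearn.cluster import KMeans

    sils = []
    for s in (0.0, 2.0, 4.5):
        cohort, _ = generate_cohort(GeneratorSpec(
            n_children=658, lipid_shift_sd=s, aa_shift_sd=s, seed=22))
        X = standardized(cohort)
        km = KMeans(3, n_init=5, random_state=0).fit(X)
        sils.append(silhouette_mean(X, km.labels_))
    assert sils[0] <= sils[1] <= sils[2]
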