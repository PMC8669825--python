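from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from ptgut.diversity import RelAbundanceTable, rarefy, relative_abundance
from ptgut.enterotyping import (
    EnterotypeFit, calinski_harabasz, detect_transitions, fit_enterotypes,
    pam, silhouette, total_cost, compare_enterotypes,
)
from ptgut.io_tables import CohortMetadata, ValidationError
from ptgut.synthetic_cohort import SynthConfig, generate_cohort

from conftest import two_blob_distances


def pam_oracle(d, k):
    """Exhaustive best medoid set by total nearest-medoid distance."""
    n = d.shape[0]
    best, best_cost = None, np.inf
    for medoids in combinations(range(n), k):
        cost = d[:, list(medoids)].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = medoids, cost
    labels = np.argmin(d[:, list(best)], axis=1)
    return labels, list(best), best_cost


def silhouette_oracle(d, labels):
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i]]
        if len(own) == 1:
            continue
        a = np.mean([d[i, j] for j in own if j != i])
        b = min(np.mean([d[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


class TestPam:
    def test_two_blobs_match_exhaustive_oracle(self):
        d, blob_labels, _ = two_blob_distances()
        labels, medoids = pam(d, 2)
        o_labels, o_medoids, o_cost = pam_oracle(d, 2)
        assert medoids == o_medoids
        assert total_cost(d, medoids) == pytest.approx(o_cost)
        # same partition as the blobs
        assert len(set(zip(labels, blob_labels))) == 2

    def test_k_n_minus_1_pairs_closest_points(self):
        rng = np.random.default_rng(0)
        coords = np.sort(rng.normal(size=6) * 5)
        d = np.abs(coords[:, None] - coords[None, :])
        labels, medoids = pam(d, 5)
        sizes = np.bincount(labels)
        assert sorted(sizes) == [1, 1, 1, 1, 2]
        _, _, o_cost = pam_oracle(d, 5)
        assert total_cost(d, medoids) == pytest.approx(o_cost)

    def test_deterministic(self):
        d, _, _ = two_blob_distances()
        l1, m1 = pam(d, 3)
        l2, m2 = pam(d, 3)
        assert np.array_equal(l1, l2) and m1 == m2

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(5):
            coords = rng.normal(size=(9, 2))
            d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            for k in (2, 3):
                _, medoids = pam(d, k)
                _, _, o_cost = pam_oracle(d, k)
                # PAM is a local search: never beats, rarely misses the optimum
                assert total_cost(d, medoids) <= o_cost + 0.05 * abs(o_cost)

    def test_invalid_k_rejected(self):
        d, _, _ = two_blob_distances()
        with pytest.raises(ValueError):
            pam(d, 1)
        with pytest.raises(ValueError):
            pam(d, 10)


class TestCalinskiHarabasz:
    def test_two_blobs_prefer_k2(self):
        # two well-separated Gaussian clouds (multivariate, so splitting a
        # cloud does not collapse the within-cluster dispersion)
        from scipy.spatial.distance import cdist

        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (8, 5))
        b = rng.normal(0, 1, (8, 5))
        b[:, 0] += 8
        x = np.vstack([a, b])
        d = cdist(x, x)
        scores = {}
        for k in (2, 3, 4):
            labels, _ = pam(d, k)
            scores[k] = calinski_harabasz(d, labels)
        assert scores[2] > scores[3] > scores[4]

    def test_equilateral_symmetry(self):
        # all pairwise distances equal: every equal-size split scores alike
        d = np.ones((6, 6)) - np.eye(6)
        s1 = calinski_harabasz(d, [0, 0, 0, 1, 1, 1])
        s2 = calinski_harabasz(d, [0, 1, 0, 1, 0, 1])
        assert s1 == pytest.approx(s2)

    def test_monotone_in_separation(self):
        prev = -np.inf
        labels = np.array([0] * 5 + [1] * 5)
        for gap in (2.0, 5.0, 20.0, 100.0):
            d, _, _ = two_blob_distances(gap=gap)
            score = calinski_harabasz(d, labels)
            assert score > prev
            prev = score

    def test_singleton_only_clustering_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            calinski_harabasz(d, [0, 1, 2])


class TestSilhouette:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(8, 2))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        labels = np.array([0, 0, 0, 1, 1, 1, 2, 2])
        s, mean = silhouette(d, labels)
        expected = silhouette_oracle(d, labels)
        assert np.allclose(s, expected, atol=1e-12)
        assert mean == pytest.approx(expected.mean())
        assert (s >= -1).all() and (s <= 1).all()

    def test_tight_far_blobs_high_mean(self):
        d, labels, _ = two_blob_distances(gap=50.0)
        _, mean = silhouette(d, labels)
        assert mean > 0.9

    def test_equidistant_point_scores_zero(self):
        # point 0 equidistant to its own cluster mate and the foreign cluster
        d = np.array([
            [0.0, 1.0, 1.0],
            [1.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
        ])
        s, _ = silhouette(d, [0, 0, 1])
        assert s[0] == pytest.approx(0.0)

    def test_singleton_cluster_scores_zero(self):
        d, _, _ = two_blob_distances()
        labels = np.array([0] + [1] * 9)
        s, _ = silhouette(d, labels)
        assert s[0] == 0.0

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(2)
        coords = rng.normal(size=(10, 3))
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        labels = np.array([0, 1] * 5)
        s, _ = silhouette(d, labels)
        ref = silhouette_samples(d, labels, metric="precomputed")
        assert np.allclose(s, ref, atol=1e-10)

    def test_single_cluster_rejected(self):
        d, _, _ = two_blob_distances()
        with pytest.raises(ValueError):
            silhouette(d, np.zeros(10, dtype=int))


class TestFitEnterotypes:
    def test_recovers_planted_two_states(self):
        table, _, _, truth = generate_cohort(SynthConfig(n_infants=30), seed=9)
        relab = relative_abundance(rarefy(table, 5000, seed=1))
        fit = fit_enterotypes(relab, range(2, 7), seed=0)
        assert fit.k == 2
        merged = fit.assignments().merge(truth.sample_states, on="sample_id")
        agree = (merged["enterotype_x"] == merged["enterotype_y"]).mean()
        assert max(agree, 1 - agree) > 0.9

    def test_cluster_names_follow_escherichia_dominance(self):
        table, _, _, truth = generate_cohort(SynthConfig(n_infants=30), seed=9)
        relab = relative_abundance(rarefy(table, 5000, seed=1))
        fit = fit_enterotypes(relab, range(2, 4), seed=0)
        prof = fit.cluster_profiles["Escherichia-Shigella"]
        named = {fit.names[c]: v for c, v in prof.items()}
        assert named["A"] > named["B"]
        # planted contrast: 45.4% vs 1.47% Escherichia-Shigella
        assert named["A"] == pytest.approx(0.454, abs=0.05)
        assert named["B"] == pytest.approx(0.0147, abs=0.05)

    def test_single_state_cohort_flags_weak_structure(self):
        config = SynthConfig(n_infants=25, p_enterotype_a=1.0,
                             transition_matrix=((1.0, 0.0), (0.0, 1.0)))
        table, _, _, _ = generate_cohort(config, seed=2)
        relab = relative_abundance(rarefy(table, 5000, seed=1))
        fit = fit_enterotypes(relab, range(2, 5), seed=0)
        assert fit.weak_structure
        assert fit.silhouette_profile[fit.k] < 0.25

    def test_partition_invariant_to_sample_order(self):
        table, _, _, _ = generate_cohort(SynthConfig(n_infants=15), seed=3)
        relab = relative_abundance(rarefy(table, 5000, seed=1))
        fit = fit_enterotypes(relab, range(2, 5), seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(relab.sample_ids))
        shuffled = RelAbundanceTable(
            [relab.sample_ids[i] for i in perm], list(relab.taxon_ids),
            relab.proportions[perm])
        fit2 = fit_enterotypes(shuffled, range(2, 5), seed=0)
        a = fit.assignments().set_index("sample_id")["enterotype"]
        b = fit2.assignments().set_index("sample_id")["enterotype"]
        b = b.loc[a.index]
        # identical partition up to cluster letter choice
        mapping = pd.crosstab(a, b)
        assert (mapping.to_numpy() > 0).sum() == fit.k

    def test_too_few_samples_rejected(self):
        relab = RelAbundanceTable(["a", "b"], ["x", "y"],
                                  np.array([[0.5, 0.5], [0.2, 0.8]]))
        with pytest.raises(ValueError):
            fit_enterotypes(relab, range(2, 3))

    def test_degenerate_identical_samples_rejected(self):
        relab = RelAbundanceTable(
            list("abcd"), ["x", "y"], np.tile([0.5, 0.5], (4, 1)))
        with pytest.raises(ValueError, match="degenerate"):
            fit_enterotypes(relab, range(2, 3))


def _manual_fit(sample_ids, enterotypes):
    k = len(set(enterotypes))
    letters = sorted(set(enterotypes))
    labels = np.array([letters.index(e) + 1 for e in enterotypes])
    return EnterotypeFit(
        k=k, sample_ids=list(sample_ids), labels=labels,
        medoid_ids=[sample_ids[0]], ch_profile={k: 1.0},
        silhouette_profile={k: 1.0},
        names={i + 1: letters[i] for i in range(k)},
        cluster_profiles=pd.DataFrame(
            np.zeros((k, 1)), index=range(1, k + 1), columns=["t"]),
        weak_structure=False)


def _manual_meta(sample_ids, infant_ids, cga):
    samples = pd.DataFrame({
        "sample_id": sample_ids, "infant_id": infant_ids,
        "corrected_ga": cga,
        "postnatal_age": [c - 28.0 for c in cga],
        "weight": 1500.0, "antibiotic": 0, "mech_vent": 0,
        "vol_mom": 900.0, "vol_dhm": 0.0, "vol_formula": 0.0,
        "fortifier": "HMF"})
    infants = pd.DataFrame({
        "infant_id": sorted(set(infant_ids)), "maternal_race": "white",
        "chorioamnionitis": 0, "prom": 0, "sex": "female",
        "delivery_mode": "c-section", "ga_birth": 28.0,
        "birth_weight": 1100.0})
    return CohortMetadata(samples, infants)


class TestTransitions:
    def test_aabb_one_transition_changer(self):
        ids = [f"s{i}" for i in range(4)]
        fit = _manual_fit(ids, ["A", "A", "B", "B"])
        meta = _manual_meta(ids, ["I1"] * 4, [29.0, 30.0, 31.0, 32.0])
        transitions, classes = detect_transitions(fit, meta)
        assert len(transitions) == 1
        row = transitions.iloc[0]
        assert (row["from_enterotype"], row["to_enterotype"]) == ("A", "B")
        assert classes.iloc[0]["class"] == "changer"

    def test_aba_two_transitions(self):
        ids = ["s0", "s1", "s2"]
        fit = _manual_fit(ids, ["A", "B", "A"])
        meta = _manual_meta(ids, ["I1"] * 3, [29.0, 30.0, 31.0])
        transitions, classes = detect_transitions(fit, meta)
        assert len(transitions) == 2
        assert classes.iloc[0]["n_transitions"] == 2

    def test_stable_infant_classified_exclusively(self):
        ids = ["s0", "s1"]
        fit = _manual_fit(ids, ["B", "B"])
        meta = _manual_meta(ids, ["I1"] * 2, [29.0, 30.0])
        _, classes = detect_transitions(fit, meta)
        assert classes.iloc[0]["class"] == "exclusively-B"

    def test_untimed_sample_rejected(self):
        ids = ["s0", "s1"]
        fit = _manual_fit(ids, ["A", "B"])
        meta = _manual_meta(ids, ["I1"] * 2, [29.0, 30.0])
        meta.samples.loc[1, "corrected_ga"] = np.nan
        with pytest.raises(ValidationError, match="time stamp"):
            detect_transitions(fit, meta)


class TestCompareEnterotypes:
    def test_identical_compositions_give_p_one(self):
        # covariate split identically between enterotypes
        ids = [f"s{i}" for i in range(8)]
        fit = _manual_fit(ids, ["A"] * 4 + ["B"] * 4)
        meta = _manual_meta(ids, [f"I{i}" for i in range(8)],
                            [29.0 + i for i in range(8)])
        meta.infants["chorioamnionitis"] = [1, 1, 0, 0, 1, 1, 0, 0]
        out = compare_enterotypes(fit, meta, categorical=("chorioamnionitis",),
                                  numeric=())
        row = out[(out.variable == "chorioamnionitis") & (out.level == "1")]
        assert row.iloc[0]["p"] == pytest.approx(1.0)

    def test_change_rows_present_with_classes(self, small_cohort):
        table, meta, _, _ = small_cohort
        relab = relative_abundance(rarefy(table, 2000, seed=7))
        fit = fit_enterotypes(relab, range(2, 4), seed=0)
        transitions, classes = detect_transitions(fit, meta)
        out = compare_enterotypes(fit, meta, classes=classes)
        assert "change_enterotype_precedes_switch" in set(out.variable)
        assert "change_enterotype_changer_infant" in set(out.variable)
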