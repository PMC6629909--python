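import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dfcstates import (
    DwfcCollection,
    RunConfig,
    assign_groups,
    cluster_centroids,
    cluster_groups,
    one_step_cluster,
    two_step_cluster,
)


def make_collection(edges, subjects, sessions=None, window_indices=None):
    n = edges.shape[0]
    meta = pd.DataFrame(
        {
            "subject_id": subjects,
            "session_id": sessions or ["ses0"] * n,
            "window_index": window_indices
            if window_indices is not None
            else _per_subject_counter(subjects),
            "window_start": 0,
            "window_length": 20,
        }
    )
    return DwfcCollection(edges, meta)


def _per_subject_counter(subjects):
    counts = {}
    out = []
    for s in subjects:
        out.append(counts.get(s, 0))
        counts[s] = out[-1] + 1
    return out


def normalize(X):
    return (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)


def planted_samples(rng, n_per_state=30, n_states=3, dim=60, noise=0.3):
    """Noisy copies of orthogonal-ish random patterns, plus labels."""
    patterns = normalize(rng.standard_normal((n_states, dim)))
    labels = np.repeat(np.arange(n_states), n_per_state)
    X = patterns[labels] + noise * rng.standard_normal((len(labels), dim))
    return normalize(X), labels + 1, patterns


class TestAssignGroups:
    def test_group_count_and_sizes(self, small_collection, small_config):
        # 6 subjects x 20 windows, S=5 -> 4 groups of 30 samples
        assignment = assign_groups(small_collection, small_config)
        assert assignment.n_groups == 4
        assert all(len(g) == 30 for g in assignment.groups)
        # each subject contributes exactly S samples to each group
        for g in assignment.groups:
            counts = small_collection.meta.iloc[g]["subject_id"].value_counts()
            assert set(counts) == {5}

    def test_chronological_blocks_are_consecutive(self, small_collection):
        cfg = RunConfig(group_size=5, grouping_mode="chronological")
        assignment = assign_groups(small_collection, cfg)
        first = small_collection.meta.iloc[assignment.groups[0]]
        assert set(first["window_index"]) == {0, 1, 2, 3, 4}

    def test_degenerate_single_group(self, rng):
        X = normalize(rng.standard_normal((8, 20)))
        coll = make_collection(X, ["a"] * 4 + ["b"] * 4)
        cfg = RunConfig(group_size=4)
        assignment = assign_groups(coll, cfg)
        assert assignment.n_groups == 1
        assert len(assignment.groups[0]) == 8

    def test_random_mode_seeding_contract(self, small_collection):
        groups = {}
        for seed in (1, 1, 2):
            cfg = RunConfig(group_size=5, grouping_mode="random", random_seed=seed)
            a = assign_groups(small_collection, cfg)
            groups.setdefault(seed, []).append(
                [np.sort(g).tolist() for g in a.groups]
            )
        assert groups[1][0] == groups[1][1]  # same seed, same assignment
        assert groups[1][0] != groups[2][0]  # different seed differs

    def test_nondivisor_group_size_names_valid_choices(self, small_collection):
        cfg = RunConfig(group_size=3)  # 20 windows per subject
        with pytest.raises(ValueError, match=r"valid S values.*\b5\b"):
            assign_groups(small_collection, cfg)


class TestClusterGroups:
    def test_recovers_planted_patterns_per_group(self, rng):
        X, labels, patterns = planted_samples(rng)
        subjects = ["s0"] * len(labels)
        coll = make_collection(X[rng.permutation(len(labels))], subjects)
        cfg = RunConfig(group_size=90)
        assignment = assign_groups(coll, cfg)
        results = cluster_groups(assignment, coll, seed=0)
        assert len(results) == 1
        centroids = normalize(results[0].centroids)
        assert centroids.shape[0] == 3
        # every planted pattern matched by some centroid
        sims = centroids @ patterns.T / X.shape[1]
        assert np.all(sims.max(axis=0) > 0.9)

    def test_identical_samples_collapse_to_one_community(self, rng):
        base = rng.standard_normal(40)
        X = normalize(np.tile(base, (6, 1)) + 1e-9 * rng.standard_normal((6, 40)))
        coll = make_collection(X, ["a"] * 3 + ["b"] * 3)
        assignment = assign_groups(coll, RunConfig(group_size=3))
        results = cluster_groups(assignment, coll, seed=0)
        assert results[0].partition.n_communities == 1

    def test_identical_groups_give_identical_centroids(self, rng):
        X, labels, _ = planted_samples(rng, n_per_state=10)
        # two subjects with identical content -> two identical groups
        X2 = np.vstack([X, X])
        subjects = ["a"] * len(labels) + ["b"] * len(labels)
        coll = make_collection(X2, subjects)
        assignment = assign_groups(coll, RunConfig(group_size=30))
        # regroup manually: one group per subject
        assignment.groups = [
            np.arange(len(labels)),
            np.arange(len(labels), 2 * len(labels)),
        ]
        results = cluster_groups(assignment, coll, seed=0)
        c0 = normalize(results[0].centroids)
        c1 = normalize(results[1].centroids)
        sim = c0 @ c1.T / X.shape[1]
        # match up to community labeling
        assert np.allclose(np.sort(sim.max(axis=1)), 1.0, atol=1e-6)


class TestClusterCentroids:
    def test_planted_three_state_model(self, rng):
        X, labels, patterns = planted_samples(rng, n_per_state=40)
        order = rng.permutation(len(labels))
        coll = make_collection(X[order], ["s0"] * len(labels))
        cfg = RunConfig(group_size=30)
        assignment = assign_groups(coll, cfg)
        results = cluster_groups(assignment, coll, seed=1)
        model, partition, states = cluster_centroids(results, coll, seed=1)
        assert model.state_count == 3
        ari = adjusted_rand_score(labels[order], states)
        assert ari > 0.95

    def test_single_pattern_yields_single_state(self, rng):
        base = normalize(rng.standard_normal((1, 50)))
        X = normalize(
            np.tile(base, (20, 1)) + 0.1 * rng.standard_normal((20, 50))
        )
        coll = make_collection(X, ["a"] * 10 + ["b"] * 10)
        assignment = assign_groups(coll, RunConfig(group_size=5))
        results = cluster_groups(assignment, coll, seed=0)
        model, _, states = cluster_centroids(results, coll, seed=0)
        assert model.state_count == 1
        assert set(states) == {1}

    def test_every_sample_receives_exactly_one_state(
        self, small_collection, small_config
    ):
        result = two_step_cluster(small_collection, small_config)
        assert result.sample_states.shape == (len(small_collection),)
        assert np.all(result.sample_states >= 1)
        assert np.all(result.sample_states <= result.model.state_count)

    def test_state_centroids_normalized(self, small_collection, small_config):
        result = two_step_cluster(small_collection, small_config)
        c = result.model.centroids
        assert np.all(np.abs(c.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(c.std(axis=1) - 1.0) < 1e-10)


class TestTwoStepPipeline:
    def test_agrees_with_one_step_on_small_data(self, rng):
        X, labels, _ = planted_samples(rng, n_per_state=50, noise=0.25)
        order = rng.permutation(len(labels))
        coll = make_collection(X[order], ["s0"] * len(labels))
        cfg = RunConfig(group_size=50, random_seed=9)
        two = two_step_cluster(coll, cfg)
        _, one = one_step_cluster(coll, seed=9)
        assert adjusted_rand_score(one, two.sample_states) >= 0.9

    def test_deterministic_given_seed(self, small_collection, small_config):
        a = two_step_cluster(small_collection, small_config)
        b = two_step_cluster(small_collection, small_config)
        np.testing.assert_array_equal(a.sample_states, b.sample_states)
        assert a.centroid_partition.q == b.centroid_partition.q
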