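"""Two-step community clustering of dWFC samples for large datasets.

Clustering every windowed sample against every other is quadratic in
the total sample count, which is prohibitive at cohort scale. The
two-step procedure instead:

1. splits the samples into groups, each subject contributing S windows
   per group (chronologically or at random, seeded);
2. runs signed community detection within each group and keeps the
   community centroids (mean edge vector of the members);
3. runs signed community detection once more on the correlation matrix
   of all group centroids; each second-step community is a global
   *state*, and every original sample inherits the state of its group
   community.

The final state centroids (WFC-C_i) are means over all original member
samples, re-normalized to mean 0 / sd 1 like the input samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .community import Partition, optimize_partition, similarity_graph
from .config import RunConfig
from .windows import DwfcCollection


@dataclass
class GroupAssignment:
    """Partition of sample indices into first-step groups."""

    mode: str
    group_size: int
    groups: list[np.ndarray]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class StateModel:
    """Ordered set of state centroids supporting feature-score prediction.

    ``centroids`` is (n_states, n_edges); row i is WFC-C_{i+1}, the
    re-normalized mean of all samples assigned to state i+1. States are
    numbered 1..state_count. ``provenance`` maps each state to the
    (group, community) pairs that merged into it.
    """

    centroids: np.ndarray
    provenance: dict[int, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        mu = self.centroids.mean(axis=1)
        sd = self.centroids.std(axis=1)
        if np.any(np.abs(mu) > 1e-10) or np.any(np.abs(sd - 1.0) > 1e-10):
            raise ValueError("state centroids must be normalized to mean 0, sd 1")

    @property
    def state_count(self) -> int:
        return self.centroids.shape[0]


@dataclass
class GroupClusterResult:
    """First-step result for one group."""

    partition: Partition
    centroids: np.ndarray  # (n_communities, n_edges), raw means
    member_indices: list[np.ndarray]  # global sample indices per community


@dataclass
class TwoStepResult:
    assignment: GroupAssignment
    group_results: list[GroupClusterResult]
    centroid_partition: Partition
    model: StateModel
    sample_states: np.ndarray  # state id (1-based) per input sample


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot normalize a constant vector")
    return (v - v.mean(axis=-1, keepdims=True)) / sd


def assign_groups(collection: DwfcCollection, config: RunConfig) -> GroupAssignment:
    """Distribute samples into groups, S windows per subject per group.

    Chronological mode takes each subject's windows in (session,
    window) order and cuts consecutive blocks of S; random mode
    shuffles each subject's windows first (seeded). Every subject must
    have the same window count T, and S must divide T; the number of
    groups is T/S.
    """
    s = config.group_size
    meta = collection.meta
    order = np.lexsort(
        (
            meta["window_index"].to_numpy(),
            meta["session_id"].to_numpy(),
            meta["subject_id"].to_numpy(),
        )
    )
    subjects = meta["subject_id"].to_numpy()
    per_subject: dict[str, np.ndarray] = {}
    for idx in order:
        per_subject.setdefault(subjects[idx], []).append(idx)  # type: ignore[arg-type]
    counts = {len(v) for v in per_subject.values()}
    if len(counts) != 1:
        raise ValueError(
            f"subjects have unequal window counts {sorted(counts)}; "
            "grouping requires a uniform count"
        )
    t_total = counts.pop()
    if t_total % s != 0:
        divisors = [d for d in range(1, t_total + 1) if t_total % d == 0]
        raise ValueError(
            f"group size S={s} does not divide the per-subject window "
            f"count {t_total}; valid S values: {divisors}"
        )
    n_groups = t_total // s
    rng = np.random.default_rng(config.random_seed)
    groups: list[list[int]] = [[] for _ in range(n_groups)]
    for subject in sorted(per_subject):
        idx = np.asarray(per_subject[subject])
        if config.grouping_mode == "random":
            idx = idx[rng.permutation(t_total)]
        for g in range(n_groups):
            groups[g].extend(idx[g * s : (g + 1) * s])
    return GroupAssignment(
        mode=config.grouping_mode,
        group_size=s,
        groups=[np.asarray(g) for g in groups],
    )


def cluster_groups(
    assignment: GroupAssignment,
    collection: DwfcCollection,
    seed: int = 0,
) -> list[GroupClusterResult]:
    """First step: signed community detection within every group.

    Group centroids are plain means of member edge vectors (left
    un-normalized; the second-step similarity is correlation-based and
    therefore location/scale invariant).
    """
    rng = np.random.default_rng(seed)
    group_seeds = rng.integers(0, 2**31 - 1, size=assignment.n_groups)
    results = []
    for g, indices in enumerate(assignment.groups):
        if len(indices) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
        X = collection.edges[indices]
        graph = similarity_graph(X)
        partition = optimize_partition(graph, seed=int(group_seeds[g]))
        centroids = []
        members = []
        for c in range(1, partition.n_communities + 1):
            local = partition.members(c)
            centroids.append(X[local].mean(axis=0))
            members.append(indices[local])
        results.append(
            GroupClusterResult(
                partition=partition,
                centroids=np.stack(centroids),
                member_indices=members,
            )
        )
    return results


def cluster_centroids(
    group_results: list[GroupClusterResult],
    collection: DwfcCollection,
    seed: int = 0,
) -> tuple[StateModel, Partition, np.ndarray]:
    """Second step: cluster the pooled group centroids into global states.

    Returns the state model, the centroid-level partition, and the
    1-based state label of every original sample.
    """
    all_centroids = np.vstack([r.centroids for r in group_results])
    owners: list[tuple[int, int]] = []  # (group, community) per centroid row
    for g, r in enumerate(group_results):
        owners.extend((g, c + 1) for c in range(r.centroids.shape[0]))
    if all_centroids.shape[0] < 2:
        raise ValueError("need at least 2 group centroids for the second step")
    graph = similarity_graph(all_centroids)
    partition = optimize_partition(graph, seed=seed)
    sample_states = np.zeros(len(collection), dtype=int)
    provenance: dict[int, list[tuple[int, int]]] = {}
    state_centroids = []
    for state in range(1, partition.n_communities + 1):
        rows = partition.members(state)
        provenance[state] = [owners[r] for r in rows]
        member_idx = np.concatenate(
            [
                group_results[g].member_indices[c - 1]
                for g, c in provenance[state]
            ]
        )
        sample_states[member_idx] = state
        state_centroids.append(
            _normalize(collection.edges[member_idx].mean(axis=0))
        )
    model = StateModel(np.stack(state_centroids), provenance=provenance)
    return model, partition, sample_states


def two_step_cluster(
    collection: DwfcCollection, config: RunConfig
) -> TwoStepResult:
    """Full two-step pipeline: group, cluster groups, cluster centroids."""
    assignment = assign_groups(collection, config)
    group_results = cluster_groups(
        assignment, collection, seed=config.random_seed
    )
    model, centroid_partition, sample_states = cluster_centroids(
        group_results, collection, seed=config.random_seed
    )
    return TwoStepResult(
        assignment=assignment,
        group_results=group_results,
        centroid_partition=centroid_partition,
        model=model,
        sample_states=sample_states,
    )


def one_step_cluster(
    collection: DwfcCollection, seed: int = 0
) -> tuple[Partition, np.ndarray]:
    """Direct clustering of all samples at once (small-data reference).

    Returns the partition and the 1-based state label per sample. Used
    to check that the two-step shortcut agrees with the direct route
    when the data fit in one group.
    """
    graph = similarity_graph(collection.edges)
    partition = optimize_partition(graph, seed=seed)
    return partition, partition.labels.copy()
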