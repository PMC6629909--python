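"""Signed-graph community detection by modularity maximization.

Every dWFC sample (or group centroid) is a vertex; the signed edge
weight between two vertices is the Pearson correlation of their edge
vectors. Communities are found by maximizing the signed extension of
Newman's Q-modularity, with separate configuration null models for the
positive and negative layers:

    Q = (1/m) * sum_ij (A_ij - p+_ij + p-_ij) * delta(sigma_i, sigma_j)

    p+_ij = k+_i k+_j / (2 w+)      p-_ij = k-_i k-_j / (2 w-)

where A+ / A- are the positive part and magnitude of the negative part
of A, k+/k- the corresponding degree sequences, 2 w+ / 2 w- the total
weight of each layer summed over ordered pairs, and m = 2 w+ + 2 w- the
sum of absolute values of all elements of A. With no negative edges
this reduces exactly to standard weighted Newman modularity. The number
of communities is an output of the optimization, never an input.

The optimizer is a greedy multi-level scheme (Louvain-style): seeded
random sweeps of single-node moves to the neighboring community with
the largest positive Q gain, followed by aggregation of communities
into super-nodes, repeated until a full level yields no improvement.
``best_partition_exact`` enumerates all set partitions and serves as an
exact oracle for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: A full local-move pass that improves Q by less than this terminates.
CONVERGENCE_TOL = 1e-10

_SYMMETRY_TOL = 1e-12


@dataclass
class SignedGraph:
    """Symmetric signed weighted adjacency with zero diagonal."""

    A: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if A.shape[0] < 2:
            raise ValueError("graph needs at least 2 vertices")
        if not np.all(np.isfinite(A)):
            raise ValueError("adjacency contains non-finite weights")
        if np.max(np.abs(A - A.T)) > _SYMMETRY_TOL:
            raise ValueError("adjacency is not symmetric")
        A = 0.5 * (A + A.T)
        np.fill_diagonal(A, 0.0)
        if np.abs(A).sum() == 0:
            raise ValueError("graph has zero total weight")
        self.A = A

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def positive_part(self) -> np.ndarray:
        """A+ : elementwise max(A, 0)."""
        return np.clip(self.A, 0.0, None)

    @property
    def negative_magnitude(self) -> np.ndarray:
        """|A-| : magnitudes of the negative entries (nonnegative)."""
        return np.clip(-self.A, 0.0, None)

    @property
    def total_weight(self) -> float:
        """m = sum of absolute values of all elements of A."""
        return float(np.abs(self.A).sum())


@dataclass
class Partition:
    """Community assignment with its signed modularity value.

    Labels are canonicalized to contiguous 1..c in order of first
    appearance.
    """

    labels: np.ndarray
    q: float

    def __post_init__(self) -> None:
        self.labels = canonical_labels(self.labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max())

    def members(self, community: int) -> np.ndarray:
        return np.flatnonzero(self.labels == community)


def canonical_labels(labels) -> np.ndarray:
    """Relabel communities 1..c by order of first appearance."""
    labels = np.asarray(labels)
    _, inverse = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty(len(labels), dtype=int)
    for pos, code in enumerate(inverse):
        if code not in order:
            order[code] = len(order) + 1
        out[pos] = order[code]
    return out


def similarity_graph(edge_vectors: np.ndarray) -> SignedGraph:
    """Pearson-correlation similarity graph over items.

    ``edge_vectors`` is (n_items, n_features); A_ij is the correlation
    of rows i and j, with the diagonal set to 0 (self-edges excluded).
    """
    X = np.asarray(edge_vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 items of equal length")
    sds = X.std(axis=1)
    flat = np.flatnonzero(sds == 0)
    if flat.size:
        raise ValueError(f"item {int(flat[0])} has zero variance")
    A = np.corrcoef(X)
    A = np.clip(A, -1.0, 1.0)
    np.fill_diagonal(A, 0.0)
    return SignedGraph(A)


def _layer_quality(
    A_pos: np.ndarray, A_neg: np.ndarray, labels: np.ndarray
) -> float:
    """Signed Q for a two-layer representation; self-loops allowed.

    Used both on original graphs (zero diagonal) and on aggregated
    super-node graphs, where the diagonal carries within-community
    weight.
    """
    two_w_pos = A_pos.sum()
    two_w_neg = A_neg.sum()
    m = two_w_pos + two_w_neg
    n_com = labels.max() + 1
    within = 0.0
    for c in range(n_com):
        idx = np.flatnonzero(labels == c)
        block_pos = A_pos[np.ix_(idx, idx)].sum()
        block_neg = A_neg[np.ix_(idx, idx)].sum()
        within += block_pos - block_neg
    k_pos = A_pos.sum(axis=1)
    k_neg = A_neg.sum(axis=1)
    tot_pos = np.bincount(labels, weights=k_pos, minlength=n_com)
    tot_neg = np.bincount(labels, weights=k_neg, minlength=n_com)
    null = 0.0
    if two_w_pos > 0:
        null += (tot_pos**2).sum() / two_w_pos
    if two_w_neg > 0:
        null -= (tot_neg**2).sum() / two_w_neg
    return (within - null) / m


def signed_modularity(graph: SignedGraph, labels) -> float:
    """Signed Q-modularity of a partition of ``graph``.

    A pure-sign graph (no negative or no positive edges) drops the
    corresponding null term and reduces to standard weighted modularity
    on the remaining layer.
    """
    labels = np.asarray(labels)
    if labels.shape != (graph.n,):
        raise ValueError("labels must cover every vertex exactly once")
    zero_based = canonical_labels(labels) - 1
    return _layer_quality(
        graph.positive_part, graph.negative_magnitude, zero_based
    )


def _local_moves(
    A_pos: np.ndarray, A_neg: np.ndarray, labels: np.ndarray, rng
) -> tuple[np.ndarray, bool]:
    """Sweep single-node moves until a full pass gains < CONVERGENCE_TOL.

    Ties in Q gain go to the lowest-index community; node visit order
    is shuffled by ``rng`` each pass. Self-loops (aggregated graphs)
    are partition-invariant and excluded from the gains.
    """
    n = A_pos.shape[0]
    labels = labels.copy()
    two_w_pos = A_pos.sum()
    two_w_neg = A_neg.sum()
    m = two_w_pos + two_w_neg
    k_pos = A_pos.sum(axis=1)
    k_neg = A_neg.sum(axis=1)
    inv_pos = 1.0 / two_w_pos if two_w_pos > 0 else 0.0
    inv_neg = 1.0 / two_w_neg if two_w_neg > 0 else 0.0
    n_com = labels.max() + 1
    tot_pos = np.bincount(labels, weights=k_pos, minlength=n_com)
    tot_neg = np.bincount(labels, weights=k_neg, minlength=n_com)
    moved_any = False
    while True:
        pass_gain = 0.0
        for i in rng.permutation(n):
            cur = labels[i]
            link_pos = np.bincount(labels, weights=A_pos[i], minlength=n_com)
            link_neg = np.bincount(labels, weights=A_neg[i], minlength=n_com)
            link_pos[cur] -= A_pos[i, i]
            link_neg[cur] -= A_neg[i, i]
            base_pos = tot_pos.copy()
            base_neg = tot_neg.copy()
            base_pos[cur] -= k_pos[i]
            base_neg[cur] -= k_neg[i]
            score = (
                link_pos
                - k_pos[i] * base_pos * inv_pos
                - link_neg
                + k_neg[i] * base_neg * inv_neg
            )
            rel = score - score[cur]
            best = int(np.argmax(rel))
            gain = (2.0 / m) * rel[best]
            if gain > CONVERGENCE_TOL and best != cur:
                labels[i] = best
                tot_pos[cur] -= k_pos[i]
                tot_neg[cur] -= k_neg[i]
                tot_pos[best] += k_pos[i]
                tot_neg[best] += k_neg[i]
                pass_gain += gain
                moved_any = True
        if pass_gain < CONVERGENCE_TOL:
            break
    return labels, moved_any


def _aggregate(
    A_pos: np.ndarray, A_neg: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse each community into a super-node, per layer.

    Diagonal entries of the aggregated layers carry within-community
    weight, preserving Q exactly.
    """
    n_com = labels.max() + 1
    Z = np.zeros((A_pos.shape[0], n_com))
    Z[np.arange(A_pos.shape[0]), labels] = 1.0
    return Z.T @ A_pos @ Z, Z.T @ A_neg @ Z


def _greedy_once(graph: SignedGraph, rng) -> np.ndarray:
    """One multi-level greedy run; returns 0-based labels."""
    A_pos = graph.positive_part
    A_neg = graph.negative_magnitude
    node_to_com = np.arange(graph.n)  # current assignment of original nodes
    while True:
        level_labels, moved = _local_moves(
            A_pos, A_neg, np.arange(A_pos.shape[0]), rng
        )
        level_labels = canonical_labels(level_labels) - 1
        node_to_com = level_labels[node_to_com]
        if not moved or level_labels.max() + 1 == A_pos.shape[0]:
            break
        A_pos, A_neg = _aggregate(A_pos, A_neg, level_labels)
    # final refinement at single-node resolution: aggregation freezes
    # nodes into super-nodes, so one more sweep on the original graph
    # can escape optima the coarsened moves cannot
    node_to_com, _ = _local_moves(
        graph.positive_part, graph.negative_magnitude, node_to_com, rng
    )
    return canonical_labels(node_to_com) - 1


def optimize_partition(
    graph: SignedGraph,
    seed: int = 0,
    n_restarts: int = 10,
    n_perturbations: int = 15,
    perturbation_fraction: float = 0.3,
) -> Partition:
    """Greedy multi-level maximization of signed Q with restarts.

    The greedy schedule is order-dependent and single-node moves can
    stall in local optima on dense signed graphs, so each of
    ``n_restarts`` seeded runs is followed by an iterated-local-search
    phase: a random fraction of nodes is reassigned to random
    communities and the move sweep re-run, keeping the perturbed
    solution only when it improves Q. The best partition over all
    restarts is returned. Deterministic given ``seed``; never worse
    than the trivial one-community partition.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be positive")
    rng = np.random.default_rng(seed)
    A_pos = graph.positive_part
    A_neg = graph.negative_magnitude
    best_q = -np.inf
    best_labels = None
    n_kick = max(1, int(perturbation_fraction * graph.n))
    for _ in range(n_restarts):
        labels = _greedy_once(graph, rng)
        q = signed_modularity(graph, labels)
        for _ in range(n_perturbations):
            trial = labels.copy()
            idx = rng.choice(graph.n, size=n_kick, replace=False)
            trial[idx] = rng.integers(0, trial.max() + 2, size=n_kick)
            trial, _ = _local_moves(
                A_pos, A_neg, canonical_labels(trial) - 1, rng
            )
            trial_q = signed_modularity(graph, trial)
            if trial_q > q:
                labels, q = trial, trial_q
        if q > best_q:
            best_q = q
            best_labels = labels
    q_trivial = signed_modularity(graph, np.zeros(graph.n, dtype=int))
    if best_q < q_trivial:
        return Partition(np.ones(graph.n, dtype=int), q_trivial)
    return Partition(best_labels, best_q)


def iter_set_partitions(n: int):
    """Yield every partition of n items as a 0-based label array.

    Restricted-growth-string enumeration; Bell(n) partitions total.
    """
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(n_used + 1):
            labels[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(0, 0)


def best_partition_exact(graph: SignedGraph, max_n: int = 12) -> Partition:
    """Exhaustive signed-Q maximization over all set partitions.

    Exact oracle for small graphs; refuses n > ``max_n`` (Bell-number
    explosion).
    """
    if graph.n > max_n:
        raise ValueError(f"exhaustive search limited to n <= {max_n}")
    A_pos = graph.positive_part
    A_neg = graph.negative_magnitude
    best_q = -np.inf
    best = None
    for labels in iter_set_partitions(graph.n):
        q = _layer_quality(A_pos, A_neg, labels)
        if q > best_q:
            best_q = q
            best = labels
    return Partition(best, best_q)
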