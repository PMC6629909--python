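"""State assignment by feature score and state-dynamics summaries.

Once a state model exists, any windowed dWFC sample can be assigned a
state without re-clustering: its *feature score* against state i is the
Pearson correlation with the centroid WFC-C_i, and the highest score
predicts the state. Per-subject state trajectories then yield the
standard dynamic parameters: occurrence (fraction of windows per
state), transition rates between states, and mean lifetime (average
duration of uninterrupted runs of one state, in seconds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .twostep import StateModel
from .windows import DwfcCollection


@dataclass
class StateSequence:
    """Time-ordered state labels for one subject/session."""

    subject_id: str
    session_id: str
    labels: np.ndarray  # 1-based state ids, one per window, in time order
    window_seconds: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise ValueError("state sequence must be non-empty")
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")


def feature_score(edges: np.ndarray, model: StateModel) -> np.ndarray:
    """Pearson correlation of a sample with every state centroid."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape != (model.centroids.shape[1],):
        raise ValueError(
            f"sample has {edges.shape} edges, model expects "
            f"{model.centroids.shape[1]}"
        )
    sd = edges.std()
    if sd == 0:
        raise ValueError("zero-variance sample has no defined feature score")
    z = (edges - edges.mean()) / sd
    # centroids are already mean 0 / sd 1, so correlation is a dot product
    return model.centroids @ z / edges.size


def predict_state(edges: np.ndarray, model: StateModel) -> int:
    """State with the highest feature score; ties go to the lowest id."""
    return int(np.argmax(feature_score(edges, model))) + 1


def predict_states(collection: DwfcCollection, model: StateModel) -> np.ndarray:
    """Vectorized feature-score prediction for a whole collection."""
    X = collection.edges
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance sample has no defined feature score")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    scores = Z @ model.centroids.T / X.shape[1]
    return np.argmax(scores, axis=1) + 1


def matching_rate(labels_a, labels_b) -> float:
    """Fraction of items with identical labels in the same label space."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have the same length")
    return float(np.mean(a == b))


def state_sequences(
    collection: DwfcCollection,
    labels: np.ndarray,
    window_seconds: float,
) -> list[StateSequence]:
    """Split per-sample labels into time-ordered per-session sequences."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(collection),):
        raise ValueError("one label per sample required")
    meta = collection.meta.copy()
    meta["_label"] = labels
    sequences = []
    for (subject, session), grp in meta.groupby(
        ["subject_id", "session_id"], sort=True
    ):
        grp = grp.sort_values("window_index")
        sequences.append(
            StateSequence(
                subject_id=str(subject),
                session_id=str(session),
                labels=grp["_label"].to_numpy(),
                window_seconds=window_seconds,
            )
        )
    return sequences


def _run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """(state, length) for each maximal run of consecutive equal labels."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), i - start))
            start = i
    return runs


def dynamics_summary(
    sequences: list[StateSequence], n_states: int | None = None
) -> dict:
    """Occurrence, transition rates and mean lifetimes for a cohort.

    Returns a dict with:

    - ``occurrence``: DataFrame (subject x state) of the fraction of
      each subject's windows spent in each state (rows sum to 1);
    - ``transition_counts`` / ``transition_rates``: (state x state)
      DataFrames of off-diagonal transition counts pooled over all
      sequences, and the same normalized by the total transition count;
    - ``mean_lifetime_seconds``: Series of mean run length x window
      duration per state, pooled over all runs (runs never span a
      session boundary; runs truncated by a session end are included,
      which biases lifetimes slightly downward).
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    states = sorted({int(s) for seq in sequences for s in seq.labels})
    if n_states is not None:
        extra = set(states) - set(range(1, n_states + 1))
        if extra:
            raise ValueError(f"labels {sorted(extra)} outside states 1..{n_states}")
        states = list(range(1, n_states + 1))
    window_seconds = {seq.window_seconds for seq in sequences}
    if len(window_seconds) != 1:
        raise ValueError("sequences mix different window durations")
    w_sec = window_seconds.pop()

    occ_rows = {}
    for seq in sequences:
        row = occ_rows.setdefault(
            seq.subject_id, dict.fromkeys(states, 0)
        )
        for s in seq.labels:
            row[int(s)] += 1
    occurrence = pd.DataFrame.from_dict(occ_rows, orient="index")[states]
    occurrence = occurrence.div(occurrence.sum(axis=1), axis=0)
    occurrence.index.name = "subject_id"

    counts = pd.DataFrame(0, index=states, columns=states)
    run_lengths: dict[int, list[int]] = {s: [] for s in states}
    for seq in sequences:
        for (s, length) in _run_lengths(seq.labels):
            run_lengths[s].append(length)
        for a, b in zip(seq.labels[:-1], seq.labels[1:]):
            if a != b:
                counts.loc[int(a), int(b)] += 1
    total = counts.to_numpy().sum()
    rates = counts / total if total > 0 else counts.astype(float)
    lifetime = pd.Series(
        {
            s: (np.mean(lens) * w_sec if lens else np.nan)
            for s, lens in run_lengths.items()
        },
        name="mean_lifetime_seconds",
    )
    return {
        "occurrence": occurrence,
        "transition_counts": counts,
        "transition_rates": rates,
        "mean_lifetime_seconds": lifetime,
    }


def occurrence_ttest(
    occurrence: pd.DataFrame, state_a: int, state_b: int
) -> tuple[float, float]:
    """Two-sample t-test between the occurrence distributions of two
    states across subjects (standard Welch-free pooled test; a
    convenience wrapper, not a contribution of this package)."""
    t, p = stats.ttest_ind(occurrence[state_a], occurrence[state_b])
    return float(t), float(p)


def top_edges(model: StateModel, state: int, k: int = 200) -> np.ndarray:
    """Indices of the k strongest (most positive) edges of a state
    centroid, strongest first. A plain ranked-edge table stands in for
    connectogram rendering."""
    c = model.centroids[state - 1]
    order = np.argsort(c)[::-1]
    return order[:k]
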