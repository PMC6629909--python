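"""Run configuration for the dWFC state-detection pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Grouping strategies for the first clustering step.
GROUPING_MODES = ("chronological", "random")


@dataclass
class RunConfig:
    """Parameters of a full dWFC state-detection run.

    Parameters
    ----------
    window_length : int
        Sliding-window length ``L`` in timepoints. Windows are
        non-overlapping; trailing timepoints that do not fill a window
        are dropped.
    group_size : int
        Number of dWFC samples each subject contributes to each group
        (``S``) in the first clustering step. Must divide every
        subject's total window count.
    grouping_mode : str
        ``"chronological"`` (consecutive windows per group) or
        ``"random"`` (seeded per-subject shuffling before grouping).
    random_seed : int
        Seed for every stochastic operation of the run (grouping,
        community-detection node order, k-means restarts).
    kmeans_k_range : tuple[int, int]
        Inclusive range of cluster counts for the k-means baseline.
    kmeans_restarts : int
        Random restarts per K; the best restart by within-cluster
        inertia is kept.
    tr_seconds : float
        Repetition time, used to convert window counts to seconds.
    """

    window_length: int = 20
    group_size: int = 5
    grouping_mode: str = "chronological"
    random_seed: int = 0
    kmeans_k_range: tuple[int, int] = (1, 6)
    kmeans_restarts: int = 100
    tr_seconds: float = 0.72
    #: Diagonal of the similarity matrix; self-edges are excluded.
    similarity_self_weight: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be a positive integer")
        if self.group_size < 1:
            raise ValueError("group_size must be a positive integer")
        if self.grouping_mode not in GROUPING_MODES:
            raise ValueError(
                f"grouping_mode must be one of {GROUPING_MODES}, "
                f"got {self.grouping_mode!r}"
            )
        lo, hi = self.kmeans_k_range
        if lo < 1 or hi < lo:
            raise ValueError("kmeans_k_range must be a nonempty range of K >= 1")
        if self.kmeans_restarts < 1:
            raise ValueError("kmeans_restarts must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def window_seconds(self) -> float:
        """Duration of one analysis window in seconds (L x TR)."""
        return self.window_length * self.tr_seconds

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        if "kmeans_k_range" in raw:
            raw["kmeans_k_range"] = tuple(raw["kmeans_k_range"])
        known = {f for f in cls.__dataclass_fields__ if f != "similarity_self_weight"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        del data["similarity_self_weight"]  # fixed, not configurable
        data["kmeans_k_range"] = list(data["kmeans_k_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
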