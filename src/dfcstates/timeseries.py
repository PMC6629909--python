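"""Regional BOLD time-series container and validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegionalTimeSeries:
    """One subject/session's region-by-time signal matrix.

    ``values`` has shape (M regions, N timepoints) and is assumed to be
    fully preprocessed (detrended, nuisance-regressed, filtered); this
    package consumes regional signals and performs no voxel-level work.
    """

    subject_id: str
    session_id: str
    values: np.ndarray
    region_labels: list[str] = field(default_factory=list)
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D regions x timepoints matrix")
        m, n = self.values.shape
        # Pairwise correlation needs >= 2 timepoints; per-window edge
        # normalization needs at least 3 edges, hence M >= 3.
        if m < 3:
            raise ValueError(f"need at least 3 regions, got {m}")
        if n < 2:
            raise ValueError(f"need at least 2 timepoints, got {n}")
        bad = np.argwhere(~np.isfinite(self.values))
        if bad.size:
            r, c = bad[0]
            raise ValueError(
                f"non-finite value at region {r}, timepoint {c} "
                f"(subject {self.subject_id}, session {self.session_id})"
            )
        if not self.region_labels:
            self.region_labels = [f"region_{i}" for i in range(m)]
        if len(self.region_labels) != m:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {m} regions"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]
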