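"""Sliding-window dWFC extraction.

Each session's regional time series is segmented into non-overlapping
windows of length ``L``. Within a window the Pearson correlation is
computed for every unordered region pair, Fisher r-z transformed, and
the resulting M(M-1)/2 edge values are normalized to mean 0 / sd 1
within the window:

    FC_ij(s) = (FZ(r_ij(s)) - mu(s)) / sigma(s)

where mu(s) and sigma(s) are the mean and (population) standard
deviation over all edges of window s. A whole normalized edge vector is
one dWFC sample; it is the unit that gets clustered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import RegionalTimeSeries

#: Columns of the sample metadata table, in canonical order.
META_COLUMNS = [
    "subject_id",
    "session_id",
    "window_index",
    "window_start",
    "window_length",
]

#: Tolerance on the mean-0 / sd-1 normalization contract of edge vectors.
NORMALIZATION_TOL = 1e-10


def edge_index_pairs(n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical enumeration of unordered region pairs (i < j, row-major)."""
    return np.triu_indices(n_regions, k=1)


def n_edges(n_regions: int) -> int:
    """Number of unordered region pairs, M(M-1)/2."""
    return n_regions * (n_regions - 1) // 2


def segment_windows(n_timepoints: int, window_length: int) -> list[tuple[int, int]]:
    """Tile [0, N) with half-open windows [kL, (k+1)L).

    Returns floor(N/L) disjoint ranges; trailing timepoints that do not
    fill a complete window are dropped.
    """
    if window_length < 1:
        raise ValueError("window_length must be positive")
    if window_length > n_timepoints:
        raise ValueError(
            f"window length {window_length} exceeds series length {n_timepoints}"
        )
    n_windows = n_timepoints // window_length
    return [(k * window_length, (k + 1) * window_length) for k in range(n_windows)]


def fisher_z(r):
    """Fisher r-z transform, z = (1/2) ln((1+r)/(1-r)).

    Defined for |r| < 1; a correlation of exactly +-1 signals a
    degenerate window and raises.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("Fisher z undefined for |r| >= 1 (degenerate window)")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class DWFCSample:
    """One window's normalized whole-brain FC edge vector with provenance."""

    subject_id: str
    session_id: str
    window_index: int
    edges: np.ndarray
    window_start: int
    window_length: int

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        mu = self.edges.mean()
        sd = self.edges.std()
        if abs(mu) > NORMALIZATION_TOL or abs(sd - 1.0) > NORMALIZATION_TOL:
            raise ValueError(
                f"edge vector violates normalization contract "
                f"(mean={mu:.3e}, sd={sd:.6f})"
            )


class DwfcCollection:
    """A set of dWFC samples: an (n_samples, n_edges) matrix plus metadata.

    ``meta`` is a DataFrame with one row per sample and the columns in
    :data:`META_COLUMNS`; row order matches ``edges`` row order.
    """

    def __init__(self, edges: np.ndarray, meta: pd.DataFrame):
        edges = np.asarray(edges, dtype=float)
        if edges.ndim != 2:
            raise ValueError("edges must be a 2-D samples x edges matrix")
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"metadata missing columns {missing}")
        if len(meta) != edges.shape[0]:
            raise ValueError("metadata row count does not match edge matrix")
        self.edges = edges
        self.meta = meta.reset_index(drop=True)[META_COLUMNS].copy()

    def __len__(self) -> int:
        return self.edges.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[1]

    def subset(self, indices) -> "DwfcCollection":
        indices = np.asarray(indices)
        return DwfcCollection(self.edges[indices], self.meta.iloc[indices])

    @classmethod
    def from_samples(cls, samples: list[DWFCSample]) -> "DwfcCollection":
        if not samples:
            raise ValueError("cannot build a collection from zero samples")
        edges = np.stack([s.edges for s in samples])
        meta = pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in samples],
                "session_id": [s.session_id for s in samples],
                "window_index": [s.window_index for s in samples],
                "window_start": [s.window_start for s in samples],
                "window_length": [s.window_length for s in samples],
            }
        )
        return cls(edges, meta)


def compute_dwfc(
    ts: RegionalTimeSeries, window: tuple[int, int], window_index: int = 0
) -> DWFCSample:
    """Normalized Fisher-z FC edge vector for one window.

    Raises if any region has zero variance within the window or if two
    distinct regions are perfectly correlated (Fisher z undefined).
    """
    start, stop = window
    if start < 0 or stop > ts.n_timepoints or stop - start < 2:
        raise ValueError(f"window [{start}, {stop}) out of bounds or too short")
    segment = ts.values[:, start:stop]
    sds = segment.std(axis=1)
    flat = np.argwhere(sds == 0)
    if flat.size:
        raise ValueError(
            f"region {int(flat[0][0])} has zero variance in window "
            f"[{start}, {stop}) (subject {ts.subject_id}, "
            f"session {ts.session_id})"
        )
    r = np.corrcoef(segment)
    iu, ju = edge_index_pairs(ts.n_regions)
    r_edges = r[iu, ju]
    if np.any(np.abs(r_edges) >= 1.0 - 1e-15):
        k = int(np.argmax(np.abs(r_edges)))
        raise ValueError(
            f"|r| = 1 between regions {int(iu[k])} and {int(ju[k])} in "
            f"window [{start}, {stop}): Fisher z undefined"
        )
    z = np.arctanh(r_edges)
    mu = z.mean()
    sigma = z.std()  # population convention (divide by n)
    if sigma == 0:
        raise ValueError(
            f"all edges identical in window [{start}, {stop}); "
            "cannot normalize"
        )
    return DWFCSample(
        subject_id=ts.subject_id,
        session_id=ts.session_id,
        window_index=window_index,
        edges=(z - mu) / sigma,
        window_start=start,
        window_length=stop - start,
    )


def extract_samples(
    series: list[RegionalTimeSeries], window_length: int
) -> DwfcCollection:
    """Window every session independently and compute all dWFC samples.

    Sessions are segmented separately so no window spans a session
    boundary; window indices restart at 0 within each session.
    """
    if not series:
        raise ValueError("no time series supplied")
    n_regions = series[0].n_regions
    samples: list[DWFCSample] = []
    for ts in series:
        if ts.n_regions != n_regions:
            raise ValueError(
                f"region count mismatch: {ts.n_regions} vs {n_regions} "
                f"(subject {ts.subject_id}, session {ts.session_id})"
            )
        for k, window in enumerate(segment_windows(ts.n_timepoints, window_length)):
            samples.append(compute_dwfc(ts, window, window_index=k))
    return DwfcCollection.from_samples(samples)
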