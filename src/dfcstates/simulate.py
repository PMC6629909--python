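"""Synthetic BOLD-like data with planted connectivity states.

The generator emulates the one property of resting-state regional
signals this pipeline actually exploits: the region-by-region
covariance switches among a small number of recurring patterns over
time. Each planted state is a block-modular correlation matrix (a
different random grouping of regions into correlated modules per
state); within a window the signal is zero-mean Gaussian with the
active state's correlation plus isotropic observation noise. State
switches are aligned to window boundaries by default so that every
window has an unambiguous ground-truth label; a misaligned mode is
available for robustness checks. No hemodynamic response, 1/f noise or
scanner artifact is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import RegionalTimeSeries

#: Planted patterns must stay this dissimilar (edge-vector correlation).
MAX_PATTERN_SIMILARITY = 0.5


@dataclass
class PlantedStateSpec:
    """Generating conditions for a planted-state cohort.

    Defaults describe the reference synthetic cohort used throughout
    the test suite: 3 states over M = 20 regions, 20 subjects with one
    1200-timepoint session each (TR 0.72 s), windows of 20 timepoints,
    a mean dwell of 1.75 windows (~25 s, the scale of empirically
    reported state lifetimes), and moderate observation noise
    (noise_sd 0.5, i.e. noise variance a quarter of the unit signal
    variance).
    """

    n_states: int = 3
    n_regions: int = 20
    n_subjects: int = 20
    n_sessions: int = 1
    n_timepoints: int = 1200
    window_length: int = 20
    tr_seconds: float = 0.72
    mean_dwell_windows: float = 1.75
    noise_sd: float = 0.5
    within_module_corr: float = 0.6
    n_modules: int = 4
    align_to_windows: bool = True
    seed: int = 0
    state_correlations: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("need at least one state")
        if self.n_regions < 4:
            raise ValueError("need at least 4 regions")
        if self.mean_dwell_windows < 1:
            raise ValueError("mean dwell must be at least one window")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_timepoints < self.window_length:
            raise ValueError("session shorter than one window")

    @property
    def windows_per_session(self) -> int:
        return self.n_timepoints // self.window_length


def _edge_vector(corr: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    return corr[iu, ju]


def _normalized(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def make_state_patterns(
    n_states: int,
    n_regions: int,
    within_module_corr: float = 0.6,
    n_modules: int = 4,
    seed: int = 0,
    max_similarity: float = MAX_PATTERN_SIMILARITY,
    max_attempts: int = 200,
) -> list[np.ndarray]:
    """Distinct block-modular correlation matrices, one per state.

    Each state randomly reassigns regions to ``n_modules`` correlated
    modules (correlation ``within_module_corr`` inside a module, 0
    between), giving a different module layout per state — the same
    kind of contrast that distinguishes empirically reported states,
    where different functional modules dominate different states.
    Block-diagonal structure is positive semi-definite by construction.
    Layouts are resampled until all pairwise normalized edge-vector
    correlations fall below ``max_similarity``; if the separation is
    unattainable for the given geometry, raises.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_regions < 4:
        raise ValueError("n_regions must be >= 4")
    if not 0 < within_module_corr < 1:
        raise ValueError("within_module_corr must lie in (0, 1)")
    if n_modules < 2 or n_modules > n_regions:
        raise ValueError("n_modules must lie in [2, n_regions]")
    rng = np.random.default_rng(seed)

    def one_pattern() -> np.ndarray:
        assignment = np.sort(np.arange(n_regions) % n_modules)
        assignment = assignment[rng.permutation(n_regions)]
        corr = np.where(
            assignment[:, None] == assignment[None, :], within_module_corr, 0.0
        )
        np.fill_diagonal(corr, 1.0)
        return corr

    for _ in range(max_attempts):
        patterns = [one_pattern() for _ in range(n_states)]
        if n_states == 1:
            return patterns
        vecs = [_normalized(_edge_vector(p)) for p in patterns]
        sims = [
            abs(float(vecs[i] @ vecs[j]) / vecs[i].size)
            for i in range(n_states)
            for j in range(i + 1, n_states)
        ]
        if max(sims) < max_similarity:
            return patterns
    raise ValueError(
        f"could not find {n_states} patterns with pairwise similarity "
        f"< {max_similarity} for M={n_regions}, {n_modules} modules"
    )


def _state_sequence(
    n_windows: int, n_states: int, mean_dwell: float, rng
) -> np.ndarray:
    """Geometric-dwell state sequence over windows.

    Each window the chain stays with probability 1 - 1/mean_dwell and
    otherwise jumps uniformly to a different state (if any).
    """
    stay = 1.0 - 1.0 / mean_dwell if np.isfinite(mean_dwell) else 1.0
    seq = np.empty(n_windows, dtype=int)
    seq[0] = rng.integers(n_states)
    for t in range(1, n_windows):
        if n_states > 1 and rng.random() >= stay:
            others = [s for s in range(n_states) if s != seq[t - 1]]
            seq[t] = others[rng.integers(len(others))]
        else:
            seq[t] = seq[t - 1]
    return seq + 1


def simulate_bold(
    spec: PlantedStateSpec,
) -> tuple[list[RegionalTimeSeries], pd.DataFrame]:
    """Generate a cohort of state-switching regional time series.

    Returns the time series (one per subject/session) and a
    ground-truth table with columns subject_id, session_id,
    window_index, state (1-based).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.state_correlations:
        patterns = [np.asarray(p, dtype=float) for p in spec.state_correlations]
        if len(patterns) != spec.n_states:
            raise ValueError("state_correlations count differs from n_states")
    else:
        patterns = make_state_patterns(
            spec.n_states,
            spec.n_regions,
            within_module_corr=spec.within_module_corr,
            n_modules=spec.n_modules,
            seed=int(rng.integers(2**31 - 1)),
        )
    for p in patterns:
        eigmin = float(np.linalg.eigvalsh(p).min())
        if eigmin < -1e-10:
            raise ValueError(f"planted matrix not PSD (min eigenvalue {eigmin:.2e})")
    covs = [p + spec.noise_sd**2 * np.eye(spec.n_regions) for p in patterns]
    chols = [np.linalg.cholesky(c) for c in covs]

    L = spec.window_length
    n_win = spec.windows_per_session
    series: list[RegionalTimeSeries] = []
    truth_rows = []
    for subj in range(spec.n_subjects):
        for sess in range(spec.n_sessions):
            seq = _state_sequence(
                n_win, spec.n_states, spec.mean_dwell_windows, rng
            )
            X = np.empty((spec.n_regions, spec.n_timepoints))
            if spec.align_to_windows:
                bounds = [(k * L, (k + 1) * L) for k in range(n_win)]
                window_states = seq
            else:
                # shift every switch by up to half a window: labels stay
                # per-window but segment edges move off the grid
                offsets = rng.integers(-L // 2, L // 2 + 1, size=n_win)
                bounds = []
                prev = 0
                for k in range(n_win):
                    stop = min((k + 1) * L + int(offsets[k]), spec.n_timepoints)
                    stop = max(stop, prev + 1)
                    bounds.append((prev, stop))
                    prev = stop
                bounds[-1] = (bounds[-1][0], max(bounds[-1][1], n_win * L))
                window_states = seq
            for k, (start, stop) in enumerate(bounds):
                z = rng.standard_normal((stop - start, spec.n_regions))
                X[:, start:stop] = (z @ chols[window_states[k] - 1].T).T
            if n_win * L < spec.n_timepoints:  # trailing remainder
                z = rng.standard_normal(
                    (spec.n_timepoints - n_win * L, spec.n_regions)
                )
                X[:, n_win * L :] = (z @ chols[seq[-1] - 1].T).T
            sid = f"sub{subj:03d}"
            ses = f"ses{sess}"
            series.append(
                RegionalTimeSeries(
                    subject_id=sid,
                    session_id=ses,
                    values=X,
                    tr_seconds=spec.tr_seconds,
                )
            )
            for k, s in enumerate(seq):
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "session_id": ses,
                        "window_index": k,
                        "state": int(s),
                    }
                )
    return series, pd.DataFrame(truth_rows)
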