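"""Plain-text persistence for every pipeline artifact.

All formats are delimited text so that runs diff cleanly:

- time series: TSV matrix, rows = regions, columns = timepoints;
- dWFC sample store: a samples x edges TSV plus a ``.meta.tsv`` sidecar
  carrying provenance (subject, session, window index), both headed by
  a format-version comment line;
- partitions and state models: TSV with header rows.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .community import Partition
from .timeseries import RegionalTimeSeries
from .twostep import StateModel
from .windows import META_COLUMNS, DwfcCollection

logger = logging.getLogger("dfcstates")

SAMPLE_STORE_VERSION = "dfcstates-samples v1"
MODEL_STORE_VERSION = "dfcstates-model v1"


def setup_logging(logfile: str | Path | None = None, level=logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def read_time_series(
    path: str | Path,
    subject_id: str | None = None,
    session_id: str = "ses0",
    labels_path: str | Path | None = None,
    tr_seconds: float = 0.72,
    orientation: str = "regions_x_time",
) -> RegionalTimeSeries:
    """Read a delimited regions-by-timepoints matrix.

    ``orientation`` may be ``"regions_x_time"`` (default) or
    ``"time_x_regions"`` (transposed on read). Non-numeric cells,
    ragged rows and non-finite values are hard errors naming the
    offending location.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged or malformed matrix: {exc}") from exc
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy() | ~np.isfinite(numeric.to_numpy()))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-numeric or non-finite value at row {r}, column {c} "
            f"(value {frame.iat[r, c]!r})"
        )
    values = numeric.to_numpy(dtype=float)
    if orientation == "time_x_regions":
        values = values.T
    elif orientation != "regions_x_time":
        raise ValueError(f"unknown orientation {orientation!r}")
    labels = []
    if labels_path is not None:
        labels = Path(labels_path).read_text().split()
    ts = RegionalTimeSeries(
        subject_id=subject_id or path.stem,
        session_id=session_id,
        values=values,
        region_labels=labels,
        tr_seconds=tr_seconds,
    )
    logger.info(
        "read %s: M=%d regions, N=%d timepoints", path, ts.n_regions, ts.n_timepoints
    )
    return ts


def write_time_series(ts: RegionalTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.10g")


def write_samples(collection: DwfcCollection, path: str | Path) -> None:
    """Write a sample store: edge matrix TSV + ``.meta.tsv`` sidecar."""
    path = Path(path)
    header = "\t".join(f"e{i}" for i in range(collection.n_edges))
    with open(path, "w") as fh:
        fh.write(f"# {SAMPLE_STORE_VERSION}\n{header}\n")
        np.savetxt(fh, collection.edges, delimiter="\t", fmt="%.17g")
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    with open(meta_path, "w") as fh:
        fh.write(f"# {SAMPLE_STORE_VERSION}\n")
        collection.meta.to_csv(fh, sep="\t", index=False)


def read_samples(path: str | Path) -> DwfcCollection:
    """Read a sample store written by :func:`write_samples`.

    The round trip is bit-identical on edge vectors and provenance; a
    store written by a different format version is rejected.
    """
    path = Path(path)
    _check_version(path, SAMPLE_STORE_VERSION)
    edges = pd.read_csv(
        path, sep="\t", comment="#", float_precision="round_trip"
    ).to_numpy(dtype=float)
    meta_path = path.with_suffix(path.suffix + ".meta.tsv")
    _check_version(meta_path, SAMPLE_STORE_VERSION)
    meta = pd.read_csv(
        meta_path, sep="\t", comment="#", dtype={"subject_id": str, "session_id": str}
    )
    return DwfcCollection(edges, meta[META_COLUMNS])


def _check_version(path: Path, expected: str) -> None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first != f"# {expected}":
        raise ValueError(
            f"{path}: store version {first!r} does not match expected "
            f"'# {expected}'"
        )


def write_partition(
    partition: Partition, path: str | Path, item_ids=None
) -> None:
    path = Path(path)
    n = len(partition.labels)
    ids = item_ids if item_ids is not None else list(range(n))
    with open(path, "w") as fh:
        fh.write("item\tcommunity\n")
        for item, lab in zip(ids, partition.labels):
            fh.write(f"{item}\t{lab}\n")
        fh.write(f"# Q\t{partition.q:.17g}\n")


def read_partition(path: str | Path) -> Partition:
    lines = Path(path).read_text().strip().splitlines()
    q = None
    labels = []
    for line in lines[1:]:
        if line.startswith("# Q"):
            q = float(line.split("\t")[1])
        else:
            labels.append(int(line.split("\t")[1]))
    if q is None:
        raise ValueError(f"{path}: missing Q footer row")
    return Partition(np.asarray(labels), q)


def write_state_model(model: StateModel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {MODEL_STORE_VERSION}\n")
        fh.write("state\t" + "\t".join(
            f"e{i}" for i in range(model.centroids.shape[1])
        ) + "\n")
        for i, row in enumerate(model.centroids, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_state_model(path: str | Path) -> StateModel:
    path = Path(path)
    _check_version(path, MODEL_STORE_VERSION)
    frame = pd.read_csv(path, sep="\t", comment="#")
    return StateModel(frame.drop(columns="state").to_numpy(dtype=float))
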