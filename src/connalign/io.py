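"""Readers and writers for the artifact's delimited-text formats.

All files are plain delimited text with "." decimals and no locale
dependence. Region labels come from an optional header row; without one,
0-based indices are used. Internal indexing is 0-based everywhere; label
strings only appear at file boundaries.

Formats
-------
* connectome: square CSV matrix, optional header of region labels;
* time series: CSV, rows = time samples, columns = regions;
* adjacency: two-column TSV edge list of region indices (0- or 1-based);
* permutation: two-column TSV ``source_label\ttarget_label``;
* eta records: tidy long-format CSV;
* run metadata / config: YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .connectomes import Connectome, TimeSeriesMatrix
from .constraints import RegionAdjacency
from .solver import PermutationMatrix

__all__ = [
    "read_connectome",
    "write_connectome",
    "read_time_series",
    "read_adjacency",
    "write_adjacency",
    "read_permutation",
    "write_permutation",
    "write_eta_records",
    "read_config",
    "write_metadata",
]


def _sniff(path: Path) -> tuple[int | None, str]:
    """Detect header row and delimiter of a delimited matrix file.

    The C parser is used with an explicit delimiter (the python-engine
    auto-sniffing float parser is not correctly rounded, which would break
    full-precision round trips).
    """
    first = path.read_text().splitlines()[0]
    sep = "\t" if "\t" in first else (";" if ";" in first else ",")
    header = None
    for tok in first.split(sep):
        try:
            float(tok)
        except ValueError:
            header = 0
            break
    return header, sep


def read_connectome(
    path, modality: str, expected_n: int | None = None, subject_id: str = ""
) -> Connectome:
    """Read a square delimited matrix as a validated connectome.

    A non-numeric first row is treated as region labels; row order defines
    the label order used everywhere downstream.
    """
    path = Path(path)
    header, sep = _sniff(path)
    df = pd.read_csv(path, header=header, sep=sep, float_precision="round_trip")
    labels = [str(c) for c in df.columns] if header == 0 else []
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path}: connectome must be square, got {values.shape[0]}x{values.shape[1]}"
        )
    if expected_n is not None and values.shape[0] != expected_n:
        raise ValueError(
            f"{path}: expected N={expected_n}, got N={values.shape[0]}"
        )
    return Connectome(values, modality, subject_id=subject_id, labels=labels)


def write_connectome(conn: Connectome, path) -> None:
    path = Path(path)
    # default labels carry a prefix so the header row cannot be mistaken
    # for a data row on read
    labels = conn.labels or [f"r{i}" for i in range(conn.n_regions)]
    df = pd.DataFrame(conn.values, columns=labels)
    df.to_csv(path, index=False, float_format="%.17g")


def read_time_series(path, sampling_interval: float, run_id: str = "") -> TimeSeriesMatrix:
    """Read a T x N delimited time-series matrix (optional header row)."""
    path = Path(path)
    header, sep = _sniff(path)
    df = pd.read_csv(path, header=header, sep=sep, float_precision="round_trip")
    return TimeSeriesMatrix(df.to_numpy(dtype=float), sampling_interval, run_id)


def read_adjacency(path, N: int, one_based: bool = False) -> RegionAdjacency:
    """Read a two-column edge list TSV as a region adjacency graph."""
    df = pd.read_csv(path, sep=r"\s+|,|;", engine="python", header=None,
                     comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: adjacency needs two columns per edge")
    edges = df.iloc[:, :2].to_numpy(dtype=int)
    if one_based:
        edges = edges - 1
    return RegionAdjacency(N=N, edges=frozenset(map(tuple, edges.tolist())))


def write_adjacency(adj: RegionAdjacency, path) -> None:
    with open(path, "w") as fh:
        for k, l in sorted(adj.edges):
            fh.write(f"{k}\t{l}\n")


def write_permutation(P: PermutationMatrix, path, labels=None) -> None:
    """Write a permutation as a two-column TSV: source_label, target_label.

    ``P[k, l] = 1`` (``mapping[k] = l``) moves source region ``l`` to
    target position ``k``; rows are emitted in source order.
    """
    labels = list(labels) if labels else [str(i) for i in range(P.n)]
    if len(labels) != P.n:
        raise ValueError("label count does not match permutation size")
    sigma = P.inverse().mapping  # sigma[l] = final position of source l
    with open(path, "w") as fh:
        fh.write("source_label\ttarget_label\n")
        for l in range(P.n):
            fh.write(f"{labels[l]}\t{labels[sigma[l]]}\n")


def read_permutation(path, labels=None) -> PermutationMatrix:
    """Read a two-column permutation TSV; inverse of :func:`write_permutation`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["source_label", "target_label"]:
        raise ValueError(f"{path}: expected columns source_label, target_label")
    n = len(df)
    labels = list(labels) if labels else [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValueError("label count does not match permutation file")
    index = {lab: i for i, lab in enumerate(labels)}
    sigma = np.full(n, -1, dtype=np.intp)
    for _, row in df.iterrows():
        try:
            src = index[row["source_label"]]
            tgt = index[row["target_label"]]
        except KeyError as exc:
            raise ValueError(f"{path}: unknown region label {exc}") from exc
        sigma[src] = tgt
    if np.any(sigma < 0) or len(set(sigma.tolist())) != n:
        raise ValueError(
            f"{path}: not a valid permutation (duplicate or missing targets)"
        )
    return PermutationMatrix(np.argsort(sigma))


def write_eta_records(records, path) -> None:
    """Write EtaRecords as a tidy long-format CSV."""
    rows = [
        {
            "moving": r.moving,
            "reference": r.reference,
            "modality": r.modality,
            "alpha": r.alpha,
            "strategy": r.strategy,
            "in_training": r.in_training,
            "eta": r.eta,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_metadata(meta: dict, path) -> None:
    """Run-metadata sidecar (YAML): enough to reproduce the run."""
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
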