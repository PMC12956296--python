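"""Construction and validation of structural and functional connectomes.

A connectome is a symmetric ``N x N`` matrix over a cortical parcellation of
``N`` regions, split evenly between the hemispheres (the first ``N/2``
row/column indices are the left hemisphere, the last ``N/2`` the right).
Structural connectomes (SC) hold non-negative streamline counts; functional
connectomes (FC) hold Pearson correlations of region-averaged BOLD signals.

This module covers the per-subject preprocessing steps upstream of the
alignment solver: band-pass filtering of region time series, run
concatenation, voxel-to-region averaging, Pearson FC computation, SC
symmetrization, and SC rescaling to the Frobenius norm of the paired FC so
the modality-mixing weight ``alpha`` compares like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "TimeSeriesMatrix",
    "Connectome",
    "SubjectData",
    "bandpass_filter",
    "concat_runs",
    "reduce_by_label",
    "compute_fc",
    "symmetrize",
    "rescale_sc",
]

#: absolute tolerance for symmetry / unit-diagonal checks on input matrices
MATRIX_ATOL = 1e-10


@dataclass
class TimeSeriesMatrix:
    """Region-averaged signal matrix: ``T`` time samples by ``N`` regions.

    Parameters
    ----------
    values : ndarray of shape (T, N)
        One column per region, one row per time sample.
    sampling_interval : float
        Seconds per sample (the scanner TR for BOLD data).
    run_id : str
        Free-form label identifying the acquisition run.
    """

    values: np.ndarray
    sampling_interval: float
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 2 or n < 2:
            raise ValueError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite entries")
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class Connectome:
    """A symmetric region-by-region connectivity matrix.

    ``modality`` is ``"SC"`` (non-negative streamline counts) or ``"FC"``
    (Pearson correlations with unit diagonal). Matrices asymmetric by more
    than ``1e-10`` are rejected; within tolerance they are exactly
    symmetrized on construction. ``N`` must be even (two equal hemispheres).
    """

    values: np.ndarray
    modality: str
    subject_id: str = ""
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"connectome must be square, got shape {v.shape}")
        n = v.shape[0]
        if n % 2 != 0:
            raise ValueError(f"region count must be even (two hemispheres), got N={n}")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectome contains non-finite entries")
        if not np.allclose(v, v.T, rtol=0.0, atol=MATRIX_ATOL):
            raise ValueError("connectome is asymmetric beyond tolerance 1e-10")
        v = (v + v.T) / 2.0  # exact symmetry within tolerance
        if self.modality == "SC":
            if np.any(v < 0):
                raise ValueError("SC entries must be non-negative")
        elif self.modality == "FC":
            if not np.allclose(np.diag(v), 1.0, rtol=0.0, atol=MATRIX_ATOL):
                raise ValueError("FC diagonal must be 1 within tolerance 1e-10")
            if np.any(np.abs(v) > 1.0 + MATRIX_ATOL):
                raise ValueError("FC entries must lie in [-1, 1]")
        else:
            raise ValueError(f"unknown modality {self.modality!r}; expected 'SC' or 'FC'")
        if self.labels and len(self.labels) != n:
            raise ValueError("label count does not match matrix size")
        self.values = v

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def hemisphere_block(self, side: str) -> np.ndarray:
        """Diagonal block of one hemisphere (``'left'`` or ``'right'``)."""
        h = self.n_regions // 2
        if side == "left":
            return self.values[:h, :h]
        if side == "right":
            return self.values[h:, h:]
        raise ValueError("side must be 'left' or 'right'")


@dataclass
class SubjectData:
    """One subject's SC plus one or more FCs over the same parcellation."""

    sc: Connectome
    fc: list[Connectome]
    subject_id: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.fc, Connectome):
            self.fc = [self.fc]
        n = self.sc.n_regions
        for c in self.fc:
            if c.n_regions != n:
                raise ValueError("all connectomes of a subject must share N")

    @property
    def n_regions(self) -> int:
        return self.sc.n_regions


def bandpass_filter(
    ts: TimeSeriesMatrix, low_hz: float = 0.06, high_hz: float = 0.125, order: int = 8
) -> TimeSeriesMatrix:
    """Butterworth band-pass filter each region's signal, zero-phase.

    Defaults follow the standard resting-state band of 0.06-0.125 Hz with a
    Butterworth design of order 8. Filtering is applied forward-backward
    (``sosfiltfilt``), so regional signals incur no relative phase shift —
    required for correlation-based FC — at the price of doubling the
    effective attenuation order.

    Raises
    ------
    ValueError
        If the band is empty or extends to/past the Nyquist frequency, or if
        the series is too short for the filter transient (``T <= 3 * order``).
    """
    nyquist = 1.0 / (2.0 * ts.sampling_interval)
    if not (0.0 < low_hz < high_hz):
        raise ValueError(f"invalid band: need 0 < low < high, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"invalid band: high cutoff {high_hz} Hz >= Nyquist {nyquist:.6g} Hz"
        )
    if ts.n_samples <= 3 * order:
        raise ValueError(
            f"time series too short for order-{order} filter: T={ts.n_samples}"
        )
    sos = signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.sampling_interval,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, ts.values, axis=0)
    return TimeSeriesMatrix(filtered, ts.sampling_interval, ts.run_id)


def concat_runs(
    runs: list[TimeSeriesMatrix], standardize: bool = False
) -> TimeSeriesMatrix:
    """Concatenate runs along the time axis, preserving region order.

    All runs must share the region count and sampling interval. With
    ``standardize=True`` each run is z-scored per region before
    concatenation (off by default: raw concatenation).
    """
    if not runs:
        raise ValueError("no runs to concatenate")
    n = runs[0].n_regions
    dt = runs[0].sampling_interval
    blocks = []
    for r in runs:
        if r.n_regions != n:
            raise ValueError(f"region count mismatch: {r.n_regions} != {n}")
        if not np.isclose(r.sampling_interval, dt):
            raise ValueError("sampling intervals differ across runs")
        v = r.values
        if standardize:
            sd = v.std(axis=0, ddof=0)
            if np.any(sd == 0):
                raise ValueError("cannot standardize a constant region signal")
            v = (v - v.mean(axis=0)) / sd
        blocks.append(v)
    run_id = "+".join(r.run_id for r in runs if r.run_id)
    return TimeSeriesMatrix(np.vstack(blocks), dt, run_id)


def reduce_by_label(
    voxel_ts: np.ndarray, labels: np.ndarray, sampling_interval: float = 1.0,
    run_id: str = "",
) -> TimeSeriesMatrix:
    """Average voxel time series into region time series.

    ``labels`` assigns each voxel column an integer region label in
    ``1..N``; label 0 is background and is discarded. Every region label in
    ``1..max(labels)`` must own at least one voxel.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    labels = np.asarray(labels)
    if voxel_ts.ndim != 2 or labels.ndim != 1 or voxel_ts.shape[1] != labels.shape[0]:
        raise ValueError("voxel_ts must be T x V with one label per voxel column")
    n = int(labels.max(initial=0))
    if n < 1:
        raise ValueError("no region labels found (all background?)")
    missing = [j for j in range(1, n + 1) if not np.any(labels == j)]
    if missing:
        raise ValueError(f"region labels with no voxels: {missing}")
    out = np.column_stack(
        [voxel_ts[:, labels == j].mean(axis=1) for j in range(1, n + 1)]
    )
    return TimeSeriesMatrix(out, sampling_interval, run_id)


def compute_fc(ts: TimeSeriesMatrix, subject_id: str = "") -> Connectome:
    """Pearson-correlation functional connectome of a region time series.

    Raises
    ------
    ValueError
        If any region signal has zero variance (the Pearson coefficient is
        undefined there); the offending region indices are named.
    """
    sd = ts.values.std(axis=0, ddof=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise ValueError(
            f"zero-variance region signal at indices {degenerate.tolist()}; "
            "Pearson correlation is undefined"
        )
    r = np.corrcoef(ts.values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return Connectome(r, "FC", subject_id=subject_id)


def symmetrize(raw_sc: np.ndarray, subject_id: str = "") -> Connectome:
    """Symmetrize a raw streamline-count matrix as ``(S' + S'^T) / 2``."""
    raw_sc = np.asarray(raw_sc, dtype=float)
    if raw_sc.ndim != 2 or raw_sc.shape[0] != raw_sc.shape[1]:
        raise ValueError("raw SC must be square")
    if np.any(raw_sc < 0):
        raise ValueError("raw SC entries must be non-negative")
    return Connectome((raw_sc + raw_sc.T) / 2.0, "SC", subject_id=subject_id)


def rescale_sc(sc: Connectome, fc: Connectome) -> Connectome:
    """Rescale an SC to the Frobenius norm of the subject's FC.

    SC (streamline counts) and FC (correlations) live on incommensurate
    scales; giving them a common Frobenius norm makes the SC/FC mixing
    weight ``alpha`` interpretable as a genuine balance between modalities.
    The zero pattern and relative edge weights of the SC are preserved
    exactly (pure rescaling).
    """
    if sc.n_regions != fc.n_regions:
        raise ValueError("SC and FC must share N")
    sc_norm = np.linalg.norm(sc.values)
    if sc_norm == 0:
        raise ValueError("cannot rescale an all-zero SC (zero Frobenius norm)")
    factor = np.linalg.norm(fc.values) / sc_norm
    return Connectome(sc.values * factor, "SC", subject_id=sc.subject_id,
                      labels=list(sc.labels))
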