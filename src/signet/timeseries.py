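"""ROI time-series conditioning and signed connectivity matrices.

Implements the ROI-level tail of a resting-state preprocessing stream:
dummy-volume removal, nuisance regression (white matter / CSF / motion
summary regressors), band-pass filtering to the low-frequency fluctuation
range, and construction of the full signed Pearson correlation matrix.
Connectivity matrices are deliberately neither thresholded nor binarized —
downstream graph measures consume both positive and negative weights.

The canonical order of operations is
``discard -> nuisance regression -> band-pass -> correlation``;
:func:`preprocess` enforces it.  Nuisance regression and temporal filtering
do not commute, so the order is part of the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ROITimeSeries",
    "ConnectivityMatrix",
    "discard_initial_volumes",
    "regress_nuisance",
    "bandpass_filter",
    "connectivity_matrix",
    "subnetwork",
    "preprocess",
]


@dataclass(frozen=True)
class ROITimeSeries:
    """A volumes x ROIs matrix of BOLD signal averages with TR metadata."""

    values: np.ndarray
    tr_seconds: float
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if values.ndim != 2:
            raise ValueError("time-series values must be a 2-D matrix")
        if values.shape[0] < 2:
            raise ValueError("a time-series needs at least 2 volumes")
        if not np.isfinite(values).all():
            raise ValueError("time-series contains non-finite values")
        if len(self.roi_labels) != values.shape[1]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {values.shape[1]} columns"
            )
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.roi_labels))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, tr_seconds: float) -> "ROITimeSeries":
        frame = pd.read_csv(path, sep="\t")
        return cls(frame.to_numpy(dtype=float), tr_seconds, tuple(frame.columns))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric signed weighted adjacency over ROIs with zero diagonal.

    Weights are full-range signed correlations: no thresholding, no
    binarization, no Fisher transform.  |w| = 1 is tolerated (it arises on
    degenerate synthetic input such as duplicated columns).
    """

    weights: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        n = weights.shape[0]
        if weights.ndim != 2 or weights.shape != (n, n):
            raise ValueError("weights must be a square matrix")
        if len(self.roi_labels) != n:
            raise ValueError(f"{len(self.roi_labels)} labels for {n} nodes")
        if not np.isfinite(weights).all():
            raise ValueError("weights contain non-finite values")
        if not np.allclose(weights, weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(weights)).max(initial=0.0) > 1e-12:
            raise ValueError("diagonal must be zero")
        if np.abs(weights).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("|weights| must not exceed 1")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.roi_labels)
        return pd.DataFrame(self.weights, index=labels, columns=labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ConnectivityMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(frame.to_numpy(dtype=float), tuple(frame.columns))


def discard_initial_volumes(ts: ROITimeSeries, n_discard: int) -> ROITimeSeries:
    """Drop the first ``n_discard`` volumes (magnetization-equilibration dummies)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {ts.n_volumes} volumes"
        )
    if n_discard == 0:
        return ts
    return ROITimeSeries(ts.values[n_discard:], ts.tr_seconds, ts.roi_labels)


def regress_nuisance(ts: ROITimeSeries, nuisance: np.ndarray) -> ROITimeSeries:
    """Residualize every ROI column against [intercept, nuisance columns].

    Each ROI signal is replaced by its ordinary-least-squares residual, so the
    output columns are orthogonal to every nuisance regressor (and mean-free).
    A rank-deficient design triggers a warning and a pseudoinverse fit.
    """
    nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
    if nuisance.shape[0] != ts.n_volumes:
        raise ValueError(
            f"nuisance has {nuisance.shape[0]} rows but time-series has "
            f"{ts.n_volumes} volumes"
        )
    design = np.column_stack([np.ones(ts.n_volumes), nuisance])
    if design.shape[1] >= ts.n_volumes:
        raise ValueError("more nuisance regressors than volumes")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        warnings.warn(
            "nuisance design is rank deficient; using pseudoinverse",
            RuntimeWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    residuals = ts.values - design @ beta
    return ROITimeSeries(residuals, ts.tr_seconds, ts.roi_labels)


def bandpass_filter(
    ts: ROITimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> ROITimeSeries:
    """Keep only spectral content in ``[low_hz, high_hz]``.

    Realized as FFT-domain masking: the real FFT of each column is computed,
    bins with frequency outside the closed band are zeroed, and the signal is
    inverse-transformed.  The DC bin is removed whenever ``low_hz > 0``, so
    output columns are mean-free.  The default 0.01-0.08 Hz band is the
    conventional resting-state low-frequency fluctuation range.
    """
    nyq = ts.nyquist_hz
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyq + 1e-12:
        raise ValueError(
            f"high_hz={high_hz} exceeds the Nyquist frequency {nyq:.6g} Hz "
            f"for TR {ts.tr_seconds} s"
        )
    n = ts.n_volumes
    freqs = np.fft.rfftfreq(n, d=ts.tr_seconds)
    mask = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum = np.fft.rfft(ts.values, axis=0)
    spectrum[~mask] = 0.0
    filtered = np.fft.irfft(spectrum, n=n, axis=0)
    return ROITimeSeries(filtered, ts.tr_seconds, ts.roi_labels)


def connectivity_matrix(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pairwise Pearson correlation of ROI columns, diagonal forced to zero."""
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd <= 1e-12 * max(1.0, float(np.abs(ts.values).max())))
    if dead.size:
        names = ", ".join(ts.roi_labels[i] for i in dead)
        raise ValueError(f"zero-variance ROI column(s): {names}")
    corr = np.corrcoef(ts.values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return ConnectivityMatrix(corr, ts.roi_labels)


def subnetwork(cm: ConnectivityMatrix, roi_subset) -> ConnectivityMatrix:
    """Principal submatrix on ``roi_subset``, preserving the original order."""
    subset = set(roi_subset)
    unknown = subset - set(cm.roi_labels)
    if unknown:
        raise ValueError(f"unknown ROI label(s): {sorted(unknown)}")
    keep = [i for i, lab in enumerate(cm.roi_labels) if lab in subset]
    idx = np.asarray(keep, dtype=int)
    return ConnectivityMatrix(
        cm.weights[np.ix_(idx, idx)],
        tuple(cm.roi_labels[i] for i in keep),
    )


def preprocess(
    ts: ROITimeSeries,
    n_discard: int = 2,
    nuisance: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> ConnectivityMatrix:
    """Run the fixed conditioning pipeline and return the connectivity matrix.

    Order: discard initial volumes, regress nuisance signals (if provided;
    nuisance rows must match the *retained* volume count), band-pass filter,
    correlate.
    """
    out = discard_initial_volumes(ts, n_discard)
    if nuisance is not None:
        out = regress_nuisance(out, nuisance)
    out = bandpass_filter(out, low_hz, high_hz)
    return connectivity_matrix(out)
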