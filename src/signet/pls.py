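"""Brain-behavior covariance patterns via multi-response partial least squares.

Nodal-strength profiles (subjects x ROIs) are decomposed jointly against the
three cognitive domain composites (subjects x 3) with PLS2 regression.  Each
latent variable (LV) pairs a brain loading pattern over ROIs with a
behavioral loading pattern over domains, plus a per-subject score — the
degree to which that pattern is expressed in a subject.

Component count is selected by leave-one-out cross-validation: for each
candidate count the root mean squared error of prediction (RMSEP) on
held-out subjects is accumulated per response and summed over the three
domains; the count minimizing total RMSEP wins, with ties broken toward
fewer components.  Centering and scaling are recomputed inside every fold so
the held-out subject never leaks into the preprocessing.

The raw PLS solution is sign-ambiguous per component; loadings are made
reproducible by flipping each LV so that the largest-magnitude entry of its
brain loading is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.cross_decomposition import PLSRegression

__all__ = [
    "PLSModel",
    "RMSEPCurve",
    "fit_plsr",
    "loo_cv_rmsep",
    "lv_scores_for",
    "brain_loadings_raw",
    "pattern_recovery_cosine",
]


@dataclass(frozen=True)
class PLSModel:
    """A fitted PLS2 decomposition with its preprocessing parameters."""

    x_weights: np.ndarray  # nodes x components
    x_loadings: np.ndarray  # nodes x components
    x_rotations: np.ndarray  # nodes x components; projects standardized X to scores
    y_loadings: np.ndarray  # responses x components
    lv_scores: np.ndarray  # subjects x components (training X scores)
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    y_scale: np.ndarray

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "x_rotations": self.x_rotations.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "lv_scores": self.lv_scores.tolist(),
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_scale": self.y_scale.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class RMSEPCurve:
    """Leave-one-out RMSEP per candidate component count."""

    total: np.ndarray  # length max_components; total[k-1] = sum over responses
    per_response: np.ndarray  # max_components x responses
    selected_n: int


def _standardize(a: np.ndarray, scale: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = a.mean(axis=0)
    if scale:
        sd = a.std(axis=0, ddof=1)
    else:
        sd = np.ones(a.shape[1])
    return (a - mean) / sd, mean, sd


def _validate_xy(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("X/Y contain missing or non-finite values")
    for name, a in (("X", x), ("Y", y)):
        dead = np.flatnonzero(a.std(axis=0) == 0)
        if dead.size:
            raise ValueError(f"zero-variance {name} column(s) at index {dead.tolist()}")
    return x, y


def fit_plsr(
    x: np.ndarray, y: np.ndarray, n_components: int, scale_x: bool = True
) -> PLSModel:
    """Fit a PLS2 model of Y (responses) on X (predictors).

    Columns of X and Y are centered, and unit-variance scaled (X scaling can
    be disabled with ``scale_x=False``; Y is always scaled so the three
    domains contribute comparably).  Deterministic: no randomness enters the
    fit, and the per-component sign convention fixes the remaining ambiguity.
    """
    x, y = _validate_xy(x, y)
    n, p = x.shape
    max_ok = min(n - 1, p)
    if not 1 <= n_components <= max_ok:
        raise ValueError(
            f"n_components must be in [1, {max_ok}] for {n} subjects x {p} predictors"
        )
    xs, x_mean, x_scale = _standardize(x, scale_x)
    ys, y_mean, y_scale = _standardize(y, True)
    core = PLSRegression(n_components=n_components, scale=False)
    core.fit(xs, ys)

    x_weights = core.x_weights_.copy()
    x_loadings = core.x_loadings_.copy()
    x_rotations = core.x_rotations_.copy()
    y_loadings = core.y_loadings_.copy()
    scores = core.x_scores_.copy()
    # sign-fix each LV: dominant brain-loading entry positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(x_loadings[:, k])))
        if x_loadings[j, k] < 0:
            for arr in (x_weights, x_loadings, x_rotations, scores):
                arr[:, k] *= -1
            y_loadings[:, k] *= -1
    return PLSModel(
        x_weights=x_weights,
        x_loadings=x_loadings,
        x_rotations=x_rotations,
        y_loadings=y_loadings,
        lv_scores=scores,
        n_components=n_components,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        y_scale=y_scale,
    )


def lv_scores_for(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    """Project new strength profiles into the fitted latent space.

    Applies the stored centering/scaling, then the rotation matrix (which
    accounts for the deflation steps).  On the training matrix this
    reproduces the stored ``lv_scores``.
    """
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"X_new has {x_new.shape[1]} columns; model was trained on "
            f"{model.x_mean.shape[0]}"
        )
    xs = (x_new - model.x_mean) / model.x_scale
    return xs @ model.x_rotations


def _predict(model: PLSModel, x_new: np.ndarray) -> np.ndarray:
    scores = lv_scores_for(model, x_new)
    ys_hat = scores @ model.y_loadings.T
    return ys_hat * model.y_scale + model.y_mean


def brain_loadings_raw(model: PLSModel) -> np.ndarray:
    """Brain loadings expressed in raw predictor units (nodes x components).

    ``x_loadings`` live in the standardized-column space the model was fit
    in; multiplying by the per-column scale re-expresses each LV's loading
    pattern in the units of the original strength profiles, which is the
    space planted or anatomical patterns are stated in.
    """
    return model.x_loadings * model.x_scale[:, None]


def pattern_recovery_cosine(model: PLSModel, pattern: np.ndarray) -> float:
    """Cosine between a reference brain pattern and the fitted LV subspace.

    PLS loadings are identified only up to rotation within the latent
    subspace whenever successive covariance singular values are close, so
    recovery of a planted or hypothesized pattern is assessed against the
    span of the loading matrix: the principal-angle cosine between
    ``pattern`` and span(raw loadings).  1 means the pattern lies entirely
    inside the recovered subspace; values near the expected cosine of a
    random vector against a k-dim subspace mean it was not recovered.
    """
    pattern = np.asarray(pattern, dtype=float)
    loadings = brain_loadings_raw(model)
    if pattern.shape != (loadings.shape[0],):
        raise ValueError("pattern length must equal the node count")
    q, _ = np.linalg.qr(loadings)
    proj = q @ (q.T @ pattern)
    return float(np.linalg.norm(proj) / np.linalg.norm(pattern))


def loo_cv_rmsep(
    x: np.ndarray, y: np.ndarray, max_components: int, scale_x: bool = True
) -> RMSEPCurve:
    """Leave-one-out RMSEP over component counts 1..max_components."""
    x, y = _validate_xy(x, y)
    n, p = x.shape
    if n < 3:
        raise ValueError("leave-one-out selection needs at least 3 subjects")
    fold_max = min(n - 2, p)  # each training fold has n-1 subjects
    if not 1 <= max_components <= fold_max:
        raise ValueError(
            f"max_components must be in [1, {fold_max}] given fold size {n - 1}"
        )
    n_resp = y.shape[1]
    sq_err = np.zeros((max_components, n_resp))
    for i in range(n):
        keep = np.arange(n) != i
        for k in range(1, max_components + 1):
            model = fit_plsr(x[keep], y[keep], k, scale_x=scale_x)
            pred = _predict(model, x[i])[0]
            sq_err[k - 1] += (pred - y[i]) ** 2
    per_response = np.sqrt(sq_err / n)
    total = per_response.sum(axis=1)
    selected = int(np.argmin(total)) + 1  # argmin keeps the smallest count on ties
    return RMSEPCurve(total=total, per_response=per_response, selected_n=selected)
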