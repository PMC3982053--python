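"""Linear-model inference linking latent scores, modularity, SBR, and motion.

Three families of ordinary-least-squares models:

* LV-domain models — each latent-variable score regressed on the three
  cognitive domains with motor function, age, and sex as nuisance covariates
  (``LV_score ~ executive + memory + visuospatial + motor + age + sex``).
* LV-SBR and modularity-SBR models — simple regressions against the mean
  caudate specific binding ratio, asking which latent patterns, and whether
  cognitive-circuit modularity, track nigrostriatal dopaminergic integrity.
* Motion QC — the first principal component of the standardized absolute
  head-displacement summaries (x, y, z) and the mean relative displacement,
  each regressed on every variable of interest in turn, to check that
  cognition is not confounded by motion.

All p-values are two-sided and uncorrected, mirroring the typical reporting
in this literature; a Benjamini-Hochberg column is appended to tables for
reference but never gates any result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "fit_glm",
    "lv_domain_table",
    "lv_sbr_table",
    "modularity_sbr",
    "motion_qc",
]

_T_CAP = 1e12  # stands in for an infinite t on numerically perfect fits


@dataclass(frozen=True)
class AssociationResult:
    term: str
    beta: float
    t_stat: float
    dof: int
    p_two_sided: float
    n: int


def _design_frame(design) -> pd.DataFrame:
    frame = pd.DataFrame(design).copy()
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            codes, _ = pd.factorize(frame[col], sort=True)
            frame[col] = codes.astype(float)
    return frame.astype(float)


def fit_glm(response, design) -> list[AssociationResult]:
    """OLS with intercept; per-term beta, t, and two-sided p.

    ``design`` is a mapping or DataFrame of named predictor columns;
    categorical columns are factorized to numeric codes.  A singular design
    raises with the names of the collinear columns.  On a numerically exact
    fit the t statistic is capped at a large finite value with p = 0.
    """
    y = np.asarray(response, dtype=float)
    frame = _design_frame(design)
    n = len(y)
    if frame.shape[0] != n:
        raise ValueError("response and design have different lengths")
    if not (np.isfinite(y).all() and np.isfinite(frame.to_numpy()).all()):
        raise ValueError("missing or non-finite values in response/design")
    if y.std() == 0:
        raise ValueError("response has zero variance; fit is degenerate")
    exog = sm.add_constant(frame, has_constant="add")
    if n <= frame.shape[1] + 1:
        raise ValueError(
            f"need n > {frame.shape[1] + 1} subjects for {frame.shape[1]} predictors"
        )
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        # name columns that are linearly dependent on the preceding ones
        cols = exog.to_numpy()
        offenders = []
        for j in range(1, cols.shape[1]):
            if np.linalg.matrix_rank(cols[:, : j + 1]) == np.linalg.matrix_rank(
                cols[:, :j]
            ):
                offenders.append(exog.columns[j])
        raise ValueError(f"singular design; collinear column(s): {offenders}")
    fit = sm.OLS(y, exog).fit()
    dof = int(fit.df_resid)
    out = []
    for term in exog.columns:
        beta = float(fit.params[term])
        t = float(fit.tvalues[term])
        p = float(fit.pvalues[term])
        if not np.isfinite(t):
            t = np.sign(beta) * _T_CAP if beta != 0 else 0.0
            p = 0.0 if beta != 0 else 1.0
        name = "intercept" if term == "const" else str(term)
        out.append(AssociationResult(name, beta, t, dof, p, n))
    return out


def _with_bh(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    if len(table):
        table["p_bh"] = multipletests(table["p"], method="fdr_bh")[1]
    else:
        table["p_bh"] = []
    return table


def _results_to_rows(lv_name: str, results: list[AssociationResult]) -> list[dict]:
    return [
        {
            "lv": lv_name,
            "term": r.term,
            "beta": r.beta,
            "t": r.t_stat,
            "dof": r.dof,
            "p": r.p_two_sided,
            "n": r.n,
        }
        for r in results
    ]


def lv_domain_table(
    lv_scores: np.ndarray,
    domains: pd.DataFrame,
    motor,
    age,
    sex,
) -> pd.DataFrame:
    """One LV ~ domains + motor + age + sex model per latent variable.

    ``domains`` must carry 'executive', 'memory', 'visuospatial' columns.
    Returns a long table of per-term statistics (the analog of a published
    LV-behavior association table), intercept rows included.
    """
    lv_scores = np.atleast_2d(np.asarray(lv_scores, dtype=float))
    design = pd.DataFrame(
        {
            "executive": np.asarray(domains["executive"], dtype=float),
            "memory": np.asarray(domains["memory"], dtype=float),
            "visuospatial": np.asarray(domains["visuospatial"], dtype=float),
            "motor": np.asarray(motor, dtype=float),
            "age": np.asarray(age, dtype=float),
            "sex": list(sex),
        }
    )
    rows: list[dict] = []
    for k in range(lv_scores.shape[1]):
        results = fit_glm(lv_scores[:, k], design)
        rows.extend(_results_to_rows(f"LV{k + 1}", results))
    return _with_bh(pd.DataFrame(rows))


def lv_sbr_table(lv_scores: np.ndarray, sbr_mean_caudate) -> pd.DataFrame:
    """Per-LV simple regression of score on mean caudate SBR."""
    lv_scores = np.atleast_2d(np.asarray(lv_scores, dtype=float))
    sbr = np.asarray(sbr_mean_caudate, dtype=float)
    if len(sbr) < 3:
        raise ValueError("LV-SBR models need at least 3 subjects")
    rows: list[dict] = []
    for k in range(lv_scores.shape[1]):
        results = fit_glm(lv_scores[:, k], {"sbr": sbr})
        rows.extend(_results_to_rows(f"LV{k + 1}", results))
    return _with_bh(pd.DataFrame(rows))


def modularity_sbr(modularity_per_subject, sbr) -> AssociationResult:
    """OLS of per-subject cognitive-circuit Q* on mean caudate SBR (slope term)."""
    q = np.asarray(modularity_per_subject, dtype=float)
    sbr = np.asarray(sbr, dtype=float)
    if len(q) < 3:
        raise ValueError("modularity-SBR model needs at least 3 subjects")
    if q.std() == 0 or sbr.std() == 0:
        raise ValueError("zero-variance input to modularity-SBR model")
    results = fit_glm(q, {"sbr": sbr})
    return next(r for r in results if r.term == "sbr")


def motion_qc(
    motion_abs: np.ndarray, motion_rel, variables: pd.DataFrame
) -> pd.DataFrame:
    """Screen motion summaries against the variables of interest.

    PC1 is extracted from the standardized 3-column absolute-displacement
    matrix by singular value decomposition, sign-fixed so its dominant
    loading is positive.  PC1 scores and the mean relative displacement are
    each regressed on every column of ``variables`` in a separate simple
    model.  Returns a long table (motion measure x variable).
    """
    motion_abs = np.asarray(motion_abs, dtype=float)
    motion_rel = np.asarray(motion_rel, dtype=float)
    if motion_abs.ndim != 2 or motion_abs.shape[1] != 3:
        raise ValueError("motion_abs must be subjects x 3 (x, y, z)")
    if motion_abs.shape[0] < 3:
        raise ValueError("motion QC needs at least 3 subjects")
    sd = motion_abs.std(axis=0, ddof=1)
    if np.any(sd <= 1e-12 * max(1.0, np.abs(motion_abs).max())):
        raise ValueError("zero-variance displacement axis")
    z = (motion_abs - motion_abs.mean(axis=0)) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc1_dir = vt[0]
    j = int(np.argmax(np.abs(pc1_dir)))
    if pc1_dir[j] < 0:
        pc1_dir = -pc1_dir
    pc1 = z @ pc1_dir
    rows: list[dict] = []
    for measure_name, measure in (("pc1_abs_displacement", pc1),
                                  ("mean_rel_displacement", motion_rel)):
        for col in variables.columns:
            results = fit_glm(measure, {str(col): variables[col]})
            slope = next(r for r in results if r.term == str(col))
            rows.append(
                {
                    "motion_measure": measure_name,
                    "variable": str(col),
                    "beta": slope.beta,
                    "t": slope.t_stat,
                    "dof": slope.dof,
                    "p": slope.p_two_sided,
                    "n": slope.n,
                }
            )
    return _with_bh(pd.DataFrame(rows))
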