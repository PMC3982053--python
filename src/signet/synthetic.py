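"""Synthetic cohorts with the statistical structure the pipeline assumes.

Real cohorts of this kind (early Parkinson's disease, resting-state fMRI,
DaT-SPECT) live behind application-gated databases, so every downstream
stage here is driven by a generator that plants known structure:

* a modular signed base connectivity matrix over the atlas ROIs
  (planted-partition ground truth for community detection);
* per-subject latent component scores that perturb the connectivity via
  rank-one loading patterns and simultaneously drive the behavioral
  domain composites, the motor score, and the striatal binding ratio —
  the brain-behavior covariance that PLS is meant to recover;
* BOLD-like ROI time-series sampled from each subject's covariance with
  AR(1) temporal autocorrelation (212 volumes at TR 2.4 s by default);
* demographics and head-motion summaries with the documented couplings
  (motion tracks age and worse motor function, not cognition).

The first latent component is a global integration pattern: positive scores
raise connectivity everywhere, which lowers network modularity.  Because the
binding ratio loads positively on that component, cognitive-circuit
modularity and caudate SBR are negatively coupled by construction.

Everything is driven by one seeded generator: identical config + seed gives
a bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import atlas, behavior as bhv
from .timeseries import ConnectivityMatrix, ROITimeSeries

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "default_control_norms",
    "default_config",
    "planted_partition_matrix",
    "planted_covariance",
    "simulate_timeseries",
    "generate_cohort",
]

_EIG_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-generator settings; defaults emulate the target study design."""

    n_subjects: int = 30
    n_rois: int = 90
    n_volumes: int = 212
    tr_seconds: float = 2.4
    roi_labels: tuple[str, ...] = ()
    module_assignment: dict[str, int] = field(default_factory=dict)
    within_module_corr: float = 0.35
    between_module_corr: float = 0.10
    n_latent_components: int = 3
    component_brain_loadings: np.ndarray = None  # components x ROIs
    component_behavior_loadings: np.ndarray = None  # components x 3 (exec, mem, vsp)
    motor_component_weights: np.ndarray = None  # components
    sbr_component_weights: np.ndarray = None  # components
    noise_sd: float = 0.2
    ar_coefficient: float = 0.3
    n_spect_subjects: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_rois < 2 or self.n_volumes < 2:
            raise ValueError("n_subjects, n_rois, n_volumes must all be >= 2")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        for name in ("within_module_corr", "between_module_corr"):
            if abs(getattr(self, name)) >= 1:
                raise ValueError(f"|{name}| must be < 1")
        labels = self.roi_labels or _default_roi_labels(self.n_rois)
        object.__setattr__(self, "roi_labels", tuple(labels))
        if len(self.roi_labels) != self.n_rois:
            raise ValueError("roi_labels length must equal n_rois")
        assignment = dict(self.module_assignment) or _default_modules(self.roi_labels)
        missing = set(self.roi_labels) - set(assignment)
        if missing:
            raise ValueError(f"module_assignment missing ROI(s): {sorted(missing)}")
        object.__setattr__(self, "module_assignment", assignment)
        k = self.n_latent_components
        brain = self.component_brain_loadings
        if brain is None:
            brain = _default_brain_loadings(self.roi_labels)[:k]
        brain = np.atleast_2d(np.asarray(brain, dtype=float))
        if brain.shape != (k, self.n_rois):
            raise ValueError(
                f"component_brain_loadings must be {k} x {self.n_rois}"
            )
        object.__setattr__(self, "component_brain_loadings", brain)
        behav = self.component_behavior_loadings
        if behav is None:
            behav = _DEFAULT_BEHAVIOR_LOADINGS[:k]
        behav = np.atleast_2d(np.asarray(behav, dtype=float))
        if behav.shape != (k, 3):
            raise ValueError(f"component_behavior_loadings must be {k} x 3")
        object.__setattr__(self, "component_behavior_loadings", behav)
        for name, default in (
            ("motor_component_weights", _DEFAULT_MOTOR_WEIGHTS),
            ("sbr_component_weights", _DEFAULT_SBR_WEIGHTS),
        ):
            vec = getattr(self, name)
            if vec is None:
                vec = default[:k]
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (k,):
                raise ValueError(f"{name} must have length {k}")
            object.__setattr__(self, name, vec)
        if not 0 <= self.n_spect_subjects <= self.n_subjects:
            raise ValueError("n_spect_subjects must be in [0, n_subjects]")

    def with_overrides(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _default_roi_labels(n_rois: int) -> tuple[str, ...]:
    if n_rois == 90:
        return tuple(atlas.aal90_labels())
    return tuple(f"ROI_{i + 1:03d}" for i in range(n_rois))


def _default_modules(labels: Sequence[str], n_modules: int = 5) -> dict[str, int]:
    """Contiguous equal blocks in atlas order."""
    n = len(labels)
    n_modules = min(n_modules, n)
    bounds = np.linspace(0, n, n_modules + 1).astype(int)
    out: dict[str, int] = {}
    for m in range(n_modules):
        for i in range(bounds[m], bounds[m + 1]):
            out[labels[i]] = m + 1
    return out


# Default planted components (values chosen for test power, not realism):
#  1. global integration: small uniform loading over all ROIs; weakly tied to
#     all domains, strongly to motor function and the binding ratio.
#  2. posterior/striatal pattern tied (negatively) to memory.
#  3. dorsal fronto-parietal pattern tied (positively) to executive function.
_POSTERIOR_STRIATAL_AAL = (
    "Cingulum_Post_L", "Cingulum_Post_R", "Calcarine_L", "Calcarine_R",
    "Cuneus_L", "Cuneus_R", "Lingual_L", "Lingual_R",
    "Occipital_Sup_L", "Occipital_Sup_R", "Occipital_Mid_L", "Occipital_Mid_R",
    "Occipital_Inf_L", "Occipital_Inf_R", "Parietal_Sup_L", "Parietal_Sup_R",
    "SupraMarginal_L", "SupraMarginal_R", "Precuneus_L", "Precuneus_R",
    "Caudate_L", "Caudate_R", "Putamen_L", "Putamen_R",
)
_DORSAL_FRONTOPARIETAL_AAL = (
    "Precentral_L", "Precentral_R", "Frontal_Sup_L", "Frontal_Sup_R",
    "Frontal_Sup_Orb_L", "Frontal_Sup_Orb_R", "Frontal_Mid_L", "Frontal_Mid_R",
    "Frontal_Mid_Orb_L", "Frontal_Mid_Orb_R", "Frontal_Inf_Oper_L",
    "Frontal_Inf_Oper_R", "Frontal_Inf_Tri_L", "Frontal_Inf_Tri_R",
    "Supp_Motor_Area_L", "Supp_Motor_Area_R", "Frontal_Sup_Medial_L",
    "Frontal_Sup_Medial_R", "Postcentral_L", "Postcentral_R",
    "Parietal_Inf_L", "Parietal_Inf_R", "Angular_L", "Angular_R",
)
_GLOBAL_LOADING = 0.22
_PATTERN2_LOADING = 0.60
_PATTERN3_LOADING = 0.55
_DEFAULT_BEHAVIOR_LOADINGS = np.array(
    [[0.0, 0.0, 0.0], [0.0, -1.2, 0.0], [0.8, 0.0, 0.0]]
)
_DEFAULT_MOTOR_WEIGHTS = np.array([0.8, 0.0, 0.0])
_DEFAULT_SBR_WEIGHTS = np.array([0.8, 0.0, 0.2])


def _default_brain_loadings(labels: Sequence[str]) -> np.ndarray:
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    a1 = np.full(n, _GLOBAL_LOADING)
    a2 = np.zeros(n)
    a3 = np.zeros(n)
    for lab in _POSTERIOR_STRIATAL_AAL:
        if lab in index:
            a2[index[lab]] = _PATTERN2_LOADING
    for lab in _DORSAL_FRONTOPARIETAL_AAL:
        if lab in index:
            a3[index[lab]] = _PATTERN3_LOADING
    if not a2.any():  # generic labels: fall back to disjoint index blocks
        a2[: n // 3] = _PATTERN2_LOADING
        a3[n // 3 : 2 * (n // 3)] = _PATTERN3_LOADING
    return np.vstack([a1, a2, a3])


def default_config(**overrides) -> SyntheticConfig:
    """The study-design defaults: 30 subjects, 90 ROIs, 212 volumes, TR 2.4 s."""
    return SyntheticConfig(**overrides)


def default_control_norms() -> bhv.ControlNorms:
    """Plausible healthy-control normative statistics for the test battery."""
    mean = {
        "hvlt_trial1": 7.0, "hvlt_trial2": 9.5, "hvlt_trial3": 10.5,
        "hvlt_delayed_recall": 9.5, "benton_jlo": 26.0, "lnst": 11.0,
        "sdmt": 45.0, "semantic_fluency": 21.0, "phonemic_fluency": 13.0,
    }
    sd = {
        "hvlt_trial1": 1.8, "hvlt_trial2": 1.9, "hvlt_trial3": 1.8,
        "hvlt_delayed_recall": 2.4, "benton_jlo": 3.0, "lnst": 2.8,
        "sdmt": 9.0, "semantic_fluency": 5.0, "phonemic_fluency": 4.0,
    }
    return bhv.ControlNorms(mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# covariance construction

def _nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor, then rescale to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= _EIG_FLOOR:
        return sym
    repaired = (vecs * np.clip(vals, _EIG_FLOOR, None)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def planted_covariance(
    n_rois: int,
    module_assignment: Mapping[str, int],
    within_r: float,
    between_r: float,
    roi_labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Block-constant correlation matrix (unit diagonal), PSD-repaired.

    Entry (i, j) is ``within_r`` for ROIs sharing a module and ``between_r``
    otherwise.  Returns the matrix and its label order.
    """
    if abs(within_r) >= 1 or abs(between_r) >= 1:
        raise ValueError("|within_r| and |between_r| must be < 1")
    labels = tuple(roi_labels) if roi_labels else tuple(module_assignment)
    if len(labels) != n_rois:
        raise ValueError(f"expected {n_rois} ROIs, got {len(labels)} labels")
    missing = [lab for lab in labels if lab not in module_assignment]
    if missing:
        raise ValueError(f"module_assignment missing ROI(s): {missing}")
    modules = np.asarray([module_assignment[lab] for lab in labels])
    same = modules[:, None] == modules[None, :]
    mat = np.where(same, within_r, between_r).astype(float)
    np.fill_diagonal(mat, 1.0)
    return _nearest_psd_correlation(mat), labels


def planted_partition_matrix(
    n_rois: int,
    module_assignment: Mapping[str, int],
    within_r: float,
    between_r: float,
    roi_labels: Sequence[str] | None = None,
) -> ConnectivityMatrix:
    """Planted-partition signed adjacency (zero diagonal) over the ROIs."""
    cov, labels = planted_covariance(
        n_rois, module_assignment, within_r, between_r, roi_labels
    )
    weights = cov.copy()
    np.fill_diagonal(weights, 0.0)
    return ConnectivityMatrix(np.clip(weights, -1.0, 1.0), labels)


# ---------------------------------------------------------------------------
# sampling

def simulate_timeseries(
    cov: np.ndarray,
    n_volumes: int,
    ar_coefficient: float = 0.0,
    seed: int | np.random.Generator = 0,
    tr_seconds: float = 2.4,
    roi_labels: Sequence[str] | None = None,
) -> ROITimeSeries:
    """Sample a volumes x ROIs series with cross-ROI covariance ``cov``.

    Temporal structure is stationary AR(1): x_t = a x_{t-1} + sqrt(1-a^2) e_t
    with innovations e_t ~ N(0, cov), so the marginal covariance at every
    volume equals ``cov`` regardless of ``a``.
    """
    cov = np.asarray(cov, dtype=float)
    n_rois = cov.shape[0]
    if cov.shape != (n_rois, n_rois):
        raise ValueError("cov must be square")
    if not 0 <= ar_coefficient < 1:
        raise ValueError("ar_coefficient must lie in [0, 1)")
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    if vals.min() < -1e-8:
        raise ValueError(
            f"covariance is not positive semi-definite (min eigenvalue {vals.min():.3g})"
        )
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innovations = rng.standard_normal((n_volumes, n_rois)) @ root.T
    series = np.empty_like(innovations)
    series[0] = innovations[0]
    scale = np.sqrt(1.0 - ar_coefficient**2)
    for t in range(1, n_volumes):
        series[t] = ar_coefficient * series[t - 1] + scale * innovations[t]
    labels = tuple(roi_labels) if roi_labels else _default_roi_labels(n_rois)
    return ROITimeSeries(series, tr_seconds, labels)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the ground truth planted in it."""

    config: SyntheticConfig
    subjects: list[bhv.SubjectRecord]
    timeseries: list[ROITimeSeries]
    true_component_scores: np.ndarray  # subjects x components
    true_partition: dict[str, int]
    sbr_true: np.ndarray  # subjects (NaN outside the SPECT subsample)
    spect_counts: pd.DataFrame  # caudate_left / caudate_right / occipital
    norms: bhv.ControlNorms

    def table(self) -> pd.DataFrame:
        """Subjects x (behavioral, SBR, motion, demographic) columns."""
        rows = []
        for s in self.subjects:
            row = {
                "subject_id": s.subject_id,
                **{t: v for t, v in s.raw_test_scores.items()},
                "executive": s.domain_scores["executive"],
                "memory": s.domain_scores["memory"],
                "visuospatial": s.domain_scores["visuospatial"],
                "motor": s.motor_domain,
                "updrs_iii": s.updrs_iii,
                "age": s.age,
                "sex": s.sex,
                "sbr_mean_caudate": s.sbr_mean_caudate,
                "motion_abs_x": s.motion_abs[0],
                "motion_abs_y": s.motion_abs[1],
                "motion_abs_z": s.motion_abs[2],
                "motion_rel": s.motion_rel,
            }
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        """Serialize: one time-series TSV per subject plus one cohort table."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table().to_csv(out / "subjects.tsv", sep="\t", index=False)
        for s, ts in zip(self.subjects, self.timeseries):
            ts.to_tsv(out / f"timeseries_{s.subject_id}.tsv")


def generate_cohort(config: SyntheticConfig | None = None) -> SyntheticCohort:
    """Draw a full cohort under ``config`` (defaults: the study design)."""
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_latent_components
    base, labels = planted_covariance(
        cfg.n_rois,
        cfg.module_assignment,
        cfg.within_module_corr,
        cfg.between_module_corr,
        cfg.roi_labels,
    )
    scores = rng.standard_normal((cfg.n_subjects, k))

    # behavioral targets driven by the planted components
    domain_target = scores @ cfg.component_behavior_loadings  # subjects x 3
    motor_target = scores @ cfg.motor_component_weights
    sbr_latent = 2.0 + scores @ cfg.sbr_component_weights + rng.normal(
        0.0, cfg.noise_sd, cfg.n_subjects
    )

    norms = default_control_norms()
    domain_cols = {"executive": 0, "memory": 1, "visuospatial": 2}
    raw_tables: list[dict[str, float]] = []
    for i in range(cfg.n_subjects):
        raw: dict[str, float] = {}
        for domain, tests in bhv.DOMAIN_TESTS.items():
            target = domain_target[i, domain_cols[domain]]
            for t in tests:
                z = target + rng.normal(0.0, cfg.noise_sd)
                raw[t] = norms.mean[t] + norms.sd[t] * z
        raw_tables.append(raw)

    updrs = np.maximum(
        1,
        np.rint(
            20.0 - 10.0 * (motor_target + rng.normal(0.0, cfg.noise_sd, cfg.n_subjects))
        ).astype(int),
    )
    motor_dom = bhv.motor_domain(updrs)
    age = np.clip(rng.normal(61.7, 9.5, cfg.n_subjects), 40.0, 80.0)
    sex = np.where(rng.random(cfg.n_subjects) < 0.65, "M", "F")

    # motion tracks age and worse motor function, not cognition
    z_age = (age - age.mean()) / age.std()
    z_updrs = (updrs - updrs.mean()) / updrs.std()
    motion_latent = 0.5 * z_age + 0.5 * z_updrs + rng.normal(0.0, 0.7, cfg.n_subjects)
    motion_abs = np.clip(
        0.15
        + 0.05 * (motion_latent[:, None] + rng.normal(0.0, 0.3, (cfg.n_subjects, 3))),
        0.01,
        None,
    )
    motion_rel = np.clip(
        0.08 + 0.03 * (motion_latent + rng.normal(0.0, 0.3, cfg.n_subjects)),
        0.005,
        None,
    )

    # SPECT counts for the scanned subsample (occipital reference fixed at 1)
    spect_rows = []
    sbr_true = np.full(cfg.n_subjects, np.nan)
    asym = rng.normal(0.0, 0.05, cfg.n_subjects)
    for i in range(cfg.n_spect_subjects):
        sbr_true[i] = sbr_latent[i]
        spect_rows.append(
            {
                "subject_id": f"S{i + 1:03d}",
                "caudate_left": 1.0 + sbr_latent[i] + asym[i],
                "caudate_right": 1.0 + sbr_latent[i] - asym[i],
                "occipital": 1.0,
            }
        )
    spect_counts = pd.DataFrame(
        spect_rows, columns=["subject_id", "caudate_left", "caudate_right", "occipital"]
    )

    subjects: list[bhv.SubjectRecord] = []
    series: list[ROITimeSeries] = []
    loadings = cfg.component_brain_loadings
    for i in range(cfg.n_subjects):
        cov = base.copy()
        for c in range(k):
            cov += scores[i, c] * np.outer(loadings[c], loadings[c])
        np.fill_diagonal(cov, 1.0)
        cov = _nearest_psd_correlation(np.clip(cov, -0.99, 0.99))
        ts = simulate_timeseries(
            cov,
            cfg.n_volumes,
            cfg.ar_coefficient,
            seed=rng,
            tr_seconds=cfg.tr_seconds,
            roi_labels=labels,
        )
        series.append(ts)
        z = bhv.zscore_tests(raw_tables[i], norms)
        domains = bhv.domain_composite(z)
        sbr_mean = np.nan
        if i < cfg.n_spect_subjects:
            row = spect_counts.iloc[i]
            _, _, sbr_mean = bhv.compute_sbr(
                row["caudate_left"], row["caudate_right"], row["occipital"]
            )
        subjects.append(
            bhv.SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                raw_test_scores=raw_tables[i],
                domain_scores=domains,
                motor_domain=float(motor_dom[i]),
                updrs_iii=int(updrs[i]),
                age=float(age[i]),
                sex=str(sex[i]),
                sbr_mean_caudate=float(sbr_mean),
                motion_abs=tuple(float(v) for v in motion_abs[i]),
                motion_rel=float(motion_rel[i]),
            )
        )

    partition = {lab: cfg.module_assignment[lab] for lab in labels}
    return SyntheticCohort(
        config=cfg,
        subjects=subjects,
        timeseries=series,
        true_component_scores=scores,
        true_partition=partition,
        sbr_true=sbr_true,
        spect_counts=spect_counts,
        norms=norms,
    )
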