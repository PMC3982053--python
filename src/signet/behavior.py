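"""Cognitive domain composites, inverted motor domain, and SPECT binding ratios.

Raw neuropsychological test scores are standardized against healthy-control
norms (z = (raw - mean) / sd) and averaged within fixed domain memberships:

* memory        — the three HVLT-R learning trials plus delayed recall
* visuospatial  — Benton judgment of line orientation
* executive     — letter-number sequencing, symbol-digit modalities,
                  semantic fluency, phonemic fluency

No age or sex adjustment is applied to individual tests; those variables
enter the downstream models as covariates instead.

The motor domain inverts UPDRS part III (motor examination; higher raw =
worse) by z-scoring across the sample and negating, so that every domain
shares the "higher = better" direction and a comparable scale.

The striatal specific binding ratio from DaT-SPECT counts is
``SBR = region / occipital_reference - 1`` per caudate side, then averaged
across hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

__all__ = [
    "DOMAIN_TESTS",
    "ControlNorms",
    "SubjectRecord",
    "zscore_tests",
    "domain_composite",
    "motor_domain",
    "compute_sbr",
]

#: Fixed domain -> member-test map (test names match the behavioral table columns).
DOMAIN_TESTS: dict[str, tuple[str, ...]] = {
    "executive": ("lnst", "sdmt", "semantic_fluency", "phonemic_fluency"),
    "memory": ("hvlt_trial1", "hvlt_trial2", "hvlt_trial3", "hvlt_delayed_recall"),
    "visuospatial": ("benton_jlo",),
}


@dataclass(frozen=True)
class ControlNorms:
    """Healthy-control mean and standard deviation per test."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.mean) != set(self.sd):
            raise ValueError("norms mean/sd must cover the same tests")
        bad = [t for t, s in self.sd.items() if not s > 0]
        if bad:
            raise ValueError(f"non-positive control sd for test(s): {bad}")


@dataclass
class SubjectRecord:
    """One subject's behavioral, demographic, imaging-derived measures."""

    subject_id: str
    raw_test_scores: dict[str, float] = field(default_factory=dict)
    domain_scores: dict[str, float] = field(default_factory=dict)
    motor_domain: float = float("nan")
    updrs_iii: int = 0
    age: float = float("nan")
    sex: str = ""
    sbr_mean_caudate: float = float("nan")
    motion_abs: tuple[float, float, float] = (float("nan"),) * 3
    motion_rel: float = float("nan")


def zscore_tests(
    raw: Mapping[str, float], norms: ControlNorms
) -> dict[str, float]:
    """Convert raw test scores to control-referenced z-scores."""
    missing = [t for t in raw if t not in norms.mean]
    if missing:
        raise ValueError(f"no control norms for test(s): {missing}")
    return {t: (v - norms.mean[t]) / norms.sd[t] for t, v in raw.items()}


def domain_composite(z: Mapping[str, float]) -> dict[str, float]:
    """Average member z-scores within each cognitive domain.

    Every member test must be present; there is no silent imputation.
    """
    out: dict[str, float] = {}
    for domain, members in DOMAIN_TESTS.items():
        missing = [t for t in members if t not in z]
        if missing:
            raise ValueError(f"domain {domain!r} missing test(s): {missing}")
        out[domain] = float(np.mean([z[t] for t in members]))
    return out


def motor_domain(
    updrs_iii_all, ddof: Literal[0, 1] = 0
) -> np.ndarray:
    """Invert and scale UPDRS-III raw scores across a sample.

    Scores are z-scored over the sample (population-sd convention by
    default; ``ddof=1`` switches to the sample-sd convention) and negated,
    so higher values mean better motor function.
    """
    scores = np.asarray(updrs_iii_all, dtype=float)
    if scores.size < 2:
        raise ValueError("motor domain needs at least 2 subjects")
    sd = scores.std(ddof=ddof)
    if sd == 0:
        raise ValueError("UPDRS-III has zero variance in this sample")
    return -(scores - scores.mean()) / sd


def compute_sbr(
    caudate_left: float, caudate_right: float, occipital: float
) -> tuple[float, float, float]:
    """Specific binding ratio (left, right, mean) from regional SPECT counts.

    SBR = caudate / occipital - 1 per side; the occipital area serves as the
    non-specific reference region.  Counts-scale invariant by construction.
    """
    if occipital <= 0:
        raise ValueError("occipital reference counts must be positive")
    left = caudate_left / occipital - 1.0
    right = caudate_right / occipital - 1.0
    return left, right, (left + right) / 2.0
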