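"""End-to-end orchestration: cohort -> connectivity -> graphs -> PLS -> models.

A run executes the fixed stage order

    (synthetic cohort | user data) -> time-series conditioning ->
    whole-brain signed connectivity -> nodal strength ->
    cognitive-circuit (60-ROI) modularity -> behavioral composites ->
    PLS with LOO-RMSEP component selection -> association tables

and writes every intermediate table plus a manifest (config, seeds, package
version, content hashes) into the run directory, so a rerun with the same
config and seeds reproduces all outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, atlas
from .associations import lv_domain_table, lv_sbr_table, modularity_sbr, motion_qc
from .graph import detect_communities_signed, nodal_strength_signed
from .pls import fit_plsr, loo_cv_rmsep
from .synthetic import SyntheticConfig, generate_cohort
from .timeseries import ROITimeSeries, preprocess, subnetwork

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("signet.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for one end-to-end run."""

    mode: str = "synthetic"  # "synthetic" | "user-data"
    seed: int = 0
    n_discard: int = 2
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    pls_max_components: int = 10
    modularity_restarts: int = 100
    atlas_labels: tuple[str, ...] = ()
    circuit_labels: tuple[str, ...] = ()
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    timeseries_dir: str = ""  # user-data mode: dir of timeseries_<id>.tsv
    subjects_table: str = ""  # user-data mode: behavioral/SBR/motion table
    tr_seconds: float = 2.4

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "user-data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        labels = self.atlas_labels or tuple(atlas.aal90_labels())
        circuit = self.circuit_labels or tuple(atlas.cognitive_circuit_labels())
        object.__setattr__(self, "atlas_labels", tuple(labels))
        object.__setattr__(self, "circuit_labels", tuple(circuit))
        unknown = set(self.circuit_labels) - set(self.atlas_labels)
        if unknown:
            raise ValueError(
                f"circuit label(s) absent from atlas: {sorted(unknown)}"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_user_data(config: PipelineConfig):
    table = pd.read_csv(config.subjects_table, sep="\t")
    series = []
    for sid in table["subject_id"]:
        path = Path(config.timeseries_dir) / f"timeseries_{sid}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"stage timeseries: missing {path}")
        series.append(ROITimeSeries.from_tsv(path, config.tr_seconds))
    return table, series


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full workflow; returns the run directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    if config.mode == "synthetic":
        logger.info("stage synthetic_data: generating cohort (seed %d)", config.seed)
        syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        cohort = generate_cohort(syn)
        table = cohort.table()
        series = cohort.timeseries
    else:
        logger.info("stage load: reading user data")
        table, series = _load_user_data(config)

    n_subjects = len(series)
    logger.info("stage timeseries: conditioning %d subjects", n_subjects)
    conn = [
        preprocess(
            ts,
            n_discard=config.n_discard,
            low_hz=config.band_low_hz,
            high_hz=config.band_high_hz,
        )
        for ts in series
    ]

    logger.info("stage graph_metrics: strength and circuit modularity")
    strength = np.vstack(
        [nodal_strength_signed(cm).s_total for cm in conn]
    )
    strength_df = pd.DataFrame(
        strength, index=table["subject_id"], columns=list(conn[0].roi_labels)
    )
    rng = np.random.default_rng(config.seed)
    mod_rows = []
    for sid, cm in zip(table["subject_id"], conn):
        sub = subnetwork(cm, config.circuit_labels)
        res = detect_communities_signed(
            sub,
            n_restarts=config.modularity_restarts,
            seed=int(rng.integers(2**31 - 1)),
        )
        mod_rows.append(
            {
                "subject_id": sid,
                "q_star": res.q_star,
                "q_pos": res.q_pos,
                "q_neg": res.q_neg,
                "n_modules": res.n_modules,
            }
        )
    modularity_df = pd.DataFrame(mod_rows)

    logger.info("stage pls_covariance: LOO-RMSEP selection and fit")
    domains = table[["executive", "memory", "visuospatial"]].to_numpy(float)
    max_comp = min(config.pls_max_components, n_subjects - 2, strength.shape[1])
    curve = loo_cv_rmsep(strength, domains, max_comp)
    model = fit_plsr(strength, domains, curve.selected_n)

    logger.info("stage associations: linear models")
    assoc_domains = lv_domain_table(
        model.lv_scores,
        table[["executive", "memory", "visuospatial"]],
        table["motor"],
        table["age"],
        table["sex"],
    )
    sbr = table["sbr_mean_caudate"].to_numpy(float)
    has_sbr = np.isfinite(sbr)
    assoc_sbr = None
    mod_sbr = None
    if has_sbr.sum() >= 3:
        assoc_sbr = lv_sbr_table(model.lv_scores[has_sbr], sbr[has_sbr])
        mod_sbr = modularity_sbr(
            modularity_df["q_star"].to_numpy()[has_sbr], sbr[has_sbr]
        )
    motion = motion_qc(
        table[["motion_abs_x", "motion_abs_y", "motion_abs_z"]].to_numpy(float),
        table["motion_rel"].to_numpy(float),
        table[["executive", "memory", "visuospatial", "motor", "age"]],
    )

    logger.info("stage outputs: writing run directory")
    table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    strength_df.to_csv(out / "strength.tsv", sep="\t")
    modularity_df.to_csv(out / "modularity.tsv", sep="\t", index=False)
    model.to_json(out / "pls_model.json")
    rmsep_df = pd.DataFrame(
        {
            "n_components": np.arange(1, len(curve.total) + 1),
            "rmsep_total": curve.total,
            "rmsep_executive": curve.per_response[:, 0],
            "rmsep_memory": curve.per_response[:, 1],
            "rmsep_visuospatial": curve.per_response[:, 2],
        }
    )
    rmsep_df.to_csv(out / "rmsep.tsv", sep="\t", index=False)
    assoc_domains.to_csv(out / "assoc_lv_domains.tsv", sep="\t", index=False)
    if assoc_sbr is not None:
        assoc_sbr.to_csv(out / "assoc_lv_sbr.tsv", sep="\t", index=False)
    if mod_sbr is not None:
        pd.DataFrame([asdict(mod_sbr)]).to_csv(
            out / "assoc_modularity_sbr.tsv", sep="\t", index=False
        )
    motion.to_csv(out / "assoc_motion_qc.tsv", sep="\t", index=False)

    config_dict = asdict(config)
    config_dict["atlas_labels"] = list(config.atlas_labels)
    config_dict["circuit_labels"] = list(config.circuit_labels)
    payload = json.dumps(config_dict, sort_keys=True).encode()
    outputs = sorted(
        p.name for p in out.iterdir() if p.name not in ("manifest.json", "log.txt")
    )
    manifest = {
        "package_version": __version__,
        "config": config_dict,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": config.seed,
        "selected_components": curve.selected_n,
        "outputs": {name: _sha256(out / name) for name in outputs},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
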