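"""End-to-end orchestration of the synthetic replication workflow.

``run_pipeline`` executes simulate -> calibrate -> match -> discover
(both studies) -> select -> train -> timecourse -> correlate, writing
every artifact plus a machine-readable summary.  A single YAML config is
the source of truth for all thresholds; the config hash and seed are
recorded in a provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import calibrate_sample
from .classify import (
    fit_linear_model,
    fit_margin_model,
    loo_cv,
    time_course_scores,
)
from .core import ConfigurationError
from .diffstats import discover_markers, select_samples
from .endpoints import correlate_panel
from .matching import ToleranceScheme, build_master_list
from .selection import ScreenCriteria, StudyResult, build_panel, cross_match_masters
from .synthetic import (
    StudyConfig,
    generate_paired_studies,
    make_reference_set,
    temporal_profile,
    write_study,
)

__all__ = ["PipelineConfig", "run_pipeline", "synthetic_endpoints"]

_STAGES = (
    "simulate",
    "calibrate",
    "match",
    "discover",
    "select",
    "train",
    "timecourse",
    "correlate",
)
_DEPENDS = {
    "calibrate": "simulate",
    "match": "calibrate",
    "discover": "match",
    "select": "discover",
    "train": "select",
    "timecourse": "train",
    "correlate": "timecourse",
}


@dataclass
class PipelineConfig:
    """All knobs of the standard run recipe."""

    study: StudyConfig = field(default_factory=StudyConfig)
    n_shared_markers: int = 15
    n_discordant: int = 0
    n_b_control: int = 14
    n_b_case: int = 25
    alpha: float = 0.05
    freq_threshold: float = 0.30
    screen: ScreenCriteria = field(default_factory=ScreenCriteria)
    scheme: ToleranceScheme = field(default_factory=ToleranceScheme)
    classifier_kind: str = "both"  # linear | margin | both
    svm_C: float = 1.0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    seed: int = 1

    def validate(self) -> None:
        self.study.validate()
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if not (0 < self.freq_threshold < 1):
            raise ConfigurationError("freq_threshold must be in (0, 1)")
        if self.classifier_kind not in ("linear", "margin", "both"):
            raise ConfigurationError("classifier_kind must be linear, margin or both")
        for stage, dep in _DEPENDS.items():
            if self.stages.get(stage, True) and not self.stages.get(dep, True):
                raise ConfigurationError(
                    f"stage {stage!r} enabled but its prerequisite {dep!r} is disabled"
                )

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "study" in data and isinstance(data["study"], dict):
            study = dict(data["study"])
            for key in ("doses", "days", "peak_window", "mass_range", "time_range",
                        "time_distortion"):
                if key in study and isinstance(study[key], list):
                    study[key] = tuple(study[key])
            data["study"] = StudyConfig(**study)
        if "screen" in data and isinstance(data["screen"], dict):
            screen = dict(data["screen"])
            if isinstance(screen.get("peak_window"), list):
                screen["peak_window"] = tuple(screen["peak_window"])
            data["screen"] = ScreenCriteria(**screen)
        if "scheme" in data and isinstance(data["scheme"], dict):
            data["scheme"] = ToleranceScheme(**data["scheme"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def synthetic_endpoints(
    design: pd.DataFrame, truth, rng: np.random.Generator
) -> pd.DataFrame:
    """Endpoint table driven by the planted injury signal.

    Histopathology-style scores are monotone (noisy, discretized)
    functions of the latent dose x temporal-profile injury; BUN and
    serum creatinine respond weakly, albumin responds positively --
    mirroring the qualitative endpoint behavior the analysis expects.
    """
    cfg = truth.config
    latent = np.array(
        [
            (row.dose_mg_kg / max(cfg.doses)) * temporal_profile(row.day, cfg)
            for row in design.itertuples()
        ]
    )
    n = len(design)

    def noisy(scale_signal, noise, discrete=None):
        vals = scale_signal * latent + rng.normal(0, noise, n)
        if discrete:
            vals = np.clip(np.round(vals), 0, discrete)
        return vals

    table = pd.DataFrame(
        {
            "histopathology_score": noisy(4.0, 0.8, discrete=5),
            "necrosis_score": noisy(4.0, 1.0, discrete=5),
            "apoptosis_score": noisy(3.0, 1.0, discrete=5),
            "regeneration_score": noisy(2.0, 1.2, discrete=5),
            "bun": 15.0 + noisy(5.0, 4.0),
            "serum_creatinine": 0.4 + noisy(0.3, 0.15),
            "albumin": 1.0 + noisy(2.0, 0.8),
        },
        index=pd.Index(design["sample_id"], name="sample_id"),
    )
    return table


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, *, seed: int | None = None
) -> dict:
    """Execute the full workflow; returns the machine-readable summary."""
    config.validate()
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
        config.study = dataclasses.replace(config.study, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.config_hash, "seed": config.seed, "stages": {}}
    stages = config.stages

    def on(stage: str) -> bool:
        return bool(stages.get(stage, True))

    # --- simulate -----------------------------------------------------
    if not on("simulate"):
        raise ConfigurationError("pipeline requires the simulate stage")
    (samples_a, design_a, truth_a), (samples_b, design_b, truth_b), shared = (
        generate_paired_studies(
            config.study,
            n_shared=config.n_shared_markers,
            n_discordant=config.n_discordant,
            n_b_control=config.n_b_control,
            n_b_case=config.n_b_case,
            seed=config.seed,
        )
    )
    write_study(outdir / "study_a", samples_a, design_a, truth_a)
    write_study(outdir / "study_b", samples_b, design_b, truth_b)
    summary["stages"]["simulate"] = {
        "n_samples_a": len(samples_a),
        "n_samples_b": len(samples_b),
        "n_planted_markers_a": len(truth_a.marker_direction),
        "n_shared_markers": len(shared["shared_ids"]),
        "n_discordant": len(shared["discordant_ids"]),
    }

    # --- calibrate ----------------------------------------------------
    if not on("calibrate"):
        _finish(outdir, config, summary)
        return summary
    refs = make_reference_set(truth_a)
    cal_a = [calibrate_sample(s, refs) for s in samples_a]
    cal_b = [calibrate_sample(s, refs) for s in samples_b]
    summary["stages"]["calibrate"] = {"n_calibrated": len(cal_a) + len(cal_b)}

    # --- match --------------------------------------------------------
    if not on("match"):
        _finish(outdir, config, summary)
        return summary
    master_a = build_master_list(cal_a, config.scheme)
    master_b = build_master_list(cal_b, config.scheme)
    master_a.write(outdir / "study_a")
    master_b.write(outdir / "study_b")
    summary["stages"]["match"] = {
        "n_consensus_a": master_a.n_peptides,
        "n_consensus_b": master_b.n_peptides,
    }

    # --- discover -----------------------------------------------------
    if not on("discover"):
        _finish(outdir, config, summary)
        return summary
    lo, hi = config.study.peak_window
    case_a = select_samples(design_a, f"dose_mg_kg > 0 and {lo} <= day <= {hi}")
    ctrl_a = select_samples(design_a, "dose_mg_kg == 0")
    markers_a = discover_markers(
        master_a, case_a, ctrl_a, alpha=config.alpha, freq_threshold=config.freq_threshold
    )
    case_b = select_samples(design_b, "group == 'treated'")
    ctrl_b = select_samples(design_b, "group == 'control'")
    markers_b = discover_markers(
        master_b, case_b, ctrl_b, alpha=config.alpha, freq_threshold=config.freq_threshold
    )
    markers_a.to_csv(outdir / "study_a" / "markers.csv")
    markers_b.to_csv(outdir / "study_b" / "markers.csv")
    summary["stages"]["discover"] = {
        "n_significant_a": len(markers_a),
        "n_significant_b": len(markers_b),
    }

    # --- select -------------------------------------------------------
    if not on("select"):
        _finish(outdir, config, summary)
        return summary
    result_a = StudyResult(markers_a, master_a, design_a)
    result_b = StudyResult(markers_b, master_b, design_b)
    report = build_panel(result_a, result_b, config.screen, config.scheme)
    report.audit.to_csv(outdir / "selection_audit.csv")
    summary["stages"]["select"] = report.counts
    panel = report.final_panel
    if not panel:
        summary["stages"]["select"]["warning"] = "empty panel; downstream stages skipped"
        _finish(outdir, config, summary)
        return summary

    # --- train (on study B, the two-group training design) ------------
    if not on("train"):
        _finish(outdir, config, summary)
        return summary
    map_a2b = cross_match_masters(master_a, master_b, config.scheme)
    # train only on panel markers with a real response in the training
    # study: markers significant in study A alone have no separation in
    # study B and would receive unstable distance-2 weights
    trainable = [p for p in panel if p in report.sig_b_mapped and p in map_a2b]
    panel_b = trainable if len(trainable) >= 2 else [p for p in panel if p in map_a2b]
    train_matrix = master_b.matrix.loc[[map_a2b[p] for p in panel_b]]
    train_matrix.index = pd.Index(panel_b, name="peptide_id")
    models = {}
    aucs = {}
    if config.classifier_kind in ("linear", "both"):
        models["linear"] = fit_linear_model(panel_b, train_matrix, case_b, ctrl_b)
        aucs["linear_loo_auc"], _ = loo_cv(
            fit_linear_model, panel_b, train_matrix, case_b, ctrl_b
        )
    if config.classifier_kind in ("margin", "both"):
        fit_margin = lambda p, m, c, k: fit_margin_model(
            p, m, c, k, C=config.svm_C, seed=config.seed
        )
        models["margin"] = fit_margin(panel_b, train_matrix, case_b, ctrl_b)
        aucs["margin_loo_auc"], _ = loo_cv(
            fit_margin, panel_b, train_matrix, case_b, ctrl_b
        )
    for name, model in models.items():
        model.to_json(outdir / f"model_{name}.json")
    summary["stages"]["train"] = {"panel_size": len(panel_b), **aucs}

    # --- timecourse (score study A) -----------------------------------
    if not on("timecourse"):
        _finish(outdir, config, summary)
        return summary
    tc = {}
    matrix_a = master_a.matrix.loc[panel_b]
    for name, model in models.items():
        scores = time_course_scores(model, matrix_a, design_a)
        scores.to_csv(outdir / f"timecourse_{name}.csv")
        tc[name] = {
            "peak_treated_minus_control": float(
                scores.loc[lo:hi, scores.columns[1:]].mean().mean()
                - scores.loc[lo:hi, 0.0].mean()
            )
        }
    summary["stages"]["timecourse"] = tc

    # --- correlate ----------------------------------------------------
    if not on("correlate"):
        _finish(outdir, config, summary)
        return summary
    rng = np.random.default_rng(config.seed + 977)
    endpoints = synthetic_endpoints(design_a, truth_a, rng)
    endpoints.to_csv(outdir / "endpoints.csv")
    variables = matrix_a.T.copy()
    variables.columns = [f"peptide_{c}" for c in variables.columns]
    for name, model in models.items():
        variables[f"model_{name}"] = model.score(matrix_a)
    rho, pval = correlate_panel(variables, endpoints)
    rho.to_csv(outdir / "correlation_rho.csv")
    pval.to_csv(outdir / "correlation_p.csv")
    model_rows = [f"model_{n}" for n in models]
    summary["stages"]["correlate"] = {
        "mean_model_histopathology_rho": float(
            rho.loc[model_rows, "histopathology_score"].mean()
        )
    }

    _finish(outdir, config, summary)
    return summary


def _finish(outdir: Path, config: PipelineConfig, summary: dict) -> None:
    config.to_yaml(outdir / "config_used.yaml")
    provenance = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
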