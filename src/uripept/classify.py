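"""Panel classifiers over log-floored marker intensities.

Two model kinds:

* ``linear`` -- per-marker center/scale chosen so that every marker's
  scaled case-group mean minus scaled control-group mean equals exactly
  2 (equal-weight combination; controls score around -1, cases around
  +1).
* ``margin`` -- a linear-kernel SVM on per-marker standardized
  log intensities; decision scores increase with case-likeness.

Both support complete take-one-out cross-validation with strict
per-fold refitting of all normalization constants.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .core import DataError
from .diffstats import auc

__all__ = [
    "ClassifierModel",
    "log_floor_transform",
    "fit_linear_model",
    "fit_margin_model",
    "score_samples",
    "loo_cv",
    "time_course_scores",
]


def log_floor_transform(intensity):
    """Natural log of max(intensity, 1); undetected (0) maps to 0."""
    x = np.asarray(intensity, dtype=float)
    if (x < 0).any():
        raise DataError("intensity must be nonnegative")
    out = np.log(np.maximum(x, 1.0))
    return out if out.ndim else float(out)


@dataclass
class ClassifierModel:
    """Trained panel classifier; serializable to JSON text."""

    kind: str  # "linear" | "margin"
    panel: list
    params: dict
    meta: dict = field(default_factory=dict)

    def score(self, matrix: pd.DataFrame) -> pd.Series:
        """One score per sample (columns of ``matrix``)."""
        missing = [p for p in self.panel if p not in matrix.index]
        if missing:
            raise DataError(f"matrix is missing panel peptides {missing[:5]}")
        x = log_floor_transform(matrix.loc[self.panel].to_numpy().T)  # samples x markers
        if self.kind == "linear":
            m = np.asarray(self.params["center"])
            w = np.asarray(self.params["scale"])
            scores = ((x - m) * w).mean(axis=1)
        elif self.kind == "margin":
            mu = np.asarray(self.params["feature_mean"])
            sd = np.asarray(self.params["feature_sd"])
            coef = np.asarray(self.params["coef"])
            z = (x - mu) / sd
            scores = z @ coef + self.params["intercept"]
        else:
            raise DataError(f"unknown model kind {self.kind!r}")
        return pd.Series(scores, index=matrix.columns, name="score")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kind": self.kind,
            "panel": [int(p) if isinstance(p, (int, np.integer)) else p for p in self.panel],
            "params": {
                k: (np.asarray(v).tolist() if not np.isscalar(v) else v)
                for k, v in self.params.items()
            },
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ClassifierModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            kind=payload["kind"],
            panel=payload["panel"],
            params=payload["params"],
            meta=payload.get("meta", {}),
        )


def _panel_matrix(matrix: pd.DataFrame, panel, sample_ids) -> np.ndarray:
    missing = [p for p in panel if p not in matrix.index]
    if missing:
        raise DataError(f"matrix is missing panel peptides {missing[:5]}")
    return log_floor_transform(matrix.loc[panel, list(sample_ids)].to_numpy().T)


def fit_linear_model(
    panel, matrix: pd.DataFrame, case_ids, control_ids, *, meta: dict | None = None
) -> ClassifierModel:
    """Distance-2 linear model.

    Per marker i with case log-mean mu_c and control log-mean mu_0:
    center = (mu_c + mu_0) / 2 and scale = 2 / (mu_c - mu_0), so scaled
    case and control means sit exactly 2 apart.  Markers with equal
    group means carry no direction and are dropped with a warning.
    """
    panel = list(panel)
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise DataError("both groups must be nonempty")
    xc = _panel_matrix(matrix, panel, case_ids)
    x0 = _panel_matrix(matrix, panel, control_ids)
    mu_c = xc.mean(axis=0)
    mu_0 = x0.mean(axis=0)
    sep = mu_c - mu_0
    keep = sep != 0.0
    if not keep.all():
        dropped = [panel[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} degenerate marker(s) with equal group means",
            stacklevel=2,
        )
    if not keep.any():
        raise DataError("no usable markers: all group means equal")
    kept_panel = [p for p, k in zip(panel, keep) if k]
    center = ((mu_c + mu_0) / 2.0)[keep]
    scale = 2.0 / sep[keep]
    return ClassifierModel(
        kind="linear",
        panel=kept_panel,
        params={"center": center, "scale": scale},
        meta={"n_case": len(case_ids), "n_control": len(control_ids), **(meta or {})},
    )


def fit_margin_model(
    panel,
    matrix: pd.DataFrame,
    case_ids,
    control_ids,
    *,
    C: float = 1.0,
    seed: int = 0,
    meta: dict | None = None,
) -> ClassifierModel:
    """Linear-kernel SVM on per-marker standardized log intensities."""
    panel = list(panel)
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids or not control_ids:
        raise DataError("both groups must be nonempty")
    x = _panel_matrix(matrix, panel, control_ids + case_ids)
    y = np.r_[np.zeros(len(control_ids)), np.ones(len(case_ids))]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0
    z = (x - mu) / sd
    svm = SVC(kernel="linear", C=C, random_state=seed)
    svm.fit(z, y)
    if not hasattr(svm, "coef_"):
        raise DataError("margin model failed to converge")
    return ClassifierModel(
        kind="margin",
        panel=panel,
        params={
            "feature_mean": mu,
            "feature_sd": sd,
            "coef": svm.coef_.ravel(),
            "intercept": float(svm.intercept_[0]),
        },
        meta={
            "C": C,
            "seed": seed,
            "n_case": len(case_ids),
            "n_control": len(control_ids),
            **(meta or {}),
        },
    )


def score_samples(model: ClassifierModel, matrix: pd.DataFrame) -> pd.Series:
    """Convenience wrapper around :meth:`ClassifierModel.score`."""
    return model.score(matrix)


def loo_cv(
    fit_fn,
    panel,
    matrix: pd.DataFrame,
    case_ids,
    control_ids,
) -> tuple[float, pd.Series]:
    """Complete take-one-out cross-validation.

    Each sample is scored by a model fit (including all per-marker
    normalization constants) on the remaining samples.  Returns the AUC
    over held-out scores and the per-sample score series.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if len(case_ids) < 2 or len(control_ids) < 2:
        raise DataError("leave-one-out needs >= 2 samples per class")
    scores = {}
    for held in case_ids + control_ids:
        tr_case = [s for s in case_ids if s != held]
        tr_ctrl = [s for s in control_ids if s != held]
        model = fit_fn(panel, matrix, tr_case, tr_ctrl)
        scores[held] = float(model.score(matrix[[held]]).iloc[0])
    series = pd.Series(scores, name="loo_score")
    cv_auc = auc(series[case_ids].to_numpy(), series[control_ids].to_numpy())
    return cv_auc, series


def time_course_scores(
    model: ClassifierModel, matrix: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Mean classification score per dose x day cell, ordered by day."""
    missing = [s for s in matrix.columns if s not in set(design["sample_id"])]
    if missing:
        raise DataError(f"samples missing from design: {missing[:5]}")
    scores = model.score(matrix)
    joined = design.set_index("sample_id").loc[scores.index]
    joined = joined.assign(score=scores)
    out = (
        joined.groupby(["dose_mg_kg", "day"])["score"]
        .mean()
        .unstack("dose_mg_kg")
        .sort_index()
    )
    out.columns.name = "dose_mg_kg"
    return out
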