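"""Per-peptide differential statistics.

Detection-frequency filter, rank-sum test on ln-transformed intensities,
Benjamini-Hochberg step-up adjustment, Mann-Whitney AUC and the
case/control regulation factor.  Undetected intensities enter the rank
test as the minimum tied value (ln-floor of zero); multiplicity
correction spans only frequency-surviving peptides.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import DataError, MasterList

__all__ = [
    "frequency_filter",
    "wilcoxon_ln",
    "bh_adjust",
    "auc",
    "regulation_factor",
    "discover_markers",
    "select_samples",
]


def frequency_filter(values, case_idx, control_idx, threshold: float = 0.30) -> bool:
    """True iff detection fraction strictly exceeds ``threshold`` in
    either group (nonzero cells count as detected)."""
    values = np.asarray(values, dtype=float)
    case_idx = np.asarray(case_idx, dtype=int)
    control_idx = np.asarray(control_idx, dtype=int)
    if case_idx.size == 0 or control_idx.size == 0:
        raise DataError("frequency filter requires nonempty case and control groups")
    if not (0.0 < threshold < 1.0):
        raise DataError("threshold must be in (0, 1)")
    f_case = np.count_nonzero(values[case_idx]) / case_idx.size
    f_ctrl = np.count_nonzero(values[control_idx]) / control_idx.size
    return bool(f_case > threshold or f_ctrl > threshold)


def _ln_floor(values: np.ndarray) -> np.ndarray:
    """ln(max(x, 1)): undetected (0) and sub-unit intensities map to 0."""
    return np.log(np.maximum(np.asarray(values, dtype=float), 1.0))


def wilcoxon_ln(case, control, *, include_zeros: bool = True) -> float:
    """Two-sided two-sample rank-sum p-value on ln-transformed intensities.

    Exact by enumeration when min(n1, n2) <= 8 with no ties; midrank
    normal approximation with continuity correction otherwise.  With
    ``include_zeros=False`` undetected (0) intensities are dropped
    before testing.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if not include_zeros:
        case = case[case > 0]
        control = control[control > 0]
    if case.size < 3 or control.size < 3:
        raise DataError("each group needs >= 3 values for the rank-sum test")
    x = _ln_floor(case)
    y = _ln_floor(control)
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("degenerate data: all values identical; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DataError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def auc(case, control) -> float:
    """Mann-Whitney AUC: probability a case value exceeds a control value,
    ties counted 1/2."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise DataError("AUC requires nonempty case and control groups")
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    r_case = ranks[: case.size].sum()
    u = r_case - case.size * (case.size + 1) / 2.0
    return float(u / (case.size * control.size))


def regulation_factor(case, control, floor: float = 1.0) -> float:
    """max(mean_case, floor) / max(mean_control, floor).

    Undetected samples contribute 0 to the means; the floor caps the
    factor when a group is essentially undetected.
    """
    if floor <= 0:
        raise DataError("floor must be positive")
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise DataError("regulation factor requires nonempty groups")
    return float(max(case.mean(), floor) / max(control.mean(), floor))


def select_samples(design: pd.DataFrame, query: str) -> list[str]:
    """Sample ids matching a pandas query over the design table."""
    hit = design.query(query)
    return list(hit["sample_id"])


def discover_markers(
    master: MasterList,
    case_ids: list[str],
    control_ids: list[str],
    *,
    alpha: float = 0.05,
    freq_threshold: float = 0.30,
    floor: float = 1.0,
    include_zeros: bool = True,
    return_all: bool = False,
) -> pd.DataFrame:
    """Frequency filter -> rank-sum -> BH -> AUC -> regulation factor.

    Returns one row per significant peptide (p_adj < alpha) with columns
    n_case_detected, n_control_detected, p_raw, p_adj, auc,
    regulation_factor, direction.  ``return_all`` keeps every tested
    peptide with a ``significant`` flag.
    """
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if not case_ids or not control_ids:
        raise DataError("case/control selectors matched no samples")
    if set(case_ids) & set(control_ids):
        raise DataError("case and control sample sets overlap")

    mat = master.matrix
    case = mat[case_ids].to_numpy()
    ctrl = mat[control_ids].to_numpy()
    n1, n0 = case.shape[1], ctrl.shape[1]

    f_case = np.count_nonzero(case, axis=1) / n1
    f_ctrl = np.count_nonzero(ctrl, axis=1) / n0
    tested = np.flatnonzero((f_case > freq_threshold) | (f_ctrl > freq_threshold))

    rows = []
    pvals = []
    for i in tested:
        p = wilcoxon_ln(case[i], ctrl[i], include_zeros=include_zeros)
        pvals.append(p)
        rf = regulation_factor(case[i], ctrl[i], floor=floor)
        rows.append(
            {
                "peptide_id": master.peptides.index[i],
                "mass_da": master.peptides["mass_da"].iloc[i],
                "time_min": master.peptides["time_min"].iloc[i],
                "n_case_detected": int(np.count_nonzero(case[i])),
                "n_control_detected": int(np.count_nonzero(ctrl[i])),
                "p_raw": p,
                "auc": auc(_ln_floor(case[i]), _ln_floor(ctrl[i])),
                "regulation_factor": rf,
                "direction": int(np.sign(np.log(rf))) if rf != 1.0 else 0,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "peptide_id",
            "mass_da",
            "time_min",
            "n_case_detected",
            "n_control_detected",
            "p_raw",
            "auc",
            "regulation_factor",
            "direction",
        ],
    )
    if len(table):
        table["p_adj"] = bh_adjust(np.asarray(pvals))
        table["significant"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    table = table.set_index("peptide_id")
    if return_all:
        return table
    return table[table["significant"]].drop(columns="significant")
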