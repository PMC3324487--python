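"""Sequence annotation bookkeeping and identification acceptance gates.

Peptide sequences use one-letter residues with lowercase modification
codes: p = hydroxyproline, k = hydroxylysine, m = oxidized methionine.
The acceptance filter checks mass deviation (<=50 ppm), migration-time
plausibility against a charge-based prediction model (<=2 min), and
agreement between both search engines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError
from .diffstats import (
    auc,
    bh_adjust,
    frequency_filter,
    regulation_factor,
    wilcoxon_ln,
)

__all__ = [
    "SequenceAnnotation",
    "count_basic_residues",
    "theoretical_mass",
    "MigrationModel",
    "fit_migration_model",
    "validate_assignment",
    "find_protein_fragments",
]

# average residue masses (Da); lowercase codes are +O modifications
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_MOD_MASS = {
    "p": _RESIDUE_MASS["P"] + 15.9994,
    "k": _RESIDUE_MASS["K"] + 15.9994,
    "m": _RESIDUE_MASS["M"] + 15.9994,
}
_WATER = 18.0153
_BASIC = frozenset("KRHk")


@dataclass
class SequenceAnnotation:
    """One peptide-to-protein assignment."""

    sequence: str
    protein: str
    start: int
    stop: int
    mass_da: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.stop:
            raise DataError(f"{self.protein}: start must precede stop")
        if self.stop - self.start + 1 != len(self.sequence):
            raise DataError(
                f"{self.protein} ({self.start}-{self.stop}): sequence length "
                f"{len(self.sequence)} does not span the stated positions"
            )
        if self.mass_da is None:
            self.mass_da = theoretical_mass(self.sequence)

    @property
    def n_basic(self) -> int:
        return count_basic_residues(self.sequence)


def count_basic_residues(sequence: str) -> int:
    """Number of basic residues (K, R, H; hydroxylysine k counts as K).

    The N-terminal amine is charged too but identically for every
    peptide, so it is not counted here (it folds into the migration
    model's stratum intercept).
    """
    n = 0
    for ch in sequence:
        if ch in _BASIC:
            n += 1
        elif ch not in _RESIDUE_MASS and ch not in _MOD_MASS:
            raise DataError(f"unknown residue code {ch!r} in sequence")
    return n


def theoretical_mass(sequence: str) -> float:
    """Average-mass estimate of a (possibly modified) peptide in Da."""
    total = _WATER
    for ch in sequence:
        if ch in _RESIDUE_MASS:
            total += _RESIDUE_MASS[ch]
        elif ch in _MOD_MASS:
            total += _MOD_MASS[ch]
        else:
            raise DataError(f"unknown residue code {ch!r} in sequence")
    return total


@dataclass
class MigrationModel:
    """Per-basic-count linear regressions of migration time on log(mass)."""

    coef: dict  # n_basic -> (intercept, slope)
    residual_sd: float

    def predict(self, mass_da: float, n_basic: int) -> float:
        if mass_da <= 0:
            raise DataError("mass must be positive")
        if not self.coef:
            raise DataError("migration model has no fitted strata")
        if n_basic in self.coef:
            a, b = self.coef[n_basic]
        else:  # nearest fitted stratum stands in
            nearest = min(self.coef, key=lambda k: abs(k - n_basic))
            a, b = self.coef[nearest]
        return float(a + b * np.log(mass_da))


def fit_migration_model(table: pd.DataFrame) -> MigrationModel:
    """Fit the charge-stratified migration-time model.

    ``table`` needs columns ``sequence`` (or ``n_basic``), ``mass_da``
    and ``time_min``.  Strata with fewer than 3 peptides are excluded
    with a warning; at least 10 peptides across >= 2 strata are
    required.
    """
    tab = table.copy()
    if "n_basic" not in tab:
        tab["n_basic"] = [count_basic_residues(s) for s in tab["sequence"]]
    if len(tab) < 10 or tab["n_basic"].nunique() < 2:
        raise DataError(
            "migration model needs >= 10 peptides spanning >= 2 basic-residue counts"
        )
    coef = {}
    residuals = []
    for nb, grp in tab.groupby("n_basic"):
        if len(grp) < 3:
            warnings.warn(
                f"excluding migration stratum n_basic={nb} with {len(grp)} peptides",
                stacklevel=2,
            )
            continue
        x = np.log(grp["mass_da"].to_numpy(float))
        y = grp["time_min"].to_numpy(float)
        b, a = np.polyfit(x, y, 1)
        coef[int(nb)] = (float(a), float(b))
        residuals.append(y - (a + b * x))
    if not coef:
        raise DataError("no migration stratum had enough peptides to fit")
    resid = np.concatenate(residuals)
    dof = max(resid.size - 2 * len(coef), 1)
    return MigrationModel(coef=coef, residual_sd=float(np.sqrt((resid**2).sum() / dof)))


def validate_assignment(
    annotation: SequenceAnnotation,
    observed_mass: float,
    observed_time: float,
    model: MigrationModel,
    *,
    both_engines: bool = True,
    ppm_tol: float = 50.0,
    time_tol: float = 2.0,
) -> tuple[bool, list[str]]:
    """Acceptance gates for one sequence assignment.

    Accept iff mass deviation <= ``ppm_tol``, migration-time deviation
    from the charge-model prediction <= ``time_tol`` and the candidate
    was found by both search engines.  Returns (accepted, failure
    reasons).
    """
    if annotation.mass_da is None:
        raise DataError("annotation lacks a theoretical mass")
    reasons = []
    dev_ppm = abs(observed_mass - annotation.mass_da) / annotation.mass_da * 1e6
    if dev_ppm > ppm_tol:
        reasons.append("mass")
    predicted = model.predict(annotation.mass_da, annotation.n_basic)
    if abs(observed_time - predicted) > time_tol:
        reasons.append("migration")
    if not both_engines:
        reasons.append("engine_agreement")
    return (not reasons), reasons


def find_protein_fragments(
    annotations: pd.DataFrame,
    master_matrix: pd.DataFrame,
    protein_names,
    case_ids,
    control_ids,
    *,
    alpha: float = 0.05,
    freq_threshold: float = 0.30,
) -> pd.DataFrame:
    """Targeted differential test of all fragments of named proteins.

    ``annotations`` maps ``peptide_id`` to ``protein``; the BH family is
    the selected fragment subset only (mirroring a targeted comparison).
    Unknown protein names yield an empty result with a warning.
    """
    protein_names = list(protein_names)
    hit = annotations[annotations["protein"].isin(protein_names)]
    unknown = set(protein_names) - set(annotations["protein"])
    if unknown:
        warnings.warn(f"no fragments annotated for {sorted(unknown)}", stacklevel=2)
    if hit.empty:
        return pd.DataFrame(
            columns=["protein", "p_raw", "p_adj", "auc", "regulation_factor", "significant"]
        )
    case_ids, control_ids = list(case_ids), list(control_ids)
    rows = []
    for _, r in hit.iterrows():
        pid = r["peptide_id"]
        values = master_matrix.loc[pid]
        case = values[case_ids].to_numpy(float)
        ctrl = values[control_ids].to_numpy(float)
        all_idx = np.arange(len(case) + len(ctrl))
        pooled = np.r_[case, ctrl]
        tested = frequency_filter(
            pooled, all_idx[: len(case)], all_idx[len(case):], freq_threshold
        )
        rows.append(
            {
                "peptide_id": pid,
                "protein": r["protein"],
                "tested": tested,
                "p_raw": wilcoxon_ln(case, ctrl) if tested else np.nan,
                "auc": auc(case, ctrl),
                "regulation_factor": regulation_factor(case, ctrl),
            }
        )
    out = pd.DataFrame(rows).set_index("peptide_id")
    out["p_adj"] = np.nan
    tested_mask = out["tested"].to_numpy(bool)
    if tested_mask.any():
        out.loc[tested_mask, "p_adj"] = bh_adjust(
            out.loc[tested_mask, "p_raw"].to_numpy(float)
        )
    out["significant"] = out["p_adj"] < alpha
    return out
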