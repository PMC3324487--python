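"""Two-study biomarker selection workflow.

Candidates from each study are screened for a clear, transient
time-course response (peak-window ratio against control, with return to
baseline late in the study), intersected across studies via tolerance-
window centroid matching, combined, and finally filtered for
cross-study direction concordance.  Every admission/removal is recorded
in a per-peptide audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, MasterList
from .matching import ToleranceScheme, DEFAULT_SCHEME

__all__ = [
    "ScreenCriteria",
    "StudyResult",
    "SelectionReport",
    "temporal_response_screen",
    "group_day_means",
    "cross_match_masters",
    "intersect_studies",
    "direction_concordance",
    "build_panel",
]


@dataclass(frozen=True)
class ScreenCriteria:
    """Codified 'clear response' rule for the temporal screen."""

    r_min: float = 2.0  # minimal peak-window fold change vs control
    r_return: float = 3.0  # late-window ratio must sit in [1/r_return, r_return]
    peak_window: tuple = (3.0, 10.0)
    resolve_day: float = 29.0
    floor: float = 1.0
    geometric: bool = True  # per-day geometric (ln-scale) group means


@dataclass
class StudyResult:
    """Discovery output of one study: markers, master list and design."""

    markers: pd.DataFrame  # discover_markers output (indexed by peptide id)
    master: MasterList
    design: pd.DataFrame

    @property
    def marker_ids(self) -> list:
        return list(self.markers.index)


@dataclass
class SelectionReport:
    """Audit of the selection workflow, all ids in study-A space."""

    audit: pd.DataFrame
    sig_a: set = field(default_factory=set)
    sig_b_mapped: set = field(default_factory=set)
    intersection: set = field(default_factory=set)
    pass_a: set = field(default_factory=set)
    pass_b: set = field(default_factory=set)
    combined: set = field(default_factory=set)
    final_panel: list = field(default_factory=list)

    @property
    def counts(self) -> dict:
        return {
            "significant_a": len(self.sig_a),
            "significant_b_mapped": len(self.sig_b_mapped),
            "intersection": len(self.intersection),
            "temporal_pass_a": len(self.pass_a),
            "temporal_pass_b": len(self.pass_b),
            "combined": len(self.combined),
            "final_panel": len(self.final_panel),
        }


def temporal_response_screen(
    control_means: pd.Series,
    treated_means: pd.Series,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> bool:
    """True iff the peptide shows a clear transient response.

    (a) peak-window treated/control mean ratio >= r_min (up) or
    <= 1/r_min (down) and (b) late-window (day >= resolve_day) ratio
    within [1/r_return, r_return].  Means are raw group means per day
    (undetected contributing 0), floored before forming ratios.
    """
    if control_means is None or len(control_means) == 0:
        raise DataError("temporal screen requires control means")
    lo, hi = criteria.peak_window
    days = np.asarray(control_means.index, dtype=float)
    peak = (days >= lo) & (days <= hi)
    late = days >= criteria.resolve_day
    if not peak.any() or not late.any():
        raise DataError("day grid must cover the peak window and the late window")

    def ratio(mask: np.ndarray) -> float:
        t = max(float(treated_means.to_numpy()[mask].mean()), criteria.floor)
        c = max(float(control_means.to_numpy()[mask].mean()), criteria.floor)
        return t / c

    r_peak = ratio(peak)
    r_late = ratio(late)
    responds = r_peak >= criteria.r_min or r_peak <= 1.0 / criteria.r_min
    resolves = 1.0 / criteria.r_return <= r_late <= criteria.r_return
    return bool(responds and resolves)


def group_day_means(
    master: MasterList, design: pd.DataFrame, dose: float, *, geometric: bool = False
) -> pd.DataFrame:
    """Peptide x day table of mean intensity at one dose (zeros included).

    ``geometric=True`` returns exp(mean ln(max(x, 1))), the floored
    geometric mean, which is far less noise-sensitive for log-normal
    amplitudes than the arithmetic mean.
    """
    sub = design[design["dose_mg_kg"] == dose]
    if sub.empty:
        raise DataError(f"no samples at dose {dose}")
    out = {}
    for day, grp in sub.groupby("day"):
        block = master.matrix[list(grp["sample_id"])]
        if geometric:
            # detected values only: a missing feature says nothing about
            # amplitude and would otherwise inject baseline-sized noise
            logs = np.log(block.clip(lower=1.0)).where(block > 0)
            out[float(day)] = np.exp(logs.mean(axis=1)).fillna(1.0)
        else:
            out[float(day)] = block.mean(axis=1)
    return pd.DataFrame(out).sort_index(axis=1)


def cross_match_masters(
    master_from: MasterList,
    master_to: MasterList,
    scheme: ToleranceScheme = DEFAULT_SCHEME,
) -> dict:
    """Map consensus ids of one master list onto another via the matching
    windows applied to centroids (nearest qualifying centroid wins)."""
    out = {}
    to_mass = master_to.peptides["mass_da"].to_numpy()
    to_time = master_to.peptides["time_min"].to_numpy()
    to_ids = master_to.peptides.index.to_numpy()
    for pid, row in master_from.peptides.iterrows():
        m, t = float(row["mass_da"]), float(row["time_min"])
        mtol = scheme.mass_tolerance(m) * m * 1e-6
        ttol = scheme.time_tolerance(t)
        dm = np.abs(to_mass - m)
        dt = np.abs(to_time - t)
        ok = (dm <= mtol) & (dt <= ttol)
        if not ok.any():
            continue
        score = np.where(ok, dm / mtol + dt / ttol, np.inf)
        out[pid] = to_ids[int(np.argmin(score))]
    return out


def intersect_studies(ids_a, ids_b, id_map: dict | None = None) -> set:
    """Ids present in both studies; ``id_map`` carries B ids into A space."""
    set_a = set(ids_a)
    if id_map is None:
        return set_a & set(ids_b)
    return set_a & {id_map[b] for b in ids_b if b in id_map}


def direction_concordance(candidates: pd.DataFrame) -> tuple[list, pd.DataFrame]:
    """Retain candidates whose per-study directions agree.

    ``candidates`` needs columns ``direction_a`` and ``direction_b``
    (NaN where the study did not call the peptide).  Single-study
    candidates pass by vacuity.
    """
    for col in ("direction_a", "direction_b"):
        if col not in candidates:
            raise DataError(f"candidates missing column {col!r}")
    da = candidates["direction_a"]
    db = candidates["direction_b"]
    both = da.notna() & db.notna()
    discordant = both & (np.sign(da) != np.sign(db))
    verdict = candidates.assign(concordant=~discordant)
    retained = list(candidates.index[~discordant])
    return retained, verdict


def build_panel(
    study_a: StudyResult,
    study_b: StudyResult | None,
    criteria: ScreenCriteria = ScreenCriteria(),
    scheme: ToleranceScheme = DEFAULT_SCHEME,
    *,
    top_dose: float | None = None,
) -> SelectionReport:
    """Run screen -> intersection -> combination -> concordance.

    Study A must be the time-course study (its master/design provide the
    per-day group means used by the screen for candidates from both
    studies).  Study B may be None or empty, in which case the panel is
    study A's temporal markers.
    """
    design_a = study_a.design
    doses = sorted(design_a["dose_mg_kg"].unique())
    if doses[0] != 0:
        raise DataError("study A design has no control (dose 0) samples")
    top = float(top_dose if top_dose is not None else doses[-1])

    ctrl_means = group_day_means(
        study_a.master, design_a, 0.0, geometric=criteria.geometric
    )
    treat_means = group_day_means(
        study_a.master, design_a, top, geometric=criteria.geometric
    )

    sig_a = set(study_a.marker_ids)

    map_b2a: dict = {}
    sig_b_mapped: set = set()
    dir_b_in_a: dict = {}
    if study_b is not None and len(study_b.markers):
        map_b2a = cross_match_masters(study_b.master, study_a.master, scheme)
        for b_id in study_b.marker_ids:
            if b_id in map_b2a:
                a_id = map_b2a[b_id]
                sig_b_mapped.add(a_id)
                dir_b_in_a[a_id] = int(study_b.markers.loc[b_id, "direction"])

    intersection = sig_a & sig_b_mapped

    def screen(pid) -> bool:
        return temporal_response_screen(
            ctrl_means.loc[pid], treat_means.loc[pid], criteria
        )

    pass_a = {pid for pid in sig_a if screen(pid)}
    pass_b = {pid for pid in sig_b_mapped if screen(pid)}
    combined = pass_a | pass_b

    dir_a = {
        pid: int(study_a.markers.loc[pid, "direction"]) for pid in sig_a
    }
    audit = pd.DataFrame(
        {
            "significant_a": [pid in sig_a for pid in sorted(combined)],
            "significant_b": [pid in sig_b_mapped for pid in sorted(combined)],
            "temporal_pass": True,
            "direction_a": [dir_a.get(pid, np.nan) for pid in sorted(combined)],
            "direction_b": [dir_b_in_a.get(pid, np.nan) for pid in sorted(combined)],
        },
        index=pd.Index(sorted(combined), name="peptide_id"),
    )
    final, verdict = direction_concordance(audit)
    audit = verdict
    audit["final"] = audit.index.isin(final)
    audit["removal_reason"] = np.where(audit["final"], "", "direction_discordant")

    # screened-out candidates appear in the audit with their reason
    screened_out = (sig_a | sig_b_mapped) - combined
    if screened_out:
        extra = pd.DataFrame(
            {
                "significant_a": [pid in sig_a for pid in sorted(screened_out)],
                "significant_b": [pid in sig_b_mapped for pid in sorted(screened_out)],
                "temporal_pass": False,
                "direction_a": [dir_a.get(pid, np.nan) for pid in sorted(screened_out)],
                "direction_b": [
                    dir_b_in_a.get(pid, np.nan) for pid in sorted(screened_out)
                ],
                "concordant": np.nan,
                "final": False,
                "removal_reason": "no_temporal_response",
            },
            index=pd.Index(sorted(screened_out), name="peptide_id"),
        )
        audit = pd.concat([audit, extra]).sort_index()

    return SelectionReport(
        audit=audit,
        sig_a=sig_a,
        sig_b_mapped=sig_b_mapped,
        intersection=intersection,
        pass_a=pass_a,
        pass_b=pass_b,
        combined=combined,
        final_panel=sorted(final),
    )
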