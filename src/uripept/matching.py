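"""Cross-sample peptide matching into a master list.

Two features are considered the same peptide when their mass deviation
is within a mass-dependent ppm window (50 ppm below 4 kDa, ramping
linearly to 150 ppm at 6 kDa, constant above) and their migration-time
deviation is within a time-dependent window (1.0 min at/below 19 min,
ramping to 2.5 min at 50 min).  Clustering is greedy and deterministic:
features are processed in descending intensity, each joining the closest
qualifying centroid or seeding a new consensus peptide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MasterList, PeakListSample, StateError

__all__ = ["ToleranceScheme", "mass_tolerance", "time_tolerance", "build_master_list"]


@dataclass(frozen=True)
class ToleranceScheme:
    """Piecewise-linear tolerance anchors for mass (ppm) and time (min)."""

    mass_lo_da: float = 4000.0
    mass_hi_da: float = 6000.0
    ppm_lo: float = 50.0
    ppm_hi: float = 150.0
    time_lo_min: float = 19.0
    time_hi_min: float = 50.0
    tol_lo_min: float = 1.0
    tol_hi_min: float = 2.5

    def mass_tolerance(self, mass):
        mass = np.asarray(mass, dtype=float)
        if (mass <= 0).any():
            raise ValueError("mass must be positive")
        frac = np.clip(
            (mass - self.mass_lo_da) / (self.mass_hi_da - self.mass_lo_da), 0.0, 1.0
        )
        out = self.ppm_lo + frac * (self.ppm_hi - self.ppm_lo)
        return out if out.ndim else float(out)

    def time_tolerance(self, time):
        time = np.asarray(time, dtype=float)
        if (time <= 0).any():
            raise ValueError("time must be positive")
        frac = np.clip(
            (time - self.time_lo_min) / (self.time_hi_min - self.time_lo_min), 0.0, 1.0
        )
        out = self.tol_lo_min + frac * (self.tol_hi_min - self.tol_lo_min)
        return out if out.ndim else float(out)


DEFAULT_SCHEME = ToleranceScheme()


def mass_tolerance(mass, scheme: ToleranceScheme = DEFAULT_SCHEME):
    """Matching tolerance in ppm at a given mass (Da)."""
    return scheme.mass_tolerance(mass)


def time_tolerance(time, scheme: ToleranceScheme = DEFAULT_SCHEME):
    """Matching tolerance in minutes at a given migration time (min)."""
    return scheme.time_tolerance(time)


def build_master_list(
    samples: list[PeakListSample],
    scheme: ToleranceScheme = DEFAULT_SCHEME,
    *,
    require_calibrated: bool = True,
) -> MasterList:
    """Greedy centroid clustering of all features across samples.

    Features are processed in descending intensity (ties broken by mass,
    time, then sample id so the result is invariant to sample order).
    A feature joins the nearest centroid lying within both tolerance
    windows, unless that centroid already holds a feature from the same
    sample; otherwise it seeds a new consensus peptide.  Centroids are
    intensity-weighted running means.
    """
    if require_calibrated:
        for s in samples:
            if not s.calibrated:
                raise StateError(f"sample {s.sample_id} is not calibrated")

    sample_ids = [s.sample_id for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")

    mass = np.concatenate([s.mass for s in samples]) if samples else np.empty(0)
    time = np.concatenate([s.time for s in samples]) if samples else np.empty(0)
    inten = np.concatenate([s.intensity for s in samples]) if samples else np.empty(0)
    samp = np.concatenate(
        [np.full(len(s), i) for i, s in enumerate(samples)]
    ) if samples else np.empty(0, dtype=int)

    sid_rank = {sid: r for r, sid in enumerate(sorted(sample_ids))}
    rank = np.array([sid_rank[sample_ids[i]] for i in samp], dtype=int)
    order = np.lexsort((rank, time, mass, -inten))

    # growing centroid state
    c_mass: list[float] = []
    c_time: list[float] = []
    c_wsum: list[float] = []
    c_members: list[list[tuple[int, float]]] = []  # (sample index, intensity)
    c_samples: list[set] = []

    cm = np.empty(0)
    ct = np.empty(0)
    dirty = True
    for k in order:
        m, t, w, sj = float(mass[k]), float(time[k]), float(inten[k]), int(samp[k])
        if dirty:
            cm = np.asarray(c_mass)
            ct = np.asarray(c_time)
            dirty = False
        chosen = -1
        if cm.size:
            mtol = scheme.mass_tolerance(cm) * cm * 1e-6
            ttol = scheme.time_tolerance(ct)
            dm = np.abs(cm - m)
            dt = np.abs(ct - t)
            ok = (dm <= mtol) & (dt <= ttol)
            if ok.any():
                dist = np.where(ok, np.maximum(dm / mtol, dt / ttol), np.inf)
                comb = np.where(ok, dm / mtol + dt / ttol, np.inf)
                best_key = None
                for c in np.flatnonzero(ok):
                    if sj in c_samples[c]:
                        continue  # one feature per sample per consensus peptide
                    key = (dist[c], comb[c], c)
                    if best_key is None or key < best_key:
                        best_key = key
                        chosen = int(c)
        if chosen >= 0:
            wsum = c_wsum[chosen] + w
            c_mass[chosen] = (c_mass[chosen] * c_wsum[chosen] + m * w) / wsum
            c_time[chosen] = (c_time[chosen] * c_wsum[chosen] + t * w) / wsum
            c_wsum[chosen] = wsum
            c_members[chosen].append((sj, w))
            c_samples[chosen].add(sj)
            dirty = True
        else:
            c_mass.append(m)
            c_time.append(t)
            c_wsum.append(w)
            c_members.append([(sj, w)])
            c_samples.append({sj})
            dirty = True

    n_clusters = len(c_mass)
    # stable consensus ids: sort centroids by (mass, time)
    cid_order = np.lexsort((np.asarray(c_time), np.asarray(c_mass)))
    matrix = np.zeros((n_clusters, len(samples)))
    out_mass = np.empty(n_clusters)
    out_time = np.empty(n_clusters)
    for new_id, c in enumerate(cid_order):
        out_mass[new_id] = c_mass[c]
        out_time[new_id] = c_time[c]
        for sj, w in c_members[c]:
            matrix[new_id, sj] = w

    idx = pd.RangeIndex(n_clusters, name="peptide_id")
    peptides = pd.DataFrame({"mass_da": out_mass, "time_min": out_time}, index=idx)
    mat = pd.DataFrame(matrix, index=idx, columns=sample_ids)
    return MasterList(peptides, mat)
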