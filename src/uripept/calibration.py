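"""Migration-time/mass calibration and internal-standard normalization.

Housekeeping reference peptides are matched inside generous
pre-calibration windows and used to fit a global affine time map and a
linear ppm-offset mass map by least squares.  Internal standards drive a
single multiplicative intensity rescaling (regression through the
origin), the dilution-correction model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CalibrationError, PeakListSample, ReferenceSet

__all__ = [
    "AffineMap",
    "MassOffsetMap",
    "match_references",
    "fit_time_calibration",
    "fit_mass_calibration",
    "fit_intensity_scale",
    "normalize_intensities",
    "calibrate_sample",
]

# pre-calibration matching windows: wide enough to absorb any plausible
# raw distortion, tight enough to keep matches unambiguous
PRECAL_PPM_WINDOW = 300.0
PRECAL_TIME_WINDOW = 5.0
MIN_REFERENCES = 5


@dataclass(frozen=True)
class AffineMap:
    """t_cal = slope * t_obs + offset."""

    slope: float
    offset: float

    def __call__(self, time: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(time, dtype=float) + self.offset


@dataclass(frozen=True)
class MassOffsetMap:
    """Linear ppm error model: err_ppm(m) = a + b * m, removed on apply."""

    a: float
    b: float

    def __call__(self, mass: np.ndarray) -> np.ndarray:
        mass = np.asarray(mass, dtype=float)
        return mass / (1.0 + (self.a + self.b * mass) * 1e-6)


def match_references(
    sample: PeakListSample,
    ref_mass: np.ndarray,
    ref_time: np.ndarray,
    *,
    ppm_window: float = PRECAL_PPM_WINDOW,
    time_window: float = PRECAL_TIME_WINDOW,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-feature match of reference peptides within wide windows.

    Returns (reference indices, feature indices) for references with at
    least one candidate feature; ties broken by smallest combined
    normalized deviation.  Each feature is used at most once.
    """
    ref_mass = np.asarray(ref_mass, dtype=float)
    ref_time = np.asarray(ref_time, dtype=float)
    taken = np.zeros(len(sample), dtype=bool)
    ref_idx, feat_idx = [], []
    for r in range(ref_mass.size):
        dm_ppm = np.abs(sample.mass - ref_mass[r]) / ref_mass[r] * 1e6
        dt = np.abs(sample.time - ref_time[r])
        ok = (dm_ppm <= ppm_window) & (dt <= time_window) & ~taken
        if not ok.any():
            continue
        score = dm_ppm / ppm_window + dt / time_window
        score[~ok] = np.inf
        j = int(np.argmin(score))
        taken[j] = True
        ref_idx.append(r)
        feat_idx.append(j)
    return np.asarray(ref_idx, dtype=int), np.asarray(feat_idx, dtype=int)


def fit_time_calibration(
    sample: PeakListSample, refs: ReferenceSet, *, min_refs: int = MIN_REFERENCES
) -> AffineMap:
    """Least-squares affine map sending observed times onto reference times."""
    rm = refs.housekeeping["mass_da"].to_numpy()
    rt = refs.housekeeping["time_min"].to_numpy()
    ridx, fidx = match_references(sample, rm, rt)
    if ridx.size < min_refs:
        raise CalibrationError(
            f"sample {sample.sample_id}: only {ridx.size} housekeeping references "
            f"matched (need {min_refs}) for time calibration"
        )
    obs = sample.time[fidx]
    exp = rt[ridx]
    slope, offset = np.polyfit(obs, exp, 1)
    return AffineMap(float(slope), float(offset))


def fit_mass_calibration(
    sample: PeakListSample, refs: ReferenceSet, *, min_refs: int = MIN_REFERENCES
) -> MassOffsetMap:
    """Least-squares linear model of the ppm mass error versus mass."""
    rm = refs.housekeeping["mass_da"].to_numpy()
    rt = refs.housekeeping["time_min"].to_numpy()
    ridx, fidx = match_references(sample, rm, rt)
    if ridx.size < min_refs:
        raise CalibrationError(
            f"sample {sample.sample_id}: only {ridx.size} housekeeping references "
            f"matched (need {min_refs}) for mass calibration"
        )
    obs = sample.mass[fidx]
    exp = rm[ridx]
    err_ppm = (obs - exp) / exp * 1e6
    b, a = np.polyfit(obs, err_ppm, 1)
    return MassOffsetMap(float(a), float(b))


def fit_intensity_scale(
    sample: PeakListSample,
    refs: ReferenceSet,
    *,
    min_refs: int = MIN_REFERENCES,
    method: str = "log",
) -> float:
    """Global multiplicative factor from internal standards.

    ``method="log"`` (default) fits the through-origin regression under
    a multiplicative error model, i.e. least squares in log space:
    ln c = mean(ln ref - ln obs).  ``method="linear"`` is the plain
    through-origin fit c = sum(obs * ref) / sum(obs^2), which under
    log-normal amplitude noise is dominated by the largest standard.
    """
    rm = refs.internal_standards["mass_da"].to_numpy()
    rt = refs.internal_standards["time_min"].to_numpy()
    ri = refs.internal_standards["intensity"].to_numpy()
    ridx, fidx = match_references(sample, rm, rt)
    if ridx.size < min_refs:
        raise CalibrationError(
            f"sample {sample.sample_id}: only {ridx.size} internal standards "
            f"matched (need {min_refs}) for intensity normalization"
        )
    obs = sample.intensity[fidx]
    ref = ri[ridx]
    if (obs <= 0).any():
        raise CalibrationError(
            f"sample {sample.sample_id}: matched standards have zero intensity"
        )
    if method == "log":
        return float(np.exp(np.mean(np.log(ref) - np.log(obs))))
    if method == "linear":
        return float(np.dot(obs, ref) / np.dot(obs, obs))
    raise ValueError(f"unknown normalization method {method!r}")


def normalize_intensities(
    sample: PeakListSample, refs: ReferenceSet, *, min_refs: int = MIN_REFERENCES
) -> PeakListSample:
    """Rescale all intensities by the fitted internal-standard factor."""
    scale = fit_intensity_scale(sample, refs, min_refs=min_refs)
    return sample.replace(intensity=sample.intensity * scale)


def calibrate_sample(
    sample: PeakListSample,
    refs: ReferenceSet,
    *,
    min_refs: int = MIN_REFERENCES,
    calibrate_mass: bool = True,
) -> PeakListSample:
    """Full per-sample calibration: time, optional mass, then intensity."""
    tmap = fit_time_calibration(sample, refs, min_refs=min_refs)
    out = sample.replace(time=tmap(sample.time))
    if calibrate_mass:
        mmap = fit_mass_calibration(out, refs, min_refs=min_refs)
        out = out.replace(mass=mmap(out.mass))
    out = normalize_intensities(out, refs, min_refs=min_refs)
    return out.replace(calibrated=True)
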