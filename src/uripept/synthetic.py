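"""Synthetic CE-MS cohort generator.

Builds peak-list cohorts with the statistical structure the downstream
analysis assumes: peptide baselines drawn log-uniform, planted up/down
regulated markers with a transient temporal profile, stable housekeeping
and internal-standard peptides, ppm-scale mass noise, per-sample affine
migration-time distortion, per-sample dilution scaling and independent
missingness.  A :class:`GroundTruth` ledger records every injected
effect so tests can audit any downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConfigurationError, PeakListSample, ReferenceSet

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "temporal_profile",
    "generate_study",
    "generate_two_group_study",
    "generate_paired_studies",
    "make_reference_set",
    "intensity_matrix_from_truth",
    "write_study",
]

_BASE_LOG_RANGE = (math.log(10.0), math.log(1.0e4))


@dataclass
class StudyConfig:
    """Parameters of one simulated dosing study.

    Defaults emulate a gentamicin-style time-course design: doses
    0/150/300 mg/kg, collections on days 1..44, 3 animals per dose per
    day, a transient effect peaking on days 3-10 and resolving by day 29,
    37 internal-standard peptides and homoscedastic ln-scale noise.
    """

    n_peptides: int = 300
    n_markers_up: int = 20
    n_markers_down: int = 10
    doses: tuple = (0, 150, 300)
    days: tuple = (1, 2, 3, 7, 10, 15, 18, 22, 29, 36, 44)
    n_per_cell: int = 3
    effect_size: float = 4.0  # ln-scale group separation, in noise-SD units
    noise_sd: float = 1.0  # SD of ln-intensity
    peak_window: tuple = (3, 10)
    resolve_day: float = 29
    mass_range: tuple = (800.0, 12000.0)
    time_range: tuple = (19.0, 50.0)
    ppm_noise_sd: float = 10.0
    time_noise_sd: float = 0.1  # min
    time_distortion: tuple = (0.05, 1.0)  # (slope half-width, offset half-width min)
    intensity_scale_sd: float = 0.3  # ln-scale SD of per-sample dilution factor
    missing_rate: float = 0.1
    reduce_missing_for_up: bool = False
    n_internal_standards: int = 37
    n_housekeeping: int = 30
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_peptides",
            "n_per_cell",
            "n_internal_standards",
            "n_housekeeping",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_markers_up < 0 or self.n_markers_down < 0:
            raise ConfigurationError("n_markers_up/n_markers_down must be >= 0")
        n_special = (
            self.n_markers_up
            + self.n_markers_down
            + self.n_internal_standards
            + self.n_housekeeping
        )
        if n_special > self.n_peptides:
            raise ConfigurationError(
                "n_peptides too small for markers + internal standards + housekeeping"
            )
        if not self.doses or min(self.doses) != 0:
            raise ConfigurationError("doses must include a 0 control dose")
        if not self.days or min(self.days) <= 0:
            raise ConfigurationError("days must be positive collection days")
        lo, hi = self.peak_window
        if not (min(self.days) <= lo <= hi):
            raise ConfigurationError("peak_window must lie within the days span")
        if self.resolve_day <= hi:
            raise ConfigurationError("resolve_day must exceed the peak window end")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0 or self.effect_size < 0:
            raise ConfigurationError("noise_sd must be > 0 and effect_size >= 0")
        if self.time_distortion[0] < 0 or self.time_distortion[0] >= 1:
            raise ConfigurationError("time_distortion slope half-width must be in [0,1)")


@dataclass
class GroundTruth:
    """Ledger of everything the generator injected (used only by tests)."""

    peptide_mass: np.ndarray  # true masses, Da
    peptide_time: np.ndarray  # true migration times, min
    peptide_base_ln: np.ndarray  # baseline ln-intensities
    marker_direction: dict  # peptide id -> +1 / -1
    internal_standard_ids: np.ndarray
    housekeeping_ids: np.ndarray
    sample_distortion: dict  # sample id -> (slope, offset)
    sample_scale: dict  # sample id -> multiplicative intensity factor
    feature_peptide_ids: dict  # sample id -> peptide id per feature row
    config: StudyConfig | None = None

    def __post_init__(self) -> None:
        n = self.peptide_mass.size
        for pid in self.marker_direction:
            if not (0 <= pid < n):
                raise ConfigurationError("planted marker id outside peptide universe")
        for slope, _ in self.sample_distortion.values():
            if slope <= 0:
                raise ConfigurationError("distortion slopes must be > 0")

    @property
    def marker_ids(self) -> list[int]:
        return sorted(self.marker_direction)

    def expected_shift(self, peptide_id: int, dose: float, day: float) -> float:
        """Planted ln-scale mean shift for a peptide at a dose and day."""
        direction = self.marker_direction.get(peptide_id, 0)
        if direction == 0 or self.config is None:
            return 0.0
        cfg = self.config
        dose_frac = dose / max(cfg.doses) if dose > 0 else 0.0
        return (
            direction
            * cfg.effect_size
            * cfg.noise_sd
            * dose_frac
            * temporal_profile(day, cfg)
        )


def temporal_profile(day: float, config: StudyConfig) -> float:
    """Dimensionless effect multiplier at a collection day.

    Zero before first dose, linear rise to the peak window, flat at 1 on
    the window, then exponential decay reaching 0.05 at ``resolve_day``.
    """
    if day < 0:
        raise ValueError("day must be >= 0")
    lo, hi = config.peak_window
    if day <= 0:
        return 0.0
    if day < lo:
        return day / lo
    if day <= hi:
        return 1.0
    rate = math.log(20.0) / (config.resolve_day - hi)
    return math.exp(-rate * (day - hi))


def _draw_universe(cfg: StudyConfig, rng: np.random.Generator):
    """Peptide universe: masses/times kept apart so matching is well posed."""
    n = cfg.n_peptides
    mass = rng.uniform(*cfg.mass_range, size=n)
    time = rng.uniform(*cfg.time_range, size=n)
    # resample peptides that sit inside another peptide's joint window
    # (3x the matching tolerances) so ground-truth clusters are unambiguous
    for _ in range(50):
        clash = _find_clashes(mass, time)
        if not clash.size:
            break
        mass[clash] = rng.uniform(*cfg.mass_range, size=clash.size)
        time[clash] = rng.uniform(*cfg.time_range, size=clash.size)
    base_ln = rng.uniform(*_BASE_LOG_RANGE, size=n)
    return mass, time, base_ln


def _find_clashes(mass: np.ndarray, time: np.ndarray) -> np.ndarray:
    from .matching import mass_tolerance, time_tolerance

    order = np.argsort(mass)
    m, t = mass[order], time[order]
    clash = []
    for i in range(1, m.size):
        j = i - 1
        tol = 3e-6 * mass_tolerance(m[i]) * m[i]
        while j >= 0 and m[i] - m[j] <= tol:
            if abs(t[i] - t[j]) <= 3 * time_tolerance(t[i]):
                clash.append(order[i])
                break
            j -= 1
    return np.asarray(clash, dtype=int)


def _assign_roles(cfg: StudyConfig, rng: np.random.Generator):
    ids = rng.permutation(cfg.n_peptides)
    up = ids[: cfg.n_markers_up]
    down = ids[cfg.n_markers_up : cfg.n_markers_up + cfg.n_markers_down]
    rest = ids[cfg.n_markers_up + cfg.n_markers_down :]
    ist = rest[: cfg.n_internal_standards]
    hk = rest[cfg.n_internal_standards : cfg.n_internal_standards + cfg.n_housekeeping]
    direction = {int(i): +1 for i in up}
    direction.update({int(i): -1 for i in down})
    return direction, np.sort(ist), np.sort(hk)


def _simulate_samples(
    cfg: StudyConfig,
    rng: np.random.Generator,
    cells: list[tuple[str, float, float, str]],
    universe,
    direction: dict,
    ist: np.ndarray,
    *,
    force_peak: bool = False,
):
    """Draw one peak list per (animal, dose, day) cell.

    ``force_peak`` pins the temporal profile at 1 (two-group designs
    sampled at the response maximum).
    """
    mass, time, base_ln = universe
    n = cfg.n_peptides
    dir_vec = np.zeros(n)
    for pid, d in direction.items():
        dir_vec[pid] = d
    is_standard = np.zeros(n, dtype=bool)
    is_standard[ist] = True
    max_dose = max(cfg.doses)

    samples: list[PeakListSample] = []
    design_rows = []
    distortions: dict[str, tuple] = {}
    scales: dict[str, float] = {}
    feature_ids: dict[str, np.ndarray] = {}

    sw, ow = cfg.time_distortion
    for sample_id, dose, day, animal in cells:
        profile = 1.0 if force_peak else temporal_profile(day, cfg)
        dose_frac = dose / max_dose if dose > 0 else 0.0
        shift = dir_vec * (cfg.effect_size * cfg.noise_sd * dose_frac * profile)
        ln_int = base_ln + shift + rng.normal(0.0, cfg.noise_sd, size=n)
        scale = float(np.exp(rng.normal(0.0, cfg.intensity_scale_sd)))
        intensity = np.exp(ln_int) * scale

        slope = float(rng.uniform(1.0 - sw, 1.0 + sw))
        offset = float(rng.uniform(-ow, ow))
        obs_time = slope * time + offset + rng.normal(0.0, cfg.time_noise_sd, size=n)
        obs_mass = mass * (1.0 + rng.normal(0.0, cfg.ppm_noise_sd * 1e-6, size=n))

        drop_p = np.full(n, cfg.missing_rate)
        if cfg.reduce_missing_for_up and dose > 0:
            drop_p[(dir_vec > 0)] *= 0.5
        drop_p[is_standard] = 0.0
        keep = rng.random(n) >= drop_p

        samples.append(
            PeakListSample(
                sample_id=sample_id,
                mass=obs_mass[keep],
                time=np.clip(obs_time[keep], 1e-3, None),
                intensity=intensity[keep],
            )
        )
        design_rows.append(
            {
                "sample_id": sample_id,
                "animal_id": animal,
                "compound": "treated" if dose > 0 else "control",
                "dose_mg_kg": dose,
                "day": day,
                "group": "treated" if dose > 0 else "control",
            }
        )
        distortions[sample_id] = (slope, offset)
        scales[sample_id] = scale
        feature_ids[sample_id] = np.flatnonzero(keep)

    design = pd.DataFrame(design_rows)
    return samples, design, distortions, scales, feature_ids


def generate_study(config: StudyConfig):
    """Simulate a full dosing time-course study.

    Returns ``(samples, design, truth)``: one :class:`PeakListSample` per
    animal x day cell, a cohort design table and the ground-truth ledger.
    Fixed seed gives bitwise-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    universe = _draw_universe(config, rng)
    direction, ist, hk = _assign_roles(config, rng)

    cells = []
    for dose in config.doses:
        for a in range(config.n_per_cell):
            animal = f"d{dose:g}_a{a}"
            for day in config.days:
                cells.append((f"{animal}_day{day:g}", float(dose), float(day), animal))

    samples, design, distortions, scales, feature_ids = _simulate_samples(
        config, rng, cells, universe, direction, ist
    )
    truth = GroundTruth(
        peptide_mass=universe[0],
        peptide_time=universe[1],
        peptide_base_ln=universe[2],
        marker_direction=direction,
        internal_standard_ids=ist,
        housekeeping_ids=hk,
        sample_distortion=distortions,
        sample_scale=scales,
        feature_peptide_ids=feature_ids,
        config=config,
    )
    return samples, design, truth


def generate_two_group_study(
    config: StudyConfig,
    n_control: int,
    n_case: int,
    *,
    universe=None,
    direction: dict | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate a plain case/control cohort sampled at the response peak.

    Emulates the cis-platin style training design (e.g. 14 controls vs
    25 treated).  ``universe``/``direction`` allow sharing a peptide
    universe across paired studies.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if universe is None:
        universe = _draw_universe(config, rng)
    if direction is None:
        direction, ist, hk = _assign_roles(config, rng)
    else:
        _, ist, hk = _assign_roles(config, rng)
    day = float(config.peak_window[0])
    top = float(max(config.doses))
    cells = [(f"ctrl_{i}", 0.0, day, f"ctrl_{i}") for i in range(n_control)]
    cells += [(f"case_{i}", top, day, f"case_{i}") for i in range(n_case)]
    samples, design, distortions, scales, feature_ids = _simulate_samples(
        config, rng, cells, universe, direction, ist, force_peak=True
    )
    truth = GroundTruth(
        peptide_mass=universe[0],
        peptide_time=universe[1],
        peptide_base_ln=universe[2],
        marker_direction=direction,
        internal_standard_ids=ist,
        housekeeping_ids=hk,
        sample_distortion=distortions,
        sample_scale=scales,
        feature_peptide_ids=feature_ids,
        config=config,
    )
    return samples, design, truth


def generate_paired_studies(
    config: StudyConfig,
    *,
    n_shared: int,
    n_discordant: int = 0,
    n_b_control: int = 14,
    n_b_case: int = 25,
    seed: int | None = None,
):
    """Simulate a two-study pair over one shared peptide universe.

    Study A is the time-course study defined by ``config``; study B is a
    two-group cohort whose marker set is ``n_shared`` of A's markers, of
    which ``n_discordant`` are planted with the opposite direction
    (cross-study concordance violations).

    Returns ``(study_a, study_b, shared)`` where each study is a
    ``(samples, design, truth)`` triple and ``shared`` maps
    ``{"shared_ids": [...], "discordant_ids": [...]}``.
    """
    config.validate()
    if n_shared > config.n_markers_up + config.n_markers_down:
        raise ConfigurationError("n_shared exceeds the study A marker count")
    if n_discordant > n_shared:
        raise ConfigurationError("n_discordant exceeds n_shared")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    universe = _draw_universe(config, rng)
    direction_a, ist, hk = _assign_roles(config, rng)

    marker_ids = sorted(direction_a)
    shared_ids = [int(i) for i in rng.choice(marker_ids, size=n_shared, replace=False)]
    discordant_ids = set(int(i) for i in shared_ids[:n_discordant])
    direction_b = {
        pid: (-direction_a[pid] if pid in discordant_ids else direction_a[pid])
        for pid in shared_ids
    }

    cells_a = []
    for dose in config.doses:
        for a in range(config.n_per_cell):
            animal = f"d{dose:g}_a{a}"
            for day in config.days:
                cells_a.append(
                    (f"A_{animal}_day{day:g}", float(dose), float(day), animal)
                )
    samples_a, design_a, dist_a, scale_a, fid_a = _simulate_samples(
        config, rng, cells_a, universe, direction_a, ist
    )
    truth_a = GroundTruth(
        peptide_mass=universe[0],
        peptide_time=universe[1],
        peptide_base_ln=universe[2],
        marker_direction=direction_a,
        internal_standard_ids=ist,
        housekeeping_ids=hk,
        sample_distortion=dist_a,
        sample_scale=scale_a,
        feature_peptide_ids=fid_a,
        config=config,
    )

    day_b = float(config.peak_window[0])
    top = float(max(config.doses))
    cells_b = [(f"B_ctrl_{i}", 0.0, day_b, f"B_ctrl_{i}") for i in range(n_b_control)]
    cells_b += [(f"B_case_{i}", top, day_b, f"B_case_{i}") for i in range(n_b_case)]
    samples_b, design_b, dist_b, scale_b, fid_b = _simulate_samples(
        config, rng, cells_b, universe, direction_b, ist, force_peak=True
    )
    truth_b = GroundTruth(
        peptide_mass=universe[0],
        peptide_time=universe[1],
        peptide_base_ln=universe[2],
        marker_direction=direction_b,
        internal_standard_ids=ist,
        housekeeping_ids=hk,
        sample_distortion=dist_b,
        sample_scale=scale_b,
        feature_peptide_ids=fid_b,
        config=config,
    )
    shared = {
        "shared_ids": sorted(shared_ids),
        "discordant_ids": sorted(discordant_ids),
    }
    return (samples_a, design_a, truth_a), (samples_b, design_b, truth_b), shared


def make_reference_set(truth: GroundTruth) -> ReferenceSet:
    """Reference set (expected masses/times/intensities) from ground truth."""
    hk = pd.DataFrame(
        {
            "mass_da": truth.peptide_mass[truth.housekeeping_ids],
            "time_min": truth.peptide_time[truth.housekeeping_ids],
        }
    )
    ist = pd.DataFrame(
        {
            "mass_da": truth.peptide_mass[truth.internal_standard_ids],
            "time_min": truth.peptide_time[truth.internal_standard_ids],
            "intensity": np.exp(truth.peptide_base_ln[truth.internal_standard_ids]),
        }
    )
    return ReferenceSet(hk, ist)


def intensity_matrix_from_truth(samples, truth: GroundTruth) -> pd.DataFrame:
    """Oracle peptide x sample matrix keyed by true peptide ids (0 = missing).

    Bypasses matching; used by tests and by statistics-only simulations
    where cluster assignment is not the subject under study.
    """
    n = truth.peptide_mass.size
    mat = np.zeros((n, len(samples)))
    cols = []
    for j, s in enumerate(samples):
        pids = truth.feature_peptide_ids[s.sample_id]
        mat[pids, j] = s.intensity
        cols.append(s.sample_id)
    return pd.DataFrame(mat, index=pd.RangeIndex(n, name="peptide_id"), columns=cols)


def write_study(outdir: str | Path, samples, design: pd.DataFrame, truth: GroundTruth):
    """Write peak lists (TSV), the design table (CSV) and the truth ledger."""
    outdir = Path(outdir)
    peaks = outdir / "peaks"
    peaks.mkdir(parents=True, exist_ok=True)
    for s in samples:
        s.to_tsv(peaks / f"{s.sample_id}.tsv")
    design.to_csv(outdir / "design.csv", index=False)
    make_reference_set(truth).to_csv(outdir / "references.csv")
    truth_table = pd.DataFrame(
        {
            "peptide_id": np.arange(truth.peptide_mass.size),
            "mass_da": truth.peptide_mass,
            "time_min": truth.peptide_time,
            "base_ln_intensity": truth.peptide_base_ln,
            "direction": [
                truth.marker_direction.get(i, 0)
                for i in range(truth.peptide_mass.size)
            ],
            "internal_standard": np.isin(
                np.arange(truth.peptide_mass.size), truth.internal_standard_ids
            ),
            "housekeeping": np.isin(
                np.arange(truth.peptide_mass.size), truth.housekeeping_ids
            ),
        }
    )
    truth_table.to_csv(outdir / "ground_truth.csv", index=False)
    if truth.config is not None:
        cfg = asdict(truth.config)
        pd.Series(
            {k: str(v) for k, v in cfg.items()}, name="value"
        ).to_csv(outdir / "config.csv", index_label="field")
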