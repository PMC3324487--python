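"""Core data containers and file I/O for CE-MS peak-list processing.

A sample's feature list is a flat table of (molecular mass [Da],
migration time [min], signal intensity [AU]).  Cross-sample consensus
peptides live in a :class:`MasterList` whose intensity matrix uses 0 to
mean "not detected".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "CalibrationError",
    "DataError",
    "StateError",
    "PeakListSample",
    "ReferenceSet",
    "MasterList",
]


class ConfigurationError(ValueError):
    """Invalid configuration value; message names the offending field."""


class CalibrationError(RuntimeError):
    """Too few matched reference peptides to fit a calibration."""


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class StateError(RuntimeError):
    """Operation applied to an object in the wrong state."""


@dataclass
class PeakListSample:
    """One urine sample's deconvoluted peptide feature list.

    Parameters
    ----------
    sample_id
        Unique sample identifier.
    mass, time, intensity
        Parallel arrays: molecular mass in Da, CE migration time in
        minutes, signal intensity in arbitrary units.
    calibrated
        Whether mass/time calibration and intensity normalization have
        been applied.
    """

    sample_id: str
    mass: np.ndarray
    time: np.ndarray
    intensity: np.ndarray
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.mass = np.asarray(self.mass, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        n = self.mass.size
        if self.time.size != n or self.intensity.size != n:
            raise DataError(
                f"sample {self.sample_id}: mass/time/intensity lengths differ"
            )
        if n and (self.mass <= 0).any():
            raise DataError(f"sample {self.sample_id}: nonpositive mass")
        if n and (self.time <= 0).any():
            raise DataError(f"sample {self.sample_id}: nonpositive time")
        if n and (self.intensity < 0).any():
            raise DataError(f"sample {self.sample_id}: negative intensity")

    def __len__(self) -> int:
        return int(self.mass.size)

    def replace(self, **kwargs) -> "PeakListSample":
        return replace(self, **kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mass_da": self.mass, "time_min": self.time, "intensity": self.intensity}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, sample_id: str, frame: pd.DataFrame, calibrated: bool = False
    ) -> "PeakListSample":
        return cls(
            sample_id=sample_id,
            mass=frame["mass_da"].to_numpy(float),
            time=frame["time_min"].to_numpy(float),
            intensity=frame["intensity"].to_numpy(float),
            calibrated=calibrated,
        )

    @classmethod
    def from_tsv(
        cls, path: str | Path, sample_id: str | None = None, calibrated: bool = False
    ) -> "PeakListSample":
        path = Path(path)
        sid = sample_id if sample_id is not None else path.stem
        return cls.from_frame(sid, pd.read_csv(path, sep="\t"), calibrated=calibrated)


@dataclass
class ReferenceSet:
    """Reference peptides for calibration and intensity normalization.

    ``housekeeping`` carries (expected mass, expected time) landmarks for
    mass/migration-time calibration; ``internal_standards`` additionally
    carries a reference intensity for amplitude normalization.
    """

    housekeeping: pd.DataFrame  # columns: mass_da, time_min
    internal_standards: pd.DataFrame  # columns: mass_da, time_min, intensity

    def __post_init__(self) -> None:
        for col in ("mass_da", "time_min"):
            if col not in self.housekeeping or col not in self.internal_standards:
                raise DataError(f"reference set missing column {col!r}")
        if "intensity" not in self.internal_standards:
            raise DataError("internal standards need a reference intensity column")
        if (self.internal_standards["intensity"] <= 0).any():
            raise DataError("reference intensities must be positive")

    def to_csv(self, path: str | Path) -> None:
        hk = self.housekeeping.assign(role="housekeeping", intensity=np.nan)
        ist = self.internal_standards.assign(role="internal_standard")
        pd.concat([hk, ist], ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReferenceSet":
        table = pd.read_csv(path)
        hk = table[table["role"] == "housekeeping"][["mass_da", "time_min"]]
        ist = table[table["role"] == "internal_standard"][
            ["mass_da", "time_min", "intensity"]
        ]
        return cls(hk.reset_index(drop=True), ist.reset_index(drop=True))


@dataclass
class MasterList:
    """Cross-sample consensus peptides plus a per-sample intensity matrix.

    ``peptides`` is indexed by consensus id with centroid columns
    ``mass_da`` and ``time_min``; ``matrix`` shares that index, one column
    per sample, 0 meaning not detected.
    """

    peptides: pd.DataFrame
    matrix: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.peptides.index.equals(self.matrix.index):
            raise DataError("master list peptide table and matrix indexes differ")
        if (self.matrix.to_numpy() < 0).any():
            raise DataError("master list intensities must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    def detection_frequency(self, sample_ids: list[str]) -> pd.Series:
        """Fraction of the given samples in which each peptide is detected."""
        sub = self.matrix[sample_ids]
        return (sub > 0).sum(axis=1) / len(sample_ids)

    def write(self, outdir: str | Path, stem: str = "master") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.peptides.to_csv(outdir / f"{stem}_peptides.csv", index_label="peptide_id")
        self.matrix.to_csv(outdir / f"{stem}_matrix.csv", index_label="peptide_id")

    @classmethod
    def read(cls, outdir: str | Path, stem: str = "master") -> "MasterList":
        outdir = Path(outdir)
        peptides = pd.read_csv(outdir / f"{stem}_peptides.csv", index_col="peptide_id")
        matrix = pd.read_csv(outdir / f"{stem}_matrix.csv", index_col="peptide_id")
        return cls(peptides, matrix)
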