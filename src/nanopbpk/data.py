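"""Study designs, synthetic biodistribution data, and dataset I/O.

The five built-in designs mirror the printed in vivo study layout: two
PACA-Cbz dose groups (0.5 and 3.5 µg cabazitaxel per g body weight) and three
LipImage™ 815 dose groups (0.046, 0.15, 0.46 µg IR780 per g bw), each with
sacrifice at 1 h, 1 d, 2 d, 4 d and 14 d, four animals per time point, organ
panels {blood, liver, spleen, lung, kidney, heart, brain}, and serial blood
punctures at substance-specific times.  The in vivo measurements themselves
are unpublished, so the generator stands in for them: it simulates the model
at a chosen "true" parameter vector and applies i.i.d. multiplicative
log-normal noise — the error structure the squared-log-ratio likelihood
assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import OBSERVABLE_ORGANS, ParameterVector, observe, simulate
from .physiology import FixedKinetics, RatPhysiology

__all__ = [
    "StudyDesign",
    "ObservationRecord",
    "BiodistributionDataset",
    "builtin_designs",
    "published_median_theta",
    "generate_synthetic",
    "read_dataset",
    "write_dataset",
    "DEFAULT_NOISE_SIGMA",
    "CSV_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Default log-scale standard deviation of the multiplicative noise.
DEFAULT_NOISE_SIGMA = 0.3

#: Floor below which model predictions are excluded from generated data.
PREDICTION_FLOOR = 1e-12

CSV_COLUMNS = (
    "dataset_id",
    "substance",
    "dose_ug_per_g",
    "organ",
    "time_h",
    "animal_id",
    "value_ug_per_g",
)

_SACRIFICE_TIMES_H = (1.0, 24.0, 48.0, 96.0, 336.0)
_PACA_BLOOD_TIMES_H = (
    1.0 / 60.0,
    3.0 / 60.0,
    7.0 / 60.0,
    15.0 / 60.0,
    30.0 / 60.0,
    1.0,
    4.0,
    24.0,
    48.0,
    96.0,
    336.0,
)
_LIPIMAGE_BLOOD_TIMES_H = (15.0 / 60.0, 30.0 / 60.0, 1.0, 4.0, 24.0)


@dataclass(frozen=True)
class StudyDesign:
    """Dose group and sampling layout of one biodistribution sub-study."""

    dataset_id: str
    substance: str
    dose_per_bw: float  # µg loaded substance per g body weight
    blood_sampling_times: tuple[float, ...]  # h
    sacrifice_times: tuple[float, ...]  # h
    animals_per_timepoint: int
    organs_measured: frozenset[str]

    def __post_init__(self) -> None:
        for name, times in (
            ("blood_sampling_times", self.blood_sampling_times),
            ("sacrifice_times", self.sacrifice_times),
        ):
            arr = np.asarray(times)
            if arr.size and (np.any(arr <= 0) or np.any(np.diff(arr) <= 0)):
                raise ValueError(f"{name} must be positive and strictly increasing")
        if self.animals_per_timepoint < 1:
            raise ValueError("animals_per_timepoint must be >= 1")
        if not self.organs_measured:
            raise ValueError("organs_measured must be non-empty")
        if not self.dose_per_bw > 0:
            raise ValueError("dose_per_bw must be positive")

    def all_times(self) -> np.ndarray:
        """Sorted union of sacrifice and blood-sampling times (h)."""
        return np.unique(
            np.concatenate([self.sacrifice_times, self.blood_sampling_times])
        )


@dataclass(frozen=True)
class ObservationRecord:
    """One measured concentration: organ × time × animal, strictly positive."""

    dataset_id: str
    organ: str
    time_h: float
    animal_id: str
    value: float  # µg/g

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"observed value must be positive, got {self.value}")


@dataclass(frozen=True)
class BiodistributionDataset:
    """One dose group's observed records D, with N = len(records)."""

    design: StudyDesign
    records: tuple[ObservationRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("dataset must contain at least one record")
        bad = {r.organ for r in self.records} - set(self.design.organs_measured)
        if bad:
            raise ValueError(f"records reference organs outside the design: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset_id": [r.dataset_id for r in self.records],
                "substance": self.design.substance,
                "dose_ug_per_g": self.design.dose_per_bw,
                "organ": [r.organ for r in self.records],
                "time_h": [r.time_h for r in self.records],
                "animal_id": [r.animal_id for r in self.records],
                "value_ug_per_g": [r.value for r in self.records],
            }
        )


def builtin_designs() -> dict[str, StudyDesign]:
    """The five dose groups of the source studies, keyed by dataset id."""
    organs = frozenset(OBSERVABLE_ORGANS)
    designs = {}
    for key, dose in (("paca_low", 0.5), ("paca_high", 3.5)):
        designs[key] = StudyDesign(
            dataset_id=key,
            substance="PACA-Cbz",
            dose_per_bw=dose,
            blood_sampling_times=_PACA_BLOOD_TIMES_H,
            sacrifice_times=_SACRIFICE_TIMES_H,
            animals_per_timepoint=4,
            organs_measured=organs,
        )
    for key, dose in (
        ("lipimage_low", 0.046),
        ("lipimage_mid", 0.15),
        ("lipimage_high", 0.46),
    ):
        designs[key] = StudyDesign(
            dataset_id=key,
            substance="LipImage 815",
            dose_per_bw=dose,
            blood_sampling_times=_LIPIMAGE_BLOOD_TIMES_H,
            sacrifice_times=_SACRIFICE_TIMES_H,
            animals_per_timepoint=4,
            organs_measured=organs,
        )
    return designs


# Published posterior medians per dose group, shipped as realistic "true"
# parameter fixtures for synthetic-data generation and recovery experiments.
_PUBLISHED_MEDIANS: dict[str, tuple[float, ...]] = {
    "paca_low": (1.5, 3.9, 2.4e2, 1.3e-2, 8.4e-2, 1.4e-2),
    "paca_high": (2.1, 2.6, 2.1e2, 1.4e-2, 2.3e-1, 1.4e-2),
    "lipimage_low": (7.0, 1.3e-1, 2.7, 1.7e-1, 2.1e-1, 1.3e-2),
    "lipimage_mid": (5.4, 1.7e-1, 4.3, 1.6e-1, 3.0e-1, 8.6e-3),
    "lipimage_high": (4.5, 2.8e-1, 7.9, 2.6e-1, 4.7e-1, 1.3e-2),
}


def published_median_theta(dataset_id: str) -> ParameterVector:
    """Published median parameter estimate for a dose group (fixture)."""
    try:
        return ParameterVector.from_array(_PUBLISHED_MEDIANS[dataset_id])
    except KeyError:
        raise KeyError(
            f"unknown dataset id {dataset_id!r}; expected one of {sorted(_PUBLISHED_MEDIANS)}"
        ) from None


def generate_synthetic(
    theta_true: ParameterVector,
    design: StudyDesign,
    phys: RatPhysiology,
    fixed: FixedKinetics,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    seed: int | None = None,
) -> BiodistributionDataset:
    """Simulate the study design at ``theta_true`` and add log-normal noise.

    Every organ × sacrifice-time × animal cell and every blood-sampling-time
    × animal cell receives value = prediction × exp(ε) with
    ε ~ Normal(0, noise_sigma²), i.i.d.; the draw stream is fully determined
    by ``seed``.  Predictions below 1e-12 µg/g are excluded (logged).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)

    times = design.all_times()
    result = simulate(theta_true, phys, fixed, design.dose_per_bw, times)
    time_pos = {t: i for i, t in enumerate(times)}
    predictions = {
        organ: observe(result, organ, phys) for organ in sorted(design.organs_measured)
    }

    records: list[ObservationRecord] = []
    n_floored = 0

    def emit(organ: str, time_h: float, animal_id: str) -> None:
        nonlocal n_floored
        pred = float(predictions[organ][time_pos[time_h]])
        noisy = pred * float(np.exp(rng.normal(0.0, noise_sigma)))
        if pred < PREDICTION_FLOOR:
            n_floored += 1
            return
        records.append(
            ObservationRecord(
                dataset_id=design.dataset_id,
                organ=organ,
                time_h=time_h,
                animal_id=animal_id,
                value=noisy,
            )
        )

    for organ in sorted(design.organs_measured):
        for t in design.sacrifice_times:
            for a in range(1, design.animals_per_timepoint + 1):
                emit(organ, t, f"rat{a:02d}_t{t:g}")
    for t in design.blood_sampling_times:
        for a in range(1, design.animals_per_timepoint + 1):
            emit("blood", t, f"puncture_rat{a:02d}_t{t:g}")

    if n_floored:
        logger.info(
            "excluded %d synthetic records with predictions below %.0e µg/g",
            n_floored,
            PREDICTION_FLOOR,
        )
    return BiodistributionDataset(design=design, records=tuple(records))


def write_dataset(dataset: BiodistributionDataset, path: str | Path) -> None:
    """Write a dataset as tidy CSV (UTF-8, '.' decimal, repr-exact floats)."""
    frame = dataset.to_frame()
    frame.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | Path, design: StudyDesign | None = None) -> BiodistributionDataset:
    """Load a dataset CSV written by :func:`write_dataset`.

    Nonpositive values are dropped with a logged count.  Missing columns,
    unknown organs and unparseable numbers raise ``ValueError`` naming the
    offending column or line.  If ``design`` is omitted it is reconstructed
    from a matching built-in design (by dataset id) or, failing that, from
    the file contents.
    """
    path = Path(path)
    frame = pd.read_csv(
        path,
        dtype={"animal_id": str, "dataset_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    for col in ("time_h", "value_ug_per_g", "dose_ug_per_g"):
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[values.isna() & frame[col].notna()]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: unparseable number in column {col!r} on line {bad[0] + 2}"
            )
        frame[col] = values

    nonpositive = frame["value_ug_per_g"] <= 0
    n_dropped = int(nonpositive.sum())
    if n_dropped:
        logger.warning("%s: dropped %d nonpositive value(s) at load", path, n_dropped)
        frame = frame.loc[~nonpositive]
    if frame.empty:
        raise ValueError(f"{path}: no positive records")

    if design is None:
        dataset_id = str(frame["dataset_id"].iloc[0])
        design = builtin_designs().get(dataset_id) or _design_from_frame(frame)

    unknown = sorted(set(frame["organ"]) - set(design.organs_measured))
    if unknown:
        lines = frame.index[frame["organ"].isin(unknown)][0] + 2
        raise ValueError(
            f"{path}: unknown organ(s) {unknown} (first on line {lines})"
        )

    records = tuple(
        ObservationRecord(
            dataset_id=str(row.dataset_id),
            organ=str(row.organ),
            time_h=float(row.time_h),
            animal_id=str(row.animal_id),
            value=float(row.value_ug_per_g),
        )
        for row in frame.itertuples()
    )
    return BiodistributionDataset(design=design, records=records)


def _design_from_frame(frame: pd.DataFrame) -> StudyDesign:
    times = tuple(sorted(set(float(t) for t in frame["time_h"])))
    return StudyDesign(
        dataset_id=str(frame["dataset_id"].iloc[0]),
        substance=str(frame["substance"].iloc[0]),
        dose_per_bw=float(frame["dose_ug_per_g"].iloc[0]),
        blood_sampling_times=times,
        sacrifice_times=times,
        animals_per_timepoint=max(
            1, int(frame.groupby(["organ", "time_h"]).size().max())
        ),
        organs_measured=frozenset(frame["organ"]),
    )
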