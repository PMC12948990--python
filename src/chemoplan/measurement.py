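"""Observable quantities: caliper volumes, the observation process, necrosis.

Tumor volume is never measured directly; two caliper formulas convert a
(length, width) pair in mm to mm³:

* ``volume_lw2``   — V = length · width² / 2, the standard modified-ellipsoid
  caliper formula.  Used for protocol logic: the ~200 mm³ treatment trigger
  and the ~2000 mm³ humane endpoint.
* ``volume_geometric`` — V = (π/3)·(length·width)^{3/2}, a geometric-mean
  sphere formula.  Used as the model-facing volume in pilot-style fitting.

The two formulas generally disagree for elongated tumors, so every stored
volume carries a formula tag and both are always computed side by side.

The observation process samples a simulated trajectory's total volume on a
measurement calendar and perturbs the emitted caliper dimensions with
multiplicative log-normal noise — a synthetic stand-in for caliper error
(the real error process of the instrument is not modeled).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import Trajectory

__all__ = [
    "VolumeFormula",
    "CaliperMeasurement",
    "CaliperSeries",
    "ObservationModel",
    "volume_lw2",
    "volume_geometric",
    "dims_from_volume",
    "observe",
    "necrotic_ratio",
]


class VolumeFormula(str, enum.Enum):
    """Tag identifying which caliper-volume formula produced a number."""

    LW2 = "lw2"  # length * width^2 / 2 — protocol triggers and endpoints
    GEOMETRIC = "geometric"  # (pi/3) * (length*width)^(3/2) — model-facing


def volume_lw2(length: float, width: float) -> float:
    """Modified-ellipsoid caliper volume, ``length·width²/2`` (mm³)."""
    if length <= 0 or width <= 0:
        raise ValueError("caliper dimensions must be > 0")
    return length * width * width / 2.0


def volume_geometric(length: float, width: float) -> float:
    """Geometric-mean sphere volume, ``(π/3)·(length·width)^{3/2}`` (mm³)."""
    if length <= 0 or width <= 0:
        raise ValueError("caliper dimensions must be > 0")
    return (math.pi / 3.0) * (length * width) ** 1.5


def dims_from_volume(volume: float, aspect_ratio: float = 1.2) -> tuple[float, float]:
    """Invert ``volume_lw2``: emit (length, width) with the given length/width ratio.

    Exact inverse: ``volume_lw2(*dims_from_volume(V, r)) == V`` to round-off.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1 (length >= width)")
    # V = (r*w) * w^2 / 2  =>  w = (2V/r)^(1/3)
    width = (2.0 * volume / aspect_ratio) ** (1.0 / 3.0)
    return aspect_ratio * width, width


@dataclass(frozen=True)
class CaliperMeasurement:
    """One caliper reading: day and the two orthogonal dimensions in mm."""

    day: float
    length: float
    width: float

    def __post_init__(self):
        if self.day < 0:
            raise ValueError("day must be >= 0")
        if self.length <= 0 or self.width <= 0:
            raise ValueError("dimensions must be > 0")
        if self.length < self.width:
            warnings.warn("length < width; swapping", stacklevel=2)
            longer, shorter = self.width, self.length
            object.__setattr__(self, "length", longer)
            object.__setattr__(self, "width", shorter)

    def volume(self, formula: VolumeFormula = VolumeFormula.LW2) -> float:
        if formula is VolumeFormula.LW2:
            return volume_lw2(self.length, self.width)
        return volume_geometric(self.length, self.width)


@dataclass
class CaliperSeries:
    """Ordered caliper readings for one subject."""

    subject_id: str
    measurements: list[CaliperMeasurement] = field(default_factory=list)

    def __post_init__(self):
        days = [m.day for m in self.measurements]
        if any(d2 <= d1 for d1, d2 in zip(days, days[1:])):
            raise ValueError("measurement days must be strictly increasing")

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self):
        return iter(self.measurements)

    @property
    def days(self) -> np.ndarray:
        return np.array([m.day for m in self.measurements], dtype=float)

    def volumes(self, formula: VolumeFormula = VolumeFormula.LW2) -> np.ndarray:
        return np.array([m.volume(formula) for m in self.measurements])

    def window(self, start_day: float, end_day: float) -> "CaliperSeries":
        """Measurements with start_day <= day <= end_day (inclusive)."""
        keep = [m for m in self.measurements if start_day <= m.day <= end_day]
        return CaliperSeries(self.subject_id, keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "day": [m.day for m in self.measurements],
                "length_mm": [m.length for m in self.measurements],
                "width_mm": [m.width for m in self.measurements],
                "vol_lw2_mm3": [m.volume(VolumeFormula.LW2) for m in self.measurements],
                "vol_geom_mm3": [
                    m.volume(VolumeFormula.GEOMETRIC) for m in self.measurements
                ],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, subject_id: str | None = None):
        if subject_id is None:
            ids = df["subject_id"].unique()
            if len(ids) != 1:
                raise ValueError("frame holds multiple subjects; pass subject_id")
            subject_id = str(ids[0])
        else:
            df = df[df["subject_id"] == subject_id]
        ms = [
            CaliperMeasurement(float(r.day), float(r.length_mm), float(r.width_mm))
            for r in df.sort_values("day").itertuples()
        ]
        return cls(subject_id, ms)


@dataclass(frozen=True)
class ObservationModel:
    """Measurement calendar plus synthetic caliper noise.

    ``cadence`` is the number of days between measurements (2 = every second
    day, the main-study rhythm); ``weekday_pattern`` instead selects fixed
    weekdays (e.g. ``(0, 2, 4)`` for Mon/Wed/Fri, the thrice-weekly rhythm).
    Noise is multiplicative log-normal applied to each caliper dimension with
    the given coefficient of variation; the log-draws are mean-corrected so
    dimensions (not volumes) are unbiased.
    """

    cadence: int = 2
    noise_cv: float = 0.05
    aspect_ratio: float = 1.2
    weekday_pattern: tuple[int, ...] | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.cadence < 1:
            raise ValueError("cadence must be >= 1 day")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.weekday_pattern is not None and not all(
            0 <= d <= 6 for d in self.weekday_pattern
        ):
            raise ValueError("weekday_pattern entries must be in 0..6")

    def measurement_days(self, start: float, end: float) -> np.ndarray:
        start_i, end_i = int(math.ceil(start)), int(math.floor(end))
        if self.weekday_pattern is None:
            return np.arange(start_i, end_i + 1, self.cadence, dtype=float)
        days = np.arange(start_i, end_i + 1)
        return days[np.isin(days % 7, self.weekday_pattern)].astype(float)


def observe(
    trajectory: Trajectory,
    model: ObservationModel,
    subject_id: str = "subject",
    rng: np.random.Generator | None = None,
) -> CaliperSeries:
    """Emit a noisy caliper series from a simulated trajectory.

    With zero noise the emitted pairs reproduce the simulated total volume
    exactly through ``volume_lw2``.  Reproducible under the model's seed.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    days = model.measurement_days(trajectory.time[0], trajectory.time[-1])
    sigma = (
        math.sqrt(math.log(1.0 + model.noise_cv**2)) if model.noise_cv > 0 else 0.0
    )
    out = []
    for day in days:
        total = trajectory.state_at(float(day)).total_volume
        if total <= 0:
            continue  # below palpability; no caliper reading emitted
        length, width = dims_from_volume(total, model.aspect_ratio)
        if sigma > 0:
            length *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
            width *= math.exp(rng.normal(-0.5 * sigma**2, sigma))
        if length < width:
            length, width = width, length
        out.append(CaliperMeasurement(float(day), length, width))
    return CaliperSeries(subject_id, out)


def necrotic_ratio(necrotic_pixels: int, viable_pixels: int) -> float:
    """Necrotic tissue fraction ``N/(N+V)`` from classified pixel counts.

    0 means no necrosis (treatment ineffective); values near 1 mean the
    section is predominantly necrotic (high cytotoxic efficacy).
    """
    if necrotic_pixels < 0 or viable_pixels < 0:
        raise ValueError("pixel counts must be >= 0")
    if necrotic_pixels == 0 and viable_pixels == 0:
        raise ZeroDivisionError("necrotic ratio undefined: no classified pixels")
    return necrotic_pixels / (necrotic_pixels + viable_pixels)
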