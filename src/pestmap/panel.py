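"""Core data containers for monthly series and area-by-period count panels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MonthlySeries:
    """One category's monthly counts with an optional denominator series.

    ``t`` is the month index starting at 0 with unit steps; ``y`` is the
    count (or already-standardized value) per month.  When ``denominator``
    is present (total inquiries, or population) downstream fits standardize
    ``y`` to a percentage of it.
    """

    t: np.ndarray
    y: np.ndarray
    denominator: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-d arrays of equal length")
        if len(self.t) and not np.all(np.diff(self.t) == 1):
            raise ValueError("t must be consecutive integers (unit steps)")
        if self.denominator is not None:
            self.denominator = np.asarray(self.denominator, dtype=float)
            if self.denominator.shape != self.y.shape:
                raise ValueError("denominator must match y in length")
            if np.any(self.denominator <= 0):
                raise ValueError("denominator must be strictly positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class PanelCounts:
    """Area x period panel of observed counts with populations and offsets.

    Arrays are dense ``(n_areas, n_periods)`` matrices in lattice order;
    ``expected`` is filled by indirect standardization and serves as the
    Poisson offset of the spatiotemporal model.
    """

    area_ids: list[str]
    periods: list
    y: np.ndarray
    population: np.ndarray
    expected: np.ndarray | None = None

    def __post_init__(self) -> None:
        n, T = len(self.area_ids), len(self.periods)
        self.y = np.asarray(self.y, dtype=float)
        self.population = np.asarray(self.population, dtype=float)
        for name, arr in (("y", self.y), ("population", self.population)):
            if arr.shape != (n, T):
                raise ValueError(f"{name} must have shape ({n}, {T})")
        if np.any(self.y < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.population <= 0):
            raise ValueError(
                "populations must be strictly positive; pre-filter "
                "zero-population areas before building a panel"
            )
        if self.expected is not None:
            self.expected = np.asarray(self.expected, dtype=float)
            if self.expected.shape != (n, T):
                raise ValueError(f"expected must have shape ({n}, {T})")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    # ------------------------------------------------------------------ IO

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (area, period)."""
        n, T = self.y.shape
        frame = pd.DataFrame(
            {
                "area_id": np.repeat(self.area_ids, T),
                "period": np.tile(self.periods, n),
                "population": self.population.ravel(),
                "y": self.y.ravel(),
            }
        )
        if self.expected is not None:
            frame["E"] = self.expected.ravel()
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PanelCounts":
        """Build from a long-format frame (area_id, period, population, y[, E])."""
        required = {"area_id", "period", "population", "y"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel frame missing columns: {sorted(missing)}")
        if frame.duplicated(["area_id", "period"]).any():
            raise ValueError("one row per (area, period) required")
        areas = list(dict.fromkeys(frame["area_id"]))
        periods = sorted(frame["period"].unique().tolist())
        wide = frame.pivot(index="area_id", columns="period")
        wide = wide.reindex(index=areas, columns=pd.MultiIndex.from_product(
            [wide.columns.levels[0], periods]))
        y = wide["y"].to_numpy()
        pop = wide["population"].to_numpy()
        if np.isnan(y).any() or np.isnan(pop).any():
            raise ValueError("panel is not rectangular: missing (area, period) cells")
        expected = None
        if "E" in frame.columns:
            expected = wide["E"].to_numpy()
        return cls(areas, periods, y, pop, expected)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PanelCounts":
        return cls.from_frame(pd.read_csv(path))
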