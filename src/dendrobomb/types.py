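"""Core domain containers shared by every stage of the workflow.

The dating convention throughout is the Schulman (Southern Hemisphere)
convention: each ring is labelled with the calendar year in which its radial
growth *began* (austral spring).  A ring labelled ``t`` therefore grew from
roughly October of year ``t`` to April of year ``t + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RingWidthSeries",
    "Chronology",
    "RadiocarbonSample",
    "AtmosphericCurve",
    "ClimateSeries",
]


@dataclass(frozen=True)
class RingWidthSeries:
    """One radius's annual ring widths anchored to Schulman years.

    Parameters
    ----------
    series_id:
        Tree + radius code, e.g. ``"VTP01A"``.  ASCII, at most 8 characters
        for Tucson round-trips.
    first_year:
        Calendar year (Schulman convention) of the innermost measured ring.
    widths:
        Ring widths in mm for consecutive years starting at ``first_year``.
        A width of exactly 0 encodes a locally absent ring.
    inferred_years:
        Years whose rings were not measured but inserted during a
        missing-ring date correction (width 0, "inferred" annotation).
    """

    series_id: str
    first_year: int
    widths: tuple[float, ...]
    inferred_years: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.widths) < 2:
            raise ValueError(
                f"series {self.series_id!r}: need at least 2 rings, "
                f"got {len(self.widths)}"
            )
        if any(w < 0 for w in self.widths):
            raise ValueError(f"series {self.series_id!r}: negative ring width")
        object.__setattr__(self, "widths", tuple(float(w) for w in self.widths))

    @property
    def last_year(self) -> int:
        return self.first_year + len(self.widths) - 1

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.widths, dtype=float)

    def __len__(self) -> int:
        return len(self.widths)

    def window(self, y0: int, y1: int) -> "RingWidthSeries":
        """Sub-series covering years ``y0..y1`` (inclusive, must be inside)."""
        if y0 < self.first_year or y1 > self.last_year or y1 < y0 + 1:
            raise ValueError("window outside series span")
        i0, i1 = y0 - self.first_year, y1 - self.first_year
        return replace(self, first_year=y0, widths=self.widths[i0 : i1 + 1])


@dataclass(frozen=True)
class Chronology:
    """Detrended site chronology with per-year sample depth and signal stats.

    ``index`` is the unitless ring-width index (biweight mean of the
    detrended series); ``rbar`` the mean inter-series correlation; ``eps``
    the Expressed Population Signal at the mean sample depth; ``sss`` the
    per-year Subsample Signal Strength.
    """

    years: np.ndarray
    index: np.ndarray
    raw_mean: np.ndarray
    sample_depth: np.ndarray
    rbar: float
    eps: float
    sss: np.ndarray

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        if not np.all(np.diff(years) == 1):
            raise ValueError("chronology years must be consecutive")
        n = len(years)
        for name in ("index", "raw_mean", "sample_depth", "sss"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match years")
        if np.any(np.asarray(self.sample_depth) < 1):
            raise ValueError("index defined only where sample_depth >= 1")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "index", np.asarray(self.index, dtype=float))
        object.__setattr__(self, "raw_mean", np.asarray(self.raw_mean, dtype=float))
        object.__setattr__(
            self, "sample_depth", np.asarray(self.sample_depth, dtype=int)
        )
        object.__setattr__(self, "sss", np.asarray(self.sss, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years,
                "index": self.index,
                "raw_mean": self.raw_mean,
                "depth": self.sample_depth,
                "sss": self.sss,
            }
        )

    def indexed(self, years: np.ndarray) -> np.ndarray:
        """Index values at the requested years (NaN outside the span)."""
        out = np.full(len(years), np.nan)
        pos = np.asarray(years) - self.years[0]
        ok = (pos >= 0) & (pos < len(self.index))
        out[ok] = self.index[pos[ok].astype(int)]
        return out


@dataclass(frozen=True)
class RadiocarbonSample:
    """One ring's F14C measurement with its dendro-assigned Schulman year.

    ``year_start`` is the Schulman year t assigned by crossdating (growth
    onset); ``year_stop = t + 1`` is the year growth ceased.  ``f14c`` is
    fraction modern carbon, ``sigma`` its 1-sigma measurement uncertainty.
    Optional wood/cellulose masses (mg) support extraction-yield bookkeeping.
    """

    tree_id: str
    year_start: int
    year_stop: int
    f14c: float
    sigma: float
    wood_mg: float | None = None
    cellulose_mg: float | None = None

    def __post_init__(self) -> None:
        if self.year_stop != self.year_start + 1:
            raise ValueError(
                f"{self.tree_id} {self.year_start}: year_stop must equal "
                f"year_start + 1 (got {self.year_stop})"
            )
        if not self.f14c > 0:
            raise ValueError("f14c must be positive")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class AtmosphericCurve:
    """Atmospheric F14C record on a decimal-year axis.

    Supports linear interpolation and growing-season averaging.  Queries
    outside the tabulated span raise rather than extrapolate.
    """

    decimal_years: np.ndarray
    f14c: np.ndarray
    sigma: np.ndarray | None = None
    zone_label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.decimal_years, dtype=float)
        y = np.asarray(self.f14c, dtype=float)
        if len(x) != len(y) or len(x) < 2:
            raise ValueError("curve needs >= 2 (decimal_year, f14c) points")
        if np.any(np.diff(x) <= 0):
            raise ValueError("decimal_years must be strictly increasing")
        if np.any(y <= 0):
            raise ValueError("curve f14c values must be positive")
        object.__setattr__(self, "decimal_years", x)
        object.__setattr__(self, "f14c", y)
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            if len(s) != len(x):
                raise ValueError("sigma length mismatch")
            object.__setattr__(self, "sigma", s)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.decimal_years[0]), float(self.decimal_years[-1])

    def _check_cover(self, t: np.ndarray) -> None:
        lo, hi = self.span
        t = np.atleast_1d(t)
        if t.min() < lo or t.max() > hi:
            raise ValueError(
                f"curve {self.zone_label or '<unnamed>'} spans "
                f"[{lo:.3f}, {hi:.3f}] but was queried at "
                f"[{t.min():.3f}, {t.max():.3f}]"
            )

    def at(self, decimal_year: float | np.ndarray) -> np.ndarray | float:
        """Piecewise-linear interpolation of F14C at the given epoch(s)."""
        t = np.asarray(decimal_year, dtype=float)
        self._check_cover(t)
        out = np.interp(t, self.decimal_years, self.f14c)
        return float(out) if np.isscalar(decimal_year) else out

    def sigma_at(self, decimal_year: float | np.ndarray) -> np.ndarray | float:
        """Interpolated curve 1-sigma (0 where the curve carries none)."""
        t = np.asarray(decimal_year, dtype=float)
        self._check_cover(t)
        if self.sigma is None:
            out = np.zeros_like(t)
        else:
            out = np.interp(t, self.decimal_years, self.sigma)
        return float(out) if np.isscalar(decimal_year) else out


class ClimateSeries:
    """Monthly climate table: one row per (year, month).

    Columns: ``year``, ``month``, ``precip_mm`` (monthly accumulated
    precipitation) and ``tmax_c`` (monthly mean maximum temperature).
    Gap months inside the span are permitted but recorded in ``gaps``.
    """

    COLUMNS = ("year", "month", "precip_mm", "tmax_c")

    def __init__(self, data: pd.DataFrame):
        df = data.loc[:, list(self.COLUMNS)].copy()
        df["year"] = df["year"].astype(int)
        df["month"] = df["month"].astype(int)
        if not df["month"].between(1, 12).all():
            raise ValueError("months must be in 1..12")
        if (df["precip_mm"] < 0).any():
            raise ValueError("precip_mm must be non-negative")
        dup = df.duplicated(subset=["year", "month"])
        if dup.any():
            y, m = df.loc[dup.idxmax(), ["year", "month"]]
            raise ValueError(f"duplicate (year, month) record: ({y}, {m})")
        df = df.sort_values(["year", "month"]).reset_index(drop=True)
        self.data = df
        self._lookup = df.set_index(["year", "month"])

    @property
    def gaps(self) -> list[tuple[int, int]]:
        """(year, month) pairs missing between the first and last record."""
        df = self.data
        first = df["year"].iloc[0] * 12 + df["month"].iloc[0] - 1
        last = df["year"].iloc[-1] * 12 + df["month"].iloc[-1] - 1
        have = set(df["year"] * 12 + df["month"] - 1)
        return [(k // 12, k % 12 + 1) for k in range(first, last + 1) if k not in have]

    def value(self, year: int, month: int, variable: str) -> float:
        try:
            return float(self._lookup.loc[(year, month), variable])
        except KeyError:
            raise KeyError(f"no climate record for ({year}, {month})") from None

    def monthly(self, variable: str) -> pd.Series:
        """Series of one variable indexed by (year, month)."""
        return self._lookup[variable]

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClimateSeries):
            return NotImplemented
        return self.data.equals(other.data)
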