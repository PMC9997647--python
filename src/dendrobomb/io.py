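"""Readers and writers for the dendro and tabular formats used throughout.

Tucson (RWL) decadal ring-width files are read and written natively: the
classic 0.01 mm dialect with a ``999`` stop marker is emitted, and the
0.001 mm / ``-9999`` dialect is auto-detected on read so that files from
either tradition load without silent 10x unit errors.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import AtmosphericCurve, ClimateSeries, RadiocarbonSample, RingWidthSeries

logger = logging.getLogger(__name__)

__all__ = [
    "read_rwl",
    "write_rwl",
    "read_f14c_csv",
    "write_f14c_csv",
    "read_curve_csv",
    "write_curve_csv",
    "read_climate_csv",
    "write_climate_csv",
]

_STOP_001 = "999"  # 0.01 mm dialect stop marker
_STOP_0001 = "-9999"  # 0.001 mm dialect stop marker


class RwlParseError(ValueError):
    pass


def read_rwl(path: str | Path) -> list[RingWidthSeries]:
    """Read a Tucson decadal ring-width file.

    Widths are converted to mm from the detected unit dialect (0.01 mm when
    the series ends in ``999``, 0.001 mm when it ends in ``-9999``).  Zero
    widths (locally absent rings) are preserved.
    """
    path = Path(path)
    open_values: dict[str, list[int]] = {}
    open_next_year: dict[str, int] = {}
    first_year: dict[str, int] = {}
    done: dict[str, list[float]] = {}

    def _finish(sid: str, divisor: float) -> None:
        if sid in done:
            raise RwlParseError(f"{path}: duplicate series id {sid!r}")
        done[sid] = [v / divisor for v in open_values.pop(sid)]
        open_next_year.pop(sid)

    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        tokens = raw.split()
        if len(tokens) < 2:
            raise RwlParseError(f"{path}:{lineno}: malformed line {raw!r}")
        sid = tokens[0]
        try:
            year = int(tokens[1])
        except ValueError:
            raise RwlParseError(
                f"{path}:{lineno}: malformed decade year {tokens[1]!r}"
            ) from None
        if sid in done:
            raise RwlParseError(f"{path}:{lineno}: duplicate series id {sid!r}")
        if sid in open_values:
            if year != open_next_year[sid]:
                raise RwlParseError(
                    f"{path}:{lineno}: decade year {year} does not continue "
                    f"series {sid!r} (expected {open_next_year[sid]})"
                )
        else:
            open_values[sid] = []
            first_year[sid] = year
            open_next_year[sid] = year
        for tok in tokens[2:]:
            if tok == _STOP_0001:
                _finish(sid, 1000.0)
                break
            if tok == _STOP_001:
                _finish(sid, 100.0)
                break
            try:
                val = int(tok)
            except ValueError:
                raise RwlParseError(
                    f"{path}:{lineno}: malformed width field {tok!r}"
                ) from None
            open_values[sid].append(val)
            open_next_year[sid] += 1

    for sid in list(open_values):
        logger.warning(
            "%s: series %s has no stop marker; assuming 0.01 mm dialect", path, sid
        )
        _finish(sid, 100.0)

    if not done:
        logger.warning("%s: empty ring-width file", path)
    return [
        RingWidthSeries(series_id=sid, first_year=first_year[sid], widths=tuple(vals))
        for sid, vals in done.items()
    ]


def write_rwl(series: list[RingWidthSeries], path: str | Path) -> None:
    """Write series in the classic Tucson 0.01 mm dialect with ``999`` stops."""
    if not series:
        raise ValueError("refusing to write an empty series collection")
    lines: list[str] = []
    for s in series:
        if len(s.series_id) > 8:
            raise ValueError(f"series id {s.series_id!r} exceeds 8 characters")
        fields = []
        for w in s.widths:
            v = int(round(w * 100))
            if v >= 999:  # 999 is the reserved stop marker
                raise ValueError(
                    f"series {s.series_id!r}: width {w} mm overflows the "
                    "0.01 mm Tucson field"
                )
            fields.append(v)
        fields.append(999)
        year = s.first_year
        i = 0
        while i < len(fields):
            # each line runs to the end of the current decade
            room = 10 - (year % 10)
            chunk = fields[i : i + room]
            lines.append(
                f"{s.series_id:<8}{year:>4}" + "".join(f"{v:>6d}" for v in chunk)
            )
            year += len(chunk)
            i += len(chunk)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_f14c_csv(path: str | Path) -> list[RadiocarbonSample]:
    """Load per-ring radiocarbon measurements.

    Required columns: ``tree_id, year_start, year_stop, f14c, sigma``;
    optional ``wood_mg, cellulose_mg``.  The Schulman-year invariant
    ``year_stop == year_start + 1`` is enforced on load.
    """
    df = pd.read_csv(path, comment="#")
    required = ["tree_id", "year_start", "year_stop", "f14c", "sigma"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    samples = []
    for i, row in df.iterrows():
        try:
            samples.append(
                RadiocarbonSample(
                    tree_id=str(row["tree_id"]),
                    year_start=int(row["year_start"]),
                    year_stop=int(row["year_stop"]),
                    f14c=float(row["f14c"]),
                    sigma=float(row["sigma"]),
                    wood_mg=_to_float_or_none(row.get("wood_mg")),
                    cellulose_mg=_to_float_or_none(row.get("cellulose_mg")),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {i}: {exc}") from None
    return samples


def write_f14c_csv(samples: list[RadiocarbonSample], path: str | Path) -> None:
    rows = [
        {
            "tree_id": s.tree_id,
            "year_start": s.year_start,
            "year_stop": s.year_stop,
            "f14c": s.f14c,
            "sigma": s.sigma,
            "wood_mg": s.wood_mg,
            "cellulose_mg": s.cellulose_mg,
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_curve_csv(path: str | Path, zone_label: str | None = None) -> AtmosphericCurve:
    """Load an atmospheric F14C curve (columns ``decimal_year, f14c[, sigma]``).

    Rows are sorted and exact duplicates dropped; duplicate epochs with
    conflicting values are an error.  The zone label is taken from a
    ``# zone: ...`` header comment, the ``zone_label`` argument, or the
    file stem, in that order of preference.
    """
    path = Path(path)
    header_zone = None
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line[1:].strip().lower().startswith("zone:"):
                header_zone = line.split(":", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    if "decimal_year" not in df.columns or "f14c" not in df.columns:
        raise ValueError(f"{path}: need columns decimal_year, f14c")
    df = df.sort_values("decimal_year").drop_duplicates()
    dup = df["decimal_year"].duplicated()
    if dup.any():
        raise ValueError(
            f"{path}: conflicting values at decimal_year "
            f"{df.loc[dup, 'decimal_year'].iloc[0]}"
        )
    sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
    return AtmosphericCurve(
        decimal_years=df["decimal_year"].to_numpy(),
        f14c=df["f14c"].to_numpy(),
        sigma=sigma,
        zone_label=header_zone or zone_label or path.stem,
    )


def write_curve_csv(curve: AtmosphericCurve, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if curve.zone_label:
            fh.write(f"# zone: {curve.zone_label}\n")
        cols = {"decimal_year": curve.decimal_years, "f14c": curve.f14c}
        if curve.sigma is not None:
            cols["sigma"] = curve.sigma
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.12g")


def read_climate_csv(path: str | Path) -> ClimateSeries:
    """Load monthly climate (columns ``year, month, precip_mm, tmax_c``).

    Gap months are allowed but logged; duplicate (year, month) rows raise.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ClimateSeries.COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    clim = ClimateSeries(df)
    if clim.gaps:
        logger.warning("%s: %d gap months, e.g. %s", path, len(clim.gaps), clim.gaps[0])
    return clim


def write_climate_csv(climate: ClimateSeries, path: str | Path) -> None:
    climate.data.to_csv(path, index=False, float_format="%.10g")


def _to_float_or_none(x) -> float | None:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)
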