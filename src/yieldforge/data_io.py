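"""Station-year yield panels: reading, writing, imputation and min-max scaling.

A *panel* is the basic corpus both modelling phases consume: a matrix of
annual crop yields (kg ha^-1) with one row per station and one column per
calendar year.  Missing observations are carried as NaN so that imputation
is an explicit, inspectable step rather than a side effect of parsing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StationMeta",
    "YieldPanel",
    "NormalizationBounds",
    "read_panel",
    "write_panel",
    "impute_station_mean",
    "normalize",
    "denormalize",
]


class PanelError(ValueError):
    """Raised for structurally invalid panels or panel files."""


@dataclass(frozen=True)
class StationMeta:
    """Identity and (optional) geography of one reporting station."""

    station_id: str
    name: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    elevation_m: float | None = None

    def __post_init__(self) -> None:
        if not self.station_id:
            raise PanelError("station_id must be a non-empty string")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise PanelError(f"latitude {self.latitude} outside [-90, 90]")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise PanelError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class YieldPanel:
    """Stations x years matrix of annual yields (kg ha^-1), NaN = missing.

    Years must be strictly increasing and contiguous so lagged pairs are
    well defined; all non-missing yields must be positive.
    """

    stations: list[StationMeta]
    years: np.ndarray  # shape (n_years,), int
    values: np.ndarray  # shape (n_stations, n_years), float, NaN = missing
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        ids = [s.station_id for s in self.stations]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate station ids: {dupes}")
        if self.years.ndim != 1 or len(self.years) == 0:
            raise PanelError("years must be a non-empty 1-D array")
        diffs = np.diff(self.years)
        if np.any(diffs != 1):
            raise PanelError(
                "years must be strictly increasing and contiguous; got "
                f"{self.years.tolist()}"
            )
        if self.values.shape != (len(self.stations), len(self.years)):
            raise PanelError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.stations)} stations x {len(self.years)} years"
            )
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite <= 0):
            raise PanelError("all non-missing yields must be > 0 kg ha^-1")

    # -- convenience accessors -------------------------------------------------

    @property
    def station_ids(self) -> list[str]:
        return [s.station_id for s in self.stations]

    @property
    def n_stations(self) -> int:
        return len(self.stations)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def index_of(self, station_id: str) -> int:
        try:
            return self.station_ids.index(station_id)
        except ValueError:
            raise KeyError(f"station {station_id!r} not in panel") from None

    def series(self, station_id: str) -> np.ndarray:
        """Return one station's yield series (copy), NaN for missing years."""
        return self.values[self.index_of(station_id)].copy()

    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "YieldPanel":
        return YieldPanel(
            stations=list(self.stations),
            years=self.years.copy(),
            values=self.values.copy(),
            attrs=dict(self.attrs),
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy (station_id, year, yield_kg_ha) frame; missing rows kept as NaN."""
        recs = []
        for i, sid in enumerate(self.station_ids):
            for j, year in enumerate(self.years):
                recs.append((sid, int(year), self.values[i, j]))
        return pd.DataFrame(recs, columns=["station_id", "year", "yield_kg_ha"])


@dataclass(frozen=True)
class NormalizationBounds:
    """Min-max bounds used to map yields onto the unit interval and back."""

    w_min: float
    w_max: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.w_min) or not np.isfinite(self.w_max):
            raise PanelError("normalization bounds must be finite")
        if self.w_max <= self.w_min:
            raise PanelError(
                f"degenerate normalization range: w_min={self.w_min}, w_max={self.w_max}"
            )

    @property
    def span(self) -> float:
        return self.w_max - self.w_min


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["station_id", "year", "yield_kg_ha"]


def read_panel(
    path: str | Path,
    dialect: str = "long",
    meta_path: str | Path | None = None,
) -> YieldPanel:
    """Read a yield panel from CSV.

    Parameters
    ----------
    path
        CSV file.  ``dialect="long"`` expects columns
        ``station_id,year,yield_kg_ha``; ``dialect="wide"`` expects a ``year``
        first column and one column per station.
    meta_path
        Optional sidecar CSV ``station_id,name,latitude,longitude,elevation_m``.

    Unparseable or empty yield cells become missing (NaN).  Duplicate
    (station, year) pairs and non-contiguous years are hard errors.
    """
    path = Path(path)
    if dialect == "long":
        df = pd.read_csv(path, dtype={"station_id": str})
        missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing_cols:
            raise PanelError(f"long CSV missing columns {missing_cols}")
        dup = df.duplicated(subset=["station_id", "year"], keep=False)
        if dup.any():
            first = df.loc[dup, ["station_id", "year"]].iloc[0]
            raise PanelError(
                f"duplicate (station, year) pair: ({first['station_id']}, {first['year']})"
            )
        df["yield_kg_ha"] = pd.to_numeric(df["yield_kg_ha"], errors="coerce")
        wide = df.pivot(index="station_id", columns="year", values="yield_kg_ha")
        # preserve first-appearance station order, not pivot's lexicographic one
        order = list(dict.fromkeys(df["station_id"]))
        wide = wide.reindex(order)
    elif dialect == "wide":
        df = pd.read_csv(path)
        if df.columns[0] != "year":
            raise PanelError("wide CSV must have 'year' as its first column")
        if df["year"].duplicated().any():
            year = int(df.loc[df["year"].duplicated(), "year"].iloc[0])
            raise PanelError(f"duplicate year {year} in wide CSV")
        wide = df.set_index("year").apply(pd.to_numeric, errors="coerce").T
        wide.index = wide.index.astype(str)
    else:
        raise PanelError(f"unknown dialect {dialect!r} (expected 'long' or 'wide')")

    years = np.asarray(sorted(int(y) for y in wide.columns))
    wide = wide[[int(y) for y in years]] if list(wide.columns) != list(years) else wide

    meta_by_id: dict[str, StationMeta] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype={"station_id": str})
        for _, row in mdf.iterrows():
            meta_by_id[row["station_id"]] = StationMeta(
                station_id=row["station_id"],
                name=row.get("name"),
                latitude=row.get("latitude"),
                longitude=row.get("longitude"),
                elevation_m=row.get("elevation_m"),
            )

    stations = [
        meta_by_id.get(sid, StationMeta(station_id=str(sid)))
        for sid in wide.index
    ]
    return YieldPanel(stations=stations, years=years, values=wide.to_numpy(dtype=float))


def write_panel(panel: YieldPanel, path: str | Path, dialect: str = "long") -> None:
    """Write a panel back to CSV (inverse of :func:`read_panel`)."""
    path = Path(path)
    if dialect == "long":
        panel.to_long_frame().to_csv(path, index=False)
    elif dialect == "wide":
        df = pd.DataFrame(
            panel.values.T, index=panel.years, columns=panel.station_ids
        )
        df.index.name = "year"
        df.to_csv(path)
    else:
        raise PanelError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Imputation and scaling
# ---------------------------------------------------------------------------


def impute_station_mean(panel: YieldPanel) -> YieldPanel:
    """Replace each missing entry with its own station's mean over observed years.

    Mirrors the recovery used for gap years in national yield archives: the
    average of all the station's other observations stands in for the gap.
    Idempotent; non-missing entries are untouched.
    """
    out = panel.copy()
    for i, sid in enumerate(panel.station_ids):
        row = out.values[i]
        mask = np.isnan(row)
        if not mask.any():
            continue
        observed = row[~mask]
        if observed.size < 2:
            raise PanelError(
                f"station {sid!r} has {observed.size} observed value(s); "
                "need >= 2 to impute"
            )
        row[mask] = observed.mean()
    out.attrs["imputed"] = True
    return out


def normalize(
    series: Sequence[float] | np.ndarray,
    bounds: NormalizationBounds | None = None,
) -> tuple[np.ndarray, NormalizationBounds]:
    """Min-max scale a yield series to [0, 1]: (W - W_min) / (W_max - W_min).

    When ``bounds`` is None they are computed from the series itself.  Values
    outside the bounds (possible when training-pool bounds are applied to
    test data) map linearly outside [0, 1]; nothing is clipped, so the map
    stays exactly invertible.
    """
    arr = np.asarray(series, dtype=float)
    if bounds is None:
        finite = arr[np.isfinite(arr)]
        if finite.size < 2 or np.nanmin(finite) == np.nanmax(finite):
            raise PanelError(
                "cannot derive normalization bounds from a series with fewer "
                "than 2 distinct values"
            )
        bounds = NormalizationBounds(float(finite.min()), float(finite.max()))
    return (arr - bounds.w_min) / bounds.span, bounds


def denormalize(
    series: Sequence[float] | np.ndarray, bounds: NormalizationBounds
) -> np.ndarray:
    """Invert :func:`normalize`: W_min + value * (W_max - W_min)."""
    arr = np.asarray(series, dtype=float)
    return bounds.w_min + arr * bounds.span
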