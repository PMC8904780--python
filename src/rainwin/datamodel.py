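"""Core data types, CSV schemas, and the aggregation/filtering rules that
turn raw pitfall-trap records into analysis-ready tables.

Conventions
-----------
* All dates are ISO-8601 calendar days.
* Daily rainfall is recorded in mm at 0.5 mm resolution and must be a
  contiguous (gap-free) series.
* ``trophic_group`` takes values in :data:`TROPHIC_GROUPS`; ants are kept
  as their own group because they act as predators, scavengers and
  indirect herbivores at once.
* The "seasonal rainfall" of a year is the cumulative rainfall over the
  main growing season, fixed here to Feb 1 - Mar 31 inclusive.
* Activity densities are summed per plot and year (over trapping rounds)
  to remove intra-seasonal variability; vegetation covariates take the
  per-parameter maximum over the year's surveys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TROPHIC_GROUPS = ("herbivore", "omnivore", "predator", "detritivore", "ant")
SOIL_FRACTIONS = ("sand", "gravel", "cobble", "boulder", "large_boulder")

#: season over which "seasonal rainfall" is accumulated (month, day)
SEASON_START = (2, 1)
SEASON_END = (3, 31)


class SchemaError(ValueError):
    """A CSV or table violates its declared schema."""


class DataGapError(ValueError):
    """A rainfall series does not cover a required date range."""


class ConfigError(ValueError):
    """An invalid configuration value."""


# ---------------------------------------------------------------------------
# Rainfall
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RainfallSeries:
    """Contiguous daily precipitation record.

    Parameters
    ----------
    dates
        Strictly increasing, gap-free daily ``DatetimeIndex``.
    mm
        Daily amounts in mm, nonnegative.
    """

    dates: pd.DatetimeIndex
    mm: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        mm = np.asarray(self.mm, dtype=float)
        if len(dates) != len(mm):
            raise SchemaError("dates and amounts differ in length")
        if len(dates) == 0:
            raise SchemaError("empty rainfall series")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not np.all(deltas == 1):
            bad = int(np.flatnonzero(deltas != 1)[0])
            raise DataGapError(
                f"rainfall series has a gap after {dates[bad].date()} "
                f"(next record {dates[bad + 1].date()})"
            )
        if np.any(mm < 0) or not np.all(np.isfinite(mm)):
            raise SchemaError("rainfall amounts must be finite and >= 0")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "mm", mm)

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def start(self) -> pd.Timestamp:
        return self.dates[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.dates[-1]

    def covers(self, start, end) -> bool:
        """True if every day in [start, end] is in the series."""
        return pd.Timestamp(start) >= self.start and pd.Timestamp(end) <= self.end

    def range_sum(self, start, end) -> float:
        """Sum of daily amounts over [start, end] inclusive."""
        start, end = pd.Timestamp(start), pd.Timestamp(end)
        if start > end:
            raise ValueError(f"start {start.date()} after end {end.date()}")
        if not self.covers(start, end):
            raise DataGapError(
                f"series covers {self.start.date()}..{self.end.date()}, "
                f"required {start.date()}..{end.date()}"
            )
        i = (start - self.start).days
        j = (end - self.start).days
        return float(self.mm[i : j + 1].sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"), "mm": self.mm})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RainfallSeries":
        _require_columns(df, ["date", "mm"], "rainfall")
        try:
            dates = pd.DatetimeIndex(pd.to_datetime(df["date"], format="ISO8601"))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"rainfall: unparseable date column: {exc}") from None
        mm = pd.to_numeric(df["mm"], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(mm))
        if len(bad):
            raise SchemaError(f"rainfall: non-numeric mm at row {bad[0] + 2}")
        return cls(dates, mm)

    @classmethod
    def from_csv(cls, path) -> "RainfallSeries":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def seasonal_rainfall(series: RainfallSeries, year: int) -> float:
    """Cumulative rainfall (mm) for the main growing season of ``year``.

    The season is Feb 1 through Mar 31 inclusive (leap days counted).
    Raises :class:`DataGapError` naming the gap if the series does not
    cover the season.
    """
    start = pd.Timestamp(year=year, month=SEASON_START[0], day=SEASON_START[1])
    end = pd.Timestamp(year=year, month=SEASON_END[0], day=SEASON_END[1])
    return series.range_sum(start, end)


# ---------------------------------------------------------------------------
# Schema-checked readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def _numeric(df: pd.DataFrame, col: str, what: str, integer: bool = False) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna().to_numpy())[0])
        raise SchemaError(f"{what}: non-numeric value in '{col}' at row {row + 2}")
    if integer:
        frac = np.mod(vals.to_numpy(dtype=float), 1.0)
        nonint = np.flatnonzero(frac != 0)
        if len(nonint):
            raise SchemaError(
                f"{what}: non-integer value in '{col}' at row {int(nonint[0]) + 2}"
            )
        return vals.astype(int)
    return vals.astype(float)


def read_soil(path) -> pd.DataFrame:
    """Read per-plot soil surface texture fractions (percent)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["plot", *SOIL_FRACTIONS], "soil")
    out = pd.DataFrame({"plot": df["plot"].astype(str)})
    for c in SOIL_FRACTIONS:
        out[c] = _numeric(df, c, "soil")
        if ((out[c] < 0) | (out[c] > 100)).any():
            row = int(np.flatnonzero(((out[c] < 0) | (out[c] > 100)).to_numpy())[0])
            raise SchemaError(f"soil: '{c}' outside [0, 100] at row {row + 2}")
    return out


def read_veg(path) -> pd.DataFrame:
    """Read per-round vegetation surveys."""
    df = pd.read_csv(path, dtype=str)
    cols = ["plot", "year", "round", "total_cover", "herb_cover", "grass_cover", "n_species"]
    _require_columns(df, cols, "veg")
    out = pd.DataFrame({"plot": df["plot"].astype(str)})
    out["year"] = _numeric(df, "year", "veg", integer=True)
    out["round"] = _numeric(df, "round", "veg", integer=True)
    for c in ("total_cover", "herb_cover", "grass_cover"):
        out[c] = _numeric(df, c, "veg")
    out["n_species"] = _numeric(df, "n_species", "veg", integer=True)
    return out


def read_traps(path) -> pd.DataFrame:
    """Read long-format pitfall-trap counts (one row per plot/round/taxon)."""
    df = pd.read_csv(path, dtype=str)
    cols = ["plot", "year", "round", "start_date", "taxon", "count"]
    _require_columns(df, cols, "traps")
    out = pd.DataFrame({"plot": df["plot"].astype(str)})
    out["year"] = _numeric(df, "year", "traps", integer=True)
    out["round"] = _numeric(df, "round", "traps", integer=True)
    try:
        out["start_date"] = pd.to_datetime(df["start_date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"traps: unparseable start_date: {exc}") from None
    out["taxon"] = df["taxon"].astype(str)
    out["count"] = _numeric(df, "count", "traps", integer=True)
    if (out["count"] < 0).any():
        row = int(np.flatnonzero((out["count"] < 0).to_numpy())[0])
        raise SchemaError(f"traps: negative count at row {row + 2}")
    if (~out["round"].isin([1, 2])).any():
        row = int(np.flatnonzero((~out["round"].isin([1, 2])).to_numpy())[0])
        raise SchemaError(f"traps: round not in {{1, 2}} at row {row + 2}")
    return out


def read_taxa(path) -> pd.DataFrame:
    """Read the taxon metadata table (trophic group, ground-dwelling flag)."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, ["taxon", "trophic_group", "ground_dwelling"], "taxa")
    out = pd.DataFrame({"taxon": df["taxon"].astype(str)})
    groups = df["trophic_group"].astype(str)
    bad = ~groups.isin(TROPHIC_GROUPS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"taxa: unknown trophic_group '{groups.iloc[row]}' at row {row + 2}; "
            f"expected one of {TROPHIC_GROUPS}"
        )
    out["trophic_group"] = groups
    flags = df["ground_dwelling"].astype(str).str.strip().str.lower()
    ok = flags.isin(["true", "false", "1", "0"])
    if (~ok).any():
        row = int(np.flatnonzero((~ok).to_numpy())[0])
        raise SchemaError(f"taxa: ground_dwelling not boolean at row {row + 2}")
    out["ground_dwelling"] = flags.isin(["true", "1"])
    if out["taxon"].duplicated().any():
        dup = out.loc[out["taxon"].duplicated(), "taxon"].iloc[0]
        raise SchemaError(f"taxa: duplicate taxon entry '{dup}'")
    return out


# ---------------------------------------------------------------------------
# Filtering and aggregation
# ---------------------------------------------------------------------------


def filter_taxa(events: pd.DataFrame, info: pd.DataFrame, min_total: int = 50) -> list[str]:
    """Select the taxa retained for analysis.

    A taxon is retained iff it is predominantly ground-dwelling and its
    study-wide total activity density is at least ``min_total`` individuals
    (strictly fewer than ``min_total`` drops it; exactly ``min_total``
    keeps it).

    Parameters
    ----------
    events
        Long-format trap table with at least ``taxon`` and ``count``.
    info
        Taxon metadata as returned by :func:`read_taxa`.

    Returns
    -------
    Sorted list of retained taxon names.
    """
    if len(events) == 0:
        return []
    known = set(info["taxon"])
    unknown = sorted(set(events["taxon"]) - known)
    if unknown:
        raise SchemaError(f"taxa table has no entry for: {unknown}")
    totals = events.groupby("taxon")["count"].sum()
    ground = info.set_index("taxon")["ground_dwelling"]
    retained = [
        t
        for t, total in totals.items()
        if ground[t] and total >= min_total
    ]
    return sorted(retained)


def per_round_table(
    events: pd.DataFrame, info: pd.DataFrame, retained: list[str]
) -> pd.DataFrame:
    """One row per plot/year/round with per-group and per-taxon densities.

    Used by the moving-window scan, which keeps rounds separate to obtain
    the highest possible temporal resolution.
    """
    ev = events[events["taxon"].isin(retained)].copy()
    group_of = info.set_index("taxon")["trophic_group"]
    ev["trophic_group"] = ev["taxon"].map(group_of)
    keys = ["plot", "year", "round", "start_date"]
    wide_taxa = (
        ev.pivot_table(index=keys, columns="taxon", values="count", aggfunc="sum", fill_value=0)
        .reindex(columns=retained, fill_value=0)
    )
    wide_groups = ev.pivot_table(
        index=keys, columns="trophic_group", values="count", aggfunc="sum", fill_value=0
    ).reindex(columns=list(TROPHIC_GROUPS), fill_value=0)
    out = pd.concat([wide_groups, wide_taxa], axis=1).reset_index()
    out.columns.name = None
    return out.sort_values(keys).reset_index(drop=True)


def aggregate(
    events: pd.DataFrame,
    veg: pd.DataFrame,
    soil: pd.DataFrame,
    rainfall: RainfallSeries,
    retained: list[str],
    info: pd.DataFrame = None,
) -> pd.DataFrame:
    """Build the plot-year analysis table.

    Per plot-year (any plot-year with at least one trapping round):

    * taxon and trophic-group activity densities summed over rounds
      (retained taxa only),
    * vegetation covariates as the per-parameter maximum over the year's
      surveys,
    * seasonal (Feb-Mar) rainfall joined by year,
    * soil texture fractions joined by plot.

    A plot-year with trap records but no vegetation survey is kept with
    missing cover (NaN) and a warning.

    Returns a DataFrame with columns ``plot, year, n_rounds,
    seasonal_rainfall, total_cover, herb_cover, grass_cover, n_species``,
    the five soil fractions, one column per trophic group, and one column
    per retained taxon.
    """
    if info is None:
        raise ValueError("aggregate() requires the taxon metadata table (info=...)")
    keys = ["plot", "year"]
    ev = events[events["taxon"].isin(retained)].copy()
    group_of = info.set_index("taxon")["trophic_group"]
    ev["trophic_group"] = ev["taxon"].map(group_of)

    base = events.groupby(keys, as_index=False).agg(n_rounds=("round", "nunique"))
    wide_taxa = (
        ev.pivot_table(index=keys, columns="taxon", values="count", aggfunc="sum", fill_value=0)
        .reindex(columns=retained, fill_value=0)
        .reindex(pd.MultiIndex.from_frame(base[keys]), fill_value=0)
    )
    wide_groups = pd.DataFrame(
        {
            g: wide_taxa[[t for t in retained if group_of[t] == g]].sum(axis=1)
            for g in TROPHIC_GROUPS
        },
        index=wide_taxa.index,
    )

    veg_max = veg.groupby(keys, as_index=False)[
        ["total_cover", "herb_cover", "grass_cover", "n_species"]
    ].max()
    out = base.merge(veg_max, on=keys, how="left")
    missing_veg = out["total_cover"].isna()
    if missing_veg.any():
        miss = out.loc[missing_veg, keys].itertuples(index=False)
        warnings.warn(
            "plot-years without vegetation survey kept with missing cover: "
            + ", ".join(f"{m.plot}/{m.year}" for m in miss),
            stacklevel=2,
        )
    orphan_veg = veg.merge(base[keys], on=keys, how="left", indicator=True)
    n_orphan = (orphan_veg["_merge"] == "left_only").sum()
    if n_orphan:
        warnings.warn(
            f"{n_orphan} vegetation survey row(s) have no matching trap records",
            stacklevel=2,
        )

    out["seasonal_rainfall"] = [
        seasonal_rainfall(rainfall, int(y)) for y in out["year"]
    ]
    out = out.merge(soil, on="plot", how="left")
    if out[list(SOIL_FRACTIONS)].isna().any().any():
        missing = out.loc[out["sand"].isna(), "plot"].unique()
        raise SchemaError(f"soil table has no entry for plot(s): {sorted(missing)}")

    out = pd.concat(
        [
            out.reset_index(drop=True),
            wide_groups.reset_index(drop=True),
            wide_taxa.reset_index(drop=True),
        ],
        axis=1,
    )
    return out.sort_values(keys).reset_index(drop=True)


def build_matrix(records: pd.DataFrame, taxa: list[str]) -> pd.DataFrame:
    """Assemble the site-by-taxa activity-density matrix.

    Rows are plot-years labelled ``"<plot>:<year>"``, columns the retained
    taxa. All-zero sites are dropped with a warning (Bray-Curtis is
    undefined for empty sites); fewer than three sites is an error because
    ordination is then infeasible.
    """
    if len(taxa) < 2:
        raise ValueError("site-taxa matrix needs >= 2 taxa")
    missing = [t for t in taxa if t not in records.columns]
    if missing:
        raise SchemaError(f"records table lacks taxon column(s): {missing}")
    labels = records["plot"].astype(str) + ":" + records["year"].astype(str)
    M = records[taxa].copy()
    M.index = pd.Index(labels, name="site")
    empty = M.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"dropping {int(empty.sum())} all-zero site(s): "
            + ", ".join(M.index[empty]),
            stacklevel=2,
        )
        M = M.loc[~empty]
    if len(M) < 3:
        raise ValueError(f"only {len(M)} non-empty sites; ordination infeasible (< 3)")
    return M
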