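"""Moving-window critical-rainfall-window scan.

For each candidate window (width w in {7, 14, 30} days, offset k in
0..30 days before the trap start) the daily rainfall is summed over the
w days ending k days before trapping begins, an NB random-intercept
GLMM ``activity ~ windowed_rain + year + (1 | plot)`` is fitted on the
per-round data, and the fixed-effects adjusted R^2 is profiled against
the window position. The offset maximizing R^2 locates the group's
critical window; a plateau (contiguous offsets within 95% of the
width's maximum) describes its extent.

Day convention: offset 0 means the window ends the day before the trap
opens; rainfall falling while traps are open is never counted (traps
are roofed, and the question is antecedent rainfall).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rainwin.datamodel import DataGapError, RainfallSeries
from rainwin.glmm import GLMMFit, ModelSpec, adjusted_r2, fit_nb_glmm

DEFAULT_WIDTHS = (7, 14, 30)
DEFAULT_OFFSETS = tuple(range(31))


@dataclass(frozen=True)
class WindowSpec:
    """One window position: width in days, offset in days before trap start."""

    width: int
    offset: int

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("window width must be >= 1 day")
        if self.offset < 0:
            raise ValueError("window offset must be >= 0 days")


def window_sum(series: RainfallSeries, t0, spec: WindowSpec) -> float:
    """Rainfall (mm) summed over the ``spec.width`` days ending
    ``spec.offset`` days before ``t0``: days t0-k-w .. t0-k-1 inclusive."""
    t0 = pd.Timestamp(t0)
    start = t0 - pd.Timedelta(days=spec.offset + spec.width)
    end = t0 - pd.Timedelta(days=spec.offset + 1)
    if not series.covers(start, end):
        raise DataGapError(
            f"rainfall history covers {series.start.date()}..{series.end.date()}, "
            f"window (w={spec.width}, k={spec.offset}) before {t0.date()} needs "
            f"{start.date()}..{end.date()}"
        )
    return series.range_sum(start, end)


@dataclass
class ScanProfile:
    """Adjusted-R^2 evidence surface for one response group.

    ``frame`` has one row per (width, offset) cell with columns
    ``width, offset, r2_adj, beta_rain, z_rain, converged``. ``argmax``
    and ``plateau`` are per-width; ``best_width`` maximizes the per-width
    maximum R^2 (ties broken toward the smaller width).
    """

    response: str
    frame: pd.DataFrame
    argmax: dict = field(default_factory=dict)
    plateau: dict = field(default_factory=dict)
    best_width: int | None = None

    def max_r2(self, width: int) -> float:
        sub = self.frame[(self.frame["width"] == width) & self.frame["converged"]]
        return float(sub["r2_adj"].max()) if len(sub) else float("nan")


def _plateau(offsets: np.ndarray, r2: np.ndarray, argmax_off: int, frac: float) -> tuple:
    """Maximal contiguous run of offsets containing the argmax whose R^2
    stays within ``frac`` of the width's maximum."""
    hi = np.nanmax(r2)
    ok = r2 >= frac * hi
    i = int(np.flatnonzero(offsets == argmax_off)[0])
    lo_i = i
    while lo_i > 0 and ok[lo_i - 1] and offsets[lo_i - 1] == offsets[lo_i] - 1:
        lo_i -= 1
    hi_i = i
    while hi_i < len(offsets) - 1 and ok[hi_i + 1] and offsets[hi_i + 1] == offsets[hi_i] + 1:
        hi_i += 1
    return int(offsets[lo_i]), int(offsets[hi_i])


def scan(
    rounds: pd.DataFrame,
    rainfall: RainfallSeries,
    response: str,
    widths=DEFAULT_WIDTHS,
    offsets=DEFAULT_OFFSETS,
    year: str | None = "numeric",
    n_quad: int = 1,
    plateau_frac: float = 0.95,
) -> ScanProfile:
    """Profile adjusted R^2 over window positions for one response.

    Parameters
    ----------
    rounds
        Per-round table (one row per plot/year/round) with columns
        ``plot, year, start_date`` and the response counts. Rounds are
        kept separate for the highest temporal resolution.
    rainfall
        Daily rainfall covering every required window.
    response
        Column to model (nonnegative integer counts; percent plant cover
        should be pre-scaled to pseudo-counts by the caller).
    """
    starts = pd.to_datetime(rounds["start_date"])
    if rounds[response].nunique() < 2:
        raise ValueError(f"response '{response}' is constant; nothing to model")
    null_fit = fit_nb_glmm(rounds, ModelSpec(response=response, covariates=[], year=None))
    records = []
    warm: np.ndarray | None = None
    for w in widths:
        for k in offsets:
            spec = WindowSpec(int(w), int(k))
            rain = np.array([window_sum(rainfall, t0, spec) for t0 in starts])
            if np.std(rain) < 1e-12:
                records.append((w, k, np.nan, np.nan, np.nan, False))
                continue
            df = rounds.copy()
            df["windowed_rain"] = (rain - rain.mean()) / rain.std()
            try:
                fit = fit_nb_glmm(
                    df,
                    ModelSpec(
                        response=response, covariates=["windowed_rain"],
                        year=year, n_quad=n_quad,
                    ),
                    start=warm,
                )
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"cell (w={w}, k={k}) failed: {exc}", stacklevel=2)
                records.append((w, k, np.nan, np.nan, np.nan, False))
                continue
            warm = fit.params
            rep = adjusted_r2(fit, null_fit)
            j = fit.names.index("windowed_rain")
            records.append((w, k, rep.r2_adj, fit.beta[j], fit.z[j], fit.converged))
        warm = None
    frame = pd.DataFrame(
        records, columns=["width", "offset", "r2_adj", "beta_rain", "z_rain", "converged"]
    )
    if not frame["converged"].any():
        raise RuntimeError("no window cell converged")
    profile = ScanProfile(response=response, frame=frame)
    for w in widths:
        sub = frame[(frame["width"] == w) & frame["converged"]].dropna(subset=["r2_adj"])
        if len(sub) == 0:
            warnings.warn(f"width {w}: no converged cell; excluded", stacklevel=2)
            continue
        if len(sub) < (frame["width"] == w).sum():
            warnings.warn(
                f"width {w}: {(frame['width'] == w).sum() - len(sub)} non-converged "
                "cell(s) excluded from argmax/plateau",
                stacklevel=2,
            )
        best = sub.loc[sub["r2_adj"].idxmax()]
        profile.argmax[int(w)] = int(best["offset"])
        profile.plateau[int(w)] = _plateau(
            sub["offset"].to_numpy(), sub["r2_adj"].to_numpy(), int(best["offset"]), plateau_frac
        )
    maxima = {w: profile.max_r2(w) for w in profile.argmax}
    profile.best_width = min(maxima, key=lambda w: (-maxima[w], w))
    return profile


def compare_widths(profiles: dict) -> pd.DataFrame:
    """Rank window widths per response group by their maximal adjusted R^2.

    ``profiles`` maps group name -> :class:`ScanProfile`. Returns a table
    with the per-width maxima and the best width per group (ties broken
    toward the smaller width).
    """
    rows = []
    for name, prof in profiles.items():
        if len(prof.argmax) == 0:
            raise ValueError(f"profile for '{name}' has no scanned width")
        maxima = {w: prof.max_r2(w) for w in prof.argmax}
        best = min(maxima, key=lambda w: (-round(maxima[w], 12), w))
        row = {"response": name, "best_width": int(best)}
        for w, v in maxima.items():
            row[f"max_r2_w{w}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def plot_profile(profile: ScanProfile, path=None, width: int | None = None):
    """Plot adjusted R^2 against window offset (one line per width).

    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    widths = [width] if width is not None else sorted(profile.frame["width"].unique())
    for w in widths:
        sub = profile.frame[(profile.frame["width"] == w) & profile.frame["converged"]]
        ax.plot(sub["offset"], sub["r2_adj"], marker="o", ms=3, label=f"{w} d")
    ax.set_xlabel("window offset (days before trapping)")
    ax.set_ylabel("adjusted $R^2$")
    ax.set_title(profile.response)
    ax.legend(title="width")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
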