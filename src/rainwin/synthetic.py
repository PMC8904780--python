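"""Seeded synthetic study generator for an arid-savannah pitfall-trap design.

Emulates a multi-year field design: 30 plots sampled in two pitfall
rounds per year (>= 14 days apart, March to early April), daily rainfall
that falls highly seasonally with a February-March maximum, per-plot soil
surface texture, vegetation surveys, and negative-binomially distributed
activity densities per trophic group.

The generative model plants known ground truth so every downstream stage
is testable without field data:

* each group's latent log-mean responds to the rainfall summed over a
  7-day window ending ``lag`` days before the trap start (the group's
  critical window),
* bottom-up links act on latent (expected) abundances: plants feed
  herbivores, plants+herbivores feed omnivores, herbivores+omnivores+
  detritivores feed predators, herbivores feed ants; gravel suppresses
  plant cover,
* plot-level random intercepts and a shared year-level deviate per group
  emulate repeated sampling of the same plots and large inter-annual
  variance, and a latent plot-round "patchiness" term on the plants
  emulates microhabitat vegetation variation beyond the measured
  drivers (it propagates up the cascade, which is what makes the
  bottom-up links identifiable over and above rainfall),
* a configurable number of rare taxa (expected study total < 50) and one
  non-ground-dwelling taxon exercise the downstream filtering rules, and
* whole plot-years drop out at a configurable rate, producing the
  unbalanced panels typical of multi-year trapping.

Everything is driven by one integer seed; a fixed seed yields
byte-identical CSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from rainwin.datamodel import ConfigError, RainfallSeries, TROPHIC_GROUPS

GROUPS = ("plants",) + TROPHIC_GROUPS  # plants first: cascade is bottom-up

#: taxon composition of each arthropod group: name -> share of group mean
GROUP_TAXA = {
    "herbivore": {"cicadas": 0.60, "short_horned_grasshoppers": 0.30, "aphids": 0.10},
    "omnivore": {
        "beetles": 0.45,
        "long_horned_grasshoppers": 0.20,
        "true_bugs": 0.20,
        "cockroaches": 0.10,
        "booklice": 0.05,
    },
    "predator": {"spiders": 0.45, "mites": 0.35, "centipedes": 0.12, "scorpions": 0.08},
    "detritivore": {"springtails": 1.0},
    "ant": {"ants": 1.0},
}

#: per-round intercepts on the log scale (plants in % cover, others counts)
BASE_LOG_MEAN = {
    "plants": np.log(4.0),
    "herbivore": np.log(12.0),
    "omnivore": np.log(15.0),
    "predator": np.log(5.0),
    "detritivore": np.log(8.0),
    "ant": np.log(50.0),
}

# reference scale used to standardize the windowed-rainfall driver; the
# driver is log(1 + W) so the biological response saturates with heavy
# rainfall. Fixed constants (not data moments) so effect sizes mean the
# same thing for every seed.
W7_CENTER = 1.95  # log1p of a typical 6 mm weekly sum
W7_SCALE = 1.0

GRAVEL_CENTER = 25.0  # typical gravel %, used to center the gravel driver
GRAVEL_SCALE = 6.0


def _default_lags() -> dict:
    return {
        "plants": 8,
        "herbivore": 15,
        "predator": 15,
        "omnivore": 24,
        "detritivore": 15,
        "ant": None,
    }


def _default_effects() -> dict:
    return {
        "rain_plants": 0.35,
        "rain_herbivore": 1.1,
        "rain_omnivore": 0.7,
        "rain_predator": 0.5,
        "rain_detritivore": 0.8,
        "gravel_plants": -0.6,
        "plants_herbivore": 0.7,
        "plants_omnivore": 0.3,
        "herbivore_omnivore": 0.4,
        "herbivore_predator": 0.3,
        "omnivore_predator": 0.3,
        "detritivore_predator": 0.2,
        "herbivore_ant": 0.3,
    }


def _default_theta() -> dict:
    return {
        "plants": 30.0,
        "herbivore": 1.5,
        "omnivore": 1.5,
        "predator": 1.5,
        "detritivore": 1.0,
        "ant": 2.0,
    }


@dataclass
class SimConfig:
    """Configuration of one synthetic study.

    Defaults reproduce the emulated design: 30 plots, six years
    (2013-2018), two rounds per year at least 14 days apart, a mean
    seasonal (Feb-Mar) rainfall of 56 mm with large inter-annual
    dispersion, group-specific rainfall lags, bottom-up link
    coefficients, NB dispersions, a plot random-intercept SD, a shared
    year-level SD, plot-year dropout, and a handful of rare taxa.
    """

    seed: int = 0
    n_plots: int = 30
    years: tuple = (2013, 2014, 2015, 2016, 2017, 2018)
    rounds_per_year: int = 2
    seasonal_mean_mm: float = 56.0
    seasonal_cv: float = 1.07
    group_lags: dict = field(default_factory=_default_lags)
    group_effects: dict = field(default_factory=_default_effects)
    theta: dict = field(default_factory=_default_theta)
    sigma_plot: float = 0.3
    year_sd: float = 0.3
    plant_patchiness_sd: float = 0.6
    dropout_rate: float = 0.12
    rare_taxon_count: int = 3

    def validate(self) -> None:
        if len(self.years) == 0:
            raise ConfigError("years list is empty")
        if self.n_plots < 2:
            raise ConfigError("need n_plots >= 2")
        if self.rounds_per_year not in (1, 2):
            raise ConfigError("rounds_per_year must be 1 or 2")
        if self.seasonal_mean_mm <= 0 or self.seasonal_cv < 0:
            raise ConfigError("seasonal_mean_mm must be > 0 and seasonal_cv >= 0")
        for g, lag in self.group_lags.items():
            if lag is not None and not (0 <= lag <= 30):
                raise ConfigError(f"lag for '{g}' must lie in [0, 30], got {lag}")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.sigma_plot < 0 or self.year_sd < 0 or self.plant_patchiness_sd < 0:
            raise ConfigError("variance components must be >= 0")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def null_config(seed: int = 0, **kwargs) -> SimConfig:
    """A configuration with every rainfall/link effect and every variance
    component switched off: counts are exchangeable across plots and years.
    Used for type-I-error calibration of the downstream statistics."""
    return SimConfig(
        seed=seed,
        group_effects={k: 0.0 for k in _default_effects()},
        sigma_plot=0.0,
        year_sd=0.0,
        **kwargs,
    )


@dataclass
class SyntheticTruth:
    """Ground truth echoing the generating configuration."""

    true_lags: dict
    true_coefficients: dict
    true_sigma_plot: float
    true_theta: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Rainfall
# ---------------------------------------------------------------------------


def _day_weights(dates: pd.DatetimeIndex) -> np.ndarray:
    """Relative probability of a rain event on each calendar day.

    Gaussian peak in late February (the seasonal maximum) plus a smaller
    early-wet-season bump around late November; May-September is dry.
    """
    doy = dates.dayofyear.to_numpy(dtype=float)
    w = np.exp(-0.5 * ((doy - 51.0) / 24.0) ** 2) + 0.25 * np.exp(
        -0.5 * ((doy - 334.0) / 22.0) ** 2
    )
    dry = np.asarray((dates.month >= 5) & (dates.month <= 9))
    w[dry] = 0.0
    return w


def _quantize_preserving_sum(vals: np.ndarray, target: float) -> np.ndarray:
    """Round ``vals`` to the 0.5 mm grid so that their sum is exactly
    ``target`` (itself a multiple of 0.5), by largest-remainder allocation."""
    units = vals * 2.0
    base = np.floor(units)
    deficit = int(round(target * 2.0)) - int(base.sum())
    out = base.copy()
    if deficit > 0:
        # add half-millimetres to the largest remainders, cycling if the
        # target exceeds what one unit per event can supply
        order = np.argsort(-(units - base), kind="stable")
        np.add.at(out, order[np.arange(deficit) % len(out)], 1.0)
    else:
        for _ in range(-deficit):  # take back from the largest amounts
            i = int(np.argmax(out))
            if out[i] <= 0:
                break
            out[i] -= 1.0
    return out / 2.0


def gen_rainfall(config: SimConfig) -> RainfallSeries:
    """Generate a contiguous daily rainfall record.

    Covers Jan 1 of the year before the first study year through Dec 31
    of the last (the extra year supplies window history for early-season
    trap dates). Per calendar year a seasonal (Feb-Mar) total is drawn
    log-normally with mean ``seasonal_mean_mm`` and coefficient of
    variation ``seasonal_cv``, then disaggregated into gamma-magnitude
    events on days sampled from a Feb-Mar-peaked weight curve and
    quantized to the 0.5 mm gauge resolution without changing the
    seasonal total.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    y0, y1 = min(config.years) - 1, max(config.years)
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    mm = np.zeros(len(dates))
    cv = config.seasonal_cv
    for year in range(y0, y1 + 1):
        in_year = dates.year == year
        ydates = dates[in_year]
        if cv < 1e-9:
            total = config.seasonal_mean_mm
        else:
            s2 = np.log1p(cv**2)
            mu = np.log(config.seasonal_mean_mm) - s2 / 2.0
            total = float(rng.lognormal(mu, np.sqrt(s2)))
        w = _day_weights(ydates)
        season = np.asarray((ydates.month == 2) | (ydates.month == 3))
        n_events = max(4, int(rng.poisson(16)))
        n_season = max(2, n_events // 2)
        w_season = np.where(season, w, 0.0)
        days_a = rng.choice(len(ydates), size=n_season, p=w_season / w_season.sum())
        days_b = rng.choice(len(ydates), size=n_events - n_season, p=w / w.sum())
        amounts = rng.gamma(0.7, 1.0, size=n_events)
        daily = np.zeros(len(ydates))
        np.add.at(daily, np.concatenate([days_a, days_b]), amounts)
        s_sum = daily[season].sum()
        daily *= total / s_sum
        target = round(total * 2.0) / 2.0
        daily[season] = _quantize_preserving_sum(daily[season], target)
        off = ~season
        daily[off] = np.round(daily[off] * 2.0) / 2.0
        mm[in_year] = daily
    return RainfallSeries(dates, mm)


# ---------------------------------------------------------------------------
# Plots (soil texture)
# ---------------------------------------------------------------------------


def gen_plots(config: SimConfig) -> pd.DataFrame:
    """Per-plot soil surface texture: five fractions summing to 100%,
    sand-dominated (sand > gravel > cobble > boulder > large boulder on
    average), drawn from a Dirichlet."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[1])
    alphas = np.array([55.0, 25.0, 12.0, 6.0, 2.0])
    fracs = rng.dirichlet(alphas, size=config.n_plots) * 100.0
    plots = [f"P{i + 1:02d}" for i in range(config.n_plots)]
    df = pd.DataFrame(fracs, columns=["sand", "gravel", "cobble", "boulder", "large_boulder"])
    df.insert(0, "plot", plots)
    return df


# ---------------------------------------------------------------------------
# Full study
# ---------------------------------------------------------------------------


def _window_sum(series: RainfallSeries, t0: pd.Timestamp, lag: int, width: int = 7) -> float:
    # rainfall over the `width` days ending `lag` days before t0
    start = t0 - pd.Timedelta(days=lag + width)
    end = t0 - pd.Timedelta(days=lag + 1)
    return series.range_sum(start, end)


def gen_study(config: SimConfig):
    """Generate one complete study dataset plus its ground truth.

    Returns ``(bundle, truth)`` where ``bundle`` is a dict with keys
    ``rainfall`` (:class:`RainfallSeries`), ``soil``, ``veg``, ``traps``
    (long format) and ``taxa`` (metadata), and ``truth`` echoes the
    generating lags, coefficients and variance components.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    rainfall = gen_rainfall(config)
    soil = gen_plots(config)
    years = sorted(config.years)
    plots = list(soil["plot"])
    eff = config.group_effects
    lags = config.group_lags
    theta = config.theta

    # campaign dates, shared across plots: round 1 in the first half of
    # March, round 2 at least 14 days later (March to early April)
    round_dates = {}
    for y in years:
        r1 = pd.Timestamp(year=y, month=3, day=1) + pd.Timedelta(days=int(rng.integers(0, 14)))
        r2 = r1 + pd.Timedelta(days=14 + int(rng.integers(0, 8)))
        round_dates[y] = [r1, r2][: config.rounds_per_year]

    # variance components
    b_plot = {
        g: rng.normal(0.0, config.sigma_plot, size=len(plots)) for g in GROUPS
    }
    u_year = {g: {y: rng.normal(0.0, config.year_sd) for y in years} for g in GROUPS}

    # plot-year dropout, at least 15 plots (or all plots) retained per year
    keep_floor = min(15, config.n_plots)
    kept: dict = {}
    for y in years:
        mask = rng.random(len(plots)) >= config.dropout_rate
        if mask.sum() < keep_floor:
            dropped = np.flatnonzero(~mask)
            revive = rng.choice(dropped, size=keep_floor - int(mask.sum()), replace=False)
            mask[revive] = True
        kept[y] = mask

    # taxa metadata: core taxa + rare taxa + one non-ground-dwelling taxon
    taxa_rows = []
    for g, shares in GROUP_TAXA.items():
        for t in shares:
            taxa_rows.append((t, g, True))
    rare_names = []
    rare_groups = ["predator", "herbivore", "omnivore", "detritivore"]
    for i in range(config.rare_taxon_count):
        name = f"rare_taxon_{i + 1}"
        rare_names.append(name)
        taxa_rows.append((name, rare_groups[i % len(rare_groups)], True))
    taxa_rows.append(("flies", "omnivore", False))
    taxa = pd.DataFrame(taxa_rows, columns=["taxon", "trophic_group", "ground_dwelling"])

    gravel_z = (soil["gravel"].to_numpy() - GRAVEL_CENTER) / GRAVEL_SCALE

    def nb_draw(mean: np.ndarray, th: float) -> np.ndarray:
        lam = rng.gamma(th, np.asarray(mean) / th)
        return rng.poisson(lam)

    trap_rows = []
    veg_rows = []
    for y in years:
        # trap-setting order: each plot's rounds start 0-2 days after the
        # campaign date (same shift for both rounds, so the >= 14 day
        # inter-round interval is preserved)
        delta = rng.integers(0, 3, size=len(plots))
        for r, t0 in enumerate(round_dates[y], start=1):
            # standardized windowed-rainfall driver per group and plot
            sW = {}
            for g in GROUPS:
                lag = lags.get(g)
                if lag is None:
                    sW[g] = np.zeros(len(plots))
                else:
                    by_delta = {
                        d: (np.log1p(_window_sum(rainfall, t0 + pd.Timedelta(days=d), int(lag)))
                            - W7_CENTER) / W7_SCALE
                        for d in range(3)
                    }
                    sW[g] = np.array([by_delta[int(d)] for d in delta])
            # latent log-means per plot, built bottom-up on latent parents
            L = {}
            L["plants"] = (
                BASE_LOG_MEAN["plants"]
                + eff["rain_plants"] * sW["plants"]
                + eff["gravel_plants"] * gravel_z
                + b_plot["plants"]
                + u_year["plants"][y]
                + rng.normal(0.0, config.plant_patchiness_sd, len(plots))
            )
            c_pl = L["plants"] - BASE_LOG_MEAN["plants"]
            L["herbivore"] = (
                BASE_LOG_MEAN["herbivore"]
                + eff["rain_herbivore"] * sW["herbivore"]
                + eff["plants_herbivore"] * c_pl
                + b_plot["herbivore"]
                + u_year["herbivore"][y]
            )
            c_h = L["herbivore"] - BASE_LOG_MEAN["herbivore"]
            L["detritivore"] = (
                BASE_LOG_MEAN["detritivore"]
                + eff["rain_detritivore"] * sW["detritivore"]
                + b_plot["detritivore"]
                + u_year["detritivore"][y]
            )
            c_d = L["detritivore"] - BASE_LOG_MEAN["detritivore"]
            L["omnivore"] = (
                BASE_LOG_MEAN["omnivore"]
                + eff["rain_omnivore"] * sW["omnivore"]
                + eff["plants_omnivore"] * c_pl
                + eff["herbivore_omnivore"] * c_h
                + b_plot["omnivore"]
                + u_year["omnivore"][y]
            )
            c_o = L["omnivore"] - BASE_LOG_MEAN["omnivore"]
            L["predator"] = (
                BASE_LOG_MEAN["predator"]
                + eff["rain_predator"] * sW["predator"]
                + eff["herbivore_predator"] * c_h
                + eff["omnivore_predator"] * c_o
                + eff["detritivore_predator"] * c_d
                + b_plot["predator"]
                + u_year["predator"][y]
            )
            L["ant"] = (
                BASE_LOG_MEAN["ant"]
                + eff["herbivore_ant"] * c_h
                + b_plot["ant"]
                + u_year["ant"][y]
            )

            keep_mask = kept[y]
            starts_p = [t0 + pd.Timedelta(days=int(d)) for d in delta]
            # vegetation survey: continuous cover 0.1-50 %, gamma noise
            cover = rng.gamma(theta["plants"], np.exp(L["plants"]) / theta["plants"])
            cover = np.clip(np.round(cover, 1), 0.1, 50.0)
            split = rng.beta(2.0, 2.0, size=len(plots))
            n_species = 1 + rng.poisson(
                1.5 + 2.0 / (1.0 + np.exp(-sW["plants"])), size=len(plots)
            )
            for i, p in enumerate(plots):
                if not keep_mask[i]:
                    continue
                veg_rows.append(
                    (
                        p,
                        y,
                        r,
                        cover[i],
                        round(cover[i] * split[i] * 0.8, 1),
                        round(cover[i] * (1 - split[i]) * 0.8, 1),
                        int(n_species[i]),
                    )
                )
            # arthropod counts per taxon
            for g in TROPHIC_GROUPS:
                mu_g = np.exp(L[g])
                for t, share in GROUP_TAXA[g].items():
                    counts = nb_draw(share * mu_g, theta[g])
                    for i, p in enumerate(plots):
                        if keep_mask[i]:
                            trap_rows.append((p, y, r, starts_p[i], t, int(counts[i])))
            for name in rare_names:
                counts = nb_draw(np.full(len(plots), 0.06), 1.0)
                for i, p in enumerate(plots):
                    if keep_mask[i]:
                        trap_rows.append((p, y, r, starts_p[i], name, int(counts[i])))
            counts = nb_draw(np.full(len(plots), 3.0), 2.0)
            for i, p in enumerate(plots):
                if keep_mask[i]:
                    trap_rows.append((p, y, r, starts_p[i], "flies", int(counts[i])))

    traps = pd.DataFrame(
        trap_rows, columns=["plot", "year", "round", "start_date", "taxon", "count"]
    )
    veg = pd.DataFrame(
        veg_rows,
        columns=["plot", "year", "round", "total_cover", "herb_cover", "grass_cover", "n_species"],
    )
    truth = SyntheticTruth(
        true_lags=dict(lags),
        true_coefficients=dict(eff),
        true_sigma_plot=config.sigma_plot,
        true_theta=dict(theta),
    )
    bundle = {"rainfall": rainfall, "soil": soil, "veg": veg, "traps": traps, "taxa": taxa}
    return bundle, truth


def write_bundle(bundle, truth, outdir) -> dict:
    """Write a study bundle to CSV files (+ truth.json); returns paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    paths["rainfall"] = os.path.join(outdir, "rainfall.csv")
    bundle["rainfall"].to_csv(paths["rainfall"])
    for name in ("soil", "veg", "taxa"):
        paths[name] = os.path.join(outdir, f"{name}.csv")
        bundle[name].to_csv(paths[name], index=False)
    paths["traps"] = os.path.join(outdir, "traps.csv")
    traps = bundle["traps"].copy()
    traps["start_date"] = pd.to_datetime(traps["start_date"]).dt.strftime("%Y-%m-%d")
    traps.to_csv(paths["traps"], index=False)
    paths["truth"] = os.path.join(outdir, "truth.json")
    truth.to_json(paths["truth"])
    return paths
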