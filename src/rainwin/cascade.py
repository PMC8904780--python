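"""Bottom-up trophic-cascade GLMM suite.

Six NB random-intercept models — plant cover plus the activity densities
of herbivores, omnivores, predators, detritivores and ants per plot-year
— each regressed on seasonal rainfall, soil texture (gravel, cobble) and
the bottom-up links of a classical resource-driven food web:

* plants: rainfall, gravel, cobble
* herbivores, detritivores: + plant cover
* omnivores: + plant cover, herbivores, detritivores
* predators: rainfall, gravel, cobble, herbivores, omnivores, detritivores
* ants: rainfall, gravel, cobble, plant cover, herbivores, detritivores

Covariates deliberately excluded from a model are "not tested" (NT).
Continuous covariates are z-scored before fitting so estimates are
comparable across covariates; activity-density and plant-cover
covariates are log(x+1)-transformed first to tame their skew. Plant cover enters as a
response as pseudo-counts (percent x 10, rounded) under the NB family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rainwin.glmm import ModelSpec, fit_nb_glmm

#: responses in cascade (bottom-up) order and their tested covariates
DEFAULT_DESIGN = {
    "plants": ["seasonal_rainfall", "gravel", "cobble"],
    "herbivores": ["seasonal_rainfall", "gravel", "cobble", "plants"],
    "detritivores": ["seasonal_rainfall", "gravel", "cobble", "plants"],
    "omnivores": [
        "seasonal_rainfall", "gravel", "cobble", "plants", "herbivores", "detritivores",
    ],
    "predators": [
        "seasonal_rainfall", "gravel", "cobble", "herbivores", "omnivores", "detritivores",
    ],
    "ants": ["seasonal_rainfall", "gravel", "cobble", "plants", "herbivores", "detritivores"],
}

#: display order of covariate rows in the rendered table
ROW_ORDER = [
    "seasonal_rainfall", "gravel", "cobble", "plants", "herbivores", "omnivores", "detritivores",
]
COLUMN_ORDER = ["plants", "herbivores", "omnivores", "predators", "detritivores", "ants"]

#: mapping from cascade names to plot-year record columns
_RESPONSE_COL = {
    "plants": "total_cover",
    "herbivores": "herbivore",
    "omnivores": "omnivore",
    "predators": "predator",
    "detritivores": "detritivore",
    "ants": "ant",
}
_DENSITY_COVARIATES = {"herbivores", "omnivores", "detritivores"}


@dataclass
class CascadeDesign:
    """Tested-covariate lists per response; anything absent is NT."""

    tested: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_DESIGN.items()})

    def covariates(self, response: str) -> list[str]:
        return list(self.tested[response])


@dataclass
class CascadeSummary:
    """response x covariate matrix of estimates with Wald inference."""

    cells: pd.DataFrame  # long: response, covariate, estimate, se, z, p, converged
    fits: dict = field(default_factory=dict)
    standardized: bool = True

    def cell(self, response: str, covariate: str):
        sub = self.cells[
            (self.cells["response"] == response) & (self.cells["covariate"] == covariate)
        ]
        return None if len(sub) == 0 else sub.iloc[0]


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s"


def prepare_covariates(records: pd.DataFrame, standardize: bool = True) -> pd.DataFrame:
    """Add transformed covariate columns (suffix ``_x``) to the plot-year
    table: activity densities log(x+1)-transformed, then (optionally)
    everything z-scored."""
    df = records.copy()
    plain = {"seasonal_rainfall": "seasonal_rainfall", "gravel": "gravel",
             "cobble": "cobble"}
    for name, col in plain.items():
        df[f"{name}_x"] = df[col].astype(float)
    df["plants_x"] = np.log1p(df["total_cover"].astype(float))
    for name in _DENSITY_COVARIATES:
        df[f"{name}_x"] = np.log1p(df[_RESPONSE_COL[name]].astype(float))
    if standardize:
        for name in list(plain) + ["plants"] + sorted(_DENSITY_COVARIATES):
            col = f"{name}_x"
            sd = df[col].std(ddof=0)
            if sd > 0:
                df[col] = (df[col] - df[col].mean()) / sd
    return df


def fit_cascade(
    records: pd.DataFrame,
    design: CascadeDesign | None = None,
    year: str | None = "numeric",
    standardize: bool = True,
    cover_scale: float = 10.0,
) -> CascadeSummary:
    """Fit the six cascade models on the plot-year table.

    ``records`` must carry ``plot, year, seasonal_rainfall, gravel,
    cobble, total_cover`` and the five trophic-group density columns.
    Returns a :class:`CascadeSummary`; non-convergence is reported per
    model, never silently dropped.
    """
    design = design or CascadeDesign()
    df = prepare_covariates(records, standardize=standardize)
    df["plants_count"] = np.round(df["total_cover"].astype(float) * cover_scale).astype(int)
    rows = []
    fits = {}
    for response in COLUMN_ORDER:
        covs = design.covariates(response)
        xcols = [f"{c}_x" for c in covs]
        resp_col = "plants_count" if response == "plants" else _RESPONSE_COL[response]
        fit = fit_nb_glmm(
            df, ModelSpec(response=resp_col, covariates=xcols, group="plot", year=year)
        )
        fits[response] = fit
        for c, xc in zip(covs, xcols):
            j = fit.names.index(xc)
            rows.append(
                {
                    "response": response,
                    "covariate": c,
                    "estimate": fit.beta[j],
                    "se": fit.se[j],
                    "z": fit.z[j],
                    "p": fit.p[j],
                    "converged": fit.converged,
                }
            )
    cells = pd.DataFrame(rows)
    return CascadeSummary(cells=cells, fits=fits, standardized=standardize)


def format_cell(estimate: float, p: float) -> str:
    """Table-2-style cell: estimate with significance stars, or 'n.s'."""
    s = stars(p)
    if s == "n.s":
        return "n.s"
    return f"{estimate:.2f}{s}"


def render_table(summary: CascadeSummary) -> pd.DataFrame:
    """Render the summary as a covariate x response table with stars,
    'n.s' for non-significant cells and 'NT' for covariates not tested
    in a model."""
    out = pd.DataFrame(index=ROW_ORDER, columns=COLUMN_ORDER, dtype=object)
    for response in COLUMN_ORDER:
        for cov in ROW_ORDER:
            cell = summary.cell(response, cov)
            if cell is None:
                out.loc[cov, response] = "NT"
            else:
                out.loc[cov, response] = format_cell(cell["estimate"], cell["p"])
    out.index.name = "covariate"
    return out


def render_text(summary: CascadeSummary) -> str:
    """Aligned plain-text rendering of :func:`render_table`."""
    table = render_table(summary)
    widths = {c: max(len(c), table[c].str.len().max()) for c in table.columns}
    name_w = max(len(i) for i in table.index)
    lines = [
        " ".join([" " * name_w] + [c.rjust(widths[c]) for c in table.columns]),
    ]
    for idx, row in table.iterrows():
        lines.append(" ".join([idx.ljust(name_w)] + [row[c].rjust(widths[c]) for c in table.columns]))
    return "\n".join(lines)
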