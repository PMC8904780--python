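"""Spearman collinearity screen for the environmental covariate set.

Pairs with |r_s| above a threshold (default 0.7, strict inequality) are
pruned iteratively: the pair with the largest |r_s| loses whichever
variable scores lower on a deterministic preference rule that
operationalizes "longer gradient, better distribution" — larger range
first, then smaller absolute skewness, then lexicographic name. The
rule is independent of the input column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScreenResult:
    """Spearman correlation matrix plus pruning bookkeeping."""

    corr: pd.DataFrame
    flagged: list = field(default_factory=list)  # (var_a, var_b, r_s) with |r_s| > threshold
    dropped: list = field(default_factory=list)  # (variable, reason)
    retained: list = field(default_factory=list)
    threshold: float = 0.7

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "corr": self.corr.round(6).to_dict(),
            "flagged": [(a, b, float(r)) for a, b, r in self.flagged],
            "dropped": list(self.dropped),
            "retained": list(self.retained),
        }


def spearman_matrix(table: pd.DataFrame, threshold: float = 0.7) -> ScreenResult:
    """Pairwise Spearman rank correlation (average ranks for ties,
    pairwise-complete observations).

    Constant variables have undefined correlations; their pairs are
    recorded as missing and the variable is flagged for dropping.
    """
    cols = list(table.columns)
    corr = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    constant = [c for c in cols if table[c].dropna().nunique() <= 1]
    flagged = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            pair = table[[a, b]].dropna()
            if len(pair) < 3 or a in constant or b in constant:
                corr.loc[a, b] = corr.loc[b, a] = np.nan
                continue
            r = stats.spearmanr(pair[a], pair[b]).statistic
            corr.loc[a, b] = corr.loc[b, a] = r
            if abs(r) > threshold:
                flagged.append((a, b, float(r)))
    result = ScreenResult(corr=corr, flagged=flagged, threshold=threshold)
    result.dropped = [(c, "constant variable (r_s undefined)") for c in constant]
    return result


def _preference_key(series: pd.Series, name: str):
    """Sort key: better variables sort first."""
    x = series.dropna().to_numpy(dtype=float)
    rng = float(np.ptp(x)) if len(x) else 0.0
    skew = abs(float(stats.skew(x))) if len(x) > 2 and np.ptp(x) > 0 else np.inf
    return (-rng, skew, name)


def prune(result: ScreenResult, table: pd.DataFrame, threshold: float | None = None) -> list[str]:
    """Iteratively drop one variable from the worst flagged pair until no
    retained pair exceeds the threshold (strict: |r_s| exactly at the
    threshold keeps both). Returns the retained variables; the dropped
    ones (with reasons) are appended to ``result.dropped`` and
    ``result.retained`` is filled in."""
    if threshold is None:
        threshold = result.threshold
    retained = [c for c in result.corr.columns if c not in {d for d, _ in result.dropped}]
    corr = result.corr
    while True:
        worst = None
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                r = corr.loc[a, b]
                if np.isnan(r) or abs(r) <= threshold:
                    continue
                key = (-abs(r), *sorted([a, b]))
                if worst is None or key < worst[0]:
                    worst = (key, a, b, r)
        if worst is None:
            break
        _, a, b, r = worst
        loser = max([a, b], key=lambda c: _preference_key(table[c], c))
        result.dropped.append(
            (loser, f"|r_s|={abs(r):.3f} with '{a if loser == b else b}' > {threshold}")
        )
        retained.remove(loser)
    result.retained = retained
    return retained


def screen(table: pd.DataFrame, threshold: float = 0.7) -> ScreenResult:
    """Convenience wrapper: correlation matrix plus pruning in one call."""
    result = spearman_matrix(table, threshold)
    prune(result, table, threshold)
    return result
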