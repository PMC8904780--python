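"""Community-composition analysis: column normalization, Bray-Curtis
dissimilarity, non-metric multidimensional scaling, permutation-tested
environmental vector fitting, and sequential-SS PERMANOVA.

NMDS minimizes Kruskal stress-1,

    S = sqrt( sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2 ),

where ``d`` are configuration Euclidean distances and ``dhat`` their
isotonic (monotone, pool-adjacent-violators) regression on the rank
order of the input dissimilarities, by alternating isotonic fits with
Guttman-transform configuration updates over multiple restarts (first
start from principal coordinates, the rest random).

PERMANOVA follows the Gower-centred distance-matrix machinery:
``G = -1/2 J (D o D) J`` with sequential (Type-I) sums of squares via
hat-matrix differences and pseudo-F tests by permuting site labels.
All permutation p-values use the add-one convention
``(1 + #{perm >= obs}) / (1 + n_perm)`` and are therefore never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# Matrix preparation and dissimilarity
# ---------------------------------------------------------------------------


def normalize_columns(M: pd.DataFrame, margin: str = "taxa") -> pd.DataFrame:
    """Scale the site-taxa matrix so each margin has unit sum of squares.

    ``margin="taxa"`` (default) divides each taxon column by its
    Euclidean norm, equalizing the leverage of taxa whose activity
    densities differ by orders of magnitude; ``margin="sites"`` scales
    rows instead.
    """
    M = pd.DataFrame(M).astype(float)
    if margin == "taxa":
        norms = np.sqrt((M**2).sum(axis=0))
        zero = norms[norms == 0]
        if len(zero):
            raise ValueError(f"all-zero taxon column(s): {list(zero.index)}")
        return M / norms
    if margin == "sites":
        norms = np.sqrt((M**2).sum(axis=1))
        zero = norms[norms == 0]
        if len(zero):
            raise ValueError(f"all-zero site row(s): {list(zero.index)}")
        return M.div(norms, axis=0)
    raise ValueError(f"margin must be 'taxa' or 'sites', got {margin!r}")


def bray_curtis(M: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between sites.

    d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); 0 for identical
    sites, 1 for sites with disjoint taxon support.
    """
    M = pd.DataFrame(M)
    X = M.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires nonnegative entries")
    totals = X.sum(axis=1)
    if np.count_nonzero(totals == 0) >= 2:
        empty = list(M.index[totals == 0])
        raise ValueError(f"Bray-Curtis undefined between all-zero sites: {empty}")
    num = pdist(X, metric="cityblock")
    den = totals[:, None] + totals[None, :]
    D = squareform(num) / np.where(den > 0, den, 1.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=M.index, columns=M.index)


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class OrdinationResult:
    """NMDS solution: centred site scores, final Kruskal stress-1,
    restart diagnostics and a convergence flag (two restarts agreeing
    under Procrustes rotation)."""

    scores: pd.DataFrame
    stress: float
    n_restarts: int
    converged: bool
    restart_stress: list = field(default_factory=list)


def _pcoa_coords(D: np.ndarray, k: int) -> np.ndarray:
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def _stress_and_disparities(d: np.ndarray, order: np.ndarray):
    dhat = np.empty_like(d)
    iso = isotonic_regression(d[order], increasing=True)
    dhat[order] = iso.x
    ss_d = float(np.sum(d**2))
    if ss_d == 0:
        return np.inf, dhat
    # keep the disparity vector on the configuration's scale
    ss_hat = float(np.sum(dhat**2))
    if ss_hat > 0:
        dhat = dhat * np.sqrt(ss_d / ss_hat)
    stress = np.sqrt(np.sum((d - dhat) ** 2) / ss_d)
    return float(stress), dhat


def _guttman_update(X: np.ndarray, d: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = len(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    R = squareform(ratio)
    B = -R
    np.fill_diagonal(B, R.sum(axis=1))
    return (B @ X) / n


def procrustes_correlation(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Procrustes correlation sqrt(1 - m2) between two
    configurations (translation, rotation/reflection and scale removed)."""
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(np.asarray(X, float), np.asarray(Y, float))
    return float(np.sqrt(max(0.0, 1.0 - disparity)))


def nmds(
    D: pd.DataFrame,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS of a dissimilarity matrix into ``k`` dimensions.

    Best of ``n_restarts`` runs; the first starts from the principal-
    coordinates configuration, the rest from random Gaussian configs.
    Convergence is declared when another restart's solution matches the
    best one with Procrustes correlation >= 0.999; otherwise the result
    is returned flagged with a warning.
    """
    Dframe = pd.DataFrame(D)
    index = Dframe.index
    Dm = Dframe.to_numpy(dtype=float)
    n = len(Dm)
    if n < 4:
        raise ValueError(f"NMDS needs >= 4 sites, got {n}")
    if not np.allclose(Dm, Dm.T, atol=1e-10):
        raise ValueError("dissimilarity matrix is not symmetric")
    dvec = squareform(Dm, checks=False)
    order = np.argsort(dvec, kind="stable")
    rng = np.random.default_rng(seed)

    solutions = []
    for restart in range(n_restarts):
        if restart == 0:
            X = _pcoa_coords(Dm, k)
        else:
            X = rng.normal(size=(n, k)) * np.mean(dvec)
        best_stress, best_X = np.inf, X
        prev = np.inf
        for _ in range(max_iter):
            d = pdist(X)
            stress, dhat = _stress_and_disparities(d, order)
            if stress < best_stress:  # accepted iteration
                best_stress, best_X = stress, X.copy()
            if prev - stress < tol:
                break
            prev = stress
            X = _guttman_update(X, d, dhat)
        solutions.append((best_stress, best_X))

    stresses = [s for s, _ in solutions]
    ibest = int(np.argmin(stresses))
    best_stress, best_X = solutions[ibest]
    converged = False
    for j, (s, Xj) in enumerate(solutions):
        if j == ibest:
            continue
        if procrustes_correlation(best_X, Xj) >= 0.999:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"NMDS: no two of {n_restarts} restarts agree (best stress "
            f"{best_stress:.4f}); treat the configuration with caution",
            stacklevel=2,
        )
    X = best_X - best_X.mean(axis=0)
    # rotate to principal axes for a reproducible orientation
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    scores = pd.DataFrame(X, index=index, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(
        scores=scores,
        stress=float(best_stress),
        n_restarts=n_restarts,
        converged=converged,
        restart_stress=stresses,
    )


# ---------------------------------------------------------------------------
# Environmental vector fitting
# ---------------------------------------------------------------------------


@dataclass
class EnvFitVector:
    """One fitted environmental vector: unit direction in ordination
    space, squared correlation r^2, and a permutation p-value."""

    name: str
    direction: np.ndarray
    r2: float
    p: float


def envfit(
    scores: pd.DataFrame,
    values,
    name: str = "variable",
    n_perm: int = 1000,
    seed: int = 0,
) -> EnvFitVector:
    """Least-squares fit of one environmental variable onto the ordination.

    The centred variable is regressed on the (centred) score axes;
    r^2 = 1 - RSS/TSS. Significance is assessed by permuting the
    variable's values across sites ``n_perm`` times (add-one p-value).
    """
    X = pd.DataFrame(scores).to_numpy(dtype=float)
    v = np.asarray(values, dtype=float)
    if len(v) != len(X):
        raise ValueError(f"variable length {len(v)} != number of sites {len(X)}")
    if np.std(v) < 1e-15:
        raise ValueError(f"variable '{name}' is constant; envfit undefined")
    Xc = X - X.mean(axis=0)
    vc = v - v.mean()
    tss = float(vc @ vc)
    coef, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
    fitted = Xc @ coef
    r2 = float(fitted @ fitted) / tss
    norm = np.linalg.norm(coef)
    direction = coef / norm if norm > 0 else coef

    # explained SS of a permuted variable is ||A' v_perm||^2 with
    # A an orthonormal basis of the centred score columns
    Q, _ = np.linalg.qr(Xc)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(v)) for _ in range(n_perm)])
    V = vc[perms]  # (n_perm, n)
    explained = ((V @ Q) ** 2).sum(axis=1)
    r2_perm = explained / tss
    p = (1.0 + np.sum(r2_perm >= r2 - 1e-12)) / (1.0 + n_perm)
    return EnvFitVector(name=name, direction=direction, r2=r2, p=float(p))


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    col = data[term]
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(col.astype(str).unique())
        return np.column_stack(
            [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
    return col.to_numpy(dtype=float).reshape(-1, 1)


def permanova(
    D: pd.DataFrame,
    data: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential (Type-I) PERMANOVA of a dissimilarity matrix.

    Terms are added in the given order; each term's SS is the trace of
    its hat-matrix increment applied to the Gower-centred matrix, so the
    decomposition satisfies sum(R^2) + residual R^2 = 1 exactly.
    Categorical columns are dummy-coded; continuous ones enter as single
    columns. Returns a table with rows per term plus Residual and Total.
    """
    Dm = pd.DataFrame(D).to_numpy(dtype=float)
    n = len(Dm)
    if len(data) != n:
        raise ValueError("data rows must match the dissimilarity matrix")
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (Dm**2) @ J

    blocks = [np.ones((n, 1))]
    dfs = []
    for t in terms:
        cols = _term_columns(data, t)
        blocks.append(cols)
        dfs.append(cols.shape[1])
    Xfull = np.column_stack(blocks)
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        j = 1
        for i, t in enumerate(terms):
            j += dfs[i]
            if np.linalg.matrix_rank(Xfull[:, :j]) < j:
                raise ValueError(f"design is rank-deficient: term '{t}' is aliased")

    hats = []
    upto = blocks[0]
    H_prev = upto @ np.linalg.pinv(upto)
    for cols in blocks[1:]:
        upto = np.column_stack([upto, cols])
        Q, _ = np.linalg.qr(upto)
        H = Q @ Q.T
        hats.append(H - H_prev)
        H_prev = H
    resid_proj = np.eye(n) - H_prev

    def decompose(Gmat):
        ss_terms = np.array([float(np.sum(dH * Gmat)) for dH in hats])
        ss_res = float(np.sum(resid_proj * Gmat))
        return ss_terms, ss_res

    ss_terms, ss_res = decompose(G)
    ss_total = float(np.trace(G))
    df_terms = np.array(dfs, dtype=float)
    df_res = n - 1 - df_terms.sum()
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    F_obs = (ss_terms / df_terms) / (ss_res / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_t, ss_r = decompose(Gp)
        Fp = (ss_t / df_terms) / (ss_r / df_res)
        exceed += Fp >= F_obs - 1e-12
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for i, t in enumerate(terms):
        rows.append(
            {
                "term": t,
                "df": int(df_terms[i]),
                "SS": ss_terms[i],
                "pseudo_F": F_obs[i],
                "R2": ss_terms[i] / ss_total,
                "P": pvals[i],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": int(df_res),
            "SS": ss_res,
            "pseudo_F": np.nan,
            "R2": ss_res / ss_total,
            "P": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "pseudo_F": np.nan, "R2": 1.0, "P": np.nan}
    )
    return pd.DataFrame(rows).set_index("term")
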