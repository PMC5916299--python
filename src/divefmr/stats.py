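"""Population-level statistics linking at-sea energetics to diving behavior.

* principal-components regression of at-sea FMR on behavioral variables, with
  a strategy interaction and varimax-rotated loadings for interpretation,
* the Mantel permutation test between behavioral and energetic distance
  matrices (with explained-variance weighting of PC scores),
* Pearson correlations, and fixed-effects ANOVA (one- and two-factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "PCRegressionResult",
    "MantelResult",
    "varimax",
    "pc_regression",
    "weighted_score_distance",
    "mantel_test",
    "pearson_cor",
    "anova",
    "permutation_regression_pvalue",
]


# ---------------------------------------------------------------------------
# varimax
# ---------------------------------------------------------------------------

def varimax(
    loadings: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> np.ndarray:
    """Varimax rotation of a variables x k loading matrix (k >= 2).

    Orthogonal rotation maximizing the variance of squared loadings within
    each column (Kaiser's criterion), computed by the standard SVD iteration.
    Column signs are fixed so the largest-magnitude loading in each rotated
    column is positive. Raises on non-convergence.
    """
    L = np.asarray(loadings, dtype=float)
    p, k = L.shape
    if k < 2:
        raise ValueError("varimax needs at least 2 components")
    R = np.eye(k)
    d_old = 0.0
    for it in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        d_new = float(np.sum(s))
        if d_new < d_old * (1 + tol):
            break
        d_old = d_new
    else:
        raise RuntimeError(f"varimax did not converge in {max_iter} iterations")
    rotated = L @ R
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    return rotated * signs


def varimax_criterion(loadings: np.ndarray) -> float:
    """The varimax objective: sum over columns of the variance of squared loadings."""
    L2 = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(L2.var(axis=0)))


# ---------------------------------------------------------------------------
# principal-components regression
# ---------------------------------------------------------------------------

@dataclass
class PCRegressionResult:
    variable_names: list[str]
    explained_variance: np.ndarray  # proportion per component (all components)
    scores: np.ndarray  # animals x 2 (unrotated, used in the regressions)
    loadings_rotated: np.ndarray  # variables x 2, varimax for interpretation
    interaction_p: float
    fits: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def cumulative_variance_2pc(self) -> float:
        return float(self.explained_variance[:2].sum())


def _simple_fit(x: np.ndarray, y: np.ndarray) -> dict[str, float]:
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": int(len(x)),
    }


def pc_regression(
    behavior: pd.DataFrame,
    response: Sequence[float],
    strategy: Sequence[str],
    alpha: float = 0.05,
    rotate_scores: bool = False,
) -> PCRegressionResult:
    """Regress a per-animal response on principal components of behavior.

    The behavioral columns are standardized and decomposed by a
    correlation-matrix PCA; the first two components are retained. The
    component x strategy interaction is tested on PC1 (OLS t-test on the
    interaction coefficient); where significant at ``alpha``, per-strategy
    simple regressions on PC1 are fitted (each also reported when the
    interaction is not significant, alongside the pooled fit). PC2 is fitted
    pooled. Varimax-rotated loadings (of the unit-norm coefficient matrix)
    are reported for interpretation only; set ``rotate_scores`` to regress on
    rotated scores instead as a sensitivity option.
    """
    y = np.asarray(response, dtype=float)
    strategy = np.asarray(strategy)
    x = behavior.to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("complete cases only")
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    var_prop = s**2 / np.sum(s**2)
    coeffs = vt[:2].T
    signs = np.sign(coeffs[np.abs(coeffs).argmax(axis=0), np.arange(2)])
    coeffs = coeffs * signs
    scores = z @ coeffs
    rotated = varimax(vt[:2].T)
    if rotate_scores:
        scores = z @ rotated

    df = pd.DataFrame({"y": y, "pc1": scores[:, 0], "strategy": strategy})
    inter = smf.ols("y ~ pc1 * strategy", data=df).fit()
    inter_name = [n for n in inter.pvalues.index if ":" in n]
    interaction_p = float(inter.pvalues[inter_name].min()) if inter_name else np.nan

    result = PCRegressionResult(
        variable_names=list(behavior.columns),
        explained_variance=var_prop,
        scores=scores,
        loadings_rotated=rotated,
        interaction_p=interaction_p,
    )
    result.fits[("pc1", "all")] = _simple_fit(scores[:, 0], y)
    result.fits[("pc2", "all")] = _simple_fit(scores[:, 1], y)
    for group in np.unique(strategy):
        m = strategy == group
        if m.sum() < 3:
            result.flags.append(f"stratum {group}: fewer than 3 animals, fit skipped")
            continue
        fit = _simple_fit(scores[m, 0], y[m])
        if m.sum() < 5:
            fit["low_n"] = True
            result.flags.append(f"stratum {group}: low n ({int(m.sum())})")
        result.fits[("pc1", str(group))] = fit
    return result


def permutation_regression_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int = 999, seed: int = 0
) -> float:
    """One-sided permutation p-value for |r| of a simple regression slope."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    r_obs = abs(sps.pearsonr(x, y).statistic)
    count = 0
    for _ in range(n_perm):
        r = abs(sps.pearsonr(x, rng.permutation(y)).statistic)
        if r >= r_obs:
            count += 1
    return (count + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p_sim: float
    n_perm: int
    seed: int


def weighted_score_distance(scores: np.ndarray, explained: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix on PC scores weighted by explained variance.

    Each component is scaled by its explained-variance proportion before
    distances are taken, so dominant components dominate behavioral distance.
    """
    w = np.asarray(explained, dtype=float)
    x = np.asarray(scores, dtype=float) * w
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: Literal["greater", "two-sided"] = "greater",
) -> MantelResult:
    """Mantel permutation test between two distance matrices.

    The statistic is the Pearson correlation of the lower triangles; the null
    distribution comes from simultaneous row/column permutations of ``d2``.
    The p-value is (1 + #{r_perm >= r_obs}) / (n_perm + 1) for the one-sided
    (default) test.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.shape[0] != d1.shape[1]:
        raise ValueError("distance matrices must be square and of equal size")
    for name, d in (("d1", d1), ("d2", d2)):
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError(f"{name} must be symmetric with zero diagonal")
    n = d1.shape[0]
    tril = np.tril_indices(n, k=-1)
    v1 = d1[tril]
    r_obs = float(sps.pearsonr(v1, d2[tril]).statistic)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = sps.pearsonr(v1, d2[np.ix_(perm, perm)][tril]).statistic
        if alternative == "greater":
            hit = r >= r_obs
        else:
            hit = abs(r) >= abs(r_obs)
        count += bool(hit)
    return MantelResult(
        r=r_obs, p_sim=(count + 1) / (n_perm + 1), n_perm=n_perm, seed=seed
    )


# ---------------------------------------------------------------------------
# correlations and ANOVA
# ---------------------------------------------------------------------------

def pearson_cor(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def anova(
    values: Sequence[float],
    factors: Sequence[Sequence[str]] | Sequence[str],
    factor_names: Sequence[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Fixed-effects ANOVA with one or two factors.

    The two-factor model is additive (no interaction), Type-I sums of squares
    in the order the factors are given. Returns {term: {F, p, df, df_resid}}.
    Raises when a factor level (or a cell of the cross) is empty of data.
    """
    y = np.asarray(values, dtype=float)
    if isinstance(factors[0], str):
        factors = [factors]
    factors = [np.asarray(f) for f in factors]
    if factor_names is None:
        factor_names = [f"factor{i+1}" for i in range(len(factors))]
    for name, f in zip(factor_names, factors):
        if len(np.unique(f)) < 2:
            raise ValueError(f"{name}: need at least 2 levels")
    if len(factors) == 2:
        cells = pd.crosstab(factors[0], factors[1])
        if (cells == 0).any().any():
            empty = [
                (str(r), str(c))
                for r in cells.index
                for c in cells.columns
                if cells.loc[r, c] == 0
            ]
            raise ValueError(f"empty cell(s) in factor cross: {empty}")
    data = pd.DataFrame({"y": y})
    terms = []
    for name, f in zip(factor_names, factors):
        data[name] = f
        terms.append(f"C({name})")
    fit = smf.ols("y ~ " + " + ".join(terms), data=data).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    out: dict[str, dict[str, float]] = {}
    df_resid = float(table.loc["Residual", "df"])
    for name, term in zip(factor_names, terms):
        out[name] = {
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
            "df": float(table.loc[term, "df"]),
            "df_resid": df_resid,
        }
    return out
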