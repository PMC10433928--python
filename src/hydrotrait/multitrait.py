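"""Cross-species statistical layer.

Principal component analysis of the standardized trait matrix, OLS of
the drought-sensitivity slope on component scores, relative-importance
decomposition of R^2 (the LMG/Shapley average over regressor orderings,
implemented from first principles with bootstrap confidence intervals),
and Tukey-type multiple comparisons among species with a compact letter
display.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "RelImpResult",
    "GroupComparison",
    "pca",
    "regress_on_pcs",
    "lmg",
    "lmg_bootstrap",
    "tukey_compare",
    "fit_r2_model",
]


@dataclass(frozen=True)
class PCAResult:
    """PCA of centred, unit-variance traits.

    ``loadings`` is traits x components (orthonormal columns), ``scores``
    observations x components, and ``variance_fraction`` sums to 1.
    """

    traits: tuple[str, ...]
    loadings: np.ndarray
    scores: np.ndarray
    variance_fraction: np.ndarray


def pca(trait_matrix: pd.DataFrame) -> PCAResult:
    """Eigendecompose the trait correlation matrix.

    Columns are standardized (mean 0, sd 1, ddof 1); a constant column
    raises an error naming the trait.  Sign convention: within each
    component the largest-magnitude loading is positive, making results
    deterministic across linear-algebra backends.
    """
    if trait_matrix.isna().any().any():
        raise ValueError("trait matrix contains missing cells; impute first")
    if trait_matrix.shape[1] < 2:
        raise ValueError("need at least 2 traits")
    x = trait_matrix.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(
                f"trait {trait_matrix.columns[j]!r} is constant")
    z = (x - x.mean(axis=0)) / sd
    corr = (z.T @ z) / (z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.maximum(eigval[order], 0.0)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = z @ eigvec
    return PCAResult(tuple(trait_matrix.columns), eigvec, scores,
                     eigval / eigval.sum())


@dataclass(frozen=True)
class OLSSummary:
    params: np.ndarray
    pvalues: np.ndarray
    r2: float
    n: int
    names: tuple[str, ...]


def regress_on_pcs(response, pca_result: PCAResult,
                   k: int = 2) -> OLSSummary:
    """OLS of a response on the first ``k`` principal-component scores."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if k > pca_result.scores.shape[1]:
        raise ValueError(f"only {pca_result.scores.shape[1]} components "
                         "available")
    y = np.asarray(response, dtype=float)
    x = sm.add_constant(pca_result.scores[:, :k])
    fit = sm.OLS(y, x).fit()
    names = ("const",) + tuple(f"PC{i + 1}" for i in range(k))
    return OLSSummary(np.asarray(fit.params), np.asarray(fit.pvalues),
                      float(fit.rsquared), int(fit.nobs), names)


def _r2(y: np.ndarray, x: np.ndarray, cols: tuple[int, ...]) -> float:
    """Centred R^2 of y on the selected regressor columns."""
    if not cols:
        return 0.0
    design = np.column_stack([np.ones(y.size), x[:, cols]])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    return 1.0 - float(np.sum(resid ** 2)) / sst


@dataclass(frozen=True)
class RelImpResult:
    """LMG decomposition of R^2 with optional bootstrap intervals.

    ``shares[j]`` is regressor j's average incremental R^2 over all
    orderings of entry into the model; shares sum to the full-model R^2.
    """

    names: tuple[str, ...]
    shares: np.ndarray
    total_r2: float
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n_boot: int = 0


def lmg(response, regressors, names: tuple[str, ...] | None = None
        ) -> RelImpResult:
    """Average-over-orderings decomposition of R^2 (LMG / Shapley).

    For each regressor the incremental R^2 of adding it to every
    possible preceding set is averaged over all p! orderings.  Exact
    enumeration, p <= 8; subset R^2 values are cached so the cost is
    2^p least-squares fits.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if p > 8:
        raise ValueError("exact enumeration limited to 8 regressors")
    if y.size != n:
        raise ValueError("response and regressors disagree on n")
    full_design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(full_design) < p + 1:
        raise ValueError("regressor matrix is collinear to singularity")
    if names is None:
        names = tuple(f"x{j + 1}" for j in range(p))

    cache: dict[tuple[int, ...], float] = {}

    def r2_of(cols: tuple[int, ...]) -> float:
        key = tuple(sorted(cols))
        if key not in cache:
            cache[key] = _r2(y, x, key)
        return cache[key]

    shares = np.zeros(p)
    n_perm = math.factorial(p)
    for perm in itertools.permutations(range(p)):
        seen: tuple[int, ...] = ()
        for j in perm:
            shares[j] += r2_of(seen + (j,)) - r2_of(seen)
            seen = seen + (j,)
    shares /= n_perm
    return RelImpResult(names, shares, r2_of(tuple(range(p))))


def lmg_bootstrap(response, regressors, n_boot: int = 1000,
                  seed: int = 0,
                  names: tuple[str, ...] | None = None) -> RelImpResult:
    """Case-resampling bootstrap of the LMG shares.

    Percentile 95% intervals; resamples with fewer than p + 2 distinct
    rows (degenerate designs) are redrawn and the redraw count logged.
    """
    if n_boot < 100:
        raise ValueError("use at least 100 bootstrap runs")
    y = np.asarray(response, dtype=float)
    x = np.asarray(regressors, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    point = lmg(y, x, names)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, p))
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if np.unique(idx).size >= p + 2:
                try:
                    boot[b] = lmg(y[idx], x[idx]).shares
                    break
                except ValueError:
                    pass
            redraws += 1
    if redraws:
        logger.info("lmg_bootstrap: redrew %d degenerate resamples",
                    redraws)
    lo = np.percentile(boot, 2.5, axis=0)
    hi = np.percentile(boot, 97.5, axis=0)
    return RelImpResult(point.names, point.shares, point.total_r2,
                        lo, hi, n_boot)


@dataclass(frozen=True)
class GroupComparison:
    """One-way comparison of species means with Tukey adjustment."""

    groups: tuple[str, ...]
    means: np.ndarray
    se: np.ndarray
    n: np.ndarray
    pairwise: pd.DataFrame       # columns: group1, group2, q, p_adj
    letters: dict[str, str]
    transform: str = "none"


_TRANSFORMS = {"none": lambda v: v, "log": np.log, "sqrt": np.sqrt}


def tukey_compare(values, labels, alpha: float = 0.05,
                  transform: str = "none") -> GroupComparison:
    """All pairwise comparisons via the studentized range distribution.

    A one-way linear model supplies the pooled error variance;
    Tukey-Kramer standard errors handle unequal group sizes.  An
    optional pre-transformation (``"log"`` or ``"sqrt"``) is applied
    before fitting and recorded in the output.  Groups with a single
    value raise an error.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    v = _TRANSFORMS[transform](np.asarray(values, dtype=float))
    lab = np.asarray(labels)
    groups = tuple(pd.unique(lab))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    by = {g: v[lab == g] for g in groups}
    for g, arr in by.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    k = len(groups)
    ns = np.array([by[g].size for g in groups])
    means = np.array([by[g].mean() for g in groups])
    dfe = int(ns.sum() - k)
    mse = float(sum(np.sum((by[g] - by[g].mean()) ** 2)
                    for g in groups) / dfe)
    se = np.sqrt(mse / ns)

    pairs = list(itertools.combinations(range(k), 2))
    qs = np.empty(len(pairs))
    for idx, (i, j) in enumerate(pairs):
        # Tukey-Kramer: SE of the difference uses the harmonic form
        sed = math.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        qs[idx] = abs(means[i] - means[j]) / sed if sed > 0 else np.inf
    ps = np.minimum(stats.studentized_range.sf(qs, k, dfe), 1.0)
    pairwise = pd.DataFrame(
        [{"group1": groups[i], "group2": groups[j], "q": qs[idx],
          "p_adj": float(ps[idx])} for idx, (i, j) in enumerate(pairs)])
    letters = _compact_letters(groups, pairwise, alpha)
    return GroupComparison(groups, means, se, ns, pairwise, letters,
                           transform)


def _compact_letters(groups, pairwise: pd.DataFrame,
                     alpha: float) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Each letter marks a set of groups with no significant pairwise
    difference among them; groups sharing a letter are statistically
    indistinguishable at ``alpha``.  Ties are broken by group order.
    """
    distinct = {(r.group1, r.group2) for r in pairwise.itertuples()
                if r.p_adj < alpha}

    def differs(a, b):
        return (a, b) in distinct or (b, a) in distinct

    letter_sets: list[set] = [set(groups)]
    for g1, g2 in sorted(distinct):
        new_sets = []
        for s in letter_sets:
            if g1 in s and g2 in s:
                new_sets.extend([s - {g1}, s - {g2}])
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        letter_sets = [s for s in new_sets
                       if not any(s < t for t in new_sets)]
        # dedupe preserving order
        seen, unique = [], []
        for s in letter_sets:
            if s not in seen:
                seen.append(s)
                unique.append(s)
        letter_sets = unique
    letter_sets.sort(key=lambda s: [groups.index(g) for g in sorted(
        s, key=groups.index)])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, s in enumerate(letter_sets):
        for g in groups:
            if g in s:
                out[g] += alphabet[i]
    return out


@dataclass(frozen=True)
class R2ModelResult:
    """Two-predictor model of calibration quality with diagnostics."""

    params: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    n: int
    relimp: RelImpResult
    diagnostics: dict[str, float] = field(default_factory=dict)


def fit_r2_model(r2_values, hv, kplant, n_boot: int = 1000,
                 seed: int = 0) -> R2ModelResult:
    """Model per-tree calibration R^2 as a function of Hv and Kplant.

    Trees are pooled across species.  Returns the OLS fit, assumption
    diagnostics (Shapiro normality p of residuals, Breusch-Pagan
    heteroscedasticity p, design condition number) and the LMG shares of
    the two predictors with bootstrap confidence intervals.
    """
    y = np.asarray(r2_values, dtype=float)
    hv = np.asarray(hv, dtype=float)
    kp = np.asarray(kplant, dtype=float)
    if y.size < 6:
        raise ValueError("need at least 6 trees")
    x = np.column_stack([hv, kp])
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    resid = fit.resid
    shapiro_p = float(stats.shapiro(resid).pvalue)
    bp_p = float(het_breuschpagan(resid, design)[1])
    cond = float(np.linalg.cond(design))
    relimp = lmg_bootstrap(y, x, n_boot=n_boot, seed=seed,
                           names=("Hv", "Kplant"))
    names = ("const", "Hv", "Kplant")
    return R2ModelResult(
        params=dict(zip(names, map(float, fit.params))),
        pvalues=dict(zip(names, map(float, fit.pvalues))),
        r2=float(fit.rsquared), n=int(fit.nobs), relimp=relimp,
        diagnostics={"shapiro_p": shapiro_p, "breusch_pagan_p": bp_p,
                     "condition_number": cond})
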