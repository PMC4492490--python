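"""Covariate-set score test ("global test"), BH-FDR, Mann-Whitney, signs.

The score statistic for response y (length n) and covariate matrix X
(n x m) is

    S = (y~' X X' y~) / (m * sigma2),   y~ = y - mean(y),  sigma2 = y~'y~ / n,

with columns of X centred (and, by default, scaled to unit variance) before
use.  S asks whether the m covariates are *jointly* associated with y: it
is the average squared covariance between y~ and the covariate columns,
standardised by the response variance.  Inference is by permutation of y
(all n! rearrangements enumerated when n! is small enough, Monte Carlo
otherwise); a moment-matched scaled-chi-square approximation is available
for speed but the permutation null is the reference.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("mirdosage")

_REL_TOL = 1e-9  # tolerance for the ">= observed" tie convention


@dataclass(frozen=True)
class GlobalTestResult:
    statistic: float
    p_value: float
    method: str  # permutation | exact_enumeration | asymptotic
    n_permutations: int | None


def _as_response(y) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("response must have length >= 3")
    if not np.isfinite(y).all():
        raise ValueError("response contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("degenerate response: y is constant")
    return y


def _design(X, n: int, scale: bool) -> np.ndarray:
    """Centre (and optionally unit-scale) covariate columns.

    Constant columns carry no association signal; they are zeroed so they
    contribute 0 to the statistic while still counting in m.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows, response has length {n}")
    if X.shape[1] < 1:
        raise ValueError("X must have at least one column")
    if not np.isfinite(X).all():
        raise ValueError("covariates contain non-finite values")
    Z = X - X.mean(axis=0)
    if scale:
        sd = Z.std(axis=0)
        keep = sd > 0
        Z[:, keep] /= sd[keep]
        Z[:, ~keep] = 0.0
    return Z


def global_test_statistic(y, X, scale: bool = True) -> float:
    """Score statistic S = y~' X X' y~ / (m * sigma2).

    Invariant to adding a constant to y and to covariate column order.
    All-constant X yields 0 with a warning.
    """
    y = _as_response(y)
    n = y.size
    Z = _design(X, n, scale)
    m = Z.shape[1]
    if not Z.any():
        logger.warning("global test: all covariates constant; statistic is 0")
        return 0.0
    yc = y - y.mean()
    sigma2 = yc @ yc / n
    return float((Z.T @ yc) @ (Z.T @ yc) / (m * sigma2))


def _perm_statistics(yc: np.ndarray, Z: np.ndarray, idx: np.ndarray,
                     sigma2: float) -> np.ndarray:
    """Statistics for permuted responses yc[idx] (idx is B x n)."""
    M = yc[idx] @ Z  # (B, m)
    return np.einsum("ij,ij->i", M, M) / (Z.shape[1] * sigma2)


def draw_permutations(rng: np.random.Generator, B: int, n: int) -> np.ndarray:
    """B independent uniform permutations of range(n), as a (B, n) index array."""
    return np.argsort(rng.random((B, n)), axis=1)


def global_test_pvalue(y, X, B: int = 9_999,
                       seed: int | np.random.Generator | None = None,
                       scale: bool = True, exact_cap: int = 5_040,
                       method: str = "permutation",
                       perm_indices: np.ndarray | None = None) -> GlobalTestResult:
    """Global-test p-value for the joint association of X's columns with y.

    Permutation p uses the "as or more extreme" convention with the +1
    correction, p = (1 + #{S_perm >= S_obs}) / (B + 1); when n! <= exact_cap
    all n! permutations are enumerated instead and p = #{>=}/n!.
    ``perm_indices`` lets a caller share one drawn permutation set across
    many tests (same null; deterministic across features).
    """
    y = _as_response(y)
    n = y.size
    Z = _design(X, n, scale)
    yc = y - y.mean()
    sigma2 = yc @ yc / n
    m = Z.shape[1]
    if not Z.any():
        logger.warning("global test: all covariates constant; p = 1")
        return GlobalTestResult(0.0, 1.0, method, None)
    observed = float((Z.T @ yc) @ (Z.T @ yc) / (m * sigma2))
    cut = observed - _REL_TOL * max(1.0, abs(observed))

    if method == "asymptotic":
        return GlobalTestResult(observed, _satterthwaite_pvalue(observed, Z, n), "asymptotic", None)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")

    if perm_indices is None and math.factorial(n) <= exact_cap:
        idx = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        stats = _perm_statistics(yc, Z, idx, sigma2)
        p = float(np.mean(stats >= cut))
        return GlobalTestResult(observed, p, "exact_enumeration", int(idx.shape[0]))

    if perm_indices is None:
        if B < 99:
            raise ValueError("B must be >= 99")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        perm_indices = draw_permutations(rng, B, n)
    B = perm_indices.shape[0]
    stats = _perm_statistics(yc, Z, perm_indices, sigma2)
    p = (1.0 + int(np.sum(stats >= cut))) / (B + 1.0)
    return GlobalTestResult(observed, float(p), "permutation", B)


def _satterthwaite_pvalue(observed: float, Z: np.ndarray, n: int) -> float:
    """Moment-matched scaled chi-square null for S.

    Under an exchangeable Gaussian null, S ~ approx sum_i lambda_i chi2_1
    with lambda the eigenvalues of Z Z'/m, inflated by n/(n-1) for the
    plug-in variance estimate; matched to a * chi2_df.
    """
    m = Z.shape[1]
    K = Z @ Z.T / m
    lam = np.linalg.eigvalsh(K)
    lam = lam[lam > 1e-12 * lam.max()] * (n / (n - 1.0))
    a = float((lam ** 2).sum() / lam.sum())
    df = float(lam.sum() ** 2 / (lam ** 2).sum())
    return float(sps.chi2.sf(observed / a, df))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test (U for group_a, p).

    Exact enumeration when nA + nB <= 12 and the pooled data are untied;
    otherwise the tie-corrected normal approximation with continuity
    correction.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    untied = np.unique(pooled).size == pooled.size
    method = "exact" if (a.size + b.size <= 12 and untied) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def association_sign(y, t) -> str:
    """Sign of the Pearson correlation between a miRNA and one target.

    Exactly zero correlation maps to "positive" by convention (logged).
    """
    y = np.asarray(y, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if y.size != t.size or y.size < 3:
        raise ValueError("vectors must share a length >= 3")
    if np.ptp(y) == 0 or np.ptp(t) == 0:
        raise ValueError("constant vector: association sign undefined")
    r = float(np.corrcoef(y, t)[0, 1])
    if r == 0.0:
        logger.info("association_sign: zero correlation, reporting positive")
    return "negative" if r < 0 else "positive"
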