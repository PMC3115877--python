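"""Per-pair logistic interaction model and 1-df likelihood-ratio test.

For a pair of SNPs with additive genotype scores g1, g2 and binary disease
status Y the model is

    logit P(Y = 1) = b0 + b1*g1 + b2*g2 + b12*g1*g2

Epistasis between the two SNPs is assessed by testing H0: b12 = 0 with a
likelihood-ratio test: twice the difference between the maximized
log-likelihoods of the full model and the null model (which drops the
product term), referred to a chi-squared distribution with one degree of
freedom. Both models are maximized by Newton-Raphson (equivalently
iteratively reweighted least squares) from a zero start, in double
precision, with guards for separation and rank deficiency.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from .genotype_io import MISSING

# fitted probabilities are clamped away from {0, 1}; hitting a clamp bound or
# a coefficient beyond the guard flags separation rather than returning a
# silently diverged fit
PROB_CLAMP = 1e-10
BETA_GUARD = 30.0

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 25

STATUS_CONVERGED = "converged"
STATUS_MAX_ITER = "max_iter"
STATUS_SEPARATED = "separated"
STATUS_SINGULAR = "singular"

# ordering used to propagate the "worse" of two fit statuses
_STATUS_RANK = {
    STATUS_CONVERGED: 0,
    STATUS_MAX_ITER: 1,
    STATUS_SEPARATED: 2,
    STATUS_SINGULAR: 3,
}


class EmptyDesignError(ValueError):
    """Raised when no individual has complete data for a SNP pair."""


@dataclasses.dataclass
class PairModelFit:
    """Result of one Newton logistic fit.

    Attributes
    ----------
    beta : ndarray
        Coefficients on the log-odds scale, ordered as the design columns
        (intercept, g1, g2[, g1*g2]).
    loglik : float
        Maximized Bernoulli log-likelihood (natural log).
    n_used : int
        Individuals entering the fit after complete-case exclusion.
    iterations : int
        Newton steps taken.
    status : str
        One of converged / max_iter / separated / singular.
    """

    beta: np.ndarray
    loglik: float
    n_used: int
    iterations: int
    status: str


@dataclasses.dataclass
class InteractionResult:
    """Interaction test outcome for one unordered SNP pair."""

    snp1_id: str
    snp2_id: str
    gene1: str
    gene2: str
    lrt_stat: float | None
    p_value: float | None
    maf1: float
    maf2: float
    n_used: int
    status: str


def worse_status(a: str, b: str) -> str:
    """The less healthy of two fit statuses (converged < max_iter < separated < singular)."""
    return a if _STATUS_RANK[a] >= _STATUS_RANK[b] else b


def build_pair_design(
    g1: np.ndarray,
    g2: np.ndarray,
    y: np.ndarray,
    with_interaction: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Complete-case design matrix for one SNP pair.

    Individuals missing a genotype at either SNP are dropped. Columns are
    ``[1, g1, g2]``, plus ``g1*g2`` when *with_interaction* is set.

    Returns
    -------
    (X, y_used, n_used)

    Raises
    ------
    EmptyDesignError
        If no individual has complete data at both SNPs.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    y = np.asarray(y)
    if not (g1.shape == g2.shape == y.shape):
        raise ValueError("g1, g2 and y must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    n_used = int(ok.sum())
    if n_used == 0:
        raise EmptyDesignError("no complete cases for this SNP pair")
    a = g1[ok].astype(np.float64)
    b = g2[ok].astype(np.float64)
    cols = [np.ones(n_used), a, b]
    if with_interaction:
        cols.append(a * b)
    return np.column_stack(cols), y[ok].astype(np.float64), n_used


def log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log-likelihood with logit link, overflow-safe.

    Uses sum(y*eta - log(1 + exp(eta))) with eta = X @ beta, evaluated via
    ``logaddexp`` so saturated linear predictors contribute 0 or -|eta|
    without overflow.
    """
    eta = X @ np.asarray(beta, dtype=np.float64)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> PairModelFit:
    """Maximize the logistic log-likelihood by Newton-Raphson from a zero start.

    Convergence is declared when the log-likelihood change between successive
    iterations is below *tol*, or the largest coefficient update is below
    *tol*. The fit is flagged ``separated`` when any fitted probability hits
    the clamp bounds or a coefficient magnitude exceeds the divergence guard,
    and ``singular`` when the weighted normal-equations matrix is numerically
    rank-deficient. An all-0 or all-1 response yields ``separated`` (the
    intercept diverges), never an exception.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    beta = np.zeros(p)
    ll = log_likelihood(beta, X, y)
    total = y.sum()
    if total == 0 or total == n:
        # constant response: the intercept MLE diverges, a degenerate separation
        return PairModelFit(
            beta=beta, loglik=ll, n_used=n, iterations=0, status=STATUS_SEPARATED
        )
    status = STATUS_MAX_ITER
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        if np.any(mu <= PROB_CLAMP) or np.any(mu >= 1.0 - PROB_CLAMP):
            status = STATUS_SEPARATED
            break
        w = mu * (1.0 - mu)
        xtwx = X.T @ (X * w[:, None])
        sv = np.linalg.svd(xtwx, compute_uv=False)
        if sv[-1] <= sv[0] * 1e-12 or sv[0] == 0.0:
            status = STATUS_SINGULAR
            break
        delta = np.linalg.solve(xtwx, X.T @ (y - mu))
        beta = beta + delta
        if np.max(np.abs(beta)) > BETA_GUARD:
            status = STATUS_SEPARATED
            break
        new_ll = log_likelihood(beta, X, y)
        if abs(new_ll - ll) < tol or np.max(np.abs(delta)) < tol:
            ll = new_ll
            status = STATUS_CONVERGED
            break
        ll = new_ll
    return PairModelFit(beta=beta, loglik=ll, n_used=n, iterations=it, status=status)


def chi2_sf_1df(x: float) -> float:
    """Upper-tail probability P(chi2_1 >= x); monotone nonincreasing, in (0, 1]."""
    if x < 0:
        raise ValueError(f"chi-squared statistic must be nonnegative, got {x}")
    return float(chi2.sf(x, df=1))


def _n_distinct_genotypes(g: np.ndarray) -> int:
    # observed genotype values are in {0,1,2}; bincount beats unique at scan scale
    counts = np.bincount(g.astype(np.int64), minlength=3)
    return int(np.count_nonzero(counts))


def lrt_pair(
    g1: np.ndarray,
    g2: np.ndarray,
    y: np.ndarray,
    *,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    snp1_id: str = "snp1",
    snp2_id: str = "snp2",
    gene1: str = "",
    gene2: str = "",
    maf1: float = float("nan"),
    maf2: float = float("nan"),
) -> InteractionResult:
    """Likelihood-ratio test of the interaction coefficient for one SNP pair.

    The null model (intercept, g1, g2) and the full model (adding g1*g2) are
    fitted on the same complete-case rows; the statistic is
    ``2 * (loglik_full - loglik_null)``, clamped at zero (finite solver
    tolerance can leave a tiny negative difference), and referred to
    chi-squared with one degree of freedom. The result's status is the worse
    of the two fits; a non-converged status carries no statistic or p-value.
    A SNP with fewer than two distinct observed genotypes among the complete
    cases makes the pair ``singular`` without fitting.
    """
    X_full, y_used, n_used = build_pair_design(g1, g2, y, with_interaction=True)
    result = InteractionResult(
        snp1_id=snp1_id,
        snp2_id=snp2_id,
        gene1=gene1,
        gene2=gene2,
        lrt_stat=None,
        p_value=None,
        maf1=maf1,
        maf2=maf2,
        n_used=n_used,
        status=STATUS_SINGULAR,
    )
    if (
        _n_distinct_genotypes(X_full[:, 1]) < 2
        or _n_distinct_genotypes(X_full[:, 2]) < 2
    ):
        return result
    fit_null = fit_logistic(X_full[:, :3], y_used, tol=tol, max_iter=max_iter)
    fit_full = fit_logistic(X_full, y_used, tol=tol, max_iter=max_iter)
    status = worse_status(fit_null.status, fit_full.status)
    result.status = status
    if status == STATUS_CONVERGED:
        stat = max(0.0, 2.0 * (fit_full.loglik - fit_null.loglik))
        result.lrt_stat = stat
        result.p_value = chi2_sf_1df(stat)
    return result
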