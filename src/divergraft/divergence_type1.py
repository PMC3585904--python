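"""Type-I (heterotachy) functional-divergence detection.

A site's paired substitution counts (x, y) in the two clusters are modeled
as a two-component mixture.  Under the null component a single gamma-
distributed rate lambda ~ Gamma(shape=alpha, rate=alpha) (mean 1) is shared
by both clusters, with x | lambda ~ Poisson(D_A * lambda) and
y | lambda ~ Poisson(D_B * lambda); integrating lambda out gives a bivariate
negative-binomial-like closed form.  Under the divergent (Type-I) component
the two clusters draw *independent* gamma rates, giving a product of
negative-binomial marginals.  The mixture weight theta is the coefficient
of functional divergence — the proportion of sites whose rates are
uncorrelated between the clusters — and each site's posterior probability
(PP) of belonging to the divergent component is the per-site heterotachy
score.  D_A and D_B (expected substitutions per site per cluster, on the
tree-depth scale) are set by method of moments: E[count] = D.

Direction calls ("slow in A / fast in B" etc.) compare the per-cluster
posterior-mean rates under the divergent component with a configurable
ratio threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "Type1Model",
    "Type1SiteResult",
    "f_null",
    "f_div",
    "fit_type1",
    "type1_posteriors",
    "polarize",
]

_THETA_STARTS = (0.05, 0.3, 0.6)
_ALPHA_STARTS = (0.3, 1.0, 3.0)
_THETA_BOUNDS = (1e-6, 1.0 - 1e-6)
_ALPHA_BOUNDS = (1e-3, 1e3)


@dataclass
class Type1Model:
    """Fitted mixture: theta (divergent fraction), alpha (gamma shape),
    D_A / D_B (expected substitutions per site per cluster)."""

    theta: float
    alpha: float
    D_A: float
    D_B: float
    log_likelihood: float
    log_likelihood_null: float  # profile at theta = 0, same (alpha, D)
    n_sites: int
    converged: bool = True


@dataclass
class Type1SiteResult:
    site: int  # 1-based alignment column
    x_A: int
    x_B: int
    pp: float  # posterior probability of Type-I divergence; NaN if flagged
    rate_A: float
    rate_B: float
    direction: str  # slow_A_fast_B | slow_B_fast_A | unpolarized


def _check_params(alpha: float, D_A: float, D_B: float) -> None:
    if not (alpha > 0 and np.isfinite(alpha)):
        raise ValueError(f"alpha must be positive and finite, got {alpha}")
    if not (D_A > 0 and D_B > 0):
        raise ValueError(f"D_A and D_B must be positive, got {D_A}, {D_B}")


def log_f_null(x, y, alpha: float, D_A: float, D_B: float):
    """Log joint probability of counts under a shared gamma rate.

    Closed form: Gamma(a+x+y)/(Gamma(a) x! y!) * (a/s)^a * (D_A/s)^x *
    (D_B/s)^y with s = a + D_A + D_B.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s = alpha + D_A + D_B
    return (
        gammaln(alpha + x + y)
        - gammaln(alpha)
        - gammaln(x + 1)
        - gammaln(y + 1)
        + alpha * np.log(alpha / s)
        + x * np.log(D_A / s)
        + y * np.log(D_B / s)
    )


def log_f_div(x, y, alpha: float, D_A: float, D_B: float):
    """Log joint probability under independent per-cluster gamma rates:
    a product of negative-binomial marginals NB(shape=alpha, p=alpha/(alpha+D))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def lnb(k, D):
        return (
            gammaln(alpha + k)
            - gammaln(alpha)
            - gammaln(k + 1)
            + alpha * np.log(alpha / (alpha + D))
            + k * np.log(D / (alpha + D))
        )

    return lnb(x, D_A) + lnb(y, D_B)


def f_null(x, y, alpha: float, D_A: float, D_B: float):
    """Probability of (x, y) under the shared-rate (null) component."""
    _check_params(alpha, D_A, D_B)
    return np.exp(log_f_null(x, y, alpha, D_A, D_B))


def f_div(x, y, alpha: float, D_A: float, D_B: float):
    """Probability of (x, y) under the independent-rates (Type-I) component."""
    _check_params(alpha, D_A, D_B)
    return np.exp(log_f_div(x, y, alpha, D_A, D_B))


def _mixture_loglik(theta, alpha, x, y, w, D_A, D_B):
    ln = log_f_null(x, y, alpha, D_A, D_B)
    ld = log_f_div(x, y, alpha, D_A, D_B)
    # log[(1-theta) e^ln + theta e^ld], stable via logaddexp
    a = np.log1p(-theta) + ln
    b = np.log(theta) + ld if theta > 0 else np.full_like(ld, -np.inf)
    return float(np.sum(w * np.logaddexp(a, b)))


def fit_type1(count_table, min_sites_warn: int = 50) -> Type1Model:
    """Fit (theta, alpha) by bounded ML with multi-start; D by moments.

    Flagged sites are excluded.  Deterministic: the start grid is fixed and
    L-BFGS-B is run from every start, keeping the best optimum.
    """
    _, x_all, y_all = count_table.unflagged()
    n = len(x_all)
    if n == 0:
        raise ValueError("no unflagged sites to fit")
    if n < min_sites_warn:
        warnings.warn(f"only {n} unflagged sites; estimates may be unstable")
    D_A = float(np.mean(x_all))
    D_B = float(np.mean(y_all))
    if D_A == 0 or D_B == 0:
        raise ValueError("no signal: all counts are zero in one cluster")

    # aggregate identical (x, y) pairs: likelihood evals become O(#unique)
    pairs, w = np.unique(np.column_stack([x_all, y_all]), axis=0, return_counts=True)
    x, y = pairs[:, 0].astype(float), pairs[:, 1].astype(float)
    w = w.astype(float)

    def neg(params):
        theta, log_alpha = params
        return -_mixture_loglik(theta, np.exp(log_alpha), x, y, w, D_A, D_B)

    best = None
    for t0 in _THETA_STARTS:
        for a0 in _ALPHA_STARTS:
            res = minimize(
                neg,
                x0=[t0, np.log(a0)],
                method="L-BFGS-B",
                bounds=[_THETA_BOUNDS, (np.log(_ALPHA_BOUNDS[0]), np.log(_ALPHA_BOUNDS[1]))],
            )
            if best is None or res.fun < best.fun:
                best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("Type-I mixture optimizer failed to converge")
    theta_hat = float(best.x[0])
    alpha_hat = float(np.exp(best.x[1]))
    ll = -float(best.fun)
    # profile at theta -> 0 with the same alpha (null nested model)
    ll0_candidates = []
    for a0 in _ALPHA_STARTS:
        r0 = minimize(
            lambda p: -_mixture_loglik(0.0, np.exp(p[0]), x, y, w, D_A, D_B),
            x0=[np.log(a0)],
            method="L-BFGS-B",
            bounds=[(np.log(_ALPHA_BOUNDS[0]), np.log(_ALPHA_BOUNDS[1]))],
        )
        ll0_candidates.append(-float(r0.fun))
    ll0 = max(ll0_candidates)
    return Type1Model(
        theta=theta_hat,
        alpha=alpha_hat,
        D_A=D_A,
        D_B=D_B,
        log_likelihood=ll,
        log_likelihood_null=ll0,
        n_sites=n,
        converged=bool(best.success),
    )


def site_pp(x, y, model: Type1Model):
    """Posterior probability of Type-I divergence for counts (x, y)."""
    if model.theta == 0:
        return np.zeros_like(np.asarray(x, dtype=float))
    ln = log_f_null(x, y, model.alpha, model.D_A, model.D_B)
    ld = log_f_div(x, y, model.alpha, model.D_A, model.D_B)
    a = np.log1p(-model.theta) + ln
    b = np.log(model.theta) + ld
    return np.exp(b - np.logaddexp(a, b))


def type1_posteriors(
    count_table, model: Type1Model, polarize_ratio: float = 2.0
) -> list[Type1SiteResult]:
    """Per-site PP, posterior-mean rates, and direction calls for all sites.

    Flagged sites get pp = NaN and direction ``unpolarized``; they are
    excluded from variant designs downstream.
    """
    results: list[Type1SiteResult] = []
    pps = site_pp(count_table.x_A, count_table.x_B, model)
    for i in range(count_table.n_sites):
        xa, xb = int(count_table.x_A[i]), int(count_table.x_B[i])
        rate_A = (model.alpha + xa) / (model.alpha + model.D_A)
        rate_B = (model.alpha + xb) / (model.alpha + model.D_B)
        if count_table.flagged[i]:
            results.append(
                Type1SiteResult(i + 1, xa, xb, float("nan"), rate_A, rate_B, "unpolarized")
            )
            continue
        res = Type1SiteResult(
            site=i + 1, x_A=xa, x_B=xb, pp=float(pps[i]),
            rate_A=rate_A, rate_B=rate_B, direction="unpolarized",
        )
        res.direction = polarize(res, ratio=polarize_ratio)
        results.append(res)
    return results


def polarize(site_result: Type1SiteResult, ratio: float = 2.0) -> str:
    """Direction call: which cluster is the slow (conserved) one.

    ``slow_A_fast_B`` iff rate_B >= ratio * rate_A; the reciprocal for
    ``slow_B_fast_A``; otherwise ``unpolarized``.
    """
    if ratio <= 1:
        raise ValueError("polarization ratio must exceed 1")
    if site_result.rate_B >= ratio * site_result.rate_A:
        return "slow_A_fast_B"
    if site_result.rate_A >= ratio * site_result.rate_B:
        return "slow_B_fast_A"
    return "unpolarized"


def write_type1_table(path, results: list[Type1SiteResult], labels=("A", "B")) -> None:
    """TSV dump: site, x_A, x_B, pp, rate_A, rate_B, direction."""
    la, lb = labels
    with open(path, "w") as fh:
        fh.write(f"site\tx_{la}\tx_{lb}\tpp\trate_{la}\trate_{lb}\tdirection\n")
        for r in results:
            fh.write(
                f"{r.site}\t{r.x_A}\t{r.x_B}\t{r.pp:.6f}\t"
                f"{r.rate_A:.6f}\t{r.rate_B:.6f}\t{r.direction}\n"
            )


def read_type1_table(path) -> list[Type1SiteResult]:
    """Read back a TSV written by :func:`write_type1_table`."""
    import csv

    out: list[Type1SiteResult] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)
        for row in reader:
            out.append(
                Type1SiteResult(
                    site=int(row[0]), x_A=int(row[1]), x_B=int(row[2]),
                    pp=float(row[3]), rate_A=float(row[4]), rate_B=float(row[5]),
                    direction=row[6],
                )
            )
    return out
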