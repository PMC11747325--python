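"""Gamma-Poisson shrinkage (MGPS) for report-count disproportionality.

The observed count of each drug–event pair, ``a_i``, is modelled as
Poisson(lambda_i * E_i) where ``E_i`` is the count expected under
independence and the relative reporting rate ``lambda_i`` is drawn from a
two-component gamma mixture prior,

    lambda ~ w * Gamma(alpha1, beta1) + (1 - w) * Gamma(alpha2, beta2)

(shape/rate parameterization). Marginally ``a_i`` is then a mixture of
negative binomials, and the prior hyperparameters are fitted by EM over all
screened terms: the E-step computes component responsibilities, the M-step
maximizes each component's weighted negative-binomial likelihood
numerically. The posterior of ``lambda_i`` is again a gamma mixture, giving

* ``EBGM_i = exp(E[ln lambda_i | a_i])`` — the posterior geometric mean of
  the shrunk observed/expected ratio, and
* ``EB05_i`` — its 5th percentile, by numerical inversion of the posterior
  mixture CDF.

Shrinkage pulls small-count ratios toward the prior mass near 1, which is
what distinguishes EBGM from the raw a/E ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

__all__ = ["GammaMixture", "fit_gamma_mixture_em", "posterior_ebgm",
           "posterior_quantile", "marginal_loglik", "simulate_counts"]


@dataclass(frozen=True)
class GammaMixture:
    """Two-component gamma prior (shape alpha, rate beta; weight w on comp 1)."""

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    w: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha1, self.beta1, self.alpha2, self.beta2,
                         self.w])


def _nb_logpmf(a, alpha, beta, E):
    """log P(a) for lambda~Gamma(alpha, beta), a|lambda~Poisson(lambda E)."""
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    p = beta / (beta + E)
    return (special.gammaln(alpha + a) - special.gammaln(alpha)
            - special.gammaln(a + 1) + alpha * np.log(p)
            + a * np.log1p(-p))


def _component_logliks(a, E, prior: GammaMixture):
    l1 = _nb_logpmf(a, prior.alpha1, prior.beta1, E) + np.log(prior.w)
    l2 = _nb_logpmf(a, prior.alpha2, prior.beta2, E) + np.log1p(-prior.w)
    return l1, l2


def marginal_loglik(a, E, prior: GammaMixture) -> float:
    l1, l2 = _component_logliks(a, E, prior)
    return float(np.logaddexp(l1, l2).sum())


# log alpha / log beta kept within +-15: wide enough for any realistic
# concentration, narrow enough that gammaln(alpha + a) - gammaln(alpha)
# stays numerically accurate (it degrades catastrophically near 1e15)
_LOG_BOUND = 15.0


def _maximize_component(a, E, resp, alpha0, beta0):
    """Weighted single-component negative-binomial ML in (log alpha, log beta)."""
    a = np.asarray(a, dtype=float)

    def neg(theta):
        alpha, beta = np.exp(theta)
        return -float(np.dot(resp, _nb_logpmf(a, alpha, beta, E)))

    x0 = np.clip(np.log([alpha0, beta0]), -_LOG_BOUND, _LOG_BOUND)
    res = optimize.minimize(neg, x0, method="Nelder-Mead",
                            bounds=[(-_LOG_BOUND, _LOG_BOUND)] * 2,
                            options={"xatol": 1e-6, "fatol": 1e-9,
                                     "maxiter": 400})
    alpha, beta = np.exp(res.x)
    return float(alpha), float(beta)


def fit_gamma_mixture_em(a, E, init: GammaMixture | None = None,
                         max_iter: int = 200, tol: float = 1e-7):
    """Fit the mixture prior by EM over all (count, expected) pairs.

    Returns ``(prior, converged, loglik)``. Non-convergence after
    ``max_iter`` iterations returns the last iterate with ``converged``
    False so callers can fall back to the simplified estimator.
    """
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    if a.shape != E.shape or a.size == 0:
        raise ValueError("a and E must be equal-length, non-empty")
    if init is None:
        # component 1 near the null ratio 1, component 2 spread over signals
        ratio = (a + 0.5) / (E + 0.5)
        hi = max(np.quantile(ratio, 0.9), 2.0)
        init = GammaMixture(alpha1=2.0, beta1=2.0, alpha2=2.0,
                            beta2=2.0 / hi, w=0.7)
    prior = init
    last = -np.inf
    converged = False
    for _ in range(max_iter):
        l1, l2 = _component_logliks(a, E, prior)
        total = np.logaddexp(l1, l2)
        resp1 = np.exp(l1 - total)
        w = float(np.clip(resp1.mean(), 1e-6, 1 - 1e-6))
        alpha1, beta1 = _maximize_component(a, E, resp1, prior.alpha1,
                                            prior.beta1)
        alpha2, beta2 = _maximize_component(a, E, 1.0 - resp1, prior.alpha2,
                                            prior.beta2)
        prior = GammaMixture(alpha1, beta1, alpha2, beta2, w)
        loglik = marginal_loglik(a, E, prior)
        if abs(loglik - last) < tol * (1 + abs(loglik)):
            converged = True
            break
        last = loglik
    return prior, converged, marginal_loglik(a, E, prior)


def _posterior_pieces(a, E, prior: GammaMixture):
    a = np.asarray(a, dtype=float)
    E = np.asarray(E, dtype=float)
    l1, l2 = _component_logliks(a, E, prior)
    total = np.logaddexp(l1, l2)
    q1 = np.exp(l1 - total)
    shapes = (prior.alpha1 + a, prior.alpha2 + a)
    rates = (prior.beta1 + E, prior.beta2 + E)
    return q1, shapes, rates


def posterior_ebgm(a, E, prior: GammaMixture) -> np.ndarray:
    """exp(E[ln lambda | a]) per term (posterior geometric mean)."""
    q1, (s1, s2), (r1, r2) = _posterior_pieces(a, E, prior)
    mean_log = (q1 * (special.digamma(s1) - np.log(r1))
                + (1 - q1) * (special.digamma(s2) - np.log(r2)))
    return np.exp(mean_log)


def posterior_quantile(a, E, prior: GammaMixture, q: float = 0.05) -> np.ndarray:
    """Posterior lambda quantile per term by inverting the mixture CDF."""
    q1, (s1, s2), (r1, r2) = _posterior_pieces(a, E, prior)
    out = np.empty(np.shape(q1))
    flat = [np.ravel(x) for x in (q1, s1, s2, r1, r2)]
    res = np.ravel(out)
    for i, (w1, a1, a2, b1, b2) in enumerate(zip(*flat)):
        lo = min(stats.gamma.ppf(q / 4, a1, scale=1 / b1),
                 stats.gamma.ppf(q / 4, a2, scale=1 / b2))
        hi = max(stats.gamma.ppf(1 - (1 - q) / 4, a1, scale=1 / b1),
                 stats.gamma.ppf(1 - (1 - q) / 4, a2, scale=1 / b2))

        def cdf(x):
            return (w1 * stats.gamma.cdf(x, a1, scale=1 / b1)
                    + (1 - w1) * stats.gamma.cdf(x, a2, scale=1 / b2) - q)

        res[i] = optimize.brentq(cdf, lo, hi, xtol=1e-10, rtol=1e-10)
    return out


def simulate_counts(n_terms: int, prior: GammaMixture, rng,
                    e_low: float = 5.0, e_high: float = 200.0):
    """Draw (a, E, component) triples from the model, for calibration checks."""
    E = np.exp(rng.uniform(np.log(e_low), np.log(e_high), n_terms))
    comp1 = rng.random(n_terms) < prior.w
    lam = np.where(comp1,
                   rng.gamma(prior.alpha1, 1 / prior.beta1, n_terms),
                   rng.gamma(prior.alpha2, 1 / prior.beta2, n_terms))
    a = rng.poisson(lam * E)
    return a, E, comp1
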