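"""Zero-inflated negative binomial (ZINB) primitives.

The ZINB distribution is used twice in this package: as the count model of
the synthetic-data generator and as the reconstruction likelihood of the
macrogene autoencoder. Parameterization: mean ``mu > 0``, inverse-dispersion
("size") ``theta > 0`` and structural-zero probability ``pi in [0, 1)``:

    P(X = 0) = pi + (1 - pi) * NB(0 | mu, theta)
    P(X = x) = (1 - pi) * NB(x | mu, theta)          for x >= 1

with ``Var[NB] = mu + mu^2 / theta``, so ``theta -> inf`` recovers Poisson.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

__all__ = ["sample_zinb", "zinb_nll", "zinb_nll_grad", "zinb_nll_and_grad"]

_EPS = 1e-12


def _check_params(mean, dispersion, dropout):
    mean = np.asarray(mean, dtype=float)
    dispersion = np.asarray(dispersion, dtype=float)
    dropout = np.asarray(dropout, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("ZINB mean must be positive")
    if np.any(dispersion <= 0):
        raise ValueError("ZINB dispersion must be positive")
    if np.any((dropout < 0) | (dropout > 1)):
        raise ValueError("ZINB dropout must lie in [0, 1]")
    return mean, dispersion, dropout


def sample_zinb(mean, dispersion, dropout, n=None, seed=None, rng=None):
    """Draw ZINB counts.

    Parameters broadcast against each other; ``n`` (when given with scalar
    parameters) requests that many i.i.d. draws. Either ``seed`` or an
    existing ``numpy.random.Generator`` may be supplied.
    """
    mean, dispersion, dropout = _check_params(mean, dispersion, dropout)
    if rng is None:
        rng = np.random.default_rng(seed)
    if n is not None:
        shape = (int(n),) + np.broadcast_shapes(mean.shape, dispersion.shape, dropout.shape)
    else:
        shape = np.broadcast_shapes(mean.shape, dispersion.shape, dropout.shape)
    if np.prod(shape, dtype=int) == 0:
        return np.zeros(shape, dtype=np.int64)
    # NB as gamma-Poisson mixture; structural zeros masked on top.
    lam = rng.gamma(shape=np.broadcast_to(dispersion, shape),
                    scale=np.broadcast_to(mean / dispersion, shape))
    x = rng.poisson(lam)
    drop = rng.random(shape) < np.broadcast_to(dropout, shape)
    x = np.where(drop, 0, x)
    return x.astype(np.int64)


def _nb_logpmf(x, mu, theta):
    return (gammaln(x + theta) - gammaln(theta) - gammaln(x + 1.0)
            + theta * (np.log(theta) - np.log(theta + mu))
            + x * (np.log(mu) - np.log(theta + mu)))


def zinb_nll(x, mean, dispersion, dropout, reduce="sum"):
    """Negative log-likelihood of counts ``x`` under ZINB.

    ``dropout`` must lie in [0, 1); ``reduce`` is one of {"sum", "mean",
    "none"}.
    """
    x = np.asarray(x, dtype=float)
    mu, theta, pi = _check_params(mean, dispersion, dropout)
    if np.any(pi >= 1.0):
        raise ValueError("ZINB dropout must be < 1 for a finite likelihood")
    mu, theta, pi = np.broadcast_arrays(*np.broadcast_arrays(mu, theta, pi))
    log_nb = _nb_logpmf(x, mu, theta)
    # zeros: log(pi + (1-pi) * NB(0)) computed stably via logaddexp
    log_p0 = np.logaddexp(np.log(pi + _EPS), np.log1p(-pi) + _nb_logpmf(0.0, mu, theta))
    ll = np.where(x == 0, log_p0, np.log1p(-pi) + log_nb)
    nll = -ll
    if reduce == "sum":
        return float(np.sum(nll))
    if reduce == "mean":
        return float(np.mean(nll))
    if reduce == "none":
        return nll
    raise ValueError(f"unknown reduce mode {reduce!r}")


def zinb_nll_grad(x, mean, dispersion, dropout):
    """Elementwise gradients of the per-entry NLL w.r.t. (mean, theta, pi).

    Returns arrays broadcast to the shape of the per-entry NLL; used by the
    macrogene autoencoder's hand-written backward pass and verified against
    finite differences in the test suite.
    """
    x = np.asarray(x, dtype=float)
    mu, theta, pi = _check_params(mean, dispersion, dropout)
    if np.any(pi >= 1.0):
        raise ValueError("ZINB dropout must be < 1")
    mu, theta, pi, x = np.broadcast_arrays(mu, theta, pi, x)
    mu = mu.astype(float)
    theta = theta.astype(float)
    pi = pi.astype(float)

    tm = theta + mu
    # positive-count branch: NLL = -log(1-pi) - logNB(x)
    d_mu_pos = -(x / mu - (x + theta) / tm)
    d_theta_pos = -(digamma(x + theta) - digamma(theta)
                    + np.log(theta) - np.log(tm) + 1.0 - (x + theta) / tm)
    d_pi_pos = 1.0 / (1.0 - pi)

    # zero branch: NLL = -log(pi + (1-pi) p0), p0 = (theta/tm)^theta
    log_p0 = theta * (np.log(theta) - np.log(tm))
    p0 = np.exp(log_p0)
    mix = pi + (1.0 - pi) * p0 + _EPS
    d_mu_zero = (1.0 - pi) * p0 * (theta / tm) / mix
    d_theta_zero = -(1.0 - pi) * p0 * (np.log(theta) - np.log(tm) + mu / tm) / mix
    d_pi_zero = -(1.0 - p0) / mix

    is_zero = x == 0
    d_mu = np.where(is_zero, d_mu_zero, d_mu_pos)
    d_theta = np.where(is_zero, d_theta_zero, d_theta_pos)
    d_pi = np.where(is_zero, d_pi_zero, d_pi_pos)
    return d_mu, d_theta, d_pi


def zinb_nll_and_grad(x, mu, theta, pi, lgamma_x1=None):
    """Total NLL plus elementwise gradients, sharing intermediates.

    Hot path of the autoencoder training loop: ``mu`` is (cells x genes),
    ``theta``/``pi`` are per-gene row vectors, and ``lgamma_x1`` may cache
    ``gammaln(x + 1)`` across steps. Equivalent to ``zinb_nll(...,
    reduce="sum")`` plus ``zinb_nll_grad``.
    """
    x = np.asarray(x, dtype=float)
    if lgamma_x1 is None:
        lgamma_x1 = gammaln(x + 1.0)
    log_theta = np.log(theta)
    tm = theta + mu
    log_tm = np.log(tm)
    log_ratio = log_theta - log_tm          # log(theta / (theta+mu))
    log_p0 = theta * log_ratio
    is_zero = x == 0
    xt = x + theta

    log_nb = (gammaln(xt) - gammaln(theta) - lgamma_x1
              + log_p0 + x * (np.log(np.where(is_zero, 1.0, mu)) - log_tm))
    log1m_pi = np.log1p(-pi)
    log_mix = np.logaddexp(np.log(pi + _EPS), log1m_pi + log_p0)
    nll = float(np.sum(np.where(is_zero, -log_mix, -(log1m_pi + log_nb))))

    inv_tm = 1.0 / tm
    d_mu_pos = -(x / np.where(is_zero, 1.0, mu) - xt * inv_tm)
    dig_theta = digamma(theta)
    d_theta_pos = -(digamma(xt) - dig_theta + log_ratio + 1.0 - xt * inv_tm)
    d_pi_pos = 1.0 / (1.0 - pi)

    p0 = np.exp(log_p0)
    mix = pi + (1.0 - pi) * p0 + _EPS
    inv_mix = 1.0 / mix
    d_mu_zero = (1.0 - pi) * p0 * theta * inv_tm * inv_mix
    d_theta_zero = -(1.0 - pi) * p0 * (log_ratio + mu * inv_tm) * inv_mix
    d_pi_zero = -(1.0 - p0) * inv_mix

    d_mu = np.where(is_zero, d_mu_zero, d_mu_pos)
    d_theta = np.where(is_zero, d_theta_zero, d_theta_pos)
    d_pi = np.where(is_zero, d_pi_zero, d_pi_pos)
    return nll, d_mu, d_theta, d_pi
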