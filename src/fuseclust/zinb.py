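"""Zero-inflated negative binomial likelihood for scRNA-seq counts.

The observation model for a count x is a mixture of a point mass at zero
(a technical "dropout" with probability pi) and a negative binomial with
mean mu and dispersion theta:

    P(x) = pi * [x == 0] + (1 - pi) * NB(x | mu, theta)
    NB(x | mu, theta) = Gamma(x + theta) / (Gamma(x + 1) Gamma(theta))
                        * (theta / (theta + mu))^theta * (mu / (theta + mu))^x

As theta -> infinity the NB component approaches Poisson(mu).  The training
loss is the mean negative log-likelihood over all matrix entries; the mean
(rather than sum) keeps the multi-objective balance factors scale-free.

Two parallel implementations are provided: plain numpy (`zinb_log_prob`,
`zinb_nll`) for evaluation and testing, and an autograd version
(`zinb_nll_tensor`) used inside the training loop.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

from ._autograd import Tensor, gammaln, logaddexp

__all__ = [
    "PI_MIN", "PI_MAX", "THETA_MIN", "THETA_MAX", "MU_MIN", "MU_MAX",
    "clamp_params", "zinb_log_prob", "zinb_nll", "zinb_nll_tensor",
]

# numerical stabilisation bounds for the distribution parameters
PI_MIN, PI_MAX = 1e-6, 1.0 - 1e-6
THETA_MIN, THETA_MAX = 1e-4, 1e6
MU_MIN, MU_MAX = 1e-6, 1e6


def clamp_params(pi, mu, theta):
    pi = np.clip(pi, PI_MIN, PI_MAX)
    mu = np.clip(mu, MU_MIN, MU_MAX)
    theta = np.clip(theta, THETA_MIN, THETA_MAX)
    return pi, mu, theta


def zinb_log_prob(x, mu, theta, pi):
    """Elementwise log P_ZINB(x | pi, mu, theta); numpy arrays or scalars.

    The x = 0 branch is evaluated with log-sum-exp so a tiny NB zero
    probability cannot underflow the mixture.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    pi, mu, theta = clamp_params(np.asarray(pi, float), np.asarray(mu, float),
                                 np.asarray(theta, float))
    log_theta_frac = theta * (np.log(theta) - np.log(theta + mu))
    log_nb = (
        _sp.gammaln(x + theta) - _sp.gammaln(theta) - _sp.gammaln(x + 1.0)
        + log_theta_frac + x * (np.log(mu) - np.log(theta + mu))
    )
    zero_case = np.logaddexp(np.log(pi), np.log1p(-pi) + log_theta_frac)
    nonzero_case = np.log1p(-pi) + log_nb
    out = np.where(x == 0, zero_case, nonzero_case)
    return out if out.ndim else float(out)


def zinb_nll(r_prime, pi, mu, theta) -> float:
    """Mean negative log-likelihood over all entries of a count matrix."""
    lp = zinb_log_prob(r_prime, mu, theta, pi)
    if not np.all(np.isfinite(lp)):
        bad = np.argwhere(~np.isfinite(np.atleast_2d(lp)))
        raise FloatingPointError(f"non-finite ZINB log-likelihood at entries {bad[:5]}")
    return float(-np.mean(lp))


def zinb_nll_tensor(x: np.ndarray, pi: Tensor, mu: Tensor, theta: Tensor) -> Tensor:
    """Autograd version of :func:`zinb_nll`; ``x`` is a constant count matrix."""
    x = np.asarray(x, dtype=np.float64)
    pi = pi.clip(PI_MIN, PI_MAX)
    mu = mu.clip(MU_MIN, MU_MAX)
    theta = theta.clip(THETA_MIN, THETA_MAX)

    log_pi = pi.log()
    log_1mpi = (1.0 - pi).log()
    log_theta_frac = theta * (theta.log() - (theta + mu).log())
    log_nb = (
        gammaln(theta + x) - gammaln(theta) - Tensor(_sp.gammaln(x + 1.0))
        + log_theta_frac + x * (mu.log() - (theta + mu).log())
    )
    zero_case = logaddexp(log_pi, log_1mpi + log_theta_frac)
    nonzero_case = log_1mpi + log_nb
    mask0 = (x == 0).astype(np.float64)
    ll = mask0 * zero_case + (1.0 - mask0) * nonzero_case
    return -ll.mean()
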