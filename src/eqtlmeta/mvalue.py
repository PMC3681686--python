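"""m-values: posterior probabilities that an eQTL effect exists per tissue.

A meta-analysis p-value says whether an effect exists *somewhere*; it cannot
say in which tissues.  The m-value of tissue i is the posterior probability
that the effect is present in tissue i, obtained by exact Bayesian model
averaging over all 2^t binary *configurations* c (c_i = 1 iff tissue i has an
effect):

    m_i = sum_{c : c_i = 1} P(B | c) P(c)  /  sum_c P(B | c) P(c)

with B the observed (independent) effect estimates.  The configuration prior
is exchangeable, induced by a Beta(alpha, beta) prior on the proportion of
tissues with an effect:

    P(c) = B(n1 + alpha, n0 + beta) / B(alpha, beta)

(alpha = beta = 1 by default, i.e. uniform over the effect proportion).  Given
a configuration, tissues without an effect contribute the null density
N(beta_i; 0, se_i^2); tissues with an effect share a common true effect mu
with prior N(0, sigma_prior2), integrated out analytically, which yields the
density of their precision-weighted mean times an explicit scaling factor.

Calls use the conventional 0.9 / 0.1 thresholds: m > 0.9 predicts the effect
is present, m < 0.1 predicts it is absent, anything else is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.special import betaln, logsumexp

__all__ = [
    "MValueConfig",
    "MValueResult",
    "config_prior",
    "config_likelihood",
    "mvalues",
    "classify_effects",
]

PRESENT = "present"
ABSENT = "absent"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MValueConfig:
    """Prior settings for m-value computation.

    sigma_prior2 is the prior variance of the (standardized-scale) effect
    size; the default 0.04 corresponds to a prior sd of 0.2, the conventional
    moderate-effect prior for association studies.
    """

    alpha: float = 1.0
    beta: float = 1.0
    sigma_prior2: float = 0.04
    enumeration_limit: int = 20

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta-prior parameters must be positive")
        if self.sigma_prior2 <= 0:
            raise ValueError("sigma_prior2 must be positive")


@dataclass
class MValueResult:
    m: np.ndarray
    call: tuple[str, ...]
    config_posteriors: dict[tuple[int, ...], float] = field(repr=False)


def config_prior(c, cfg: MValueConfig = MValueConfig()) -> float:
    """Exchangeable prior mass of one binary configuration."""
    c = np.atleast_1d(np.asarray(c, dtype=int))
    if c.size == 0:
        raise ValueError("configuration must be nonempty")
    if not np.isin(c, (0, 1)).all():
        raise ValueError("configuration entries must be 0 or 1")
    n1 = int(c.sum())
    n0 = c.size - n1
    return float(
        np.exp(betaln(n1 + cfg.alpha, n0 + cfg.beta) - betaln(cfg.alpha, cfg.beta))
    )


def _log_normal_pdf(x: np.ndarray, var: np.ndarray) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + x**2 / var)


def _log_config_likelihood(
    beta: np.ndarray, v: np.ndarray, c: np.ndarray, sigma_prior2: float
) -> float:
    """log P(B | c): null densities for c_i = 0; integrated common effect
    (scaling factor times the density of the precision-weighted mean under
    N(0, pooled variance + sigma_prior2)) for c_i = 1."""
    null_idx = c == 0
    alt_idx = c == 1
    out = float(np.sum(_log_normal_pdf(beta[null_idx], v[null_idx])))
    if alt_idx.any():
        w = 1.0 / v[alt_idx]
        w_sum = float(np.sum(w))
        mean = float(np.sum(w * beta[alt_idx]) / w_sum)
        # scaling factor from integrating the shared effect analytically
        log_scale = (
            float(np.sum(_log_normal_pdf(beta[alt_idx], v[alt_idx])))
            + 0.5 * np.log(2.0 * np.pi / w_sum)
            + 0.5 * w_sum * mean**2
        )
        out += log_scale + float(
            _log_normal_pdf(np.asarray(mean), np.asarray(1.0 / w_sum + sigma_prior2))
        )
    return out


def config_likelihood(
    beta, se, c, cfg: MValueConfig = MValueConfig()
) -> float:
    """Density of the observed estimates under one configuration, P(B | c)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    c = np.atleast_1d(np.asarray(c, dtype=int))
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    if beta.shape != se.shape or beta.shape != c.shape:
        raise ValueError("beta, se and c must have equal length")
    return float(np.exp(_log_config_likelihood(beta, se**2, c, cfg.sigma_prior2)))


def mvalues(beta, se, cfg: MValueConfig = MValueConfig()) -> MValueResult:
    """Exact posterior effect-existence probabilities by full enumeration.

    Enumerates all 2^t configurations (t capped by ``cfg.enumeration_limit``);
    log-space accumulation keeps tiny tail densities stable.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    se = np.atleast_1d(np.asarray(se, dtype=float))
    if beta.shape != se.shape or beta.ndim != 1:
        raise ValueError("beta and se must be 1-D arrays of equal length")
    if np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    t = beta.size
    if t > cfg.enumeration_limit:
        raise ValueError(
            f"{t} tissues exceed the exact enumeration limit "
            f"({cfg.enumeration_limit}); reduce the tissue set"
        )
    v = se**2
    configs = list(product((0, 1), repeat=t))
    log_weights = np.empty(len(configs))
    for idx, c in enumerate(configs):
        carr = np.asarray(c, dtype=int)
        log_prior = betaln(carr.sum() + cfg.alpha, t - carr.sum() + cfg.beta) - betaln(
            cfg.alpha, cfg.beta
        )
        log_weights[idx] = log_prior + _log_config_likelihood(
            beta, v, carr, cfg.sigma_prior2
        )
    log_total = logsumexp(log_weights)
    post = np.exp(log_weights - log_total)
    m = np.zeros(t)
    for idx, c in enumerate(configs):
        for i in range(t):
            if c[i]:
                m[i] += post[idx]
    m = np.clip(m, 0.0, 1.0)
    return MValueResult(
        m=m,
        call=classify_effects(m),
        config_posteriors={c: float(p) for c, p in zip(configs, post)},
    )


def classify_effects(m, hi: float = 0.9, lo: float = 0.1) -> tuple[str, ...]:
    """Threshold posterior probabilities into present/absent/ambiguous calls.

    Strict inequalities: m exactly at a threshold stays ambiguous.
    """
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("thresholds must satisfy 0 <= lo < hi <= 1")
    m = np.atleast_1d(np.asarray(m, dtype=float))
    calls = []
    for mi in m:
        if mi > hi:
            calls.append(PRESENT)
        elif mi < lo:
            calls.append(ABSENT)
        else:
            calls.append(AMBIGUOUS)
    return tuple(calls)
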