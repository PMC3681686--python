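"""Tissue-by-tissue baseline: per-tissue simple regression with an F-test.

Each tissue is analyzed on its own with the additive linear model
``y = mu + beta * x + e`` and the F-test of ``beta = 0`` (equivalently the
two-sided t-test; F = t^2 with (1, n-2) degrees of freedom).  A SNP/probe
pair is declared an eQTL if any tissue's p-value falls below the per-tissue
Bonferroni threshold ``alpha_meta / t``, which matches the overall false
positive rate of a meta-analysis test run at ``alpha_meta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datamodel import ExpressionMatrix, GenotypeVector, TissueSampleMap

__all__ = ["TissueFit", "fit_single_tissue", "tbt_scan", "tbt_fits_for_probe"]

#: smallest reported p-value; a perfect fit's p underflows to this floor
P_FLOOR = 1e-300


@dataclass(frozen=True)
class TissueFit:
    """Single-tissue regression summary for one SNP/probe pair."""

    tissue_id: str
    beta: float
    se: float
    t_stat: float
    F: float
    df: int
    p: float


def fit_single_tissue(y, x, tissue_id: str = "") -> TissueFit:
    """OLS slope of expression on dosage with the exact F/t test.

    Requires n >= 3 (one residual degree of freedom) and non-constant
    dosages.  A perfect fit has zero residual variance; its p-value is
    reported at the 1e-300 floor and F as infinity.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    n = y.size
    if n < 3:
        raise ValueError("at least 3 samples are required per tissue")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("dosages are constant; the slope is not identifiable")
    yc = y - y.mean()
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    df = n - 2
    rss = float(resid @ resid)
    if rss <= 0:
        # perfect fit: zero residual variance; report the p floor and F = inf
        tiny_se = float(np.sqrt(np.finfo(float).tiny))
        return TissueFit(
            tissue_id=tissue_id, beta=beta, se=tiny_se,
            t_stat=np.inf if beta != 0 else 0.0, F=np.inf, df=df, p=P_FLOOR,
        )
    sigma2 = rss / df
    se = float(np.sqrt(sigma2 / sxx))
    t_stat = beta / se
    F = t_stat**2
    p = float(max(stats.f.sf(F, 1, df), P_FLOOR))
    return TissueFit(
        tissue_id=tissue_id, beta=beta, se=se, t_stat=t_stat, F=F, df=df, p=p
    )


def tbt_fits_for_probe(
    expr: Sequence[ExpressionMatrix],
    geno: GenotypeVector,
    maps: Sequence[TissueSampleMap],
    probe: str,
) -> list[TissueFit]:
    """Fit every tissue separately for one SNP/probe pair."""
    fits = []
    for em, m in zip(expr, maps):
        y = em.probe_row(probe)
        x = geno.values_for(m.sample_ids)
        fits.append(fit_single_tissue(y, x, tissue_id=m.tissue_id))
    return fits


def tbt_scan(
    fits_by_pair: dict[tuple[str, str], Sequence[TissueFit]],
    alpha_meta: float,
) -> dict[tuple[str, str], dict]:
    """Call eQTLs from per-tissue fits at the Bonferroni-matched threshold.

    ``fits_by_pair`` maps (snp_id, probe_id) to that pair's per-tissue fits.
    A pair is significant when its smallest per-tissue p-value falls below
    ``alpha_meta / t``; the same per-tissue threshold drives the p-value-based
    presence calls.
    """
    if not (0.0 < alpha_meta < 1.0):
        raise ValueError("alpha_meta must lie in (0, 1)")
    out: dict[tuple[str, str], dict] = {}
    for pair, fits in fits_by_pair.items():
        t = len(fits)
        threshold = alpha_meta / t
        pvals = np.array([f.p for f in fits])
        out[pair] = {
            "significant": bool(np.min(pvals) < threshold),
            "threshold": threshold,
            "tissue_present": tuple(bool(p < threshold) for p in pvals),
            "min_p": float(np.min(pvals)),
        }
    return out
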