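"""End-to-end analysis of one SNP/probe pair across tissues.

The full pipeline for a pair is:

1. standardize each tissue's probe row (mean 0, unit variance);
2. single-tissue regressions (the tissue-by-tissue baseline, also feeding
   the error correction);
3. variance-component estimation on the stacked design (per-probe mode fits
   the null design without dosage columns once and reuses the components for
   every SNP; per-SNP mode refits under the full design);
4. GLS per-tissue effects and covariance under the fitted V;
5. marginal error correction (t -> normal quantile matching against the
   single-tissue fits; optional);
6. decorrelation into independent-style (beta, se);
7. fixed-effects / random-effects / traditional random-effects meta-analysis
   with Cochran's Q and I2;
8. m-values with present/absent/ambiguous calls.

`TissueLayout` caches everything that depends only on which individuals
contributed which tissue (the sharing matrix and its eigendecomposition, the
intercept block), so scanning many SNPs and probes over a fixed cohort stays
cheap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import mvalue as mv
from .datamodel import (
    ExpressionMatrix,
    GenotypeVector,
    TissueSampleMap,
    build_sharing_matrix,
    standardize_expression,
)
from .meta_analysis import MetaResult, Re2NullTable, meta_analyze
from .mixed_model import (
    EffectEstimates,
    SpectralKernel,
    VarianceComponents,
    decorrelate,
    estimate_variance_components,
    marginal_error_correction,
)
from .tbt import TissueFit, fit_single_tissue

__all__ = ["AnalysisConfig", "PairAnalysis", "TissueLayout", "analyze_pair"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the per-pair pipeline."""

    df_correction: bool = True
    per_snp_components: bool = False
    mvalue_config: mv.MValueConfig = field(default_factory=mv.MValueConfig)
    mvalue_hi: float = 0.9
    mvalue_lo: float = 0.1
    re2_null: Re2NullTable | None = None
    compute_mvalues: bool = True


@dataclass
class PairAnalysis:
    """Everything the pipeline computes for one SNP/probe pair."""

    snp_id: str
    probe_id: str
    tissue_ids: tuple[str, ...]
    tissue_fits: list[TissueFit]
    components: VarianceComponents
    effects: EffectEstimates          # GLS, after optional error correction
    decorrelated: EffectEstimates
    meta: MetaResult
    mvalues: mv.MValueResult | None


class TissueLayout:
    """Precomputed structure for a fixed assignment of samples to tissues."""

    def __init__(self, maps: Sequence[TissueSampleMap]):
        self.maps = list(maps)
        self.tissue_ids = tuple(m.tissue_id for m in self.maps)
        self.sizes = np.array([m.n_samples for m in self.maps])
        self.n_obs = int(self.sizes.sum())
        self.n_tissues = len(self.maps)
        self.K = build_sharing_matrix(self.maps).astype(float)
        self.kernel = SpectralKernel(self.K)
        t = self.n_tissues
        self.intercept_block = np.zeros((self.n_obs, t))
        offsets = np.concatenate([[0], np.cumsum(self.sizes)])
        self._offsets = offsets
        for j in range(t):
            self.intercept_block[offsets[j] : offsets[j + 1], j] = 1.0

    def stack_tissue_vectors(self, per_tissue: Sequence[np.ndarray]) -> np.ndarray:
        return np.concatenate([np.asarray(v, dtype=float) for v in per_tissue])

    def snp_block(self, dosage_per_tissue: Sequence[np.ndarray]) -> np.ndarray:
        Z = np.zeros((self.n_obs, self.n_tissues))
        for j, d in enumerate(dosage_per_tissue):
            Z[self._offsets[j] : self._offsets[j + 1], j] = d
        return Z

    # -- fast spectral-space GLS --------------------------------------------

    def _gls_spectral(
        self, y: np.ndarray, X: np.ndarray, comps: VarianceComponents
    ) -> EffectEstimates:
        yt = self.kernel.rotate(y)
        Xt = self.kernel.rotate(X)
        d = comps.sigma_g2 * self.kernel.eigenvalues + comps.sigma_e2
        w = 1.0 / d
        A = Xt.T @ (Xt * w[:, None])
        A_inv = np.linalg.inv(A)
        full_beta = A_inv @ (Xt.T @ (yt * w))
        t = self.n_tissues
        cov = A_inv[t:, t:]
        return EffectEstimates(
            beta=full_beta[t:],
            cov=cov,
            se=np.sqrt(np.diag(cov)),
            decorrelated=False,
            intercepts=full_beta[:t],
        )

    def analyze(
        self,
        y_per_tissue: Sequence[np.ndarray],
        dosage_per_tissue: Sequence[np.ndarray],
        cfg: AnalysisConfig = AnalysisConfig(),
        *,
        snp_id: str = "snp",
        probe_id: str = "probe",
        standardize: bool = True,
        components: VarianceComponents | None = None,
    ) -> PairAnalysis:
        """Run the pipeline on already-extracted per-tissue vectors.

        ``components`` short-circuits the variance-component fit (used when
        scanning many SNPs against one probe in per-probe mode).
        """
        ys = []
        for v in y_per_tissue:
            v = np.asarray(v, dtype=float)
            if standardize:
                sd = v.std(ddof=1)
                if sd <= 1e-12:
                    raise ValueError("zero-variance expression cannot be analyzed")
                v = (v - v.mean()) / sd
            ys.append(v)

        fits = [
            fit_single_tissue(yv, dv, tissue_id=tid)
            for yv, dv, tid in zip(ys, dosage_per_tissue, self.tissue_ids)
        ]

        y = self.stack_tissue_vectors(ys)
        Z = self.snp_block(dosage_per_tissue)
        X_full = np.hstack([self.intercept_block, Z])
        if components is None:
            X_vc = X_full if cfg.per_snp_components else self.intercept_block
            components = estimate_variance_components(y, X_vc, kernel=self.kernel)

        effects = self._gls_spectral(y, X_full, components)
        if cfg.df_correction:
            effects = marginal_error_correction(effects, fits)
        try:
            decorrelated = decorrelate(effects)
        except ValueError:
            # the un-correlated construction is undefined when some inverse
            # row sum of the effect covariance is non-positive (possible on
            # small noisy designs); fall back to the marginal variances,
            # i.e. treat the estimates as independent
            logging.getLogger(__name__).warning(
                "un-correlated variances undefined for %s/%s; "
                "falling back to marginal variances", snp_id, probe_id,
            )
            decorrelated = EffectEstimates(
                beta=effects.beta.copy(),
                cov=effects.cov.copy(),
                se=np.sqrt(np.diag(effects.cov)),
                decorrelated=True,
                intercepts=effects.intercepts,
            )
        meta = meta_analyze(decorrelated.beta, decorrelated.se, cfg.re2_null)
        mres = None
        if cfg.compute_mvalues:
            mres = mv.mvalues(decorrelated.beta, decorrelated.se, cfg.mvalue_config)
            mres = mv.MValueResult(
                m=mres.m,
                call=mv.classify_effects(mres.m, cfg.mvalue_hi, cfg.mvalue_lo),
                config_posteriors=mres.config_posteriors,
            )
        return PairAnalysis(
            snp_id=snp_id,
            probe_id=probe_id,
            tissue_ids=self.tissue_ids,
            tissue_fits=fits,
            components=components,
            effects=effects,
            decorrelated=decorrelated,
            meta=meta,
            mvalues=mres,
        )

    def fit_null_components(self, y_per_tissue: Sequence[np.ndarray],
                            standardize: bool = True) -> VarianceComponents:
        """Per-probe variance components under the intercept-only design."""
        ys = []
        for v in y_per_tissue:
            v = np.asarray(v, dtype=float)
            if standardize:
                v = (v - v.mean()) / v.std(ddof=1)
            ys.append(v)
        y = self.stack_tissue_vectors(ys)
        return estimate_variance_components(
            y, self.intercept_block, kernel=self.kernel
        )


def analyze_pair(
    expr: Sequence[ExpressionMatrix],
    geno: GenotypeVector,
    maps: Sequence[TissueSampleMap],
    probe: str,
    cfg: AnalysisConfig = AnalysisConfig(),
    *,
    layout: TissueLayout | None = None,
    standardize: bool = True,
) -> PairAnalysis:
    """Convenience wrapper taking the datamodel containers directly."""
    if layout is None:
        layout = TissueLayout(maps)
    ys = [em.probe_row(probe) for em in expr]
    dosages = [geno.values_for(m.sample_ids) for m in maps]
    return layout.analyze(
        ys, dosages, cfg,
        snp_id=geno.snp_id, probe_id=probe, standardize=standardize,
    )
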