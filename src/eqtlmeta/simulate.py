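"""Synthetic multi-tissue eQTL data and the simulation experiments.

The generative model draws one probe's stacked expression from

    y ~ MVN(0, sigma_g2 * K + sigma_e2 * I)

where K is the individual-sharing matrix of the study design (the same
individual's measurements in different tissues share a random effect), then
adds ``effect_size * dosage`` to the tissues in which the simulated eQTL has
an effect.  Genotypes are Binomial(2, maf) dosages per individual.

Study conditions follow the repeated-measures design the power analysis
assumes: 100 individuals, four tissues all collected from every individual,
minor allele frequency 30%, and four scenarios with an effect in 1, 2, 3 or
all 4 tissues.  The variance coefficients default to sigma_g2 = 0.3 and
sigma_e2 = 0.7 (an across-tissue correlation of 0.3 on the standardized
scale) as stand-ins for averaged real-data components; scenario effect sizes
(0.8, 0.7, 0.7, 0.5) were calibrated once so the leading method lands
mid-range power (~0.5-0.6) at the default genome-wide-style threshold of
1e-5.

Three experiments are provided:

* ``run_power_experiment`` — detection power of TBT / FE / RE2 / DL over
  replicate eQTLs, with I2 summaries per scenario;
* ``run_calibration_experiment`` — type-I error of the full pipeline versus a
  naive meta-analysis that skips the mixed model, under null data with shared
  individuals;
* ``split_permute_experiment`` — splits one real-style tissue into pseudo-
  tissues, destroys the effect in a chosen subset by permutation, and measures
  how many gold-standard eQTLs each method recovers and how accurately the
  m-value and p-value rules predict the per-tissue effect pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .datamodel import (
    ExpressionMatrix,
    GenotypeVector,
    TissueSampleMap,
    row_individual_indicator,
)
from .meta_analysis import Re2NullTable
from .mvalue import ABSENT, PRESENT
from .pipeline import AnalysisConfig, TissueLayout
from .tbt import fit_single_tissue

__all__ = [
    "SimulationSpec",
    "make_tissue_maps",
    "simulate_genotypes",
    "simulate_expression",
    "run_power_experiment",
    "run_calibration_experiment",
    "split_permute_experiment",
    "SCENARIO_EFFECT_SIZES",
]

#: default variance coefficients (standardized-expression scale)
DEFAULT_SIGMA_G2 = 0.3
DEFAULT_SIGMA_E2 = 0.7
#: per-scenario SNP effects for 1, 2, 3, 4 effect tissues (see module docstring)
SCENARIO_EFFECT_SIZES = {1: 0.8, 2: 0.7, 3: 0.7, 4: 0.5}
#: default meta-analysis significance threshold of the power experiment
DEFAULT_POWER_ALPHA = 1e-5


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions of one simulated multi-tissue eQTL experiment."""

    n_individuals: int = 100
    n_tissues: int = 4
    maf: float = 0.3
    sigma_g2: float = DEFAULT_SIGMA_G2
    sigma_e2: float = DEFAULT_SIGMA_E2
    effect_size: float = 0.0
    effect_tissues: frozenset[int] = frozenset()
    sharing: str | float = "full"
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.sigma_g2 < 0 or self.sigma_e2 <= 0:
            raise ValueError("variance coefficients must be sigma_g2 >= 0, sigma_e2 > 0")
        object.__setattr__(self, "effect_tissues", frozenset(self.effect_tissues))
        if any(t < 0 or t >= self.n_tissues for t in self.effect_tissues):
            raise ValueError("effect_tissues must index existing tissues")
        if isinstance(self.sharing, str):
            if self.sharing not in ("full", "none"):
                raise ValueError("sharing must be 'full', 'none' or a fraction")
        elif not (0.0 <= float(self.sharing) <= 1.0):
            raise ValueError("sharing fraction must lie in [0, 1]")


def make_tissue_maps(
    n_individuals: int, n_tissues: int, sharing: str | float = "full"
) -> list[TissueSampleMap]:
    """Sample maps for the requested sharing regime.

    ``full``: every individual contributes every tissue.  ``none``: tissues
    have disjoint individuals.  A fraction f: the first round(f * n)
    individuals contribute all tissues, the rest are unique per tissue
    (emulating partially-overlapping cohorts such as 34% or 11% sharing).
    """
    if sharing == "full":
        shared = n_individuals
    elif sharing == "none":
        shared = 0
    else:
        shared = int(round(float(sharing) * n_individuals))
    maps = []
    for t in range(n_tissues):
        ids = [f"I{i:04d}" for i in range(shared)]
        ids += [f"T{t}_I{i:04d}" for i in range(shared, n_individuals)]
        maps.append(TissueSampleMap(tissue_id=f"tissue{t + 1}", sample_ids=tuple(ids)))
    return maps


def simulate_genotypes(
    n: int, maf: float, seed_or_rng, sample_ids: Sequence[str] | None = None,
    snp_id: str = "snp1",
) -> GenotypeVector:
    """Binomial(2, maf) allele dosages per individual, reproducible by seed."""
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    dosages = rng.binomial(2, maf, size=n).astype(float)
    if sample_ids is None:
        sample_ids = [f"I{i:04d}" for i in range(n)]
    return GenotypeVector(snp_id=snp_id, dosage=dict(zip(sample_ids, dosages)))


def _stacked_null_draws(
    rng: np.random.Generator,
    M: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    n_draws: int,
) -> np.ndarray:
    """Draws from MVN(0, sigma_g2 * M M' + sigma_e2 * I), shape (n_draws, N).

    Sampled exactly as individual effects plus residual noise, which is the
    factorized form of the covariance (K = M M').
    """
    n_ind = M.shape[1]
    g = rng.normal(scale=np.sqrt(sigma_g2), size=(n_draws, n_ind))
    e = rng.normal(scale=np.sqrt(sigma_e2), size=(n_draws, M.shape[0]))
    return g @ M.T + e


def simulate_expression(
    spec: SimulationSpec,
    geno: GenotypeVector,
    maps: Sequence[TissueSampleMap] | None = None,
    rng: np.random.Generator | None = None,
) -> list[ExpressionMatrix]:
    """Generate expression for all replicates (one probe row per replicate).

    Returns one :class:`ExpressionMatrix` per tissue whose probe rows
    ``rep0001 ...`` are independent draws from the generative model, with the
    SNP effect added in ``spec.effect_tissues``.
    """
    if maps is None:
        maps = make_tissue_maps(spec.n_individuals, spec.n_tissues, spec.sharing)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    M = row_individual_indicator(maps)
    y = _stacked_null_draws(rng, M, spec.sigma_g2, spec.sigma_e2, spec.n_replicates)
    sizes = [m.n_samples for m in maps]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    for t in spec.effect_tissues:
        dos = geno.values_for(maps[t].sample_ids)
        y[:, offsets[t] : offsets[t + 1]] += spec.effect_size * dos
    probe_ids = tuple(f"rep{r + 1:04d}" for r in range(spec.n_replicates))
    out = []
    for t, m in enumerate(maps):
        out.append(
            ExpressionMatrix(
                tissue_id=m.tissue_id,
                probe_ids=probe_ids,
                sample_ids=m.sample_ids,
                values=y[:, offsets[t] : offsets[t + 1]],
            )
        )
    return out


def _nonconstant_dosages(
    rng: np.random.Generator, n: int, maf: float
) -> np.ndarray:
    """Binomial dosages, redrawn in the (vanishingly rare) all-equal case."""
    for _ in range(1000):
        d = rng.binomial(2, maf, size=n).astype(float)
        if d.min() != d.max():
            return d
    raise RuntimeError("could not draw a polymorphic genotype vector")


def _replicate_pipeline(
    spec: SimulationSpec,
    cfg: AnalysisConfig,
    collect_naive: bool = False,
    collect_mvalues: bool = False,
):
    """Yield per-replicate analysis results (generator shared by experiments)."""
    maps = make_tissue_maps(spec.n_individuals, spec.n_tissues, spec.sharing)
    layout = TissueLayout(maps)
    M = row_individual_indicator(maps)
    rng = np.random.default_rng(spec.seed)
    sizes = [m.n_samples for m in maps]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    cfg = AnalysisConfig(
        df_correction=cfg.df_correction,
        per_snp_components=cfg.per_snp_components,
        mvalue_config=cfg.mvalue_config,
        mvalue_hi=cfg.mvalue_hi,
        mvalue_lo=cfg.mvalue_lo,
        re2_null=cfg.re2_null,
        compute_mvalues=collect_mvalues,
    )
    for _ in range(spec.n_replicates):
        stacked = _stacked_null_draws(rng, M, spec.sigma_g2, spec.sigma_e2, 1)[0]
        dosage_ind = _nonconstant_dosages(rng, spec.n_individuals, spec.maf)
        dosage_map = dict(
            zip([f"I{i:04d}" for i in range(spec.n_individuals)], dosage_ind)
        )
        dosage_per_tissue = []
        ys = []
        for t, m in enumerate(maps):
            # unshared individuals get their own independently drawn dosage
            d = np.array(
                [
                    dosage_map.setdefault(s, float(rng.binomial(2, spec.maf)))
                    for s in m.sample_ids
                ]
            )
            if d.min() == d.max():
                d = _nonconstant_dosages(rng, m.n_samples, spec.maf)
            dosage_per_tissue.append(d)
            yv = stacked[offsets[t] : offsets[t + 1]].copy()
            if t in spec.effect_tissues:
                yv += spec.effect_size * d
            ys.append(yv)
        result = layout.analyze(ys, dosage_per_tissue, cfg)
        naive = None
        if collect_naive:
            naive = result.tissue_fits
        yield result, naive


def run_power_experiment(
    spec: SimulationSpec,
    methods: Iterable[str] = ("TBT", "FE", "RE2", "DL"),
    alpha: float = DEFAULT_POWER_ALPHA,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Detection fraction of each method over replicate eQTLs.

    Meta-analysis methods are thresholded at ``alpha``; TBT at ``alpha / t``
    per tissue so the study-wide false positive rates match.  Also returns
    quartiles of the I2 heterogeneity statistic across replicates.
    """
    methods = [m.upper() for m in methods]
    unknown = set(methods) - {"TBT", "FE", "RE2", "DL"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    hits = {m: 0 for m in methods}
    i2s = []
    t = spec.n_tissues
    for result, _ in _replicate_pipeline(spec, cfg):
        meta = result.meta
        i2s.append(meta.I2)
        if "TBT" in hits and min(f.p for f in result.tissue_fits) < alpha / t:
            hits["TBT"] += 1
        if "FE" in hits and meta.p_fe < alpha:
            hits["FE"] += 1
        if "RE2" in hits and meta.p_re2 < alpha:
            hits["RE2"] += 1
        if "DL" in hits and meta.p_dl < alpha:
            hits["DL"] += 1
    n = spec.n_replicates
    i2s = np.asarray(i2s)
    return {
        "power": {m: hits[m] / n for m in methods},
        "alpha": alpha,
        "tbt_alpha": alpha / t,
        "n_replicates": n,
        "I2_quartiles": tuple(np.percentile(i2s, [25, 50, 75])),
        "I2_mean": float(i2s.mean()),
    }


def run_calibration_experiment(
    n_replicates: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    spec: SimulationSpec | None = None,
    re2_null: Re2NullTable | None = None,
    df_correction: bool = True,
) -> dict:
    """Type-I error of the pipeline versus a naive correlation-blind FE.

    Null data (no SNP effect anywhere) with the default full-sharing design.
    The naive arm feeds per-tissue OLS estimates straight into inverse-
    variance meta-analysis, ignoring that tissues share individuals — the
    anti-conservative shortcut the mixed model exists to fix.
    """
    from .meta_analysis import fixed_effects

    if spec is None:
        spec = SimulationSpec(n_replicates=n_replicates, seed=seed)
    else:
        spec = SimulationSpec(
            n_individuals=spec.n_individuals, n_tissues=spec.n_tissues,
            maf=spec.maf, sigma_g2=spec.sigma_g2, sigma_e2=spec.sigma_e2,
            effect_size=0.0, effect_tissues=frozenset(), sharing=spec.sharing,
            n_replicates=n_replicates, seed=seed,
        )
    cfg = AnalysisConfig(re2_null=re2_null, df_correction=df_correction)
    rej = {"FE": 0, "RE2": 0, "DL": 0, "naive_FE": 0, "TBT": 0}
    t = spec.n_tissues
    for result, fits in _replicate_pipeline(spec, cfg, collect_naive=True):
        meta = result.meta
        if meta.p_fe < alpha:
            rej["FE"] += 1
        if meta.p_re2 < alpha:
            rej["RE2"] += 1
        if meta.p_dl < alpha:
            rej["DL"] += 1
        if min(f.p for f in fits) < alpha / t:
            rej["TBT"] += 1
        _, p_naive, _, _ = fixed_effects(
            [f.beta for f in fits], [f.se for f in fits]
        )
        if p_naive < alpha:
            rej["naive_FE"] += 1
    return {
        "alpha": alpha,
        "n_replicates": n_replicates,
        "rates": {k: v / n_replicates for k, v in rej.items()},
    }


def run_recovery_experiment(
    n_replicates: int = 200,
    seed: int = 0,
    effect_size: float = 1.0,
    spec: SimulationSpec | None = None,
) -> dict:
    """Parameter recovery: refit variance components and effects from
    generated data and report median relative errors.

    The eQTL is given a strong effect (default 1.0 on the unit-noise scale)
    in every tissue so the effect-recovery error reflects estimation quality
    rather than sampling noise around a weak signal.  Components are
    re-estimated under the full design (per-SNP mode) and expression is left
    unstandardized so estimates are on the generative scale.
    """
    if spec is None:
        spec = SimulationSpec()
    maps = make_tissue_maps(spec.n_individuals, spec.n_tissues, spec.sharing)
    layout = TissueLayout(maps)
    M = row_individual_indicator(maps).astype(float)
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig(
        df_correction=False, per_snp_components=True, compute_mvalues=False
    )
    sizes = [m.n_samples for m in maps]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    errs_g, errs_e, errs_b = [], [], []
    for _ in range(n_replicates):
        y = _stacked_null_draws(rng, M, spec.sigma_g2, spec.sigma_e2, 1)[0]
        x = _nonconstant_dosages(rng, spec.n_individuals, spec.maf)
        ys = [
            y[offsets[t] : offsets[t + 1]] + effect_size * x
            for t in range(spec.n_tissues)
        ]
        res = layout.analyze(ys, [x] * spec.n_tissues, cfg, standardize=False)
        errs_g.append(abs(res.components.sigma_g2 - spec.sigma_g2) / spec.sigma_g2)
        errs_e.append(abs(res.components.sigma_e2 - spec.sigma_e2) / spec.sigma_e2)
        errs_b.extend(np.abs(res.effects.beta - effect_size) / abs(effect_size))
    return {
        "median_rel_err_sigma_g2": float(np.median(errs_g)),
        "median_rel_err_sigma_e2": float(np.median(errs_e)),
        "median_rel_err_beta": float(np.median(errs_b)),
        "n_replicates": n_replicates,
        "effect_size": effect_size,
    }


# ---------------------------------------------------------------------------
# Split-and-permute heterogeneity experiment
# ---------------------------------------------------------------------------

def split_permute_experiment(
    expression: np.ndarray,
    dosage: np.ndarray,
    n_groups: int,
    effect_groups: Sequence[int],
    seed: int,
    *,
    gold_pairs: Sequence[int] | None = None,
    gold_alpha: float = 1e-4,
    alpha: float | None = None,
    n_iterations: int = 10,
    cfg: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Split one tissue into pseudo-tissues and permute away chosen effects.

    ``expression`` is probes x samples from a single tissue, ``dosage`` the
    matching per-sample genotypes of one SNP.  Gold-standard eQTL probes are
    those whose single-tissue regression on the full cohort passes
    ``gold_alpha`` (or pass explicit row indices).  Each iteration partitions
    the samples into ``n_groups`` equal pseudo-tissues (trailing samples
    dropped), permutes expression within every group *not* in
    ``effect_groups`` — which preserves the distribution but destroys the
    genotype link — and analyzes every gold probe.

    ``alpha`` defaults to ``gold_alpha``: detection and per-tissue prediction
    in the pseudo-tissues use the same threshold that defined the gold
    standard, mirroring how the original single-tissue eQTL set is hunted in
    the split data.

    Reports, averaged over iterations: how many gold eQTLs each method
    recovers (meta p < alpha; TBT min p < alpha / n_groups), and how often the
    m-value rule (m > 0.9 in effect groups, m < 0.1 elsewhere; anything in
    between is ambiguous) and the p-value rule (p below / above
    ``alpha / n_groups``) reproduce the true effect pattern.
    """
    if alpha is None:
        alpha = gold_alpha
    expression = np.atleast_2d(np.asarray(expression, dtype=float))
    dosage = np.asarray(dosage, dtype=float)
    n = expression.shape[1]
    if dosage.shape != (n,):
        raise ValueError("dosage must have one entry per expression column")
    effect_groups = sorted(set(int(g) for g in effect_groups))
    if any(g < 0 or g >= n_groups for g in effect_groups):
        raise ValueError("effect_groups must index the pseudo-tissues")
    group_size = n // n_groups
    if group_size < 3:
        raise ValueError("pseudo-tissues need at least 3 samples each")
    n_used = group_size * n_groups
    if n_used < n:
        import logging

        logging.getLogger(__name__).warning(
            "split_permute_experiment: dropping %d trailing samples", n - n_used
        )

    if gold_pairs is None:
        gold_pairs = [
            i
            for i in range(expression.shape[0])
            if fit_single_tissue(expression[i], dosage).p < gold_alpha
        ]
    gold_pairs = list(gold_pairs)

    rng = np.random.default_rng(seed)
    maps = [
        TissueSampleMap(
            tissue_id=f"group{g + 1}",
            sample_ids=tuple(f"G{g}_S{i}" for i in range(group_size)),
        )
        for g in range(n_groups)
    ]
    layout = TissueLayout(maps)
    truth = [PRESENT if g in effect_groups else ABSENT for g in range(n_groups)]

    recovery = {m: np.zeros(n_iterations) for m in ("TBT", "FE", "RE2", "DL")}
    m_correct = np.zeros(n_iterations)
    m_incorrect = np.zeros(n_iterations)
    m_ambiguous = np.zeros(n_iterations)
    p_correct = np.zeros(n_iterations)
    p_incorrect = np.zeros(n_iterations)
    n_predicted = np.zeros(n_iterations)

    for it in range(n_iterations):
        perm = rng.permutation(n)[:n_used]
        groups = perm.reshape(n_groups, group_size)
        scramble = [
            rng.permutation(group_size) if g not in effect_groups else None
            for g in range(n_groups)
        ]
        for probe in gold_pairs:
            ys, ds = [], []
            for g in range(n_groups):
                idx = groups[g]
                yv = expression[probe, idx]
                if scramble[g] is not None:
                    yv = yv[scramble[g]]
                ys.append(yv)
                ds.append(dosage[idx])
            if any(d.min() == d.max() for d in ds):
                continue
            res = layout.analyze(ys, ds, cfg)
            meta = res.meta
            tbt_hit = min(f.p for f in res.tissue_fits) < alpha / n_groups
            recovery["TBT"][it] += tbt_hit
            recovery["FE"][it] += meta.p_fe < alpha
            recovery["RE2"][it] += meta.p_re2 < alpha
            recovery["DL"][it] += meta.p_dl < alpha
            detected = tbt_hit or meta.p_fe < alpha or meta.p_re2 < alpha
            if not detected:
                continue
            n_predicted[it] += 1
            calls = res.mvalues.call
            if all(c == tr for c, tr in zip(calls, truth)):
                m_correct[it] += 1
            elif any(c == "ambiguous" for c in calls):
                m_ambiguous[it] += 1
            else:
                m_incorrect[it] += 1
            p_thresh = alpha / n_groups
            p_calls = [
                PRESENT if f.p < p_thresh else ABSENT for f in res.tissue_fits
            ]
            if all(c == tr for c, tr in zip(p_calls, truth)):
                p_correct[it] += 1
            else:
                p_incorrect[it] += 1

    return {
        "n_gold": len(gold_pairs),
        "n_iterations": n_iterations,
        "recovery_mean": {m: float(v.mean()) for m, v in recovery.items()},
        "prediction": {
            "n_predicted_mean": float(n_predicted.mean()),
            "mvalue_correct_mean": float(m_correct.mean()),
            "mvalue_incorrect_mean": float(m_incorrect.mean()),
            "mvalue_ambiguous_mean": float(m_ambiguous.mean()),
            "pvalue_correct_mean": float(p_correct.mean()),
            "pvalue_incorrect_mean": float(p_incorrect.mean()),
        },
    }
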