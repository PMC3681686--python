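"""Core data containers and the stacked mixed-model design encoding.

A multi-tissue eQTL dataset consists of a genotype table (SNPs x individuals),
one expression table per tissue (probes x samples), and a sample map recording
which individuals contributed which tissue.  Because the same individual can
contribute several tissues ("repeated measures"), expression values across
tissues are correlated.  The analysis stacks all tissues' expression for one
probe into a single vector ``y`` with tissue-specific intercept and dosage
columns, plus a 0/1 *sharing matrix* marking pairs of rows that come from the
same individual; that matrix is the support of the random-effect covariance in
the mixed model.

Row ordering is tissue-major: tissue 1's samples in sample-map order, then
tissue 2's, and so on.  This fixed layout makes every matrix in the design
reproducible byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TissueSampleMap",
    "GenotypeVector",
    "ExpressionMatrix",
    "StackedDesign",
    "build_sharing_matrix",
    "stack_design",
    "standardize_expression",
    "read_genotype_table",
    "read_expression_table",
    "read_sample_map",
    "write_sample_map",
]

#: tolerance below which a probe's within-tissue variance counts as zero
ZERO_VARIANCE_TOL = 1e-12


@dataclass(frozen=True)
class TissueSampleMap:
    """Which individuals contributed a given tissue, in fixed order."""

    tissue_id: str
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if len(self.sample_ids) == 0:
            raise ValueError(f"tissue {self.tissue_id!r} has no samples")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(
                f"tissue {self.tissue_id!r} lists duplicate sample ids"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GenotypeVector:
    """Allele dosages of one SNP, keyed by individual id.

    Dosages are arbitrary real values (0/1/2 for a human biallelic SNP, 0/1
    for an inbred cross); no frequency filtering is applied here.
    """

    snp_id: str
    dosage: Mapping[str, float]

    def __post_init__(self) -> None:
        for sample, value in self.dosage.items():
            if not np.isfinite(value):
                raise ValueError(
                    f"non-finite dosage for sample {sample!r} in SNP {self.snp_id!r}"
                )

    def values_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.dosage]
        if missing:
            raise KeyError(
                f"SNP {self.snp_id!r} has no genotype for samples: {missing}"
            )
        return np.asarray([self.dosage[s] for s in sample_ids], dtype=float)


@dataclass
class ExpressionMatrix:
    """Probe-by-sample expression values for one tissue."""

    tissue_id: str
    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = tuple(self.probe_ids)
        self.sample_ids = tuple(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"tissue {self.tissue_id!r}: values shape {self.values.shape} "
                f"does not match {len(self.probe_ids)} probes x "
                f"{len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"tissue {self.tissue_id!r}: non-finite expression values")

    def probe_row(self, probe: str) -> np.ndarray:
        try:
            i = self.probe_ids.index(probe)
        except ValueError:
            raise KeyError(
                f"probe {probe!r} is absent from tissue {self.tissue_id!r}"
            ) from None
        return self.values[i]


@dataclass
class StackedDesign:
    """The stacked repeated-measures encoding of one probe across tissues.

    ``y`` holds all tissues' (standardized) expression for the probe;
    ``intercept_block`` (N x t) carries one indicator column per tissue;
    ``snp_block`` (N x t) carries each tissue's dosages in that tissue's rows
    and zeros elsewhere; ``sharing_matrix`` (N x N) is 1 where two rows belong
    to the same individual.
    """

    y: np.ndarray
    intercept_block: np.ndarray
    snp_block: np.ndarray
    sharing_matrix: np.ndarray
    tissue_index: tuple[str, ...]
    sample_index: tuple[str, ...]

    @property
    def n_obs(self) -> int:
        return self.y.shape[0]

    @property
    def n_tissues(self) -> int:
        return self.intercept_block.shape[1]

    @property
    def fixed_effects_matrix(self) -> np.ndarray:
        """Full design matrix: tissue intercepts followed by tissue dosages."""
        return np.hstack([self.intercept_block, self.snp_block])


def build_sharing_matrix(maps: Sequence[TissueSampleMap]) -> np.ndarray:
    """0/1 matrix over stacked rows marking same-individual pairs.

    Entry (i, j) is 1 exactly when rows i and j (tissue-major order) were
    measured on the same individual, including the diagonal.  Equals M M^T for
    the row-to-individual indicator M, hence always symmetric PSD.
    """
    if len(maps) == 0:
        raise ValueError("at least one tissue is required")
    stacked_ids: list[str] = []
    for m in maps:
        stacked_ids.extend(m.sample_ids)
    ids = np.asarray(stacked_ids, dtype=object)
    share = (ids[:, None] == ids[None, :]).astype(np.int8)
    return share


def row_individual_indicator(maps: Sequence[TissueSampleMap]) -> np.ndarray:
    """Row-to-individual 0/1 indicator M with ``M @ M.T`` the sharing matrix."""
    stacked: list[str] = []
    for m in maps:
        stacked.extend(m.sample_ids)
    individuals = list(dict.fromkeys(stacked))  # stable first-appearance order
    col = {s: j for j, s in enumerate(individuals)}
    M = np.zeros((len(stacked), len(individuals)), dtype=np.int8)
    for i, s in enumerate(stacked):
        M[i, col[s]] = 1
    return M


def stack_design(
    expr: Sequence[ExpressionMatrix],
    geno: GenotypeVector,
    maps: Sequence[TissueSampleMap],
    probe: str,
) -> StackedDesign:
    """Stack one probe's expression across tissues into the mixed-model design.

    Raises ``KeyError`` if the probe is missing from a tissue or a sample has
    no genotype.  Expression is taken as stored; standardize per tissue first
    (see :func:`standardize_expression`) for the scale the model assumes.
    """
    if len(expr) != len(maps):
        raise ValueError("one ExpressionMatrix per TissueSampleMap is required")
    t = len(maps)
    y_parts: list[np.ndarray] = []
    dosage_parts: list[np.ndarray] = []
    tissue_index: list[str] = []
    sample_index: list[str] = []
    for em, m in zip(expr, maps):
        if em.tissue_id != m.tissue_id:
            raise ValueError(
                f"tissue order mismatch: expression {em.tissue_id!r} vs map {m.tissue_id!r}"
            )
        if tuple(em.sample_ids) != tuple(m.sample_ids):
            raise ValueError(
                f"tissue {m.tissue_id!r}: expression columns do not match the sample map"
            )
        y_parts.append(em.probe_row(probe))
        dosage_parts.append(geno.values_for(m.sample_ids))
        tissue_index.extend([m.tissue_id] * m.n_samples)
        sample_index.extend(m.sample_ids)

    sizes = [m.n_samples for m in maps]
    n_total = sum(sizes)
    intercept_block = np.zeros((n_total, t))
    snp_block = np.zeros((n_total, t))
    offset = 0
    for j, (size, dos) in enumerate(zip(sizes, dosage_parts)):
        intercept_block[offset : offset + size, j] = 1.0
        snp_block[offset : offset + size, j] = dos
        offset += size

    return StackedDesign(
        y=np.concatenate(y_parts),
        intercept_block=intercept_block,
        snp_block=snp_block,
        sharing_matrix=build_sharing_matrix(maps),
        tissue_index=tuple(tissue_index),
        sample_index=tuple(sample_index),
    )


def standardize_expression(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every probe row to mean 0, unit (n-1) variance within the tissue.

    Raises ``ValueError`` listing the offending probes if any row has
    (numerically) zero variance, since a constant probe carries no signal and
    would divide by zero.
    """
    if len(expr.sample_ids) < 2:
        raise ValueError(
            f"tissue {expr.tissue_id!r}: need at least 2 samples to standardize"
        )
    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1, ddof=1)
    degenerate = np.flatnonzero(sd <= ZERO_VARIANCE_TOL)
    if degenerate.size:
        names = [expr.probe_ids[i] for i in degenerate]
        raise ValueError(
            f"tissue {expr.tissue_id!r}: zero-variance probes cannot be "
            f"standardized: {names}"
        )
    return ExpressionMatrix(
        tissue_id=expr.tissue_id,
        probe_ids=expr.probe_ids,
        sample_ids=expr.sample_ids,
        values=centered / sd[:, None],
    )


# ---------------------------------------------------------------------------
# Tab-separated I/O.  All files carry a single header line, UTF-8, '.' decimal.
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> pd.DataFrame:
    """Genotype TSV: ``snp_id<TAB>sample1<TAB>...``; returns SNPs x samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError(f"{path}: genotype table contains non-finite dosages")
    return df


def genotype_vector(df: pd.DataFrame, snp_id: str) -> GenotypeVector:
    if snp_id not in df.index:
        raise KeyError(f"SNP {snp_id!r} not present in the genotype table")
    return GenotypeVector(snp_id=snp_id, dosage=df.loc[snp_id].to_dict())


def read_expression_table(path, tissue_id: str) -> ExpressionMatrix:
    """Expression TSV: ``probe_id<TAB>sample1<TAB>...``; probes x samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(
        tissue_id=tissue_id,
        probe_ids=tuple(str(p) for p in df.index),
        sample_ids=tuple(str(s) for s in df.columns),
        values=df.to_numpy(dtype=float),
    )


def read_sample_map(path) -> list[TissueSampleMap]:
    """Sample-map TSV: ``tissue_id<TAB>sample_id``, one row per contribution.

    Tissue order follows first appearance in the file; sample order within a
    tissue follows file order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: sample map needs tissue_id and sample_id columns")
    tissue_col, sample_col = df.columns[:2]
    maps: list[TissueSampleMap] = []
    for tissue in dict.fromkeys(df[tissue_col]):
        samples = tuple(df.loc[df[tissue_col] == tissue, sample_col])
        maps.append(TissueSampleMap(tissue_id=str(tissue), sample_ids=samples))
    return maps


def write_sample_map(maps: Sequence[TissueSampleMap], path) -> None:
    rows = [
        {"tissue_id": m.tissue_id, "sample_id": s}
        for m in maps
        for s in m.sample_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
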