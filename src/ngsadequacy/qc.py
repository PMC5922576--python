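"""Replicate-based quality-control gates for a multi-analyte assay.

Three gates:

* copy number — the mean coefficient of variation (sample sd / mean) across
  repeated reads of each gene; above 30% all copy-number results are rejected.
* mRNA — per-gene replicate variance compared to the reference-range variance
  by a chi-squared variance-ratio test; a significant difference rejects all
  mRNA results.
* sequencing error — the rate of non-reproducible variants seen in only one
  library replicate, and from it the probability the case contains at least
  one false positive among its reported (concordant) variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "QCResult",
    "VariantReplication",
    "SequencingErrorEstimate",
    "copy_number_qc",
    "mrna_qc",
    "sequencing_error_rate",
    "copy_number_cv_matrix",
    "mrna_qc_flags_matrix",
    "read_reference_range",
]

COPY_NUMBER_CV_LIMIT = 0.30


@dataclass(frozen=True)
class QCResult:
    analyte: str
    statistic: float
    threshold: float
    passed: bool
    reason: str
    p_value: float | None = None
    excluded_genes: tuple[str, ...] = ()


@dataclass(frozen=True)
class VariantReplication:
    """Which library replicates a candidate variant was observed in."""

    variant_id: str
    replicate_presence: frozenset[int]

    def __post_init__(self) -> None:
        if not self.replicate_presence:
            raise ValueError(f"variant {self.variant_id}: empty replicate presence set")


@dataclass(frozen=True)
class SequencingErrorEstimate:
    singleton_rate: float
    per_variant_fp: float
    n_variants: int
    n_concordant: int
    case_fp_probability: float


def _as_gene_reads(reads: Mapping[str, Sequence[float]] | pd.DataFrame) -> dict[str, np.ndarray]:
    if isinstance(reads, pd.DataFrame):
        if not {"gene", "reads"} <= set(reads.columns):
            raise ValueError("reads frame needs columns gene, reads")
        return {
            str(gene): grp["reads"].to_numpy(dtype=float)
            for gene, grp in reads.groupby("gene", sort=True)
        }
    return {str(g): np.asarray(v, dtype=float) for g, v in reads.items()}


def copy_number_qc(
    reads: Mapping[str, Sequence[float]] | pd.DataFrame,
    cv_limit: float = COPY_NUMBER_CV_LIMIT,
) -> QCResult:
    """Average per-gene coefficient of variation; > ``cv_limit`` rejects.

    CV uses the sample (n-1) standard deviation.  Genes with mean zero have
    an undefined CV and are excluded (and logged).
    """
    gene_reads = _as_gene_reads(reads)
    if not gene_reads:
        raise ValueError("copy_number_qc needs at least one gene")
    cvs: list[float] = []
    excluded: list[str] = []
    for gene, vals in gene_reads.items():
        if len(vals) < 2:
            raise ValueError(f"gene {gene}: need >= 2 repeated reads for a CV")
        if np.any(vals < 0):
            raise ValueError(f"gene {gene}: read counts must be non-negative")
        mean = vals.mean()
        if mean == 0:
            excluded.append(gene)
            logger.warning("copy-number QC: gene %s has mean 0 reads; CV undefined, excluded", gene)
            continue
        cvs.append(float(vals.std(ddof=1) / mean))
    if not cvs:
        raise ValueError("no gene with a defined CV")
    statistic = float(np.mean(cvs))
    passed = statistic <= cv_limit
    return QCResult(
        analyte="copy_number",
        statistic=statistic,
        threshold=cv_limit,
        passed=passed,
        reason="average CV within limit" if passed else
        f"average CV {statistic:.3f} exceeds {cv_limit:.2f}; all copy-number results rejected",
        excluded_genes=tuple(excluded),
    )


def read_reference_range(path) -> pd.DataFrame:
    """Reference range table: TSV with columns gene, mean, variance."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "mean", "variance"} - set(df.columns)
    if missing:
        raise ValueError(f"reference range missing columns: {sorted(missing)}")
    return df


def mrna_qc(
    reads: Mapping[str, Sequence[float]] | pd.DataFrame,
    reference_variance: Mapping[str, float] | pd.DataFrame,
    alpha: float = 0.05,
) -> QCResult:
    """Compare replicate variance per gene to the reference-range variance.

    Statistic: sum over genes of (n_g - 1) * s_g^2 / sigma_g^2, referred to a
    chi-squared distribution with sum(n_g - 1) degrees of freedom, two-sided
    at ``alpha``.  Genes absent from the reference range are excluded and
    logged; an empty overlap is an error.
    """
    gene_reads = _as_gene_reads(reads)
    if isinstance(reference_variance, pd.DataFrame):
        ref = {str(r.gene): float(r.variance) for r in reference_variance.itertuples(index=False)}
    else:
        ref = {str(g): float(v) for g, v in reference_variance.items()}

    stat = 0.0
    df = 0
    excluded: list[str] = []
    for gene, vals in gene_reads.items():
        if gene not in ref:
            excluded.append(gene)
            logger.warning("mRNA QC: gene %s absent from reference range; excluded", gene)
            continue
        if len(vals) < 2:
            raise ValueError(f"gene {gene}: need >= 2 repeated reads")
        sigma2 = ref[gene]
        if sigma2 <= 0:
            raise ValueError(f"gene {gene}: reference variance must be > 0")
        stat += (len(vals) - 1) * float(vals.var(ddof=1)) / sigma2
        df += len(vals) - 1
    if df == 0:
        raise ValueError("no overlap between observed genes and the reference range")
    cdf = stats.chi2.cdf(stat, df)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    passed = p >= alpha
    return QCResult(
        analyte="mrna",
        statistic=float(stat),
        threshold=alpha,
        passed=passed,
        reason="replicate variance consistent with reference range" if passed else
        "replicate variance differs from reference range; all mRNA results rejected",
        p_value=p,
        excluded_genes=tuple(excluded),
    )


def sequencing_error_rate(
    variants: Iterable[VariantReplication],
    per_variant_fp: float | None = None,
) -> SequencingErrorEstimate:
    """Singleton-variant rate and case-level false-positive probability.

    The singleton rate is the fraction of candidate variants observed in
    exactly one library replicate.  The per-variant false-positive estimate
    defaults to half the singleton rate (a singleton is an error in one of
    two replicates); the case-level probability that at least one reported
    (concordant) variant is a false positive is 1 - (1 - fp)^k for k
    concordant variants.
    """
    variants = list(variants)
    n = len(variants)
    if n == 0:
        return SequencingErrorEstimate(0.0, 0.0, 0, 0, 0.0)
    singles = sum(1 for v in variants if len(v.replicate_presence) == 1)
    concordant = n - singles
    rate = singles / n
    fp = rate / 2.0 if per_variant_fp is None else float(per_variant_fp)
    if not 0.0 <= fp <= 1.0:
        raise ValueError(f"per-variant FP estimate must lie in [0, 1], got {fp}")
    case_fp = float(-np.expm1(concordant * np.log1p(-min(fp, 1.0 - 1e-300))))
    return SequencingErrorEstimate(
        singleton_rate=rate,
        per_variant_fp=fp,
        n_variants=n,
        n_concordant=concordant,
        case_fp_probability=case_fp,
    )


# ---------------------------------------------------------------------------
# vectorized cohort-scale paths (same statistics as the scalar gates above;
# unit tests assert the two paths agree)


def copy_number_cv_matrix(reads: np.ndarray) -> np.ndarray:
    """Mean per-gene CV for stacked cases.

    ``reads`` has shape (..., genes, replicates); returns shape (...,).
    """
    reads = np.asarray(reads, dtype=float)
    mean = reads.mean(axis=-1)
    sd = reads.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return np.nanmean(cv, axis=-1)


def mrna_qc_flags_matrix(
    reads: np.ndarray, reference_variance: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Vectorized mRNA gate over stacked cases.

    ``reads``: (..., genes, replicates); ``reference_variance``: (genes,).
    Returns a boolean pass array of shape (...,).
    """
    reads = np.asarray(reads, dtype=float)
    sigma2 = np.asarray(reference_variance, dtype=float)
    n_rep = reads.shape[-1]
    s2 = reads.var(axis=-1, ddof=1)
    stat = ((n_rep - 1) * s2 / sigma2).sum(axis=-1)
    df = reads.shape[-2] * (n_rep - 1)
    cdf = stats.chi2.cdf(stat, df)
    p = np.minimum(1.0, 2.0 * np.minimum(cdf, 1.0 - cdf))
    return p >= alpha
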