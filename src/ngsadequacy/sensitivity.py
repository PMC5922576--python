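"""Mutation-detection sensitivity for duplicate-library targeted sequencing.

A somatic mutation is called at a base in one library replicate when at least
``c`` mutant reads are present *and* at least a proportion ``r`` of the reads
are mutant, i.e. when the mutant read count reaches ``max(c, ceil(r * n))``
for coverage ``n``.  Modeling the mutant read count as Binomial(n, m) — with
``m`` the expected mutant allele frequency, by default half the tumor-nuclei
fraction for a heterozygous clonal mutation — the per-replicate detection
sensitivity is the binomial upper tail above that threshold.

When every read over a base is wild type, a sharper bound applies: assuming a
mutation, if present, would sit at frequency ``r``, the false-negative
probability is ``(1 - r)**n`` and the sensitivity is ``1 - (1 - r)**n``.

Replicate sensitivities are combined under a concordance policy (default:
a mutation must be called in every replicate, so sensitivities multiply).
Per-gene sensitivity is the prior-weighted average of combined base
sensitivities, with weights drawn from somatic-mutation catalog priors; a
gene whose weighted sensitivity falls below the reporting threshold
(default 99%) is classified as low coverage and reported as indeterminate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CallingParams",
    "CoverageRecord",
    "TumorContext",
    "BaseSensitivity",
    "GeneSensitivity",
    "PriorWeights",
    "call_threshold",
    "binomial_power_sensitivity",
    "all_wt_sensitivity",
    "base_sensitivity",
    "gene_sensitivity",
    "expected_mutation_frequency",
    "panel_gene_sensitivity",
    "read_coverage",
    "sensitivity_report",
    "write_report",
]

#: valid replicate-combination policies
POLICIES = ("both", "either")


@dataclass(frozen=True)
class CallingParams:
    """Mutation-calling rule: >= ``c`` mutant reads and mutant fraction >= ``r``.

    ``sensitivity_threshold`` is the gene-level reporting floor: a gene with
    prior-weighted sensitivity below it is flagged low coverage.
    """

    c: int = 5
    r: float = 0.02
    sensitivity_threshold: float = 0.99

    def __post_init__(self) -> None:
        if int(self.c) != self.c or self.c < 1:
            raise ValueError(f"c must be an integer >= 1, got {self.c!r}")
        if not 0.0 < self.r <= 1.0:
            raise ValueError(f"r must lie in (0, 1], got {self.r!r}")
        if not 0.0 < self.sensitivity_threshold < 1.0:
            raise ValueError(
                f"sensitivity_threshold must lie in (0, 1), got {self.sensitivity_threshold!r}"
            )


@dataclass(frozen=True)
class CoverageRecord:
    """Read counts for one base of one gene in one library replicate."""

    gene: str
    position: int
    replicate: int
    n: int
    mutant_reads: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"total reads must be >= 0, got {self.n}")
        if not 0 <= self.mutant_reads <= self.n:
            raise ValueError(
                f"mutant_reads must lie in [0, n]={self.n}, got {self.mutant_reads}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class TumorContext:
    """Tumor-nuclei fraction and the expected mutant allele frequency m.

    m defaults to half the purity (heterozygous clonal mutation in a diploid
    background); pass an explicit m to override, e.g. for amplified loci.
    """

    tumor_purity: float
    m: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0.0 < self.tumor_purity <= 1.0:
            raise ValueError(f"tumor purity must lie in (0, 1], got {self.tumor_purity}")
        if self.m is None:
            object.__setattr__(self, "m", self.tumor_purity / 2.0)
        if not 0.0 < self.m <= 1.0:
            raise ValueError(f"m must lie in (0, 1], got {self.m}")


@dataclass(frozen=True)
class BaseSensitivity:
    """Detection sensitivity at one base: per replicate and combined."""

    gene: str
    position: int
    per_replicate: tuple[float, ...]
    combined: float
    method: str  # "all_wt" when every replicate used the all-WT bound
    single_replicate: bool = False


@dataclass(frozen=True)
class GeneSensitivity:
    gene: str
    weighted_sensitivity: float
    low_coverage: bool
    n_bases: int


def expected_mutation_frequency(tumor_purity: float) -> float:
    """Expected mutant allele frequency: half the tumor-nuclei fraction."""
    if not 0.0 < tumor_purity <= 1.0:
        raise ValueError(f"tumor purity must lie in (0, 1], got {tumor_purity}")
    return tumor_purity / 2.0


def _ceil_rn(r: float, n) -> np.ndarray:
    """ceil(r*n) with a snap-to-integer guard against binary-float noise.

    0.02 * 1000 evaluates to 20.000000000000004; a bare ceil would demand 21
    mutant reads where the rule means 20.
    """
    rn = np.multiply(r, n, dtype=float)
    nearest = np.round(rn)
    snap = np.abs(rn - nearest) <= 1e-9 * np.maximum(1.0, np.abs(nearest))
    return np.where(snap, nearest, np.ceil(rn))


def call_threshold(n: int, params: CallingParams) -> int:
    """Minimum mutant reads needed to call a mutation at coverage ``n``."""
    if n < 0:
        raise ValueError(f"coverage must be >= 0, got {n}")
    return int(max(params.c, _ceil_rn(params.r, n)))


def binomial_power_sensitivity(n, params: CallingParams, m):
    """P(call | mutation) under a Binomial(n, m) mutant-read model.

    Returns P(X >= max(c, ceil(r*n))) via the binomial survival function
    (regularized incomplete beta underneath), stable to n >= 1e6.  Accepts
    scalars or broadcastable arrays for ``n`` and ``m``.
    """
    n_arr = np.asarray(n)
    m_arr = np.asarray(m, dtype=float)
    if np.any(n_arr < 0):
        raise ValueError("coverage n must be >= 0")
    if np.any((m_arr < 0.0) | (m_arr > 1.0)):
        raise ValueError("mutant frequency m must lie in [0, 1]")
    k = np.maximum(float(params.c), _ceil_rn(params.r, n_arr))
    out = stats.binom.sf(k - 1.0, n_arr, m_arr)
    if np.isscalar(n) and np.isscalar(m):
        return float(out)
    return out


def all_wt_sensitivity(n, r: float, *, observed_mutant_reads: int = 0):
    """Sensitivity 1 - (1-r)**n when all reads over the base were wild type.

    ``r`` is the frequency a mutation is assumed to have if present.  The
    bound is only valid for an all-wild-type base; passing a nonzero observed
    mutant count is a contract violation.
    """
    if observed_mutant_reads:
        raise ValueError(
            "all-WT sensitivity bound misused: base has observed mutant reads; "
            "use binomial_power_sensitivity instead"
        )
    if not 0.0 < r <= 1.0:
        raise ValueError(f"assumed mutant frequency r must lie in (0, 1], got {r}")
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("coverage n must be >= 0")
    if r == 1.0:
        out = np.where(n_arr > 0, 1.0, 0.0)
    else:
        out = -np.expm1(n_arr * np.log1p(-r))
    if np.isscalar(n):
        return float(out)
    return out


def combine_replicates(sensitivities: Sequence[float], policy: str = "both") -> float:
    """Combine per-replicate sensitivities.

    ``both``: the mutation must be called in every replicate (product, under
    independence) — concordance, consistent with treating singleton-replicate
    variants as sequencing error.  ``either``: called in at least one
    replicate (complement product).
    """
    s = np.asarray(sensitivities, dtype=float)
    if policy == "both":
        return float(np.prod(s))
    if policy == "either":
        return float(-np.expm1(np.sum(np.log1p(-np.minimum(s, 1.0 - 1e-300)))))
    raise ValueError(f"unknown replicate policy {policy!r}; expected one of {POLICIES}")


def base_sensitivity(
    records: Sequence[CoverageRecord],
    params: CallingParams,
    m: float,
    policy: str = "both",
    expected_replicates: int = 2,
) -> BaseSensitivity:
    """Sensitivity at one base from its replicate coverage records.

    A replicate that observed zero mutant reads uses the all-WT bound at the
    calling proportion ``r``; otherwise the standard binomial power at ``m``.
    A base observed in fewer than ``expected_replicates`` libraries falls back
    to the available replicates and is flagged ``single_replicate``.
    """
    if not records:
        raise ValueError("base_sensitivity requires at least one coverage record")
    gene, position = records[0].gene, records[0].position
    if any((rec.gene, rec.position) != (gene, position) for rec in records):
        raise ValueError("all records must cover the same (gene, position)")
    reps = [rec.replicate for rec in records]
    if len(set(reps)) != len(reps):
        raise ValueError(f"duplicate replicate indices for {gene}:{position}")

    per: list[float] = []
    methods: list[str] = []
    for rec in sorted(records, key=lambda rc: rc.replicate):
        if rec.mutant_reads == 0:
            per.append(all_wt_sensitivity(rec.n, params.r))
            methods.append("all_wt")
        else:
            per.append(binomial_power_sensitivity(rec.n, params, m))
            methods.append("binomial_power")
    combined = combine_replicates(per, policy)
    return BaseSensitivity(
        gene=gene,
        position=position,
        per_replicate=tuple(per),
        combined=combined,
        method="all_wt" if all(meth == "all_wt" for meth in methods) else "binomial_power",
        single_replicate=len(records) < expected_replicates,
    )


class PriorWeights:
    """Per-base mutation prior weights keyed by (gene, position).

    Weights stand in for catalog-derived prior probabilities of a somatic
    mutation at each panel position.  They are normalized within each gene
    before averaging, so any per-gene rescaling leaves results unchanged;
    zero-weight bases simply do not contribute.
    """

    def __init__(self, table: Mapping[tuple[str, int], float]):
        bad = {key: w for key, w in table.items() if w < 0 or not math.isfinite(w)}
        if bad:
            raise ValueError(f"weights must be finite and >= 0; offending entries: {bad}")
        self._table = dict(table)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PriorWeights":
        required = {"gene", "position", "weight"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        return cls(
            {
                (str(row.gene), int(row.position)): float(row.weight)
                for row in df.itertuples(index=False)
            }
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PriorWeights":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": gene, "position": pos, "weight": w}
            for (gene, pos), w in sorted(self._table.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "position", "weight"])

    def weight(self, gene: str, position: int) -> float:
        try:
            return self._table[(gene, position)]
        except KeyError:
            raise KeyError(f"no prior weight for {gene}:{position}") from None

    def __len__(self) -> int:
        return len(self._table)


def gene_sensitivity(
    bases: Sequence[BaseSensitivity],
    weights: PriorWeights,
    params: CallingParams,
) -> GeneSensitivity:
    """Prior-weighted mean of combined base sensitivities for one gene.

    Zero-weight bases are excluded from the average (catalog priors are
    sparse); a gene whose every base has weight zero is rejected.
    """
    if not bases:
        raise ValueError("gene_sensitivity requires at least one base")
    gene = bases[0].gene
    if any(b.gene != gene for b in bases):
        raise ValueError("all base sensitivities must belong to one gene")
    w = np.array([weights.weight(b.gene, b.position) for b in bases], dtype=float)
    s = np.array([b.combined for b in bases], dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"all prior weights for gene {gene} are zero")
    ws = float(np.dot(w / total, s))
    return GeneSensitivity(
        gene=gene,
        weighted_sensitivity=ws,
        low_coverage=ws < params.sensitivity_threshold,
        n_bases=len(bases),
    )


def panel_gene_sensitivity(
    n: np.ndarray,
    mutant_reads: np.ndarray,
    weights: np.ndarray,
    params: CallingParams,
    m,
    policy: str = "both",
) -> np.ndarray:
    """Vectorized gene sensitivities over a whole panel (and cohort).

    ``n`` and ``mutant_reads`` have shape (..., genes, bases, replicates);
    ``weights`` has shape (genes, bases); ``m`` must broadcast against the
    leading axes of ``n`` (e.g. per-specimen m reshaped to (S, 1, 1, 1)).
    Implements exactly the scalar path: all-WT bound where a replicate saw
    zero mutant reads, binomial power elsewhere, product combination under
    the ``both`` policy, per-gene weight normalization.
    Returns an array of shape (..., genes).
    """
    n = np.asarray(n)
    mutant_reads = np.asarray(mutant_reads)
    w = np.asarray(weights, dtype=float)
    if policy not in POLICIES:
        raise ValueError(f"unknown replicate policy {policy!r}")
    wsum = w.sum(axis=-1, keepdims=True)
    if np.any(wsum <= 0):
        raise ValueError("every gene needs at least one positive prior weight")

    s_power = binomial_power_sensitivity(n, params, np.broadcast_to(m, n.shape))
    s_wt = all_wt_sensitivity(n, params.r)
    s = np.where(mutant_reads == 0, s_wt, s_power)
    if policy == "both":
        combined = s.prod(axis=-1)
    else:
        combined = -np.expm1(np.log1p(-np.clip(s, 0.0, 1.0 - 1e-16)).sum(axis=-1))
    return (combined * (w / wsum)).sum(axis=-1)


# ---------------------------------------------------------------------------
# tabular I/O

COVERAGE_COLUMNS = ("gene", "position", "replicate", "n", "mutant_reads")


def read_coverage(path: str | Path) -> pd.DataFrame:
    """Read a per-base coverage table (TSV or CSV by extension).

    Columns: gene, position, replicate, n, mutant_reads.  Positions are
    1-based, panel-local coordinates; no genome build is implied.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = set(COVERAGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    return df[list(COVERAGE_COLUMNS)]


def records_from_frame(df: pd.DataFrame) -> Iterable[list[CoverageRecord]]:
    """Group a coverage frame into per-(gene, position) record lists."""
    for (gene, pos), grp in df.groupby(["gene", "position"], sort=True):
        yield [
            CoverageRecord(
                gene=str(gene),
                position=int(pos),
                replicate=int(row.replicate),
                n=int(row.n),
                mutant_reads=int(row.mutant_reads),
            )
            for row in grp.itertuples(index=False)
        ]


def sensitivity_report(
    coverage: pd.DataFrame,
    weights: PriorWeights,
    params: CallingParams,
    m: float,
    policy: str = "both",
) -> pd.DataFrame:
    """Per-gene sensitivity report from a coverage table.

    Returns a frame with columns gene, weighted_sensitivity, low_coverage,
    n_bases, sorted by gene.
    """
    per_gene: dict[str, list[BaseSensitivity]] = {}
    for records in records_from_frame(coverage):
        bs = base_sensitivity(records, params, m, policy=policy)
        per_gene.setdefault(bs.gene, []).append(bs)
    rows = [gene_sensitivity(bases, weights, params) for gene, bases in sorted(per_gene.items())]
    return pd.DataFrame(
        {
            "gene": [g.gene for g in rows],
            "weighted_sensitivity": [g.weighted_sensitivity for g in rows],
            "low_coverage": [g.low_coverage for g in rows],
            "n_bases": [g.n_bases for g in rows],
        }
    )


def write_report(report: pd.DataFrame, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write the per-gene report as TSV and an optional JSON summary."""
    report.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        summary = {
            row.gene: {
                "sensitivity": row.weighted_sensitivity,
                "low_coverage": bool(row.low_coverage),
            }
            for row in report.itertuples(index=False)
        }
        Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True))
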