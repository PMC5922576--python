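"""Cohort-level statistics: binning, QNS accounting, and range comparisons.

Specimens are binned by tumor-nuclei percentage (default 1-3, 3-5, 5-10,
10-25, 25-100) and by tissue area in mm^2 (default <=5, 5-10, 10-20, 20-30,
>30).  Count outcomes (low-coverage genes, drug associations) are compared
across bins by one-way ANOVA followed, when the omnibus test is significant,
by Tukey's HSD against the highest range; proportion outcomes (QNS, mRNA QC
pass) use chi-squared tests with exact Clopper-Pearson intervals per bin.
All tests use alpha = 0.05 by default.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

__all__ = [
    "BinScheme",
    "QnsEstimate",
    "ComparisonResult",
    "clopper_pearson",
    "read_s2",
    "qns_rate",
    "compare_bins",
    "mrna_pass_rates",
    "render_figures",
]

#: canonical cohort-table columns
REQUIRED_COLUMNS = (
    "percent_tumor_nuclei",
    "area_mm2",
    "qns",
    "low_coverage_genes",
    "drug_associations",
    "mrna_qc_pass",
)


def _labels(edges: Sequence[float], unit: str) -> list[str]:
    out = []
    for lo, hi in zip(edges, edges[1:]):
        if math.isinf(hi):
            out.append(f">{lo:g}{unit}")
        elif lo == edges[0]:
            out.append(f"{lo:g}-{hi:g}{unit}" if lo > 0 else f"<={hi:g}{unit}")
        else:
            out.append(f"{lo:g}-{hi:g}{unit}")
    return out


@dataclass(frozen=True)
class BinScheme:
    """Bin edges for the two adequacy axes.

    Intervals are left-open/right-closed except the lowest, which includes
    its left edge.  The highest range on each axis is the reference group
    for the pairwise comparisons.
    """

    tumor_edges: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0, 25.0, 100.0)
    area_edges: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, math.inf)

    def __post_init__(self) -> None:
        for name, edges in (("tumor", self.tumor_edges), ("area", self.area_edges)):
            if len(edges) < 3:
                raise ValueError(f"{name} edges must define >= 2 bins")
            if any(a >= b for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} edges must be strictly increasing: {edges}")

    @property
    def tumor_labels(self) -> list[str]:
        return _labels(self.tumor_edges, "%")

    @property
    def area_labels(self) -> list[str]:
        return _labels(self.area_edges, "mm2")

    def tumor_bin(self, percent_values) -> pd.Categorical:
        """Bin tumor-nuclei percentages (0-100 scale)."""
        return pd.cut(
            np.asarray(percent_values, dtype=float),
            bins=list(self.tumor_edges),
            labels=self.tumor_labels,
            right=True,
            include_lowest=True,
        )

    def area_bin(self, area_values) -> pd.Categorical:
        return pd.cut(
            np.asarray(area_values, dtype=float),
            bins=list(self.area_edges),
            labels=self.area_labels,
            right=True,
            include_lowest=True,
        )

    def highest(self, axis: str) -> str:
        return self.tumor_labels[-1] if axis == "tumor" else self.area_labels[-1]

    def assign(self, table: pd.DataFrame, axis: str) -> pd.Categorical:
        if axis == "tumor":
            return self.tumor_bin(table["percent_tumor_nuclei"])
        if axis == "area":
            return self.area_bin(table["area_mm2"])
        raise ValueError(f"axis must be 'tumor' or 'area', got {axis!r}")


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - confidence, method="beta")
    return float(0.0 if k == 0 else lo), float(1.0 if k == n else hi)


def read_s2(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a cohort dataset (XLSX, TSV or CSV) into the canonical table.

    ``column_map`` renames source columns to the canonical names; extra
    columns are kept but ignored by the statistics (a note is logged).  A
    missing mandatory column is a hard error naming the column; rows whose
    numeric fields fail coercion are dropped and reported by index.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="," if path.suffix.lower() == ".csv" else "\t")
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing mandatory column(s): {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS and c != "specimen_id"]
    if extra:
        logger.info("cohort table: ignoring extra columns %s", extra)

    out = df.copy()
    bad: set[int] = set()
    # QNS rows legitimately carry no outcome counts, so NaN inputs are fine;
    # a value that *fails* coercion (non-numeric text) marks a bad row.
    for col in ("percent_tumor_nuclei", "area_mm2", "low_coverage_genes", "drug_associations"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad |= set(out.index[coerced.isna() & out[col].notna()])
        out[col] = coerced

    def _to_bool(v):
        if pd.isna(v):
            return pd.NA
        if isinstance(v, (bool, np.bool_, int, np.integer)):
            return bool(v)
        return str(v).strip().lower() in ("true", "1", "yes", "y")

    for col in ("qns", "mrna_qc_pass"):
        out[col] = out[col].map(_to_bool)
    if bad:
        logger.warning("cohort table: dropping %d row(s) failing type coercion: %s",
                       len(bad), sorted(bad)[:20])
        out = out.drop(index=sorted(bad))
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class QnsEstimate:
    rate: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int


def qns_rate(table: pd.DataFrame, cancelled_before_ngs: int = 0) -> QnsEstimate:
    """Overall QNS proportion with an exact 95% interval.

    Specimens cancelled before sequencing (no tissue in the block) are not
    rows of the dataset but count toward both numerator and denominator.
    """
    if cancelled_before_ngs < 0:
        raise ValueError("cancelled count must be >= 0")
    flagged = int(table["qns"].fillna(False).astype(bool).sum())
    k = flagged + cancelled_before_ngs
    n = len(table) + cancelled_before_ngs
    if n == 0:
        raise ValueError("empty cohort")
    lo, hi = clopper_pearson(k, n)
    return QnsEstimate(rate=k / n, ci_low=lo, ci_high=hi, numerator=k, denominator=n)


@dataclass(frozen=True)
class ComparisonResult:
    """Per-bin estimates plus omnibus and vs-highest-range tests."""

    outcome: str
    axis: str
    test: str  # "anova_tukey" or "chi_squared"
    alpha: float
    omnibus_stat: float
    omnibus_p: float
    bins: pd.DataFrame  # bin, n, estimate, (sem | ci_low, ci_high)
    significant_vs_highest: dict[str, bool]
    highest_bin: str


def _analysis_rows(table: pd.DataFrame, outcome: str) -> pd.DataFrame:
    rows = table[~table["qns"].fillna(False).astype(bool)].copy()
    return rows[rows[outcome].notna()]


def compare_bins(
    table: pd.DataFrame,
    outcome: str,
    scheme: BinScheme = BinScheme(),
    axis: str = "tumor",
    alpha: float = 0.05,
    kind: str | None = None,
) -> ComparisonResult:
    """Omnibus test across bins, then pairwise tests against the highest range.

    ``kind`` is "count" (ANOVA + Tukey HSD) or "proportion" (chi-squared);
    inferred from the outcome dtype when omitted.  Pairwise flags are only
    raised when the omnibus test is significant at ``alpha``.  QNS rows and
    rows with a missing outcome are excluded.
    """
    rows = _analysis_rows(table, outcome)
    if kind is None:
        kind = "proportion" if rows[outcome].dropna().isin([0, 1, True, False]).all() and (
            rows[outcome].dtype == bool or set(rows[outcome].dropna().unique()) <= {0, 1, True, False}
        ) else "count"
    bins = scheme.assign(rows, axis)
    rows = rows.assign(_bin=bins)
    rows = rows[rows["_bin"].notna()]
    groups = {str(label): grp[outcome].to_numpy() for label, grp in rows.groupby("_bin", observed=True)}
    if len(groups) < 2:
        raise ValueError(f"compare_bins needs >= 2 non-empty bins, got {len(groups)}")
    highest = scheme.highest(axis)
    if highest not in groups:
        raise ValueError(f"highest range {highest!r} is empty; no reference group")

    labels = [lab for lab in (scheme.tumor_labels if axis == "tumor" else scheme.area_labels) if lab in groups]
    flags: dict[str, bool] = {lab: False for lab in labels if lab != highest}

    if kind == "count":
        data = [np.asarray(groups[lab], dtype=float) for lab in labels]
        f_stat, omni_p = stats.f_oneway(*data)
        if omni_p < alpha:
            res = stats.tukey_hsd(*data)
            hi_idx = labels.index(highest)
            for i, lab in enumerate(labels):
                if lab != highest:
                    flags[lab] = bool(res.pvalue[i, hi_idx] < alpha)
        est = pd.DataFrame(
            {
                "bin": labels,
                "n": [len(groups[lab]) for lab in labels],
                "estimate": [float(np.mean(groups[lab])) for lab in labels],
                "sem": [
                    float(stats.sem(groups[lab], ddof=1)) if len(groups[lab]) > 1 else np.nan
                    for lab in labels
                ],
            }
        )
        return ComparisonResult(outcome, axis, "anova_tukey", alpha, float(f_stat),
                                float(omni_p), est, flags, highest)

    # proportions
    succ = {lab: int(np.sum(np.asarray(groups[lab], dtype=bool))) for lab in labels}
    tot = {lab: len(groups[lab]) for lab in labels}
    contingency = np.array([[succ[lab], tot[lab] - succ[lab]] for lab in labels])
    if contingency[:, 1].sum() == 0 or contingency[:, 0].sum() == 0:
        chi2_stat, omni_p = 0.0, 1.0  # all pass or all fail: trivially homogeneous
    else:
        chi2_stat, omni_p = stats.chi2_contingency(contingency, correction=False)[:2]
    if omni_p < alpha:
        hi = labels.index(highest)
        for lab in labels:
            if lab == highest:
                continue
            sub = contingency[[labels.index(lab), hi]]
            if sub[:, 0].sum() == 0 or sub[:, 1].sum() == 0:
                continue
            _, p_pair = stats.chi2_contingency(sub, correction=False)[:2]
            flags[lab] = bool(p_pair < alpha)
    cis = [clopper_pearson(succ[lab], tot[lab]) for lab in labels]
    est = pd.DataFrame(
        {
            "bin": labels,
            "n": [tot[lab] for lab in labels],
            "estimate": [succ[lab] / tot[lab] for lab in labels],
            "ci_low": [c[0] for c in cis],
            "ci_high": [c[1] for c in cis],
        }
    )
    return ComparisonResult(outcome, axis, "chi_squared", alpha, float(chi2_stat),
                            float(omni_p), est, flags, highest)


def mrna_pass_rates(
    table: pd.DataFrame,
    scheme: BinScheme = BinScheme(),
    axis: str = "tumor",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Per-bin mRNA QC pass proportions with a chi-squared homogeneity test."""
    return compare_bins(table, "mrna_qc_pass", scheme, axis=axis, alpha=alpha, kind="proportion")


def render_figures(results: Sequence[ComparisonResult], outdir: str | Path) -> list[Path]:
    """Bar charts with CI/SEM whiskers, one per outcome x axis, plus the
    plotted numbers as TSV.  Deterministic file names; returns written paths."""
    from matplotlib.backends.backend_agg import FigureCanvasAgg
    from matplotlib.figure import Figure

    outdir = Path(outdir)
    written: list[Path] = []
    if not results:
        return written
    outdir.mkdir(parents=True, exist_ok=True)
    for res in results:
        stem = f"{res.outcome}__{res.axis}"
        df = res.bins.copy()
        fig = Figure(figsize=(5.0, 3.4))
        FigureCanvasAgg(fig)
        ax = fig.add_subplot(111)
        x = np.arange(len(df))
        if "sem" in df.columns:
            yerr = df["sem"].to_numpy()
        else:
            yerr = np.vstack(
                [df["estimate"] - df["ci_low"], df["ci_high"] - df["estimate"]]
            )
        ax.bar(x, df["estimate"], yerr=np.nan_to_num(yerr), capsize=3, color="#4878a8")
        ax.set_xticks(x)
        ax.set_xticklabels(df["bin"], rotation=30, ha="right")
        ax.set_ylabel(res.outcome.replace("_", " "))
        ax.set_xlabel(f"{res.axis} bin")
        ax.set_title(f"{res.outcome} by {res.axis} (omnibus p={res.omnibus_p:.3g})")
        fig.tight_layout()
        png = outdir / f"{stem}.png"
        fig.savefig(png, dpi=120)
        tsv = outdir / f"{stem}.tsv"
        df.to_csv(tsv, sep="\t", index=False)
        written += [png, tsv]
    return written


def summary_json(qns: QnsEstimate, results: Sequence[ComparisonResult], path: str | Path) -> None:
    """Machine-readable analysis summary."""
    payload = {
        "qns": {
            "rate": qns.rate,
            "ci": [qns.ci_low, qns.ci_high],
            "numerator": qns.numerator,
            "denominator": qns.denominator,
        },
        "comparisons": [
            {
                "outcome": r.outcome,
                "axis": r.axis,
                "test": r.test,
                "omnibus_p": r.omnibus_p,
                "significant_vs_highest": r.significant_vs_highest,
                "bins": r.bins.to_dict(orient="records"),
            }
            for r in results
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
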