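"""Seeded simulation experiments: parameter recovery and statistical calibration.

These drive the full pipeline (synthetic cohort -> sensitivity -> rule engine
-> bin statistics) across replications and measure how often the known,
generated structure is recovered, plus frequentist calibration of the
interval and multiple-comparison machinery.  Shared by the test suite and
the reporting script so both exercise identical code paths.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import stats

from . import qc
from .cohort import BinScheme, clopper_pearson, compare_bins
from .synthetic import CohortConfig, generate_cohort, measure_cohort

__all__ = [
    "parameter_recovery",
    "clopper_pearson_coverage",
    "tukey_familywise_error",
    "mrna_qc_pass_calibration",
    "association_null_type_i_error",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    # keep derived seeds below 2**31 so they stay plain ints everywhere
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def parameter_recovery(
    seed: int,
    n_specimens: int = 2000,
    n_replications: int = 100,
    config: CohortConfig | None = None,
) -> dict:
    """How often the pipeline recovers the generated adequacy effects.

    For each replication: draw a cohort, run the measurement pipeline, then
    test (i) low-coverage gene counts elevated in the tumor bins below 5%
    (both sub-5% bins flagged vs the highest range, with higher means) and
    (ii) drug-association counts depressed in the 1-3% tumor bin (flagged,
    with a lower mean).  Returns the per-effect success fractions.
    """
    scheme = BinScheme()
    low_label, mid_label = scheme.tumor_labels[0], scheme.tumor_labels[1]
    highest = scheme.tumor_labels[-1]
    low_cov_hits = 0
    assoc_hits = 0
    for child in _child_seeds(seed, n_replications):
        cfg = replace(config, seed=child, n_specimens=n_specimens) if config else CohortConfig(
            seed=child, n_specimens=n_specimens
        )
        table = measure_cohort(generate_cohort(cfg))

        res = compare_bins(table, "low_coverage_genes", scheme, axis="tumor", kind="count")
        means = dict(zip(res.bins["bin"], res.bins["estimate"]))
        if (
            res.significant_vs_highest.get(low_label, False)
            and res.significant_vs_highest.get(mid_label, False)
            and means[low_label] > means[highest]
            and means[mid_label] > means[highest]
        ):
            low_cov_hits += 1

        res = compare_bins(table, "drug_associations", scheme, axis="tumor", kind="count")
        means = dict(zip(res.bins["bin"], res.bins["estimate"]))
        if res.significant_vs_highest.get(low_label, False) and means[low_label] < means[highest]:
            assoc_hits += 1
    return {
        "low_coverage_success_rate": low_cov_hits / n_replications,
        "association_success_rate": assoc_hits / n_replications,
        "n_replications": n_replications,
        "n_specimens": n_specimens,
    }


def clopper_pearson_coverage(
    seed: int,
    n_draws: int = 10000,
    settings: tuple[tuple[int, float], ...] = ((30, 0.064), (100, 0.5), (500, 0.02), (2723, 0.064)),
) -> dict:
    """Empirical coverage of the exact binomial interval at several (n, p)."""
    rng = np.random.default_rng(seed)
    out = {}
    for n, p in settings:
        ks = rng.binomial(n, p, size=n_draws)
        covered = 0
        for k, count in zip(*np.unique(ks, return_counts=True)):
            lo, hi = clopper_pearson(int(k), n)
            covered += count * (lo <= p <= hi)
        out[f"n={n},p={p}"] = covered / n_draws
    out["min_coverage"] = min(v for k, v in out.items() if k.startswith("n="))
    out["n_draws"] = n_draws
    return out


def tukey_familywise_error(
    seed: int,
    n_replications: int = 2000,
    n_groups: int = 3,
    n_per_group: int = 20,
    alpha: float = 0.05,
) -> dict:
    """Fraction of equal-mean simulations where Tukey HSD flags any pair."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replications):
        groups = rng.standard_normal((n_groups, n_per_group))
        res = stats.tukey_hsd(*groups)
        off = res.pvalue[np.triu_indices(n_groups, k=1)]
        hits += bool((off < alpha).any())
    return {"familywise_error": hits / n_replications, "n_replications": n_replications}


def mrna_qc_pass_calibration(
    seed: int,
    n_cases: int = 1000,
    n_genes: int = 20,
    n_replicates: int = 2,
    alpha: float = 0.05,
) -> dict:
    """Pass rate of the mRNA gate on data drawn from the reference range.

    With replicate reads drawn from the reference distribution itself the
    two-sided chi-squared gate should pass ~(1 - alpha) of cases.
    """
    rng = np.random.default_rng(seed)
    means = rng.uniform(500.0, 2000.0, size=n_genes)
    sd = 0.1 * means
    reads = rng.normal(means[None, :, None], sd[None, :, None], size=(n_cases, n_genes, n_replicates))
    flags = qc.mrna_qc_flags_matrix(reads, sd**2, alpha=alpha)
    return {"pass_rate": float(flags.mean()), "n_cases": n_cases}


def association_null_type_i_error(
    seed: int,
    n_replications: int = 400,
    n_specimens: int = 500,
) -> dict:
    """Type-I error of the bin comparisons on a structureless cohort.

    Effect switches off (flat association means, fixed allele frequency, no
    mass->depth coupling); counts the replications where any tumor bin is
    flagged against the highest range for the association outcome.
    """
    scheme = BinScheme()
    hits = 0
    for child in _child_seeds(seed, n_replications):
        cfg = CohortConfig(
            seed=child,
            n_specimens=n_specimens,
            association_effects=False,
            coverage_effects=False,
            n_genes=4,
            bases_per_gene=5,
            n_mrna_genes=5,
            n_cn_genes=5,
        )
        table = measure_cohort(generate_cohort(cfg))
        res = compare_bins(table, "drug_associations", scheme, axis="tumor", kind="count")
        hits += bool(any(res.significant_vs_highest.values()))
    return {"type_i_error": hits / n_replications, "n_replications": n_replications}
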