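"""Synthetic specimen cohorts with the adequacy structure of a clinical series.

The generator emulates a consecutive clinical cohort: specimen geometry and
tumor content drawn from configurable bin distributions, a small fraction
cancelled before sequencing (no tissue left in the block), a configurable
overall QNS rate, duplicate-library per-base coverage from an overdispersed
(negative binomial) depth model scaled by the recoverable input mass
(area x curls / 500 mm^2, curls capped by availability), sequencing-error
mutant reads everywhere plus true mutations at catalog hotspot bases with
allele frequency half the tumor-nuclei fraction, per-specimen multi-analyte
findings wired to a generated drug-rule library, and replicate reads feeding
the mRNA and copy-number QC gates.

Two structural levers matter downstream:

* low-coverage gene counts are NOT injected — they emerge from the detection
  model itself, because the expected allele frequency m = purity/2 falls
  below the calling proportion r in low-tumor specimens;
* drug-association counts follow configurable per-bin means (the default
  drops from 21 in the highest ranges to 3 in the <=5 mm^2 area bin and 10
  in the 1-3% tumor bin), combined across the two axes by min().

Setting ``coverage_effects=False`` (fixed m, no mass->depth coupling) and
``association_effects=False`` (flat bin means) yields a structureless null
cohort for type-I-error calibration.  Ground truth (true association counts,
true mutant genes, input-mass factors) is retained on every record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import qc
from .rules import ANALYTES, Criterion, Finding, PatientProfile, Rule, evaluate
from .sensitivity import CallingParams, PriorWeights, panel_gene_sensitivity

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "measure_cohort",
           "export_s2_like", "config_from_yaml"]

_DRUGS = (
    "erlotinib", "trastuzumab", "imatinib", "vemurafenib", "crizotinib",
    "olaparib", "pembrolizumab", "everolimus", "cetuximab", "palbociclib",
    "lapatinib", "sunitinib", "bevacizumab", "tamoxifen", "enzalutamide",
)

#: printed case mix of the emulated series (counts; remainder = other)
DEFAULT_DIAGNOSIS_MIX = {
    "nsclc": 624,
    "breast": 507,
    "colon": 222,
    "pancreatic": 110,
    "unknown_primary": 129,
    "other": 1131,
}


@dataclass(kw_only=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.  ``seed`` is mandatory."""

    seed: int
    n_specimens: int = 2000
    #: overall QNS proportion, including pre-sequencing cancellations
    qns_rate: float = 0.064
    #: fraction cancelled before sequencing (24/2,723 in the emulated series)
    cancelled_rate: float = 24.0 / 2723.0
    tumor_bin_edges: tuple[float, ...] = (1.0, 3.0, 5.0, 10.0, 25.0, 100.0)
    tumor_bin_probs: tuple[float, ...] = (0.06, 0.08, 0.14, 0.24, 0.48)
    area_bin_edges: tuple[float, ...] = (1.0, 5.0, 10.0, 20.0, 30.0, 100.0)
    area_bin_probs: tuple[float, ...] = (0.08, 0.12, 0.20, 0.15, 0.45)
    #: mean mutation-library depth at full input mass
    mean_depth: float = 13656.0
    depth_dispersion: float = 8.0
    error_rate: float = 5e-4
    n_genes: int = 20
    bases_per_gene: int = 20
    mutation_rate_per_gene: float = 0.10
    replicates: int = 2
    calling: CallingParams = field(default_factory=CallingParams)
    target_area_mm2: float = 500.0
    max_curls: int = 40
    n_rules: int = 30
    base_mean_associations: float = 21.0
    tumor_bin_association_means: tuple[float, ...] = (10.0, 18.0, 19.0, 20.0, 21.0)
    area_bin_association_means: tuple[float, ...] = (3.0, 15.0, 18.0, 20.0, 21.0)
    association_effects: bool = True
    coverage_effects: bool = True
    #: fixed mutant allele frequency used when coverage_effects is off
    m_override: float = 0.25
    n_mrna_genes: int = 20
    mrna_ref_cv: float = 0.10
    n_cn_genes: int = 20
    cn_cv: float = 0.10
    cn_fail_rate: float = 0.02
    diagnosis_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX))

    def __post_init__(self) -> None:
        if self.seed is None or int(self.seed) != self.seed:
            raise ValueError("an integer seed is mandatory for reproducibility")
        if self.n_specimens < 0:
            raise ValueError("n_specimens must be >= 0")
        if not 0.0 <= self.qns_rate <= 1.0 or not 0.0 <= self.cancelled_rate <= 1.0:
            raise ValueError("rates must lie in [0, 1]")
        if self.cancelled_rate > self.qns_rate:
            raise ValueError("cancelled_rate cannot exceed the overall qns_rate")
        for name, edges, probs in (
            ("tumor", self.tumor_bin_edges, self.tumor_bin_probs),
            ("area", self.area_bin_edges, self.area_bin_probs),
        ):
            if len(probs) != len(edges) - 1:
                raise ValueError(f"{name}: need one probability per bin")
            if any(p < 0 for p in probs) or not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name}: bin probabilities must be >= 0 and sum to 1")
            if any(a >= b for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name}: bin edges must be strictly increasing")
        for name, means, edges in (
            ("tumor", self.tumor_bin_association_means, self.tumor_bin_edges),
            ("area", self.area_bin_association_means, self.area_bin_edges),
        ):
            if len(means) != len(edges) - 1:
                raise ValueError(f"{name}: need one association mean per bin")
        if self.base_mean_associations > self.n_rules:
            raise ValueError("base mean association count cannot exceed the rule count")


@dataclass
class SyntheticCohort:
    """Generated raw material plus retained ground truth."""

    config: CohortConfig
    n_cancelled: int
    specimens: pd.DataFrame  # one row per received, non-cancelled specimen
    coverage_n: np.ndarray  # (rows, genes, bases, replicates); 0 for QNS rows
    coverage_mut: np.ndarray
    weights_array: np.ndarray  # (genes, bases)
    prior_weights: PriorWeights
    genes: list[str]
    rules: list[Rule]
    findings_present: np.ndarray  # (rows, n_rules) bool
    mrna_reads: np.ndarray  # (rows, n_mrna_genes, replicates)
    mrna_ref: pd.DataFrame  # gene, mean, variance
    cn_reads: np.ndarray  # (rows, n_cn_genes, replicates)

    def profile(self, i: int) -> PatientProfile:
        """Patient profile for specimen row ``i`` (explicit panel findings)."""
        prof = PatientProfile()
        present = self.findings_present[i]
        for j, rule in enumerate(self.rules):
            crit = rule.criteria[0]
            prof.set(crit.analyte, crit.target, Finding("present" if present[j] else "absent"))
        return prof


def _build_rules(n_rules: int) -> list[Rule]:
    rules: list[Rule] = []
    for j in range(n_rules):
        analyte = ANALYTES[j % len(ANALYTES)]
        target = f"TGT{j:02d}"
        rules.append(
            Rule(
                rule_id=f"R{j + 1:03d}",
                drug=_DRUGS[j % len(_DRUGS)],
                criteria=(Criterion(analyte=analyte, target=target, op="present"),),
                note=f"{analyte} marker {target} positive",
            )
        )
    return rules


def _hotspot_weights(rng: np.random.Generator, n_genes: int, n_bases: int) -> np.ndarray:
    """Sparse, hotspot-heavy per-base priors: a shuffled power law per gene."""
    ranks = np.arange(1, n_bases + 1, dtype=float) ** -1.5
    w = np.tile(ranks, (n_genes, 1))
    for g in range(n_genes):
        rng.shuffle(w[g])
    return w / w.sum(axis=1, keepdims=True)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G, B, R = cfg.n_genes, cfg.bases_per_gene, cfg.replicates
    genes = [f"GENE{g:02d}" for g in range(G)]

    n_cancelled = int(rng.binomial(cfg.n_specimens, cfg.cancelled_rate)) if cfg.n_specimens else 0
    rows = cfg.n_specimens - n_cancelled
    denom = 1.0 - cfg.cancelled_rate
    p_post = (cfg.qns_rate - cfg.cancelled_rate) / denom if denom > 0 else 0.0
    qns = rng.random(rows) < p_post

    tedges = np.asarray(cfg.tumor_bin_edges)
    aedges = np.asarray(cfg.area_bin_edges)
    t_idx = rng.choice(len(cfg.tumor_bin_probs), size=rows, p=cfg.tumor_bin_probs)
    a_idx = rng.choice(len(cfg.area_bin_probs), size=rows, p=cfg.area_bin_probs)
    tumor_pct = rng.uniform(tedges[t_idx], tedges[t_idx + 1])
    area = rng.uniform(aedges[a_idx], aedges[a_idx + 1])

    fill = rng.uniform(0.6, 1.0, size=rows)
    aspect = rng.uniform(1.0, 3.0, size=rows)
    width = np.sqrt(area / (aspect * fill))
    length = aspect * width

    curls = np.minimum(np.ceil(cfg.target_area_mm2 / area), cfg.max_curls).astype(int)
    if cfg.coverage_effects:
        mass = np.minimum(1.0, area * curls / cfg.target_area_mm2)
        m_row = tumor_pct / 100.0 / 2.0
    else:
        mass = np.ones(rows)
        m_row = np.full(rows, cfg.m_override)

    # duplicate-library per-base coverage: negative binomial around the
    # mass-limited mean depth
    k = cfg.depth_dispersion
    mu = cfg.mean_depth * mass
    p_nb = k / (k + np.maximum(mu, 1e-9))
    shape = (rows, G, B, R)
    cov_n = rng.negative_binomial(k, p_nb[:, None, None, None], size=shape).astype(np.int64)
    mut = rng.binomial(cov_n, cfg.error_rate)

    weights = _hotspot_weights(rng, G, B)
    hot = weights.argmax(axis=1)  # catalog hotspot base per gene
    mutated = rng.random((rows, G)) < cfg.mutation_rate_per_gene
    n_hot = cov_n[:, np.arange(G), hot, :]
    signal = rng.binomial(n_hot, np.clip(m_row, 0.0, 1.0)[:, None, None])
    signal = np.where(mutated[:, :, None], signal, 0)
    mut_hot = np.minimum(n_hot, mut[:, np.arange(G), hot, :] + signal)
    mut[:, np.arange(G), hot, :] = mut_hot

    # QNS specimens carry no coverage
    cov_n[qns] = 0
    mut[qns] = 0

    # drug-association structure: per-bin mean counts, combined by min()
    if cfg.association_effects:
        t_mean = np.asarray(cfg.tumor_bin_association_means)[t_idx]
        a_mean = np.asarray(cfg.area_bin_association_means)[a_idx]
        mu_assoc = np.minimum(t_mean, a_mean)
    else:
        mu_assoc = np.full(rows, cfg.base_mean_associations)
    p_finding = np.clip(mu_assoc / cfg.n_rules, 0.0, 1.0)
    findings = rng.random((rows, cfg.n_rules)) < p_finding[:, None]

    # mRNA replicate reads drawn from the reference distribution itself
    mrna_means = rng.uniform(500.0, 2000.0, size=cfg.n_mrna_genes)
    mrna_sd = cfg.mrna_ref_cv * mrna_means
    mrna_reads = rng.normal(mrna_means[None, :, None], mrna_sd[None, :, None],
                            size=(rows, cfg.n_mrna_genes, R))
    mrna_ref = pd.DataFrame(
        {"gene": [f"MRNA{g:02d}" for g in range(cfg.n_mrna_genes)],
         "mean": mrna_means, "variance": mrna_sd**2}
    )

    # copy-number replicate reads: tight repeats, with a small failure mode
    cn_means = rng.uniform(50.0, 200.0, size=cfg.n_cn_genes)
    cn_fail = rng.random(rows) < cfg.cn_fail_rate
    cn_sd_factor = np.where(cn_fail, 0.5, cfg.cn_cv)
    cn_reads = np.abs(
        rng.normal(
            cn_means[None, :, None],
            cn_sd_factor[:, None, None] * cn_means[None, :, None],
            size=(rows, cfg.n_cn_genes, R),
        )
    )

    diag_names = list(cfg.diagnosis_mix)
    diag_w = np.asarray([cfg.diagnosis_mix[d] for d in diag_names], dtype=float)
    diagnosis = rng.choice(diag_names, size=rows, p=diag_w / diag_w.sum())

    specimens = pd.DataFrame(
        {
            "specimen_id": [f"SP{i + 1:05d}" for i in range(rows)],
            "diagnosis": diagnosis,
            "length_mm": length,
            "width_mm": width,
            "fill_fraction": fill,
            "area_mm2": area,
            "percent_tumor_nuclei": tumor_pct,
            "qns": qns,
            "curls": curls,
            "mass_factor": mass,
            "true_association_count": findings.sum(axis=1),
            "n_true_mutant_genes": mutated.sum(axis=1),
        }
    )

    prior = PriorWeights(
        {(genes[g], b + 1): float(weights[g, b]) for g in range(G) for b in range(B)}
    )
    return SyntheticCohort(
        config=cfg,
        n_cancelled=n_cancelled,
        specimens=specimens,
        coverage_n=cov_n,
        coverage_mut=mut,
        weights_array=weights,
        prior_weights=prior,
        genes=genes,
        rules=_build_rules(cfg.n_rules),
        findings_present=findings,
        mrna_reads=mrna_reads,
        mrna_ref=mrna_ref,
        cn_reads=cn_reads,
    )


def measure_cohort(cohort: SyntheticCohort) -> pd.DataFrame:
    """Run the measurement stages on a generated cohort.

    Low-coverage gene counts come from the detection-sensitivity model,
    drug-association counts from the rule engine, and QC flags from the
    replicate gates.  QNS specimens carry no results (NA outcomes).
    Returns a cohort table consumable by :mod:`ngsadequacy.cohort`.
    """
    cfg = cohort.config
    df = cohort.specimens.copy()
    rows = len(df)
    qns = df["qns"].to_numpy(bool)
    ok = ~qns

    low_cov = np.full(rows, np.nan)
    if ok.any():
        m = (df["percent_tumor_nuclei"].to_numpy() / 100.0 / 2.0)
        if not cfg.coverage_effects:
            m = np.full(rows, cfg.m_override)
        gene_s = panel_gene_sensitivity(
            cohort.coverage_n[ok],
            cohort.coverage_mut[ok],
            cohort.weights_array,
            cfg.calling,
            m[ok, None, None, None],
        )
        low_cov[ok] = (gene_s < cfg.calling.sensitivity_threshold).sum(axis=1)

    assoc = np.full(rows, np.nan)
    for i in np.flatnonzero(ok):
        assoc[i] = evaluate(cohort.profile(i), cohort.rules).association_count

    ref_var = cohort.mrna_ref["variance"].to_numpy()
    mrna_pass = np.where(ok, qc.mrna_qc_flags_matrix(cohort.mrna_reads, ref_var), False)
    cn_pass = np.where(ok, qc.copy_number_cv_matrix(cohort.cn_reads) <= qc.COPY_NUMBER_CV_LIMIT, False)

    df["low_coverage_genes"] = low_cov
    df["drug_associations"] = assoc
    df["mrna_qc_pass"] = pd.array(np.where(ok, mrna_pass, None), dtype="boolean")
    df["copy_number_qc_pass"] = pd.array(np.where(ok, cn_pass, None), dtype="boolean")
    return df


PUBLIC_COLUMNS = (
    "specimen_id",
    "diagnosis",
    "length_mm",
    "width_mm",
    "fill_fraction",
    "area_mm2",
    "percent_tumor_nuclei",
    "qns",
    "mrna_qc_pass",
    "copy_number_qc_pass",
    "low_coverage_genes",
    "drug_associations",
)

GROUND_TRUTH_COLUMNS = (
    "specimen_id",
    "curls",
    "mass_factor",
    "true_association_count",
    "n_true_mutant_genes",
)


def export_s2_like(
    cohort: SyntheticCohort,
    path: str | Path | None = None,
    ground_truth_path: str | Path | None = None,
    table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One public row per received specimen; ground truth goes to a side file.

    Pass a pre-computed ``table`` (from :func:`measure_cohort`) to avoid
    re-measuring; the public view excludes generator ground-truth columns.
    Written as TSV (or XLSX if the path says so); loadable by
    :func:`ngsadequacy.cohort.read_s2` and round-trips losslessly.
    """
    if table is None:
        table = measure_cohort(cohort)
    public = table.loc[:, list(PUBLIC_COLUMNS)]
    if path is not None:
        path = Path(path)
        if path.suffix.lower() == ".xlsx":
            public.to_excel(path, index=False)
        else:
            public.to_csv(path, sep="\t", index=False)
    if ground_truth_path is not None:
        table.loc[:, list(GROUND_TRUTH_COLUMNS)].to_csv(ground_truth_path, sep="\t", index=False)
    return public


def config_from_yaml(path: str | Path, seed: int | None = None) -> CohortConfig:
    """Load a CohortConfig from a YAML mapping; ``seed`` overrides the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("cohort config must be a YAML mapping")
    if "calling" in raw:
        raw["calling"] = CallingParams(**raw["calling"])
    for key in ("tumor_bin_edges", "tumor_bin_probs", "area_bin_edges", "area_bin_probs",
                "tumor_bin_association_means", "area_bin_association_means"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if seed is not None:
        raw["seed"] = seed
    return CohortConfig(**raw)
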