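"""Tissue geometry: bounding-rectangle area, curl planning, FNA pass counts.

Specimen surface area is estimated at accessioning as the smallest rectangle
the tissue fits into (longest dimension, then the perpendicular) scaled by a
visually-estimated fill fraction — 100% for a perfect rectangle, pi/4 = 79%
for a perfect circle.  Ten-micron sections ("curls") are cut from the FFPE
block targeting up to 500 mm^2 of tissue per nucleic-acid type, so the curl
count is ceil(target / area).  For fine-needle aspirates, a pass is modeled
as contributing a longitudinal tissue core of inner diameter x core length,
and the pass count is the ceiling of the required area over that per-pass
area.  Adequacy thresholds default to >= 10 mm^2 with >= 5% tumor nuclei.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Specimen",
    "CurlPlan",
    "NeedleSpec",
    "AdequacyThresholds",
    "AdequacyVerdict",
    "specimen_area",
    "circle_fill_fraction",
    "curls_needed",
    "plan_curls",
    "fna_passes",
    "adequacy_check",
    "load_gauge_table",
]

DEFAULT_TARGET_AREA_MM2 = 500.0
DEFAULT_CURL_THICKNESS_UM = 10.0
DEFAULT_CORE_LENGTH_MM = 10.0
DEFAULT_REQUIRED_AREA_MM2 = 10.0


def load_gauge_table(path: str | Path | None = None) -> dict[int, float]:
    """Needle gauge -> inner diameter (mm), strictly decreasing in gauge.

    Ships the standard regular-wall hypodermic chart (14-25G); pass a TSV
    with columns gauge, inner_diameter_mm to override.
    """
    if path is None:
        source = resources.files("ngsadequacy.data").joinpath("needle_gauge.tsv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = {"gauge", "inner_diameter_mm"} - set(df.columns)
    if missing:
        raise ValueError(f"gauge table missing columns: {sorted(missing)}")
    table = {int(r.gauge): float(r.inner_diameter_mm) for r in df.itertuples(index=False)}
    gauges = sorted(table)
    if any(table[a] <= table[b] for a, b in zip(gauges, gauges[1:])):
        raise ValueError("inner diameter must strictly decrease as gauge number increases")
    return table


_DEFAULT_GAUGE_TABLE: dict[int, float] | None = None


def _gauge_table() -> dict[int, float]:
    global _DEFAULT_GAUGE_TABLE
    if _DEFAULT_GAUGE_TABLE is None:
        _DEFAULT_GAUGE_TABLE = load_gauge_table()
    return _DEFAULT_GAUGE_TABLE


def specimen_area(length_mm: float, width_mm: float, fill_fraction: float) -> float:
    """Bounding-rectangle area scaled by the tissue fill fraction (mm^2)."""
    if length_mm <= 0 or width_mm <= 0:
        raise ValueError("specimen dimensions must be positive")
    if not 0.0 < fill_fraction <= 1.0:
        raise ValueError(f"fill fraction must lie in (0, 1], got {fill_fraction}")
    return length_mm * width_mm * fill_fraction


def circle_fill_fraction() -> float:
    """Fill fraction of a perfect circle in its bounding square: pi/4."""
    return math.pi / 4.0


@dataclass(frozen=True)
class Specimen:
    """Measured tissue geometry plus the pathologist's tumor-nuclei fraction.

    ``length_mm``/``width_mm`` are normalized so length >= width;
    ``percent_tumor_nuclei`` is stored as a fraction in (0, 1].
    """

    length_mm: float
    width_mm: float
    fill_fraction: float
    percent_tumor_nuclei: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("specimen dimensions must be positive")
        if self.width_mm > self.length_mm:
            length, width = self.width_mm, self.length_mm
            object.__setattr__(self, "length_mm", length)
            object.__setattr__(self, "width_mm", width)
        if not 0.0 < self.fill_fraction <= 1.0:
            raise ValueError(f"fill fraction must lie in (0, 1], got {self.fill_fraction}")
        if not 0.0 < self.percent_tumor_nuclei <= 1.0:
            raise ValueError(
                f"tumor-nuclei fraction must lie in (0, 1], got {self.percent_tumor_nuclei}"
            )

    @property
    def area_mm2(self) -> float:
        return specimen_area(self.length_mm, self.width_mm, self.fill_fraction)


def curls_needed(area_mm2: float, target_area_mm2: float = DEFAULT_TARGET_AREA_MM2) -> int:
    """Curls to cut to reach the target tissue area: ceil(target / area)."""
    if area_mm2 <= 0:
        raise ValueError(f"specimen area must be positive, got {area_mm2}")
    if target_area_mm2 <= 0:
        raise ValueError(f"target area must be positive, got {target_area_mm2}")
    return max(1, math.ceil(target_area_mm2 / area_mm2))


@dataclass(frozen=True)
class CurlPlan:
    target_area_mm2: float
    curl_thickness_um: float
    curls_per_nucleic_acid: int
    achievable: bool  # False when the uncapped plan exceeded the configured maximum


def plan_curls(
    area_mm2: float,
    target_area_mm2: float = DEFAULT_TARGET_AREA_MM2,
    curl_thickness_um: float = DEFAULT_CURL_THICKNESS_UM,
    max_curls: int | None = None,
) -> CurlPlan:
    """Curl plan with an optional availability cap.

    Block depth is not measurable at accessioning, so availability is a
    configured cap rather than an inference; a capped plan is marked not
    achievable and the lab proceeds with whatever tissue is available.
    """
    wanted = curls_needed(area_mm2, target_area_mm2)
    if max_curls is not None and wanted > max_curls:
        return CurlPlan(target_area_mm2, curl_thickness_um, max_curls, achievable=False)
    return CurlPlan(target_area_mm2, curl_thickness_um, wanted, achievable=True)


@dataclass(frozen=True)
class NeedleSpec:
    """FNA needle: gauge, inner diameter, and assumed core length per pass."""

    gauge: int
    inner_diameter_mm: float
    core_length_mm: float = DEFAULT_CORE_LENGTH_MM

    def __post_init__(self) -> None:
        if self.inner_diameter_mm <= 0 or self.core_length_mm <= 0:
            raise ValueError("needle dimensions must be positive")

    @classmethod
    def from_gauge(
        cls,
        gauge: int,
        core_length_mm: float = DEFAULT_CORE_LENGTH_MM,
        table: dict[int, float] | None = None,
    ) -> "NeedleSpec":
        table = table if table is not None else _gauge_table()
        if gauge not in table:
            raise KeyError(f"gauge {gauge} not in lookup table (have {sorted(table)})")
        return cls(gauge=gauge, inner_diameter_mm=table[gauge], core_length_mm=core_length_mm)

    @property
    def area_per_pass_mm2(self) -> float:
        # longitudinal-section model: the embedded face of the core
        return self.inner_diameter_mm * self.core_length_mm


def fna_passes(needle: NeedleSpec, required_area_mm2: float = DEFAULT_REQUIRED_AREA_MM2) -> int:
    """Number of FNA passes needed to bank ``required_area_mm2`` of tissue."""
    if required_area_mm2 <= 0:
        raise ValueError("required area must be positive")
    return math.ceil(required_area_mm2 / needle.area_per_pass_mm2)


class AdequacyVerdict(str, Enum):
    ADEQUATE = "adequate"
    MARGINAL = "marginal"
    INADEQUATE = "inadequate"


@dataclass(frozen=True)
class AdequacyThresholds:
    """Inclusive floors: 'at least 10 mm^2' means 10.0 passes."""

    adequate_area_mm2: float = 10.0
    adequate_tumor_fraction: float = 0.05
    marginal_area_mm2: float = 5.0
    marginal_tumor_fraction: float = 0.03


def adequacy_check(
    specimen: Specimen, thresholds: AdequacyThresholds = AdequacyThresholds()
) -> AdequacyVerdict:
    """Adequacy verdict from area and tumor content.

    Adequate: area and tumor fraction both at or above the adequate floors.
    Marginal: area at or above the marginal floor OR tumor fraction at or
    above the marginal floor.  Otherwise inadequate.
    """
    area = specimen.area_mm2
    tumor = specimen.percent_tumor_nuclei
    if area >= thresholds.adequate_area_mm2 and tumor >= thresholds.adequate_tumor_fraction:
        return AdequacyVerdict.ADEQUATE
    if area >= thresholds.marginal_area_mm2 or tumor >= thresholds.marginal_tumor_fraction:
        return AdequacyVerdict.MARGINAL
    return AdequacyVerdict.INADEQUATE
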