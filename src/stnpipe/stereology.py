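"""Optical-fractionator stereology: density, volume and precision.

Cells are counted in optical dissectors (a counting frame of known area
times a dissector height) placed on a systematic sampling grid across a
series of sections.  Because the full structure is not sampled, the
primary output is cell density (cells/mm^3) within the sampled volume;
reference volumes come from the Cavalieri estimator and estimator
precision from a coefficient-of-error (CE) decomposition into counting
noise and systematic-sampling variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FractionatorDesign",
    "StereologySample",
    "CEEstimate",
    "dissector_volume",
    "fractionator_density",
    "cavalieri_volume",
    "ce_estimate",
    "percent_change",
]

UM3_PER_MM3 = 1e9


@dataclass(frozen=True)
class FractionatorDesign:
    """Sampling geometry of the optical fractionator (lengths in um)."""

    frame_width_um: float = 50.0
    frame_height_um: float = 50.0
    dissector_height_um: float = 20.0
    grid_step_x_um: float = 150.0
    grid_step_y_um: float = 150.0
    section_thickness_um: float = 40.0
    section_period: int = 3

    def __post_init__(self):
        dims = (
            self.frame_width_um,
            self.frame_height_um,
            self.dissector_height_um,
            self.grid_step_x_um,
            self.grid_step_y_um,
            self.section_thickness_um,
        )
        if any(d <= 0 for d in dims) or self.section_period < 1:
            raise ValueError("all design dimensions must be positive")
        if self.frame_width_um > self.grid_step_x_um or self.frame_height_um > self.grid_step_y_um:
            raise ValueError("counting frame must fit within a grid cell")


@dataclass
class StereologySample:
    """Per-(section, ROI) dissector counts plus sampling geometry.

    ``table`` columns: section_id, roi, n_sites, count and (optionally)
    area_um2 for the Cavalieri estimator.
    """

    table: pd.DataFrame
    design: FractionatorDesign

    def __post_init__(self):
        required = {"section_id", "roi", "n_sites", "count"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"stereology table missing columns {sorted(missing)}")
        if (self.table["count"] < 0).any() or (self.table["n_sites"] < 1).any():
            raise ValueError("counts must be >= 0 and sites >= 1")

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, design: FractionatorDesign) -> "StereologySample":
        return cls(pd.read_csv(path), design)


def dissector_volume(design: FractionatorDesign) -> tuple[float, float]:
    """(dissector volume um^3, sampling grid area um^2) of a design."""
    volume = design.frame_width_um * design.frame_height_um * design.dissector_height_um
    grid_area = design.grid_step_x_um * design.grid_step_y_um
    return volume, grid_area


def fractionator_density(sample: StereologySample) -> dict[str, float]:
    """Cell density (cells/mm^3) per ROI: total count over sampled volume."""
    volume_um3, _ = dissector_volume(sample.design)
    out = {}
    for roi, sub in sample.table.groupby("roi"):
        sites = int(sub["n_sites"].sum())
        if sites == 0:
            raise ValueError(f"ROI {roi!r} has zero sampling sites")
        total = float(sub["count"].sum())
        out[str(roi)] = total / (sites * volume_um3) * UM3_PER_MM3
    return out


def cavalieri_volume(section_areas_um2, thickness_um: float, period: int) -> float:
    """Cavalieri volume estimate in mm^3.

    ``period x thickness x sum(areas)``: every counted section represents
    ``period`` consecutive sections of the series.
    """
    areas = np.asarray(section_areas_um2, dtype=float)
    if thickness_um <= 0 or period < 1:
        raise ValueError("thickness must be positive and period >= 1")
    return float(period * thickness_um * areas.sum() / UM3_PER_MM3)


@dataclass(frozen=True)
class CEEstimate:
    """Coefficient-of-error decomposition for a section series.

    ``noise_ce`` is the counting-noise term 1/sqrt(total count);
    ``srs_ce`` is the systematic-(section-)sampling component from the
    Gundersen-Jensen transitive estimator with smoothness class m; and
    ``total_ce`` combines the two in quadrature.
    """

    noise_ce: float
    srs_ce: float
    total_ce: float
    m: int


def ce_estimate(section_counts, estimator: str = "noise", m: int = 1) -> float | CEEstimate:
    """Precision of a fractionator count from its per-section counts.

    ``estimator="noise"`` returns the Poisson counting-noise CE,
    1/sqrt(sum Q).  ``estimator="section-series"`` returns a CEEstimate
    with the Gundersen-Jensen systematic-sampling component (smoothness
    class m in {0, 1}) alongside the noise term; its headline ``total_ce``
    adds the two variances.
    """
    q = np.asarray(section_counts, dtype=float)
    if q.size < 3:
        raise ValueError("need at least 3 sections")
    total = q.sum()
    if total == 0:
        raise ValueError("CE undefined for a zero total count")
    noise_ce = 1.0 / np.sqrt(total)
    if estimator == "noise":
        return float(noise_ce)
    if estimator != "section-series":
        raise ValueError(f"unknown CE estimator {estimator!r}")
    if m not in (0, 1):
        raise ValueError("smoothness class m must be 0 or 1")
    a = float(np.sum(q * q))
    b = float(np.sum(q[:-1] * q[1:]))
    c = float(np.sum(q[:-2] * q[2:]))
    denom = 240.0 if m == 1 else 12.0
    var_srs = max((3.0 * (a - total) - 4.0 * b + c) / denom, 0.0)
    srs_ce = np.sqrt(var_srs) / total
    total_ce = np.sqrt(total + var_srs) / total
    return CEEstimate(float(noise_ce), float(srs_ce), float(total_ce), m)


def percent_change(mean_a: float, mean_b: float) -> float:
    """Percent change of a relative to b: 100 * (a - b) / b."""
    if mean_b == 0:
        raise ValueError("reference mean must be nonzero")
    return 100.0 * (mean_a - mean_b) / mean_b
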