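"""Case-file I/O, structured run reports, and scripted study reproductions.

A *case* is a JSON document describing the targets (analytic spheres or mesh
files), the setup uncertainty (translational margin ``m_s`` **or** SD
``sigma_s``, rotational SD ``sigma_d``, coverage ``alpha``), and optional
optimizer / lattice overrides.  :func:`run_case` orchestrates geometry →
expansion → optimization and returns a serializable :class:`RunReport` whose
rows mirror the COG/COV/COS/(NSO)/optimizer comparison.

Reproduction helpers regenerate the simulation-study tables: the two-sphere
normalized-optimum sweep (:func:`reproduce_table1`), the along-segment
normalized-volume curves (:func:`sweep_line`) and the planar normalized-volume
heat map (:func:`heatmap_table`).
"""

from __future__ import annotations

import importlib.metadata
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .expansion import MarginVolumeEvaluator
from .geometry import (
    TargetSet,
    center_of_geometry,
    center_of_surface,
    center_of_volume,
    make_mesh_target,
    make_sphere_target,
    two_sphere_phantom,
)
from .margin_model import SetupUncertainty
from .optimize import OptimizerConfig, SearchSpace, compare_isocenters

__all__ = [
    "CaseSpec",
    "RunReport",
    "load_case",
    "save_case",
    "run_case",
    "report_to_tsv",
    "reproduce_table1",
    "sweep_line",
    "heatmap_table",
]

try:
    __version__ = importlib.metadata.version("isomargin")
except importlib.metadata.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


class SphereSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    center: tuple[float, float, float]
    diameter: float = Field(gt=0.0)


class TargetSpec(BaseModel):
    """Exactly one of ``sphere`` or ``mesh_path``."""

    model_config = ConfigDict(extra="forbid")
    label: str
    sphere: Optional[SphereSpec] = None
    mesh_path: Optional[str] = None

    @model_validator(mode="after")
    def _one_source(self) -> "TargetSpec":
        if (self.sphere is None) == (self.mesh_path is None):
            raise ValueError(f"target {self.label!r}: give exactly one of sphere or mesh_path")
        return self


class UncertaintySpec(BaseModel):
    """Exactly one of ``m_s`` (translational margin, mm) or ``sigma_s`` (SD, mm)."""

    model_config = ConfigDict(extra="forbid")
    m_s: Optional[float] = Field(default=None, ge=0.0)
    sigma_s: Optional[float] = Field(default=None, ge=0.0)
    sigma_d: float = Field(ge=0.0, description="rotational SD, degrees")
    alpha: float = Field(default=0.95, gt=0.0, lt=1.0)

    @model_validator(mode="after")
    def _one_parameterization(self) -> "UncertaintySpec":
        if (self.m_s is None) == (self.sigma_s is None):
            raise ValueError("give exactly one of m_s or sigma_s")
        return self

    def build(self) -> SetupUncertainty:
        if self.m_s is not None:
            return SetupUncertainty.from_margin(self.m_s, self.sigma_d, self.alpha)
        return SetupUncertainty(self.sigma_s, self.sigma_d, self.alpha)


class OptimizerSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["asa", "grid"] = "asa"
    grid_step: float = Field(default=1.0, gt=0.0)
    seed: int = 0
    max_evaluations: int = Field(default=2000, gt=0)
    no_improvement_stop: int = Field(default=300, gt=0)
    reanneal_interval: int = Field(default=50, gt=0)
    initial_temperature: float = Field(default=1.0, gt=0.0)
    temperature_scale: float = Field(default=1.0, gt=0.0)
    with_nso: bool = False


class GridSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    inner_spacing: float = Field(default=1.0, gt=0.0, description="optimization lattice, mm")
    final_spacing: float = Field(default=0.5, gt=0.0, description="measurement lattice, mm")


class CaseSpec(BaseModel):
    """Serializable description of one isocenter-selection problem."""

    model_config = ConfigDict(extra="forbid")
    targets: list[TargetSpec] = Field(min_length=1)
    uncertainty: UncertaintySpec
    optimizer: OptimizerSpec = OptimizerSpec()
    grid: GridSpec = GridSpec()

    @model_validator(mode="after")
    def _unique_labels(self) -> "CaseSpec":
        labels = [t.label for t in self.targets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"target labels must be unique, got {labels}")
        return self

    def build_targets(self, base_dir: Path | None = None) -> TargetSet:
        out = []
        for t in self.targets:
            if t.sphere is not None:
                out.append(make_sphere_target(t.sphere.center, t.sphere.diameter, label=t.label))
            else:
                path = Path(t.mesh_path)
                if base_dir is not None and not path.is_absolute():
                    path = base_dir / path
                out.append(make_mesh_target(path, label=t.label))
        return TargetSet(tuple(out))

    def build_optimizer_config(self) -> OptimizerConfig:
        o = self.optimizer
        return OptimizerConfig(
            method=o.method,
            grid_step=o.grid_step,
            seed=o.seed,
            inner_spacing=self.grid.inner_spacing,
            final_spacing=self.grid.final_spacing,
            max_evaluations=o.max_evaluations,
            no_improvement_stop=o.no_improvement_stop,
            reanneal_interval=o.reanneal_interval,
            initial_temperature=o.initial_temperature,
            temperature_scale=o.temperature_scale,
            with_nso=o.with_nso,
        )


class IsoRow(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    position: tuple[float, float, float]
    v_margin: float
    normalized_to_cog: float
    evaluations_used: int = 0


class RunReport(BaseModel):
    """Result of :func:`run_case`: the comparison table plus reproducibility metadata."""

    model_config = ConfigDict(extra="forbid")
    case: CaseSpec
    rows: list[IsoRow]
    version: str
    seed: int
    inner_spacing: float
    final_spacing: float

    def row(self, label: str) -> IsoRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)


def load_case(path) -> CaseSpec:
    """Load and schema-validate a JSON case file (defaults filled in)."""
    with open(path) as fh:
        data = json.load(fh)
    return CaseSpec.model_validate(data)


def save_case(case: CaseSpec, path) -> None:
    Path(path).write_text(case.model_dump_json(indent=2, exclude_none=True) + "\n")


def run_case(case: CaseSpec, base_dir: Path | None = None) -> RunReport:
    """Run the full pipeline for one case: geometry → expansion → optimization."""
    ts = case.build_targets(base_dir=base_dir)
    u = case.uncertainty.build()
    cfg = case.build_optimizer_config()
    rows = compare_isocenters(ts, u, cfg)
    return RunReport(
        case=case,
        rows=[
            IsoRow(
                label=r.label,
                position=tuple(r.position),
                v_margin=r.v_margin,
                normalized_to_cog=r.normalized_to_cog,
                evaluations_used=r.evaluations_used,
            )
            for r in rows
        ],
        version=__version__,
        seed=case.optimizer.seed,
        inner_spacing=case.grid.inner_spacing,
        final_spacing=case.grid.final_spacing,
    )


def report_to_tsv(report: RunReport) -> str:
    """Flat TSV rendering of the comparison table."""
    lines = ["label\tx_mm\ty_mm\tz_mm\tv_margin_mm3\tnormalized_to_cog\tevaluations"]
    for r in report.rows:
        x, y, z = r.position
        lines.append(
            f"{r.label}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t{r.v_margin:.3f}"
            f"\t{r.normalized_to_cog:.4f}\t{r.evaluations_used}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Study reproductions
# ---------------------------------------------------------------------------

#: The two-sphere sweep: D1 columns x D2 rows for each rotational SD.
TABLE1_D1 = (5.0, 10.0)
TABLE1_D2 = (5.0, 10.0, 20.0, 30.0, 40.0)
TABLE1_SIGMA_D = (0.5, 1.0)


def _two_sphere_cell(
    d1: float,
    d2: float,
    sigma_d: float,
    m_s: float = 2.0,
    alpha: float = 0.95,
    inner_spacing: float = 1.0,
    final_spacing: float = 0.5,
    grid_step: float = 1.0,
) -> dict:
    """Normalized optimal margin volume for one two-sphere configuration (segment NSO)."""
    ts = two_sphere_phantom(d1, d2)
    u = SetupUncertainty.from_margin(m_s, sigma_d, alpha)
    cfg = OptimizerConfig(
        method="grid",
        grid_step=grid_step,
        inner_spacing=inner_spacing,
        final_spacing=final_spacing,
    )
    rows = compare_isocenters(ts, u, cfg)
    by = {r.label: r for r in rows}
    return {
        "sigma_d": sigma_d,
        "d1": d1,
        "d2": d2,
        "normalized_optimal": by["NSO"].normalized_to_cog,
        "optimal_x_mm": float(by["NSO"].position[0]),
        "evaluations": by["NSO"].evaluations_used,
    }


def reproduce_table1(
    cells: Sequence[tuple[float, float, float]] | None = None,
    m_s: float = 2.0,
    alpha: float = 0.95,
    inner_spacing: float = 1.0,
    final_spacing: float = 0.5,
) -> pd.DataFrame:
    """Two-sphere sweep of normalized optimal margin volumes.

    ``cells`` is an optional subset of ``(d1, d2, sigma_d)`` triples; by
    default all 20 combinations (D1 in {5, 10}, D2 in {5, 10, 20, 30, 40},
    sigma_d in {0.5, 1.0} degrees, M_S = 2 mm, 100 mm separation) are run.
    """
    if cells is None:
        cells = [
            (d1, d2, sd) for sd in TABLE1_SIGMA_D for d1 in TABLE1_D1 for d2 in TABLE1_D2
        ]
    records = [
        _two_sphere_cell(
            d1, d2, sd, m_s=m_s, alpha=alpha,
            inner_spacing=inner_spacing, final_spacing=final_spacing,
        )
        for d1, d2, sd in cells
    ]
    return pd.DataFrame.from_records(records)


def sweep_line(
    ts: TargetSet,
    u: SetupUncertainty,
    step: float = 1.0,
    spacing: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Normalized margin volume along the segment joining two target centroids.

    Returns a ``(position_mm, v_margin_mm3, normalized)`` table (position is
    arc length from the first target's centroid) plus the arc-length positions
    of COG, COV, COS and the curve minimum.  Two targets only.
    """
    if ts.n != 2:
        raise ValueError("sweep_line requires exactly two targets")
    space = SearchSpace.from_targets(ts, restriction="segment")
    ev = MarginVolumeEvaluator(ts, u, spacing=spacing, search_bounds=(space.lower, space.upper))
    lo, hi = space.param_bounds()
    positions = np.arange(lo[0], hi[0] + step / 2, step)
    values = np.array([ev(space.to_point(np.array([t]))) for t in positions])
    cog_value = ev(center_of_geometry(ts))
    df = pd.DataFrame(
        {
            "position_mm": positions,
            "v_margin_mm3": values,
            "normalized": values / cog_value,
        }
    )
    marks = {
        "cog": float(space.to_params(center_of_geometry(ts))[0]),
        "cov": float(space.to_params(center_of_volume(ts))[0]),
        "cos": float(space.to_params(center_of_surface(ts))[0]),
        "optimal": float(positions[int(np.argmin(values))]),
    }
    return df, marks


def heatmap_table(
    ts: TargetSet,
    u: SetupUncertainty,
    step: float = 2.0,
    spacing: float = 1.0,
    half_width: float = 20.0,
) -> pd.DataFrame:
    """Planar normalized-margin-volume map around the segment joining two targets.

    Candidates lie in the plane spanned by the segment direction and a
    perpendicular axis through the COG (``half_width`` mm each side).  Columns:
    ``x, y, z`` (candidate position, mm) and ``value`` (normalized volume);
    exportable as delimited text.
    """
    if ts.n != 2:
        raise ValueError("heatmap_table requires exactly two targets")
    a, b = ts.targets[0].centroid, ts.targets[1].centroid
    e1 = (b - a) / np.linalg.norm(b - a)
    # any perpendicular axis
    trial = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, trial)
    e2 /= np.linalg.norm(e2)
    length = float(np.linalg.norm(b - a))
    t_axis = np.arange(0.0, length + step / 2, step)
    s_axis = np.arange(-half_width, half_width + step / 2, step)
    lows = np.minimum.reduce([a + s * e2 for s in (-half_width, half_width)] + [a, b])
    highs = np.maximum.reduce([a + s * e2 for s in (-half_width, half_width)] + [a, b])
    ev = MarginVolumeEvaluator(ts, u, spacing=spacing, search_bounds=(lows, highs))
    cog_value = ev(center_of_geometry(ts))
    records = []
    for t in t_axis:
        for s in s_axis:
            p = a + t * e1 + s * e2
            records.append({"x": p[0], "y": p[1], "z": p[2], "value": ev(p) / cog_value})
    return pd.DataFrame.from_records(records)
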