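"""Pressure-ratio parameter sweeps, normalisation and scenario statistics.

The study grid crosses total guard-cell pressures (2-9 MPa by default)
with pressure split ratios (0.1-0.9).  Pore areas are normalised per
total pressure against the maximum over the ratio grid; the scalar
stress summary per case is the top-decile mean Cauchy trace.  Replicate
meshes for scenario statistics come from seeded template jitter standing
in for biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import metrics
from .fem import LoadCase, MembraneModel, SolverOptions, solve_equilibrium
from .geometry import DEFAULT_SC_PRESSURE, StomatalTemplate, build_complex, default_materials
from .material import WallMaterial
from .mesh import SurfaceMesh

__all__ = [
    "DEFAULT_TOTALS",
    "DEFAULT_RATIOS",
    "make_load_grid",
    "run_pressure_sweep",
    "normalise_pore_areas",
    "make_replicate_templates",
    "compare_stress_scenarios",
    "paired_geometry_test",
    "SweepError",
]

DEFAULT_TOTALS = tuple(float(t) for t in range(2, 10))  # 2..9 MPa
DEFAULT_RATIOS = tuple(round(0.1 * k, 1) for k in range(1, 10))  # 0.1..0.9


class SweepError(RuntimeError):
    """Raised when a sweep cannot produce usable results."""


def make_load_grid(
    totals=DEFAULT_TOTALS,
    ratios=DEFAULT_RATIOS,
    sc_pressure: float = DEFAULT_SC_PRESSURE,
) -> list[LoadCase]:
    """Cartesian product of totals and ratios; defaults give the 8 x 9 grid."""
    totals = list(totals)
    ratios = list(ratios)
    if not totals or not ratios:
        raise ValueError("totals and ratios must be non-empty")
    return [
        LoadCase(total=float(t), ratio=float(r), sc_pressure=sc_pressure)
        for t in totals
        for r in ratios
    ]


def _case_order(grid: list[LoadCase]) -> list[LoadCase]:
    """Solve low pressures first and fan out from the balanced split."""
    return sorted(grid, key=lambda lc: (lc.total, abs(lc.ratio - 0.5), lc.ratio))


def run_pressure_sweep(
    mesh: SurfaceMesh,
    materials: dict[str, WallMaterial],
    grid: list[LoadCase],
    options: SolverOptions | None = None,
    replicate: int = 0,
    warm_start: bool = True,
    keep_states: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict]:
    """Solve every load case and tabulate pore metrics and stress summaries.

    Cases are warm-started from the nearest previously solved case in
    (T, r) for speed; non-converged cases are recorded and excluded from
    normalisation, and more than 20% failures aborts the sweep.
    """
    if not grid:
        raise ValueError("empty load grid")
    opts = options or SolverOptions()
    model = MembraneModel(mesh, materials)
    rows = []
    states: dict[tuple[float, float], object] = {}
    solved: list[tuple[float, float, np.ndarray]] = []
    t_span = max(lc.total for lc in grid) - min(lc.total for lc in grid) or 1.0

    for lc in _case_order(grid):
        x0 = None
        if warm_start and solved:
            key = min(
                solved,
                key=lambda s: abs(s[0] - lc.total) / t_span + abs(s[1] - lc.ratio),
            )
            x0 = key[2]
        state = solve_equilibrium(model, lc, opts, x0=x0)
        if state.converged:
            solved.append((lc.total, lc.ratio, state.positions))
        pm = metrics.pore_metrics(mesh, state.positions)
        rows.append(
            {
                "morphology": _morphology_of(mesh),
                "replicate": replicate,
                "total_pressure": lc.total,
                "ratio": lc.ratio,
                "pore_area": pm.pore_area,
                "pore_width": pm.pore_width,
                "pore_length": pm.pore_length,
                "top_decile_mean_stress": metrics.top_decile_mean_stress(state.cauchy_trace),
                "converged": state.converged,
                "iterations": state.iterations,
            }
        )
        if keep_states:
            states[(lc.total, lc.ratio)] = state

    df = pd.DataFrame(rows).sort_values(["total_pressure", "ratio"]).reset_index(drop=True)
    n_fail = int((~df["converged"]).sum())
    if n_fail > 0.2 * len(df):
        raise SweepError(
            f"{n_fail}/{len(df)} load cases failed to converge; "
            f"failed cases: {df.loc[~df['converged'], ['total_pressure', 'ratio']].values.tolist()}"
        )
    df = normalise_pore_areas(df)
    return (df, states) if keep_states else df


def _morphology_of(mesh: SurfaceMesh) -> str:
    return "dumbbell" if any(n.startswith("SC") for n in mesh.cell_names.values()) else "kidney"


def normalise_pore_areas(df: pd.DataFrame) -> pd.DataFrame:
    """Divide pore areas by the per-(replicate, total-pressure) maximum.

    Only converged rows enter the maximum and receive a normalised value;
    non-converged rows get NaN.  Groups with no converged row are dropped
    with a warning.  Idempotent.
    """
    df = df.copy()
    out = np.full(len(df), np.nan)
    for (_, _), idx in df.groupby(["replicate", "total_pressure"]).groups.items():
        sub = df.loc[idx]
        conv = sub["converged"].astype(bool)
        if not conv.any():
            import warnings

            warnings.warn("pressure group with no converged solves dropped from normalisation")
            continue
        mx = sub.loc[conv, "pore_area"].max()
        out[np.asarray(sub.index[conv])] = sub.loc[conv, "pore_area"] / mx
    df["normalised_pore_area"] = out
    return df


def make_replicate_templates(
    base: StomatalTemplate, n: int, seed: int = 0, rel_jitter: float = 0.05
) -> list[StomatalTemplate]:
    """Seeded ±5% template jitter standing in for biological replicates.

    Bulb/tube radii and wall thicknesses are jittered independently and
    uniformly; the first replicate is the unperturbed base template.
    """
    rng = np.random.default_rng(seed)
    out = [base]
    for k in range(1, n):
        f = lambda: 1.0 + rel_jitter * (2 * rng.random() - 1)
        out.append(
            replace(
                base,
                bulb_radius=base.bulb_radius * f(),
                tube_radius=base.tube_radius * f(),
                wall_thickness_bulb=base.wall_thickness_bulb * f(),
                wall_thickness_rod=base.wall_thickness_rod * f(),
                random_seed=int(rng.integers(2**31 - 1)),
            )
        )
    return out


def compare_stress_scenarios(
    sweep: pd.DataFrame,
    total_pressure: float = 5.0,
    scenario_ratios=(0.5, 0.7, 0.9),
    alpha: float = 0.05,
):
    """ANOVA + Tukey HSD across pressure scenarios ("50:50", "70:30", "90:10").

    ``sweep`` must hold one row per (replicate, total_pressure, ratio) with
    the top-decile mean stress; replicates are the statistical units.
    """
    from .stats import anova_tukey

    groups = {}
    sub = sweep[(sweep["total_pressure"] == total_pressure) & sweep["converged"]]
    for r in scenario_ratios:
        label = f"{int(r * 100)}:{int(round((1 - r) * 100))}"
        vals = sub.loc[np.isclose(sub["ratio"], r), "top_decile_mean_stress"].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"scenario {label} needs >= 2 replicates (got {len(vals)})")
        groups[label] = vals
    return anova_tukey(groups, alpha=alpha)


def paired_geometry_test(values_gc1, values_gc2, alpha: float = 0.05):
    """Paired GC1-vs-GC2 comparison; see :func:`stomamech.stats.paired_location_test`."""
    from .stats import paired_location_test

    return paired_location_test(values_gc1, values_gc2, alpha=alpha)


def run_morphology_sweep(
    morphology: str,
    template: StomatalTemplate | None = None,
    materials: dict[str, WallMaterial] | None = None,
    totals=DEFAULT_TOTALS,
    ratios=DEFAULT_RATIOS,
    sc_pressure: float = DEFAULT_SC_PRESSURE,
    options: SolverOptions | None = None,
    replicate: int = 0,
) -> pd.DataFrame:
    """Convenience wrapper: default template + materials -> sweep table."""
    from .geometry import default_dumbbell_template, default_kidney_template

    if template is None:
        template = (
            default_dumbbell_template() if morphology == "dumbbell" else default_kidney_template()
        )
    mesh = build_complex(template)
    mats = materials or default_materials(morphology)
    grid = make_load_grid(totals, ratios, sc_pressure if morphology == "dumbbell" else 0.0)
    return run_pressure_sweep(mesh, mats, grid, options, replicate=replicate)
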