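"""Load grids, normalisation and replicate generation."""

import numpy as np
import pandas as pd
import pytest

from stomamech import LoadCase, default_dumbbell_template
from stomamech.sweep import (
    DEFAULT_RATIOS,
    DEFAULT_TOTALS,
    make_load_grid,
    make_replicate_templates,
    normalise_pore_areas,
)


def test_default_grid_is_eight_by_nine():
    grid = make_load_grid()
    assert len(grid) == 72
    assert len(DEFAULT_TOTALS) == 8 and len(DEFAULT_RATIOS) == 9
    assert {lc.total for lc in grid} == set(range(2, 10))


def test_single_case_splits_pressure_exactly():
    (lc,) = make_load_grid([2.0], [0.5])
    assert lc.p_gc1 == lc.p_gc2 == 1.0
    assert lc.p_gc1 + lc.p_gc2 == lc.total


def test_symmetric_ratios_transpose_pressures():
    a, b = make_load_grid([4.0], [0.3, 0.7])
    assert (a.p_gc1, a.p_gc2) == pytest.approx((b.p_gc2, b.p_gc1))
    assert a.p_gc1 + a.p_gc2 == a.total


def test_empty_grid_rejected():
    with pytest.raises(ValueError):
        make_load_grid([], [0.5])
    with pytest.raises(ValueError):
        LoadCase(2.0, 0.0)
    with pytest.raises(ValueError):
        LoadCase(-1.0, 0.5)


def _frame(areas, converged=None, T=2.0):
    n = len(areas)
    return pd.DataFrame(
        {
            "replicate": [0] * n,
            "total_pressure": [T] * n,
            "ratio": np.linspace(0.1, 0.9, n),
            "pore_area": areas,
            "converged": converged if converged is not None else [True] * n,
        }
    )


def test_normalisation_divides_by_group_maximum():
    df = normalise_pore_areas(_frame([10.0, 8.0, 5.0]))
    assert list(df["normalised_pore_area"]) == [1.0, 0.8, 0.5]


def test_single_row_group_normalises_to_one():
    df = normalise_pore_areas(_frame([7.3]))
    assert df["normalised_pore_area"].iloc[0] == 1.0


def test_normalisation_is_idempotent():
    df = normalise_pore_areas(_frame([10.0, 8.0, 5.0]))
    again = normalise_pore_areas(df)
    assert np.array_equal(
        df["normalised_pore_area"].values, again["normalised_pore_area"].values
    )


def test_unconverged_rows_excluded_from_normalisation():
    df = normalise_pore_areas(_frame([10.0, 99.0, 5.0], [True, False, True]))
    assert df["normalised_pore_area"].iloc[0] == 1.0  # 99 ignored
    assert np.isnan(df["normalised_pore_area"].iloc[1])
    assert df.groupby(["replicate", "total_pressure"])["normalised_pore_area"].max().iloc[0] == 1.0


def test_all_failed_group_dropped_with_warning():
    with pytest.warns(UserWarning):
        df = normalise_pore_areas(_frame([1.0, 2.0], [False, False]))
    assert df["normalised_pore_area"].isna().all()


def test_warm_started_sweep_matches_cold_solves(kidney_mesh):
    """Spot re-solves from rest agree with warm-started sweep results."""
    from stomamech import SolverOptions
    from stomamech.geometry import default_materials
    from stomamech.sweep import run_pressure_sweep

    grid = make_load_grid([2.0, 3.0], [0.5], sc_pressure=0.0)
    mats = default_materials("kidney")
    warm = run_pressure_sweep(kidney_mesh, mats, grid, SolverOptions(), warm_start=True)
    cold = run_pressure_sweep(kidney_mesh, mats, grid, SolverOptions(), warm_start=False)
    assert warm["pore_area"].to_numpy() == pytest.approx(
        cold["pore_area"].to_numpy(), rel=1e-3
    )


def test_replicate_templates_jitter_within_five_percent():
    base = default_dumbbell_template()
    reps = make_replicate_templates(base, 6, seed=3)
    assert reps[0] == base
    for r in reps[1:]:
        assert abs(r.bulb_radius / base.bulb_radius - 1) <= 0.05
        assert abs(r.wall_thickness_rod / base.wall_thickness_rod - 1) <= 0.05
    again = make_replicate_templates(base, 6, seed=3)
    assert reps == again  # deterministic
    assert len({r.bulb_radius for r in reps}) == 6  # actually distinct
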