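"""Figure-level analyses: ratio sweeps, cost analysis, chi sweep.

Each analysis solves the model over a grid and tabulates the derived
statistics into a tidy DataFrame with one row per grid point and a
stable column order.  The pipeline is deterministic: re-running with
the same configuration reproduces the tables exactly.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .metrics import compute_metrics, total_yield
from .parameters import ModelParameters
from .simulate import (
    RATIO_GRID_FULL,
    RATIO_GRID_MIXED,
    ScenarioConfig,
    solve_scenario,
    sweep_chi,
    sweep_initial_ratio,
)

__all__ = [
    "SWEEP_COLUMNS",
    "reference_density",
    "run_ratio_analysis",
    "run_cost_analysis",
    "run_chi_analysis",
]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = (
    "medium_label",
    "init_frac_C",
    "chi",
    "total_yield",
    "normalized_yield",
    "rf_c",
    "prop_c_initial",
    "prop_c_final",
    "delta_pp",
    "p_tot",
    "g_tot",
    "c_rel",
)


def reference_density(params: ModelParameters, **scenario_kwargs) -> float:
    """Producer-monoculture stationary yield in the glutamic-acid medium.

    All normalized yields divide by this value, so the producer GA run
    itself normalizes to 1.  Warns if the run has not reached stationary
    phase by ``t_end`` (relative slope of the total yield > 1e-4).
    """
    scenario = ScenarioConfig.for_medium("GA_GLY", 0.0, **scenario_kwargs)
    traj = solve_scenario(params, scenario)
    t_end = scenario.t_end
    y_end = total_yield(traj)
    dt = 0.01 * t_end
    slope = (y_end - total_yield(traj, t_end - dt)) / (dt * y_end)
    if abs(slope) > 1e-4:
        warnings.warn(
            f"reference GA run not stationary at t_end={t_end}: relative slope {slope:.3g}",
            stacklevel=2,
        )
    return y_end


def _sweep_rows(
    pairs, medium: str, chi: float, ref: float
) -> list[dict]:
    rows = []
    for frac, traj in pairs:
        report = compute_metrics(traj, reference_density=ref)
        rows.append(
            {
                "medium_label": medium,
                "init_frac_C": frac,
                "chi": chi,
                "total_yield": report.total_yield,
                "normalized_yield": report.normalized_yield,
                "rf_c": report.rf_c,
                "prop_c_initial": report.prop_c_initial,
                "prop_c_final": report.prop_c_final,
                "delta_pp": 100.0 * (report.prop_c_final - report.prop_c_initial),
                "p_tot": report.p_tot,
                "g_tot": report.g_tot,
                "c_rel": report.c_rel,
            }
        )
    return rows


def run_ratio_analysis(
    params: ModelParameters,
    ratio_grid: Sequence[float] = RATIO_GRID_FULL,
    media: Sequence[str] = ("GA_GLY", "BSA_GLY"),
    **scenario_kwargs,
) -> pd.DataFrame:
    """Sweep the initial non-producer fraction in each medium.

    Returns one row per (medium, fraction) with yield, fitness,
    proportion and cost statistics; ``delta_pp`` is the absolute change
    of the non-producer percentage over the run (percentage points).
    """
    ref = reference_density(params, **scenario_kwargs)
    rows: list[dict] = []
    for medium in media:
        base = ScenarioConfig.for_medium(medium, 0.0, **scenario_kwargs)
        pairs = sweep_initial_ratio(params, base, ratio_grid, base.W0 + base.C0)
        rows.extend(_sweep_rows(pairs, medium, params.chi, ref))
    frame = pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
    for medium in media:
        sub = frame[(frame.medium_label == medium) & frame.delta_pp.notna()]
        mixed = sub[(sub.init_frac_C > 0) & (sub.init_frac_C < 1)]
        if not mixed.empty:
            best = mixed.loc[mixed.delta_pp.idxmax()]
            logger.info(
                "%s: greatest absolute non-producer increase %.1f pp at initial fraction %.0f%%",
                medium,
                best.delta_pp,
                100 * best.init_frac_C,
            )
    return frame


def run_cost_analysis(
    params: ModelParameters,
    ratio_grid: Sequence[float] = RATIO_GRID_MIXED,
    **scenario_kwargs,
) -> pd.DataFrame:
    """Relative cost of protease production per (medium, initial fraction).

    Computed on the coculture trajectory of each grid point.  Checks the
    context dependence: the glutamic-acid medium cost must stay below the
    BSA-medium cost at every matched fraction.
    """
    frame = run_ratio_analysis(params, ratio_grid, **scenario_kwargs)
    if params.chi == 0:
        return frame  # no cost anywhere; the context contrast is vacuous
    ga = frame[frame.medium_label == "GA_GLY"].set_index("init_frac_C").c_rel
    bsa = frame[frame.medium_label == "BSA_GLY"].set_index("init_frac_C").c_rel
    if not (ga < bsa).all():
        raise AssertionError(
            "expected GA-medium relative cost below BSA-medium cost at every fraction; "
            f"got GA={ga.to_dict()}, BSA={bsa.to_dict()}"
        )
    return frame


def run_chi_analysis(
    params: ModelParameters,
    chi_grid: Sequence[float] = tuple(np.linspace(0.0, 2.0, 9)),
    init_fracs: Sequence[float] = RATIO_GRID_MIXED,
    medium: str = "BSA_GLY",
    **scenario_kwargs,
) -> pd.DataFrame:
    """Sweep the absolute cost chi in [0, 2*chi_s] at fixed initial fractions.

    Reproduces the construction where both axes are model outputs: each
    row pairs the realized relative cost with the final non-producer
    proportion for one (chi, initial fraction).
    """
    if any(chi < 0 or chi > 2.0 for chi in chi_grid):
        raise ValueError("chi_grid must lie within [0, 2]")
    ref = reference_density(params, **scenario_kwargs)
    rows: list[dict] = []
    for frac in init_fracs:
        scenario = ScenarioConfig.for_medium(medium, frac, **scenario_kwargs)
        for chi, traj in sweep_chi(params, scenario, chi_grid):
            rows.extend(_sweep_rows([(frac, traj)], medium, chi, ref))
    return pd.DataFrame(rows, columns=list(SWEEP_COLUMNS))
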