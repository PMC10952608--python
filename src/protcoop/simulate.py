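"""Scenario definitions, stiff integration and parameter sweeps.

A *scenario* fixes the initial condition of the coculture: the two
vegetative inocula ``W0``/``C0`` and the nutrient context.  Two media
contexts are predefined:

``GA_GLY``
    Glutamic acid + glycerol: all nutrient is directly accessible
    (``A0 = 1``, ``B0 = 0``).  Neither strain needs the proteases.
``BSA_GLY``
    BSA + glycerol: nutrient is polymeric and must be enzymatically
    degraded before use (``B0 = 5``), with a small accessible carryover
    (``A0 = 0.006``) capturing the brief initial growth observed when
    cells are transferred between media.

Spores, degraded nutrient and enzyme always start at zero.  The default
horizon is ``t_end = 100`` model-time units, by which all headline
scenarios are stationary.  The BSA-medium nutrient abundances are a
calibration (chosen so that the producer monoculture reaches stationary
yield within the horizon while degradation remains rate-limiting in
mixed cultures); they are exposed in the scenario for recalibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import _rhs_unchecked
from .parameters import N_STATE, STATE_VARS, ModelParameters

__all__ = [
    "MEDIA",
    "DEFAULT_TOTAL_INOCULUM",
    "DEFAULT_T_END",
    "RATIO_GRID_FULL",
    "RATIO_GRID_MIXED",
    "ScenarioConfig",
    "Trajectory",
    "SolverError",
    "solve_scenario",
    "sweep_initial_ratio",
    "sweep_chi",
]

logger = logging.getLogger(__name__)

#: Default initial nutrient abundances (A0, B0) per medium context.
MEDIA: dict[str, tuple[float, float]] = {
    "GA_GLY": (1.0, 0.0),
    "BSA_GLY": (0.006, 5.0),
}

#: Default total vegetative inoculum (mirrors an OD600-0.01 inoculum).
DEFAULT_TOTAL_INOCULUM = 0.01

#: Default simulation horizon in model-time units.
DEFAULT_T_END = 100.0

#: Experimental mixing grid as initial non-producer fractions
#: (WT:Δ8 = 100:0, 95:5, 85:15, 75:25, 50:50, 25:75, 0:100).
RATIO_GRID_FULL: tuple[float, ...] = (0.0, 0.05, 0.15, 0.25, 0.5, 0.75, 1.0)

#: The mixed-culture subset of the grid (both strains present).
RATIO_GRID_MIXED: tuple[float, ...] = (0.05, 0.15, 0.25, 0.5, 0.75)


@dataclass(frozen=True)
class ScenarioConfig:
    """Initial conditions, medium context and solver settings for one run."""

    W0: float
    C0: float
    A0: float
    B0: float
    t_end: float = DEFAULT_T_END
    medium_label: str = "GA_GLY"
    solver_rel_tol: float = 1e-8
    solver_abs_tol: float = 1e-10
    n_output_points: int = 501

    def __post_init__(self) -> None:
        for name in ("W0", "C0", "A0", "B0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0; got {getattr(self, name)}")
        if not self.t_end > 0:
            raise ValueError(f"t_end must be > 0; got {self.t_end}")
        if self.n_output_points < 2:
            raise ValueError("n_output_points must be >= 2")
        if self.medium_label not in MEDIA:
            raise ValueError(
                f"unknown medium_label {self.medium_label!r}; expected one of {sorted(MEDIA)}"
            )

    @classmethod
    def for_medium(
        cls,
        medium_label: str,
        frac_nonproducer: float = 0.0,
        total_inoculum: float = DEFAULT_TOTAL_INOCULUM,
        A0: float | None = None,
        B0: float | None = None,
        **kwargs,
    ) -> "ScenarioConfig":
        """Build a scenario from a medium label and an initial Δ8 fraction."""
        if not 0.0 <= frac_nonproducer <= 1.0:
            raise ValueError(f"frac_nonproducer must be in [0, 1]; got {frac_nonproducer}")
        if total_inoculum < 0:
            raise ValueError("total_inoculum must be >= 0")
        a0_def, b0_def = MEDIA[medium_label]
        return cls(
            W0=(1.0 - frac_nonproducer) * total_inoculum,
            C0=frac_nonproducer * total_inoculum,
            A0=a0_def if A0 is None else A0,
            B0=b0_def if B0 is None else B0,
            medium_label=medium_label,
            **kwargs,
        )

    @property
    def frac_nonproducer_initial(self) -> float:
        total = self.W0 + self.C0
        return self.C0 / total if total > 0 else float("nan")

    def initial_state(self) -> np.ndarray:
        """Flat initial state; spores, Bd and E always start at zero."""
        return np.array([self.W0, self.C0, 0.0, 0.0, self.B0, 0.0, self.A0, 0.0])


class SolverError(RuntimeError):
    """Raised when the stiff integrator fails on a scenario."""

    def __init__(self, scenario: ScenarioConfig, last_time: float, message: str):
        self.scenario = scenario
        self.last_time = last_time
        super().__init__(
            f"integration failed at t={last_time:.6g} for scenario {scenario}: {message}"
        )


@dataclass(frozen=True)
class Trajectory:
    """Dense solution of the ODE system for one scenario.

    ``states`` holds the solution on a uniform output grid with any
    sub-tolerance negative undershoots clipped to zero; ``evaluate``
    interpolates the solver's dense output at arbitrary times (also
    clipped), which the metrics layer uses for quadrature.
    """

    times: np.ndarray
    states: np.ndarray  # shape (n_times, 8), columns ordered as STATE_VARS
    params: ModelParameters
    scenario: ScenarioConfig
    dense_eval: Callable[[np.ndarray], np.ndarray] = field(repr=False)

    def evaluate(self, t) -> np.ndarray:
        """State at time(s) ``t`` in ``[0, t_end]``; negative clips to 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.scenario.t_end):
            raise ValueError(f"time {t} outside [0, {self.scenario.t_end}]")
        out = np.clip(self.dense_eval(t), 0.0, None)
        return out  # shape (8,) for scalar t, (8, n) for vector t

    def series(self, name: str) -> np.ndarray:
        """One state component on the output grid, by name."""
        return self.states[:, STATE_VARS.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        """Output-grid solution as a tidy DataFrame (time + 8 components)."""
        import pandas as pd

        frame = pd.DataFrame(self.states, columns=list(STATE_VARS))
        frame.insert(0, "time", self.times)
        return frame


def solve_scenario(params: ModelParameters, scenario: ScenarioConfig) -> Trajectory:
    """Integrate the ODE system over ``[0, t_end]`` with a stiff solver.

    Uses LSODA (automatic stiffness detection, analogous in role to
    MATLAB's ode15s) with dense output retained for the quadrature in
    the metrics layer.
    """
    y0 = scenario.initial_state()
    times = np.linspace(0.0, scenario.t_end, scenario.n_output_points)
    result = solve_ivp(
        lambda t, y: _rhs_unchecked(y, params),
        (0.0, scenario.t_end),
        y0,
        method="LSODA",
        rtol=scenario.solver_rel_tol,
        atol=scenario.solver_abs_tol,
        t_eval=times,
        dense_output=True,
    )
    if not result.success:
        last = result.t[-1] if result.t.size else 0.0
        raise SolverError(scenario, last, result.message)
    logger.info(
        "solved %s scenario (W0=%g, C0=%g, A0=%g, B0=%g, chi=%g): %d rhs evaluations",
        scenario.medium_label,
        scenario.W0,
        scenario.C0,
        scenario.A0,
        scenario.B0,
        params.chi,
        result.nfev,
    )
    states = np.clip(result.y.T, 0.0, None)
    return Trajectory(
        times=times,
        states=states,
        params=params,
        scenario=scenario,
        dense_eval=result.sol,
    )


def sweep_initial_ratio(
    params: ModelParameters,
    base: ScenarioConfig,
    ratios: Sequence[float],
    total_inoculum: float = DEFAULT_TOTAL_INOCULUM,
) -> list[tuple[float, Trajectory]]:
    """Solve the base scenario for each initial non-producer fraction.

    Each fraction ``q`` replaces the inoculum with ``W0 = (1-q) * total``
    and ``C0 = q * total``; nutrients, horizon and solver settings come
    from ``base``.
    """
    out: list[tuple[float, Trajectory]] = []
    for q in ratios:
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"initial fraction must be in [0, 1]; got {q}")
        scenario = replace(base, W0=(1.0 - q) * total_inoculum, C0=q * total_inoculum)
        try:
            out.append((q, solve_scenario(params, scenario)))
        except SolverError as err:
            raise SolverError(scenario, err.last_time, f"(fraction {q}) {err}") from err
    return out


def sweep_chi(
    params: ModelParameters,
    scenario: ScenarioConfig,
    chi_values: Sequence[float],
) -> list[tuple[float, Trajectory]]:
    """Re-solve one scenario across absolute production costs ``chi``."""
    out: list[tuple[float, Trajectory]] = []
    for chi in chi_values:
        if chi < 0:
            raise ValueError(f"chi must be >= 0; got {chi}")
        out.append((chi, solve_scenario(params.with_chi(chi), scenario)))
    return out
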