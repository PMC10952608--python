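"""Derived statistics: yield, relative fitness, and the relative cost.

Three quantities summarise a coculture trajectory:

* **Total yield** — all biomass (vegetative cells plus spores),
  ``W + C + Ws + Cs``, evaluated at the end of the run and optionally
  normalized against the producer-monoculture stationary density in the
  glutamic-acid medium.

* **Relative fitness of the non-producer**, the fold change of its
  population share over the run::

      RF_C = [C/(W+C)] at t_end  /  [C0/(W0+C0)]

  The default uses vegetative densities; ``include_spores=True``
  switches to lineage-inclusive shares ``(C+Cs)/(W+Ws+C+Cs)``, the
  quantity a CFU count measures (spores germinate on plates).

* **Relative cost of protease production** — the ratio of the
  time-integrated production penalty to the time-integrated potential
  growth, both restricted to the *active-growth interval*::

      T     = { t <= t_end : chi*f(E) < gamma_A*g(A) + gamma_Bd*g(Bd) }
      P_tot = integral over T of chi*f(E) dt
      G_tot = integral over T of gamma_A*g(A) + gamma_Bd*g(Bd) dt
      C_rel = P_tot / G_tot

  The strict inequality defining ``T`` makes ``0 <= C_rel <= 1``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .model import _g
from .parameters import ModelParameters
from .simulate import Trajectory

__all__ = [
    "MetricsReport",
    "total_yield",
    "relative_fitness",
    "nonproducer_proportion",
    "active_growth_interval",
    "relative_cost",
    "compute_metrics",
]

_IDX = {"W": 0, "C": 1, "Ws": 2, "Cs": 3, "B": 4, "Bd": 5, "A": 6, "E": 7}

#: Absolute time tolerance for locating the boundaries of T.
_INTERVAL_XTOL = 1e-6


def total_yield(traj: Trajectory, t: float | None = None) -> float:
    """Total biomass ``W + C + Ws + Cs`` at time ``t`` (default ``t_end``)."""
    if t is None:
        t = traj.scenario.t_end
    y = traj.evaluate(t)
    return float(y[0] + y[1] + y[2] + y[3])


def relative_fitness(traj: Trajectory, include_spores: bool = False) -> float:
    """Fold change of the non-producer's population share over the run.

    Raises if the non-producer is absent initially or the final
    population is empty (the ratio is undefined, not infinite).

    With the default vegetative shares, runs in which every cell has
    sporulated well before ``t_end`` leave ``W`` and ``C`` decaying
    exponentially below the solver's absolute tolerance.  Both lineages
    then decay at the identical sporulation rate, so their share ratio
    is frozen; the share is therefore read at the latest time at which
    the vegetative population is still numerically resolved, which
    equals the ``t_end`` share.
    """
    sc = traj.scenario
    if sc.C0 <= 0 or sc.W0 + sc.C0 <= 0:
        raise ValueError("relative fitness undefined: non-producer absent at t=0")
    share0 = sc.C0 / (sc.W0 + sc.C0)
    y = traj.evaluate(sc.t_end)
    if include_spores:
        c_final = y[1] + y[3]
        total_final = y[0] + y[1] + y[2] + y[3]
        if total_final <= 0:
            raise ValueError("relative fitness undefined: final population is empty")
        return float((c_final / total_final) / share0)
    floor = max(1e3 * sc.solver_abs_tol, 1e-12)
    if y[0] + y[1] >= floor:
        return float((y[1] / (y[0] + y[1])) / share0)
    veg = traj.states[:, 0] + traj.states[:, 1]
    resolved = np.nonzero(veg >= floor)[0]
    if resolved.size == 0:
        raise ValueError("relative fitness undefined: final population is empty")
    last = traj.states[resolved[-1]]
    return float((last[1] / (last[0] + last[1])) / share0)


def nonproducer_proportion(traj: Trajectory, t: float | None = None) -> float:
    """Lineage-inclusive non-producer fraction ``(C+Cs)/(W+C+Ws+Cs)`` at ``t``."""
    if t is None:
        t = traj.scenario.t_end
    y = traj.evaluate(t)
    total = y[0] + y[1] + y[2] + y[3]
    if total <= 0:
        raise ValueError(f"non-producer proportion undefined: empty population at t={t}")
    return float((y[1] + y[3]) / total)


def _growth_margin(traj: Trajectory):
    """Margin function m(t) = gamma_A g(A) + gamma_Bd g(Bd) - chi f(E).

    T is the set where m > 0.
    """
    p = traj.params

    def margin(t: float) -> float:
        y = traj.evaluate(t)
        growth = p.gamma_A * _g(y[_IDX["A"]], p.k1, p.k2) + p.gamma_Bd * _g(
            y[_IDX["Bd"]], p.k1, p.k2
        )
        return growth - p.chi * p.k5 * (1.0 - y[_IDX["E"]] / p.k6)

    return margin


def active_growth_interval(
    traj: Trajectory, n_scan: int = 4001
) -> list[tuple[float, float]]:
    """The active-growth set T as a finite union of time spans.

    The margin's sign is scanned on a dense uniform grid and each sign
    change is refined by bracketing to absolute time tolerance 1e-6.
    An empty list (no active growth) is a valid return.
    """
    t_end = traj.scenario.t_end
    margin = _growth_margin(traj)
    ts = np.linspace(0.0, t_end, n_scan)
    p = traj.params
    ys = traj.evaluate(ts)
    growth = p.gamma_A * _g(ys[_IDX["A"]], p.k1, p.k2) + p.gamma_Bd * _g(
        ys[_IDX["Bd"]], p.k1, p.k2
    )
    pos = growth - p.chi * p.k5 * (1.0 - ys[_IDX["E"]] / p.k6) > 0.0

    spans: list[tuple[float, float]] = []
    inside = bool(pos[0])
    start = 0.0
    for i in range(1, n_scan):
        if bool(pos[i]) != inside:
            boundary = brentq(margin, ts[i - 1], ts[i], xtol=_INTERVAL_XTOL)
            if inside:
                spans.append((start, float(boundary)))
            else:
                start = float(boundary)
            inside = not inside
    if inside:
        spans.append((start, t_end))
    return spans


def relative_cost(
    traj: Trajectory, spans: Sequence[tuple[float, float]] | None = None
) -> tuple[float, float, float]:
    """Return ``(P_tot, G_tot, C_rel)`` for one trajectory.

    Integrals are computed by adaptive quadrature over each span of the
    active-growth interval using the dense solution.  An empty T yields
    ``(0, 0, 0)``: no division happened, so no cost was paid during
    growth.  The result is clipped to the analytic bound [0, 1] only to
    absorb quadrature round-off.
    """
    p = traj.params
    if spans is None:
        spans = active_growth_interval(traj)
    if not spans:
        return 0.0, 0.0, 0.0

    def penalty(t: float) -> float:
        E = traj.evaluate(t)[_IDX["E"]]
        return p.chi * p.k5 * (1.0 - E / p.k6)

    def growth(t: float) -> float:
        y = traj.evaluate(t)
        return p.gamma_A * _g(y[_IDX["A"]], p.k1, p.k2) + p.gamma_Bd * _g(
            y[_IDX["Bd"]], p.k1, p.k2
        )

    p_tot = g_tot = 0.0
    for a, b in spans:
        for func, acc in ((penalty, "p"), (growth, "g")):
            value, err = quad(func, a, b, epsabs=1e-12, epsrel=1e-9, limit=500)
            if err > max(1e-8, 1e-6 * abs(value)):
                raise RuntimeError(
                    f"quadrature did not converge on span ({a:.6g}, {b:.6g}): "
                    f"estimated error {err:.3g}"
                )
            if acc == "p":
                p_tot += value
            else:
                g_tot += value
    c_rel = p_tot / g_tot if g_tot > 0 else 0.0
    return p_tot, g_tot, float(min(max(c_rel, 0.0), 1.0))


@dataclass(frozen=True)
class MetricsReport:
    """All derived quantities for one trajectory."""

    total_yield: float
    normalized_yield: float
    rf_c: float
    prop_c_initial: float
    prop_c_final: float
    p_tot: float
    g_tot: float
    c_rel: float
    t_interval: tuple[tuple[float, float], ...]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["t_interval"] = [list(span) for span in self.t_interval]
        return d


def compute_metrics(
    traj: Trajectory,
    reference_density: float | None = None,
    include_spores: bool = False,
) -> MetricsReport:
    """Assemble the full report for one trajectory.

    ``reference_density`` is the producer-monoculture GA stationary
    yield used to normalize; omitted, the normalized yield equals the
    raw yield.  ``rf_c`` is NaN for producer monocultures (undefined).
    """
    sc = traj.scenario
    yield_end = total_yield(traj)
    spans = active_growth_interval(traj)
    p_tot, g_tot, c_rel = relative_cost(traj, spans)
    try:
        rf = relative_fitness(traj, include_spores=include_spores)
    except ValueError:
        rf = float("nan")
    prop0 = sc.frac_nonproducer_initial
    prop_end = nonproducer_proportion(traj) if yield_end > 0 else float("nan")
    ref = reference_density if reference_density is not None else 1.0
    return MetricsReport(
        total_yield=yield_end,
        normalized_yield=yield_end / ref,
        rf_c=rf,
        prop_c_initial=prop0,
        prop_c_final=prop_end,
        p_tot=p_tot,
        g_tot=g_tot,
        c_rel=c_rel,
        t_interval=tuple(spans),
    )
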