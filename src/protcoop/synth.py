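"""Synthetic wet-lab observations generated from model trajectories.

The generator emulates the structure of the study's assays so the
analysis layer can be exercised end-to-end without laboratory data:

* OD600 growth curves read at a few fixed clock times, with
  multiplicative lognormal noise (positive, heteroscedastic, like a
  plate reader);
* serial-dilution colony counts: total CFU, post-heat-treatment CFU
  (spores — heat is modelled as killing every vegetative cell and
  sparing every spore, the operational definition of a spore count),
  and per-strain counts from fluorescently marked colonies, all with
  Poisson noise at the plate level;
* supernatant protease activity (fluorescence) normalized to OD.

Model time is mapped to clock time linearly: ``t = 100`` model units
corresponds to 48 h, the coculture endpoint of the experimental design.
All randomness flows from a single seed through ``numpy`` bit
generators; replicates receive independent child seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import ModelParameters
from .simulate import (
    DEFAULT_TOTAL_INOCULUM,
    RATIO_GRID_FULL,
    ScenarioConfig,
    Trajectory,
    solve_scenario,
)

__all__ = [
    "HOURS_PER_MODEL_TIME",
    "OBS_COLUMNS",
    "ObservationTable",
    "observe_od",
    "observe_cfu",
    "observe_protease",
    "generate_study",
    "estimate_spore_fraction",
    "estimate_nonproducer_fraction",
]

#: Linear clock-time mapping: t = 100 model units <-> 48 h.
HOURS_PER_MODEL_TIME = 0.48

#: Conversion from nondimensional cell density to CFU/mL (1 OD ~ 1e8 CFU/mL).
DEFAULT_CELLS_PER_UNIT = 1e8

#: Plate counts outside this range are not reliably countable.
DEFAULT_COUNTABLE_RANGE = (30, 300)

#: Column order of every observation table.
OBS_COLUMNS = (
    "time_h",
    "od600",
    "cfu_total",
    "cfu_spores",
    "cfu_strain_marked",
    "protease_activity",
    "protease_per_od",
)


def _model_time(traj: Trajectory, time_h: float) -> float:
    t = time_h / HOURS_PER_MODEL_TIME
    if not 0.0 <= t <= traj.scenario.t_end:
        raise ValueError(
            f"{time_h} h maps to model time {t:.4g}, outside [0, {traj.scenario.t_end}]"
        )
    return t


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class ObservationTable:
    """One culture tube's synthetic time course plus its provenance."""

    data: pd.DataFrame
    medium_label: str
    init_frac_C: float
    replicate_id: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame with the metadata replicated onto every row."""
        frame = self.data.copy()
        frame["medium_label"] = self.medium_label
        frame["init_frac_C"] = self.init_frac_C
        frame["replicate_id"] = self.replicate_id
        frame["seed"] = self.seed
        return frame


def observe_od(
    traj: Trajectory,
    times_h: Sequence[float],
    noise_cv: float = 0.1,
    seed=None,
    od_scale: float = 1.0,
) -> np.ndarray:
    """Simulated OD600 readings at the given clock times.

    ``od = od_scale * (W+C+Ws+Cs)(t) * exp(eps)`` with
    ``eps ~ Normal(0, noise_cv^2)`` drawn independently per reading.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0; got {noise_cv}")
    rng = _rng(seed)
    out = np.empty(len(times_h))
    for i, time_h in enumerate(times_h):
        y = traj.evaluate(_model_time(traj, time_h))
        truth = od_scale * (y[0] + y[1] + y[2] + y[3])
        eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
        out[i] = truth * np.exp(eps)
    return out


def choose_dilution(
    expected_count: float, countable_range: tuple[float, float] = DEFAULT_COUNTABLE_RANGE
) -> float:
    """Smallest power-of-ten dilution putting the expectation on a countable plate."""
    low, high = countable_range
    dilution = 1.0
    while expected_count / dilution > high:
        dilution *= 10.0
    if expected_count / dilution < low:
        raise ValueError(
            f"no power-of-ten dilution places the expected count {expected_count:.3g} "
            f"within the countable range [{low}, {high}]"
        )
    return dilution


def observe_cfu(
    traj: Trajectory,
    time_h: float,
    dilution_factor: float | None = None,
    seed=None,
    cells_per_unit: float = DEFAULT_CELLS_PER_UNIT,
    countable_range: tuple[float, float] = DEFAULT_COUNTABLE_RANGE,
    count_noise: bool = True,
) -> dict[str, float]:
    """Simulated serial-dilution plating of one sample.

    Plate counts are Poisson with mean density/dilution; the heat
    treatment spares exactly the spore compartments ``Ws + Cs``; the
    strain-marked count splits the total plate count binomially by the
    non-producer lineage share.  All counts are scaled back by the
    dilution, so values are on the CFU/mL scale.  ``count_noise=False``
    returns the expectations (useful for round-trip checks).
    """
    rng = _rng(seed)
    y = traj.evaluate(_model_time(traj, time_h))
    total = (y[0] + y[1] + y[2] + y[3]) * cells_per_unit
    spores = (y[2] + y[3]) * cells_per_unit
    frac_c = (y[1] + y[3]) / (y[0] + y[1] + y[2] + y[3]) if total > 0 else 0.0

    dilution = dilution_factor if dilution_factor is not None else choose_dilution(
        total, countable_range
    )
    if count_noise:
        n_total = rng.poisson(total / dilution)
        n_spores = rng.poisson(spores / dilution)
        n_marked = rng.binomial(n_total, frac_c) if n_total > 0 else 0
    else:
        n_total = total / dilution
        n_spores = spores / dilution
        n_marked = n_total * frac_c
    return {
        "cfu_total": n_total * dilution,
        "cfu_spores": n_spores * dilution,
        "cfu_strain_marked": n_marked * dilution,
        "dilution": dilution,
    }


def observe_protease(
    traj: Trajectory,
    time_h: float,
    gain: float = 1.0,
    noise_cv: float = 0.1,
    seed=None,
    od_scale: float = 1.0,
) -> tuple[float, float]:
    """Simulated supernatant protease fluorescence and its OD-normalized form.

    ``activity = gain * E(t) * exp(eps)``; the OD in the denominator
    carries its own independent noise draw of the same magnitude,
    matching the assay where activity and OD are separate measurements.
    """
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0; got {noise_cv}")
    rng = _rng(seed)
    y = traj.evaluate(_model_time(traj, time_h))
    eps_a = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
    activity = gain * y[7] * np.exp(eps_a)
    od = observe_od(traj, [time_h], noise_cv=noise_cv, seed=rng, od_scale=od_scale)[0]
    per_od = activity / od if od > 0 else float("nan")
    return float(activity), float(per_od)


def generate_study(
    params: ModelParameters,
    media: Sequence[str] = ("GA_GLY", "BSA_GLY"),
    ratios: Sequence[float] = RATIO_GRID_FULL,
    n_replicates: int = 3,
    seed: int = 0,
    times_h: Sequence[float] = (6.0, 12.0, 24.0, 48.0),
    noise_cv: float = 0.1,
    count_noise: bool = True,
    total_inoculum: float = DEFAULT_TOTAL_INOCULUM,
    cells_per_unit: float = DEFAULT_CELLS_PER_UNIT,
    gain: float = 1.0,
) -> list[ObservationTable]:
    """Full synthetic study: both media x mixing grid x replicates.

    One trajectory is solved per (medium, ratio); replicates differ only
    in their noise draws, each from an independent child seed of the
    top-level ``seed``.  ``n_replicates = 0`` yields an empty collection.
    """
    tables: list[ObservationTable] = []
    seedseq = np.random.SeedSequence(seed)
    children = iter(seedseq.spawn(max(1, len(media) * len(ratios) * n_replicates)))
    for medium in media:
        for ratio in ratios:
            scenario = ScenarioConfig.for_medium(medium, ratio, total_inoculum)
            traj = solve_scenario(params, scenario)
            for rep in range(n_replicates):
                child = next(children)
                child_seed = int(child.generate_state(1)[0] % (2**31))
                rng = np.random.default_rng(child_seed)
                rows = []
                for time_h in times_h:
                    od = observe_od(traj, [time_h], noise_cv, rng)[0]
                    cfu = observe_cfu(
                        traj,
                        time_h,
                        seed=rng,
                        cells_per_unit=cells_per_unit,
                        count_noise=count_noise,
                    )
                    act, per_od = observe_protease(traj, time_h, gain, noise_cv, rng)
                    rows.append(
                        {
                            "time_h": time_h,
                            "od600": od,
                            "cfu_total": cfu["cfu_total"],
                            "cfu_spores": cfu["cfu_spores"],
                            "cfu_strain_marked": cfu["cfu_strain_marked"],
                            "protease_activity": act,
                            "protease_per_od": per_od,
                        }
                    )
                tables.append(
                    ObservationTable(
                        data=pd.DataFrame(rows, columns=list(OBS_COLUMNS)),
                        medium_label=medium,
                        init_frac_C=float(ratio),
                        replicate_id=rep,
                        seed=child_seed,
                    )
                )
    return tables


def estimate_spore_fraction(table: ObservationTable, time_h: float | None = None) -> float:
    """Spore share of the population from one row's plate counts."""
    row = _select_row(table, time_h)
    if row["cfu_total"] <= 0:
        raise ValueError("spore fraction undefined: zero total count")
    return float(row["cfu_spores"] / row["cfu_total"])


def estimate_nonproducer_fraction(
    table: ObservationTable, time_h: float | None = None
) -> float:
    """Non-producer share from the strain-marked colony counts."""
    row = _select_row(table, time_h)
    if row["cfu_total"] <= 0:
        raise ValueError("strain fraction undefined: zero total count")
    return float(row["cfu_strain_marked"] / row["cfu_total"])


def _select_row(table: ObservationTable, time_h: float | None) -> pd.Series:
    data = table.data
    if data.empty:
        raise ValueError("observation table is empty")
    if time_h is None:
        return data.iloc[-1]
    match = data[data["time_h"] == time_h]
    if match.empty:
        raise ValueError(f"no observation at {time_h} h")
    return match.iloc[0]
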