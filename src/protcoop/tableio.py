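"""Readers and writers for the delimited tables the package produces.

All tables are UTF-8, LF-newline, tab-separated text with a header row,
'.' decimal separators and a stable column order.  Observation tables
carry their metadata (medium, initial fraction, replicate, seed) as
ordinary columns so a file round-trips without sidecars.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .experiments import SWEEP_COLUMNS
from .synth import OBS_COLUMNS, ObservationTable

__all__ = [
    "read_observation_table",
    "write_observation_table",
    "read_sweep_table",
    "write_sweep_table",
]

logger = logging.getLogger(__name__)

_OBS_FILE_COLUMNS = tuple(OBS_COLUMNS) + (
    "medium_label",
    "init_frac_C",
    "replicate_id",
    "seed",
)


def _check_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _write(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def write_observation_table(table: ObservationTable, path: str | Path) -> None:
    _write(table.to_frame()[list(_OBS_FILE_COLUMNS)], path)


def read_observation_table(path: str | Path) -> ObservationTable:
    """Load one observation table, validating its schema.

    Rows where the spore count exceeds the total count are tolerated
    with a warning: independent Poisson draws can produce them.
    """
    frame = pd.read_csv(path, sep="\t")
    _check_columns(frame, _OBS_FILE_COLUMNS, path)
    bad = frame[frame["cfu_spores"] > frame["cfu_total"]]
    if not bad.empty:
        logger.warning(
            "%s: %d row(s) with cfu_spores > cfu_total (tolerated; sampling noise)",
            path,
            len(bad),
        )
    meta_cols = ["medium_label", "init_frac_C", "replicate_id", "seed"]
    meta = frame[meta_cols].drop_duplicates()
    if len(meta) != 1:
        raise ValueError(f"{path}: expected exactly one metadata combination, got {len(meta)}")
    medium, frac, rep, seed = meta.iloc[0]
    return ObservationTable(
        data=frame[list(OBS_COLUMNS)].reset_index(drop=True),
        medium_label=str(medium),
        init_frac_C=float(frac),
        replicate_id=int(rep),
        seed=int(seed),
    )


def write_sweep_table(frame: pd.DataFrame, path: str | Path) -> None:
    _check_columns(frame, SWEEP_COLUMNS, path)
    _write(frame[list(SWEEP_COLUMNS)], path)


def read_sweep_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    _check_columns(frame, SWEEP_COLUMNS, path)
    return frame
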