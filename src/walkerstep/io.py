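"""Table and trajectory I/O.

All tables are plain CSV with UTF-8 encoding, '.' decimal separator and a
mandatory header row. The yield-curve schema is shared by every stage of
the pipeline:

    step_size_nm, fuel_conc_M, yield, yield_se, source

with ``yield`` in [0, 1], ``fuel_conc_M`` in SI molar and ``source`` one of
"synthetic", "model", "manual" or "true". ``yield_se`` may be empty.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .fret import BurstSet
from .polymer import ChainSample

__all__ = [
    "YIELD_COLUMNS",
    "BURST_COLUMNS",
    "CONTACT_COLUMNS",
    "read_yield_table",
    "write_yield_table",
    "read_bursts",
    "write_bursts",
    "write_contact_table",
    "write_xyz",
]

YIELD_COLUMNS = ["step_size_nm", "fuel_conc_M", "yield", "yield_se", "source"]
BURST_COLUMNS = ["efficiency", "condition_d_nm", "condition_F1_M", "seed"]
CONTACT_COLUMNS = ["d_nm", "p_contact", "p_stderr", "dG_rel_kBT", "n_samples", "seed"]

_KNOWN_SOURCES = {"synthetic", "model", "manual", "true"}


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def read_yield_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a yield-curve CSV."""
    df = pd.read_csv(path)
    _require_columns(df, YIELD_COLUMNS, path)
    df = df[YIELD_COLUMNS].copy()
    for col in ("step_size_nm", "fuel_conc_M", "yield", "yield_se"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df.empty:
        raise ValueError(f"{path}: yield table has no rows")
    y = df["yield"]
    if ((y < 0) | (y > 1)).any():
        raise ValueError(f"{path}: yield values must lie in [0, 1]")
    if (df["fuel_conc_M"] < 0).any() or (df["step_size_nm"] < 0).any():
        raise ValueError(f"{path}: step sizes and concentrations must be >= 0")
    bad = set(df["source"].astype(str)) - _KNOWN_SOURCES
    if bad:
        raise ValueError(f"{path}: unknown source value(s) {sorted(bad)}")
    return df


def write_yield_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a yield-curve CSV (schema-checked)."""
    _require_columns(df, YIELD_COLUMNS, path)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[YIELD_COLUMNS].to_csv(path, index=False)
    return path


def write_bursts(burst_sets: Iterable[BurstSet], path: str | Path) -> Path:
    """Write burst sets as one long-format CSV (one row per burst)."""
    frames = []
    for bs in burst_sets:
        frames.append(
            pd.DataFrame(
                {
                    "efficiency": bs.efficiencies,
                    "condition_d_nm": bs.condition_d_nm,
                    "condition_F1_M": bs.condition_F1_M,
                    "seed": bs.seed,
                }
            )
        )
    if not frames:
        raise ValueError("no burst sets to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_bursts(path: str | Path) -> list[BurstSet]:
    """Read a long-format burst CSV back into per-condition burst sets."""
    df = pd.read_csv(path)
    _require_columns(df, BURST_COLUMNS, path)
    sets = []
    for (d, f1, seed), group in df.groupby(
        ["condition_d_nm", "condition_F1_M", "seed"], sort=True
    ):
        sets.append(
            BurstSet(
                efficiencies=group["efficiency"].to_numpy(),
                condition_d_nm=float(d),
                condition_F1_M=float(f1),
                seed=int(seed),
            )
        )
    if not sets:
        raise ValueError(f"{path}: burst table has no rows")
    return sets


def write_contact_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a contact-probability grid CSV."""
    _require_columns(df, CONTACT_COLUMNS, path)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_xyz(samples: dict[str, ChainSample], path: str | Path, max_conformations: int = 100) -> Path:
    """Dump sampled bead positions as plain text for visual inspection.

    One bead per line: arm id, conformation index, bead index, x, y, z (nm).
    Requires samples built with ``keep_beads=True``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# arm conformation bead x_nm y_nm z_nm\n")
        for arm_id, sample in samples.items():
            if sample.beads is None:
                raise ValueError(f"arm {arm_id!r} was sampled without keep_beads=True")
            for ci in range(min(max_conformations, sample.beads.shape[0])):
                for bi, (x, y, z) in enumerate(sample.beads[ci]):
                    fh.write(f"{arm_id} {ci} {bi} {x:.3f} {y:.3f} {z:.3f}\n")
    return path
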