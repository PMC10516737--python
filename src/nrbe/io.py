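"""Readers and writers for the delimited-text interchange formats.

Counts tables are CSV/TSV with a header row and columns
``cell_line, arm, dose_gy, replicate, cells_seeded, colonies``; spectra and
RBE curves are two-column delimited text (energy, value) with ``#``
comments, energies in eV unless declared MeV.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import ColonyCountRecord, SurvivalPoint
from .spectrum import NeutronSpectrum, RBEEnergyCurve

__all__ = [
    "SchemaError",
    "read_counts_table",
    "write_counts_table",
    "read_spectrum",
    "read_rbe_curve",
    "write_survival_table",
    "read_survival_table",
]

COUNTS_COLUMNS = ("cell_line", "arm", "dose_gy", "replicate", "cells_seeded", "colonies")

EV_PER_MEV = 1.0e6


class SchemaError(ValueError):
    """Input table violates the expected schema; message itemizes every problem."""


def _read_delimited(path) -> pd.DataFrame:
    # sniff comma vs tab from the header line
    text = Path(path).read_text(encoding="utf-8")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(_io.StringIO(text), sep=sep)


def read_counts_table(path) -> list[ColonyCountRecord]:
    """Parse and validate a colony-count table into records.

    Raises
    ------
    SchemaError
        Missing columns, non-numeric cells, negative values or duplicate
        (cell_line, arm, dose, replicate) keys; all problems are listed.
    ValueError
        If the table has no data rows.
    """
    df = _read_delimited(path)
    problems: list[str] = []
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("empty counts table")

    for col in ("dose_gy", "replicate", "cells_seeded", "colonies"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()] if df[col].notna().any() else []
        for idx in df.index[converted.isna()]:
            problems.append(f"row {idx}: non-numeric {col} value {df.at[idx, col]!r}")
        df[col] = converted

    keys = df[["cell_line", "arm", "dose_gy", "replicate"]].apply(tuple, axis=1)
    for idx in df.index[keys.duplicated()]:
        problems.append(f"row {idx}: duplicate (cell_line, arm, dose, replicate) key {keys[idx]}")

    records: list[ColonyCountRecord] = []
    if not problems:
        for idx, row in df.iterrows():
            try:
                records.append(
                    ColonyCountRecord(
                        cell_line=str(row["cell_line"]),
                        arm=str(row["arm"]),
                        dose=float(row["dose_gy"]),
                        cells_seeded=float(row["cells_seeded"]),
                        colonies=float(row["colonies"]),
                        replicate=int(row["replicate"]),
                    )
                )
            except ValueError as exc:
                problems.append(f"row {idx}: {exc}")
    if problems:
        raise SchemaError("; ".join(problems))
    return records


def write_counts_table(records: Sequence[ColonyCountRecord], path) -> None:
    """Write records back out in the canonical column order."""
    df = pd.DataFrame(
        {
            "cell_line": [r.cell_line for r in records],
            "arm": [r.arm for r in records],
            "dose_gy": [r.dose for r in records],
            "replicate": [r.replicate for r in records],
            "cells_seeded": [r.cells_seeded for r in records],
            "colonies": [r.colonies for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def _read_two_column(path, energy_unit: str) -> tuple[np.ndarray, np.ndarray]:
    if energy_unit not in ("eV", "MeV"):
        raise ValueError(f"energy unit must be 'eV' or 'MeV', got {energy_unit!r}")
    raw = np.loadtxt(path, comments="#", delimiter=None, ndmin=2)
    if raw.shape[1] == 1:  # comma-delimited fallback
        raw = np.loadtxt(path, comments="#", delimiter=",", ndmin=2)
    if raw.shape[1] < 2:
        raise SchemaError(f"{path}: expected two columns (energy, value)")
    energy = raw[:, 0] * (EV_PER_MEV if energy_unit == "MeV" else 1.0)
    return energy, raw[:, 1]


def read_spectrum(path, energy_unit: str = "eV") -> NeutronSpectrum:
    """Read a fluence spectrum from two-column text (energy, density)."""
    energy, fluence = _read_two_column(path, energy_unit)
    return NeutronSpectrum(energy=energy, fluence=fluence)


def read_rbe_curve(path, energy_unit: str = "eV") -> RBEEnergyCurve:
    """Read an RBE(E) curve from two-column text (energy, RBE)."""
    energy, rbe = _read_two_column(path, energy_unit)
    return RBEEnergyCurve(energy=energy, rbe=rbe)


def write_survival_table(points_by_arm: dict, path) -> None:
    """Write a tidy survival table (cell_line, arm, dose_gy, sf, sd, n).

    ``points_by_arm`` maps (cell_line, arm) -> list of SurvivalPoint.
    Fixed float formatting and sorted ordering keep reruns byte-identical.
    """
    rows = []
    for (line, arm), points in sorted(points_by_arm.items()):
        for pt in points:
            rows.append((line, arm, pt.dose, pt.sf, pt.sd, pt.n))
    df = pd.DataFrame(rows, columns=["cell_line", "arm", "dose_gy", "sf", "sd", "n"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_survival_table(path) -> dict:
    """Inverse of :func:`write_survival_table`."""
    df = _read_delimited(path)
    out: dict = {}
    for _, row in df.iterrows():
        key = (str(row["cell_line"]), str(row["arm"]))
        out.setdefault(key, []).append(
            SurvivalPoint(
                dose=float(row["dose_gy"]),
                sf=float(row["sf"]),
                sd=float(row["sd"]),
                n=int(row["n"]),
            )
        )
    return out
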