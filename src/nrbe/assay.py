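"""Clonogenic (colony formation) assay processing.

Raw colony counts are converted to survival fractions in two steps: the
unirradiated control arm defines the plating efficiency (PE), and each
irradiated tube's colony yield is normalized by seeded cells and PE.
Replicates at the same dose are aggregated as the mean of per-replicate
survival fractions with the sample standard deviation (n-1 denominator),
which is how survival curves in this field are conventionally plotted
(mean ± SD over 2-3 tubes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ARMS",
    "ColonyCountRecord",
    "SurvivalPoint",
    "DegenerateControlError",
    "plating_efficiency",
    "survival_fractions",
    "replicate_survival_fractions",
]

#: Recognized radiation arms: the reference photon arm and the mixed beam.
ARMS = ("gamma", "neutron_beam")


class DegenerateControlError(ValueError):
    """Raised when a control tube yields zero colonies (PE of 0 cannot normalize)."""


@dataclass(frozen=True)
class ColonyCountRecord:
    """One tube of a clonogenic assay.

    Parameters
    ----------
    cell_line : str
        Label of the cell line (e.g. ``"SAS"``).
    arm : str
        Radiation arm, one of :data:`ARMS`. Controls belong to the arm
        whose experiment they accompany (each arm carries its own control
        tube).
    dose : float
        Absorbed dose in Gy; 0 marks a control tube.
    cells_seeded : float
        Number of cells seeded in the tube; must be positive.
    colonies : float
        Colonies counted after incubation. Integer for real or Poisson
        data; the zero-noise synthetic mode produces exact (fractional)
        expected counts.
    replicate : int
        Replicate index within (cell_line, arm, dose).
    """

    cell_line: str
    arm: str
    dose: float
    cells_seeded: float
    colonies: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if not self.cells_seeded > 0:
            raise ValueError("cells_seeded must be positive")
        if self.colonies < 0:
            raise ValueError("colonies must be non-negative")
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


@dataclass(frozen=True)
class SurvivalPoint:
    """Replicate-aggregated survival at one dose.

    ``sf`` is the mean of per-replicate survival fractions, ``sd`` the
    sample standard deviation of those replicates (0 when ``n == 1``),
    ``n`` the replicate count.
    """

    dose: float
    sf: float
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if not self.sf > 0:
            raise ValueError("survival fraction must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


def plating_efficiency(controls: Sequence[ColonyCountRecord]) -> float:
    """Mean fraction of seeded, unirradiated cells that form colonies.

    Parameters
    ----------
    controls : sequence of ColonyCountRecord
        Control tubes; every record must have ``dose == 0``.

    Returns
    -------
    float
        Mean over replicates of colonies / cells_seeded.

    Raises
    ------
    ValueError
        If the list is empty or contains an irradiated record.
    DegenerateControlError
        If any control tube has zero colonies.
    """
    if len(controls) == 0:
        raise ValueError("no control records")
    for rec in controls:
        if rec.dose != 0:
            raise ValueError(f"control record has nonzero dose {rec.dose}")
        if rec.colonies == 0:
            raise DegenerateControlError(
                f"degenerate control: zero colonies in replicate {rec.replicate}"
            )
    pe = float(np.mean([r.colonies / r.cells_seeded for r in controls]))
    if pe > 1:
        warnings.warn(f"plating efficiency {pe:.3f} exceeds 1", stacklevel=2)
    return pe


def _replicate_sf_by_dose(
    records: Sequence[ColonyCountRecord], pe: float
) -> dict[float, np.ndarray]:
    if not 0 < pe <= 1:
        raise ValueError(f"plating efficiency must be in (0, 1], got {pe}")
    arms = {r.arm for r in records}
    if len(arms) > 1:
        raise ValueError(f"records mix arms {sorted(arms)}; process one arm at a time")
    by_dose: dict[float, list[float]] = {}
    for rec in records:
        if rec.dose <= 0:
            raise ValueError("irradiated records must have dose > 0")
        by_dose.setdefault(rec.dose, []).append(rec.colonies / rec.cells_seeded / pe)
    return {d: np.asarray(v, dtype=float) for d, v in sorted(by_dose.items())}


def survival_fractions(
    records: Sequence[ColonyCountRecord],
    pe: float,
    clip: bool = False,
    drop_unestimable: bool = False,
) -> list[SurvivalPoint]:
    """Aggregate irradiated colony counts into per-dose survival points.

    Per replicate SF = (colonies / cells_seeded) / pe; per dose the mean,
    sample SD and replicate count are returned, sorted by dose. Survival
    fractions above 1 are retained (and flagged) unless ``clip`` is set:
    clipping would bias the log-scale fit downward.

    A dose where every replicate yields zero colonies has no defined
    survival point on the log scale; by default this is an error, with
    ``drop_unestimable`` the dose level is omitted with a warning (the
    standard handling when the highest dose outruns the seeded cells).

    Raises
    ------
    ValueError
        If records mix arms, contain controls, or all replicates at a dose
        have zero colonies (the SF is unestimable on the log scale).
    """
    points: list[SurvivalPoint] = []
    for dose, sfs in _replicate_sf_by_dose(records, pe).items():
        mean_sf = float(np.mean(sfs))
        if mean_sf == 0:
            if drop_unestimable:
                warnings.warn(
                    f"dropping {dose} Gy: zero colonies in every replicate", stacklevel=2
                )
                continue
            raise ValueError(f"unestimable SF: zero colonies in every replicate at {dose} Gy")
        if mean_sf > 1:
            warnings.warn(
                f"survival fraction {mean_sf:.4f} > 1 at {dose} Gy"
                + (" (clipped)" if clip else " (retained)"),
                stacklevel=2,
            )
            if clip:
                mean_sf = 1.0
        sd = float(np.std(sfs, ddof=1)) if len(sfs) > 1 else 0.0
        points.append(SurvivalPoint(dose=dose, sf=mean_sf, sd=sd, n=len(sfs)))
    return points


def replicate_survival_fractions(
    records: Sequence[ColonyCountRecord], pe: float, drop_unestimable: bool = False
) -> dict[float, np.ndarray]:
    """Per-dose arrays of replicate-level survival fractions.

    The replicate-level view (rather than the aggregated
    :class:`SurvivalPoint`) is what the nonparametric bootstrap of the
    D10 endpoint resamples. With ``drop_unestimable``, dose levels whose
    replicates are all zero are omitted, mirroring
    :func:`survival_fractions`.
    """
    by_dose = _replicate_sf_by_dose(records, pe)
    if drop_unestimable:
        by_dose = {d: v for d, v in by_dose.items() if np.any(v > 0)}
    return by_dose
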