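"""Three-phase drug mass balance from interrupted dialysis.

At each interruption time the donor dispersion is centrifuged, giving the
drug mass in the nanoparticle dispersion medium (DM); the receiving phase
(RP) is assayed cumulatively.  The nanoparticle-matrix fraction (NPM) is
obtained by closure:

    %NPM = 100 - %DM - %RP

because the matrix itself is never assayed.  A retention check then asks
whether %NPM stays within a band over a time window — the operational form
of "the entrapped fraction remained virtually constant".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, MassBalanceError

__all__ = ["PhasePartition", "partition", "retention_series",
           "read_partition_csv", "partitions_to_frame"]

#: relative assay-error tolerance on dm + rp vs total
MASS_TOLERANCE = 0.02


@dataclass(frozen=True)
class PhasePartition:
    """Percent drug in NP matrix / dispersion medium / receiving phase."""

    time_h: float
    pct_npm: float
    pct_dm: float
    pct_rp: float

    def __post_init__(self) -> None:
        if abs(self.pct_npm + self.pct_dm + self.pct_rp - 100.0) > 1e-6:
            raise DomainError("phase percentages must sum to 100")
        for name in ("pct_npm", "pct_dm", "pct_rp"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 100.0 + 1e-9:
                raise DomainError(f"{name} = {v} outside [0, 100]")


def partition(
    total_mass: float,
    dm_mass: float,
    rp_cum_mass: float,
    time_h: float,
    tolerance: float = MASS_TOLERANCE,
) -> PhasePartition:
    """Mass balance at one interruption time.

    Parameters are masses in mg: total drug load, drug assayed in the
    dispersion medium, and cumulative drug transported to the receiving
    phase.  The matrix percentage is computed by difference.

    Raises
    ------
    MassBalanceError
        If ``dm + rp`` exceeds the total load by more than ``tolerance``
        (relative), i.e. the assays are inconsistent.
    """
    if total_mass <= 0:
        raise DomainError(f"total_mass must be > 0, got {total_mass}")
    if dm_mass < 0 or rp_cum_mass < 0:
        raise DomainError("phase masses must be non-negative")
    excess = dm_mass + rp_cum_mass - total_mass
    if excess > tolerance * total_mass:
        raise MassBalanceError(
            f"dm + rp = {dm_mass + rp_cum_mass:g} mg exceeds total "
            f"{total_mass:g} mg beyond {tolerance:.0%} tolerance"
        )
    pct_dm = 100.0 * dm_mass / total_mass
    pct_rp = 100.0 * rp_cum_mass / total_mass
    if excess > 0:  # within tolerance: renormalize so closure stays >= 0
        scale = 100.0 / (pct_dm + pct_rp)
        pct_dm *= scale
        pct_rp *= scale
    return PhasePartition(
        time_h=time_h,
        pct_npm=100.0 - pct_dm - pct_rp,
        pct_dm=pct_dm,
        pct_rp=pct_rp,
    )


def retention_series(
    partitions: Sequence[PhasePartition],
    window: tuple[float, float] | None = None,
    tolerance_points: float = 5.0,
) -> dict:
    """Summarize matrix retention over a time window.

    Returns min/max/mean of %NPM inside ``window`` (default: all times) and
    a ``constant`` flag that is true iff the %NPM range does not exceed
    ``tolerance_points`` percentage points.  A decrease of cumulative %RP
    between consecutive times is physically suspect (transport is
    cumulative) and triggers a data-quality warning, not an error.
    """
    if len(partitions) == 0:
        raise InsufficientDataError("no partitions given")
    times = np.array([p.time_h for p in partitions])
    if np.any(np.diff(times) <= 0):
        raise DomainError("partition times must be strictly increasing")
    if len(partitions) < 2:
        raise InsufficientDataError("need >= 2 partitions for a retention series")

    rp = np.array([p.pct_rp for p in partitions])
    if np.any(np.diff(rp) < -1e-9):
        warnings.warn(
            "cumulative receiving-phase percentage decreases over time; "
            "check assay data",
            stacklevel=2,
        )

    if window is None:
        window = (float(times[0]), float(times[-1]))
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise InsufficientDataError(f"no partitions inside window {window}")
    npm = np.array([p.pct_npm for p in partitions])[mask]
    rng = float(npm.max() - npm.min())
    return {
        "window": (lo, hi),
        "n": int(mask.sum()),
        "min_pct_npm": float(npm.min()),
        "max_pct_npm": float(npm.max()),
        "mean_pct_npm": float(npm.mean()),
        "range_pct_npm": rng,
        "constant": rng <= tolerance_points,
        "tolerance_points": tolerance_points,
    }


def read_partition_csv(path) -> list[PhasePartition]:
    """Read interruption data: time_h,total_mg,dm_mg,rp_cum_mg."""
    df = pd.read_csv(path)
    return [
        partition(row.total_mg, row.dm_mg, row.rp_cum_mg, row.time_h)
        for row in df.sort_values("time_h").itertuples()
    ]


def partitions_to_frame(partitions: Sequence[PhasePartition]) -> pd.DataFrame:
    """Tabulate a partition series (time_h, pct_npm, pct_dm, pct_rp)."""
    return pd.DataFrame(
        {
            "time_h": [p.time_h for p in partitions],
            "pct_npm": [p.pct_npm for p in partitions],
            "pct_dm": [p.pct_dm for p in partitions],
            "pct_rp": [p.pct_rp for p in partitions],
        }
    )
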