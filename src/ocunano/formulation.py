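"""Formulation-level bookkeeping for medicated nanoparticle batches.

Encapsulation efficiency (EE) is the fraction of the loaded drug that ends
up associated with the nanoparticle phase after self-assembly:

    EE = (M_t - M_s) / M_t

where ``M_t`` is the total drug mass used for the preparation and ``M_s``
is the mass recovered in the supernatant after ultracentrifugation.  EE is
stored as a fraction in [0, 1]; percent rendering happens only at the
reporting layer.

Measured batch characteristics (size, polydispersity, zeta potential, EE)
ship as a read-only fixture; they are instrument readings, never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import DomainError

__all__ = [
    "NPBatch",
    "DoseSplit",
    "encapsulation_efficiency",
    "dose_split",
    "load_np_batches",
]


@dataclass(frozen=True)
class NPBatch:
    """Measured characteristics of one medicated nanoparticle batch.

    Parameters
    ----------
    label : str
        Formulation label (e.g. ``"QA-Ch"``).
    size_nm : float
        Hydrodynamic diameter in nm (DLS z-average), > 0.
    pdi : float
        Polydispersity index in [0, 1].
    zeta_mV : float
        Zeta potential in mV (sign reflects surface charge).
    ee : float
        Encapsulation efficiency as a fraction in [0, 1].
    """

    label: str
    size_nm: float
    pdi: float
    zeta_mV: float
    ee: float

    def __post_init__(self) -> None:
        if self.size_nm <= 0:
            raise DomainError(f"size_nm must be > 0, got {self.size_nm}")
        if not 0.0 <= self.pdi <= 1.0:
            raise DomainError(f"pdi must be in [0, 1], got {self.pdi}")
        if not 0.0 <= self.ee <= 1.0:
            raise DomainError(f"ee must be in [0, 1], got {self.ee}")


@dataclass(frozen=True)
class DoseSplit:
    """Partition of a drug dose between the entrapped and free pools (mg)."""

    total_mass: float
    entrapped_mass: float
    free_mass: float

    def __post_init__(self) -> None:
        if min(self.total_mass, self.entrapped_mass, self.free_mass) < 0:
            raise DomainError("all masses must be non-negative")
        closure = abs(self.entrapped_mass + self.free_mass - self.total_mass)
        scale = max(self.total_mass, 1.0)
        if closure > 1e-9 * scale:
            raise DomainError(
                f"entrapped + free != total (off by {closure:g} mg)"
            )


def encapsulation_efficiency(total_mass: float, supernatant_mass: float) -> float:
    """Encapsulation efficiency (M_t - M_s)/M_t as a fraction in [0, 1].

    Parameters
    ----------
    total_mass : float
        Total drug mass M_t used for the nanoparticle preparation (mg), > 0.
    supernatant_mass : float
        Drug mass M_s assayed in the supernatant after centrifugation (mg).

    Raises
    ------
    DomainError
        If ``total_mass <= 0`` or ``supernatant_mass`` lies outside
        ``[0, total_mass]`` (either signals an assay inconsistency).
    """
    if total_mass <= 0:
        raise DomainError(f"total_mass must be > 0, got {total_mass}")
    if supernatant_mass < 0 or supernatant_mass > total_mass:
        raise DomainError(
            "supernatant mass outside [0, total]: assay inconsistency "
            f"(M_s={supernatant_mass}, M_t={total_mass})"
        )
    return (total_mass - supernatant_mass) / total_mass


def dose_split(total_mass: float, ee: float) -> DoseSplit:
    """Split a dose into entrapped and free drug given an EE fraction."""
    if total_mass < 0:
        raise DomainError(f"total_mass must be >= 0, got {total_mass}")
    if not 0.0 <= ee <= 1.0:
        raise DomainError(f"ee must be in [0, 1], got {ee}")
    entrapped = ee * total_mass
    return DoseSplit(total_mass, entrapped, total_mass - entrapped)


def load_np_batches() -> list[NPBatch]:
    """Load the measured nanoparticle batch characteristics fixture."""
    with resources.files("ocunano.data").joinpath("np_characteristics.csv").open() as fh:
        df = pd.read_csv(fh)
    return [
        NPBatch(
            label=row.label,
            size_nm=row.size_nm,
            pdi=row.pdi,
            zeta_mV=row.zeta_mV,
            ee=row.ee_pct / 100.0,
        )
        for row in df.itertuples()
    ]
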