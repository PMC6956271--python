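"""Passive DLS microrheology: correlogram -> tracer MSD -> G', G'', eta*.

Tracer particles embedded in the medium report its viscoelasticity through
their thermal motion.  The chain implemented here is the standard one for
single-angle DLS instruments:

1. Siegert relation: g2(tau) = 1 + beta * |g1(tau)|^2, so the field
   correlation is g1 = sqrt((g2 - 1) / beta).
2. Gaussian displacement statistics in 3-D: g1 = exp(-q^2 MSD / 6), hence
   MSD(tau) = -(6 / q^2) ln g1, with scattering vector
   q = (4 pi n / lambda) sin(theta / 2).
3. Mason's local power-law generalized Stokes-Einstein relation (GSER):
   with alpha(omega) = d ln MSD / d ln tau at tau = 1/omega,

       |G*(omega)| = kB T / (pi a MSD(1/omega) Gamma(1 + alpha)),
       G'  = |G*| cos(pi alpha / 2),   G'' = |G*| sin(pi alpha / 2),
       eta* = |G*| / omega.

   alpha = 1 is a Newtonian fluid (G'' = omega eta, G' = 0); alpha = 0 is
   an elastic plateau (G' = kB T / (pi a delta^2)).

Mucoadhesion is scored by the complex-viscosity thickening that adding
nanoparticles causes in a mucin dispersion: synergistic interaction between
nanoparticle surfaces and mucin glycoproteins raises eta* (and G') above
the plain-mucin spectrum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn

from .errors import DomainError, InsufficientDataError, InsufficientSignalError

__all__ = [
    "Correlogram",
    "ComplexModulus",
    "scattering_vector",
    "msd_from_g2",
    "gser_moduli",
    "mucoadhesion_compare",
    "read_correlogram_csv",
    "KB",
]

KB = 1.380649e-23  # J/K

# Zetasizer-style backscatter defaults (633 nm HeNe, aqueous, 173 deg)
DEFAULT_WAVELENGTH_NM = 633.0
DEFAULT_REF_INDEX = 1.33
DEFAULT_ANGLE_DEG = 173.0
DEFAULT_TEMPERATURE_K = 298.15
DEFAULT_TRACER_RADIUS_NM = 250.0  # 500 nm polystyrene latex tracer

#: absolute floor on g2 - 1 below which lags are discarded regardless of
#: the estimated noise level (guards against float cancellation in g2 - 1)
SIGNAL_FLOOR = 1e-9


@dataclass
class Correlogram:
    """Baseline-normalized intensity autocorrelation of a tracer sample."""

    lags: np.ndarray  # s, strictly increasing
    g2: np.ndarray
    beta: float = 0.8  # coherence factor, (0, 1]
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    ref_index: float = DEFAULT_REF_INDEX
    angle_deg: float = DEFAULT_ANGLE_DEG
    temperature_K: float = DEFAULT_TEMPERATURE_K
    tracer_radius_nm: float = DEFAULT_TRACER_RADIUS_NM

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.lags.shape != self.g2.shape:
            raise DomainError("lags and g2 must have equal length")
        if np.any(np.diff(self.lags) <= 0) or np.any(self.lags <= 0):
            raise DomainError("lags must be positive and strictly increasing")
        if not 0.0 < self.beta <= 1.0:
            raise DomainError(f"beta must be in (0, 1], got {self.beta}")
        if np.any(self.g2 < 1.0 - 0.05):
            raise DomainError("g2 below baseline 1 beyond tolerance")
        if self.tracer_radius_nm <= 0 or self.temperature_K <= 0:
            raise DomainError("tracer radius and temperature must be > 0")


@dataclass
class ComplexModulus:
    """Viscoelastic spectra on an angular-frequency grid."""

    omegas: np.ndarray  # rad/s, strictly increasing
    g_prime: np.ndarray  # Pa
    g_dprime: np.ndarray  # Pa
    eta_star: np.ndarray  # Pa s
    alpha: np.ndarray = field(default=None)  # local log-log MSD slope

    def __post_init__(self) -> None:
        for name in ("omegas", "g_prime", "g_dprime", "eta_star"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.omegas) <= 0):
            raise DomainError("omegas must be strictly increasing")
        mag = np.hypot(self.g_prime, self.g_dprime)
        if np.any(np.abs(self.eta_star - mag / self.omegas) > 1e-9 * np.maximum(mag / self.omegas, 1e-300)):
            raise DomainError("eta_star inconsistent with |G*|/omega")


def scattering_vector(
    wavelength_nm: float, ref_index: float, angle_deg: float
) -> float:
    """Scattering vector magnitude q = (4 pi n / lambda) sin(theta/2), 1/m."""
    if wavelength_nm <= 0 or ref_index <= 0:
        raise DomainError("wavelength and refractive index must be > 0")
    if not 0.0 < angle_deg <= 180.0:
        raise DomainError(f"detection angle must be in (0, 180], got {angle_deg}")
    lam = wavelength_nm * 1e-9
    return 4.0 * math.pi * ref_index / lam * math.sin(math.radians(angle_deg) / 2.0)


def msd_from_g2(c: Correlogram) -> tuple[np.ndarray, np.ndarray]:
    """Invert a correlogram to the tracer mean-squared displacement.

    Lags whose signal g2 - 1 falls below 3x the long-lag baseline noise SD
    (estimated from the last decade of lags) or below an absolute float
    floor are discarded.  Returns ``(retained_lags_s, msd_m2)``.
    """
    signal = c.g2 - 1.0
    # baseline noise from the last 10% of lags (tail should have decayed)
    ntail = max(len(signal) // 10, 3)
    noise_sd = float(np.std(signal[-ntail:]))
    thresh = max(3.0 * noise_sd, SIGNAL_FLOOR)
    keep = signal > thresh
    if not keep.any():
        raise InsufficientSignalError(
            "no lags with g2 - 1 above the noise floor"
        )
    ratio = signal[keep] / c.beta
    if np.any(ratio > 1.0):
        warnings.warn(
            "g2 - 1 exceeds beta at some lags (beta likely set too low); "
            "clipping g1 to 1, MSD biased toward 0 there",
            stacklevel=2,
        )
        ratio = np.minimum(ratio, 1.0)
    g1 = np.sqrt(ratio)
    q = scattering_vector(c.wavelength_nm, c.ref_index, c.angle_deg)
    with np.errstate(divide="ignore"):
        msd = -(6.0 / q**2) * np.log(g1)
    msd = np.maximum(msd, 0.0)
    return c.lags[keep], msd


def _local_loglog_slope(tau: np.ndarray, msd: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered-difference d ln MSD / d ln tau with a moving-average smoother.

    One-sided differences at the boundaries; the smoother uses a centered
    ``window``-point mean with shrinking windows at the edges.
    """
    lt = np.log(tau)
    lm = np.log(msd)
    alpha = np.gradient(lm, lt)
    half = window // 2
    smoothed = np.empty_like(alpha)
    for i in range(len(alpha)):
        lo, hi = max(0, i - half), min(len(alpha), i + half + 1)
        smoothed[i] = alpha[lo:hi].mean()
    return smoothed


def gser_moduli(
    tau: np.ndarray,
    msd: np.ndarray,
    tracer_radius_nm: float = DEFAULT_TRACER_RADIUS_NM,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
) -> ComplexModulus:
    """Viscoelastic spectra from an MSD series via the local power-law GSER.

    Evaluated at omega = 1/tau for every retained lag; the local log-log
    MSD slope alpha is clamped to [0, 1] (sub-diffusive to diffusive), which
    guarantees G', G'' >= 0.
    """
    tau = np.asarray(tau, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if np.any(msd <= 0):
        raise DomainError("MSD must be > 0 at every retained lag")
    if len(tau) < 5 or tau[-1] / tau[0] < 10.0:
        raise InsufficientDataError(
            "need >= 5 MSD points spanning at least one decade of lag"
        )
    a_m = tracer_radius_nm * 1e-9
    alpha = np.clip(_local_loglog_slope(tau, msd), 0.0, 1.0)
    gstar = KB * temperature_K / (math.pi * a_m * msd * gamma_fn(1.0 + alpha))
    gp = gstar * np.cos(math.pi * alpha / 2.0)
    gpp = gstar * np.sin(math.pi * alpha / 2.0)
    omega = 1.0 / tau
    order = np.argsort(omega)
    return ComplexModulus(
        omegas=omega[order],
        g_prime=gp[order],
        g_dprime=gpp[order],
        eta_star=(gstar / omega)[order],
        alpha=alpha[order],
    )


def moduli_from_correlogram(c: Correlogram) -> ComplexModulus:
    """Convenience: full correlogram -> moduli chain."""
    tau, msd = msd_from_g2(c)
    return gser_moduli(tau, msd, c.tracer_radius_nm, c.temperature_K)


def mucoadhesion_compare(
    moduli_mucin: ComplexModulus,
    moduli_mix: ComplexModulus,
    threshold: float = 0.10,
    n_grid: int = 50,
) -> dict:
    """Score nanoparticle mucoadhesion by viscosity thickening of mucin.

    Both spectra are interpolated (log-log) onto a common grid spanning the
    overlap of their frequency ranges; per-frequency ratios
    eta*(mix)/eta*(mucin) and G'(mix)/G'(mucin) are reported.  The mixture
    is classified mucoadhesive iff the median eta* ratio exceeds
    ``1 + threshold`` (default +10%).
    """
    lo = max(moduli_mucin.omegas[0], moduli_mix.omegas[0])
    hi = min(moduli_mucin.omegas[-1], moduli_mix.omegas[-1])
    if lo >= hi:
        raise DomainError("frequency grids do not overlap")
    grid = np.geomspace(lo, hi, n_grid)

    def _interp(m: ComplexModulus, y: np.ndarray) -> np.ndarray:
        return np.exp(
            np.interp(np.log(grid), np.log(m.omegas), np.log(np.maximum(y, 1e-300)))
        )

    eta_ratio = _interp(moduli_mix, moduli_mix.eta_star) / _interp(
        moduli_mucin, moduli_mucin.eta_star
    )
    gp_ratio = _interp(moduli_mix, moduli_mix.g_prime) / np.maximum(
        _interp(moduli_mucin, moduli_mucin.g_prime), 1e-300
    )
    med = float(np.median(eta_ratio))
    return {
        "omega_grid": grid,
        "eta_star_ratio": eta_ratio,
        "g_prime_ratio": gp_ratio,
        "median_eta_star_ratio": med,
        "mucoadhesive": med > 1.0 + threshold,
        "threshold": threshold,
    }


def rank_mucoadhesion(
    moduli_mucin: ComplexModulus,
    mixtures: dict[str, ComplexModulus],
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Rank candidate formulations by median eta* thickening over mucin."""
    rows = []
    for label, m in mixtures.items():
        rep = mucoadhesion_compare(moduli_mucin, m, threshold=threshold)
        rows.append(
            {
                "label": label,
                "median_eta_star_ratio": rep["median_eta_star_ratio"],
                "median_g_prime_ratio": float(np.median(rep["g_prime_ratio"])),
                "mucoadhesive": rep["mucoadhesive"],
            }
        )
    df = pd.DataFrame(rows).sort_values(
        "median_eta_star_ratio", ascending=False, ignore_index=True
    )
    return df


def read_correlogram_csv(path, **instrument) -> Correlogram:
    """Read a correlogram CSV (lag_s,g2); instrument constants as kwargs."""
    df = pd.read_csv(path)
    if not {"lag_s", "g2"} <= set(df.columns):
        raise DomainError("correlogram CSV needs columns lag_s,g2")
    df = df.sort_values("lag_s")
    return Correlogram(
        lags=df["lag_s"].to_numpy(float), g2=df["g2"].to_numpy(float), **instrument
    )
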