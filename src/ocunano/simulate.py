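"""Synthetic-data generators with known ground truth for every stage.

Each generator inverts the model its analysis counterpart fits, so the
full pipeline can be exercised round-trip with recoverable truth:

- dialysis: exponential donor decay C_d(t) = C_d0 exp(-Km Ff t) with
  multiplicative assay noise;
- release: Higuchi line Q = k sqrt(t) + b with additive noise, clamped to
  [0, 100];
- pharmacokinetics: zero-order absorption (gel-erosion controlled input)
  with first-order elimination, producing the rise-to-plateau shape, then
  per-time-point destructive sampling (n animals, relative assay CV);
- DLS: Newtonian / Maxwell / elastic-plateau MSD models pushed through the
  Gaussian-displacement and Siegert relations to an intensity correlogram;
- imaging: isotropic Gaussian spots (bead sigma convolved with the PSF
  sigma in quadrature) on a Poisson-noise background at a stated peak SNR.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math

import numpy as np

from .dialysis import DialysisRun
from .errors import DomainError
from .microrheology import (
    KB,
    Correlogram,
    DEFAULT_ANGLE_DEG,
    DEFAULT_REF_INDEX,
    DEFAULT_TEMPERATURE_K,
    DEFAULT_TRACER_RADIUS_NM,
    DEFAULT_WAVELENGTH_NM,
    scattering_vector,
)
from .pk import PKProfile
from .release import ReleaseCurve
from .sizing import FWHM_FACTOR

__all__ = [
    "gen_dialysis_run",
    "gen_release_curve",
    "gen_pk_profile",
    "pk_true_concentration",
    "pk_true_auc",
    "gen_dls_g2",
    "gen_bead_image",
]

DEFAULT_DIALYSIS_TIMES_H = np.arange(0.5, 5.01, 0.5)
DEFAULT_RELEASE_TIMES_MIN = np.arange(30.0, 301.0, 30.0)
DEFAULT_PK_TIMES_H = np.array([0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0])


def gen_dialysis_run(
    km: float,
    ff: float,
    cd0: float = 100.0,
    times=None,
    noise: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic",
    role: str | None = None,
    replicate: int = 0,
) -> DialysisRun:
    """Donor-phase decay C_d(t) = cd0 exp(-km ff t) (1 + eps).

    ``eps`` is i.i.d. Normal(0, noise) multiplicative assay error.  A run
    with ``ff = 1`` emulates the free-drug control.
    """
    if km <= 0:
        raise DomainError(f"km must be > 0, got {km}")
    if not 0.0 <= ff <= 1.0:
        raise DomainError(f"ff must be in [0, 1], got {ff}")
    if noise < 0:
        raise DomainError("noise must be >= 0")
    t = np.asarray(DEFAULT_DIALYSIS_TIMES_H if times is None else times, float)
    rng = np.random.default_rng(seed)
    conc = cd0 * np.exp(-km * ff * t)
    if noise > 0:
        conc = conc * (1.0 + rng.normal(0.0, noise, size=t.shape))
    conc = np.clip(conc, 1e-12 * cd0, cd0 * 1.049)
    if role is None:
        role = "control" if ff == 1.0 else "formulation"
    return DialysisRun(
        label=label, role=role, times=t, donor_conc=conc, cd0=cd0,
        replicate=replicate,
    )


def gen_release_curve(
    slope: float,
    intercept: float = 0.0,
    times_min=None,
    noise: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic",
    replicate: int = 0,
) -> ReleaseCurve:
    """Higuchi release Q(t) = slope sqrt(t) + intercept + Normal(0, noise).

    ``noise`` is an additive SD in percentage points.  Values are clamped
    to [0, 100].
    """
    if noise < 0:
        raise DomainError("noise must be >= 0")
    t = np.asarray(DEFAULT_RELEASE_TIMES_MIN if times_min is None else times_min,
                   float)
    rng = np.random.default_rng(seed)
    q = slope * np.sqrt(t) + intercept
    if noise > 0:
        q = q + rng.normal(0.0, noise, size=t.shape)
    return ReleaseCurve(
        label=label, replicate=replicate, times=t,
        released_pct=np.clip(q, 0.0, 100.0),
    )


def pk_true_concentration(
    t, k_in: float, t_plateau_end: float, k_el: float
) -> np.ndarray:
    """Noiseless zero-order-input / first-order-elimination profile (ug/mL)."""
    t = np.asarray(t, dtype=float)
    css = k_in / k_el
    rising = css * (1.0 - np.exp(-k_el * np.minimum(t, t_plateau_end)))
    decayed = rising * np.exp(-k_el * np.maximum(t - t_plateau_end, 0.0))
    return decayed


def pk_true_auc(
    k_in: float, t_plateau_end: float, k_el: float,
    t_start: float = 0.0, t_end: float = 10.0,
) -> float:
    """Closed-form integral of the true profile over [t_start, t_end]."""
    from scipy.integrate import quad

    val, _ = quad(
        lambda x: float(pk_true_concentration(x, k_in, t_plateau_end, k_el)),
        t_start, t_end, points=[t_plateau_end] if t_start < t_plateau_end < t_end else None,
        limit=200,
    )
    return float(val)


def k_in_for_auc(
    target_auc: float,
    t_plateau_end: float = 10.0,
    k_el: float = 3.0,
    t_end: float = 10.0,
) -> float:
    """Zero-order input rate whose true profile integrates to ``target_auc``.

    Valid for ``t_end <= t_plateau_end`` (the window the exposure metric
    uses), where AUC = (k_in / k_el) (t_end - (1 - exp(-k_el t_end)) / k_el).
    """
    if t_end > t_plateau_end:
        raise DomainError("closed form requires t_end <= t_plateau_end")
    factor = t_end - (1.0 - math.exp(-k_el * t_end)) / k_el
    return target_auc * k_el / factor


def gen_pk_profile(
    k_in: float,
    t_plateau_end: float = 10.0,
    k_el: float = 3.0,
    sd_rel: float = 0.15,
    n: int = 6,
    times=None,
    seed: int | None = None,
    label: str = "synthetic",
) -> PKProfile:
    """Sparse-sampling PK summary from the plateau-shaped true profile.

    At each sampling time, ``n`` independent animals are assayed with
    relative error ``sd_rel`` (Normal, truncated at zero); the per-time
    mean, SD (ddof=1) and n are emitted, mimicking destructive aqueous-humor
    sampling.
    """
    if k_in <= 0 or k_el <= 0 or t_plateau_end <= 0:
        raise DomainError("all rates and the plateau end must be > 0")
    if sd_rel < 0 or n < 1:
        raise DomainError("sd_rel must be >= 0 and n >= 1")
    t = np.asarray(DEFAULT_PK_TIMES_H if times is None else times, float)
    rng = np.random.default_rng(seed)
    truth = pk_true_concentration(t, k_in, t_plateau_end, k_el)
    means = np.empty_like(truth)
    sds = np.empty_like(truth)
    for i, c in enumerate(truth):
        samples = np.maximum(c * (1.0 + rng.normal(0.0, sd_rel, size=n)), 0.0)
        means[i] = samples.mean()
        sds[i] = samples.std(ddof=1) if n > 1 else 0.0
    return PKProfile(
        label=label, times_h=t, mean_conc=means, sd_conc=sds,
        n_per_time=np.full(t.shape, n, dtype=int),
    )


def _msd_model(model: str, tau: np.ndarray, params: dict,
               tracer_radius_nm: float, temperature_K: float) -> np.ndarray:
    a = tracer_radius_nm * 1e-9
    kt = KB * temperature_K
    if model == "newtonian":
        eta = params["eta"]  # Pa s
        if eta <= 0:
            raise DomainError("eta must be > 0")
        d = kt / (6.0 * math.pi * eta * a)
        return 6.0 * d * tau
    if model == "maxwell":
        g0, lam = params["G0"], params["lam"]
        if g0 <= 0 or lam <= 0:
            raise DomainError("G0 and lam must be > 0")
        eta = g0 * lam
        # creep compliance of a Maxwell element: J(t) = 1/G0 + t/eta
        return kt / (math.pi * a) * (1.0 / g0 + tau / eta)
    if model == "plateau":
        delta2 = params["delta2"]  # m^2
        if delta2 <= 0:
            raise DomainError("delta2 must be > 0")
        return np.full_like(tau, delta2)
    raise DomainError(f"unknown DLS model {model!r}")


def gen_dls_g2(
    model: str = "newtonian",
    params: dict | None = None,
    lags=None,
    beta: float = 0.8,
    noise: float = 0.0,
    seed: int | None = None,
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
    ref_index: float = DEFAULT_REF_INDEX,
    angle_deg: float = DEFAULT_ANGLE_DEG,
    temperature_K: float = DEFAULT_TEMPERATURE_K,
    tracer_radius_nm: float = DEFAULT_TRACER_RADIUS_NM,
) -> Correlogram:
    """Correlogram of a tracer in a model medium.

    Models: ``newtonian`` (params: eta, Pa s), ``maxwell`` (params: G0 in
    Pa, lam in s), ``plateau`` (params: delta2, m^2 — a frozen tracer).
    The MSD is pushed through g1 = exp(-q^2 MSD / 6) and the Siegert
    relation g2 = 1 + beta g1^2; ``noise`` is additive Gaussian SD on g2.
    """
    params = params or {}
    tau = np.asarray(
        np.logspace(-6, 0, 200) if lags is None else lags, dtype=float
    )
    rng = np.random.default_rng(seed)
    msd = _msd_model(model, tau, params, tracer_radius_nm, temperature_K)
    q = scattering_vector(wavelength_nm, ref_index, angle_deg)
    g1 = np.exp(-(q**2) * msd / 6.0)
    g2 = 1.0 + beta * g1**2
    if noise > 0:
        g2 = g2 + rng.normal(0.0, noise, size=tau.shape)
    return Correlogram(
        lags=tau, g2=g2, beta=beta, wavelength_nm=wavelength_nm,
        ref_index=ref_index, angle_deg=angle_deg,
        temperature_K=temperature_K, tracer_radius_nm=tracer_radius_nm,
    )


def gen_bead_image(
    diameters_um,
    positions_um=None,
    shape: tuple[int, int] = (256, 256),
    pixel_size_um: float = 0.03,
    psf_sigma_um: float = 0.0,
    snr: float = 20.0,
    background: float = 20.0,
    seed: int | None = None,
) -> np.ndarray:
    """Fluorescence micrograph of Gaussian beads with Poisson noise.

    Each bead of diameter d renders as an isotropic Gaussian spot with
    sigma_eff^2 = (d / 2.3548)^2 + psf_sigma^2 — i.e. the apparent size a
    FWHM measurement sees.  Peak amplitude A (counts) is set so the Poisson
    SNR at the peak, A / sqrt(A + background), equals ``snr``.  Returns a
    float image of Poisson counts.
    """
    diameters = np.atleast_1d(np.asarray(diameters_um, dtype=float))
    if np.any(diameters <= 0):
        raise DomainError("diameters must be > 0")
    if snr <= 0 or pixel_size_um <= 0:
        raise DomainError("snr and pixel size must be > 0")
    ny, nx = shape
    if positions_um is None and len(diameters) == 0:
        positions_um = []
    elif positions_um is None:
        # spread beads on a grid with margins
        k = len(diameters)
        cols = int(np.ceil(np.sqrt(k)))
        rows_n = int(np.ceil(k / cols))
        xs = (np.arange(cols) + 0.5) / cols * nx * pixel_size_um
        ys = (np.arange(rows_n) + 0.5) / rows_n * ny * pixel_size_um
        positions_um = [(ys[i // cols], xs[i % cols]) for i in range(k)]
    rng = np.random.default_rng(seed)
    amp = (snr**2 + snr * math.sqrt(snr**2 + 4.0 * background)) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    yy = yy * pixel_size_um
    xx = xx * pixel_size_um
    img = np.full(shape, float(background))
    for d, (cy, cx) in zip(diameters, positions_um):
        sigma = math.sqrt((d / FWHM_FACTOR) ** 2 + psf_sigma_um**2)
        img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2)))
    return rng.poisson(img).astype(float)
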