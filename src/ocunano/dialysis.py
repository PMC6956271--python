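"""Reversible drug binding inferred from dynamic-dialysis donor decay.

Under sink conditions the donor-phase drug concentration of a dialysis cell
decays log-linearly,

    ln(100 * C_d / C_d0) = ln(100) - Km * Ff * t,

where ``Km`` (h^-1) is the membrane dialysis-rate constant and ``Ff`` is the
free (non-interacting) drug fraction.  A plain drug solution has ``Ff = 1``,
so the control slope magnitude *is* ``Km``; a formulation's slope magnitude
divided by ``Km`` gives its free fraction, and ``100 * (1 - Ff)`` is the
percentage reversibly bound to polymer or adsorbed on the nanoparticle
surface (the "Interaction %").

The intercept is fitted freely rather than pinned to ``ln(100) = 4.605``;
its deviation from 4.605 is a diagnostic for a mis-measured ``C_d0`` or a
violated sink condition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InsufficientDataError

__all__ = [
    "DialysisRun",
    "BindingResult",
    "fit_log_linear",
    "calibrate_km",
    "bound_fraction",
    "analyze_runs",
    "read_dialysis_csv",
]

LN100 = math.log(100.0)

#: relative headroom allowed on donor_conc above cd0 (measurement noise)
CONC_TOLERANCE = 0.05


@dataclass
class DialysisRun:
    """Donor-phase concentration time course of one dialysis experiment.

    ``role`` distinguishes the free-drug control (used to calibrate the
    membrane constant) from polymer/nanoparticle formulations.
    """

    label: str
    role: str  # "control" | "formulation"
    times: np.ndarray  # h, strictly increasing
    donor_conc: np.ndarray  # same units as cd0
    cd0: float
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.donor_conc = np.asarray(self.donor_conc, dtype=float)
        if self.role not in ("control", "formulation"):
            raise DomainError(f"role must be control|formulation, got {self.role!r}")
        if self.times.shape != self.donor_conc.shape:
            raise DomainError("times and donor_conc must have equal length")
        if len(self.times) < 3:
            raise InsufficientDataError(
                f"need >= 3 time points, got {len(self.times)}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.cd0 <= 0:
            raise DomainError(f"cd0 must be > 0, got {self.cd0}")
        if np.any(self.donor_conc > self.cd0 * (1.0 + CONC_TOLERANCE)):
            raise DomainError("donor_conc exceeds cd0 beyond measurement tolerance")


@dataclass
class BindingResult:
    """Log-linear fit of one dialysis run, optionally completed with Km/Ff."""

    label: str
    slope_mag: float  # h^-1, magnitude of the fitted slope
    intercept: float
    r2: float
    km: float | None = None
    ff: float | None = None
    interaction_pct: float | None = None
    warnings: list[str] = field(default_factory=list)


def fit_log_linear(run: DialysisRun) -> BindingResult:
    """Ordinary least squares of ln(100*C_d/C_d0) on t.

    Returns the slope magnitude, the freely fitted intercept (compare with
    ln(100) = 4.605 as a sink-condition diagnostic) and r^2.  A positive
    fitted slope (donor concentration rising) is physically impossible under
    sink transport and is flagged, not raised.
    """
    if np.any(run.donor_conc <= 0):
        raise DomainError("donor_conc must be > 0 for the log transform")
    y = np.log(100.0 * run.donor_conc / run.cd0)
    res = stats.linregress(run.times, y)
    warns: list[str] = []
    if res.slope > 0:
        warns.append("rising-donor: positive fitted slope")
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return BindingResult(
        label=run.label,
        slope_mag=abs(float(res.slope)),
        intercept=float(res.intercept),
        r2=r2,
        warnings=warns,
    )


def calibrate_km(control: BindingResult) -> float:
    """Membrane constant Km from the free-drug control fit (Ff = 1)."""
    if control.slope_mag <= 0:
        raise DomainError(
            "degenerate calibration: control slope is zero (no transport)"
        )
    return control.slope_mag


def bound_fraction(fit: BindingResult, km: float) -> BindingResult:
    """Complete a binding fit with Ff = slope/Km and Interaction %.

    Ratios marginally above 1 (noise) are clamped to 1 with a warning,
    since the bound percentage is defined on [0, 100].
    """
    if km <= 0:
        raise DomainError(f"km must be > 0, got {km}")
    raw = fit.slope_mag / km
    warns = list(fit.warnings)
    if raw > 1.0:
        warns.append(f"free-fraction ratio {raw:.4f} > 1 clamped to 1")
    ff = min(max(raw, 0.0), 1.0)
    return replace(
        fit,
        km=km,
        ff=ff,
        interaction_pct=100.0 * (1.0 - ff),
        warnings=warns,
    )


def _pooled_fit(runs: Sequence[DialysisRun]) -> BindingResult:
    times = np.concatenate([r.times for r in runs])
    y = np.concatenate(
        [np.log(100.0 * r.donor_conc / r.cd0) for r in runs]
    )
    res = stats.linregress(times, y)
    return BindingResult(
        label=runs[0].label,
        slope_mag=abs(float(res.slope)),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
    )


def analyze_runs(
    runs: Iterable[DialysisRun],
    pooled: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full binding analysis over replicate dialysis runs.

    Per label: per-replicate log-linear fits (or one pooled fit), mean +/- SD
    of slope magnitudes, Km calibrated from the control label, free fraction,
    Interaction %, and a two-sided Student's t-test of each formulation's
    replicate slopes against the control's.

    Returns a DataFrame with one row per label, control first.
    """
    runs = list(runs)
    by_label: dict[str, list[DialysisRun]] = {}
    for r in runs:
        by_label.setdefault(r.label, []).append(r)

    control_labels = [lab for lab, rs in by_label.items() if rs[0].role == "control"]
    if len(control_labels) != 1:
        raise DomainError(
            f"exactly one control label required, found {control_labels}"
        )
    control_label = control_labels[0]

    slopes: dict[str, np.ndarray] = {}
    fits: dict[str, BindingResult] = {}
    for lab, rs in by_label.items():
        per_rep = [fit_log_linear(r) for r in rs]
        slopes[lab] = np.array([f.slope_mag for f in per_rep])
        if pooled and len(rs) > 1:
            fits[lab] = _pooled_fit(rs)
        else:
            mean_fit = per_rep[0] if len(per_rep) == 1 else BindingResult(
                label=lab,
                slope_mag=float(slopes[lab].mean()),
                intercept=float(np.mean([f.intercept for f in per_rep])),
                r2=float(np.mean([f.r2 for f in per_rep])),
                warnings=sum((f.warnings for f in per_rep), []),
            )
            fits[lab] = mean_fit

    km = calibrate_km(fits[control_label])
    rows = []
    order = [control_label] + [l for l in by_label if l != control_label]
    for lab in order:
        f = fits[lab]
        s = slopes[lab]
        if lab == control_label:
            ff = interaction = p_vs_control = np.nan
        else:
            done = bound_fraction(f, km)
            ff, interaction = done.ff, done.interaction_pct
            if len(s) >= 2 and len(slopes[control_label]) >= 2:
                p_vs_control = float(
                    stats.ttest_ind(s, slopes[control_label]).pvalue
                )
            else:
                p_vs_control = np.nan
        rows.append(
            {
                "label": lab,
                "role": by_label[lab][0].role,
                "n_replicates": len(s),
                "slope_mag": f.slope_mag,
                "slope_sd": float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                "intercept": f.intercept,
                "r2": f.r2,
                "km": km,
                "ff": ff,
                "interaction_pct": interaction,
                "p_vs_control": p_vs_control,
                "significant": bool(p_vs_control < alpha)
                if np.isfinite(p_vs_control)
                else False,
            }
        )
        if abs(fits[lab].intercept - LN100) > 0.5:
            warnings.warn(
                f"{lab}: intercept {fits[lab].intercept:.3f} far from "
                f"ln(100) = {LN100:.3f}; check C_d0 or sink conditions",
                stacklevel=2,
            )
    return pd.DataFrame(rows)


def read_dialysis_csv(path) -> list[DialysisRun]:
    """Read dialysis runs from CSV: label,role,replicate,time_h,donor_conc.

    ``cd0`` is the concentration at t = 0 if present, otherwise the
    concentration at the smallest time of the replicate.
    """
    df = pd.read_csv(path)
    required = {"label", "role", "replicate", "time_h", "donor_conc"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"dialysis CSV missing columns: {sorted(missing)}")
    runs = []
    for (label, role, rep), grp in df.groupby(
        ["label", "role", "replicate"], sort=False
    ):
        grp = grp.sort_values("time_h")
        t = grp["time_h"].to_numpy(float)
        c = grp["donor_conc"].to_numpy(float)
        cd0 = float(c[0]) if t[0] == 0 else float(c[0])
        if t[0] == 0:  # drop the explicit t=0 row from the fit grid
            t, c = t[1:], c[1:]
        runs.append(
            DialysisRun(
                label=str(label), role=str(role), times=t, donor_conc=c,
                cd0=cd0, replicate=int(rep),
            )
        )
    return runs
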