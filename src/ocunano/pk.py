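"""Noncompartmental analysis of sparse aqueous-humor concentration data.

Each animal contributes a single aqueous-humor sample (destructive
sampling), so the concentration-time data are per-time-point summaries
(mean, SD, n) rather than individual profiles.  The exposure metric is the
linear trapezoidal AUC over 0-10 h,

    AUC = sum (t_{i+1} - t_i)(C_i + C_{i+1}) / 2,

whose sampling variance under independent time points follows by
propagating the per-time-point variance of the mean through the trapezoidal
weights (Bailer's method for destructive designs):

    Var(AUC) = sum w_i^2 sd_i^2 / n_i,
    w_0 = (t_1 - t_0)/2,  w_i = (t_{i+1} - t_{i-1})/2,  w_N = (t_N - t_{N-1})/2.

Two formulations are compared with z = (AUC_a - AUC_b)/sqrt(Var_a + Var_b)
against the standard normal (or a t reference with Satterthwaite degrees of
freedom, via ``use_t=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTestError, DomainError

__all__ = [
    "PKProfile",
    "AUCResult",
    "trapezoid_auc",
    "relative_auc",
    "compare_auc",
    "read_pk_csv",
    "analyze_pk",
]


@dataclass
class PKProfile:
    """Sparse-sampling concentration-time summary for one formulation."""

    label: str
    times_h: np.ndarray
    mean_conc: np.ndarray  # ug/mL
    sd_conc: np.ndarray
    n_per_time: np.ndarray  # animals (eyes) per time point

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_conc = np.asarray(self.mean_conc, dtype=float)
        self.sd_conc = np.asarray(self.sd_conc, dtype=float)
        self.n_per_time = np.asarray(self.n_per_time, dtype=int)
        lens = {len(self.times_h), len(self.mean_conc), len(self.sd_conc),
                len(self.n_per_time)}
        if len(lens) != 1:
            raise DomainError("all PKProfile arrays must have equal length")
        if np.any(np.diff(self.times_h) <= 0):
            raise DomainError("times must be strictly increasing")
        if self.times_h[0] < 0:
            raise DomainError("times must be >= 0")
        if np.any(self.mean_conc < 0) or np.any(self.sd_conc < 0):
            raise DomainError("concentrations and SDs must be non-negative")
        if np.any(self.n_per_time < 1):
            raise DomainError("n per time point must be >= 1")


@dataclass
class AUCResult:
    """Trapezoidal AUC with propagated variance and optional ratio."""

    label: str
    auc: float  # ug h/mL
    var_auc: float
    auc_rel: float | None = None


def _windowed(profile: PKProfile, t_start: float, t_end: float,
              baseline_zero: bool) -> PKProfile:
    """Restrict a profile to [t_start, t_end], interpolating the endpoints.

    If the window starts at 0 and no t = 0 sample exists, a zero
    concentration is prepended (topical instillation: no drug on board
    before dosing).  Interior window endpoints not on the grid are linearly
    interpolated (mean and SD; n from the nearest sample) — an
    approximation noted for the variance.
    """
    t = profile.times_h
    if t_start < t[0]:
        if t_start == 0.0 and baseline_zero:
            t = np.concatenate([[0.0], t])
            profile = replace(
                profile,
                times_h=t,
                mean_conc=np.concatenate([[0.0], profile.mean_conc]),
                sd_conc=np.concatenate([[0.0], profile.sd_conc]),
                n_per_time=np.concatenate([[profile.n_per_time[0]],
                                           profile.n_per_time]),
            )
        else:
            raise DomainError(
                f"window start {t_start} before first sample {t[0]}"
            )
    if t_end > profile.times_h[-1] + 1e-12:
        raise DomainError(
            f"window end {t_end} beyond last sample {profile.times_h[-1]}"
        )

    t = profile.times_h
    new_t = np.unique(np.concatenate([t, [t_start, t_end]]))
    mean = np.interp(new_t, t, profile.mean_conc)
    sd = np.interp(new_t, t, profile.sd_conc)
    n = profile.n_per_time[np.searchsorted(t, new_t).clip(0, len(t) - 1)]
    keep = (new_t >= t_start - 1e-12) & (new_t <= t_end + 1e-12)
    return replace(
        profile, times_h=new_t[keep], mean_conc=mean[keep],
        sd_conc=sd[keep], n_per_time=n[keep],
    )


def trapezoid_auc(
    profile: PKProfile,
    t_start: float = 0.0,
    t_end: float = 10.0,
    baseline_zero: bool = True,
) -> AUCResult:
    """Linear trapezoidal AUC over [t_start, t_end] with Bailer variance."""
    if t_end <= t_start:
        raise DomainError("t_end must exceed t_start")
    p = _windowed(profile, t_start, t_end, baseline_zero)
    t, c = p.times_h, p.mean_conc
    auc = float(np.trapezoid(c, t))
    w = np.empty_like(t)
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    if len(t) > 2:
        w[1:-1] = (t[2:] - t[:-2]) / 2.0
    var = float(np.sum(w**2 * p.sd_conc**2 / p.n_per_time))
    return AUCResult(label=profile.label, auc=auc, var_auc=var)


def relative_auc(test: AUCResult, control: AUCResult, decimals: int = 1) -> float:
    """AUC ratio versus control, rounded for reporting (default 1 decimal)."""
    if control.auc <= 0:
        raise DomainError("control AUC must be > 0")
    return round(test.auc / control.auc, decimals)


def compare_auc(
    a: AUCResult,
    b: AUCResult,
    alpha: float = 0.05,
    use_t: bool = False,
    profiles: tuple[PKProfile, PKProfile] | None = None,
    t_start: float = 0.0,
    t_end: float = 10.0,
) -> dict:
    """Sparse-sampling AUC comparison by variance-propagation z (or t) test.

    With ``use_t=True`` the reference distribution is Student's t with
    Satterthwaite degrees of freedom pooled over the two profiles'
    per-time-point variance components (``profiles`` must then be given).
    """
    se = np.sqrt(a.var_auc + b.var_auc)
    if se == 0:
        raise DegenerateTestError("both AUC variances are zero")
    z = (a.auc - b.auc) / se
    if use_t:
        if profiles is None:
            raise DomainError("use_t=True requires the source profiles")
        comps = []
        for p in profiles:
            q = _windowed(p, t_start, t_end, True)
            t = q.times_h
            w = np.empty_like(t)
            w[0] = (t[1] - t[0]) / 2.0
            w[-1] = (t[-1] - t[-2]) / 2.0
            if len(t) > 2:
                w[1:-1] = (t[2:] - t[:-2]) / 2.0
            comps.append((w**2 * q.sd_conc**2 / q.n_per_time,
                          np.maximum(q.n_per_time - 1, 1)))
        num = sum(float(np.sum(c)) for c, _ in comps) ** 2
        den = sum(float(np.sum(c**2 / d)) for c, d in comps)
        df = num / den if den > 0 else np.inf
        p_val = float(2.0 * stats.t.sf(abs(z), df))
        method = f"t (Satterthwaite df={df:.1f})"
    else:
        p_val = float(2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return {
        "statistic": float(z),
        "p": p_val,
        "significant": bool(p_val < alpha),
        "method": method,
        "alpha": alpha,
        "delta_auc": float(a.auc - b.auc),
    }


def read_pk_csv(path) -> list[PKProfile]:
    """Read PK summaries from CSV: label,time_h,mean_conc_ug_ml,sd_conc,n."""
    df = pd.read_csv(path)
    required = {"label", "time_h", "mean_conc_ug_ml", "sd_conc", "n"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"PK CSV missing columns: {sorted(missing)}")
    profiles = []
    for label, grp in df.groupby("label", sort=False):
        grp = grp.sort_values("time_h")
        profiles.append(
            PKProfile(
                label=str(label),
                times_h=grp["time_h"].to_numpy(float),
                mean_conc=grp["mean_conc_ug_ml"].to_numpy(float),
                sd_conc=grp["sd_conc"].to_numpy(float),
                n_per_time=grp["n"].to_numpy(int),
            )
        )
    return profiles


def analyze_pk(
    profiles,
    control_label: str,
    t_start: float = 0.0,
    t_end: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """AUC, SD, relative AUC, and significance vs control for each profile."""
    profiles = list(profiles)
    results = {p.label: trapezoid_auc(p, t_start, t_end) for p in profiles}
    if control_label not in results:
        raise DomainError(f"control label {control_label!r} not in profiles")
    control = results[control_label]
    rows = []
    for p in profiles:
        r = results[p.label]
        if p.label == control_label:
            rel, pval, sig = np.nan, np.nan, False
        else:
            rel = relative_auc(r, control)
            cmp = compare_auc(r, control, alpha=alpha)
            pval, sig = cmp["p"], cmp["significant"]
        rows.append(
            {
                "label": p.label,
                "auc": r.auc,
                "auc_sd": float(np.sqrt(r.var_auc)),
                "auc_rel": rel,
                "p_vs_control": pval,
                "significant": sig,
            }
        )
    return pd.DataFrame(rows)
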