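"""Inference chain for DNA-bundle resonators.

From fitted resonance peaks this module derives: modal-ratio beam/string
classification, effective Young's modulus from the fundamental-frequency vs
R/L^2 regression, cross-section asymmetry from the vacuum doublet splitting,
per-condition summaries, and dose-response (titration) analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beam import (
    BEAM_RATIO_21,
    BEAM_RATIO_32,
    STRING_RATIO_21,
    STRING_RATIO_32,
    clamped_clamped_modal_factors,
)
from .units import PA_TO_GPA

__all__ = [
    "BundleMeasurement",
    "ConditionSummary",
    "modal_ratios",
    "classify_configuration",
    "fit_frequency_vs_geometry",
    "young_modulus_from_slope",
    "young_modulus_per_bundle",
    "asymmetry_from_split",
    "summarize_conditions",
    "titration_summary",
]

KNOWN_DOSES = {"4x": 4.0, "2x": 2.0, "1x": 1.0, "0.5x": 0.5, "0.05x": 0.05, "0.01x": 0.01}


@dataclass
class BundleMeasurement:
    """Everything inferred for one bundle."""

    bundle_id: str
    condition: str
    length: float                       # m
    diameter: float                     # m
    frequencies: list = field(default_factory=list)      # fitted air-mode f0 (Hz)
    frequency_stderrs: list = field(default_factory=list)
    q_factors: dict = field(default_factory=dict)        # {"air": [...], "vacuum": [...]}
    ratio_21: float | None = None
    ratio_32: float | None = None
    classification: str | None = None
    young_modulus: float | None = None  # Pa (per-bundle inversion)
    omega: float | None = None          # frequency-space asymmetry
    dose: str | None = None


@dataclass
class ConditionSummary:
    condition: str
    n: int
    e_mean: float | None = None         # Pa
    e_std: float | None = None
    e_pooled: float | None = None       # from the pooled regression slope
    e_pooled_stderr: float | None = None
    omega_mean: float | None = None
    omega_std: float | None = None
    q_mean_air: float | None = None
    q_mean_vacuum: float | None = None
    splitting_change_percent: float | None = None   # vs pristine


def modal_ratios(frequencies, stderrs=None):
    """Consecutive-mode frequency ratios (f2/f1, f3/f2) with propagated
    uncertainty from the peak-fit standard errors.

    Returns a dict with keys ratio_21, ratio_32 (None when the needed modes
    are absent) and matching *_stderr entries.
    """
    f = [x for x in frequencies if x is not None]
    if len(f) < 2:
        raise ValueError("at least two fitted modes are required for a modal ratio")
    s = list(stderrs) if stderrs is not None else [np.nan] * len(f)

    def ratio(i, j):
        r = f[j] / f[i]
        sr = (
            r * math.sqrt((s[i] / f[i]) ** 2 + (s[j] / f[j]) ** 2)
            if np.isfinite(s[i]) and np.isfinite(s[j])
            else np.nan
        )
        return r, sr

    r21, s21 = ratio(0, 1)
    out = {"ratio_21": r21, "ratio_21_stderr": s21, "ratio_32": None, "ratio_32_stderr": None}
    if len(f) >= 3:
        r32, s32 = ratio(1, 2)
        out["ratio_32"], out["ratio_32_stderr"] = r32, s32
        if r32 == 1.0 or r21 == 1.0:
            out["degenerate"] = True
    return out


def classify_configuration(ratio_21, ratio_32=None, stderr_21=np.nan, stderr_32=np.nan):
    """Classify a bundle as beam / string / indeterminate from its mode ratios.

    Each ratio axis is normalized by the gap between the theoretical beam
    (2.7565, 1.9604) and string (2, 1.5) values, and the bundle is assigned
    the nearer point in that normalized space — unless the two distances
    differ by less than the (normalized, propagated) ratio uncertainty, in
    which case the call returns ``indeterminate``.
    """
    gaps = (BEAM_RATIO_21 - STRING_RATIO_21, BEAM_RATIO_32 - STRING_RATIO_32)
    coords = [(ratio_21, BEAM_RATIO_21, STRING_RATIO_21, gaps[0], stderr_21)]
    if ratio_32 is not None:
        coords.append((ratio_32, BEAM_RATIO_32, STRING_RATIO_32, gaps[1], stderr_32))
    d_beam = math.sqrt(sum(((r - b) / g) ** 2 for r, b, _, g, _ in coords))
    d_string = math.sqrt(sum(((r - s) / g) ** 2 for r, _, s, g, _ in coords))
    sig2 = sum((se / g) ** 2 for *_, g, se in coords if np.isfinite(se))
    sigma = math.sqrt(sig2) if sig2 > 0 else 0.0
    if abs(d_beam - d_string) <= sigma:
        label = "indeterminate"
    else:
        label = "beam" if d_beam < d_string else "string"
    return {"label": label, "distance_beam": d_beam, "distance_string": d_string}


def fit_frequency_vs_geometry(points, through_origin: bool = True):
    """Linear fit of the fundamental frequency against x = R/L^2.

    For an unstressed beam f1 = [lam1^2/(4 pi)] sqrt(E/rho) * (R/L^2), which
    has no intercept; the default therefore regresses through the origin.  A
    free-intercept diagnostic fit is available to expose systematic offsets.

    Parameters
    ----------
    points:
        Iterable of (f1_hz, radius_m, length_m).

    Returns
    -------
    dict with slope, slope_stderr, r_squared (and intercept/intercept_stderr
    when through_origin is False).
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError(f"at least 3 bundles are required for the geometry fit, got {len(pts)}")
    f1 = np.array([p[0] for p in pts], dtype=float)
    x = np.array([p[1] / p[2] ** 2 for p in pts], dtype=float)
    if np.any(x <= 0) or np.any(f1 <= 0):
        raise ValueError("frequencies, radii and lengths must be positive")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all bundles share the same R/L^2")
    if through_origin:
        sxx = float(np.sum(x * x))
        slope = float(np.sum(x * f1) / sxx)
        resid = f1 - slope * x
        dof = len(pts) - 1
        slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
        ss_tot = float(np.sum(f1**2))  # uncentered total SS for the no-intercept model
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        return {"slope": slope, "slope_stderr": slope_se, "r_squared": r2, "n": len(pts)}
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, f1, rcond=None)
    resid = f1 - X @ beta
    dof = len(pts) - 2
    cov = float(np.sum(resid**2)) / dof * np.linalg.inv(X.T @ X)
    ss_tot = float(np.sum((f1 - f1.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return {
        "slope": float(beta[0]),
        "slope_stderr": math.sqrt(cov[0, 0]),
        "intercept": float(beta[1]),
        "intercept_stderr": math.sqrt(cov[1, 1]),
        "r_squared": r2,
        "n": len(pts),
    }


def young_modulus_from_slope(slope: float, density: float, slope_stderr: float = np.nan,
                             density_stderr: float = 0.0):
    """Invert the f1 vs R/L^2 slope to the effective Young's modulus:

        slope = lam1^2/(4 pi) sqrt(E/rho)   =>   E = rho (4 pi slope / lam1^2)^2.

    First-order uncertainty propagation from the slope SE (and, optionally,
    a density uncertainty).
    """
    if slope <= 0 or density <= 0:
        raise ValueError("slope and density must be > 0")
    lam1 = clamped_clamped_modal_factors(1)[0]
    e = density * (4.0 * math.pi * slope / lam1**2) ** 2
    var = 0.0
    if np.isfinite(slope_stderr):
        var += (2.0 * e / slope * slope_stderr) ** 2
    if density_stderr:
        var += (e / density * density_stderr) ** 2
    return {"young_modulus": e, "young_modulus_stderr": math.sqrt(var) if var else np.nan,
            "density_used": density}


def young_modulus_per_bundle(f1: float, radius: float, length: float, density: float) -> float:
    """Per-bundle inversion of the unstressed-beam fundamental:
    E = rho (4 pi f1 L^2 / (lam1^2 R))^2."""
    lam1 = clamped_clamped_modal_factors(1)[0]
    return density * (4.0 * math.pi * f1 * length**2 / (lam1**2 * radius)) ** 2


def asymmetry_from_split(f_fast: float, f_slow: float, d_min: float | None = None):
    """Cross-section asymmetry from a resolved vacuum doublet.

    Returns the frequency-space asymmetry Omega = (f_f - f_s)/f_f, the exact
    diameter ratio d_max/d_min = f_f/f_s implied by the elliptical-beam
    model, and — when a nominal minor diameter is supplied — the implied
    diameter difference d_max - d_min.

    The diameter-space definition Omega_d = (d_max - d_min)/d_min equals the
    frequency form only to first order; both conversions are reported, and
    ``diameter_difference`` uses the first-order (diameter-space) form
    Omega * d_min while ``diameter_difference_exact`` uses the exact ratio.
    """
    if not (f_fast >= f_slow > 0):
        raise ValueError("require f_fast >= f_slow > 0 (caller must order the doublet)")
    omega_freq = (f_fast - f_slow) / f_fast
    ratio = f_fast / f_slow
    out = {
        "omega": omega_freq,
        "diameter_ratio": ratio,
        "omega_diameter_exact": ratio - 1.0,   # (d_max - d_min)/d_min from the exact ratio
    }
    if d_min is not None:
        if d_min <= 0:
            raise ValueError("d_min must be > 0")
        out["diameter_difference"] = omega_freq * d_min
        out["diameter_difference_exact"] = (ratio - 1.0) * d_min
    return out


def diameter_difference_from_omega(omega: float, d_min: float) -> float:
    """Implied d_max - d_min for an asymmetry factor Omega = (d_max-d_min)/d_min."""
    if d_min <= 0:
        raise ValueError("d_min must be > 0")
    return omega * d_min


def _mean_std(values):
    v = [x for x in values if x is not None and np.isfinite(x)]
    if not v:
        return None, None
    mean = float(np.mean(v))
    std = float(np.std(v, ddof=1)) if len(v) >= 2 else None
    return mean, std


def summarize_conditions(
    measurements: list[BundleMeasurement],
    densities: dict | None = None,
    reference: str = "pristine",
) -> list[ConditionSummary]:
    """Per-condition mean/std of E, Omega and Q, plus the pooled-regression E
    and the relative splitting change versus the reference condition."""
    by_cond: dict[str, list[BundleMeasurement]] = {}
    for m in measurements:
        by_cond.setdefault(m.condition, []).append(m)
    summaries = {}
    for cond, group in by_cond.items():
        e_mean, e_std = _mean_std([m.young_modulus for m in group])
        om_mean, om_std = _mean_std([m.omega for m in group])
        q_air, _ = _mean_std([q for m in group for q in m.q_factors.get("air", [])])
        q_vac, _ = _mean_std([q for m in group for q in m.q_factors.get("vacuum", [])])
        s = ConditionSummary(
            condition=cond, n=len(group), e_mean=e_mean, e_std=e_std,
            omega_mean=om_mean, omega_std=om_std, q_mean_air=q_air, q_mean_vacuum=q_vac,
        )
        pts = [
            (m.frequencies[0], m.diameter / 2.0, m.length)
            for m in group
            if m.frequencies and m.frequencies[0]
        ]
        if len(pts) >= 3 and densities is not None and cond in densities:
            fit = fit_frequency_vs_geometry(pts)
            inv = young_modulus_from_slope(fit["slope"], densities[cond], fit["slope_stderr"])
            s.e_pooled = inv["young_modulus"]
            s.e_pooled_stderr = inv["young_modulus_stderr"]
        summaries[cond] = s
    ref = summaries.get(reference)
    if ref is not None and ref.omega_mean:
        for cond, s in summaries.items():
            if s.omega_mean is not None:
                s.splitting_change_percent = 100.0 * (s.omega_mean / ref.omega_mean - 1.0)
    return list(summaries.values())


def titration_summary(measurements: list[BundleMeasurement], saturation_dose: float = 1.0):
    """Dose-response table for a titration series (per-dose mean/std of E),
    plus a monotone-trend check below saturation (lower dose -> higher E,
    toward the pristine value) and a plateau flag at/above saturation
    (over-saturation means differing by less than the pooled std).
    """
    rows = []
    for m in measurements:
        if m.dose is None:
            continue
        key = str(m.dose).lower()
        if key in KNOWN_DOSES:
            dose = KNOWN_DOSES[key]
        else:
            try:
                dose = float(key.rstrip("x"))
            except ValueError:
                raise ValueError(f"unknown dose label {m.dose!r}") from None
        rows.append({"dose": dose, "e": m.young_modulus})
    if not rows:
        raise ValueError("no dose-labelled measurements supplied")
    df = pd.DataFrame(rows)
    if df["dose"].nunique() < 2:
        raise ValueError("at least two dose levels are required")
    table = (
        df.groupby("dose")["e"]
        .agg(e_mean="mean", e_std=lambda v: v.std(ddof=1) if len(v) >= 2 else np.nan, n="count")
        .reset_index()
        .sort_values("dose", ascending=False, ignore_index=True)
    )
    below = table[table["dose"] < saturation_dose].sort_values("dose", ascending=False)
    sat_and_below = pd.concat(
        [table[table["dose"] == saturation_dose], below]
    )
    means = sat_and_below["e_mean"].to_numpy()
    monotone_below_saturation = bool(len(means) >= 2 and np.all(np.diff(means) > 0))
    over = table[table["dose"] >= saturation_dose]
    if len(over) >= 2:
        spread = float(over["e_mean"].max() - over["e_mean"].min())
        pooled = float(np.nanmean(over["e_std"].to_numpy()))
        plateau = bool(np.isfinite(pooled) and spread <= pooled)
        underpowered = False
    else:
        plateau, underpowered = None, True
    return {
        "table": table,
        "monotone_below_saturation": monotone_below_saturation,
        "plateau": plateau,
        "plateau_underpowered": underpowered,
    }


def summary_frame(summaries: list[ConditionSummary]) -> pd.DataFrame:
    """Flatten summaries into a table with E in GPa for reporting."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": s.condition,
                "n": s.n,
                "E_mean_gpa": s.e_mean * PA_TO_GPA if s.e_mean else None,
                "E_std_gpa": s.e_std * PA_TO_GPA if s.e_std else None,
                "E_pooled_gpa": s.e_pooled * PA_TO_GPA if s.e_pooled else None,
                "omega_mean": s.omega_mean,
                "omega_std": s.omega_std,
                "Q_air": s.q_mean_air,
                "Q_vacuum": s.q_mean_vacuum,
                "splitting_change_percent": s.splitting_change_percent,
            }
        )
    return pd.DataFrame(rows)
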