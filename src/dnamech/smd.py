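"""Post-processing of constant-force steered-MD pulling results.

Converts per-force equilibrium lengths into a stress-strain curve
(strain in percent of the starting length, stress = force over the helix
cross-section area), fits the Young's modulus E_SMD by linear regression,
and summarizes hydrogen-bond-count time series.

The helix cross-section area and the starting length L0 are not universal
constants; defaults are pi*(1 nm)^2 for the area (B/A-form helix radius
~1 nm) and 22.4 nm for L0 (66 bp at a 3.4 A rise).  Absolute E_SMD scales
inversely with the chosen area; relative comparisons between systems do not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .units import NM_TO_M, PN_TO_N

__all__ = [
    "PullingRecord",
    "StressStrainCurve",
    "HBondSeries",
    "DEFAULT_HELIX_AREA_NM2",
    "DEFAULT_L0_NM",
    "strain_percent",
    "stress_from_force",
    "build_stress_strain",
    "fit_e_smd",
    "hbond_loss",
    "equilibrium_length",
    "read_pulling_table",
    "write_pulling_table",
]

DEFAULT_HELIX_AREA_NM2 = math.pi * 1.0**2     # pi*(1 nm)^2
DEFAULT_L0_NM = 22.4                           # 66 bp * 3.4 A


@dataclass(frozen=True)
class PullingRecord:
    """One constant-force pulling simulation outcome."""

    system: str                 # e.g. DNA | DNA/YOYO-1 | DNA/CisPt
    replicate: int
    force_pn: float             # applied force (pN)
    length_nm: float            # equilibrium length under that force (nm)
    intercalant_count: int | None = None

    def __post_init__(self):
        if self.force_pn < 0:
            raise ValueError("force must be >= 0")
        if self.length_nm <= 0:
            raise ValueError("length must be > 0")


@dataclass
class StressStrainCurve:
    """Replicate-averaged stress-strain curve for one system."""

    system: str
    stress_pa: np.ndarray        # per force level
    strain_percent: np.ndarray
    strain_stderr: np.ndarray    # SE over replicates, in percent points
    l0_nm: float
    helix_area_nm2: float
    n_replicates: np.ndarray = field(default_factory=lambda: np.array([]))


def strain_percent(length_nm: float, l0_nm: float) -> float:
    """Engineering strain in percent: 100 (L - L0)/L0.

    Negative values (compression) are allowed but flagged with a warning.
    """
    if l0_nm <= 0:
        raise ValueError("reference length L0 must be > 0")
    s = 100.0 * (length_nm - l0_nm) / l0_nm
    if s < 0:
        warnings.warn(f"negative strain {s:.3g}% (compression)", stacklevel=2)
    return s


def stress_from_force(force_pn: float, helix_area_nm2: float = DEFAULT_HELIX_AREA_NM2) -> float:
    """Axial stress in Pa from a pulling force over the helix cross section.

    1 pN / nm^2 = 1 MPa.
    """
    if helix_area_nm2 <= 0:
        raise ValueError("helix cross-section area must be > 0")
    return (force_pn * PN_TO_N) / (helix_area_nm2 * NM_TO_M**2)


def equilibrium_length(time_ns: np.ndarray, length_nm: np.ndarray, tail_fraction: float = 0.25) -> float:
    """Equilibrium length from a pulling time series: mean of the final
    ``tail_fraction`` of the trajectory."""
    time_ns = np.asarray(time_ns, float)
    length_nm = np.asarray(length_nm, float)
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    n_tail = max(int(round(tail_fraction * len(length_nm))), 1)
    return float(np.mean(length_nm[-n_tail:]))


def build_stress_strain(
    records: list[PullingRecord],
    l0_nm: float = DEFAULT_L0_NM,
    helix_area_nm2: float = DEFAULT_HELIX_AREA_NM2,
) -> StressStrainCurve:
    """Aggregate pulling records into a replicate-averaged stress-strain curve.

    Strain is averaged over the replicates at each force level; the per-force
    standard error of that mean is retained for weighting the modulus fit.
    """
    if not records:
        raise ValueError("no pulling records supplied")
    systems = {r.system for r in records}
    if len(systems) != 1:
        raise ValueError(f"records must come from a single system, got {sorted(systems)}")
    df = pd.DataFrame(
        {"force_pn": [r.force_pn for r in records], "length_nm": [r.length_nm for r in records]}
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # compression flagged at record level if needed
        df["strain"] = [strain_percent(l, l0_nm) for l in df["length_nm"]]
    g = df.groupby("force_pn")["strain"]
    agg = g.agg(
        mean="mean",
        sem=lambda v: v.std(ddof=1) / math.sqrt(len(v)) if len(v) >= 2 else 0.0,
        n="count",
    ).reset_index().sort_values("force_pn", ignore_index=True)
    stress = np.array([stress_from_force(fp, helix_area_nm2) for fp in agg["force_pn"]])
    return StressStrainCurve(
        system=records[0].system,
        stress_pa=stress,
        strain_percent=agg["mean"].to_numpy(),
        strain_stderr=agg["sem"].to_numpy(),
        l0_nm=l0_nm,
        helix_area_nm2=helix_area_nm2,
        n_replicates=agg["n"].to_numpy(),
    )


def fit_e_smd(curve: StressStrainCurve):
    """Young's modulus from the slope of the stress-strain diagram.

    Weighted least squares of stress on strain (strain in percent, so
    E_SMD = slope * 100); weights are inverse-variance from the per-force
    strain standard errors when available, otherwise uniform.  Returns the
    modulus in Pa with its standard error.
    """
    stress = np.asarray(curve.stress_pa, float)
    strain = np.asarray(curve.strain_percent, float)
    if len(stress) < 3:
        raise ValueError(f"at least 3 force levels are required, got {len(stress)}")
    order = np.argsort(stress)
    if np.any(np.diff(strain[order]) < 0):
        warnings.warn("strain is not monotone in force; fit returned anyway", stacklevel=2)
    se = np.asarray(curve.strain_stderr, float)
    w = np.ones_like(stress)
    if np.all(np.isfinite(se)) and np.any(se > 0):
        floor = np.min(se[se > 0])
        w = 1.0 / np.maximum(se, floor) ** 2
    # WLS with intercept: stress = b0 + b1 * strain
    X = np.column_stack([np.ones_like(strain), strain])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ stress)
    resid = stress - X @ beta
    dof = len(stress) - 2
    s2 = float(resid @ W @ resid) / dof if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(xtwx)
    slope, slope_se = float(beta[1]), math.sqrt(max(cov[1, 1], 0.0))
    return {
        "e_smd": slope * 100.0,                 # percent-strain convention
        "e_smd_stderr": slope_se * 100.0,
        "intercept_pa": float(beta[0]),
        "n_levels": len(stress),
        "l0_nm": curve.l0_nm,
        "helix_area_nm2": curve.helix_area_nm2,
        "system": curve.system,
    }


@dataclass
class HBondSeries:
    """Hydrogen-bond count versus simulation time for one system."""

    time_ns: np.ndarray
    count: np.ndarray
    system: str = ""

    def __post_init__(self):
        self.time_ns = np.asarray(self.time_ns, float)
        self.count = np.asarray(self.count)
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.count < 0) or not np.allclose(self.count, np.round(self.count)):
            raise ValueError("hydrogen-bond counts must be non-negative integers")


def hbond_loss(
    series: HBondSeries,
    window_initial: tuple[float, float],
    window_final: tuple[float, float],
) -> float:
    """Percent change in mean H-bond count between two time windows:
    100 (mean_final - mean_initial)/mean_initial.  Negative = loss."""
    def window_mean(lo, hi, name):
        if hi <= lo:
            raise ValueError(f"{name} window must have positive length")
        sel = (series.time_ns >= lo) & (series.time_ns <= hi)
        if not sel.any():
            raise ValueError(f"{name} window [{lo}, {hi}] ns contains no samples")
        return float(np.mean(series.count[sel]))

    m0 = window_mean(*window_initial, "initial")
    m1 = window_mean(*window_final, "final")
    return 100.0 * (m1 - m0) / m0


# ---------------------------------------------------------------------------
# Table I/O: delimited text with columns (system, replicate, force_pN, length_nm)

PULLING_COLUMNS = ["system", "replicate", "force_pN", "length_nm"]


def write_pulling_table(records: list[PullingRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"system": r.system, "replicate": r.replicate,
             "force_pN": r.force_pn, "length_nm": r.length_nm}
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_pulling_table(path: str | Path) -> list[PullingRecord]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in PULLING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pulling table {path} is missing column(s): {', '.join(missing)}")
    return [
        PullingRecord(
            system=str(row.system), replicate=int(row.replicate),
            force_pn=float(row.force_pN), length_nm=float(row.length_nm),
        )
        for row in df.itertuples()
    ]
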