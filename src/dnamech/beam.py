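"""Closed-form flexural resonance model for suspended DNA-bundle resonators.

A bundle suspended between two pillars is modelled as a doubly clamped
(clamped-clamped) elastic beam.  The module provides the Euler-Bernoulli
eigenvalue solver, the stressed/unstressed beam frequencies, the taut-string
limit, elliptical-cross-section mode splitting, and the mass-sensing figures
of merit (responsivity and limit of detection).

All computation is strictly SI; attogram / GPa conversions happen only at
presentation boundaries (see :mod:`dnamech.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .units import KG_TO_AG

__all__ = [
    "BundleGeometry",
    "MaterialState",
    "Mode",
    "SensitivityReport",
    "clamped_clamped_modal_factors",
    "beam_frequencies",
    "general_beam_frequencies",
    "string_frequencies",
    "high_tension_limit_check",
    "split_frequencies",
    "mass_of_bundle",
    "sensitivity",
    "limit_of_detection",
    "BEAM_RATIO_21",
    "BEAM_RATIO_32",
    "STRING_RATIO_21",
    "STRING_RATIO_32",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite_positive(name: str, value: float) -> None:
    _require(np.isfinite(value) and value > 0, f"{name} must be finite and > 0, got {value!r}")


@dataclass(frozen=True)
class BundleGeometry:
    """Geometry of one suspended bundle.

    Parameters
    ----------
    length:
        Suspended length L between the clamping pillars (m).
    diameter:
        Nominal diameter d of the circular idealization (m).
    d_max, d_min:
        Major/minor diameters of the elliptical cross section (m).  Default
        to ``diameter`` (circular section).
    """

    length: float
    diameter: float
    d_max: float = None  # type: ignore[assignment]
    d_min: float = None  # type: ignore[assignment]

    def __post_init__(self):
        _finite_positive("length", self.length)
        _finite_positive("diameter", self.diameter)
        if self.d_max is None:
            object.__setattr__(self, "d_max", self.diameter)
        if self.d_min is None:
            object.__setattr__(self, "d_min", self.diameter)
        _finite_positive("d_max", self.d_max)
        _finite_positive("d_min", self.d_min)
        _require(self.d_min <= self.d_max, f"d_min ({self.d_min}) must not exceed d_max ({self.d_max})")

    @property
    def radius(self) -> float:
        """Radius R = d/2 of the circular idealization (m)."""
        return self.diameter / 2.0

    @property
    def area(self) -> float:
        """Cross-section area A = pi R^2 (m^2)."""
        return math.pi * self.radius**2

    @property
    def second_moment(self) -> float:
        """Second moment of area I = pi R^4 / 4 of the circular section (m^4)."""
        return math.pi * self.radius**4 / 4.0

    @property
    def is_circular(self) -> bool:
        return self.d_max == self.d_min

    def to_dict(self) -> dict:
        return {
            "length_m": self.length,
            "diameter_m": self.diameter,
            "d_max_m": self.d_max,
            "d_min_m": self.d_min,
        }


@dataclass(frozen=True)
class MaterialState:
    """Effective elastic state of the bundle material for one condition.

    ``young_modulus`` is the *effective* Young's modulus of the composite
    bundle (Pa), not of a single duplex; ``density`` in kg m^-3;
    ``axial_stress`` is the tensile prestress sigma (Pa, >= 0).
    """

    young_modulus: float
    density: float
    axial_stress: float = 0.0

    def __post_init__(self):
        _finite_positive("young_modulus", self.young_modulus)
        _finite_positive("density", self.density)
        _require(
            np.isfinite(self.axial_stress) and self.axial_stress >= 0,
            f"axial_stress must be finite and >= 0, got {self.axial_stress!r}",
        )

    def to_dict(self) -> dict:
        return {
            "young_modulus_pa": self.young_modulus,
            "density_kg_m3": self.density,
            "axial_stress_pa": self.axial_stress,
        }


@dataclass(frozen=True)
class Mode:
    """One flexural mode: index, modal factor, frequency and vibration plane."""

    index: int
    modal_factor: float
    frequency: float
    plane: str = "single"  # single | fast | slow


@dataclass(frozen=True)
class SensitivityReport:
    """Mass-sensing figures of merit of one resonator."""

    mass: float                    # kg
    frequency: float               # Hz (fundamental)
    sensitivity: float             # Hz/kg, negative per the df/dm sign convention
    relative_frequency_stability: float | None = None
    limit_of_detection: float | None = None   # kg

    @property
    def sensitivity_hz_per_ag(self) -> float:
        """|S| in Hz per attogram (presentation units)."""
        return abs(self.sensitivity) / KG_TO_AG

    @property
    def mass_ag(self) -> float:
        return self.mass * KG_TO_AG

    @property
    def limit_of_detection_ag(self) -> float | None:
        if self.limit_of_detection is None:
            return None
        return self.limit_of_detection * KG_TO_AG


def _characteristic(lam: float) -> float:
    # cos(lam)*cosh(lam) = 1 rewritten as cos(lam) - sech(lam) = 0 to avoid
    # cosh overflow for high modes; same roots for lam > 0.
    return math.cos(lam) - 1.0 / math.cosh(lam)


def clamped_clamped_modal_factors(n_modes: int) -> np.ndarray:
    """First ``n_modes`` nonzero roots of the clamped-clamped characteristic
    equation cos(lam) cosh(lam) = 1.

    Root k lies in (k*pi, (k+1)*pi); each is bracketed and solved with
    Brent's method to ~1e-12 so consecutive factors are strictly increasing.
    """
    if not isinstance(n_modes, (int, np.integer)) or n_modes < 1:
        raise ValueError(f"n_modes must be a positive integer, got {n_modes!r}")
    roots = []
    for k in range(1, n_modes + 1):
        lo, hi = k * math.pi, (k + 1) * math.pi
        roots.append(brentq(_characteristic, lo, hi, xtol=1e-13, rtol=1e-15))
    return np.asarray(roots)


# Frozen analytic mode-ratio constants for the two limiting configurations.
_LAM = clamped_clamped_modal_factors(3)
BEAM_RATIO_21: float = float((_LAM[1] / _LAM[0]) ** 2)   # ~2.7565
BEAM_RATIO_32: float = float((_LAM[2] / _LAM[1]) ** 2)   # ~1.9604
STRING_RATIO_21: float = 2.0
STRING_RATIO_32: float = 1.5


def general_beam_frequencies(
    geometry: BundleGeometry, material: MaterialState, n_modes: int = 3
) -> list[Mode]:
    """Frequencies of a prestressed clamped-clamped beam from the general
    area/second-moment form

        f_n = lam_n^2/(2 pi L^2) sqrt(E I/(rho A)) sqrt(1 + sigma A L^2/(E I lam_n^2))

    using A = pi R^2 and I = pi R^4/4 of the circular section.
    """
    lam = clamped_clamped_modal_factors(n_modes)
    L = geometry.length
    E, rho, sigma = material.young_modulus, material.density, material.axial_stress
    A, I = geometry.area, geometry.second_moment
    base = lam**2 / (2.0 * math.pi * L**2) * math.sqrt(E * I / (rho * A))
    tension = np.sqrt(1.0 + sigma * A * L**2 / (E * I * lam**2))
    return [
        Mode(index=n + 1, modal_factor=float(lam[n]), frequency=float(base[n] * tension[n]))
        for n in range(n_modes)
    ]


def beam_frequencies(
    geometry: BundleGeometry, material: MaterialState, n_modes: int = 3
) -> list[Mode]:
    """Flexural frequencies of the circular clamped-clamped bundle,

        f_n = lam_n^2/(4 pi L^2) sqrt(E R^2/rho) sqrt(1 + 4 sigma L^2/(E R^2 lam_n^2)),

    reducing at sigma = 0 to the unstressed form f_n = lam_n^2/(4 pi) (R/L^2) sqrt(E/rho).
    """
    if not geometry.is_circular:
        raise ValueError(
            "beam_frequencies requires a circular section (d_max == d_min); "
            "use split_frequencies for elliptical bundles"
        )
    lam = clamped_clamped_modal_factors(n_modes)
    L, R = geometry.length, geometry.radius
    E, rho, sigma = material.young_modulus, material.density, material.axial_stress
    base = lam**2 / (4.0 * math.pi * L**2) * math.sqrt(E * R**2 / rho)
    tension = np.sqrt(1.0 + 4.0 * sigma * L**2 / (E * R**2 * lam**2))
    return [
        Mode(index=n + 1, modal_factor=float(lam[n]), frequency=float(base[n] * tension[n]))
        for n in range(n_modes)
    ]


def string_frequencies(
    geometry: BundleGeometry, material: MaterialState, n_modes: int = 3
) -> list[Mode]:
    """Taut-string frequencies f_n = n/(2L) sqrt(sigma/rho), integer modal factors.

    Valid when axial tension dominates flexural rigidity; consecutive-mode
    ratios are exactly 2/1, 3/2, ... regardless of the prefactor.
    """
    if material.axial_stress <= 0:
        raise ValueError("string model undefined without tension (axial_stress must be > 0)")
    L = geometry.length
    v = math.sqrt(material.axial_stress / material.density)
    return [
        Mode(index=n, modal_factor=float(n), frequency=n * v / (2.0 * L), plane="single")
        for n in range(1, n_modes + 1)
    ]


@dataclass(frozen=True)
class TensionLimitCheck:
    """Result of comparing the stressed-beam model against its tension-dominated limit."""

    applicable: bool
    tension_term: float | None = None          # sigma A L^2 / (E I lam_n^2), mode 1
    ratios: tuple[float, ...] = field(default_factory=tuple)  # beam f_n / (lam_n/(2 pi L) sqrt(sigma/rho))


def high_tension_limit_check(
    geometry: BundleGeometry, material: MaterialState, n_modes: int = 3
) -> TensionLimitCheck:
    """Check that the stressed-beam frequencies approach lam_n/(2 pi L) sqrt(sigma/rho)
    when the tension term sigma A L^2/(E I lam_n^2) is large.

    With sigma = 0 the limit is undefined and the check reports not-applicable.
    """
    if material.axial_stress == 0:
        return TensionLimitCheck(applicable=False)
    lam = clamped_clamped_modal_factors(n_modes)
    modes = beam_frequencies(geometry, material, n_modes)
    L = geometry.length
    v = math.sqrt(material.axial_stress / material.density)
    limit = lam / (2.0 * math.pi * L) * v
    ratios = tuple(m.frequency / lf for m, lf in zip(modes, limit))
    term = float(
        material.axial_stress * geometry.area * L**2
        / (material.young_modulus * geometry.second_moment * lam[0] ** 2)
    )
    return TensionLimitCheck(applicable=True, tension_term=term, ratios=ratios)


def _ellipse_section(d_max: float, d_min: float) -> tuple[float, float, float]:
    """Area and major/minor second moments of an elliptical section with
    diameters d_max, d_min: A = pi d_max d_min/4, I = pi a^3 b/4 in semi-axes
    (= pi d_max^3 d_min/64 and pi d_max d_min^3/64)."""
    A = math.pi * d_max * d_min / 4.0
    I_major = math.pi * d_max**3 * d_min / 64.0
    I_minor = math.pi * d_max * d_min**3 / 64.0
    return A, I_major, I_minor


def split_frequencies(
    geometry: BundleGeometry, material: MaterialState, n_modes: int = 1
) -> list[tuple[Mode, Mode]]:
    """Fast/slow flexural doublet of an elliptical, unstressed bundle.

    The two orthogonal planes see the two second moments of the ellipse, so

        f_{M,m} = lam_n^2/(2 pi L^2) sqrt(E I_{M,m} / (rho A)),

    giving the exact identity f_M/f_m = d_max/d_min.  Splitting is modelled on
    the unstressed beam; tension in the bundles is negligible for this purpose.
    Returns [(fast, slow), ...] per mode; degenerates to the circular value
    when d_max == d_min.
    """
    if material.axial_stress != 0:
        raise ValueError("split_frequencies models the unstressed beam; axial_stress must be 0")
    lam = clamped_clamped_modal_factors(n_modes)
    L = geometry.length
    E, rho = material.young_modulus, material.density
    A, I_M, I_m = _ellipse_section(geometry.d_max, geometry.d_min)
    pairs = []
    for n in range(n_modes):
        pref = lam[n] ** 2 / (2.0 * math.pi * L**2)
        f_fast = pref * math.sqrt(E * I_M / (rho * A))
        # sqrt(I_m/I_M) = d_min/d_max exactly; derive the slow mode from it so
        # the splitting identity holds to machine precision
        f_slow = f_fast * geometry.d_min / geometry.d_max
        pairs.append(
            (
                Mode(index=n + 1, modal_factor=float(lam[n]), frequency=f_fast, plane="fast"),
                Mode(index=n + 1, modal_factor=float(lam[n]), frequency=f_slow, plane="slow"),
            )
        )
    return pairs


def mass_of_bundle(geometry: BundleGeometry, material: MaterialState) -> float:
    """Resonator mass m = rho pi R^2 L (kg) of the circular idealization."""
    return material.density * geometry.area * geometry.length


def sensitivity(frequency: float, mass: float) -> float:
    """Mass responsivity S = df/dm = -f/(2m) (Hz per kg; negative by convention)."""
    _require(frequency >= 0, "frequency must be >= 0")
    _finite_positive("mass", mass)
    return -frequency / (2.0 * mass)


def limit_of_detection(mass: float, relative_frequency_stability: float) -> float:
    """Smallest detectable added mass given the fractional frequency stability df/f:

        dm_min = 2 m (df/f)    [kg]

    i.e. the mass change whose frequency shift |S| dm equals the resolvable
    shift f (df/f).
    """
    _finite_positive("mass", mass)
    _finite_positive("relative_frequency_stability", relative_frequency_stability)
    return 2.0 * mass * relative_frequency_stability


def sensitivity_report(
    geometry: BundleGeometry,
    material: MaterialState,
    relative_frequency_stability: float | None = None,
) -> SensitivityReport:
    """Convenience wrapper: fundamental frequency, mass, S and (optionally) LOD."""
    f1 = beam_frequencies(geometry, material, 1)[0].frequency
    m = mass_of_bundle(geometry, material)
    S = sensitivity(f1, m)
    lod = (
        limit_of_detection(m, relative_frequency_stability)
        if relative_frequency_stability is not None
        else None
    )
    return SensitivityReport(
        mass=m,
        frequency=f1,
        sensitivity=S,
        relative_frequency_stability=relative_frequency_stability,
        limit_of_detection=lod,
    )
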