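"""Synthetic-data generator for the whole pipeline.

Emulates the two data sources the analysis consumes, with the statistical
structure of the real experiment:

* **Vibrometry** — populations of suspended DNA-bundle resonators (lengths
  10-15 um, diameters 30-100 nm, ~7% diameter variability), with air spectra
  showing the first three flexural modes at Q ~ 5-8 and vacuum spectra
  showing the fundamental split into a fast/slow doublet at Q ~ 250.
  Condition presets carry the effective Young's modulus (5.3 / 8.1 / 12.6 /
  2.6 GPa for pristine / YOYO-1 / GelRed / CisPt), the density (1700 kg/m3
  pristine, 1500 kg/m3 intercalated) and the asymmetry multiplier vs the
  pristine Omega = 1.15%.  These are generator *inputs* for recovery
  testing, never claimed as outputs.

* **Steered MD** — constant-force pulling tables (8 forces x 3 replicates)
  from linear elasticity at preset moduli, and hydrogen-bond count series.

Every sampler takes an explicit seed or Generator; identical seeds give
byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .beam import BundleGeometry, MaterialState, beam_frequencies, split_frequencies
from .smd import DEFAULT_HELIX_AREA_NM2, DEFAULT_L0_NM, HBondSeries, PullingRecord, stress_from_force
from .spectra import Spectrum, synthesize_spectrum, write_spectrum

__all__ = [
    "ConditionPreset",
    "GeneratorConfig",
    "CONDITION_PRESETS",
    "SMD_PRESETS",
    "BASE_OMEGA",
    "sample_bundles",
    "sample_population",
    "air_spectrum_for",
    "vacuum_spectrum_for",
    "generate_experiment",
    "generate_pulling_tables",
    "generate_hbond_series",
]

# Pristine average cross-section asymmetry (d_max - d_min)/d_min.
BASE_OMEGA = 0.0115


@dataclass(frozen=True)
class ConditionPreset:
    """Ground-truth material state for one condition."""

    name: str
    young_modulus: float        # Pa (population mean)
    density: float              # kg m^-3
    omega: float                # (d_max - d_min)/d_min
    air_q: tuple = (5.0, 8.0, 8.0)   # per air mode
    vacuum_q: float = 250.0
    e_cv: float = 0.20          # population coefficient of variation of E

    def __post_init__(self):
        if min(self.young_modulus, self.density, self.vacuum_q) <= 0:
            raise ValueError("preset values must be positive")
        if self.omega < 0 or self.e_cv < 0:
            raise ValueError("omega and e_cv must be >= 0")


CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "pristine": ConditionPreset("pristine", 5.3e9, 1700.0, BASE_OMEGA * 1.00),
    "YOYO-1": ConditionPreset("YOYO-1", 8.1e9, 1500.0, BASE_OMEGA * 1.32),
    "GelRed": ConditionPreset("GelRed", 12.6e9, 1500.0, BASE_OMEGA * 1.82),
    "CisPt": ConditionPreset("CisPt", 2.6e9, 1500.0, BASE_OMEGA * 1.21),
}

# Steered-MD ground truths: modulus (Pa) and intercalant count per system.
SMD_PRESETS: dict[str, dict] = {
    "DNA": {"e_smd": 1.50e9, "intercalants": 0},
    "DNA/YOYO-1": {"e_smd": 2.61e9, "intercalants": 16},
    "DNA/CisPt": {"e_smd": 1.11e9, "intercalants": 7},
    "DNA/YOYO-1-sub": {"e_smd": 1.98e9, "intercalants": 8},
    "DNA/CisPt-sub": {"e_smd": 1.23e9, "intercalants": 3},
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the vibrometry generator.

    ``frequency_noise`` is the fractional measurement jitter applied to the
    synthesized mode frequencies (the per-bundle measurement uncertainty is
    not published; 1.5% is a calibration choice).  ``diameter_variability``
    is the fractional deviation of the resonating diameter from the nominal
    one recorded in the manifest.  ``omega_cv`` is the per-bundle spread of
    the asymmetry factor (0 = condition-average asymmetry for every bundle).
    """

    n_bundles: int = 25
    length_range: tuple = (10e-6, 15e-6)       # m
    diameter_range: tuple = (30e-9, 100e-9)    # m
    diameter_variability: float = 0.07
    frequency_noise: float = 0.015
    omega_cv: float = 0.0
    points_air: int = 2400
    points_vacuum: int = 1600
    snr_air: float = 20.0
    snr_vacuum: float = 20.0

    def __post_init__(self):
        if self.n_bundles < 1:
            raise ValueError("n_bundles must be >= 1")
        for name in ("length_range", "diameter_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be ordered and positive")


@dataclass(frozen=True)
class BundleTruth:
    """One sampled bundle with its ground truth and noiseless model frequencies."""

    bundle_id: str
    condition: str
    geometry_nominal: BundleGeometry       # what the manifest reports
    geometry_true: BundleGeometry          # what actually resonates (elliptical)
    material: MaterialState
    omega_true: float


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_bundles(
    config: GeneratorConfig, preset: ConditionPreset, seed
) -> list[BundleTruth]:
    """Sample a bundle population for one condition.

    L ~ U(10, 15) um and nominal d ~ U(30, 100) nm (the experiment reports
    only these ranges); per-bundle E ~ N(E0, cv*E0) truncated positive; the
    resonating diameter deviates from nominal by the diameter variability;
    the elliptical section has d_max/d_min = 1 + Omega.
    """
    rng = _rng(seed)
    out = []
    for i in range(config.n_bundles):
        L = rng.uniform(*config.length_range)
        d_nom = rng.uniform(*config.diameter_range)
        d_true = d_nom * (1.0 + rng.normal(0.0, config.diameter_variability))
        d_true = max(d_true, 0.2 * d_nom)
        e = rng.normal(preset.young_modulus, preset.e_cv * preset.young_modulus)
        while e <= 0.05 * preset.young_modulus:
            e = rng.normal(preset.young_modulus, preset.e_cv * preset.young_modulus)
        omega = preset.omega
        if config.omega_cv > 0:
            omega = max(preset.omega * (1.0 + rng.normal(0.0, config.omega_cv)), 0.0)
        geom_nom = BundleGeometry(length=L, diameter=d_nom)
        geom_true = BundleGeometry(
            length=L, diameter=d_true, d_max=d_true * (1.0 + omega), d_min=d_true
        )
        out.append(
            BundleTruth(
                bundle_id=f"{preset.name}-{i:03d}",
                condition=preset.name,
                geometry_nominal=geom_nom,
                geometry_true=geom_true,
                material=MaterialState(young_modulus=e, density=preset.density),
                omega_true=omega,
            )
        )
    return out


def sample_population(
    config: GeneratorConfig,
    presets: dict[str, ConditionPreset] | None = None,
    seed=0,
) -> pd.DataFrame:
    """Sample bundles for every condition and attach *measured* (jittered)
    mode frequencies, without rasterizing spectra.

    The air modes get independent fractional jitter per mode; the vacuum
    doublet gets a common-mode jitter (splitting is read within a single
    spectrum, so drift moves the pair together).

    Returns a tidy frame with one row per bundle: geometry, truth, and the
    measured f1..f3 (air) and fast/slow fundamental (vacuum).
    """
    presets = presets if presets is not None else CONDITION_PRESETS
    rng = _rng(seed)
    rows = []
    for name in presets:
        preset = presets[name]
        for b in sample_bundles(config, preset, rng):
            circ = BundleGeometry(length=b.geometry_true.length, diameter=b.geometry_true.diameter)
            modes = beam_frequencies(circ, b.material, 3)
            f_air = [
                m.frequency * (1.0 + rng.normal(0.0, config.frequency_noise)) for m in modes
            ]
            (fast, slow), = split_frequencies(b.geometry_true, b.material, 1)
            common = 1.0 + rng.normal(0.0, config.frequency_noise)
            rows.append(
                {
                    "bundle_id": b.bundle_id,
                    "condition": b.condition,
                    "length_m": b.geometry_nominal.length,
                    "diameter_m": b.geometry_nominal.diameter,
                    "diameter_true_m": b.geometry_true.diameter,
                    "e_true_pa": b.material.young_modulus,
                    "density_kg_m3": b.material.density,
                    "omega_true": b.omega_true,
                    "f1_air_hz": f_air[0],
                    "f2_air_hz": f_air[1],
                    "f3_air_hz": f_air[2],
                    "f_fast_vacuum_hz": fast.frequency * common,
                    "f_slow_vacuum_hz": slow.frequency * common,
                }
            )
    return pd.DataFrame(rows)


def air_spectrum_for(
    row, config: GeneratorConfig, preset: ConditionPreset, rng
) -> Spectrum:
    """Rasterize the air spectrum of one sampled bundle: three flexural
    modes at the preset air quality factors, with decreasing drive and
    additive white noise at the configured SNR."""
    f = [row["f1_air_hz"], row["f2_air_hz"], row["f3_air_hz"]]
    heights = (1.0, 0.6, 0.35)
    modes = [
        (fi, qi, h / qi) for fi, qi, h in zip(f, preset.air_q, heights)
    ]
    grid = np.linspace(0.5 * f[0], 1.25 * f[2], config.points_air)
    return synthesize_spectrum(
        modes, grid, noise_sd=max(heights) / config.snr_air, rng=rng,
        environment="air", bundle_id=row["bundle_id"],
    )


def vacuum_spectrum_for(
    row, config: GeneratorConfig, preset: ConditionPreset, rng
) -> Spectrum:
    """Rasterize the vacuum spectrum: the fundamental doublet at the vacuum
    quality factor, on a narrow grid around the pair."""
    f_fast, f_slow = row["f_fast_vacuum_hz"], row["f_slow_vacuum_hz"]
    center = 0.5 * (f_fast + f_slow)
    q = preset.vacuum_q
    modes = [(f_slow, q, 1.0 / q), (f_fast, q, 0.9 / q)]
    grid = np.linspace(0.96 * center, 1.04 * center, config.points_vacuum)
    return synthesize_spectrum(
        modes, grid, noise_sd=1.0 / config.snr_vacuum, rng=rng,
        environment="vacuum", bundle_id=row["bundle_id"],
    )


MANIFEST_NAME = "manifest.tsv"
TRUTH_NAME = "truth.tsv"


def generate_experiment(
    config: GeneratorConfig,
    out_dir: str | Path,
    presets: dict[str, ConditionPreset] | None = None,
    seed: int = 0,
    doses: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Generate a full synthetic experiment on disk.

    For every bundle of every condition, writes an air spectrum (three
    modes) and a vacuum spectrum (doublet fundamental), plus a manifest
    linking files to geometry/condition and a ground-truth table.  Returns
    the manifest frame.
    """
    presets = presets if presets is not None else CONDITION_PRESETS
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pop = sample_population(config, presets, seed)
    rng = _rng(np.random.default_rng(seed).integers(2**31))  # raster noise stream
    manifest_rows = []
    for _, row in pop.iterrows():
        preset = presets[row["condition"]]
        for env, maker in (("air", air_spectrum_for), ("vacuum", vacuum_spectrum_for)):
            spec = maker(row, config, preset, rng)
            spec.metadata.update({"temperature_c": 25, "rh_percent": 60, "seed": seed})
            fname = f"{row['bundle_id']}_{env}.tsv"
            write_spectrum(spec, out_dir / fname)
            manifest_rows.append(
                {
                    "bundle_id": row["bundle_id"],
                    "condition": row["condition"],
                    "dose": (doses or {}).get(row["condition"], ""),
                    "length_m": row["length_m"],
                    "diameter_m": row["diameter_m"],
                    "environment": env,
                    "spectrum_file": fname,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out_dir / MANIFEST_NAME, sep="\t", index=False)
    truth_cols = [
        "bundle_id", "condition", "length_m", "diameter_m", "diameter_true_m",
        "e_true_pa", "density_kg_m3", "omega_true",
        "f1_air_hz", "f2_air_hz", "f3_air_hz", "f_fast_vacuum_hz", "f_slow_vacuum_hz",
    ]
    pop[truth_cols].to_csv(out_dir / TRUTH_NAME, sep="\t", index=False)
    return manifest


def generate_pulling_tables(
    presets: dict[str, dict] | None = None,
    forces_pn: np.ndarray | None = None,
    replicates: int = 3,
    strain_noise: float = 0.02,
    l0_nm: float = DEFAULT_L0_NM,
    helix_area_nm2: float = DEFAULT_HELIX_AREA_NM2,
    seed: int = 0,
) -> dict[str, list[PullingRecord]]:
    """Constant-force pulling tables from linear elasticity.

    For each system the equilibrium length at force F follows
    strain% = 100 * stress/E with stress = F/area, perturbed by fractional
    Gaussian noise per replicate.  Defaults: 8 uniformly spaced forces
    (50-400 pN) x 3 replicates, 2% relative strain noise.
    """
    presets = presets if presets is not None else SMD_PRESETS
    if forces_pn is None:
        forces_pn = np.linspace(50.0, 400.0, 8)
    forces_pn = np.asarray(forces_pn, float)
    if len(forces_pn) < 3:
        raise ValueError("at least 3 force levels are required")
    rng = _rng(seed)
    out: dict[str, list[PullingRecord]] = {}
    for system in presets:
        e = presets[system]["e_smd"]
        records = []
        for force in forces_pn:
            stress = stress_from_force(force, helix_area_nm2)
            strain_true = 100.0 * stress / e
            for rep in range(1, replicates + 1):
                strain = strain_true
                if force > 0 and strain_noise > 0:
                    strain = strain_true * (1.0 + rng.normal(0.0, strain_noise))
                records.append(
                    PullingRecord(
                        system=system,
                        replicate=rep,
                        force_pn=float(force),
                        length_nm=l0_nm * (1.0 + strain / 100.0),
                        intercalant_count=presets[system].get("intercalants"),
                    )
                )
        out[system] = records
    return out


_HBOND_PROFILES = {
    # (initial count, fractional loss over the run): 66-bp duplex baseline.
    # Losses chosen so that means over the first/last 2 ns windows show
    # ~30% loss (pristine), near-stability (YOYO-1) and >40% loss (CisPt).
    "DNA": (160, 0.33),
    "DNA/YOYO-1": (160, 0.02),
    "DNA/CisPt": (140, 0.50),
}


def generate_hbond_series(
    system: str, duration_ns: float = 20.0, n_points: int = 201, seed: int = 0
) -> HBondSeries:
    """Hydrogen-bond count trajectory under maximum load.

    Pristine DNA decays ~30% over the run, DNA/YOYO-1 stays nearly stable,
    and DNA/CisPt starts lower (its adducts already break pairing) and loses
    >40%.  Counts follow a linear trend with small integer jitter.
    """
    if system not in _HBOND_PROFILES:
        raise ValueError(f"unknown system {system!r}; choose from {sorted(_HBOND_PROFILES)}")
    n0, loss = _HBOND_PROFILES[system]
    rng = _rng(seed)
    t = np.linspace(0.0, duration_ns, n_points)
    trend = n0 * (1.0 - loss * t / duration_ns)
    counts = np.round(trend + rng.normal(0.0, 2.0, size=t.shape)).clip(min=0).astype(int)
    return HBondSeries(time_ns=t, count=counts, system=system)
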