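"""Vibrometer-style amplitude spectra: synthesis and fitting.

The lineshape is the driven damped harmonic oscillator amplitude

    A(f) = a f0^2 / sqrt((f0^2 - f^2)^2 + (f0 f / Q)^2),

the standard model for a piezo-driven flexural resonator read out with a
laser Doppler vibrometer.  Its half-power (3 dB, amplitude factor 1/sqrt(2))
bandwidth equals f0/Q in the high-Q limit, so the "resonance frequency over
3 dB bandwidth" quality-factor definition is recovered exactly.

Absolute amplitudes are arbitrary in practice (the transduction gain is
unknown); all downstream inference uses only f0 and Q.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import math

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "Spectrum",
    "ResonancePeak",
    "sho_response",
    "synthesize_spectrum",
    "detect_peaks",
    "fit_resonance",
    "q_from_3db",
    "resolve_doublet",
    "write_spectrum",
    "read_spectrum",
    "FitNotConvergedError",
]

# A two-peak fit must beat the single-peak fit by this much AIC to declare a
# resolved doublet; ties resolve conservatively to a single peak.
DOUBLET_AIC_MARGIN = 10.0


class FitNotConvergedError(RuntimeError):
    """Raised when a resonance fit fails to converge or to improve on a flat model."""


@dataclass
class Spectrum:
    """A frequency-amplitude trace for one bundle in one environment."""

    frequency: np.ndarray       # Hz, strictly increasing
    amplitude: np.ndarray       # m (arbitrary gain), >= 0 before noise
    environment: str = "air"    # air | vacuum
    bundle_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequency = np.asarray(self.frequency, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.frequency.ndim != 1 or self.frequency.size < 2:
            raise ValueError("frequency grid must be 1-D with at least 2 points")
        if np.any(np.diff(self.frequency) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.amplitude.shape != self.frequency.shape:
            raise ValueError("amplitude and frequency must have the same shape")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitudes must be finite")
        if self.environment not in ("air", "vacuum"):
            raise ValueError(f"environment must be 'air' or 'vacuum', got {self.environment!r}")

    def window(self, f_lo: float, f_hi: float) -> "Spectrum":
        """Sub-spectrum restricted to [f_lo, f_hi]."""
        sel = (self.frequency >= f_lo) & (self.frequency <= f_hi)
        if sel.sum() < 8:
            raise ValueError(f"window [{f_lo}, {f_hi}] Hz contains fewer than 8 samples")
        return Spectrum(
            self.frequency[sel], self.amplitude[sel], self.environment, self.bundle_id,
            dict(self.metadata),
        )


@dataclass(frozen=True)
class ResonancePeak:
    """A fitted resonance: center, quality factor, amplitude, and standard errors."""

    f0: float
    q: float
    amplitude: float            # drive amplitude a (peak height ~ a*Q)
    background: float = 0.0
    f0_stderr: float = np.nan
    q_stderr: float = np.nan
    amplitude_stderr: float = np.nan
    mode_index: int | None = None
    plane: str = "single"

    def __post_init__(self):
        if self.f0 <= 0 or self.q <= 0:
            raise ValueError(f"f0 and q must be > 0 (got f0={self.f0}, q={self.q})")

    @property
    def bandwidth(self) -> float:
        """Approximate 3 dB bandwidth f0/Q (Hz)."""
        return self.f0 / self.q


def sho_response(
    f: np.ndarray | float, f0: float, q: float, drive_amplitude: float = 1.0
) -> np.ndarray | float:
    """Driven damped harmonic oscillator amplitude response.

    At f = f0 the value is drive_amplitude * Q; the half-power bandwidth is
    ~ f0/Q for Q >> 1.
    """
    if f0 <= 0 or q <= 0:
        raise ValueError("f0 and q must be > 0")
    f = np.asarray(f, dtype=float)
    denom = np.sqrt((f0**2 - f**2) ** 2 + (f0 * f / q) ** 2)
    return drive_amplitude * f0**2 / denom


def _sho_bg(f, f0, q, amp, bg):
    return sho_response(f, f0, q, amp) + bg


def _sho2_bg(f, f0a, qa, ampa, f0b, qb, ampb, bg):
    return sho_response(f, f0a, qa, ampa) + sho_response(f, f0b, qb, ampb) + bg


def synthesize_spectrum(
    modes,
    f_grid: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    environment: str = "air",
    bundle_id: str = "",
    drive_amplitudes=None,
) -> Spectrum:
    """Sum of damped-oscillator responses plus additive white Gaussian noise.

    Parameters
    ----------
    modes:
        Sequence of (f0_hz, Q) pairs or (f0_hz, Q, drive_amplitude) triples.
        Vacuum doublets are expressed simply as two closely spaced entries.
    noise_sd:
        Standard deviation of the additive amplitude noise (same arbitrary
        units as the response). Must be >= 0.
    rng:
        Seed or Generator; required (explicitly) whenever noise_sd > 0 so
        spectra are reproducible.
    """
    if len(modes) == 0:
        raise ValueError("modes must be non-empty")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    f_grid = np.asarray(f_grid, dtype=float)
    amp = np.zeros_like(f_grid)
    for i, mode in enumerate(modes):
        if len(mode) == 3:
            f0, q, a = mode
        else:
            f0, q = mode
            a = drive_amplitudes[i] if drive_amplitudes is not None else 1.0
        amp += sho_response(f_grid, f0, q, a)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("an explicit rng/seed is required when noise_sd > 0")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        amp = amp + rng.normal(0.0, noise_sd, size=f_grid.shape)
    return Spectrum(f_grid, amp, environment=environment, bundle_id=bundle_id)


def detect_peaks(spectrum: Spectrum, min_prominence: float | None = None) -> np.ndarray:
    """Candidate resonance frequencies: local maxima above a prominence floor.

    The trace is lightly smoothed (Savitzky-Golay) before detection so that
    single-sample noise excursions do not register.  ``min_prominence``
    defaults to the larger of 10x the post-smoothing noise scale and 5% of
    the smoothed dynamic range.  Returns a (possibly empty) array of
    frequencies ordered by frequency; deterministic for fixed input.
    """
    y = spectrum.amplitude
    n = len(y)
    window = max(min(15, (n // 20) * 2 + 1), 5)
    ys = savgol_filter(y, window_length=window, polyorder=2) if n > window else y
    if min_prominence is None:
        resid = y - ys
        sigma_raw = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        sigma_smooth = sigma_raw * math.sqrt(1.2 / window)
        span = float(ys.max() - ys.min())
        scale = float(np.max(np.abs(ys))) or 1.0
        if not np.isfinite(span) or span <= 1e-9 * scale:
            return np.array([])
        min_prominence = max(10.0 * sigma_smooth, 0.05 * span, 1e-12 * span)
    idx, _ = find_peaks(ys, prominence=min_prominence)
    return spectrum.frequency[idx]


def _initial_q(spectrum: Spectrum, f_c: float) -> float:
    """Crude Q guess from the half-height width around the candidate,
    measured on a lightly smoothed trace so noise cannot collapse the width."""
    f, y = spectrum.frequency, spectrum.amplitude
    n = len(y)
    window = max(min(15, (n // 20) * 2 + 1), 5)
    ys = savgol_filter(y, window_length=window, polyorder=2) if n > window else y
    i = int(np.argmin(np.abs(f - f_c)))
    base = np.percentile(ys, 10)
    half = base + (ys[i] - base) / 2.0
    lo = i
    while lo > 0 and ys[lo] > half:
        lo -= 1
    hi = i
    while hi < n - 1 and ys[hi] > half:
        hi += 1
    step = float(np.median(np.diff(f)))
    width = max(f[hi] - f[lo], 3.0 * step)
    return float(np.clip(f_c / width, 1.0, f_c / (3.0 * step)))


def fit_resonance(
    spectrum: Spectrum,
    candidate: float | None = None,
    window_bandwidths: float = 5.0,
) -> ResonancePeak:
    """Nonlinear least-squares fit of one damped-oscillator peak plus a
    constant background.

    The fit window spans ``window_bandwidths`` estimated bandwidths either
    side of the candidate (the spectrum maximum when no candidate is given).
    Raises :class:`FitNotConvergedError` when the fit does not converge or
    does not improve on a constant model.
    """
    if candidate is None:
        candidate = float(spectrum.frequency[np.argmax(spectrum.amplitude)])
    q0 = _initial_q(spectrum, candidate)
    bw = candidate / q0
    try:
        win = spectrum.window(candidate - window_bandwidths * bw, candidate + window_bandwidths * bw)
    except ValueError:
        win = spectrum
    f, y = win.frequency, win.amplitude
    bg0 = float(np.percentile(y, 10))
    peak_height = float(np.max(y) - bg0)
    if peak_height <= 0:
        raise FitNotConvergedError("window contains no peak above background")
    # a credible peak must be at least a few grid steps wide
    step = float(np.median(np.diff(f)))
    q_max = max(candidate / (3.0 * step), 2.0 * q0)
    model = Model(_sho_bg)
    params = model.make_params(
        f0=dict(value=candidate, min=f[0], max=f[-1]),
        q=dict(value=min(q0, q_max), min=0.5, max=q_max),
        amp=dict(value=peak_height / q0, min=0),
        bg=dict(value=bg0),
    )
    result = model.fit(y, params, f=f)
    sse_const = float(np.sum((y - y.mean()) ** 2))
    if not result.success or not np.isfinite(result.chisqr):
        raise FitNotConvergedError(f"resonance fit failed: {result.message}")
    if result.chisqr >= sse_const:
        raise FitNotConvergedError(
            "resonance fit no better than a constant model (no peak in window?)"
        )
    p = result.params
    return ResonancePeak(
        f0=p["f0"].value,
        q=p["q"].value,
        amplitude=p["amp"].value,
        background=p["bg"].value,
        f0_stderr=p["f0"].stderr if p["f0"].stderr is not None else np.nan,
        q_stderr=p["q"].stderr if p["q"].stderr is not None else np.nan,
        amplitude_stderr=p["amp"].stderr if p["amp"].stderr is not None else np.nan,
    )


def q_from_3db(spectrum: Spectrum, peak: ResonancePeak | float) -> float:
    """Quality factor from the 3 dB bandwidth: Q = f0 / (f_hi - f_lo), with
    f_lo, f_hi the linearly interpolated crossings of amplitude = peak/sqrt(2).

    The amplitude (not power) convention is used: 3 dB down means a factor
    1/sqrt(2) on amplitude.  Raises when a crossing lies outside the trace,
    naming the missing side.
    """
    f0 = peak.f0 if isinstance(peak, ResonancePeak) else float(peak)
    f, y = spectrum.frequency, spectrum.amplitude
    i0 = int(np.argmin(np.abs(f - f0)))
    # refine to the local maximum
    lo_lim = max(i0 - len(f) // 4, 0)
    hi_lim = min(i0 + len(f) // 4 + 1, len(f))
    i0 = lo_lim + int(np.argmax(y[lo_lim:hi_lim]))
    peak_amp = y[i0]
    target = peak_amp / np.sqrt(2.0)

    def cross(idx_range, side: str) -> float:
        for i in idx_range:
            if y[i] < target:
                j = i + 1 if side == "lower" else i - 1
                # linear interpolation between i and its inner neighbour j
                return f[i] + (target - y[i]) * (f[j] - f[i]) / (y[j] - y[i])
        raise ValueError(f"{side} half-power crossing lies outside the spectrum")

    f_lo = cross(range(i0, -1, -1), "lower")
    f_hi = cross(range(i0, len(f)), "upper")
    return f[i0] / (f_hi - f_lo)


def resolve_doublet(
    spectrum: Spectrum, window: tuple[float, float] | None = None
) -> tuple[ResonancePeak, ResonancePeak | None, bool]:
    """Joint two-peak fit of a (possibly) split mode.

    Returns ``(fast, slow, resolved)``.  When the two-peak model does not
    beat the single-peak model by at least ``DOUBLET_AIC_MARGIN`` of AIC the
    doublet is declared unresolved and ``(peak, None, False)`` is returned.
    Fast = higher frequency, slow = lower.
    """
    win = spectrum if window is None else spectrum.window(*window)
    single = fit_resonance(win)
    f, y = win.frequency, win.amplitude
    # initialise the pair from the two highest detected maxima, else split the single fit
    cands = detect_peaks(win)
    if len(cands) >= 2:
        heights = [y[np.argmin(np.abs(f - c))] for c in cands]
        top = np.argsort(heights)[-2:]
        fa, fb = sorted(cands[top])
    else:
        half_bw = single.f0 / single.q / 2.0
        fa, fb = single.f0 - half_bw, single.f0 + half_bw
    step = float(np.median(np.diff(f)))
    q_max = max(fa / (3.0 * step), 2.0 * single.q)
    model = Model(_sho2_bg)
    params = model.make_params(
        f0a=dict(value=fa, min=f[0], max=f[-1]),
        qa=dict(value=min(single.q, q_max), min=0.5, max=q_max),
        ampa=dict(value=single.amplitude / 2.0, min=0),
        f0b=dict(value=fb, min=f[0], max=f[-1]),
        qb=dict(value=min(single.q, q_max), min=0.5, max=q_max),
        ampb=dict(value=single.amplitude / 2.0, min=0),
        bg=dict(value=single.background),
    )
    double = model.fit(y, params, f=f)
    # AIC of the single-peak fit on the same window
    n = len(y)
    resid_single = y - _sho_bg(f, single.f0, single.q, single.amplitude, single.background)
    aic_single = n * np.log(np.sum(resid_single**2) / n) + 2 * 4
    resolved = (
        double.success
        and np.isfinite(double.aic)
        and (aic_single - double.aic) >= DOUBLET_AIC_MARGIN
        and abs(double.params["f0a"].value - double.params["f0b"].value)
        > abs(f[1] - f[0])  # distinct beyond one grid step
    )
    if not resolved:
        return (single, None, False)

    def mk(tag: str, plane: str) -> ResonancePeak:
        p = double.params
        return ResonancePeak(
            f0=p[f"f0{tag}"].value,
            q=p[f"q{tag}"].value,
            amplitude=p[f"amp{tag}"].value,
            background=p["bg"].value,
            f0_stderr=p[f"f0{tag}"].stderr if p[f"f0{tag}"].stderr is not None else np.nan,
            q_stderr=p[f"q{tag}"].stderr if p[f"q{tag}"].stderr is not None else np.nan,
            plane=plane,
        )

    a, b = mk("a", "fast"), mk("b", "fast")
    fast, slow = (a, b) if a.f0 >= b.f0 else (b, a)
    fast = ResonancePeak(**{**fast.__dict__, "plane": "fast"})
    slow = ResonancePeak(**{**slow.__dict__, "plane": "slow"})
    return (fast, slow, True)


# ---------------------------------------------------------------------------
# File I/O: two-column delimited text with '#'-prefixed metadata header.

def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"# bundle_id: {spectrum.bundle_id}",
        f"# environment: {spectrum.environment}",
    ]
    for k, v in spectrum.metadata.items():
        lines.append(f"# {k}: {v}")
    lines.append("frequency_hz\tamplitude_m")
    body = "\n".join(
        f"{fq:.10g}\t{am:.10g}" for fq, am in zip(spectrum.frequency, spectrum.amplitude)
    )
    path.write_text("\n".join(lines) + "\n" + body + "\n")
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a spectrum file; tolerates tab or comma delimiters."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        text_lines = fh.readlines()
    for line in text_lines:
        if line.startswith("#") and ":" in line:
            k, v = line[1:].split(":", 1)
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, comment="#", sep=None, engine="python")
    bundle_id = meta.pop("bundle_id", "")
    environment = meta.pop("environment", "air")
    return Spectrum(
        df.iloc[:, 0].to_numpy(),
        df.iloc[:, 1].to_numpy(),
        environment=environment,
        bundle_id=bundle_id,
        metadata=meta,
    )
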