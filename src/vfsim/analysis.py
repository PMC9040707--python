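"""Post-processing of coupled runs.

Fundamental frequency by FFT of the marker vibration trace, fluid-to-tissue
power transfer and accumulated work, total pressure along the duct, and
station-wise comparison of two intraglottal pressure profiles on a common
arc-length coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import VfsimError


@dataclass
class SpectrumResult:
    """One-sided magnitude spectrum and its dominant non-DC peak."""

    frequencies: np.ndarray   # Hz
    amplitudes: np.ndarray    # signal units
    fundamental: float        # Hz, frequency of the largest non-DC peak
    resolution: float         # Hz, 1 / window length


def fundamental_frequency(signal: np.ndarray, dt: float,
                          interpolate: bool = False) -> SpectrumResult:
    """Dominant oscillation frequency of a time series.

    The mean is removed, the full series is transformed without padding or
    windowing, and the fundamental is the frequency of the maximum-magnitude
    bin (ties broken toward the lowest frequency).  ``interpolate=True``
    refines the peak by quadratic interpolation of the neighbouring bin
    magnitudes, for resolution finer than 1/T.

    Raises for a constant (non-oscillating) signal.
    """
    y = np.asarray(signal, dtype=float)
    if y.size < 8:
        raise VfsimError("need at least 8 samples for a spectrum")
    if dt <= 0:
        raise VfsimError("dt must be positive")
    scale = np.max(np.abs(np.asarray(signal, dtype=float)))
    y = y - y.mean()
    if np.max(np.abs(y)) <= 1e-12 * max(scale, 1e-300):
        raise VfsimError("no oscillation detected (constant signal)")
    amp = np.abs(np.fft.rfft(y)) / y.size
    freqs = np.fft.rfftfreq(y.size, dt)
    k = 1 + int(np.argmax(amp[1:]))          # argmax takes the first maximum
    fund = freqs[k]
    if interpolate and 1 <= k < len(amp) - 1:
        # refine by maximizing the continuous-frequency DTFT magnitude
        from scipy.optimize import minimize_scalar
        t = np.arange(y.size) * dt
        res = minimize_scalar(
            lambda f: -np.abs(np.sum(y * np.exp(-2j * np.pi * f * t))),
            bounds=(freqs[k - 1], freqs[k + 1]), method="bounded",
            options={"xatol": 1e-3 * freqs[1]})
        fund = float(res.x)
    return SpectrumResult(frequencies=freqs, amplitudes=amp,
                          fundamental=float(fund),
                          resolution=float(freqs[1] - freqs[0]))


@dataclass
class PowerSeries:
    """Work-rate series and its running time integral."""

    time: np.ndarray
    work_rate: np.ndarray    # W
    accumulated: np.ndarray  # J, trapezoidal integral, E(0) = 0


def accumulate_work(time: np.ndarray, work_rate: np.ndarray) -> PowerSeries:
    time = np.asarray(time, dtype=float)
    work_rate = np.asarray(work_rate, dtype=float)
    acc = np.zeros_like(work_rate)
    acc[1:] = np.cumsum(0.5 * (work_rate[1:] + work_rate[:-1])
                        * np.diff(time))
    return PowerSeries(time=time, work_rate=work_rate, accumulated=acc)


def work_rate(tractions: np.ndarray, velocities: np.ndarray,
              areas: np.ndarray):
    """Fluid-to-tissue power E-dot = sum (f . v) dS over the wetted surface.

    ``tractions`` are facet traction vectors (Pa), ``velocities`` the facet
    surface velocities, ``areas`` the facet areas.  Returns the total power
    (W) and the per-facet power density f . v (W/m^2), the quantity
    contoured over the fold surface.
    """
    f = np.asarray(tractions, dtype=float)
    v = np.asarray(velocities, dtype=float)
    a = np.asarray(areas, dtype=float)
    if f.shape != v.shape or f.shape[0] != a.shape[0]:
        raise VfsimError("traction/velocity/area arrays do not conform")
    density = np.einsum("fi,fi->f", f, v)
    return float(np.sum(density * a)), density


def total_pressure(p, V, rho: float = 1.0):
    """Total (stagnation) pressure p + rho V^2 / 2."""
    if rho <= 0:
        raise VfsimError("density must be positive")
    return np.asarray(p, dtype=float) + 0.5 * rho * np.asarray(V, float) ** 2


@dataclass
class ProfileComparison:
    x: np.ndarray
    diff: np.ndarray          # a - b on the common grid (Pa)
    max_abs: float
    rms: float
    max_abs_normalized: float  # by P_in
    rms_normalized: float
    x_at_max: float
    segment_at_max: str


def pressure_profile_comparison(x_a, p_a, x_b, p_b, P_in: float = 1.0,
                                classify=None, n: int = 200
                                ) -> ProfileComparison:
    """Resample two pressure profiles to a common arc-length grid and report
    max/RMS discrepancies, optionally labelling the segment of the maximum.

    ``classify`` maps an arc-length coordinate to a segment name (e.g.
    ``LumenProfile.classify``); profiles must overlap in x.
    """
    x_a, p_a = np.asarray(x_a, float), np.asarray(p_a, float)
    x_b, p_b = np.asarray(x_b, float), np.asarray(p_b, float)
    for x in (x_a, x_b):
        if np.any(np.diff(x) <= 0):
            raise VfsimError("profile stations must be strictly increasing")
    lo, hi = max(x_a[0], x_b[0]), min(x_a[-1], x_b[-1])
    if lo >= hi:
        raise VfsimError("profiles do not overlap in arc length")
    x = np.linspace(lo, hi, n)
    diff = np.interp(x, x_a, p_a) - np.interp(x, x_b, p_b)
    i_max = int(np.argmax(np.abs(diff)))
    max_abs = float(np.abs(diff[i_max]))
    rms = float(np.sqrt(np.mean(diff ** 2)))
    seg = classify(float(x[i_max])) if classify else "unclassified"
    return ProfileComparison(
        x=x, diff=diff, max_abs=max_abs, rms=rms,
        max_abs_normalized=max_abs / abs(P_in),
        rms_normalized=rms / abs(P_in),
        x_at_max=float(x[i_max]), segment_at_max=seg)


def marker_trace(states, geometry, node: int | None = None) -> np.ndarray:
    """Lateral (z) displacement trace of the vibration marker node.

    The marker is the medial-surface node of one fold nearest the mid
    anterior-posterior, mid glottal-gap location (chosen at mesh generation
    and recorded on the geometry for reproducibility).  ``states`` is a
    sequence of :class:`SolidState` or of displacement arrays.
    """
    if node is None:
        node = geometry.marker_node
    if not len(geometry.medial_grids) or geometry.medial_grids[0].size == 0:
        raise VfsimError("geometry has no medial (lumen) surface")
    out = np.empty(len(states))
    for i, s in enumerate(states):
        u = getattr(s, "displacement", s)
        out[i] = u[node, 2]
    return out


def spectrum_energy_identity(signal: np.ndarray) -> tuple:
    """(time-domain energy, spectral energy) of a mean-removed signal.

    Equal by Parseval's theorem; exposed for consistency checking.
    """
    y = np.asarray(signal, float)
    y = y - y.mean()
    spec = np.fft.rfft(y)
    n = y.size
    w = np.full(spec.size, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    return float(np.sum(y ** 2)), float(np.sum(w * np.abs(spec) ** 2) / n)
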