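"""Synthetic experiment-like data: noisy build-up curves, scan maps, spectra.

The real measurements behind this analysis are SQUID-detected ultralow-field
NMR signals; none are distributed with the package.  These generators emulate
their statistical structure -- mono-exponential build-up with additive
Gaussian noise, scan maps with i.i.d. per-point noise, and Lorentzian spectra
at a stated signal-to-noise ratio -- so that every analysis stage can be
exercised end-to-end.  All generators are pure functions of their parameters
and the seed.

Default emulation parameters follow the experimental conditions: plateau
polarization 1.1% (averaged over free and bound pyruvate), build-up time
constants 25.8 s (LIGHT-SABRE) and 15.8 s (SABRE-SHEATH), 12 time points over
[0, 80] s, carbon linewidths below 0.3 Hz at single-shot SNR above 8000.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .dynamics import BuildUpCurve
from .observables import SpectrumRecord, measure_fwhm
from .protocols import ScanResult

__all__ = [
    "NoiseSpec",
    "default_buildup_times",
    "gen_buildup",
    "gen_scan_map",
    "gen_spectrum",
    "DEFAULTS",
]

#: Experiment-emulation defaults (averaged-basis plateau, seconds, Hz).
DEFAULTS = {
    "p_max": 0.011,
    "t_hyp_light_sabre_s": 25.8,
    "t_hyp_sheath_s": 15.8,
    "n_time_points": 12,
    "t_max_s": 80.0,
    "buildup_noise_sigma": 0.0005,
    "fwhm_hz": 0.3,
    "snr": 8000.0,
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise with a reproducible seed."""

    sigma: float
    seed: int
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.kind != "gaussian":
            raise ValueError(f"unsupported noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_buildup_times() -> np.ndarray:
    """The default sampling grid: 12 points over [0, 80] s."""
    return np.linspace(0.0, DEFAULTS["t_max_s"], DEFAULTS["n_time_points"])


def gen_buildup(
    p_max: float,
    t_hyp: float,
    times: Sequence[float] | None = None,
    noise: NoiseSpec | None = None,
) -> BuildUpCurve:
    """Noisy mono-exponential build-up curve p(t) = p_max(1 - exp(-t/T))."""
    if not (t_hyp > 0):
        raise ValueError("t_hyp must be positive")
    t = np.asarray(
        default_buildup_times() if times is None else times, dtype=float
    )
    mean = p_max * (1.0 - np.exp(-t / t_hyp))
    if noise is not None and noise.sigma > 0:
        mean = mean + noise.rng().normal(0.0, noise.sigma, size=t.shape)
    return BuildUpCurve(t, mean, kind="synthetic")


def gen_scan_map(base: ScanResult, noise: NoiseSpec) -> ScanResult:
    """Add i.i.d. Gaussian noise to every grid point of a scan result.

    Grids and map keys are preserved; extrema metadata is recomputed on the
    noisy maps.  With sigma = 0 the input maps are returned unchanged.
    """
    rng = noise.rng()
    maps = {}
    for kind, m in base.maps.items():
        noisy = m.copy()
        if noise.sigma > 0:
            noisy = noisy + rng.normal(0.0, noise.sigma, size=m.shape)
        maps[kind] = noisy
    out = ScanResult(base.axis_amplitude.copy(), base.axis_offset.copy(), maps)
    out.locate_extrema()
    return out


def gen_spectrum(
    centers_hz: Sequence[float],
    amplitudes: Sequence[float],
    fwhm_hz: float,
    snr: float,
    seed: int = 0,
    freq_range_hz: tuple[float, float] | None = None,
    n_points: int = 4096,
) -> SpectrumRecord:
    """Synthetic absorption spectrum: Lorentzian lines plus white noise.

    Each line is a Lorentzian of peak height ``amplitude`` and full width at
    half maximum ``fwhm_hz``.  Noise is white Gaussian scaled so that the
    tallest peak divided by the noise RMS equals ``snr``; ``snr = inf``
    disables noise.
    """
    if not (fwhm_hz > 0):
        raise ValueError("fwhm must be positive")
    centers = np.asarray(centers_hz, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if centers.shape != amps.shape or centers.size == 0:
        raise ValueError("centers and amplitudes must be equal-length, non-empty")
    if freq_range_hz is None:
        span = max(10.0 * fwhm_hz, np.ptp(centers) + 10.0 * fwhm_hz)
        freq_range_hz = (centers.min() - span / 2, centers.max() + span / 2)
    f = np.linspace(freq_range_hz[0], freq_range_hz[1], int(n_points))
    hwhm = fwhm_hz / 2.0
    signal = np.zeros_like(f)
    for c, a in zip(centers, amps):
        signal += a * hwhm ** 2 / ((f - c) ** 2 + hwhm ** 2)
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        sigma = signal.max() / snr
        signal = signal + np.random.default_rng(seed).normal(0.0, sigma, size=f.shape)
    rec = SpectrumRecord(f, signal.astype(complex))
    rec.lines = measure_fwhm(f, np.abs(signal))
    return rec
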