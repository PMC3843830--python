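"""Receptor-noise-limited (RNL) colour discrimination of UV stimuli.

Quantum catches are integrals of reflectance x illumination x receptor
sensitivity over 300-700 nm. Chromatic distance follows the
Vorobyev-Osorio receptor-noise-limited model in the bright-light (Weber)
regime: log receptor contrasts Delta f_i = ln(q_i^a / q_i^b) are combined
with per-channel noise e_i into a distance in just-noticeable-difference
(JND) units; Delta S = 1 is the discrimination threshold.

The stimuli are double-Gaussian reflectance spectra: a UV peak plus a
long-wavelength peak on a small baseline. The threshold experiment reduces
the UV peak amplitude in 1% steps until the reduced spectrum differs from
the original by more than 1 JND; a required reduction of 100% is treated
as "not discriminable".
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .spectra import Spectrum
from .visual_system import VisualSystem

NOT_DISCRIMINABLE = None  # sentinel stored in ThresholdCurve.threshold_percent


@dataclass(frozen=True)
class StimulusSpec:
    """Double-Gaussian reflectance: UV peak + long-wavelength peak + baseline."""

    uv_peak_nm: float = 320.0
    uv_amplitude: float = 0.5
    uv_fwhm_nm: float = 36.0
    long_peak_nm: float = 520.0
    long_amplitude: float = 0.5
    long_fwhm_nm: float = 96.0
    baseline: float = 0.05

    def __post_init__(self) -> None:
        if self.uv_amplitude < 0 or self.long_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.uv_fwhm_nm <= 0 or self.long_fwhm_nm <= 0:
            raise ValueError("FWHM values must be positive")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive (channels must catch photons)")


@dataclass(frozen=True)
class ThresholdCurve:
    """Discrimination threshold (% UV-amplitude reduction) per UV peak position.

    ``threshold_percent`` holds NaN where no amplitude reduction up to and
    including 100% is discriminable.
    """

    uv_peaks_nm: np.ndarray
    threshold_percent: np.ndarray  # NaN = not discriminable

    def __post_init__(self) -> None:
        object.__setattr__(self, "uv_peaks_nm", np.asarray(self.uv_peaks_nm, dtype=float))
        object.__setattr__(self, "threshold_percent",
                           np.asarray(self.threshold_percent, dtype=float))
        if self.uv_peaks_nm.size != self.threshold_percent.size:
            raise ValueError("mismatched curve arrays")

    def __len__(self) -> int:
        return self.uv_peaks_nm.size

    @property
    def discriminable(self) -> np.ndarray:
        return ~np.isnan(self.threshold_percent)


def _gaussian(grid: np.ndarray, peak: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((grid - peak) / sigma) ** 2)


def make_stimulus(spec: StimulusSpec, grid: np.ndarray) -> Spectrum:
    """Render a stimulus specification as a reflectance spectrum."""
    grid = np.asarray(grid, dtype=float)
    if not (grid[0] <= spec.uv_peak_nm <= grid[-1]
            and grid[0] <= spec.long_peak_nm <= grid[-1]):
        raise ValueError("stimulus peaks must lie within the wavelength grid")
    vals = (spec.baseline
            + spec.uv_amplitude * _gaussian(grid, spec.uv_peak_nm, spec.uv_fwhm_nm)
            + spec.long_amplitude * _gaussian(grid, spec.long_peak_nm, spec.long_fwhm_nm))
    return Spectrum(grid, vals, kind="reflectance")


def quantum_catches(system: VisualSystem, reflectance: Spectrum,
                    illum: Spectrum) -> np.ndarray:
    """Per-channel quantum catch q_i = integral of R * I * S_i (trapezoid rule)."""
    if not reflectance.same_grid(illum):
        raise ValueError("reflectance and illuminant are not on the same grid")
    grid = reflectance.wavelengths
    for ch in system.channels:
        if not np.array_equal(ch.sensitivity.wavelengths, grid):
            raise ValueError(f"channel {ch.name!r} sensitivity not on the stimulus grid")
    integrand = reflectance.values * illum.values
    q = np.array([np.trapezoid(integrand * ch.sensitivity.values, grid)
                  for ch in system.channels])
    if np.any(q <= 0):
        blind = [system.channels[i].name for i in np.flatnonzero(q <= 0)]
        raise ValueError(f"channel(s) blind to stimulus (zero quantum catch): {blind}")
    return q


def delta_s(system: VisualSystem, catches_a: Sequence[float],
            catches_b: Sequence[float]) -> float:
    """RNL chromatic distance in JND between two quantum-catch vectors.

    For n channels with noise e_i and log contrasts Delta f_i:

        dS^2 = sum_{i<j} (Df_i - Df_j)^2 prod_{k not in {i,j}} e_k^2
               -----------------------------------------------------
                       sum_i prod_{k != i} e_k^2

    which reduces to the familiar closed forms for di-, tri- and
    tetrachromats.
    """
    qa = np.asarray(catches_a, dtype=float)
    qb = np.asarray(catches_b, dtype=float)
    e = system.noise
    if qa.size != e.size or qb.size != e.size:
        raise ValueError("catch vectors must match the system's channel count")
    if np.any(qa <= 0) or np.any(qb <= 0):
        raise ValueError("quantum catches must be positive")
    df = np.log(qa / qb)
    e2 = e ** 2
    prod_all = np.prod(e2)
    # prod over k != i, computed stably as prod_all / e2_i
    prod_minus_one = prod_all / e2
    denom = prod_minus_one.sum()
    num = 0.0
    n = e.size
    for i in range(n):
        for j in range(i + 1, n):
            num += (df[i] - df[j]) ** 2 * prod_all / (e2[i] * e2[j])
    return float(np.sqrt(num / denom))


def _reduced(spec: StimulusSpec, percent: int) -> StimulusSpec:
    return replace(spec, uv_amplitude=spec.uv_amplitude * (1.0 - percent / 100.0))


def discrimination_threshold(system: VisualSystem, spec: StimulusSpec,
                             illum: Spectrum) -> int | None:
    """Smallest % reduction of the UV peak exceeding 1 JND, or None.

    The UV-peak amplitude is reduced in 1% steps; the threshold is the first
    step at which the contrast to the original stimulus exceeds 1 JND
    (strict inequality). If that requires the full 100% reduction — removing
    the peak entirely — or if even full removal stays below 1 JND, the
    stimulus position counts as not discriminable.
    """
    grid = illum.wavelengths
    q_ref = quantum_catches(system, make_stimulus(spec, grid), illum)
    for k in range(1, 101):
        q_red = quantum_catches(system, make_stimulus(_reduced(spec, k), grid), illum)
        if delta_s(system, q_ref, q_red) > 1.0:
            return None if k == 100 else k
    return NOT_DISCRIMINABLE


def threshold_sweep(system: VisualSystem, base_spec: StimulusSpec, illum: Spectrum,
                    uv_start: float = 320.0, uv_stop: float = 420.0,
                    uv_step: float = 1.0, long_offset: float = 200.0) -> ThresholdCurve:
    """Discrimination thresholds for UV peaks swept across ``uv_start..uv_stop``.

    The long-wavelength peak shifts together with the UV peak, keeping a
    fixed offset (200 nm by default, anchoring the 320/520 nm starting pair).
    """
    peaks = np.arange(uv_start, uv_stop + 0.5 * uv_step, uv_step)
    thresholds = np.full(peaks.size, np.nan)
    for i, p in enumerate(peaks):
        spec = replace(base_spec, uv_peak_nm=float(p), long_peak_nm=float(p) + long_offset)
        t = discrimination_threshold(system, spec, illum)
        if t is not None:
            thresholds[i] = t
    return ThresholdCurve(peaks, thresholds)


def discrimination_limit(curve: ThresholdCurve) -> float | None:
    """Shortest UV-peak wavelength at which any amplitude difference is discriminable."""
    if len(curve) == 0:
        raise ValueError("empty threshold curve")
    idx = np.flatnonzero(curve.discriminable)
    if idx.size == 0:
        return None
    return float(curve.uv_peaks_nm[idx[0]])
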