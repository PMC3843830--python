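"""Receptor sensitivities, ocular-media screening, and visual-system assembly.

Cone spectral sensitivities are generated from the Govardovskii et al. (2000)
A1 visual-pigment template (alpha plus beta band), the field-standard
nomogram for vertebrate pigments, then screened by an ocular media
transmittance (OMT) curve. Screening is a plain pointwise product and is
deliberately NOT renormalized: the loss of absolute sensitivity caused by
the ocular media is part of what the model describes.

A :class:`VisualSystem` bundles 2-4 screened channels with per-channel
noise. Channel noise follows the receptor-noise-limited convention for
bright light: e_i = nu * sqrt(eta_ref / eta_i), where nu is the Weber
fraction of the most abundant channel and eta_i the relative abundance of
channel i.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .spectra import DEFAULT_GRID, Spectrum

# Govardovskii et al. (2000) A1 template constants, kept in one block so an
# alternative template can be swapped in.
A1_TEMPLATE = {
    "A": 69.7,
    "B": 28.0,
    "b": 0.922,
    "C": -14.9,
    "c": 1.104,
    "D": 0.674,
    # alpha-band position term: a = a0 + a1 * exp(-(lmax - 300)^2 / a2)
    "a0": 0.8795,
    "a1": 0.0459,
    "a2": 11940.0,
    # beta band: amplitude, peak and width as linear functions of lmax
    "beta_amp": 0.26,
    "beta_peak0": 189.0,
    "beta_peak1": 0.315,
    "beta_width0": -40.5,
    "beta_width1": 0.195,
}

# Surrogate receptor parameter sets for the two model species: single cones
# sws1/sws2/mws/lws with relative abundances 1:2:2:4 and a Weber fraction of
# 0.1 for the most abundant (lws) channel. The sws1 peaks come from
# microspectrophotometry (budgerigar 371 nm UVS, chicken 418 nm VS); the
# remaining peaks are the published values for each species.
BUDGERIGAR_LAMBDA_MAX = (371.0, 440.0, 499.0, 566.0)
CHICKEN_LAMBDA_MAX = (418.0, 455.0, 508.0, 571.0)
DEFAULT_ABUNDANCES = (1.0, 2.0, 2.0, 4.0)
DEFAULT_WEBER_FRACTION = 0.1
CHANNEL_NAMES = ("sws1", "sws2", "mws", "lws")


def pigment_template(lambda_max: float, grid: np.ndarray | None = None) -> Spectrum:
    """Normalized A1 pigment absorbance spectrum peaking at ``lambda_max``.

    Valid for lambda_max in [330, 600] nm (the template's calibration
    range). The returned spectrum has maximum value exactly 1.
    """
    if not 330.0 <= lambda_max <= 600.0:
        raise ValueError(f"lambda_max {lambda_max} nm outside template validity [330, 600]")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    t = A1_TEMPLATE
    x = lambda_max / grid
    a = t["a0"] + t["a1"] * np.exp(-((lambda_max - 300.0) ** 2) / t["a2"])
    alpha = 1.0 / (
        np.exp(t["A"] * (a - x))
        + np.exp(t["B"] * (t["b"] - x))
        + np.exp(t["C"] * (t["c"] - x))
        + t["D"]
    )
    beta_peak = t["beta_peak0"] + t["beta_peak1"] * lambda_max
    beta_width = t["beta_width0"] + t["beta_width1"] * lambda_max
    beta = t["beta_amp"] * np.exp(-(((grid - beta_peak) / beta_width) ** 2))
    vals = alpha + beta
    return Spectrum(grid, vals / vals.max(), kind="sensitivity",
                    name=f"A1_{lambda_max:g}nm")


def apply_ocular_media(pigment: Spectrum, omt: Spectrum) -> Spectrum:
    """Screen a pigment sensitivity by an OMT curve (pointwise product)."""
    if not pigment.same_grid(omt):
        raise ValueError("pigment and OMT are not on the same wavelength grid")
    return pigment.with_values(pigment.values * omt.values, kind="sensitivity")


def effective_peak(sensitivity: Spectrum) -> float:
    """Wavelength of maximum sensitivity, refined by a parabolic fit.

    Fits a parabola through the grid argmax and its two neighbours, giving
    sub-grid precision on smooth spectra. Screening by ocular media shifts
    this peak toward longer wavelengths when the cut-off approaches the
    pigment's absorbance peak.
    """
    vals, wl = sensitivity.values, sensitivity.wavelengths
    if vals.max() <= 0:
        raise ValueError("degenerate (all-zero) sensitivity spectrum")
    i = int(np.argmax(vals))
    if i == 0 or i == len(vals) - 1:
        return float(wl[i])
    y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(wl[i])
    # vertex of the parabola through three equally spaced samples
    delta = 0.5 * (y0 - y2) / denom
    step = wl[i + 1] - wl[i]
    return float(wl[i] + delta * step)


@dataclass(frozen=True)
class ReceptorChannel:
    """One cone channel: pigment peak, relative abundance and screened sensitivity."""

    name: str
    pigment_lambda_max: float
    abundance: float
    sensitivity: Spectrum

    def __post_init__(self) -> None:
        if self.abundance <= 0:
            raise ValueError("channel abundance must be positive")
        if np.any(self.sensitivity.values < 0):
            raise ValueError("sensitivity must be non-negative")


@dataclass(frozen=True)
class VisualSystem:
    """An ordered set of receptor channels with receptor-noise values."""

    channels: tuple[ReceptorChannel, ...]
    weber_fraction: float
    name: str = ""

    def __post_init__(self) -> None:
        if not 2 <= len(self.channels) <= 4:
            raise ValueError("a visual system needs 2-4 channels")
        if self.weber_fraction <= 0:
            raise ValueError("Weber fraction must be positive")

    @property
    def noise(self) -> np.ndarray:
        """Per-channel noise e_i = nu * sqrt(eta_ref / eta_i)."""
        eta = np.array([c.abundance for c in self.channels])
        return self.weber_fraction * np.sqrt(eta.max() / eta)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def sensitivities(self) -> np.ndarray:
        return np.vstack([c.sensitivity.values for c in self.channels])


def droplet_longpass(cut_nm: float, grid: np.ndarray,
                     steepness: float = 0.08) -> Spectrum:
    """Oil-droplet long-pass filter template (logistic cut-on at ``cut_nm``).

    Optional per-channel filtering; disabled by default in the standard
    system builds since sws1 droplets are transparent.
    """
    vals = 1.0 / (1.0 + np.exp(-steepness * (grid - cut_nm)))
    return Spectrum(grid, vals, kind="transmittance", name=f"droplet_{cut_nm:g}")


def build_visual_system(channels: Sequence[Mapping], omt: Spectrum,
                        weber_fraction: float = DEFAULT_WEBER_FRACTION,
                        name: str = "") -> VisualSystem:
    """Assemble a visual system from channel descriptions and an OMT curve.

    Each channel mapping needs ``name``, ``lambda_max`` and ``abundance``;
    an optional ``droplet_cut`` (nm) applies an oil-droplet long-pass filter
    before ocular screening.
    """
    if omt is None:
        raise ValueError("an ocular media transmittance spectrum is required")
    built = []
    for ch in channels:
        if "lambda_max" not in ch:
            raise ValueError(f"channel {ch.get('name', '?')!r} lacks lambda_max")
        sens = pigment_template(float(ch["lambda_max"]), omt.wavelengths)
        if ch.get("droplet_cut") is not None:
            sens = apply_ocular_media(
                sens, droplet_longpass(float(ch["droplet_cut"]), omt.wavelengths))
        sens = apply_ocular_media(sens, omt)
        built.append(ReceptorChannel(
            name=str(ch.get("name", f"ch{len(built)}")),
            pigment_lambda_max=float(ch["lambda_max"]),
            abundance=float(ch.get("abundance", 1.0)),
            sensitivity=sens,
        ))
    return VisualSystem(tuple(built), weber_fraction, name=name)


def standard_system(pigments: str, omt: Spectrum,
                    weber_fraction: float = DEFAULT_WEBER_FRACTION) -> VisualSystem:
    """Build one of the two tetrachromatic model systems.

    ``pigments`` is ``"UVS"`` (budgerigar parameter set) or ``"VS"``
    (chicken parameter set).
    """
    table = {"UVS": BUDGERIGAR_LAMBDA_MAX, "VS": CHICKEN_LAMBDA_MAX}
    if pigments not in table:
        raise ValueError("pigments must be 'UVS' or 'VS'")
    channels = [
        {"name": n, "lambda_max": lm, "abundance": ab}
        for n, lm, ab in zip(CHANNEL_NAMES, table[pigments], DEFAULT_ABUNDANCES)
    ]
    return build_visual_system(channels, omt, weber_fraction,
                               name=f"{pigments}-tetrachromat")
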