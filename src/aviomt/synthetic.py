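"""Synthetic inputs: sigmoidal OMT curves, species tables, and the D65 illuminant.

Measured ocular-media transmittance (OMT) curves of birds are smooth
long-pass functions: near zero in the deep UV, a cut-off region a few tens
of nm wide, and a flat plateau through the visible. The generator emulates
them with a logistic

    T(lambda) = plateau / (1 + exp(-(lambda - lambda50) / s)) + noise

where ``lambda50`` is the half-transmittance wavelength (for plateau 1 it
equals lambda_T0.5 exactly) and ``s`` sets the cut-off steepness (the
10-90% width is about 4.4 * s). Species tables are generated with the
empirically motivated structure of the real data: UVS pigments peak in
359-373 nm, VS pigments in 404-421 nm, and lambda_T0.5 increases linearly
with eye axial length.

All generators take an explicit integer seed; there is no global random
state.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .species import SpeciesTable
from .spectra import DEFAULT_GRID, Spectrum

# surrogate cut-off parameters for the three average OMT classes; lambda50
# values are the class means of the reference table, and the steepness
# reflects the steeper cut-off of UV-transparent (UVS-bird) media
OMT_CLASS_PARAMS = {
    "uv": {"lambda_t50": 323.0, "slope_scale": 6.0},      # parrots, UVS-passerines
    "v": {"lambda_t50": 358.0, "slope_scale": 10.0},      # owls, landfowl, VS-passerines
    "raptor": {"lambda_t50": 379.0, "slope_scale": 8.0},  # diurnal raptors
}

UVS_LAMBDA_MAX_RANGE = (359.0, 373.0)
VS_LAMBDA_MAX_RANGE = (404.0, 421.0)

#: group sizes mirroring the reference table
DEFAULT_GROUP_SIZES = {
    "parrot": 3, "UVS-passerine": 10, "VS-passerine": 7,
    "owl": 4, "landfowl": 3, "raptor": 4, "other": 7,
}
UVS_GROUPS = ("parrot", "UVS-passerine")


@dataclass(frozen=True)
class OmtGenSpec:
    """Parameters of one synthetic OMT curve."""

    lambda_t50_target: float
    slope_scale: float = 8.0
    plateau: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 300.0 < self.lambda_t50_target < 450.0:
            raise ValueError("lambda_t50_target must lie in (300, 450) nm")
        if self.slope_scale <= 0:
            raise ValueError("slope_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class SpeciesGenSpec:
    """Parameters of a synthetic species table with matched OMT curves.

    lambda_T0.5 is drawn as ``intercept + slope * axial_length + noise``;
    the defaults give the realistic spread of about 315-375 nm across eye
    sizes of 6-30 mm.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    uvs_lambda_max_range: tuple[float, float] = UVS_LAMBDA_MAX_RANGE
    vs_lambda_max_range: tuple[float, float] = VS_LAMBDA_MAX_RANGE
    # UVS birds (parrots, small passerines) are small-bodied; the class
    # contrast in lambda_T0.5 emerges through the eye-size relation
    uvs_axial_range_mm: tuple[float, float] = (6.0, 12.0)
    vs_axial_range_mm: tuple[float, float] = (8.0, 30.0)
    t50_intercept: float = 300.0
    t50_slope_per_mm: float = 2.5
    t50_noise_sd: float = 6.0
    omt_noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t50_noise_sd < 0 or self.omt_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")


def synth_omt_spectrum(spec: OmtGenSpec, grid: np.ndarray | None = None) -> Spectrum:
    """Generate one logistic OMT curve with optional Gaussian noise.

    Sampled on the common 1 nm grid by default, clipped at zero, and
    bit-reproducible for a fixed seed.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    vals = spec.plateau / (1.0 + np.exp(-(grid - spec.lambda_t50_target) / spec.slope_scale))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vals = vals + rng.normal(0.0, spec.noise_sd, size=grid.size)
    return Spectrum(grid, np.clip(vals, 0.0, None), kind="transmittance",
                    name=f"synth_omt_{spec.lambda_t50_target:g}")


def named_average_omt(name: str, grid: np.ndarray | None = None) -> Spectrum:
    """Surrogate for one of the three average OMT classes, or a clear medium.

    ``name`` is ``uv``, ``v``, ``raptor`` (noiseless logistic with the class
    parameters) or ``identity`` (perfectly transparent media).
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    key = name.lower().replace("-omt", "")
    if key == "identity":
        return Spectrum(grid, np.ones(grid.size), kind="transmittance", name="identity")
    if key not in OMT_CLASS_PARAMS:
        raise ValueError(f"unknown OMT class {name!r}; expected uv, v, raptor or identity")
    p = OMT_CLASS_PARAMS[key]
    return synth_omt_spectrum(
        OmtGenSpec(lambda_t50_target=p["lambda_t50"], slope_scale=p["slope_scale"]), grid
    )


def synth_species_table(spec: SpeciesGenSpec,
                        grid: np.ndarray | None = None
                        ) -> tuple[SpeciesTable, dict[str, Spectrum]]:
    """Generate a species table plus one matching OMT spectrum per species."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(spec.seed)
    rows = []
    spectra: dict[str, Spectrum] = {}
    for group, n in spec.group_sizes.items():
        is_uvs = group in UVS_GROUPS
        lm_lo, lm_hi = (spec.uvs_lambda_max_range if is_uvs
                        else spec.vs_lambda_max_range)
        axial_range = spec.uvs_axial_range_mm if is_uvs else spec.vs_axial_range_mm
        for i in range(n):
            name = f"synthetic_{group}_{i}"
            axial = rng.uniform(*axial_range)
            t50 = (spec.t50_intercept + spec.t50_slope_per_mm * axial
                   + (rng.normal(0.0, spec.t50_noise_sd) if spec.t50_noise_sd > 0 else 0.0))
            t50 = float(np.clip(t50, 305.0, 445.0))
            rows.append({
                "order": "synthetic",
                "common_name": name,
                "species": name,
                "pigment_class": "UVS" if is_uvs else "VS",
                "pigment_lambda_max": float(rng.uniform(lm_lo, lm_hi)),
                "lambda_t50": t50,
                "axial_length_mm": float(axial),
                "group_label": group,
                "notes": "",
            })
            omt_seed = int(rng.integers(0, 2**31 - 1))
            spectra[name] = synth_omt_spectrum(
                OmtGenSpec(lambda_t50_target=t50,
                           slope_scale=6.0 if is_uvs else 10.0,
                           noise_sd=spec.omt_noise_sd, seed=omt_seed),
                grid,
            )
    table = SpeciesTable(pd.DataFrame(rows))
    return table, spectra


def standard_illuminant_d65(grid: np.ndarray | None = None,
                            units: str = "photon") -> Spectrum:
    """CIE D65 daylight interpolated to the grid.

    ``units="energy"`` returns the bundled relative spectral power;
    ``units="photon"`` converts to relative photon flux (power times
    wavelength) and renormalizes to unit trapezoid integral over the grid.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    ref = importlib.resources.files("aviomt.data") / "cie_d65.csv"
    with importlib.resources.as_file(ref) as p:
        tab = pd.read_csv(p)
    wl = tab["wavelength_nm"].to_numpy(dtype=float)
    power = tab["relative_power"].to_numpy(dtype=float)
    if grid[0] < wl[0] or grid[-1] > wl[-1]:
        raise ValueError(f"grid must lie within the tabulated span [{wl[0]}, {wl[-1]}] nm")
    vals = np.interp(grid, wl, power)
    if units == "energy":
        return Spectrum(grid, vals, kind="illuminant-energy", name="D65")
    if units == "photon":
        photons = vals * grid
        photons = photons / np.trapezoid(photons, grid)
        return Spectrum(grid, photons, kind="illuminant-photon", name="D65")
    raise ValueError(f"unknown units {units!r}; expected 'photon' or 'energy'")
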