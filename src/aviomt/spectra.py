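"""Spectrum container, tabular I/O and ocular-media transmittance metrics.

A :class:`Spectrum` is a sampled function of wavelength on a strictly
increasing grid. All downstream computations (pigment screening, quantum
catches, group averages) operate on spectra resampled to a common grid,
by default 300-700 nm at 1 nm.

The transmittance metrics implemented here are the standard descriptors of
ocular media transparency: the 50%-transmittance wavelength lambda_T0.5
(lower = more UV reaches the retina), the per-5%-interval cut-off slopes,
and the fraction of 300-400 nm photons transmitted to the retina under a
given illuminant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: common wavelength grid used throughout: 300-700 nm sampled at 1 nm
DEFAULT_GRID = np.arange(300.0, 701.0, 1.0)

VALID_KINDS = frozenset(
    {"transmittance", "reflectance", "sensitivity", "illuminant-photon", "illuminant-energy"}
)


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectral function.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm.
    values
        Non-negative, finite values, one per wavelength. Unitless
        (transmittance/reflectance as fractions; sensitivities and
        illuminants in relative units).
    kind
        One of ``transmittance``, ``reflectance``, ``sensitivity``,
        ``illuminant-photon``, ``illuminant-energy``.
    name
        Optional series label (e.g. species name).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "transmittance"
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and of equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectrum values must be non-negative")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float),
                       kind=self.kind if kind is None else kind)

    def same_grid(self, other: "Spectrum") -> bool:
        return (len(self) == len(other)
                and bool(np.array_equal(self.wavelengths, other.wavelengths)))


def _require_same_grid(*spectra: Spectrum) -> None:
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise ValueError("spectra are not on identical wavelength grids")


def read_spectra_table(path: str | Path, layout: str = "wide",
                       kind: str = "transmittance",
                       percent: bool = False) -> list[Spectrum]:
    """Read spectra from a delimited text file (CSV or TSV).

    Wide layout: first column ``wavelength_nm``, one value column per
    spectrum. Long layout: columns ``series``, ``wavelength_nm``, ``value``.
    Rows may appear in any wavelength order; spectra are returned sorted
    ascending. Set ``percent=True`` when values are recorded in percent;
    they are divided by 100 on read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if layout not in {"wide", "long"}:
        raise ValueError(f"layout must be 'wide' or 'long', got {layout!r}")

    def _numeric(col: pd.Series, label: str) -> np.ndarray:
        out = pd.to_numeric(col, errors="coerce")
        bad = out.isna() & col.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric cell in column {label!r} at data row {row}")
        if out.isna().any():
            row = int(np.flatnonzero(out.isna().to_numpy())[0])
            raise ValueError(f"missing value in column {label!r} at data row {row}")
        return out.to_numpy(dtype=float)

    scale = 0.01 if percent else 1.0
    spectra: list[Spectrum] = []
    if layout == "wide":
        wl_col = df.columns[0]
        wl = _numeric(df[wl_col], wl_col)
        if np.unique(wl).size != wl.size:
            raise ValueError("duplicate wavelengths in input file")
        order = np.argsort(wl)
        for col in df.columns[1:]:
            vals = _numeric(df[col], col)
            spectra.append(Spectrum(wl[order], vals[order] * scale, kind=kind, name=str(col)))
    else:
        required = {"series", "wavelength_nm", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"long layout requires columns {sorted(required)}")
        for series, sub in df.groupby("series", sort=False):
            wl = _numeric(sub["wavelength_nm"], "wavelength_nm")
            if np.unique(wl).size != wl.size:
                raise ValueError(f"duplicate wavelengths in series {series!r}")
            vals = _numeric(sub["value"], "value")
            order = np.argsort(wl)
            spectra.append(Spectrum(wl[order], vals[order] * scale, kind=kind, name=str(series)))
    return spectra


def write_spectra_table(spectra: Sequence[Spectrum], path: str | Path) -> None:
    """Write spectra sharing one grid to a wide-layout CSV."""
    _require_same_grid(*spectra)
    data = {"wavelength_nm": spectra[0].wavelengths}
    for i, s in enumerate(spectra):
        data[s.name or f"spectrum_{i}"] = s.values
    pd.DataFrame(data).to_csv(path, index=False)


def resample_linear(s: Spectrum, grid: Iterable[float]) -> Spectrum:
    """Linearly interpolate a spectrum onto a new grid (no extrapolation)."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if grid[0] < s.wavelengths[0] or grid[-1] > s.wavelengths[-1]:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond data span "
            f"[{s.wavelengths[0]}, {s.wavelengths[-1]}]; extrapolation refused")
    return replace(s, wavelengths=grid, values=np.interp(grid, s.wavelengths, s.values))


def smooth_running_average(s: Spectrum, window: int = 11) -> Spectrum:
    """Centered running average with a symmetrically shrinking window.

    At each sample the half-width is ``min((window-1)//2, distance to either
    edge)`` so the output has the same length as the input and endpoint
    values are preserved exactly.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = len(s)
    if window > n:
        raise ValueError("window longer than spectrum")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(s.values)))
    idx = np.arange(n)
    radius = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - radius, idx + radius + 1
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return s.with_values(out)


def normalize_to_range_max(s: Spectrum, lo: float = 300.0, hi: float = 700.0) -> Spectrum:
    """Divide all values by the maximum attained within [lo, hi] nm."""
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no samples within [{lo}, {hi}] nm")
    peak = float(s.values[mask].max())
    if peak <= 0:
        raise ValueError("in-range maximum is not positive; cannot normalize")
    return s.with_values(s.values / peak)


def average_spectra(group: Sequence[Spectrum]) -> tuple[Spectrum, Spectrum]:
    """Pointwise mean and sample standard deviation of spectra on one grid.

    With a single spectrum the sd is zero everywhere.
    """
    if len(group) == 0:
        raise ValueError("no spectra to average")
    _require_same_grid(*group)
    stack = np.vstack([s.values for s in group])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(stack.shape[1])
    proto = group[0]
    return proto.with_values(mean), proto.with_values(sd)


def _in_range_argmax(s: Spectrum, lo: float = 300.0, hi: float = 700.0) -> int:
    mask = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not mask.any():
        raise ValueError(f"no samples within [{lo}, {hi}] nm")
    sub = np.flatnonzero(mask)
    return int(sub[np.argmax(s.values[sub])])


def wavelength_at_level(s: Spectrum, level: float,
                        lo: float = 300.0, hi: float = 700.0) -> float:
    """Wavelength of the first downward crossing of ``level``.

    Scans from the in-range maximum toward shorter wavelengths and
    interpolates linearly between the two samples bracketing the first
    crossing. ``wavelength_at_level(s, 0.5)`` is lambda_T0.5 for a
    normalized transmittance curve. The scan direction makes the statistic
    robust to non-monotone noise on the short-wavelength tail.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    imax = _in_range_argmax(s, lo, hi)
    if s.values[imax] < level:
        raise ValueError(f"level {level} not attained: maximum is {s.values[imax]:.4g}")
    vals, wl = s.values, s.wavelengths
    for j in range(imax, 0, -1):
        upper, lower = vals[j], vals[j - 1]
        if lower <= level <= upper and upper > lower:
            frac = (level - lower) / (upper - lower)
            return float(wl[j - 1] + frac * (wl[j] - wl[j - 1]))
        if lower == level == upper:
            return float(wl[j - 1])
    if vals[0] == level:
        return float(wl[0])
    raise ValueError(f"level {level} not attained below the spectrum maximum")


def lambda_t50(s: Spectrum) -> float:
    """The 50%-transmittance wavelength of a normalized OMT curve."""
    return wavelength_at_level(s, 0.5)


def cutoff_slopes(s: Spectrum, n_intervals: int = 20) -> np.ndarray:
    """Average transmittance change per nm in each 5% transmittance interval.

    The cut-off region of a normalized transmittance curve is divided into
    ``n_intervals`` equal transmittance bands (5% each by default). For band
    k the slope is ``0.05 / (lambda at (k+1)*5% - lambda at k*5%)``,
    in transmittance fraction per nm. Bands whose bounding levels are not
    attained by the curve are NaN. The level 0% is taken as the exact
    crossing of zero when attained, otherwise the band is NaN; the 100%
    level is the wavelength of the in-range maximum (where the normalized
    curve equals 1).
    """
    mask = (s.wavelengths >= 300.0) & (s.wavelengths <= 700.0)
    if not np.isclose(s.values[mask].max(), 1.0):
        raise ValueError("cutoff_slopes expects a normalized spectrum (in-range max == 1)")
    step = 1.0 / n_intervals
    levels = np.arange(n_intervals + 1) * step
    crossings = np.full(n_intervals + 1, np.nan)
    imax = _in_range_argmax(s)
    crossings[-1] = float(s.wavelengths[imax])
    vals, wl = s.values, s.wavelengths
    for k, level in enumerate(levels[:-1]):
        if level == 0.0:
            # exact zero crossing below the max, if the curve attains 0
            for j in range(imax, 0, -1):
                if vals[j - 1] == 0.0 and vals[j] > 0.0:
                    crossings[k] = float(wl[j - 1])
                    break
                if vals[j - 1] == 0.0 and vals[j] == 0.0:
                    crossings[k] = float(wl[j - 1])
                    break
            continue
        try:
            crossings[k] = wavelength_at_level(s, float(level))
        except ValueError:
            pass
    widths = np.diff(crossings)
    with np.errstate(invalid="ignore", divide="ignore"):
        slopes = step / widths
    return slopes


def retinal_uv_fraction(omt: Spectrum, illum: Spectrum,
                        lo: float = 300.0, hi: float = 400.0) -> float:
    """Fraction of illuminant photons in [lo, hi] nm transmitted to the retina.

    Trapezoid-rule ratio of the transmitted to the incident photon integral
    over the UV window; lies in [0, 1] for transmittance in [0, 1].
    """
    _require_same_grid(omt, illum)
    mask = (omt.wavelengths >= lo) & (omt.wavelengths <= hi)
    if mask.sum() < 2:
        raise ValueError(f"fewer than two samples within [{lo}, {hi}] nm")
    wl = omt.wavelengths[mask]
    incident = np.trapezoid(illum.values[mask], wl)
    if incident <= 0:
        raise ValueError("illuminant carries no energy in the UV window")
    transmitted = np.trapezoid(illum.values[mask] * omt.values[mask], wl)
    return float(transmitted / incident)


def process_omt(raw: Spectrum, window: int = 11, grid: np.ndarray | None = None) -> Spectrum:
    """Standard OMT post-processing: resample, smooth, normalize.

    Resamples the raw measurement to the common 1 nm grid (clipped to the
    measured span), applies the 11-point running average, and normalizes to
    the in-range maximum.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    sub = grid[(grid >= raw.wavelengths[0]) & (grid <= raw.wavelengths[-1])]
    if sub.size < window:
        raise ValueError("measured span too short for the requested grid/window")
    s = resample_linear(raw, sub)
    s = smooth_running_average(s, window)
    return normalize_to_range_max(s)
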