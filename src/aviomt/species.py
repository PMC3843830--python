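"""Species metadata table: pigment class, lambda_T0.5, eye size, group labels.

The packaged reference table covers 38 bird species from 11 orders with
their sws1 pigment class (UVS or VS), pigment peak wavelength where
measured, the 50%-transmittance wavelength of the ocular media, and a group
label used by the comparative analyses (parrot, UVS-passerine,
VS-passerine, owl, landfowl, raptor, or other). "other" marks species kept
out of the group statistics (fewer than three congeners or atypical ocular
media).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

PIGMENT_CLASSES = ("UVS", "VS")
GROUP_LABELS = ("parrot", "UVS-passerine", "VS-passerine", "owl",
                "landfowl", "raptor", "other")

#: species with unexpectedly low UV transmittance for their eye size,
#: suspected of UV-blocking lens pigmentation; excluded (together with all
#: raptors) before fitting the eye-size curve's exponential form
LOW_UV_TRANSMITTANCE_OUTLIERS = (
    "Buteo buteo",
    "Accipiter nisus",
    "Milvus milvus",
    "Falco tinnunculus",
    "Apus apus",
    "Podiceps cristatus",
)

REQUIRED_COLUMNS = ("species", "pigment_class", "lambda_t50", "group_label")


@dataclass(frozen=True)
class SpeciesTable:
    """Validated species metadata table."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"species table lacks required columns: {missing}")
        bad_class = set(df["pigment_class"].dropna()) - set(PIGMENT_CLASSES)
        if bad_class:
            raise ValueError(f"unknown pigment classes: {sorted(bad_class)}")
        if df["pigment_class"].isna().any():
            raise ValueError("pigment_class must be present for every species")
        t50 = df["lambda_t50"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t50)) or np.any(t50 < 300) or np.any(t50 > 700):
            raise ValueError("lambda_t50 must be finite and within [300, 700] nm")
        bad_group = set(df["group_label"].dropna()) - set(GROUP_LABELS)
        if bad_group:
            raise ValueError(f"unknown group labels: {sorted(bad_group)}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, **column_values) -> pd.DataFrame:
        out = self.df
        for col, val in column_values.items():
            out = out[out[col] == val]
        return out

    def lambda_t50(self, **column_values) -> np.ndarray:
        return self.subset(**column_values)["lambda_t50"].to_numpy(dtype=float)


def read_species_table(path: str | Path) -> SpeciesTable:
    """Read a species metadata CSV."""
    df = pd.read_csv(path)
    return SpeciesTable(df)


def load_reference_table() -> SpeciesTable:
    """Load the packaged 38-species reference table."""
    ref = importlib.resources.files("aviomt.data") / "table1.csv"
    with importlib.resources.as_file(ref) as p:
        return read_species_table(p)
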