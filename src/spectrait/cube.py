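"""In-memory hyperspectral cube container."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .bands import BandGrid

CUBE_KINDS = ("dn", "reflectance", "absorbance")


@dataclass
class SpectralCube:
    """A rows x cols x bands hyperspectral array.

    ``kind`` states the radiometric quantity stored: raw digital numbers
    (``"dn"``), calibrated ``"reflectance"`` or ``"absorbance"``
    (log10(1/R)).  ``mask`` is an optional rows x cols boolean foreground
    map (True = keep).
    """

    values: np.ndarray
    grid: BandGrid
    kind: str = "dn"
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be rows x cols x bands")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"cube has {self.values.shape[2]} bands but grid has {len(self.grid)}"
            )
        if self.kind not in CUBE_KINDS:
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape[:2]:
                raise ValueError("mask shape must match spatial dimensions")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def band_image(self, wavelength_nm: float) -> np.ndarray:
        """Spatial image at the band nearest ``wavelength_nm``."""
        return self.values[:, :, self.grid.nearest_band(wavelength_nm)]
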