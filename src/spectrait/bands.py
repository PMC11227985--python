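"""Wavelength band grids for SWIR grain spectra.

The imaging system sampled here covers 980-2500 nm in 256 bands (~6 nm
spacing).  A :class:`BandGrid` records band-center wavelengths and resolves
wavelength -> band-index queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_WL_MIN = 980.0
DEFAULT_WL_MAX = 2500.0
DEFAULT_N_BANDS = 256


@dataclass(frozen=True)
class BandGrid:
    """Ordered band-center wavelengths (nm).

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing band centers in nanometres.
    """

    wavelengths_nm: np.ndarray
    resolution_nm: float = field(init=False)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("a BandGrid needs at least two bands")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("band wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "resolution_nm", float(np.median(np.diff(wl))))

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def nearest_band(self, wavelength_nm: float) -> int:
        """Index of the band center closest to ``wavelength_nm``.

        Ties between two equidistant centers resolve to the lower index.
        Raises ``ValueError`` for wavelengths outside the grid range.
        """
        wl = self.wavelengths_nm
        if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside grid range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        d = np.abs(wl - wavelength_nm)
        return int(np.argmin(d))  # argmin takes the first (lower) index on ties

    def subset(self, keep: np.ndarray) -> "BandGrid":
        """New grid restricted to the band indices in ``keep`` (order kept)."""
        return BandGrid(self.wavelengths_nm[np.asarray(keep, dtype=int)])


def default_grid(
    n_bands: int = DEFAULT_N_BANDS,
    wl_min: float = DEFAULT_WL_MIN,
    wl_max: float = DEFAULT_WL_MAX,
) -> BandGrid:
    """Evenly spaced grid emulating the 256-band 980-2500 nm SWIR imager."""
    return BandGrid(np.linspace(wl_min, wl_max, n_bands))
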