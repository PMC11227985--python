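"""Hypercube -> clean mean absorbance spectrum per sample.

The preprocessing chain mirrors standard SWIR grain-imaging practice:

1. dark/white reference calibration of raw digital numbers to reflectance,
   ``R_t = (DN_o - DN_d) / (DN_w - DN_d) * R_w``;
2. absorbance ``A = log10(1/R)``;
3. foreground masking from the absorbance contrast between 1300 and
   1450 nm (grain pixels show a deep water/starch feature, the ~10 %
   reflectance cardboard background is flat);
4. per-band +/- k-SD outlier pixel rejection;
5. averaging surviving pixels into one spectrum per sample;
6. edge-band trimming and across-sample min-max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bands import BandGrid
from .cube import SpectralCube

#: leading / trailing noisy edge bands dropped before normalization; for the
#: 256-band grid this leaves the 247 bands the GAN and wavelet stages use.
DEFAULT_TRIM_HEAD = 4
DEFAULT_TRIM_TAIL = 5


@dataclass
class Spectrum:
    """One per-sample absorbance spectrum on a band grid."""

    values: np.ndarray
    grid: BandGrid
    normalized: bool = False
    norm_params: Optional[tuple[np.ndarray, np.ndarray]] = None  # (min, max) per band

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.grid),):
            raise ValueError("spectrum length must match grid")


@dataclass
class SpectrumSet:
    """samples x bands absorbance matrix paired with grain protein content.

    ``gpc`` is percent of grain dry weight.  ``provenance`` distinguishes
    measured samples from GAN-simulated ones.
    """

    spectra: np.ndarray
    gpc: np.ndarray
    grid: BandGrid
    sample_ids: list[str] = field(default_factory=list)
    provenance: str = "measured"
    normalized: bool = False
    norm_params: Optional[tuple[np.ndarray, np.ndarray]] = None

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.gpc = np.asarray(self.gpc, dtype=float)
        if self.spectra.shape[0] != self.gpc.shape[0]:
            raise ValueError("spectra and gpc row counts differ")
        if self.spectra.shape[1] != len(self.grid):
            raise ValueError("spectra band count must match grid")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:04d}" for i in range(self.n_samples)]
        if self.provenance == "measured" and np.any(self.gpc <= 0):
            raise ValueError("measured GPC must be positive")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_bands(self) -> int:
        return self.spectra.shape[1]


class DegenerateReferenceError(ValueError):
    """White minus dark reference is not positive at some band."""


def convert_to_reflectance(
    dn_cube: SpectralCube,
    dark: np.ndarray,
    white: np.ndarray,
    white_reflectance: float = 0.99,
) -> SpectralCube:
    """Dark/white calibration of a DN cube to reflectance.

    ``dark`` and ``white`` may be per-band vectors or full per-pixel cubes
    broadcastable against the data.
    """
    if dn_cube.kind != "dn":
        raise ValueError("convert_to_reflectance expects a DN cube")
    dark = np.asarray(dark, dtype=float)
    white = np.asarray(white, dtype=float)
    denom = white - dark
    bad = np.asarray(denom <= 0)
    if bad.any():
        # report band indices regardless of reference shape
        band_axis_bad = bad if bad.ndim == 1 else bad.any(axis=tuple(range(bad.ndim - 1)))
        bands = np.flatnonzero(np.atleast_1d(band_axis_bad))
        raise DegenerateReferenceError(
            f"white - dark reference is <= 0 at band indices {bands.tolist()}"
        )
    refl = (dn_cube.values - dark) / denom * white_reflectance
    return SpectralCube(refl, dn_cube.grid, kind="reflectance", mask=dn_cube.mask)


def reflectance_to_absorbance(cube: SpectralCube) -> SpectralCube:
    """Absorbance A = log10(1/R); requires positive reflectance off-mask."""
    if cube.kind != "reflectance":
        raise ValueError("reflectance_to_absorbance expects a reflectance cube")
    vals = cube.values
    consider = np.ones(vals.shape[:2], dtype=bool) if cube.mask is None else cube.mask
    nonpos = (vals <= 0) & consider[:, :, None]
    if nonpos.any():
        raise ValueError(
            f"nonpositive reflectance in {int(nonpos.any(axis=2).sum())} unmasked pixels"
        )
    out = np.full_like(vals, np.nan)
    ok = consider[:, :, None] & (vals > 0)
    out[ok] = np.log10(1.0 / vals[ok])
    return SpectralCube(out, cube.grid, kind="absorbance", mask=cube.mask)


def mask_foreground(
    abs_cube: SpectralCube,
    wl_low: float = 1300.0,
    wl_high: float = 1450.0,
    threshold: float = 0.5,
) -> np.ndarray:
    """Foreground = pixels with |A(1450) - A(1300)| above ``threshold``."""
    if abs_cube.kind != "absorbance":
        raise ValueError("mask_foreground expects an absorbance cube")
    a_low = abs_cube.band_image(wl_low)
    a_high = abs_cube.band_image(wl_high)
    return np.abs(a_high - a_low) > threshold


def remove_outlier_pixels(
    abs_cube: SpectralCube, mask: np.ndarray, k: float = 2.0
) -> tuple[np.ndarray, int]:
    """Drop foreground pixels outside mean +/- k*SD in any band (single pass).

    Returns the reduced mask and the number of pixels removed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("need at least 2 foreground pixels")
    pix = abs_cube.values[mask]                     # n_fg x bands
    mean = pix.mean(axis=0)
    sd = pix.std(axis=0, ddof=0)
    # SD == 0 bands can never flag a pixel (no exceedance possible)
    with np.errstate(invalid="ignore"):
        exceed = np.abs(pix - mean) > k * sd
    exceed[:, sd == 0] = False
    bad = exceed.any(axis=1)
    if bad.all():
        raise ValueError("outlier rejection removed every foreground pixel")
    reduced = mask.copy()
    fg_idx = np.flatnonzero(mask.ravel())
    reduced.ravel()[fg_idx[bad]] = False
    return reduced, int(bad.sum())


def mean_masked_spectrum(abs_cube: SpectralCube, mask: np.ndarray) -> Spectrum:
    """Per-band arithmetic mean over surviving foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no pixels to average")
    return Spectrum(abs_cube.values[mask].mean(axis=0), abs_cube.grid)


def preprocess_cube(
    dn_cube: SpectralCube,
    dark: np.ndarray,
    white: np.ndarray,
    white_reflectance: float = 0.99,
    mask_threshold: float = 0.5,
    outlier_k: float = 2.0,
) -> tuple[Spectrum, np.ndarray]:
    """Full chain: DN -> reflectance -> absorbance -> mask -> outlier
    rejection -> mean spectrum.  Returns (spectrum, final mask)."""
    refl = convert_to_reflectance(dn_cube, dark, white, white_reflectance)
    absorb = reflectance_to_absorbance(refl)
    mask = mask_foreground(absorb, threshold=mask_threshold)
    mask, _ = remove_outlier_pixels(absorb, mask, k=outlier_k)
    return mean_masked_spectrum(absorb, mask), mask


def trim_indices(
    n_bands: int,
    head: int = DEFAULT_TRIM_HEAD,
    tail: int = DEFAULT_TRIM_TAIL,
    drop: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Band indices kept after trimming noisy edges (or an explicit drop list)."""
    if drop is not None:
        keep = np.setdiff1d(np.arange(n_bands), np.asarray(drop, dtype=int))
    else:
        keep = np.arange(head, n_bands - tail)
    if keep.size < 2:
        raise ValueError("trimming left fewer than 2 bands")
    return keep


def trim_and_normalize(
    spectrum_set: SpectrumSet,
    head: int = DEFAULT_TRIM_HEAD,
    tail: int = DEFAULT_TRIM_TAIL,
    drop: Optional[Sequence[int]] = None,
) -> SpectrumSet:
    """Trim edge bands then min-max normalize each band across samples.

    Normalization is per band (across samples), preserving inter-sample
    amplitude differences that carry the protein signal; the per-band
    (min, max) pair is stored so generated spectra can be mapped back to
    absorbance units with :func:`denormalize`.
    """
    if spectrum_set.n_samples < 2:
        raise ValueError("need at least 2 samples to normalize across samples")
    keep = trim_indices(spectrum_set.n_bands, head, tail, drop)
    sub = spectrum_set.spectra[:, keep]
    lo = sub.min(axis=0)
    hi = sub.max(axis=0)
    flat = np.flatnonzero(hi == lo)
    if flat.size:
        raise ValueError(f"constant band(s) after trimming at kept indices {flat.tolist()}")
    norm = (sub - lo) / (hi - lo)
    return SpectrumSet(
        norm,
        spectrum_set.gpc.copy(),
        spectrum_set.grid.subset(keep),
        sample_ids=list(spectrum_set.sample_ids),
        provenance=spectrum_set.provenance,
        normalized=True,
        norm_params=(lo, hi),
    )


def denormalize(spectrum_set: SpectrumSet) -> np.ndarray:
    """Invert min-max normalization using the stored per-band parameters."""
    if not spectrum_set.normalized or spectrum_set.norm_params is None:
        raise ValueError("spectrum set is not normalized")
    lo, hi = spectrum_set.norm_params
    return spectrum_set.spectra * (hi - lo) + lo


# ---------------------------------------------------------------------------
# CSV round trip: columns sample_id, wl_<wavelength>, ..., gpc


def write_spectra_csv(spectrum_set: SpectrumSet, path: str | Path) -> None:
    cols = {f"wl_{w:07.1f}": spectrum_set.spectra[:, j]
            for j, w in enumerate(spectrum_set.grid.wavelengths_nm)}
    df = pd.DataFrame({"sample_id": spectrum_set.sample_ids, **cols,
                       "gpc": spectrum_set.gpc})
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path, provenance: str = "measured") -> SpectrumSet:
    df = pd.read_csv(path)
    wl_cols = [c for c in df.columns if c.startswith("wl_")]
    wl = np.array([float(c[3:]) for c in wl_cols])
    order = np.argsort(wl)
    return SpectrumSet(
        df[[wl_cols[i] for i in order]].to_numpy(float),
        df["gpc"].to_numpy(float),
        BandGrid(wl[order]),
        sample_ids=[str(s) for s in df["sample_id"]],
        provenance=provenance,
    )
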