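"""Synthetic data generators with known ground truth.

Three generators cover the pipeline's inputs end to end:

* :func:`simulate_spectrum_set` — per-sample SWIR absorbance spectra whose
  shape follows dry grain optics: a smooth baseline, fixed absorption
  features near 1200/1450/1800/1950 nm (starch, sugars, lignin O-H / C-H
  overtones) and protein features at 1510 and 1690 nm whose depth scales
  linearly with grain protein content;
* :func:`simulate_hypercube` — a raw digital-number hypercube with dark and
  white reference scans, grain pixels on a flat ~10 % reflectance cardboard
  background and the true foreground mask;
* :func:`simulate_genotypes_with_trait` — structured genotypes (two
  subpopulations, local linkage disequilibrium along each chromosome) with
  planted causal SNPs and a heritability-controlled GPC.

Every generator is deterministic under its seed and returns its ground
truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .bands import BandGrid, default_grid
from .cube import SpectralCube
from .gwas import GenotypeMatrix
from .preprocess import SpectrumSet


@dataclass
class SpectralModelParams:
    """Parameters of the synthetic grain absorbance model."""

    grid: BandGrid = field(default_factory=default_grid)
    #: polynomial coefficients of the baseline in scaled wavelength units
    baseline_coeffs: tuple[float, ...] = (0.55, 0.15, -0.10)
    #: fixed absorption features: (center nm, width nm, depth)
    fixed_features: tuple[tuple[float, float, float], ...] = (
        (1200.0, 40.0, 0.35),
        (1450.0, 45.0, 0.80),
        (1800.0, 55.0, 0.30),
        (1950.0, 50.0, 0.55),
    )
    #: protein-linked features: (center nm, width nm); depth = slope * GPC
    trait_features: tuple[tuple[float, float], ...] = ((1510.0, 30.0), (1690.0, 35.0))
    trait_slope: float = 0.02        # absorbance units per % GPC
    noise_sd: float = 0.01           # per-band absorbance noise
    variety_sd: float = 0.02         # per-sample smooth baseline offset

    def __post_init__(self) -> None:
        for c, w, d in self.fixed_features:
            if w <= 0 or d < 0:
                raise ValueError("feature widths must be > 0 and depths >= 0")
        for c, w in self.trait_features:
            if w <= 0:
                raise ValueError("trait feature widths must be > 0")
        if self.trait_slope <= 0:
            raise ValueError("trait slope must be positive")
        if self.noise_sd < 0 or self.variety_sd < 0:
            raise ValueError("noise SDs must be nonnegative")


#: default GPC distribution (% dry weight): truncated normal
GPC_MEAN, GPC_SD, GPC_BOUNDS = 5.7, 0.45, (4.0, 8.0)


def draw_gpc(n: int, rng: np.random.Generator, mean: float = GPC_MEAN,
             sd: float = GPC_SD, bounds: tuple[float, float] = GPC_BOUNDS) -> np.ndarray:
    """Truncated-normal GPC draws."""
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def grain_absorbance(
    gpc: np.ndarray, params: SpectralModelParams,
    variety_effect: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Noise-free absorbance spectra (samples x bands) for given GPC values."""
    wl = params.grid.wavelengths_nm
    x = (wl - wl[0]) / (wl[-1] - wl[0])          # scaled [0, 1]
    base = np.polyval(list(reversed(params.baseline_coeffs)), x)
    spec = np.tile(base, (len(gpc), 1))
    for c, w, d in params.fixed_features:
        spec += d * np.exp(-((wl - c) ** 2) / (2 * w * w))
    for c, w in params.trait_features:
        depth = params.trait_slope * np.asarray(gpc)[:, None]
        spec += depth * np.exp(-((wl - c) ** 2) / (2 * w * w))
    if variety_effect is not None:
        spec += np.asarray(variety_effect)[:, None]
    return spec


def simulate_spectrum_set(
    n: int,
    params: Optional[SpectralModelParams] = None,
    gpc_values: Optional[np.ndarray] = None,
    seed: int = 0,
) -> tuple[SpectrumSet, dict]:
    """Synthetic spectrum+GPC set with ground truth.

    GPC values may be supplied (e.g. from a genetic simulation) or drawn
    from the default truncated normal.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    params = params or SpectralModelParams()
    rng = np.random.default_rng(seed)
    gpc = draw_gpc(n, rng) if gpc_values is None else np.asarray(gpc_values, float)
    if gpc.shape != (n,):
        raise ValueError("gpc_values length must equal n")
    variety = rng.normal(0.0, params.variety_sd, size=n)
    clean = grain_absorbance(gpc, params, variety)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    truth = {"clean_spectra": clean, "variety_effect": variety, "params": params}
    return SpectrumSet(noisy, gpc, params.grid, provenance="measured"), truth


# ---------------------------------------------------------------------------
# Hypercube


def simulate_hypercube(
    rows: int = 24,
    cols: int = 24,
    n_grain_pixels: int = 120,
    params: Optional[SpectralModelParams] = None,
    gpc: float = GPC_MEAN,
    background_reflectance: float = 0.10,
    dark_dn: float = 100.0,
    white_dn: float = 4000.0,
    white_reflectance: float = 0.99,
    pixel_noise_sd: float = 0.0,
    seed: int = 0,
) -> dict:
    """Raw DN hypercube + references + true mask for preprocessing tests.

    Grain pixels carry the synthetic grain absorbance spectrum (absorbance
    contrast between 1300 and 1450 nm well above 0.5); the background is
    flat at ~10 % reflectance, emulating the black cardboard sample holder.
    DN values are synthesized by inverting the reflectance calibration with
    the chosen dark/white levels.
    """
    if n_grain_pixels < 1:
        raise ValueError("need at least one grain pixel")
    if n_grain_pixels > rows * cols:
        raise ValueError("foreground larger than the image")
    params = params or SpectralModelParams()
    rng = np.random.default_rng(seed)
    n_bands = len(params.grid)

    grain_abs = grain_absorbance(np.array([gpc]), params)[0]
    grain_refl = 10.0 ** (-grain_abs)

    refl = np.full((rows, cols, n_bands), background_reflectance)
    flat = rng.choice(rows * cols, size=n_grain_pixels, replace=False)
    mask = np.zeros(rows * cols, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(rows, cols)
    refl[mask] = grain_refl
    if pixel_noise_sd > 0:
        # grain pixels differ mainly by overall brightness (orientation,
        # packing), modelled as a per-pixel absorbance offset shared across
        # bands; applied in absorbance space so the 1300/1450 nm contrast
        # rule stays decisive
        offset = rng.normal(0.0, pixel_noise_sd, size=(n_grain_pixels, 1))
        refl[mask] = 10.0 ** (-(grain_abs + offset))

    dark = np.full(n_bands, dark_dn)
    white = np.full(n_bands, white_dn)
    dn = dark + refl / white_reflectance * (white - dark)
    return {
        "dn_cube": SpectralCube(dn, params.grid, kind="dn"),
        "dark": dark,
        "white": white,
        "white_reflectance": white_reflectance,
        "true_mask": mask,
        "true_reflectance": refl,
        "grain_absorbance": grain_abs,
        "gpc": gpc,
    }


# ---------------------------------------------------------------------------
# Genotypes + trait


@dataclass
class TraitGenetics:
    """Planted genetic architecture for the synthetic trait.

    With ``causal_indices=None`` the generator plants the effect at a
    well-tagged common SNP (minor allele frequency >= 0.2 with several
    strong local proxies), emulating the dense-marker regime of real
    resequencing panels where every causal variant is surrounded by tags.
    """

    causal_indices: Optional[tuple[int, ...]] = None
    effects: tuple[float, ...] = (1.0,)
    h2: float = 0.5
    gpc_mean: float = GPC_MEAN
    gpc_sd: float = GPC_SD
    bounds: tuple[float, float] = GPC_BOUNDS

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if (self.causal_indices is not None
                and len(self.causal_indices) != len(self.effects)):
            raise ValueError("one effect per causal SNP required")
        if self.bounds[0] >= self.bounds[1]:
            raise ValueError("bounds must be ordered")


def _well_tagged_causal(
    dosages: np.ndarray, chrom_of: np.ndarray,
    maf_min: float = 0.2, tag_r2: float = 0.5, min_tags: int = 4,
    window: int = 6,
) -> int:
    """Index of a common, well-tagged SNP near the middle of chromosome 1.

    Scans outward from the chromosome-1 midpoint and returns the first SNP
    with MAF >= ``maf_min`` and at least ``min_tags`` markers within
    ``window`` map steps at r^2 >= ``tag_r2``; falls back to the most-tagged
    candidate if none qualifies.
    """
    on = np.flatnonzero(chrom_of == chrom_of[0])
    mid = on[len(on) // 2]
    window = min(window, max(1, (len(on) - 1) // 2))
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    best, best_tags = None, -1
    for off in range(0, len(on)):
        for j in ([mid] if off == 0 else [mid - off, mid + off]):
            if j < on[0] or j > on[-1]:
                continue
            x = dosages[:, j]
            if x.std() == 0:
                continue
            if best is None:          # fallback: nearest polymorphic SNP
                best = j
            if maf[j] < maf_min or j < on[0] + window or j > on[-1] - window:
                continue
            tags = 0
            for k in range(j - window, j + window + 1):
                if k == j or dosages[:, k].std() == 0:
                    continue
                r = np.corrcoef(x, dosages[:, k])[0, 1]
                tags += r * r >= tag_r2
            if tags >= min_tags:
                return j
            if tags > best_tags:
                best, best_tags = j, tags
    if best is None:
        raise ValueError("no polymorphic SNP available for the causal effect")
    return best


def _mosaic_haplotype(
    founders: np.ndarray,
    chrom_of: np.ndarray,
    recomb_rate: float,
    mutation_rate: float,
    rng: np.random.Generator,
    founder_weights: np.ndarray,
) -> np.ndarray:
    """One haplotype as a recombinant mosaic of founder haplotypes."""
    n_founders, n_snp = founders.shape
    switch = rng.random(n_snp) < recomb_rate
    switch[0] = True
    switch |= np.r_[True, chrom_of[1:] != chrom_of[:-1]]
    seg_id = np.cumsum(switch) - 1
    choice = rng.choice(n_founders, size=seg_id[-1] + 1, p=founder_weights)
    hap = founders[choice[seg_id], np.arange(n_snp)].copy()
    mut = rng.random(n_snp) < mutation_rate
    hap[mut] = 1.0 - hap[mut]
    return hap


def simulate_genotypes_with_trait(
    n_ind: int = 200,
    n_snp: int = 500,
    genetics: Optional[TraitGenetics] = None,
    n_chrom: int = 2,
    snp_spacing_bp: int = 10_000,
    founders_per_subpop: int = 5,
    founder_reuse: float = 0.9,
    own_pool_weight: float = 0.85,
    # mean founder segment length = spacing / recomb_rate ~ 200 kb, matching
    # the LD decay scale of rice diversity panels
    recomb_rate: float = 0.05,
    mutation_rate: float = 0.02,
    inbred: bool = True,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray, dict]:
    """Structured genotypes with haplotype-block LD and a heritable GPC.

    A rice diversity panel is a collection of essentially homozygous inbred
    lines descending from a modest pool of ancestral haplotypes, so linkage
    disequilibrium is blocky: runs of SNPs tag the same founder bipartition
    (near-perfect local r^2) and correlation decays over the ~200 kb
    haplotype-block/recombination scale.  Each individual's haplotype is a
    recombinant mosaic over the founder pool, sampled mostly from its own
    subpopulation's half of the pool (which creates the population
    structure), with rare mutations; inbred individuals carry the haplotype
    twice.  GPC is the causal-dosage score rescaled so the genetic share of
    variance equals ``h2``, plus environmental noise, mapped onto the
    default GPC distribution.
    """
    genetics = genetics or TraitGenetics()
    if genetics.causal_indices is not None and any(
            c >= n_snp or c < 0 for c in genetics.causal_indices):
        raise ValueError("causal index outside SNP range")
    rng = np.random.default_rng(seed)

    pop = rng.integers(0, 2, size=n_ind)
    # SNPs split across chromosomes in contiguous blocks
    chrom_of = np.repeat(np.arange(n_chrom), int(np.ceil(n_snp / n_chrom)))[:n_snp]

    # Founder pool: within a haplotype block, consecutive SNPs tag the SAME
    # founder bipartition (perfect proxies, as in selfing panels); a new
    # bipartition is drawn with probability 1 - founder_reuse per SNP step,
    # so block length is geometric with mean 1/(1 - founder_reuse) steps and
    # r^2 decays like founder_reuse^d (~200 kb scale at the defaults).
    m = 2 * founders_per_subpop

    def _new_bipartition() -> np.ndarray:
        while True:
            c = (rng.random(m) < rng.uniform(0.15, 0.85)).astype(float)
            if 0 < c.sum() < m:        # a SNP must split the founder pool
                return c

    founders = np.empty((m, n_snp))
    carrier = _new_bipartition()
    for j in range(n_snp):
        new_block = (j == 0 or chrom_of[j] != chrom_of[j - 1]
                     or rng.random() >= founder_reuse)
        if new_block:
            carrier = _new_bipartition()
        founders[:, j] = carrier

    # population structure: each subpopulation samples mosaics mostly from
    # its own half of the founder pool
    weights = np.full((2, m), (1.0 - own_pool_weight) / founders_per_subpop)
    weights[0, :founders_per_subpop] = own_pool_weight / founders_per_subpop
    weights[1, founders_per_subpop:] = own_pool_weight / founders_per_subpop

    dosages = np.empty((n_ind, n_snp))
    for i in range(n_ind):
        h1 = _mosaic_haplotype(founders, chrom_of, recomb_rate,
                               mutation_rate, rng, weights[pop[i]])
        h2_hap = h1 if inbred else _mosaic_haplotype(
            founders, chrom_of, recomb_rate, mutation_rate, rng, weights[pop[i]])
        dosages[i] = h1 + h2_hap

    causal_indices = (genetics.causal_indices
                      if genetics.causal_indices is not None
                      else (_well_tagged_causal(dosages, chrom_of),))
    g_raw = dosages[:, list(causal_indices)] @ np.asarray(genetics.effects)
    var_g = float(np.var(g_raw))
    if genetics.h2 > 0:
        if var_g <= 0:
            raise ValueError("requested h2 > 0 but causal SNPs carry no variance")
        g_c = (g_raw - g_raw.mean()) / np.sqrt(var_g) * genetics.gpc_sd * np.sqrt(genetics.h2)
    else:
        g_c = np.zeros(n_ind)
    e_sd = genetics.gpc_sd * np.sqrt(1.0 - genetics.h2)
    gpc = genetics.gpc_mean + g_c + rng.normal(0.0, e_sd, size=n_ind)
    gpc = np.clip(gpc, *genetics.bounds)

    if missing_rate > 0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages = dosages.astype(float)
        dosages[miss] = np.nan

    pos = np.concatenate([
        (np.arange((chrom_of == c).sum()) + 1) * snp_spacing_bp
        for c in range(n_chrom)
    ])
    chroms = (chrom_of + 1).astype(str)
    snp_map = pd.DataFrame({
        "chrom": chroms,
        "pos": pos,
        "id": [f"SNP{c}.{p}" for c, p in zip(chroms, pos)],
    })
    geno = GenotypeMatrix(dosages, snp_map)
    truth = {
        "causal_ids": [snp_map["id"][i] for i in causal_indices],
        "causal_indices": list(causal_indices),
        "effects": list(genetics.effects),
        "h2_target": genetics.h2,
        "subpopulation": pop,
        "genetic_values": g_c,
    }
    return geno, gpc, truth
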