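# Methods

`spectrait` implements a complete desk-scale workflow for estimating rice
grain protein content (GPC, % of dry weight) from shortwave-infrared (SWIR)
hyperspectral imagery and for mapping the trait genetically, with every
stage testable against synthetic data of known ground truth.

## Hypercube preprocessing

Raw push-broom scans are digital-number (DN) cubes of shape
rows x cols x 256 bands spanning 980-2500 nm.  Calibration follows the
standard two-reference scheme,

    R_t = (DN_o - DN_d) / (DN_w - DN_d) * R_w,

with dark current `DN_d`, white-standard scan `DN_w` and the standard's
known reflectance `R_w` (default 0.99).  Absorbance is `A = log10(1/R)`.
Grain pixels are segmented by the contrast between the 1300 nm shoulder and
the 1450 nm water/starch absorption: a pixel is foreground when
`|A(1450) - A(1300)| > 0.5`.  The threshold and wavelength pair are
configurable; the absolute value makes the rule indifferent to the sign of
the background contrast.  Outlying pixels are removed in a single pass: a
foreground pixel is dropped if it leaves the mean +/- 2 SD envelope in any
band (per-band statistics over foreground pixels; a zero-SD band can never
flag a pixel).  Surviving pixels are averaged into one spectrum per sample.

Before modelling, 9 noisy edge bands are trimmed (4 leading, 5 trailing by
default, index lists configurable), leaving 247 bands, and each band is
min-max normalized **across samples** into [0, 1].  Per-band (min, max)
pairs are stored so generated spectra can be mapped back to absorbance
units; normalizing per band rather than per sample preserves the
inter-sample amplitude differences that carry the protein signal.

GPC reference values come from Kjeldahl total nitrogen via the rice
conversion factor 5.82 (`protein % = 5.82 x N %`).

## Joint-vector GAN augmentation

Small calibration sets limit model generalization.  The augmentation stage
learns the joint distribution of (spectrum, GPC) with a one-dimensional
deep convolutional generative adversarial network (DCGAN) and samples
simulated pairs from it.

The training currency is a length-248 *joint vector*: the 247-band
normalized spectrum with GPC/10 inserted immediately after the band nearest
1510 nm — a protein absorption band, so the trait sits among spectrally
related entries rather than at a noisy curve edge.  Insertion (not
replacement) makes encoding lossless: splitting the vector returns the
exact spectrum and GPC.

Architecture (248 = 31 x 2^3 factorizes the upsampling cleanly):

* Generator: 100-d Gaussian latent -> dense to 64 channels x 31 ->
  three fractional-stride (x2) transposed 1-D convolutions
  (31 -> 62 -> 124 -> 248), batch norm + ReLU on hidden layers, sigmoid
  output so samples live in [0, 1] like the normalized training data.
* Discriminator: mirrored stride-2 1-D convolutions with LeakyReLU(0.2),
  batch norm on all but the first layer, dense head with sigmoid
  real/simulated probability.

Training uses binary cross-entropy and Adam (learning rate 2e-4, beta1 0.5),
batch size 8, up to 10,000 epochs in production settings; everything is
configurable and bitwise-reproducible under a fixed seed.  The networks are
implemented directly in NumPy (dense, conv, transposed conv, batch norm,
Adam, with hand-written backward passes verified against finite
differences), which keeps the package dependency-light and deterministic on
a single CPU.

Generation-epoch selection is automated: each checkpoint generates a
sample whose GPC distribution is compared with the measured one by the sum
of absolute differences of six summary statistics (min, Q1, median, mean,
Q3, max); the checkpoint with the smallest distance wins.  Generated
samples whose GPC falls outside 1.5 x IQR Tukey fences are discarded before
use (factor configurable).

## Wavelet features

Spectra are decomposed with a dense continuous wavelet transform: the
Gaussian second derivative ("Mexican hat") as mother wavelet, L2
normalization `1/sqrt(a)`, scales {2, 3, 4, 5}, translation evaluated at
every band so each coefficient `WF_{lambda,a}` is directly comparable to
the band at `lambda`.  The transform runs in band-index coordinates (the
grid is uniform) with symmetric-reflection boundary handling; the kernel is
truncated at 8a samples, where the wavelet is below 1e-12, and
boundary-affected columns are flagged.  The implementation agrees with a
direct brute-force summation of the transform integral to 1e-8.

Feature screening keeps the ceiling of 5 % of columns with the largest
|Pearson r| against GPC (ties break by label order).  Recursive feature
elimination with a partial-least-squares backbone then drops the feature
with the smallest absolute standardized coefficient one at a time,
recording fivefold-CV mean squared error at every size; the size minimizing
CV MSE wins, with ties going to the smaller subset.

## Calibration models and evaluation

Four algorithms are supported — PLSR, RBF support-vector regression,
random forest regression and Bayesian linear regression — each grid-searched
by fivefold cross-validated MSE over small default grids (PLSR components
1-20; SVR C in {0.1, 1, 10, 100}, gamma in {scale, 0.01, 0.1}; forest size
{100, 300} x depth {None, 10}; Bayesian ridge at library defaults), with the
same fold assignment reused across the grid.  Estimators come from
scikit-learn behind the module's interface.

Metrics follow chemometric convention: `R^2 = 1 - SSE/SST` about the
measured mean (deliberately *not* squared Pearson correlation — it
penalizes biased predictions), `RMSE` in % GPC, and `RRMSE = RMSE / mean
(measured) x 100`.  Negative validation R^2 (worse than predicting the
mean) is reported as 0; the raw value is kept internally.

The data-augmentation experiment fixes a validation set and trains on a
ten-row design — 50/150/276 measured samples, then 276 measured plus
50/100/200/300/500/700/997 simulated — with 10 random repeats per row and
per-row mean metrics, reproducing the structure of the augmentation curve.

## Mixed-model GWAS

Association uses the standard mixed linear model

    y = X alpha + Q beta + u + e,  u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with SNP dosages X (0/1/2, missing mean-imputed per SNP), principal-
component structure covariates Q, and a VanRaden method-1 genomic
relationship matrix K.  SNP QC retains markers with MAF > 0.05 and call
rate > 0.90.  The variance ratio is REML-estimated once under the null
model after eigendecomposition of K (the P3D/EMMAX approximation;
per-SNP re-estimation is available behind a flag) and each SNP is tested
by a t-test in the whitened model.  With K = I and no covariates this
reduces exactly to per-SNP ordinary least squares.  A Bonferroni threshold
(0.01/n) is computed and reported, but the operative default is
-log10 p = 4, reflecting the moderate power of GPC association panels.

Locus calling follows LD-decay clumping: significant SNPs on one
chromosome merge while consecutive significant SNPs are closer than 200 kb;
a locus reports its minimum-p member as lead SNP only when it contains at
least 4 significant SNPs ("more than 3"; the count and a stricter
map-adjacency variant are configurable).  Two lead lists are compared by
greedy nearest-first one-to-one matching within 100 kb.

`mlm_scan(..., loco=True)` rebuilds K per chromosome from all other
chromosomes (leave-one-chromosome-out).  This matters at desk scale: with
a 500-SNP panel, a trait-linked haplotype block is a few percent of an
all-SNP K and partially absorbs its own association signal (proximal
contamination), whereas in a resequencing panel of several hundred thousand
markers the same block is a negligible fraction of K.  The recovery
analyses and the orchestrated pipeline therefore use LOCO; the plain
all-SNP K remains the default of `mlm_scan` itself.

## Synthetic data: what it emulates, and what it does not

**Spectra.** Absorbance = smooth low-order polynomial baseline + fixed
Gaussian absorption features near 1200, 1450, 1800 and 1950 nm (O-H and
C-H overtones of starch, sugars and lignin; widths 40-55 nm) + protein
features at 1510 and 1690 nm whose depth is `0.02 x GPC` absorbance units +
a per-sample baseline offset (variety effect, SD 0.02) + band-independent
noise (SD 0.01).  GPC is truncated-normal with mean 5.7 %, SD 0.45 %,
bounds [4, 8] — a plausible japonica panel distribution.  The generator
does not model scattering physics, water-band saturation or
instrument-specific stray light; passing tests show the pipeline recovers
a linear trait-to-feature encoding under realistic noise, not that it
calibrates any particular instrument.

**Hypercubes.** Grain pixels carry the grain spectrum (per-pixel brightness
offsets shared across bands, as grain orientation and packing mainly shift
overall reflectance); the background is flat at ~10 % reflectance (black
cardboard); DN values are synthesized by inverting the calibration
equation with flat dark/white references.

**Genotypes.** A rice diversity panel is a set of essentially homozygous
inbred lines descended from a modest haplotype pool, so LD is blocky.  The
generator draws a global pool of 10 founder haplotypes in which runs of
SNPs tag the same founder bipartition (a new bipartition with probability
0.1 per 10 kb step, giving geometric haplotype blocks of ~100 kb and an
r^2 decay reaching ~0.05 by 200-300 kb, matching the LD-decay scale that
motivates the 200 kb locus rule); every bipartition splits the pool, as a
polymorphic site must.  Individuals are recombinant mosaics (mean segment
200 kb) sampled mostly (85 %) from their own subpopulation's half of the
pool — producing two subpopulations at Fst ~ 0.05 — doubled into homozygous
dosages, with per-site discordance 0.02 capping proxy r^2 near 0.9, as
observed in real panels.  The trait is the causal-dosage score rescaled so
the genetic variance share hits the target h^2, plus Gaussian environment.
By default the causal effect is planted at a well-tagged common SNP
(MAF >= 0.2 with >= 4 local proxies at r^2 >= 0.5): at real resequencing
density (~0.6 kb between markers) every causal variant has dozens of tags,
and conditioning the desk-scale fixture the same way tests the method
rather than the sparsity of a 10 kb-spaced toy map.  The generator does not
model coalescent genealogies, recombination hotspots or selection.

## Numerical choices

* Nearest-band lookup: minimum |lambda - center|, ties to the lower index.
* Min-max normalization rejects constant bands by name; inversion is exact
  to 1e-12.
* CWT prefactor is `1/sqrt(a)` (L2 convention); the `1/a` (L1) variant is a
  one-line change in the kernel construction.
* REML optimization is a bounded scalar search over log(delta) in [-8, 8]
  seeded by a 17-point grid; non-finite objectives raise.
* p-values are clipped away from zero at the float minimum before taking
  logs.
* Batch norm uses eps 1e-5, momentum 0.1, and running statistics for
  generation-time (eval) forward passes.
* All simulations, fold assignments, GAN training loops and samplers take
  explicit integer seeds; reruns are bitwise identical on one CPU.

## Problem sizes used in the tests

The bundled analyses run at desk scale by design: 256-band spectra with
276-sample training / 238-sample validation splits for calibration, a
64-sample set and 300 epochs for adversarial-training checks, and
200-line x 500-SNP panels for GWAS recovery.  These sizes exercise every
code path while keeping the full suite inside a coffee break.

## Known limitations

* The GAN at a few hundred epochs matches the trait distribution loosely;
  distribution-quality results comparable to long production runs need the
  full 8,000-10,000-epoch schedule.
* The P3D approximation holds variance components fixed across SNPs; for
  traits with very large single-locus effects exact per-SNP REML (available
  via `p3d=False`) is slightly more powerful.
* The ENVI reader covers the common header fields (BIL/BSQ/BIP, data types
  1-5 and 12) and single-file cubes only.
* `evaluate` clamps negative validation R^2 to zero for reporting, so model
  rankings among very poor models should use the retained raw value.
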