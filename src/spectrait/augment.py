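"""DCGAN data augmentation for joint spectrum + GPC vectors.

The training currency is a length-248 joint vector: a 247-band normalized
absorbance spectrum with the trait (GPC / 10) inserted immediately after
the band nearest the 1510 nm protein absorption feature.  A 1-D DCGAN
learns the joint distribution; sampling the trained generator yields
simulated spectrum+GPC pairs that extend small calibration sets.

Generator:  100-d Gaussian latent -> dense to 64 x 31 -> three x2
transposed convolutions (31 -> 62 -> 124 -> 248) with batch norm + ReLU,
sigmoid output so samples live in [0, 1] like the normalized inputs.
Discriminator: mirrored stride-2 convolutions with LeakyReLU(0.2), batch
norm on all but the first conv, dense head with a sigmoid real/simulated
probability.  Both are trained with binary cross-entropy and Adam
(lr 2e-4, beta1 0.5), batch size 8.

Generation-epoch selection is automated: checkpoints are compared to the
measured GPC distribution by the sum of absolute differences of six
summary statistics (min, Q1, median, mean, Q3, max) and the closest
checkpoint wins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .bands import BandGrid
from .preprocess import SpectrumSet

TRAIT_WAVELENGTH_NM = 1510.0
TRAIT_SCALE = 10.0


# ---------------------------------------------------------------------------
# Joint vectors


def trait_slot_for(grid: BandGrid, wavelength_nm: float = TRAIT_WAVELENGTH_NM) -> int:
    """Insertion index of the trait entry: just after the band nearest 1510 nm."""
    return grid.nearest_band(wavelength_nm) + 1


def build_joint_vector(spectrum: np.ndarray, gpc: float, trait_slot: int) -> np.ndarray:
    """Insert GPC/10 into a normalized spectrum; length grows by one."""
    s = np.asarray(spectrum, dtype=float)
    g = gpc / TRAIT_SCALE
    if not 0.0 <= g <= 1.0:
        raise ValueError(f"GPC/{TRAIT_SCALE:g} = {g} outside [0, 1]")
    if not 0 <= trait_slot <= s.size:
        raise ValueError("trait slot outside vector")
    return np.insert(s, trait_slot, g)


def split_joint_vector(v: np.ndarray, trait_slot: int,
                       expected_len: Optional[int] = None) -> tuple[np.ndarray, float]:
    """Inverse of :func:`build_joint_vector`: (spectrum, GPC in %)."""
    v = np.asarray(v, dtype=float)
    if expected_len is not None and v.size != expected_len:
        raise ValueError(f"joint vector length {v.size}, expected {expected_len}")
    gpc = float(v[trait_slot]) * TRAIT_SCALE
    return np.delete(v, trait_slot), gpc


def joint_matrix(spectrum_set: SpectrumSet,
                 trait_slot: Optional[int] = None) -> tuple[np.ndarray, int]:
    """Stack a normalized SpectrumSet into joint vectors."""
    if not spectrum_set.normalized:
        raise ValueError("joint vectors require a normalized spectrum set")
    slot = trait_slot_for(spectrum_set.grid) if trait_slot is None else trait_slot
    rows = [build_joint_vector(s, g, slot)
            for s, g in zip(spectrum_set.spectra, spectrum_set.gpc)]
    return np.asarray(rows), slot


# ---------------------------------------------------------------------------
# Config / networks


@dataclass
class GanConfig:
    latent_dim: int = 100
    output_len: int = 248
    batch_size: int = 8
    max_epochs: int = 10_000
    checkpoint_every: int = 500
    lr: float = 2e-4
    beta1: float = 0.5
    base_channels: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.latent_dim, self.output_len, self.batch_size) <= 0:
            raise ValueError("latent_dim, output_len, batch_size must be positive")
        if self.output_len % 8 != 0:
            raise ValueError("output_len must be divisible by 8 (three x2 upsamplings)")


def build_generator(config: GanConfig, rng: np.random.Generator) -> nn.Sequential:
    c = config.base_channels
    l0 = config.output_len // 8
    return nn.Sequential([
        nn.Dense(config.latent_dim, c * l0, rng),
        nn.Reshape((c, l0)),
        nn.BatchNorm1d(c),
        nn.ReLU(),
        nn.ConvTranspose1d(c, c // 2, rng),
        nn.BatchNorm1d(c // 2),
        nn.ReLU(),
        nn.ConvTranspose1d(c // 2, c // 4, rng),
        nn.BatchNorm1d(c // 4),
        nn.ReLU(),
        nn.ConvTranspose1d(c // 4, 1, rng),
        nn.Sigmoid(),
    ])


def build_discriminator(config: GanConfig, rng: np.random.Generator) -> nn.Sequential:
    c = config.base_channels
    l0 = config.output_len // 8
    return nn.Sequential([
        nn.Conv1d(1, c // 4, rng),
        nn.LeakyReLU(0.2),
        nn.Conv1d(c // 4, c // 2, rng),
        nn.BatchNorm1d(c // 2),
        nn.LeakyReLU(0.2),
        nn.Conv1d(c // 2, c, rng),
        nn.BatchNorm1d(c),
        nn.LeakyReLU(0.2),
        nn.Flatten(),
        nn.Dense(c * l0, 1, rng),
        nn.Sigmoid(),
    ])


@dataclass
class GeneratorCheckpoint:
    epoch: int
    state: list[dict]
    config: GanConfig


def save_checkpoint(ckpt: GeneratorCheckpoint, path: str | Path) -> None:
    arrays = {}
    for i, d in enumerate(ckpt.state):
        for k, v in d.items():
            arrays[f"{i}:{k}"] = v
    meta = json.dumps({"epoch": ckpt.epoch, "config": vars(ckpt.config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> GeneratorCheckpoint:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    n_layers = max(int(k.split(":")[0]) for k in data.files if ":" in k) + 1
    state: list[dict] = [{} for _ in range(n_layers)]
    for k in data.files:
        if ":" in k:
            i, name = k.split(":", 1)
            state[int(i)][name] = data[k]
    return GeneratorCheckpoint(meta["epoch"], state, GanConfig(**meta["config"]))


# ---------------------------------------------------------------------------
# Training


def train_dcgan(
    joint_vectors: np.ndarray,
    config: Optional[GanConfig] = None,
) -> tuple[list[GeneratorCheckpoint], pd.DataFrame]:
    """Adversarial training; returns generator checkpoints and a loss trace.

    The checkpoint list always includes epoch 0 (the untrained generator)
    and the final epoch.  Training is bitwise-reproducible for a fixed
    config seed and data.
    """
    X = np.asarray(joint_vectors, dtype=float)
    config = config or GanConfig(output_len=X.shape[1])
    if X.ndim != 2 or X.shape[1] != config.output_len:
        raise ValueError(f"joint vectors must be n x {config.output_len}")
    if X.shape[0] < config.batch_size:
        raise ValueError("need at least one full batch of training vectors")
    if X.min() < 0 or X.max() > 1:
        raise ValueError("joint vectors must lie in [0, 1]")

    rng = np.random.default_rng(config.seed)
    G = build_generator(config, rng)
    D = build_discriminator(config, rng)
    optG = nn.Adam(G, lr=config.lr, beta1=config.beta1)
    optD = nn.Adam(D, lr=config.lr, beta1=config.beta1)

    checkpoints = [GeneratorCheckpoint(0, G.state(), config)]
    trace = []
    n = X.shape[0]
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            real = X[perm[start:start + config.batch_size]][:, None, :]
            bs = real.shape[0]
            z = rng.normal(size=(bs, config.latent_dim))
            fake = G.forward(z, train=True)

            # --- discriminator step
            p_real = D.forward(real, train=True)
            loss_r, grad_r = nn.bce_loss_and_grad(p_real, 1.0)
            D.backward(grad_r)
            grads_real = [{k: g.copy() for k, g in lay.grads.items()} for lay in D.layers]
            p_fake = D.forward(fake, train=True)
            loss_f, grad_f = nn.bce_loss_and_grad(p_fake, 0.0)
            D.backward(grad_f)
            for lay, gr in zip(D.layers, grads_real):
                for k in lay.grads:
                    lay.grads[k] = lay.grads[k] + gr[k]
            optD.step()

            # --- generator step (fresh noise, push D(fake) toward 1)
            z = rng.normal(size=(bs, config.latent_dim))
            fake = G.forward(z, train=True)
            p_fake = D.forward(fake, train=True)
            loss_g, grad = nn.bce_loss_and_grad(p_fake, 1.0)
            grad_fake = D.backward(grad)
            G.backward(grad_fake)
            optG.step()

            d_losses.append(loss_r + loss_f)
            g_losses.append(loss_g)
        d_mean, g_mean = float(np.mean(d_losses)), float(np.mean(g_losses))
        if not (np.isfinite(d_mean) and np.isfinite(g_mean)):
            raise RuntimeError(f"adversarial training diverged at epoch {epoch}")
        trace.append({"epoch": epoch, "d_loss": d_mean, "g_loss": g_mean})
        if epoch % config.checkpoint_every == 0 or epoch == config.max_epochs:
            checkpoints.append(GeneratorCheckpoint(epoch, G.state(), config))
    return checkpoints, pd.DataFrame(trace)


def generate_simulated_set(
    checkpoint: GeneratorCheckpoint,
    n: int,
    grid: BandGrid,
    seed: int = 0,
    trait_slot: Optional[int] = None,
) -> SpectrumSet:
    """Sample n joint vectors from a generator checkpoint and split them."""
    if n < 1:
        raise ValueError("n must be >= 1")
    config = checkpoint.config
    if config.output_len != len(grid) + 1:
        raise ValueError("checkpoint output length does not match grid + trait")
    rng = np.random.default_rng(seed)
    G = build_generator(config, np.random.default_rng(0))
    G.load_state(checkpoint.state)
    z = rng.normal(size=(n, config.latent_dim))
    joint = G.forward(z, train=False)[:, 0, :]
    slot = trait_slot_for(grid) if trait_slot is None else trait_slot
    spectra = np.empty((n, len(grid)))
    gpc = np.empty(n)
    for i in range(n):
        spectra[i], gpc[i] = split_joint_vector(joint[i], slot, config.output_len)
    return SpectrumSet(spectra, gpc, grid, provenance="simulated", normalized=True)


# ---------------------------------------------------------------------------
# Similarity diagnostics and epoch selection


@dataclass
class SimilarityReport:
    epoch: int
    real_summary: dict[str, float]
    sim_summary: dict[str, float]
    distance: float


def six_number_summary(x: np.ndarray) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"min": float(x.min()), "q1": float(q1), "median": float(med),
            "mean": float(x.mean()), "q3": float(q3), "max": float(x.max())}


def gpc_similarity_report(real_gpc: np.ndarray, sim_gpc: np.ndarray,
                          epoch: int = -1) -> SimilarityReport:
    """Distance = sum of |differences| of the six summary statistics."""
    rs = six_number_summary(real_gpc)
    ss = six_number_summary(sim_gpc)
    distance = float(sum(abs(rs[k] - ss[k]) for k in rs))
    return SimilarityReport(epoch, rs, ss, distance)


def remove_gpc_outliers(spectrum_set: SpectrumSet, iqr_factor: float = 1.5) -> SpectrumSet:
    """Drop generated samples whose GPC falls outside Tukey IQR fences."""
    g = spectrum_set.gpc
    q1, q3 = np.percentile(g, [25, 75])
    lo, hi = q1 - iqr_factor * (q3 - q1), q3 + iqr_factor * (q3 - q1)
    keep = (g >= lo) & (g <= hi)
    return SpectrumSet(
        spectrum_set.spectra[keep], g[keep], spectrum_set.grid,
        sample_ids=[s for s, k in zip(spectrum_set.sample_ids, keep) if k],
        provenance=spectrum_set.provenance,
        normalized=spectrum_set.normalized,
        norm_params=spectrum_set.norm_params,
    )


def select_epoch(
    checkpoints: Sequence[GeneratorCheckpoint],
    real_gpc: np.ndarray,
    grid: BandGrid,
    n_sim: int = 200,
    seed: int = 0,
) -> tuple[GeneratorCheckpoint, list[SimilarityReport]]:
    """Pick the checkpoint whose generated GPC distribution is closest to
    the measured one (minimum six-summary distance; ties -> earlier epoch)."""
    reports = []
    for ckpt in checkpoints:
        sim = generate_simulated_set(ckpt, n_sim, grid, seed=seed)
        reports.append(gpc_similarity_report(real_gpc, sim.gpc, epoch=ckpt.epoch))
    best = min(range(len(reports)), key=lambda i: (reports[i].distance, i))
    return checkpoints[best], reports
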