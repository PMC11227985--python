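"""End-to-end orchestration of the GPC estimation + GWAS workflow.

``run_pipeline`` executes the full chain on synthetic data with known
ground truth: genotype simulation -> GPC -> spectra -> normalization ->
DCGAN augmentation -> wavelet features -> PLSR calibration -> GWAS of
measured and estimated GPC -> lead-SNP overlap.  Every stage is a pure
function of (inputs, config, seed); a manifest records the seed and a
parameter hash so reruns are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import augment, gwas, models, simulate, wavelets
from .preprocess import SpectrumSet, trim_and_normalize, write_spectra_csv

log = logging.getLogger("spectrait.pipeline")


@dataclass
class PipelineConfig:
    """All stage parameters with workflow defaults pre-filled."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    # population / simulation sizes
    n_individuals: int = 200
    n_snps: int = 500
    n_validation: int = 120
    causal_variance: float = 0.25
    noise_sd: float = 0.01
    # augmentation
    gan_epochs: int = 300
    gan_checkpoint_every: int = 100
    n_simulated: int = 200
    # features
    scales: tuple[int, ...] = (2, 3, 4, 5)
    top_fraction: float = 0.05
    use_rfe: bool = True
    # modelling
    algorithm: str = "PLSR"
    n_train: int = 140
    # gwas
    pcs: int = 3
    loco: bool = True
    threshold_neglog10: float = 4.0
    locus_kb: float = 200.0
    min_run: int = 4
    overlap_kb: float = 100.0
    # stage toggles
    run_augment: bool = True
    run_gwas: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in raw:
            raw["scales"] = tuple(raw["scales"])
        return cls(**raw)

    def param_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages; returns a report dict and writes outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "param_hash": config.param_hash()}
    rng_seed = config.seed

    # --- simulate genotypes + trait -> spectra -----------------------------
    t0 = _stage("simulate")
    h2 = config.causal_variance
    geno, gpc, truth = simulate.simulate_genotypes_with_trait(
        n_ind=config.n_individuals, n_snp=config.n_snps,
        genetics=simulate.TraitGenetics(h2=h2),
        seed=rng_seed,
    )
    params = simulate.SpectralModelParams(noise_sd=config.noise_sd)
    measured, _ = simulate.simulate_spectrum_set(
        config.n_individuals, params, gpc_values=gpc, seed=rng_seed + 1)
    val_set, _ = simulate.simulate_spectrum_set(
        config.n_validation, params, seed=rng_seed + 2)
    write_spectra_csv(measured, out / "spectra.csv")
    report["n_individuals"] = config.n_individuals
    report["causal_ids"] = truth["causal_ids"]

    # --- preprocess: trim + normalize --------------------------------------
    _stage("preprocess")
    norm = trim_and_normalize(measured)
    lo, hi = norm.norm_params
    keep = np.searchsorted(measured.grid.wavelengths_nm,
                           norm.grid.wavelengths_nm)
    val_norm = SpectrumSet(
        np.clip((val_set.spectra[:, keep] - lo) / (hi - lo), 0.0, 1.0),
        val_set.gpc, norm.grid, provenance="measured", normalized=True,
        norm_params=(lo, hi),
    )

    # --- augment ------------------------------------------------------------
    sim_set = None
    if config.run_augment:
        _stage("augment")
        joint, slot = augment.joint_matrix(norm)
        gan_cfg = augment.GanConfig(
            output_len=joint.shape[1], max_epochs=config.gan_epochs,
            checkpoint_every=config.gan_checkpoint_every, seed=rng_seed,
        )
        ckpts, trace = augment.train_dcgan(joint, gan_cfg)
        trace.to_csv(out / "gan_loss.csv", index=False)
        best, reports = augment.select_epoch(
            ckpts, norm.gpc, norm.grid, n_sim=config.n_simulated, seed=rng_seed)
        sim_set = augment.generate_simulated_set(
            best, config.n_simulated, norm.grid, seed=rng_seed + 3)
        sim_set = augment.remove_gpc_outliers(sim_set)
        write_spectra_csv(sim_set, out / "sim.csv")
        report["gan_selected_epoch"] = best.epoch
        report["gan_similarity"] = [
            {"epoch": r.epoch, "distance": r.distance} for r in reports]

    # --- wavelet features ----------------------------------------------------
    _stage("features")
    wf = wavelets.cwt_transform(norm, config.scales)
    corr = wavelets.feature_gpc_correlations(wf, norm.gpc)
    top = wavelets.select_top_fraction(wf, corr, config.top_fraction)
    subset = (wavelets.rfe_optimal_subset(wf, top, norm.gpc, seed=rng_seed)
              if config.use_rfe else top)
    (out / "features.json").write_text(json.dumps({
        "labels": subset.labels,
        "correlations": list(map(float, subset.correlations)),
        "provenance": subset.provenance,
    }, indent=1))
    report["n_features"] = len(subset.labels)

    wf_val = wavelets.cwt_transform(val_norm, config.scales)
    X_meas = wavelets.feature_matrix_for(wf, subset)
    X_val = wavelets.feature_matrix_for(wf_val, subset)

    # --- models: estimated value 1 (measured only) and 2 (augmented) --------
    _stage("train")
    rng = np.random.default_rng(rng_seed + 4)
    tr_idx = rng.choice(config.n_individuals, size=config.n_train, replace=False)
    m1 = models.fit_regression(X_meas[tr_idx], norm.gpc[tr_idx],
                               config.algorithm, seed=rng_seed)
    est1 = m1.predict(X_meas)
    metrics1 = models.evaluate(m1.predict(X_val), val_norm.gpc)
    report["estimated_value_1"] = metrics1.as_dict()

    est2 = None
    if sim_set is not None and sim_set.n_samples >= 2:
        wf_sim = wavelets.cwt_transform(sim_set, config.scales)
        X_sim = wavelets.feature_matrix_for(wf_sim, subset)
        X_aug = np.vstack([X_meas[tr_idx], X_sim])
        y_aug = np.concatenate([norm.gpc[tr_idx], sim_set.gpc])
        m2 = models.fit_regression(X_aug, y_aug, config.algorithm, seed=rng_seed)
        est2 = m2.predict(X_meas)
        metrics2 = models.evaluate(m2.predict(X_val), val_norm.gpc)
        report["estimated_value_2"] = metrics2.as_dict()
    preds = pd.DataFrame({"sample_id": measured.sample_ids, "measured": gpc,
                          "estimated_1": est1})
    if est2 is not None:
        preds["estimated_2"] = est2
    preds.to_csv(out / "predictions.csv", index=False)

    # --- gwas ----------------------------------------------------------------
    if config.run_gwas:
        _stage("gwas")
        geno_qc, qc_report = gwas.snp_qc(geno)
        K = gwas.kinship_matrix(geno_qc)
        Q = gwas.structure_covariates(geno_qc, q=config.pcs)
        report["qc"] = qc_report
        traits = {"measured": gpc, "estimated_1": est1}
        if est2 is not None:
            traits["estimated_2"] = est2
        leads = {}
        for name, y in traits.items():
            res = gwas.mlm_scan(y, geno_qc, Q=Q, K=K, loco=config.loco)
            res = gwas.call_loci(res, config.threshold_neglog10,
                                 config.locus_kb, config.min_run)
            gwas.write_association_tsv(res, out / f"gwas_{name}.tsv")
            leads[name] = res.lead_snps
            report[f"leads_{name}"] = (
                [] if res.lead_snps is None else list(res.lead_snps["id"]))
            if config.make_plots:
                gwas.manhattan_plot(res, out / f"manhattan_{name}.png")
                gwas.qq_plot(res, out / f"qq_{name}.png")
        overlaps = {}
        for name in [k for k in traits if k != "measured"]:
            shared = gwas.compare_leads(leads["measured"], leads[name],
                                        config.overlap_kb)
            shared.to_csv(out / f"overlap_measured_vs_{name}.csv", index=False)
            overlaps[name] = shared.to_dict("records")
        report["lead_overlaps"] = overlaps

    manifest = {
        "seed": config.seed,
        "param_hash": config.param_hash(),
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
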