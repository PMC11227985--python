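"""Mixed-linear-model GWAS of grain protein content.

The association model is the standard MLM

    y = X alpha + Q beta + u + e,   u ~ N(0, sigma_g^2 K),  e ~ N(0, sigma_e^2 I)

with SNP dosage X, population-structure covariates Q (genotype principal
components) and a VanRaden genomic relationship matrix K.  Variance
components are estimated once by REML under the null model (P3D/EMMAX
approximation): after eigendecomposing K the model is rotated into
independent coordinates and each SNP is tested by weighted least squares
with a t-test on its effect.  With K = I this reduces exactly to per-SNP
ordinary least squares.

Locus calling follows LD-decay-based clumping: significant SNPs
(-log10 p >= 4 by default) closer than 200 kb on the same chromosome merge
into a locus; a locus reports a lead SNP (its strongest member) only when
it contains at least four significant SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class GenotypeMatrix:
    """individuals x SNPs dosage matrix (0/1/2, NaN = missing) with a map."""

    dosages: np.ndarray
    snp_map: pd.DataFrame          # columns: chrom, pos, id
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be individuals x SNPs")
        if len(self.snp_map) != self.dosages.shape[1]:
            raise ValueError("SNP map length must equal SNP count")
        for col in ("chrom", "pos", "id"):
            if col not in self.snp_map.columns:
                raise ValueError(f"SNP map missing column {col!r}")
        pos = self.snp_map.groupby("chrom", sort=False)["pos"]
        if not pos.apply(lambda s: bool(np.all(np.diff(s) >= 0))).all():
            raise ValueError("positions must be nondecreasing within chromosome")
        if not self.sample_ids:
            self.sample_ids = [f"I{i:04d}" for i in range(self.dosages.shape[0])]

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class GwasResult:
    table: pd.DataFrame            # chrom, pos, id, beta, se, p, neglog10p
    threshold_neglog10: float
    loci: list[dict] = field(default_factory=list)
    lead_snps: pd.DataFrame | None = None
    bonferroni_neglog10: float | None = None


# ---------------------------------------------------------------------------
# I/O


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Biallelic SNPs from a VCF as alt-allele dosages."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, chroms, poss, ids = [], [], [], []
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
        dos = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        ids.append(var.ID or f"SNP{var.CHROM}.{var.POS}")
    if not rows:
        raise ValueError("no biallelic SNPs in VCF")
    snp_map = pd.DataFrame({"chrom": chroms, "pos": poss, "id": ids})
    return GenotypeMatrix(np.asarray(rows).T, snp_map, sample_ids=samples)


def read_dosage_csv(dosage_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Dosage CSV (rows = individuals, first column = sample id) + SNP map CSV."""
    dos = pd.read_csv(dosage_path, index_col=0)
    snp_map = pd.read_csv(map_path)
    return GenotypeMatrix(dos.to_numpy(float), snp_map,
                          sample_ids=[str(s) for s in dos.index])


def write_association_tsv(result: GwasResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC and model components


def snp_qc(
    geno: GenotypeMatrix, maf_min: float = 0.05, call_min: float = 0.90
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Retain SNPs with MAF > maf_min and call rate > call_min."""
    D = geno.dosages
    call_rate = 1.0 - np.isnan(D).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p_alt = np.nanmean(D, axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    maf = np.where(np.isnan(maf), 0.0, maf)
    keep = (maf > maf_min) & (call_rate > call_min)
    report = {
        "n_input": geno.n_snps,
        "n_fail_maf": int((~(maf > maf_min)).sum()),
        "n_fail_call": int((~(call_rate > call_min)).sum()),
        "n_retained": int(keep.sum()),
    }
    if not keep.any():
        raise ValueError("QC removed every SNP")
    return (
        GenotypeMatrix(D[:, keep], geno.snp_map.loc[keep].reset_index(drop=True),
                       sample_ids=list(geno.sample_ids)),
        report,
    )


def _imputed_centered(geno: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per SNP; return (centered matrix, freqs)."""
    D = geno.dosages.copy()
    mean = np.nanmean(D, axis=0)
    nan = np.isnan(D)
    D[nan] = np.broadcast_to(mean, D.shape)[nan]
    return D - mean, mean / 2.0


def kinship_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    K = Z Z' / (2 sum p_j (1 - p_j)) with Z the mean-centered dosage matrix.
    """
    Z, p = _imputed_centered(geno)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic; kinship undefined")
    K = Z @ Z.T / denom
    return (K + K.T) / 2.0


def structure_covariates(geno: GenotypeMatrix, q: int = 3) -> np.ndarray:
    """First q principal components of the centered dosage matrix.

    Deterministic sign convention: the largest-magnitude loading of each
    component is made positive.
    """
    if q >= geno.n_individuals:
        raise ValueError("q must be smaller than the number of individuals")
    Z, _ = _imputed_centered(geno)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    pcs = U[:, :q] * s[:q]
    for j in range(q):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


# ---------------------------------------------------------------------------
# Mixed-model scan


def _reml_neg_loglik(log_delta: float, s: np.ndarray, yr: np.ndarray,
                     Xr: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = delta * s + 1.0
    n, p = Xr.shape
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    XtWy = Xw.T @ yr
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    rss = float(r @ (r / w))
    if rss <= 0:
        return np.inf
    sigma2 = rss / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(sigma2) + np.sum(np.log(w)) + logdet_xwx)


def mlm_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    Q: Optional[np.ndarray] = None,
    K: Optional[np.ndarray] = None,
    p3d: bool = True,
    loco: bool = False,
) -> GwasResult:
    """Per-SNP mixed-model association p-values.

    The variance ratio delta = sigma_g^2 / sigma_e^2 is REML-estimated under
    the null (intercept + Q) and held fixed across SNPs (P3D); with
    ``p3d=False`` it is re-estimated for every SNP.  Each SNP effect is
    tested by a t-test in the rotated (whitened) model, so the reduction
    K = I, Q = None recovers ordinary least squares exactly.

    ``loco=True`` rebuilds the kinship per chromosome from all OTHER
    chromosomes (leave-one-chromosome-out), avoiding proximal contamination
    — with small marker panels a single trait-linked haplotype block can be
    a sizeable fraction of an all-SNP kinship and absorb its own signal.
    An explicitly passed ``K`` is ignored in LOCO mode.
    """
    if loco:
        return _mlm_scan_loco(y, geno, Q, p3d)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != geno.n_individuals:
        raise ValueError("phenotype length must match individuals")
    if K is None:
        K = kinship_matrix(geno)
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("K shape mismatch")
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    s = np.clip(s, 0.0, None)

    X0 = np.ones((n, 1)) if Q is None else np.column_stack([np.ones(n), Q])
    if np.linalg.matrix_rank(X0) < X0.shape[1]:
        raise ValueError("singular fixed-effect design (intercept + Q)")
    yr = U.T @ y
    X0r = U.T @ X0

    def fit_delta(Xr: np.ndarray) -> float:
        grid = np.linspace(-8.0, 8.0, 17)
        vals = [_reml_neg_loglik(g, s, yr, Xr) for g in grid]
        g0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            _reml_neg_loglik, bounds=(g0 - 1.5, g0 + 1.5), args=(s, yr, Xr),
            method="bounded", options={"xatol": 1e-6},
        )
        if not np.isfinite(res.fun):
            raise RuntimeError("REML failed to converge (non-finite objective)")
        return float(np.exp(res.x))

    delta0 = fit_delta(X0r)

    Dimp, _ = _imputed_centered(geno)
    Gr = U.T @ (Dimp + 0.0)   # centered, imputed dosages in rotated space
    p0 = X0r.shape[1]
    betas = np.empty(geno.n_snps)
    ses = np.empty(geno.n_snps)
    pvals = np.empty(geno.n_snps)
    for j in range(geno.n_snps):
        Xr = np.column_stack([X0r, Gr[:, j]])
        delta = delta0 if p3d else fit_delta(Xr)
        w = delta * s + 1.0
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        try:
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            betas[j], ses[j], pvals[j] = np.nan, np.nan, 1.0
            continue
        beta = XtWX_inv @ (Xw.T @ yr)
        r = yr - Xr @ beta
        df = n - (p0 + 1)
        sigma2 = float(r @ (r / w)) / df
        se = np.sqrt(sigma2 * XtWX_inv[-1, -1])
        t = beta[-1] / se
        betas[j], ses[j] = beta[-1], se
        pvals[j] = 2.0 * stats.t.sf(abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    table = geno.snp_map.copy()
    table["beta"] = betas
    table["se"] = ses
    table["p"] = pvals
    table["neglog10p"] = -np.log10(pvals)
    bonf = -np.log10(0.01 / geno.n_snps)
    return GwasResult(table=table, threshold_neglog10=4.0,
                      bonferroni_neglog10=bonf)


def _mlm_scan_loco(y, geno, Q, p3d) -> GwasResult:
    chroms = geno.snp_map["chrom"].to_numpy()
    unique = list(dict.fromkeys(chroms))
    if len(unique) < 2:
        return mlm_scan(y, geno, Q=Q, K=None, p3d=p3d, loco=False)
    pieces = []
    for chrom in unique:
        on = chroms == chrom
        sub = GenotypeMatrix(geno.dosages[:, on],
                             geno.snp_map.loc[on].reset_index(drop=True),
                             sample_ids=list(geno.sample_ids))
        rest = GenotypeMatrix(geno.dosages[:, ~on],
                              geno.snp_map.loc[~on].reset_index(drop=True),
                              sample_ids=list(geno.sample_ids))
        K_c = kinship_matrix(rest)
        res_c = mlm_scan(y, sub, Q=Q, K=K_c, p3d=p3d, loco=False)
        res_c.table.index = np.flatnonzero(on)
        pieces.append(res_c.table)
    table = pd.concat(pieces).sort_index().reset_index(drop=True)
    bonf = -np.log10(0.01 / geno.n_snps)
    return GwasResult(table=table, threshold_neglog10=4.0,
                      bonferroni_neglog10=bonf)


# ---------------------------------------------------------------------------
# Locus calling and lead comparison


def call_loci(
    result: GwasResult,
    threshold_neglog10: float = 4.0,
    locus_kb: float = 200.0,
    min_run: int = 4,
    strict_map_adjacency: bool = False,
) -> GwasResult:
    """Merge significant SNPs into loci and pick lead SNPs.

    Significant SNPs on one chromosome merge while consecutive significant
    SNPs are closer than ``locus_kb``.  A locus yields a lead SNP (its
    minimum-p member) only when it holds at least ``min_run`` significant
    SNPs; with ``strict_map_adjacency`` the run must also be uninterrupted
    by non-significant SNPs in full map order.
    """
    tab = result.table
    sig = tab[tab["neglog10p"] >= threshold_neglog10]
    loci: list[dict] = []
    leads: list[dict] = []
    max_gap = locus_kb * 1000.0
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        cluster: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cluster and row["pos"] - cluster[-1]["pos"] >= max_gap:
                loci.append(_finish_locus(cluster, tab, min_run,
                                          strict_map_adjacency, leads))
                cluster = []
            cluster.append(row)
        if cluster:
            loci.append(_finish_locus(cluster, tab, min_run,
                                      strict_map_adjacency, leads))
    result.loci = loci
    result.lead_snps = pd.DataFrame(
        leads, columns=["chrom", "pos", "id", "p", "neglog10p"]
    )
    result.threshold_neglog10 = threshold_neglog10
    return result


def _finish_locus(cluster, full_table, min_run, strict, leads) -> dict:
    chrom = cluster[0]["chrom"]
    ids = [r["id"] for r in cluster]
    locus = {
        "chrom": chrom,
        "start": int(cluster[0]["pos"]),
        "end": int(cluster[-1]["pos"]),
        "n_snps": len(cluster),
        "snp_ids": ids,
        "lead": None,
    }
    qualifies = len(cluster) >= min_run
    if qualifies and strict:
        # require min_run members adjacent in full map order
        chrom_tab = full_table[full_table["chrom"] == chrom].reset_index(drop=True)
        map_idx = chrom_tab.index[chrom_tab["id"].isin(ids)].to_numpy()
        runs = np.split(map_idx, np.flatnonzero(np.diff(map_idx) != 1) + 1)
        qualifies = max(len(r) for r in runs) >= min_run
    if qualifies:
        best = min(cluster, key=lambda r: r["p"])
        locus["lead"] = best["id"]
        leads.append({k: best[k] for k in ("chrom", "pos", "id", "p", "neglog10p")})
    return locus


def compare_leads(
    leads_a: pd.DataFrame, leads_b: pd.DataFrame, window_kb: float = 100.0
) -> pd.DataFrame:
    """Greedy one-to-one matching of lead SNPs within ``window_kb``.

    Pairs on the same chromosome are matched nearest-first; each lead can be
    shared at most once.  Returns a table of shared pairs with distances.
    """
    pairs = []
    if leads_a is None or leads_b is None or leads_a.empty or leads_b.empty:
        return pd.DataFrame(columns=["chrom", "id_a", "pos_a", "id_b", "pos_b",
                                     "distance_bp"])
    for ia, ra in leads_a.iterrows():
        for ib, rb in leads_b.iterrows():
            if ra["chrom"] != rb["chrom"]:
                continue
            d = abs(int(ra["pos"]) - int(rb["pos"]))
            if d <= window_kb * 1000.0:
                pairs.append((d, ia, ib, ra, rb))
    pairs.sort(key=lambda t: t[0])
    used_a: set = set()
    used_b: set = set()
    rows = []
    for d, ia, ib, ra, rb in pairs:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append({"chrom": ra["chrom"], "id_a": ra["id"], "pos_a": int(ra["pos"]),
                     "id_b": rb["id"], "pos_b": int(rb["pos"]), "distance_bp": d})
    return pd.DataFrame(rows, columns=["chrom", "id_a", "pos_a", "id_b", "pos_b",
                                       "distance_bp"])


# ---------------------------------------------------------------------------
# Plots


def manhattan_plot(result: GwasResult, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0.0
    ticks, tick_labels = [], []
    for i, (chrom, grp) in enumerate(tab.groupby("chrom", sort=False)):
        x = grp["pos"].to_numpy(float) + offset
        ax.scatter(x, grp["neglog10p"], s=4,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks.append(offset + grp["pos"].mean())
        tick_labels.append(str(chrom))
        offset += grp["pos"].max() + 1e6
    ax.axhline(result.threshold_neglog10, color="red", ls="--", lw=0.8)
    ax.set_xticks(ticks, tick_labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qq_plot(result: GwasResult, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = np.sort(result.table["p"].to_numpy(float))
    exp = -np.log10((np.arange(1, p.size + 1) - 0.5) / p.size)
    obs = -np.log10(p)
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.plot(exp, obs, ".", ms=3)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "r--", lw=0.8)
    ax.set_xlabel("expected -log10(p)")
    ax.set_ylabel("observed -log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
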