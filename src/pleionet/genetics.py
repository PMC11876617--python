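"""Genotype QC, gene-window SNP partitioning, kinship and REML heritability.

Covers minor-allele-frequency filtering, LD-nearest-neighbor imputation,
LD pruning, per-site nucleotide diversity, strand-aware gene windows,
SNP-to-partition assignment, the realized-relationship kinship
K = XX'/n_p, single-kinship REML narrow-sense heritability via
eigendecomposition, size-matched gene-set permutation nulls, and the
three-condition module-selection rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import GenotypeMatrix

__all__ = [
    "maf_filter",
    "impute_nn_ld",
    "ld_r2",
    "ld_prune",
    "nucleotide_diversity",
    "gene_windows",
    "assign_snps_to_partition",
    "kinship",
    "KinshipMatrix",
    "reml_h2",
    "HeritabilityEstimate",
    "empirical_null_h2",
    "PartitionNull",
    "select_modules",
]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def _allele_freq(dosage: np.ndarray) -> np.ndarray:
    """Alt allele frequency per SNP; missing calls excluded."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(dosage, axis=0) / 2.0


def maf_filter(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> GenotypeMatrix:
    """Remove SNPs with minor allele frequency strictly below ``maf_min``."""
    p = _allele_freq(genotypes.dosage)
    maf = np.minimum(p, 1.0 - p)
    keep = np.where(~np.isnan(maf) & (maf >= maf_min))[0]
    return genotypes.subset_snps(keep)


def ld_r2(snp_i: np.ndarray, snp_j: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (complete cases)."""
    x = np.asarray(snp_i, dtype=float)
    y = np.asarray(snp_j, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def impute_nn_ld(genotypes: GenotypeMatrix, min_r2: float = 0.2) -> GenotypeMatrix:
    """Fill missing calls from the most LD-correlated SNP, else the mode.

    A missing call at SNP s for individual i takes individual i's genotype
    at the non-missing SNP with the highest complete-case r-squared to s;
    neighbors below ``min_r2`` are not trusted and the SNP's modal
    genotype is used instead.
    """
    D = genotypes.dosage.copy()
    n, m = D.shape
    missing_cols = np.where(np.isnan(D).any(axis=0))[0]
    for s in missing_cols:
        col = D[:, s]
        obs = ~np.isnan(col)
        if not obs.any():
            raise ValueError(f"SNP column {s} is entirely missing")
        vals, counts = np.unique(col[obs], return_counts=True)
        mode = vals[np.argmax(counts)]
        r2 = np.array(
            [ld_r2(col, D[:, t]) if t != s else np.nan for t in range(m)]
        )
        order = np.argsort(np.nan_to_num(r2, nan=-1.0))[::-1]
        for i in np.where(~obs)[0]:
            filled = False
            for t in order:
                if np.isnan(r2[t]) or r2[t] < min_r2:
                    break
                if not np.isnan(genotypes.dosage[i, t]):
                    D[i, s] = genotypes.dosage[i, t]
                    filled = True
                    break
            if not filled:
                D[i, s] = mode
    out = GenotypeMatrix(
        dosage=D,
        snps=genotypes.snps.copy(),
        individuals=list(genotypes.individuals),
        subpop=genotypes.subpop,
    )
    return out


def ld_prune(
    genotypes: GenotypeMatrix,
    r2_max: float = 0.7,
    window: int = 50,
    step: int = 5,
    unit: str = "snp",
) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained SNP indices.

    The window spans ``window`` consecutive SNPs (or base pairs with
    unit='bp') and advances by ``step``; within a window the later SNP of
    any pair with r-squared >= ``r2_max`` is dropped.  Deterministic and
    label-independent (position order only).
    """
    D = genotypes.dosage
    pos = genotypes.snps["pos"].to_numpy()
    m = D.shape[1]
    keep = np.ones(m, dtype=bool)
    if unit == "snp":
        windows = ((s, min(s + window, m)) for s in range(0, m, step))
    elif unit == "bp":
        # window spans `window` bp from each start SNP; start advances by
        # `step` SNPs so behaviour is defined even on sparse maps
        windows = (
            (i, int(np.searchsorted(pos, pos[i] + window, side="left")))
            for i in range(0, m, step)
        )
    else:
        raise ValueError("unit must be 'snp' or 'bp'")
    for lo, hi in windows:
        idx = [i for i in range(lo, hi) if keep[i]]
        if len(idx) < 2:
            continue
        block = D[:, idx]
        if np.isnan(block).any():
            r2_mat = np.array(
                [[ld_r2(block[:, a], block[:, b]) for b in range(len(idx))]
                 for a in range(len(idx))]
            )
        else:
            sd = block.std(axis=0)
            ok = sd > 0
            r2_mat = np.zeros((len(idx), len(idx)))
            if ok.sum() >= 2:
                sub = np.corrcoef(block[:, ok], rowvar=False)
                r2_mat[np.ix_(ok, ok)] = sub * sub
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if keep[idx[b]] and r2_mat[a, b] >= r2_max:
                    keep[idx[b]] = False
    return np.where(keep)[0]


def nucleotide_diversity(genotypes: GenotypeMatrix) -> pd.Series:
    """Per-SNP average pairwise difference between line calls.

    Lines are treated as haploid calls (inbred convention): dosage 0 and 2
    map to allele values 0 and 1, a heterozygous dosage contributes 0.5.
    pi is the mean absolute call difference over all line pairs.
    """
    D = genotypes.dosage
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least two individuals")
    pis = np.full(D.shape[1], np.nan)
    for s in range(D.shape[1]):
        calls = D[:, s][~np.isnan(D[:, s])] / 2.0
        k = len(calls)
        if k < 2:
            continue
        n0 = int(np.sum(calls == 0.0))
        nh = int(np.sum(calls == 0.5))
        n1 = int(np.sum(calls == 1.0))
        diff_sum = n0 * n1 * 1.0 + 0.5 * nh * (n0 + n1)
        pis[s] = diff_sum / (k * (k - 1) / 2.0)
    return pd.Series(pis, index=genotypes.snps["id"].to_numpy(), name="pi")


# ---------------------------------------------------------------------------
# windows and partitions
# ---------------------------------------------------------------------------


def gene_windows(
    gene_models: pd.DataFrame, up: int = 2000, down: int = 2000
) -> pd.DataFrame:
    """Strand-aware proximal windows around gene bodies (1-based, closed).

    For a + strand gene [start, end] the window is [start - up, end + down];
    for - strand, [start - down, end + up]; clamped at 1.  Malformed
    records (start > end, unknown strand) are skipped with a warning.
    """
    rows = []
    for rec in gene_models.itertuples(index=False):
        strand = getattr(rec, "strand", "+")
        if rec.start > rec.end or strand not in ("+", "-"):
            warnings.warn(f"skipping malformed gene record {rec.id}", stacklevel=2)
            continue
        if strand == "+":
            lo, hi = rec.start - up, rec.end + down
        else:
            lo, hi = rec.start - down, rec.end + up
        rows.append((rec.id, rec.chrom, max(lo, 1), hi))
    return pd.DataFrame(rows, columns=["gene", "chrom", "window_start", "window_end"])


def assign_snps_to_partition(
    genotypes: GenotypeMatrix, windows: pd.DataFrame
) -> np.ndarray:
    """Indices of SNPs falling within any window (closed interval, union)."""
    snp_chroms = set(genotypes.snps["chrom"].astype(str))
    offenders = sorted(set(windows["chrom"].astype(str)) - snp_chroms)
    if offenders:
        raise ValueError(f"window chromosomes absent from panel: {offenders}")
    pos = genotypes.snps["pos"].to_numpy()
    chrom = genotypes.snps["chrom"].astype(str).to_numpy()
    mask = np.zeros(len(pos), dtype=bool)
    for rec in windows.itertuples(index=False):
        mask |= (chrom == str(rec.chrom)) & (pos >= rec.window_start) & (
            pos <= rec.window_end
        )
    return np.where(mask)[0]


# ---------------------------------------------------------------------------
# kinship and REML
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    K: np.ndarray
    n_snps: int
    individuals: list[str]
    normalization: str = "allele-frequency standardized"


def kinship(
    genotypes: GenotypeMatrix, snp_subset: np.ndarray | None = None
) -> KinshipMatrix:
    """Realized relationship K = XX'/n_p from the standardized dosage matrix.

    Columns are centered at 2p and scaled by sqrt(2p(1-p)); monomorphic
    SNPs (zero scale) are dropped with a warning.  Requires a complete
    (imputed) panel.
    """
    D = genotypes.dosage if snp_subset is None else genotypes.dosage[:, snp_subset]
    if D.shape[1] == 0:
        raise ValueError("empty SNP subset")
    if np.isnan(D).any():
        raise ValueError("kinship requires a complete panel; impute first")
    p = D.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    poly = scale > 0
    if not poly.all():
        warnings.warn(
            f"dropping {int((~poly).sum())} monomorphic SNPs from kinship",
            stacklevel=2,
        )
    D = D[:, poly]
    if D.shape[1] == 0:
        raise ValueError("no polymorphic SNPs in subset")
    X = (D - 2.0 * p[poly]) / scale[poly]
    K = (X @ X.T) / X.shape[1]
    return KinshipMatrix(K=K, n_snps=X.shape[1], individuals=list(genotypes.individuals))


@dataclass
class HeritabilityEstimate:
    sigma_g2: float
    sigma_e2: float
    h2: float
    loglik: float
    converged: bool

    @property
    def sigma_p2(self) -> float:
        return self.sigma_g2 + self.sigma_e2


def _eigen_k(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, U = np.linalg.eigh(K)
    if s.min() < -1e-6 * max(abs(s.max()), 1.0):
        raise ValueError("kinship matrix is not PSD within tolerance")
    return np.clip(s, 0.0, None), U


def reml_h2(
    y: np.ndarray,
    K: np.ndarray | KinshipMatrix,
    X: np.ndarray | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
    ratio_bounds: tuple[float, float] = (1e-6, 1e6),
) -> HeritabilityEstimate:
    """Single-kinship REML via the eigendecomposition profile likelihood.

    The model y = Xb + g + e with g ~ N(0, sigma_g^2 K) and
    e ~ N(0, sigma_e^2 I) is profiled over the variance ratio
    r = sigma_g^2 / sigma_e^2 on a log scale; sigma_e^2 and the fixed
    effects are solved in closed form at each r.  X defaults to an
    intercept.  h2 = sigma_g^2 / sigma_p^2.  Pass a precomputed
    eigendecomposition of K via ``eig`` when scanning many phenotypes.
    """
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if Kmat.shape != (n, n):
        raise ValueError("y length does not match K")
    if np.std(y) == 0:
        raise ValueError("constant phenotype")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    s, U = _eigen_k(Kmat) if eig is None else eig
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(log_r: float) -> float:
        r = np.exp(log_r)
        w = r * s + 1.0
        Xw = Xt / w[:, None]
        xtx = Xt.T @ Xw
        beta = np.linalg.solve(xtx, Xw.T @ yt)
        resid = yt - Xt @ beta
        rss = float((resid / w) @ resid)
        sigma_e2 = rss / (n - p)
        sign, logdet = np.linalg.slogdet(xtx)
        if sign <= 0:
            return np.inf
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma_e2) + 1.0)
            + np.sum(np.log(w))
            + logdet
        )
        return -ll

    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    # compare against the boundaries (bounded Brent can sit near but not at)
    candidates = [(neg_restricted_ll(v), v) for v in (lo, hi)]
    candidates.append((res.fun, float(res.x)))
    best_nll, best_logr = min(candidates)
    r = float(np.exp(best_logr))
    w = r * s + 1.0
    Xw = Xt / w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    resid = yt - Xt @ beta
    sigma_e2 = float((resid / w) @ resid) / (n - p)
    sigma_g2 = r * sigma_e2
    # at the lower ratio bound the genetic component is effectively zero
    if best_logr <= lo + 1e-9:
        sigma_g2 = 0.0
    h2 = sigma_g2 / (sigma_g2 + sigma_e2) if sigma_g2 + sigma_e2 > 0 else 0.0
    return HeritabilityEstimate(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        h2=float(h2),
        loglik=-best_nll,
        converged=bool(getattr(res, "success", True)),
    )


# ---------------------------------------------------------------------------
# permutation nulls and module selection
# ---------------------------------------------------------------------------


@dataclass
class PartitionNull:
    partition: str
    observed_h2: float
    null_h2: np.ndarray
    percentile: float
    n_perm: int

    @property
    def null_mean(self) -> float:
        return float(self.null_h2.mean())


def _partition_h2(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    models: pd.DataFrame,
    genes: list[str],
    up: int,
    down: int,
    prune: bool,
    r2_max: float,
) -> float | None:
    sub = models[models["id"].isin(genes)]
    wins = gene_windows(sub, up=up, down=down)
    idx = assign_snps_to_partition(genotypes, wins)
    if len(idx) == 0:
        return None
    if prune:
        part = genotypes.subset_snps(idx)
        kept = ld_prune(part, r2_max=r2_max)
        part = part.subset_snps(kept)
    else:
        part = genotypes.subset_snps(idx)
    try:
        km = kinship(part)
    except ValueError:
        return None
    return reml_h2(y, km).h2


def empirical_null_h2(
    y: np.ndarray,
    genotypes: GenotypeMatrix,
    gene_models: pd.DataFrame,
    partition_genes: list[str],
    up: int = 2000,
    down: int = 2000,
    n_perm: int = 1000,
    seed: int = 0,
    prune: bool = True,
    r2_max: float = 0.7,
    label: str = "partition",
) -> PartitionNull:
    """Size-matched gene-set permutation null for a partition's h2.

    Each replicate draws as many genes as the partition from the universe
    with the partition's genes removed, builds their proximal-window SNP
    partition, prunes, computes kinship and REML h2.  The observed h2's
    percentile within the null is reported.
    """
    universe = [g for g in gene_models["id"] if g not in set(partition_genes)]
    if len(universe) < len(partition_genes):
        raise ValueError("gene universe too small for size-matched draws")
    obs = _partition_h2(
        y, genotypes, gene_models, list(partition_genes), up, down, prune, r2_max
    )
    if obs is None:
        raise ValueError("partition has no usable SNPs")
    rng = np.random.default_rng(seed)
    null = []
    while len(null) < n_perm:
        draw = list(rng.choice(universe, size=len(partition_genes), replace=False))
        h2 = _partition_h2(y, genotypes, gene_models, draw, up, down, prune, r2_max)
        if h2 is not None:
            null.append(h2)
    null = np.asarray(null)
    percentile = float(np.mean(null < obs) * 100.0)
    return PartitionNull(
        partition=label,
        observed_h2=obs,
        null_h2=null,
        percentile=percentile,
        n_perm=n_perm,
    )


def select_modules(
    module_stats: pd.DataFrame,
    genomewide_h2: float,
    p_cutoff: float = 0.05,
    share_threshold: float = 0.8,
) -> list[str]:
    """Modules passing the three selection conditions.

    Requires columns module, trait_p, observed_h2, null_mean.  A module is
    selected when (i) its module-trait correlation p < p_cutoff, (ii) its
    observed h2 exceeds its permutation-null mean, and (iii) its observed
    h2 is at least ``share_threshold`` of the genome-wide h2.
    """
    selected = []
    for rec in module_stats.itertuples(index=False):
        vals = (rec.trait_p, rec.observed_h2, rec.null_mean)
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in vals):
            warnings.warn(f"module {rec.module} missing statistics; skipped",
                          stacklevel=2)
            continue
        if (
            rec.trait_p < p_cutoff
            and rec.observed_h2 > rec.null_mean
            and rec.observed_h2 >= share_threshold * genomewide_h2
        ):
            selected.append(rec.module)
    return selected
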