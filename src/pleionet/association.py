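"""Phenotype BLUPs, phenotypic PCs, GBLUP, association and epistasis scans.

The replicated-field model fits genotype and block-within-year as random
effects (year fixed) by EM-REML and returns per-genotype BLUPs.  Scans
come in three flavors: a fixed-effect GLM F-test, a kinship mixed model
with null-model variance components and GLS per SNP, and a multivariate
likelihood-ratio test for joint (pleiotropic) effects with per-trait
variance-ratio whitening.  Multiplicity control is Benjamini-Hochberg
(partition scans, q < 0.2) or Bonferroni (candidate-gene scans,
alpha = 0.05).  The epistasis scan adds a peak-SNP x test-SNP interaction
to the mixed model and Wald-tests the additive x additive effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genetics import KinshipMatrix, _eigen_k, kinship, reml_h2
from .simulate import GenotypeMatrix

__all__ = [
    "fit_blups",
    "BlupResult",
    "phpc",
    "PhPCResult",
    "gblup",
    "GblupResult",
    "bic_select_pcs",
    "glm_association",
    "mlm_association",
    "multitrait_lrt",
    "leave_one_chrom_kinship",
    "bh_fdr",
    "bonferroni",
    "epistasis_scan",
]


# ---------------------------------------------------------------------------
# BLUPs (replicated field design)
# ---------------------------------------------------------------------------


@dataclass
class BlupResult:
    blups: pd.Series  # per-genotype BLUP
    grand_mean: float
    sigma_g2: float
    sigma_b2: float  # block within year
    sigma_e2: float
    n_iter: int
    converged: bool


def _incidence(labels: pd.Series) -> tuple[np.ndarray, list]:
    cats = list(pd.unique(labels))
    idx = {c: i for i, c in enumerate(cats)}
    Z = np.zeros((len(labels), len(cats)))
    Z[np.arange(len(labels)), [idx[v] for v in labels]] = 1.0
    return Z, cats


def fit_blups(
    records: pd.DataFrame,
    trait: str,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BlupResult:
    """EM-REML BLUPs for Y = mu + year + genotype + block(year) + error.

    Year enters as a fixed effect; genotype and block-nested-in-year are
    independent random effects.  Blocks are keyed as (year, block) so the
    same block label in different years is a distinct level.
    """
    df = records.dropna(subset=[trait])
    if len(df) < 2 or df["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and >= 2 observations")
    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    years = pd.get_dummies(df["year"].astype(str), drop_first=True).to_numpy(float)
    X = np.column_stack([np.ones(n), years]) if years.size else np.ones((n, 1))
    Zg, geno_levels = _incidence(df["genotype"])
    Zb, _ = _incidence(
        df["year"].astype(str).str.cat(df["block"].astype(str), sep="|")
    )
    q_g, q_b = Zg.shape[1], Zb.shape[1]
    p = X.shape[1]

    var_y = float(np.var(y, ddof=1))
    sg2, sb2, se2 = var_y / 3, var_y / 3, var_y / 3
    W = np.hstack([X, Zg, Zb])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C = WtW.copy()
        sl_g = slice(p, p + q_g)
        sl_b = slice(p + q_g, p + q_g + q_b)
        C[sl_g, sl_g] += np.eye(q_g) * (se2 / max(sg2, 1e-12))
        C[sl_b, sl_b] += np.eye(q_b) * (se2 / max(sb2, 1e-12))
        Cinv = np.linalg.inv(C)
        sol = Cinv @ Wty
        u_g = sol[sl_g]
        u_b = sol[sl_b]
        se2_new = (yty - float(sol @ Wty)) / (n - p)
        sg2_new = (float(u_g @ u_g) + se2_new * float(np.trace(Cinv[sl_g, sl_g]))) / q_g
        sb2_new = (float(u_b @ u_b) + se2_new * float(np.trace(Cinv[sl_b, sl_b]))) / q_b
        delta = max(abs(sg2_new - sg2), abs(sb2_new - sb2), abs(se2_new - se2))
        sg2, sb2, se2 = max(sg2_new, 1e-12), max(sb2_new, 1e-12), max(se2_new, 1e-12)
        if delta < tol:
            converged = True
            break
    # final solve at converged components
    C = WtW.copy()
    C[p : p + q_g, p : p + q_g] += np.eye(q_g) * (se2 / sg2)
    C[p + q_g :, p + q_g :] += np.eye(q_b) * (se2 / sb2)
    sol = np.linalg.solve(C, Wty)
    blups = pd.Series(sol[p : p + q_g], index=geno_levels, name=trait)
    return BlupResult(
        blups=blups.sort_index(),
        grand_mean=float(sol[0]),
        sigma_g2=sg2,
        sigma_b2=sb2,
        sigma_e2=se2,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# phenotypic PCs and GBLUP
# ---------------------------------------------------------------------------


@dataclass
class PhPCResult:
    scores: pd.DataFrame  # genotypes x components
    loadings: pd.DataFrame  # traits x components
    percent_variance: np.ndarray


def phpc(trait_blups: pd.DataFrame) -> PhPCResult:
    """PCA of centered, unit-variance trait BLUPs (PhPC1, PhPC2, ...)."""
    if trait_blups.shape[1] < 2 or trait_blups.shape[0] < 3:
        raise ValueError("need >= 2 traits and >= 3 genotypes")
    X = trait_blups.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant trait")
    Z = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2
    pct = var / var.sum() * 100.0
    comps = [f"PhPC{i + 1}" for i in range(len(s))]
    return PhPCResult(
        scores=pd.DataFrame(u * s, index=trait_blups.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=trait_blups.columns, columns=comps),
        percent_variance=pct,
    )


@dataclass
class GblupResult:
    gebv: pd.Series
    h2: float
    sigma_g2: float
    sigma_e2: float
    accuracy: float | None = None  # cor(GEBV, observed) on held-out lines


def gblup(
    y_train: pd.Series,
    K: KinshipMatrix,
    test_ids: list[str] | None = None,
    y_test: pd.Series | None = None,
) -> GblupResult:
    """GEBVs from a kinship BLUP model trained on observed lines.

    Variance components come from REML on the training block; GEBVs for
    every individual are sigma_g^2 K[:, train] V^-1 (y - mu) with
    V = sigma_g^2 K_train + sigma_e^2 I.  Held-out accuracy is the Pearson
    correlation of GEBV with observation on ``test_ids``.
    """
    ids = list(K.individuals)
    pos = {g: i for i, g in enumerate(ids)}
    train = [g for g in y_train.index if g in pos]
    ti = np.array([pos[g] for g in train])
    yv = y_train.loc[train].to_numpy(dtype=float)
    K_tt = K.K[np.ix_(ti, ti)]
    est = reml_h2(yv, K_tt)
    if est.sigma_g2 == 0:
        gebv = pd.Series(0.0, index=ids, name="gebv")
        warnings.warn("zero genetic variance: all GEBVs are 0", stacklevel=2)
        return GblupResult(gebv=gebv, h2=0.0, sigma_g2=0.0, sigma_e2=est.sigma_e2)
    V = est.sigma_g2 * K_tt + est.sigma_e2 * np.eye(len(ti))
    Vinv = np.linalg.inv(V)
    ones = np.ones(len(ti))
    mu = float(ones @ Vinv @ yv) / float(ones @ Vinv @ ones)
    alpha = Vinv @ (yv - mu)
    gebv_all = est.sigma_g2 * (K.K[:, ti] @ alpha)
    gebv = pd.Series(gebv_all, index=ids, name="gebv")
    acc = None
    if test_ids is not None and y_test is not None:
        held = [g for g in test_ids if g in pos and g in y_test.index]
        if len(held) >= 3:
            acc = float(np.corrcoef(gebv.loc[held], y_test.loc[held])[0, 1])
    return GblupResult(
        gebv=gebv, h2=est.h2, sigma_g2=est.sigma_g2, sigma_e2=est.sigma_e2,
        accuracy=acc,
    )


# ---------------------------------------------------------------------------
# covariate selection and scans
# ---------------------------------------------------------------------------


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rss.size == 0:  # rank deficient or saturated
        resid = y - X @ beta
        rss_val = float(resid @ resid)
    else:
        rss_val = float(rss[0])
    return rss_val, beta, rank


def _as_snp_matrix(snps, n: int) -> np.ndarray:
    """Coerce a SNP vector or matrix to shape (n, m)."""
    S = np.asarray(snps, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if S.shape[0] != n:
        raise ValueError("snp array length does not match phenotype")
    return S


def bic_select_pcs(y: np.ndarray, genotype_pcs: np.ndarray, k_max: int = 10) -> int:
    """Number of leading structure PCs minimizing BIC for y ~ 1 + PCs."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n <= k_max + 2:
        k_max = max(n - 3, 0)
        warnings.warn(f"k_max reduced to {k_max} for sample size", stacklevel=2)
    best_k, best_bic = 0, np.inf
    for k in range(k_max + 1):
        X = np.column_stack([np.ones(n), genotype_pcs[:, :k]])
        rss, _, _ = _ols_rss(X, y)
        bic = n * np.log(max(rss, 1e-300) / n) + (k + 1) * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, k
    return best_k


def _scan_frame(ids, effects, stats_, pvals, model: str) -> pd.DataFrame:
    out = pd.DataFrame(
        {"id": ids, "model": model, "effect": effects, "stat": stats_, "p": pvals}
    )
    ok = out["p"].notna()
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    out["q"] = q
    out["significant_fdr"] = out["q"] < 0.2
    return out


def glm_association(
    y: np.ndarray,
    snps: np.ndarray,
    covariates: np.ndarray | None = None,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP F-test of the dosage term added to a covariate-only model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    S = _as_snp_matrix(snps, n)
    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.column_stack([X0, covariates])
    rss0, _, rank0 = _ols_rss(X0, y)
    ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(S.shape[1])]
    effects, fstats, pvals = [], [], []
    for j in range(S.shape[1]):
        s = S[:, j]
        X1 = np.column_stack([X0, s])
        rss1, beta, rank1 = _ols_rss(X1, y)
        if np.std(s) == 0 or rank1 <= rank0:
            effects.append(np.nan)
            fstats.append(np.nan)
            pvals.append(np.nan)
            continue
        df2 = n - rank1
        F = (rss0 - rss1) / (rss1 / df2)
        effects.append(float(beta[-1]))
        fstats.append(float(F))
        pvals.append(float(stats.f.sf(F, 1, df2)))
    return _scan_frame(ids, effects, fstats, pvals, "GLM")


def _whiten(K: KinshipMatrix | np.ndarray, y, X0, eig=None):
    """Null-model variance components, then GLS whitening transform."""
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    s, U = _eigen_k(Kmat) if eig is None else eig
    est = reml_h2(y, Kmat, X=X0, eig=(s, U))
    ratio = est.sigma_g2 / est.sigma_e2 if est.sigma_e2 > 0 else 0.0
    w = ratio * s + 1.0
    T = (U / np.sqrt(w)).T  # rows scaled: T = diag(w^-1/2) U'
    return T, est


def mlm_association(
    y: np.ndarray,
    snps: np.ndarray,
    covariates: np.ndarray | None,
    K: KinshipMatrix | np.ndarray,
    snp_ids: list[str] | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Kinship mixed-model scan with null-model variance components.

    Variance components are estimated once under the covariate-only null
    (the population-parameters-previously-determined convention); each SNP
    is then tested by an F-test on the whitened (GLS) model.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.column_stack([X0, covariates])
    T, _ = _whiten(K, y, X0, eig=eig)
    yw = T @ y
    X0w = T @ X0  # the whitened intercept is a column of T @ 1, not ones
    Sw = T @ _as_snp_matrix(snps, n)
    rss0, _, rank0 = _ols_rss(X0w, yw)
    ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(Sw.shape[1])]
    effects, fstats, pvals = [], [], []
    for j in range(Sw.shape[1]):
        X1 = np.column_stack([X0w, Sw[:, j]])
        rss1, beta, rank1 = _ols_rss(X1, yw)
        if rank1 <= rank0:
            effects.append(np.nan)
            fstats.append(np.nan)
            pvals.append(np.nan)
            continue
        df2 = n - rank1
        F = (rss0 - rss1) / (rss1 / df2)
        effects.append(float(beta[-1]))
        fstats.append(float(F))
        pvals.append(float(stats.f.sf(F, 1, df2)))
    return _scan_frame(ids, effects, fstats, pvals, "MLM")


def multitrait_lrt(
    Y: np.ndarray | pd.DataFrame,
    snps: np.ndarray,
    covariates: np.ndarray | None = None,
    K: KinshipMatrix | np.ndarray | None = None,
    snp_ids: list[str] | None = None,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of a SNP's joint effect on t traits.

    Kinship is absorbed approximately: each trait is whitened by its own
    null-model variance ratio (shared eigenvectors), then the LRT compares
    multivariate regressions with and without the SNP;
    LRT = n (log det S0 - log det S1) ~ chi2 with t degrees of freedom.
    At t = 1 this reduces exactly to the single-trait likelihood ratio.
    """
    Ym = Y.to_numpy(dtype=float) if isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if Ym.ndim == 1:
        Ym = Ym[:, None]
    n, t = Ym.shape
    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.column_stack([X0, covariates])
    S = _as_snp_matrix(snps, n)
    ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(S.shape[1])]

    if K is not None:
        Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, float)
        s_eig, U = _eigen_k(Kmat) if eig is None else eig
        Yw = np.empty_like(Ym)
        X0w_list, Sw_list = [], []
        for j in range(t):
            T, _ = _whiten(Kmat, Ym[:, j], X0, eig=(s_eig, U))
            Yw[:, j] = T @ Ym[:, j]
            X0w_list.append(T @ X0)
            Sw_list.append(T @ S)
    else:
        Yw = Ym
        X0w_list = [X0] * t
        Sw_list = [S] * t

    lrts, pvals = [], []
    for j_snp in range(S.shape[1]):
        R0 = np.empty((n, t))
        R1 = np.empty((n, t))
        singular = False
        for j in range(t):
            X0j = X0w_list[j]
            sj = Sw_list[j][:, j_snp]
            _, b0, _ = _ols_rss(X0j, Yw[:, j])
            R0[:, j] = Yw[:, j] - X0j @ b0
            X1j = np.column_stack([X0j, sj])
            _, b1, rank1 = _ols_rss(X1j, Yw[:, j])
            if rank1 < X1j.shape[1]:
                singular = True
                break
            R1[:, j] = Yw[:, j] - X1j @ b1
        if singular:
            lrts.append(np.nan)
            pvals.append(np.nan)
            continue
        S0 = (R0.T @ R0) / n
        S1 = (R1.T @ R1) / n
        sign0, ld0 = np.linalg.slogdet(S0)
        sign1, ld1 = np.linalg.slogdet(S1)
        if sign0 <= 0 or sign1 <= 0:
            raise ValueError("singular residual covariance")
        lrt = n * (ld0 - ld1)
        lrts.append(float(lrt))
        pvals.append(float(stats.chi2.sf(lrt, df=t)))
    return _scan_frame(ids, [np.nan] * len(ids), lrts, pvals, "multitrait-LRT")


def leave_one_chrom_kinship(genotypes: GenotypeMatrix, chrom: str) -> KinshipMatrix:
    """Kinship from all SNPs not on the held-out chromosome."""
    chroms = genotypes.snps["chrom"].astype(str)
    if chroms.nunique() < 2:
        raise ValueError("leave-one-chromosome-out needs >= 2 chromosomes")
    keep = np.where((chroms != str(chrom)).to_numpy())[0]
    if len(keep) == 0:
        raise ValueError("held-out chromosome covers all SNPs")
    return kinship(genotypes, keep)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, order-invariant)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> tuple[float, np.ndarray]:
    """Per-test threshold alpha/m and the significance flags at it."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return alpha, np.zeros(0, dtype=bool)
    threshold = alpha / p.size
    return threshold, p < threshold


# ---------------------------------------------------------------------------
# epistasis
# ---------------------------------------------------------------------------


def epistasis_scan(
    y: np.ndarray,
    peak_snp: np.ndarray,
    snp_set: np.ndarray,
    covariates: np.ndarray | None,
    K: KinshipMatrix | np.ndarray,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Additive x additive interaction scan against a fixed peak SNP.

    Fits Y = Q gamma + S1 a1 + S2 a2 + S1S2 beta + u + e with
    u ~ N(0, 2K sigma_G^2); variance components come from the null
    (no-interaction) model and fixed effects are solved by GLS on the
    whitened data.  The reported p is the Wald test of beta.  Test SNPs
    identical to the peak, or whose interaction column is collinear with
    the main effects, are flagged and skipped.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    s1 = np.asarray(peak_snp, dtype=float)
    if np.std(s1) == 0:
        raise ValueError("peak SNP is constant")
    S = _as_snp_matrix(snp_set, n)
    ids = snp_ids if snp_ids is not None else [f"snp{i}" for i in range(S.shape[1])]
    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        X0 = np.column_stack([X0, covariates])
    Kmat = K.K if isinstance(K, KinshipMatrix) else np.asarray(K, float)
    # mu ~ N(0, 2K sigma_G^2): the factor 2 is absorbed into the ratio
    T, _ = _whiten(2.0 * Kmat, y, np.column_stack([X0, s1]))
    yw = T @ y
    rows = []
    for j in range(S.shape[1]):
        s2 = S[:, j]
        if np.array_equal(s2, s1):
            rows.append((ids[j], np.nan, np.nan, np.nan, np.nan, "peak"))
            continue
        inter = s1 * s2
        X = np.column_stack([X0, s1, s2, inter])
        Xw = T @ X
        rank = np.linalg.matrix_rank(Xw)
        if rank < X.shape[1]:
            rows.append((ids[j], np.nan, np.nan, np.nan, np.nan, "collinear"))
            continue
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        dof = n - X.shape[1]
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
        se_beta = float(np.sqrt(cov[-1, -1]))
        tstat = beta[-1] / se_beta
        p = float(2.0 * stats.t.sf(abs(tstat), dof))
        rows.append(
            (ids[j], float(beta[-3]), float(beta[-2]), float(beta[-1]), p, "ok")
        )
    out = pd.DataFrame(
        rows, columns=["id", "alpha1", "alpha2", "beta", "p_beta", "status"]
    )
    ok = out["status"] == "ok"
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(out.loc[ok, "p_beta"], method="fdr_bh")[1]
    out["q_beta"] = q
    return out
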