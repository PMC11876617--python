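"""Expression-time staging and triad relative expression.

Normalizes counts, selects the most dynamically expressed genes, fits a
cubic B-spline trajectory through the first two principal components of a
reference developmental series, and assigns each sample a continuous
expression time (ET) by nearest-curve projection.  Also provides triad
relative-expression shares (mutant-a / mutant-b / control) and
hypergeometric category enrichment with Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "size_factors",
    "vst_approx",
    "filter_expressed",
    "filter_replicates",
    "select_dynamic_genes",
    "ExpressionTimeStager",
    "fit_trajectory",
    "assign_expression_time",
    "relative_expression_triad",
    "category_enrichment",
]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scale factors.

    The reference is the per-gene geometric mean across samples; a
    sample's factor is the median over genes of its count divided by that
    reference, using only genes expressed in every sample.
    """
    mat = counts.to_numpy(dtype=float)
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene is expressed in all samples")
    sub = mat[all_pos]
    ref = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def vst_approx(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1); a zero count maps to zero."""
    f = factors.reindex(counts.columns).to_numpy(dtype=float)
    if np.any(f <= 0):
        raise ValueError("size factors must be positive")
    return pd.DataFrame(
        np.log2(counts.to_numpy(dtype=float) / f + 1.0),
        index=counts.index,
        columns=counts.columns,
    )


def filter_expressed(counts: pd.DataFrame, min_row_mean: float = 5.0) -> pd.DataFrame:
    """Keep genes whose row mean count is strictly above the threshold."""
    keep = counts.mean(axis=1) > min_row_mean
    if not keep.any():
        warnings.warn("no gene passes the expression filter", stacklevel=2)
    return counts.loc[keep]


def filter_replicates(
    expr: pd.DataFrame, metadata: pd.DataFrame, r_min: float = 0.92
) -> list[str]:
    """Drop poorly correlated replicates within each sample group.

    Within each (genotype, tissue, stage) group, the sample with the
    lowest mean within-group Pearson correlation is dropped iteratively
    until all remaining pairs have r >= r_min or only two samples remain.
    """
    retained: list[str] = []
    groups = metadata.groupby(["genotype", "tissue", "stage"], sort=False)
    for _, grp in groups:
        members = [s for s in grp["sample_id"] if s in expr.columns]
        while len(members) > 2:
            cor = np.corrcoef(expr[members].to_numpy(dtype=float), rowvar=False)
            off = cor[~np.eye(len(members), dtype=bool)]
            if off.min() >= r_min:
                break
            mean_cor = (cor.sum(axis=0) - 1.0) / (len(members) - 1)
            members.pop(int(np.argmin(mean_cor)))
        if len(members) == 2:
            r = np.corrcoef(
                expr[members[0]].to_numpy(dtype=float),
                expr[members[1]].to_numpy(dtype=float),
            )[0, 1]
            if r < r_min:
                warnings.warn(
                    f"group reduced to best pair below r_min ({members})",
                    stacklevel=2,
                )
        retained.extend(members)
    return retained


def select_dynamic_genes(
    expr: pd.DataFrame, metadata: pd.DataFrame, n: int = 500
) -> list[str]:
    """Rank genes by variance of per-stage mean expression; return the top n.

    The per-stage averaging suppresses replicate noise so the statistic
    captures trajectory amplitude.  Ties break on gene id (stable).
    """
    stages = metadata.set_index("sample_id").loc[expr.columns, "stage"]
    if stages.nunique() < 2:
        raise ValueError("need at least two stages to rank dynamic genes")
    stage_means = expr.T.groupby(stages.to_numpy()).mean().T
    var = stage_means.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-var[g], g))
    if n > len(order):
        warnings.warn("fewer genes than requested; returning all", stacklevel=2)
        n = len(order)
    return order[:n]


# ---------------------------------------------------------------------------
# trajectory model
# ---------------------------------------------------------------------------


def _bspline_basis(t: np.ndarray, knots: np.ndarray, df: int, degree: int = 3):
    """Cubic B-spline design matrix with `df` basis columns (bs()-style)."""
    n_interior = df - degree
    lo, hi = knots[0], knots[-1]
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(knots, qs)
    else:
        interior = np.array([])
    full = np.concatenate(
        [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
    )
    tt = np.clip(t, lo, hi)
    return interpolate.BSpline.design_matrix(tt, full, degree).toarray(), full


@dataclass
class ETAssignment:
    sample_id: str
    et: float
    distance: float
    extrapolated: bool = False


class ExpressionTimeStager:
    """Fit a PC-space trajectory through reference samples and stage others.

    fit() runs PCA (two components) on the standardized dynamic-gene
    expression of the reference samples, assigns each reference sample a
    provisional time equal to its stage rank, and least-squares fits a
    cubic B-spline with `df` degrees of freedom per PC coordinate against
    provisional time.  transform() projects new samples onto the stored
    loadings and reads ET off the nearest point of the fitted curve on a
    dense time grid.

    Fitted attributes carry a trailing underscore (genes_, loadings_,
    coef_, grid_, curve_).
    """

    def __init__(self, df: int = 3, grid_points: int = 1000):
        self.df = df
        self.grid_points = grid_points

    def fit(
        self,
        expr: pd.DataFrame,
        dynamic_genes: list[str],
        reference_samples: list[str],
        stage_order: dict[str, float] | pd.Series,
    ) -> "ExpressionTimeStager":
        if len(reference_samples) < self.df + 1:
            raise ValueError("fewer reference samples than spline df + 1")
        stage_of = (
            stage_order if isinstance(stage_order, pd.Series) else pd.Series(stage_order)
        )
        t = stage_of.reindex(reference_samples).to_numpy(dtype=float)
        if np.unique(t).size < 3:
            raise ValueError("reference samples must span >= 3 ordered stages")

        X = expr.loc[dynamic_genes, reference_samples].to_numpy(dtype=float).T
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.all(sd == 0):
            raise ValueError("constant expression matrix: degenerate PCA")
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (X - self.mean_) / self.scale_
        # PCA via SVD; loadings_ columns are orthonormal gene directions
        _, s, vt = np.linalg.svd(Z, full_matrices=False)
        if s[1] <= 1e-12 * max(s[0], 1.0):
            raise ValueError("degenerate PCA: fewer than two informative components")
        self.loadings_ = vt[:2].T
        pcs = Z @ self.loadings_

        basis, self.knots_ = _bspline_basis(t, np.sort(np.unique(t)), self.df)
        design = np.column_stack([np.ones(len(t)), basis])
        self.coef_, *_ = np.linalg.lstsq(design, pcs, rcond=None)
        self.t_min_, self.t_max_ = float(t.min()), float(t.max())
        self.genes_ = list(dynamic_genes)
        self._build_grid(self.grid_points)
        return self

    def _build_grid(self, n: int) -> None:
        self.grid_ = np.linspace(self.t_min_, self.t_max_, n)
        basis = interpolate.BSpline.design_matrix(
            self.grid_, self.knots_, 3
        ).toarray()
        design = np.column_stack([np.ones(n), basis])
        self.curve_ = design @ self.coef_

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        """Assign ET and distance-to-curve for each column of expr."""
        missing = [g for g in self.genes_ if g not in expr.index]
        if missing:
            raise ValueError(f"samples lack model genes: {missing[:5]}...")
        X = expr.loc[self.genes_].to_numpy(dtype=float).T
        Z = (X - self.mean_) / self.scale_
        pcs = Z @ self.loadings_
        d2 = ((pcs[:, None, :] - self.curve_[None, :, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        out = pd.DataFrame(
            {
                "et": self.grid_[idx],
                "distance": np.sqrt(d2[np.arange(len(idx)), idx]),
                "extrapolated": (idx == 0) | (idx == len(self.grid_) - 1),
            },
            index=expr.columns,
        )
        return out


def fit_trajectory(
    expr: pd.DataFrame,
    dynamic_genes: list[str],
    reference_samples: list[str],
    stage_order: dict[str, float] | pd.Series,
    df: int = 3,
) -> ExpressionTimeStager:
    return ExpressionTimeStager(df=df).fit(
        expr, dynamic_genes, reference_samples, stage_order
    )


def assign_expression_time(
    model: ExpressionTimeStager, expr: pd.DataFrame
) -> pd.DataFrame:
    return model.transform(expr)


# ---------------------------------------------------------------------------
# triad shares and enrichment
# ---------------------------------------------------------------------------


def relative_expression_triad(
    tpm_a: pd.Series, tpm_b: pd.Series, tpm_control: pd.Series
) -> pd.DataFrame:
    """Per-gene relative-expression shares within a genotype triad.

    Each genotype's share is its TPM divided by the triad sum, so the
    three shares sum to one; genes whose triad total is zero get NaN.
    """
    a = tpm_a.to_numpy(dtype=float)
    b = tpm_b.reindex(tpm_a.index).to_numpy(dtype=float)
    c = tpm_control.reindex(tpm_a.index).to_numpy(dtype=float)
    if np.nanmin([a.min(), b.min(), c.min()]) < 0:
        raise ValueError("TPM values must be non-negative")
    total = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(
            (total > 0)[:, None], np.column_stack([a, b, c]) / total[:, None], np.nan
        )
    return pd.DataFrame(
        shares, index=tpm_a.index, columns=["mutant_a", "mutant_b", "control"]
    )


def category_enrichment(
    query_genes: list[str] | set[str],
    universe: list[str] | set[str],
    category_map: dict[str, set[str]] | pd.Series,
    q_cutoff: float = 0.1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per category with BH q-values."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes) & universe
    if not set(query_genes) <= universe:
        warnings.warn("query genes outside universe are ignored", stacklevel=2)
    if isinstance(category_map, pd.Series):
        cmap: dict[str, set[str]] = {}
        for gene, cat in category_map.items():
            cmap.setdefault(cat, set()).add(gene)
        category_map = cmap
    rows = []
    for cat, members in category_map.items():
        members = set(members) & universe
        overlap = len(members & query)
        # P(X >= overlap), so overlap 0 gives p = 1
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(members), len(query)))
        rows.append((cat, overlap, len(members), min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["category", "overlap", "category_size", "p"])
    if len(table):
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
        table["significant"] = table["q"] <= q_cutoff
    else:
        table["q"] = []
        table["significant"] = []
    return table.sort_values("p", kind="stable").reset_index(drop=True)
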