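"""Signed weighted co-expression networks, modules and preservation.

Builds signed adjacencies from biweight midcorrelation (or Pearson),
derives the topological overlap matrix (TOM), detects modules by
average-linkage clustering on TOM dissimilarity with a size floor and
eigengene-based merging, correlates module eigengenes with traits, and
tests cross-network module preservation against size-matched random gene
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "correlation_matrix",
    "signed_adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "module_trait_correlation",
    "preservation_test",
    "submodule_overlap",
    "preserved_edges",
    "degree_centrality",
    "ModuleEigengene",
    "PreservationResult",
]


# ---------------------------------------------------------------------------
# correlation and adjacency
# ---------------------------------------------------------------------------


def _bicor_vectors(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted, unit-norm row vectors whose dot products give bicor.

    Rows with zero MAD cannot be midweighted; they fall back to the
    standardized (Pearson) vector, so mixed pairs yield a Pearson-bicor
    hybrid as in the reference formulation.
    """
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
        w = np.square(1.0 - np.square(u)) * (np.abs(u) < 1.0)
    w = np.nan_to_num(w, nan=0.0, posinf=0.0, neginf=0.0)
    vec = dev * w
    if zero_mad.any():
        centered = X[zero_mad] - X[zero_mad].mean(axis=1, keepdims=True)
        vec[zero_mad] = centered
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vec / norms, zero_mad


def correlation_matrix(expr: pd.DataFrame, method: str = "bicor") -> pd.DataFrame:
    """Gene-gene correlation (rows = genes) by bicor or Pearson.

    bicor uses the biweight midcorrelation with tuning constant 9 x MAD;
    genes with zero MAD fall back to Pearson for their pairs (warned).
    """
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if method == "pearson":
        cor = np.corrcoef(X)
    elif method == "bicor":
        vec, zero_mad = _bicor_vectors(X)
        if zero_mad.any():
            warnings.warn(
                f"{int(zero_mad.sum())} genes have zero MAD; Pearson fallback",
                stacklevel=2,
            )
        cor = vec @ vec.T
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    cor = np.clip(cor, -1.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor: pd.DataFrame | np.ndarray, beta: int = 6):
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta."""
    if int(beta) != beta or beta < 1:
        raise ValueError("beta must be a positive integer")
    arr = cor.to_numpy() if isinstance(cor, pd.DataFrame) else np.asarray(cor)
    adj = np.power((1.0 + arr) / 2.0, beta)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(adj, index=cor.index, columns=cor.columns)
    return adj


def tom_similarity(adjacency: pd.DataFrame | np.ndarray):
    """Topological overlap: TOM_ij = (l_ij + a_ij) / (min(k_i,k_j) + 1 - a_ij).

    l_ij sums shared-neighbor adjacency a_iu * a_uj over u != i, j and
    k_i is node i's connectivity.  Expects a symmetric adjacency in [0,1]
    with zero diagonal; the returned matrix has unit diagonal.
    """
    A = adjacency.to_numpy(dtype=float) if isinstance(adjacency, pd.DataFrame) else np.asarray(adjacency, dtype=float)
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return tom


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


@dataclass
class ModuleEigengene:
    module: str
    scores: pd.Series  # unit-norm per-sample score
    variance_explained: float


def module_eigengene(expr: pd.DataFrame, module_genes: list[str]) -> ModuleEigengene:
    """First PC of the standardized member expression, sign-anchored.

    The score vector is unit norm and its sign is fixed so the mean
    correlation with member genes is positive.
    """
    if len(module_genes) == 0:
        raise ValueError("module is empty")
    X = expr.loc[module_genes].to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    var_explained = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else 0.0
    # sign convention: mean loading (u column) positive
    if u[:, 0].sum() < 0:
        score = -score
    return ModuleEigengene(
        module="",
        scores=pd.Series(score, index=expr.columns, name="eigengene"),
        variance_explained=var_explained,
    )


def _to_tree_index(Z: np.ndarray, n_leaves: int) -> dict[int, tuple[int, int]]:
    """Internal-node id -> (left child, right child) for a linkage matrix."""
    return {
        n_leaves + k: (int(Z[k, 0]), int(Z[k, 1])) for k in range(Z.shape[0])
    }


def _subtree_size(tree: dict, node: int, n_leaves: int) -> int:
    size, stack = 0, [node]
    while stack:
        k = stack.pop()
        if k < n_leaves:
            size += 1
        else:
            stack.extend(tree[k])
    return size


def _branch_root(tree: dict, leaf_ids: list[int], n_leaves: int) -> int:
    """Smallest subtree containing all given leaves."""
    want = set(leaf_ids)
    if len(want) == 1:
        return leaf_ids[0]
    parent: dict[int, int] = {}
    for node, (a, b) in tree.items():
        parent[a] = node
        parent[b] = node
    # walk up from one leaf until the subtree covers all wanted leaves
    node = leaf_ids[0]
    while node in parent:
        node = parent[node]
        if _covers(tree, node, want, n_leaves):
            return node
    return node


def _covers(tree: dict, node: int, want: set[int], n_leaves: int) -> bool:
    found, stack = 0, [node]
    while stack:
        k = stack.pop()
        if k < n_leaves:
            if k in want:
                found += 1
        else:
            stack.extend(tree[k])
    return found == len(want)


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    min_size: int = 30,
    merge_cut: float = 0.25,
    cut_height: float = 0.99,
) -> pd.Series:
    """Cluster genes on TOM dissimilarity into labelled modules.

    Average-linkage hierarchical clustering on 1 - TOM is cut at
    ``cut_height`` times the tallest merge (branches joining in the top
    1% of the dendrogram height stay separate); branches smaller than
    ``min_size`` become "unassigned".  When expression is supplied,
    modules whose eigengenes correlate above 1 - merge_cut are merged
    iteratively until stable.  Labels are deterministic, ordered by size
    ("M1" largest).
    """
    genes = list(tom.index)
    D = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    if np.allclose(D, 0.0):
        return pd.Series("M1", index=genes, name="module")
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cut_height * Z[:, 2].max(), criterion="distance")

    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(i)

    # split each branch top-down while both children stay above the size
    # floor; eigengene merging below re-joins any over-splits
    tree = _to_tree_index(Z, len(genes))

    def leaves(node: int) -> list[int]:
        out, stack = [], [node]
        n_leaves = len(genes)
        while stack:
            k = stack.pop()
            if k < n_leaves:
                out.append(k)
            else:
                stack.extend(tree[k])
        return out

    def split(node: int) -> list[list[int]]:
        n_leaves = len(genes)
        if node < n_leaves:
            return [[node]]
        left, right = tree[node]
        lsz = 1 if left < n_leaves else _subtree_size(tree, left, n_leaves)
        rsz = 1 if right < n_leaves else _subtree_size(tree, right, n_leaves)
        if min(lsz, rsz) < min_size:
            return [leaves(node)]
        return split(left) + split(right)

    modules: list[list[str]] = []
    for idx_list in groups.values():
        if len(idx_list) < min_size:
            continue
        # locate the subtree root covering exactly this branch
        branch_root = _branch_root(tree, idx_list, len(genes))
        for chunk in split(branch_root):
            if len(chunk) >= min_size:
                modules.append([genes[i] for i in chunk])

    if expr is not None and merge_cut > 0 and len(modules) > 1:
        while True:
            scores = [module_eigengene(expr, m).scores.to_numpy() for m in modules]
            if len(scores) < 2:
                break
            cor = np.corrcoef(np.vstack(scores))
            np.fill_diagonal(cor, -np.inf)
            i, j = np.unravel_index(np.argmax(cor), cor.shape)
            if cor[i, j] <= 1.0 - merge_cut:
                break
            merged = modules[i] + modules[j]
            modules = [m for k, m in enumerate(modules) if k not in (i, j)]
            modules.append(merged)

    modules.sort(key=lambda m: (-len(m), m[0]))
    label = pd.Series("unassigned", index=genes, name="module")
    for k, m in enumerate(modules, start=1):
        label.loc[m] = f"M{k}"
    return label


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame, strong: float = 0.8
) -> pd.DataFrame:
    """Pearson r and Student t p per (module, trait); flag |r| > strong.

    p = two-sided from t = r sqrt((n-2)/(1-r^2)) with n-2 df.
    """
    rows = []
    n = len(eigengenes)
    for module in eigengenes.columns:
        e = eigengenes[module].to_numpy(dtype=float)
        for trait in traits.columns:
            y = traits[trait].reindex(eigengenes.index).to_numpy(dtype=float)
            if np.std(y) == 0 or np.std(e) == 0:
                rows.append((module, trait, np.nan, np.nan, False))
                continue
            r = float(np.corrcoef(e, y)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            rows.append((module, trait, r, p, abs(r) > strong))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p", "strong"])


# ---------------------------------------------------------------------------
# preservation
# ---------------------------------------------------------------------------


@dataclass
class PreservationResult:
    module: str
    size: int
    observed: float
    z: float
    p: float
    null_mean: float
    null_sd: float
    n_perm: int


def _preservation_stat(
    idx: np.ndarray, adj_ref: np.ndarray, adj_test: np.ndarray
) -> float:
    """Composite of density (test) and cross-network connectivity agreement."""
    sub_t = adj_test[np.ix_(idx, idx)]
    sub_r = adj_ref[np.ix_(idx, idx)]
    m = len(idx)
    off = ~np.eye(m, dtype=bool)
    density = float(sub_t[off].mean())
    k_r = sub_r.sum(axis=1) - np.diag(sub_r)
    k_t = sub_t.sum(axis=1) - np.diag(sub_t)
    if np.std(k_r) == 0 or np.std(k_t) == 0:
        conn = 0.0
    else:
        conn = float(np.corrcoef(k_r, k_t)[0, 1])
    return 0.5 * (density + conn)


def preservation_test(
    adj_ref: pd.DataFrame,
    adj_test: pd.DataFrame,
    modules: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[PreservationResult]:
    """Permutation Z test of module preservation in a second network.

    The observed composite statistic (mean of within-module density in the
    test network and the ref/test correlation of intramodular
    connectivity) is compared with the same statistic on ``n_perm``
    size-matched random gene sets; one-sided p assumes normality of the
    null.
    """
    shared = [g for g in adj_ref.index if g in set(adj_test.index)]
    ref = adj_ref.loc[shared, shared].to_numpy(dtype=float)
    test = adj_test.loc[shared, shared].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)
    results = []
    for module in sorted(modules.unique()):
        if module == "unassigned":
            continue
        members = [g for g in modules.index[modules == module] if g in pos]
        if len(members) < 3:
            warnings.warn(f"module {module} smaller than 3 shared genes; skipped",
                          stacklevel=2)
            continue
        idx = np.array([pos[g] for g in members])
        obs = _preservation_stat(idx, ref, test)
        null = np.empty(n_perm)
        for b in range(n_perm):
            rand = rng.choice(len(shared), size=len(idx), replace=False)
            null[b] = _preservation_stat(rand, ref, test)
        sd = float(null.std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate permutation null for module {module}")
        z = (obs - null.mean()) / sd
        results.append(
            PreservationResult(
                module=module,
                size=len(members),
                observed=obs,
                z=float(z),
                p=float(stats.norm.sf(z)),
                null_mean=float(null.mean()),
                null_sd=sd,
                n_perm=n_perm,
            )
        )
    return results


def submodule_overlap(
    module_ref: set[str], module_test: set[str], universe: set[str]
) -> tuple[int, float]:
    """Overlap count and one-sided Fisher/hypergeometric enrichment p."""
    universe = set(universe)
    a = set(module_ref) & universe
    b = set(module_test) & universe
    if not a or not b:
        return 0, 1.0
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))
    return k, min(p, 1.0)


def preserved_edges(
    net_a: pd.DataFrame, net_b: pd.DataFrame, weight_threshold: float
) -> pd.DataFrame:
    """Classify node-pair edges as preserved, a-specific or b-specific.

    An edge exists in a network when its weight >= threshold; it is
    preserved when it exists in both.  Input adjacencies share a node
    universe.
    """
    shared = [g for g in net_a.index if g in set(net_b.index)]
    A = net_a.loc[shared, shared].to_numpy(dtype=float) >= weight_threshold
    B = net_b.loc[shared, shared].to_numpy(dtype=float) >= weight_threshold
    rows = []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            if A[i, j] and B[i, j]:
                status = "preserved"
            elif A[i, j]:
                status = "a_specific"
            elif B[i, j]:
                status = "b_specific"
            else:
                continue
            rows.append((shared[i], shared[j], status))
    return pd.DataFrame(rows, columns=["node1", "node2", "status"])


def degree_centrality(graph, node) -> float:
    """Degree divided by n - 1 on a simple graph."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("degree centrality undefined for n < 2")
    return graph.degree(node) / (n - 1)
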