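"""Directed regulatory-network inference from expression.

For each target gene a tree-ensemble regression of its variance-normalized
expression on all transcription-factor expressions (excluding itself)
yields per-TF importance scores; edges at or above a weight cutoff form
the directed TF -> target network.  Predictions can be validated against a
binding-derived gold standard with a permutation null.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

__all__ = ["GRNInferencer", "infer_grn", "validate_against_binding"]


class GRNInferencer:
    """Tree-ensemble regulatory network inference (GENIE3-style).

    Parameters
    ----------
    n_trees:
        Trees per target-gene random forest.
    weight_cutoff:
        Edges with importance below this are dropped (kept at >= cutoff).
    max_features:
        Feature subsampling per split, forwarded to the forest.
    random_state:
        Base seed; each target derives its own stream, so fits are
        deterministic and independent of target order.

    After fit, ``network_`` holds the weighted digraph and
    ``importances_`` the full TF x target importance frame.
    """

    def __init__(
        self,
        n_trees: int = 1000,
        weight_cutoff: float = 0.005,
        max_features: float | str = "sqrt",
        random_state: int = 0,
    ):
        self.n_trees = n_trees
        self.weight_cutoff = weight_cutoff
        self.max_features = max_features
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_trees": self.n_trees,
            "weight_cutoff": self.weight_cutoff,
            "max_features": self.max_features,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "GRNInferencer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, expr: pd.DataFrame, tf_list: list[str]) -> "GRNInferencer":
        """Infer the network from a genes x samples expression frame."""
        tfs = [t for t in tf_list if t in expr.index]
        if len(tfs) != len(tf_list):
            raise ValueError("tf_list contains genes absent from the expression matrix")
        if expr.shape[1] < 10:
            raise ValueError("need at least 10 samples")
        X_all = expr.loc[tfs].to_numpy(dtype=float).T  # samples x TFs
        graph = nx.DiGraph()
        graph.add_nodes_from(expr.index)
        imp = pd.DataFrame(0.0, index=tfs, columns=expr.index)
        tf_pos = {t: i for i, t in enumerate(tfs)}
        for k, target in enumerate(expr.index):
            y = expr.loc[target].to_numpy(dtype=float)
            sd = y.std()
            if sd == 0:
                continue  # constant target: no edges
            y = (y - y.mean()) / sd
            if target in tf_pos:
                cols = [i for i in range(len(tfs)) if i != tf_pos[target]]
            else:
                cols = list(range(len(tfs)))
            if not cols:
                continue
            forest = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features=self.max_features,
                random_state=(self.random_state * 1_000_003 + k) % (2**31 - 1),
                n_jobs=1,
            )
            forest.fit(X_all[:, cols], y)
            imp.iloc[cols, imp.columns.get_loc(target)] = forest.feature_importances_
            for i, w in zip(cols, forest.feature_importances_):
                if w >= self.weight_cutoff:
                    graph.add_edge(tfs[i], target, weight=float(w))
        self.importances_ = imp
        self.network_ = graph
        self.regulators_ = tfs
        return self


def infer_grn(
    expr: pd.DataFrame,
    tf_list: list[str],
    n_trees: int = 1000,
    weight_cutoff: float = 0.005,
    seed: int = 0,
) -> nx.DiGraph:
    """Functional wrapper over :class:`GRNInferencer`; returns the digraph."""
    return (
        GRNInferencer(n_trees=n_trees, weight_cutoff=weight_cutoff, random_state=seed)
        .fit(expr, tf_list)
        .network_
    )


def validate_against_binding(
    grn: nx.DiGraph,
    regulator: str,
    gold_target_set: set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Predicted-target accuracy against a binding gold set, with a null.

    accuracy = |predicted & gold| / |predicted|.  The null distribution
    draws size-matched random target sets from the network's target
    universe (nodes with at least one incoming edge) and recomputes the
    accuracy of the prediction against each.
    """
    gold = set(gold_target_set)
    if not gold:
        raise ValueError("empty gold target set")
    predicted = set(grn.successors(regulator))
    if not predicted:
        raise ValueError(f"regulator {regulator!r} has no predicted targets")
    universe = sorted({v for _, v in grn.edges()})
    accuracy = len(predicted & gold) / len(predicted)
    rng = np.random.default_rng(seed)
    size = min(len(gold), len(universe))
    null = np.empty(n_perm)
    for b in range(n_perm):
        rand_gold = set(rng.choice(universe, size=size, replace=False))
        null[b] = len(predicted & rand_gold) / len(predicted)
    return {
        "accuracy": accuracy,
        "null_95th": float(np.percentile(null, 95)),
        "null_mean": float(null.mean()),
        "exceeds_null": accuracy > float(np.percentile(null, 95)),
        "n_predicted": len(predicted),
    }
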