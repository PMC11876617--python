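"""Three-node motif census, enrichment against randomized nulls, and FFLs.

A triad (unordered node triple) of a simple digraph falls into one of the
16 directed isomorphism classes; ten of those classes carry at least three
arcs (a mutual pair counts as two arcs) and are the motif classes of
interest.  The census iterates only over connected triples (every triple
sharing at least one arc), classifies each by canonicalizing its 6-bit arc
mask over the 6 node permutations, and compares counts with an ensemble of
uniformly randomized networks of identical node and edge count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "TRIAD_NAMES",
    "triad_classes",
    "classify_triad",
    "triad_census",
    "TriadCensus",
    "randomize_network",
    "motif_enrichment",
    "MotifEnrichment",
    "enumerate_ffls",
    "rank_tfs_by_motifs",
    "ffl_position_stats",
    "first_neighbors",
]

# ordered pairs of local node slots; bit i of a mask marks arc _PAIRS[i]
_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
_PAIR_INDEX = {p: i for i, p in enumerate(_PAIRS)}

# the 16 standard triad isomorphism classes (M-A-N labelling)
TRIAD_NAMES = [
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
]


def _canonical(mask: int) -> int:
    best = 1 << 6
    for perm in itertools.permutations(range(3)):
        out = 0
        for i, (a, b) in enumerate(_PAIRS):
            if mask & (1 << i):
                out |= 1 << _PAIR_INDEX[(perm[a], perm[b])]
        best = min(best, out)
    return best


def _build_tables() -> tuple[dict[int, str], dict[str, int]]:
    canon_to_name: dict[int, str] = {}
    arc_count: dict[str, int] = {}
    for name in TRIAD_NAMES:
        g = nx.triad_graph(name)  # representative on nodes a, b, c
        order = {n: i for i, n in enumerate(sorted(g.nodes()))}
        mask = 0
        for u, v in g.edges():
            mask |= 1 << _PAIR_INDEX[(order[u], order[v])]
        canon_to_name[_canonical(mask)] = name
        arc_count[name] = g.number_of_edges()
    return canon_to_name, arc_count


_CANON_TO_NAME, _ARC_COUNT = _build_tables()
_MASK_TO_NAME = {m: _CANON_TO_NAME[_canonical(m)] for m in range(64)}


def triad_classes() -> list[str]:
    """The triad classes with >= 3 arcs; exactly ten of the sixteen."""
    return [n for n in TRIAD_NAMES if _ARC_COUNT[n] >= 3]


def classify_triad(graph: nx.DiGraph, u, v, w) -> str:
    """Isomorphism class of the sub-digraph induced on {u, v, w}."""
    nodes = (u, v, w)
    mask = 0
    for i, (a, b) in enumerate(_PAIRS):
        if graph.has_edge(nodes[a], nodes[b]):
            mask |= 1 << i
    return _MASK_TO_NAME[mask]


@dataclass
class TriadCensus:
    """Counts of >=3-arc triad classes plus the number of triples scanned."""

    counts: dict[str, int] = field(default_factory=dict)
    total_connected_triples: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _connected_triples(graph: nx.DiGraph):
    und = {n: set() for n in graph.nodes()}
    for a, b in graph.edges():
        und[a].add(b)
        und[b].add(a)
    seen: set[tuple] = set()
    for a, b in graph.edges():
        u, v = (a, b) if str(a) <= str(b) else (b, a)
        for w in und[a] | und[b]:
            if w == a or w == b:
                continue
            key = tuple(sorted((a, b, w), key=str))
            if key not in seen:
                seen.add(key)
                yield key
    # triples connected only through one center with no arc between leaves
    # are already covered: any connected triple contains >= 1 arc


def triad_census(graph: nx.DiGraph) -> TriadCensus:
    """Classify every connected node triple; count >=3-arc classes.

    Complexity is bounded by edges x neighborhood size, not C(n, 3).
    """
    counts = {name: 0 for name in triad_classes()}
    total = 0
    for u, v, w in _connected_triples(graph):
        total += 1
        name = classify_triad(graph, u, v, w)
        if name in counts:
            counts[name] += 1
    return TriadCensus(counts=counts, total_connected_triples=total)


def randomize_network(
    graph: nx.DiGraph, n_perm: int = 1000, seed: int = 0
) -> list[nx.DiGraph]:
    """Uniform random digraphs with the same node set and arc count.

    Each replicate draws m distinct ordered pairs (no self-loops)
    uniformly from the n(n-1) possibilities.
    """
    nodes = list(graph.nodes())
    n = len(nodes)
    m = graph.number_of_edges()
    if m > n * (n - 1):
        raise ValueError("more arcs than ordered pairs available")
    rng = np.random.default_rng(seed)
    out = []
    npairs = n * (n - 1)
    for _ in range(n_perm):
        if npairs <= 4 * m or npairs <= 10_000:
            idx = rng.choice(npairs, size=m, replace=False)
        else:
            chosen: set[int] = set()
            while len(chosen) < m:
                chosen.update(rng.integers(0, npairs, size=m - len(chosen)).tolist())
            idx = np.fromiter(chosen, dtype=np.int64)
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        for k in idx:
            i, r = divmod(int(k), n - 1)
            j = r if r < i else r + 1
            g.add_edge(nodes[i], nodes[j])
        out.append(g)
    return out


@dataclass
class MotifEnrichment:
    klass: str
    observed: int
    null_mean: float
    null_sd: float
    z: float
    concentration: float
    enriched: bool


def motif_enrichment(
    observed: TriadCensus,
    null_ensemble: list[TriadCensus],
    z_threshold: float = 20.0,
    concentration_threshold: float = 0.10,
) -> list[MotifEnrichment]:
    """Z-score each >=3-arc class against the randomized-null census.

    concentration is the class count over the total >=3-arc census count;
    a class is flagged enriched when Z exceeds ``z_threshold`` and
    concentration is at least ``concentration_threshold``.
    """
    if len(null_ensemble) < 2:
        raise ValueError("need at least two null replicates")
    total = max(observed.total, 1)
    results = []
    for name in triad_classes():
        obs = observed.counts.get(name, 0)
        null = np.array([c.counts.get(name, 0) for c in null_ensemble], dtype=float)
        mu, sd = float(null.mean()), float(null.std(ddof=1))
        if sd == 0:
            if obs == mu:
                z = 0.0
            else:
                warnings.warn(f"degenerate null for class {name}; Z set to inf",
                              stacklevel=2)
                z = float(np.inf) if obs > mu else float(-np.inf)
        else:
            z = (obs - mu) / sd
        conc = obs / total
        results.append(
            MotifEnrichment(
                klass=name,
                observed=obs,
                null_mean=mu,
                null_sd=sd,
                z=z,
                concentration=conc,
                enriched=bool(z > z_threshold and conc >= concentration_threshold),
            )
        )
    return results


def enumerate_ffls(graph: nx.DiGraph) -> list[tuple]:
    """All (X, Y, Z) with arcs X->Y, X->Z and Y->Z.

    A triple carrying additional arcs still yields each FFL sub-pattern it
    contains, so counts reflect FFL instances, not FFL-class triads.
    """
    out = []
    for x, y in graph.edges():
        if x == y:
            continue
        succ_x = set(graph.successors(x))
        for z in graph.successors(y):
            if z != x and z != y and z in succ_x:
                out.append((x, y, z))
    return out


def rank_tfs_by_motifs(
    graph: nx.DiGraph, top_k: int = 100, mode: str = "clique"
) -> list[tuple[str, int, float, int]]:
    """Rank nodes by occurrence in fully connected three-node subgraphs.

    ``clique`` mode (default) counts triples whose underlying undirected
    graph is a triangle (every pair connected by >= 1 arc, hence >= 3 arcs
    total); ``census`` mode counts all connected triples with >= 3 arcs.
    Returns (node, count, frequency per 10,000 occurrences, rank) for the
    top_k nodes, ties broken by node id.
    """
    counts: dict = {}
    classes3 = set(triad_classes())
    for u, v, w in _connected_triples(graph):
        if mode == "clique":
            pairs_connected = all(
                graph.has_edge(a, b) or graph.has_edge(b, a)
                for a, b in ((u, v), (u, w), (v, w))
            )
            if not pairs_connected:
                continue
        elif mode == "census":
            if classify_triad(graph, u, v, w) not in classes3:
                continue
        else:
            raise ValueError(f"unknown mode {mode!r}")
        for node in (u, v, w):
            counts[node] = counts.get(node, 0) + 1
    if not counts:
        return []
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [
        (node, c, c / total * 10_000.0, rank + 1)
        for rank, (node, c) in enumerate(ranked[:top_k])
    ]


def ffl_position_stats(
    ffls: list[tuple],
    family_map: dict | None = None,
    q_cutoff: float = 0.1,
):
    """Occurrence counts at FFL positions X, Y, Z; optional family enrichment.

    Position counts tally each gene's appearances per slot.  With a
    gene -> family map, per-family hypergeometric enrichment is computed at
    each position against the universe of genes appearing anywhere in the
    FFL list (genes missing from the map are ignored with a warning).
    """
    import pandas as pd

    from .expression_time import category_enrichment

    counts: dict[str, dict] = {"X": {}, "Y": {}, "Z": {}}
    for x, y, z in ffls:
        for slot, gene in zip("XYZ", (x, y, z)):
            counts[slot][gene] = counts[slot].get(gene, 0) + 1
    position_counts = pd.DataFrame(counts).fillna(0).astype(int)
    position_counts.index.name = "gene"

    enrichment = None
    if family_map is not None:
        if not ffls:
            raise ValueError("FFL list is empty; nothing to enrich")
        universe = set(position_counts.index)
        unknown = universe - set(family_map)
        if unknown:
            warnings.warn(f"{len(unknown)} FFL genes missing from family map",
                          stacklevel=2)
        fam: dict[str, set] = {}
        for gene in universe & set(family_map):
            fam.setdefault(family_map[gene], set()).add(gene)
        tables = {}
        for slot in "XYZ":
            query = {g for g in counts[slot] if g in family_map}
            tables[slot] = category_enrichment(query, universe & set(family_map), fam,
                                               q_cutoff=q_cutoff)
        enrichment = tables
    return position_counts, enrichment


def first_neighbors(graph: nx.DiGraph, gene, direction: str = "both") -> nx.DiGraph:
    """Induced subgraph on a gene and its in-/out-neighbors."""
    if gene not in graph:
        raise KeyError(f"{gene!r} not in graph")
    nodes = {gene}
    if direction in ("in", "both"):
        nodes |= set(graph.predecessors(gene))
    if direction in ("out", "both"):
        nodes |= set(graph.successors(gene))
    if direction not in ("in", "out", "both"):
        raise ValueError("direction must be 'in', 'out' or 'both'")
    return graph.subgraph(nodes).copy()
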