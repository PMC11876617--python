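"""Synthetic-data generators for every pipeline input.

Each generator is a pure function of its config (which carries the seed):
the same config yields byte-identical output.  The generators emulate the
statistical structure the downstream analyses assume -- a developmental
expression gradient with genotype-specific heterochronic shifts,
block-correlated co-expression modules, TF->target regulatory wiring with
planted three-node motifs, structured genotype panels with phenotypes of
chosen heritability and shared causal loci, and read-depth profiles with
planted deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionSimConfig",
    "RegulatorySimConfig",
    "GenoPhenoSimConfig",
    "ReadDepthSimConfig",
    "ExpressionPanel",
    "GenotypeMatrix",
    "PhenotypeTable",
    "gen_expression_panel",
    "gen_regulatory_truth",
    "gen_genotypes",
    "gen_phenotypes",
    "gen_read_depth",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class ExpressionSimConfig:
    """Design of a simulated expression panel.

    stages maps ordered stage labels to strictly increasing latent times;
    genotypes maps genotype labels to a heterochronic offset in latent-time
    units (the control should carry offset 0).  module_spec lists
    (size, within-module correlation) blocks drawn from the non-dynamic
    gene pool.  noise_sd is the log2-scale replicate noise.
    """

    n_genes: int = 2000
    n_dynamic: int = 500
    stages: dict[str, float] = field(
        default_factory=lambda: {
            "stage1": 1.0,
            "stage2": 2.0,
            "stage3": 3.0,
            "stage4": 4.0,
            "stage5": 5.0,
        }
    )
    genotypes: dict[str, float] = field(default_factory=lambda: {"control": 0.0})
    n_replicates: int = 4
    noise_sd: float = 0.25
    module_spec: list[tuple[int, float]] = field(default_factory=list)
    nb_dispersion: float = 0.1
    count_depth: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dynamic > self.n_genes:
            raise ValueError("n_dynamic must be <= n_genes")
        times = list(self.stages.values())
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("stage latent times must be strictly increasing")
        for size, rho in self.module_spec:
            if not 0.0 <= rho <= 1.0:
                raise ValueError("within-module correlation must be in [0, 1]")
            if size < 1:
                raise ValueError("module size must be positive")
        if self.n_dynamic + sum(s for s, _ in self.module_spec) > self.n_genes:
            raise ValueError(
                "dynamic genes plus module genes exceed n_genes; "
                "modules are drawn from the non-dynamic pool"
            )
        if self.n_replicates < 1 or self.n_genes < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class RegulatorySimConfig:
    """Ground-truth regulatory network + consistent expression.

    planted_motifs maps a motif name to the number of copies embedded on
    disjoint node triples.  Supported names: ``ffl`` (X->Y, X->Z, Y->Z),
    ``mutual_out`` (X<->Y, X->Z, Y->Z) and ``regulating_mutual``
    (X->Y, X->Z, Y<->Z).  edge_noise is the sd of Gaussian noise added to
    each regulated gene's expression relative to its signal sd; at 0 every
    regulated gene is an exact function of its true regulators.
    """

    n_tfs: int = 30
    n_targets: int = 100
    planted_motifs: dict[str, int] = field(default_factory=dict)
    edge_noise: float = 0.1
    n_samples: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name, k in self.planted_motifs.items():
            if name not in ("ffl", "mutual_out", "regulating_mutual"):
                raise ValueError(f"unknown motif class {name!r}")
            if k < 0:
                raise ValueError("planted motif counts must be non-negative")
        if self.edge_noise < 0:
            raise ValueError("edge_noise must be non-negative")
        # feasibility on disjoint triples: ffl/mutual_out take 2 TFs + 1
        # target, regulating_mutual takes 3 TFs
        need_tf = 2 * self.planted_motifs.get("ffl", 0)
        need_tf += 2 * self.planted_motifs.get("mutual_out", 0)
        need_tf += 3 * self.planted_motifs.get("regulating_mutual", 0)
        need_tg = self.planted_motifs.get("ffl", 0) + self.planted_motifs.get(
            "mutual_out", 0
        )
        if need_tf > self.n_tfs or need_tg > self.n_targets:
            raise ValueError("requested motif counts infeasible for n_tfs/n_targets")


@dataclass
class GenoPhenoSimConfig:
    """Structured genotype panel with two phenotypes.

    LD follows a first-order Markov haplotype-copying model (probability
    ld_rho of copying the previous SNP's allele); subpopulation allele
    frequencies diverge from a common ancestral frequency under a
    Balding-Nichols beta model with parameter fst.  Phenotypes draw causal
    effects inside causal_windows (bp intervals on the single simulated
    chromosome) and are scaled so realized heritability matches h2_targets
    exactly in the genetic-value sense.
    """

    n_individuals: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    n_subpops: int = 1
    fst: float = 0.0
    causal_windows: list[tuple[int, int]] = field(default_factory=list)
    h2_targets: tuple[float, ...] = (0.5, 0.5)
    genetic_correlation: float = 0.5
    snp_spacing: int = 100
    missing_rate: float = 0.0
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        for h2 in self.h2_targets:
            if not 0 <= h2 < 1:
                raise ValueError("h2 targets must be in [0, 1)")
        if not -1 <= self.genetic_correlation <= 1:
            raise ValueError("genetic_correlation must be in [-1, 1]")
        span = self.n_snps * self.snp_spacing
        for a, b in self.causal_windows:
            if a > b or a < 1 or b > span:
                raise ValueError("causal windows must lie within the simulated range")


@dataclass
class ReadDepthSimConfig:
    """Binned read-depth panel with planted region deletions."""

    n_lines: int = 200
    n_bins: int = 5
    sv_absent_fraction: float = 0.3
    mean_coverage: float = 100.0
    residual_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.sv_absent_fraction <= 1:
            raise ValueError("sv_absent_fraction must be in [0, 1]")
        if not 0 <= self.residual_rate <= 1:
            raise ValueError("residual_rate must be in [0, 1]")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionPanel:
    """TPM-like abundances, negative-binomial counts, metadata and truth."""

    tpm: pd.DataFrame  # genes x samples
    counts: pd.DataFrame  # genes x samples
    metadata: pd.DataFrame  # sample_id, genotype, tissue, stage, replicate
    latent_time: pd.Series  # true latent time per sample
    dynamic_genes: list[str]
    module_assignment: dict[str, int]  # gene -> planted module index


@dataclass
class GenotypeMatrix:
    """Dosage-coded biallelic SNP panel (NaN marks missing calls)."""

    dosage: np.ndarray  # individuals x SNPs, values {0,1,2} or NaN
    snps: pd.DataFrame  # chrom, pos (1-based), id, ref, alt
    individuals: list[str]
    subpop: np.ndarray | None = None  # truth labels when simulated

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosage=self.dosage[:, index],
            snps=self.snps.iloc[np.asarray(index)].reset_index(drop=True),
            individuals=list(self.individuals),
            subpop=self.subpop,
        )


@dataclass
class PhenotypeTable:
    """Replicated field records plus per-line values and simulation truth."""

    records: pd.DataFrame  # genotype, year, block, plant, trait_*
    line_values: pd.DataFrame  # one row per genotype (genetic + line noise)
    genetic_values: pd.DataFrame  # true breeding values per genotype
    realized_h2: tuple[float, ...]


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------

_PATTERNS = (
    lambda x: x,
    lambda x: x**2,
    lambda x: np.sin(np.pi * x),
    lambda x: np.cos(np.pi * x),
    lambda x: 1.0 / (1.0 + np.exp(-6.0 * (x - 0.5))),
)


def gen_expression_panel(cfg: ExpressionSimConfig) -> ExpressionPanel:
    """Simulate a genes x samples panel along a developmental gradient.

    Dynamic genes follow smooth functions of latent time, shifted per
    genotype by its heterochronic offset; module genes share a latent
    factor (constant within a genotype/stage group) at the configured
    correlation; replicates differ only by log-scale noise.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{i:05d}" for i in range(cfg.n_genes)]
    stage_labels = list(cfg.stages)
    t_lo = min(cfg.stages.values())
    t_hi = max(cfg.stages.values())
    span = max(t_hi - t_lo, 1.0)

    samples, genos, stages, reps, times = [], [], [], [], []
    for geno, offset in cfg.genotypes.items():
        for stage in stage_labels:
            for r in range(cfg.n_replicates):
                samples.append(f"{geno}.{stage}.r{r + 1}")
                genos.append(geno)
                stages.append(stage)
                reps.append(r + 1)
                times.append(cfg.stages[stage] + offset)
    times = np.asarray(times)
    n_samples = len(samples)

    baseline = rng.normal(4.0, 1.0, size=cfg.n_genes)
    log2 = np.tile(baseline[:, None], (1, n_samples))

    # dynamic genes: amplitude-scaled smooth patterns of normalized time
    x = (times - t_lo) / span
    for gi in range(cfg.n_dynamic):
        f = _PATTERNS[int(rng.integers(len(_PATTERNS)))]
        amp = rng.uniform(1.5, 3.5) * (1 if rng.random() < 0.5 else -1)
        log2[gi] += amp * f(x)

    # module genes share a per-(genotype, stage) latent factor
    module_assignment: dict[str, int] = {}
    group_key = [f"{g}|{s}" for g, s in zip(genos, stages)]
    group_ids = {k: i for i, k in enumerate(dict.fromkeys(group_key))}
    group_index = np.array([group_ids[k] for k in group_key])
    nxt = cfg.n_dynamic
    for mi, (size, rho) in enumerate(cfg.module_spec):
        factor_group = rng.normal(0.0, 1.0, size=len(group_ids))
        if len(group_ids) > 1 and factor_group.std() > 0:
            # standardize the realization so the planted within-module
            # correlation is not biased by the factor's sampling variance
            factor_group = (factor_group - factor_group.mean()) / factor_group.std()
        factor = factor_group[group_index]
        if rho >= 1.0:
            load = 1.0
            indiv_sd = 0.0
        else:
            # cor(g1, g2) = load^2 / (load^2 + indiv_sd^2) = rho
            indiv_sd = 1.0
            load = math.sqrt(rho / (1.0 - rho))
        for gi in range(nxt, nxt + size):
            indiv = rng.normal(0.0, indiv_sd, size=len(group_ids))[group_index]
            log2[gi] += load * factor + indiv
            module_assignment[genes[gi]] = mi
        nxt += size

    if cfg.noise_sd > 0:
        log2 += rng.normal(0.0, cfg.noise_sd, size=log2.shape)

    tpm = np.power(2.0, log2)
    mean_counts = tpm * (cfg.count_depth / max(tpm.mean(), 1e-12))
    if cfg.nb_dispersion > 0:
        lam = rng.gamma(
            shape=1.0 / cfg.nb_dispersion,
            scale=mean_counts * cfg.nb_dispersion,
        )
    else:
        lam = mean_counts
    counts = rng.poisson(lam).astype(np.int64)

    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "genotype": genos,
            "tissue": "tassel",
            "stage": stages,
            "replicate": reps,
        }
    )
    return ExpressionPanel(
        tpm=pd.DataFrame(tpm, index=genes, columns=samples),
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        metadata=meta,
        latent_time=pd.Series(times, index=samples, name="latent_time"),
        dynamic_genes=genes[: cfg.n_dynamic],
        module_assignment=module_assignment,
    )


# ---------------------------------------------------------------------------
# regulatory truth
# ---------------------------------------------------------------------------


def gen_regulatory_truth(
    cfg: RegulatorySimConfig,
) -> tuple[nx.DiGraph, pd.DataFrame, list[str]]:
    """Ground-truth directed network plus expression consistent with it.

    Returns (truth graph, genes x samples expression, TF list).  Every
    regulated gene's expression is a weighted sum of its generating
    parents plus ``edge_noise``-scaled Gaussian noise; a single-parent
    target is an exact copy (weight 1) of its regulator when edge_noise
    is 0.  Planted motifs occupy disjoint node triples, so the truth graph
    contains at least the requested count of each class.
    """
    rng = np.random.default_rng(cfg.seed)
    tfs = [f"TF{i:04d}" for i in range(cfg.n_tfs)]
    targets = [f"G{i:05d}" for i in range(cfg.n_targets)]
    g = nx.DiGraph()
    g.add_nodes_from(tfs + targets)

    # generation parents (acyclic) may differ from truth arcs for mutual
    # pairs, where the second node is generated as a copy of the first
    gen_parents: dict[str, list[str]] = {}
    free_tfs = list(tfs)
    free_targets = list(targets)

    def take_tfs(k: int) -> list[str]:
        out = [free_tfs.pop() for _ in range(k)]
        return out

    for _ in range(cfg.planted_motifs.get("ffl", 0)):
        x, y = take_tfs(2)
        z = free_targets.pop()
        g.add_edges_from([(x, y), (x, z), (y, z)])
        gen_parents[y] = [x]
        gen_parents[z] = [x, y]
    for _ in range(cfg.planted_motifs.get("mutual_out", 0)):
        x, y = take_tfs(2)
        z = free_targets.pop()
        g.add_edges_from([(x, y), (y, x), (x, z), (y, z)])
        gen_parents[y] = [x]  # mutual partner generated as a copy
        gen_parents[z] = [x, y]
    for _ in range(cfg.planted_motifs.get("regulating_mutual", 0)):
        x, y, z = take_tfs(3)
        g.add_edges_from([(x, y), (x, z), (y, z), (z, y)])
        gen_parents[y] = [x]
        gen_parents[z] = [x, y]

    # wire remaining targets to 1-3 random TFs
    for t in free_targets:
        k = int(rng.integers(1, 4))
        parents = list(rng.choice(tfs, size=min(k, len(tfs)), replace=False))
        g.add_edges_from([(p, t) for p in parents])
        gen_parents[t] = parents

    # expression: roots ~ N(0,1); regulated genes in dependency order
    expr: dict[str, np.ndarray] = {}
    for tf in tfs:
        if tf not in gen_parents:
            expr[tf] = rng.normal(0.0, 1.0, size=cfg.n_samples)

    def emit(node: str) -> np.ndarray:
        if node in expr:
            return expr[node]
        parents = gen_parents[node]
        if len(parents) == 1:
            signal = emit(parents[0]).copy()
        else:
            w = rng.uniform(0.5, 1.5, size=len(parents))
            w *= rng.choice([-1.0, 1.0], size=len(parents))
            signal = sum(wi * emit(p) for wi, p in zip(w, parents))
        sd = float(np.std(signal))
        noise = (
            rng.normal(0.0, cfg.edge_noise * (sd if sd > 0 else 1.0), cfg.n_samples)
            if cfg.edge_noise > 0
            else 0.0
        )
        expr[node] = signal + noise
        return expr[node]

    for node in tfs + targets:
        emit(node)

    mat = pd.DataFrame(
        np.vstack([expr[n] for n in tfs + targets]),
        index=tfs + targets,
        columns=[f"s{i:03d}" for i in range(cfg.n_samples)],
    )
    return g, mat, tfs


# ---------------------------------------------------------------------------
# genotypes and phenotypes
# ---------------------------------------------------------------------------


def gen_genotypes(cfg: GenoPhenoSimConfig) -> GenotypeMatrix:
    """Simulate a dosage panel with Markov-copying LD and subpopulations."""
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_snps
    p_anc = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)

    if cfg.n_subpops > 1 and cfg.fst > 0:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        freqs = rng.beta(a, b, size=(cfg.n_subpops, m))
        subpop = np.repeat(np.arange(cfg.n_subpops), math.ceil(n / cfg.n_subpops))[:n]
    else:
        freqs = np.tile(p_anc, (max(cfg.n_subpops, 1), 1))
        subpop = np.repeat(np.arange(max(cfg.n_subpops, 1)), math.ceil(n / max(cfg.n_subpops, 1)))[:n]

    p_ind = freqs[subpop]  # n x m per-individual frequencies
    dosage = np.zeros((n, m), dtype=float)
    for _hap in range(2):
        base = (rng.random((n, m)) < p_ind).astype(np.int8)
        hap = np.empty((n, m), dtype=np.int8)
        hap[:, 0] = base[:, 0]
        if cfg.ld_rho > 0:
            copy = rng.random((n, m)) < cfg.ld_rho
            for j in range(1, m):
                hap[:, j] = np.where(copy[:, j], hap[:, j - 1], base[:, j])
        else:
            hap[:, 1:] = base[:, 1:]
        dosage += hap

    if cfg.missing_rate > 0:
        mask = rng.random((n, m)) < cfg.missing_rate
        dosage[mask] = np.nan

    pos = 1 + np.arange(m) * cfg.snp_spacing
    snps = pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "id": [f"snp{i:06d}" for i in range(m)],
            "ref": "A",
            "alt": "T",
        }
    )
    individuals = [f"line{i:04d}" for i in range(n)]
    return GenotypeMatrix(dosage=dosage, snps=snps, individuals=individuals, subpop=subpop)


def gen_phenotypes(genotypes: GenotypeMatrix, cfg: GenoPhenoSimConfig) -> PhenotypeTable:
    """Two traits with chosen h2 and shared causal loci, plus field records.

    Causal SNPs are those inside cfg.causal_windows; effect pairs are drawn
    bivariate normal with the configured genetic correlation.  Genetic
    values are rescaled so var(g)/var(g+e) equals each trait's target
    exactly; year and block-within-year effects are layered on top of the
    line value to produce a replicated record table.
    """
    if not cfg.causal_windows:
        raise ValueError("causal window set is empty")
    rng = np.random.default_rng(cfg.seed + 1)
    pos = genotypes.snps["pos"].to_numpy()
    causal = np.zeros(genotypes.n_snps, dtype=bool)
    for a, b in cfg.causal_windows:
        causal |= (pos >= a) & (pos <= b)
    if not causal.any():
        raise ValueError("causal windows overlap no simulated SNP")

    X = np.nan_to_num(genotypes.dosage[:, causal], nan=0.0)
    X = X - X.mean(axis=0)
    n_causal = X.shape[1]
    n_traits = len(cfg.h2_targets)
    rho = cfg.genetic_correlation
    # common-factor construction gives exact correlation, including |rho|=1
    common = rng.normal(size=n_causal)
    effects = np.empty((n_causal, n_traits))
    for t in range(n_traits):
        if abs(rho) == 1.0:
            effects[:, t] = common * (1.0 if t == 0 or rho > 0 else -1.0)
        else:
            own = rng.normal(size=n_causal)
            s = math.copysign(1.0, rho) if t > 0 else 1.0
            r = abs(rho)
            effects[:, t] = (
                common if t == 0 else s * (math.sqrt(r) * common + math.sqrt(1 - r) * own)
            )

    genetic = X @ effects  # n x t
    n = genotypes.n_individuals
    line_vals = np.zeros_like(genetic)
    realized = []
    for t, h2 in enumerate(cfg.h2_targets):
        g = genetic[:, t]
        vg = float(np.var(g))
        if h2 == 0 or vg == 0:
            genetic[:, t] = 0.0
            g = genetic[:, t]
            e = rng.normal(0.0, 1.0, size=n)
        else:
            g = g * math.sqrt(h2 / vg)  # var(g) = h2, total variance 1
            genetic[:, t] = g
            e = rng.normal(0.0, math.sqrt(1.0 - h2), size=n)
        line_vals[:, t] = g + e
        tot = float(np.var(g) + np.var(e))
        realized.append(float(np.var(g) / tot) if tot > 0 else 0.0)

    trait_cols = [f"trait_{t + 1}" for t in range(n_traits)]
    ids = genotypes.individuals
    years, blocks_per_year, plants = 3, 2, 3
    rows = []
    year_eff = rng.normal(0.0, 0.3, size=years)
    block_eff = rng.normal(0.0, 0.2, size=(years, blocks_per_year))
    for j in range(years):
        for k in range(blocks_per_year):
            for s in range(plants):
                noise = rng.normal(0.0, 0.5, size=(n, n_traits))
                vals = line_vals + year_eff[j] + block_eff[j, k] + noise
                for i, gid in enumerate(ids):
                    rows.append(
                        [gid, 2018 + j, f"y{j}b{k}", s + 1, *vals[i].tolist()]
                    )
    records = pd.DataFrame(
        rows, columns=["genotype", "year", "block", "plant", *trait_cols]
    )
    return PhenotypeTable(
        records=records,
        line_values=pd.DataFrame(line_vals, index=ids, columns=trait_cols),
        genetic_values=pd.DataFrame(genetic, index=ids, columns=trait_cols),
        realized_h2=tuple(realized),
    )


# ---------------------------------------------------------------------------
# read depth
# ---------------------------------------------------------------------------


def gen_read_depth(cfg: ReadDepthSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-line binned read counts with planted deletions.

    Carrier lines draw Poisson(mean_coverage) per bin; lines lacking the
    region draw Poisson(mean_coverage * residual_rate) (residual
    mismapping).  Returns (table, truth) where truth is 'present'/'absent'
    per line.
    """
    rng = np.random.default_rng(cfg.seed)
    absent = rng.random(cfg.n_lines) < cfg.sv_absent_fraction
    lam = np.where(absent, cfg.mean_coverage * cfg.residual_rate, cfg.mean_coverage)
    counts = rng.poisson(lam[:, None], size=(cfg.n_lines, cfg.n_bins))
    lines = [f"line{i:04d}" for i in range(cfg.n_lines)]
    table = pd.DataFrame(
        counts, index=lines, columns=[f"bin_{b + 1}" for b in range(cfg.n_bins)]
    )
    table["total"] = table.sum(axis=1)
    truth = pd.Series(np.where(absent, "absent", "present"), index=lines, name="truth")
    return table, truth
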