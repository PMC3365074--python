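"""Pathway crosstalk on a weighted protein-interaction network.

Each network node carries the differential-expression p-value of its gene at
a chosen stage; each edge carries the co-expression p-value of its endpoint
pair (two-sided Pearson test over the stage's samples). The three p-values of
an edge e = {x, y} are combined into an edge score by Fisher's method,

    S(e) = -2 * (ln p_diff(x) + ln p_diff(y) + ln p_coexpr(x, y)),

which is nonnegative and strictly decreasing in each p-value (Stouffer's Z is
available as an alternative combiner). The crosstalk score of a pathway pair
(Pi, Pj) sums S(e) over the overlap O_ij — the edges with one endpoint in each
pathway, edges inside the intersection counting once. Significance is
assessed by a permutation null: random gene-set pairs of the same sizes drawn
from the pathway-covered portion of the network, with the add-one empirical
p-value P(random C >= observed C).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset
from .deg import moderated_t
from .enrichment import PathwaySet

logger = logging.getLogger(__name__)

COMBINE_FISHER = "fisher"
COMBINE_STOUFFER = "stouffer"

_P_FLOOR = np.finfo(float).tiny


def edge_score(p1: float, p2: float, p3: float, method: str = COMBINE_FISHER) -> float:
    """Combine an edge's three p-values into a nonnegative score.

    ``fisher``: S = -2 (ln p1 + ln p2 + ln p3), the default and the scale the
    crosstalk statistics are reported on. ``stouffer``: the normalized sum of
    normal quantiles (can be negative for weak evidence). Zero p-values are
    floored at the smallest positive float with a warning.
    """
    ps = np.array([p1, p2, p3], dtype=float)
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(ps == 0):
        warnings.warn("zero p-value floored at the machine minimum")
        ps = np.maximum(ps, _P_FLOOR)
    return float(_combine(ps[None, :], method)[0])


def _combine(ps: np.ndarray, method: str) -> np.ndarray:
    if method == COMBINE_FISHER:
        return -2.0 * np.log(ps).sum(axis=1)
    if method == COMBINE_STOUFFER:
        z = stats.norm.isf(np.minimum(ps, 1 - 1e-16))
        return z.sum(axis=1) / np.sqrt(ps.shape[1])
    raise ValueError(f"unknown combination method {method!r}")


@dataclasses.dataclass
class WeightedPPINetwork:
    """Simple PPI graph with node and edge significance weights.

    ``edges_u``/``edges_v`` index into ``nodes``; ``node_p`` are per-gene
    differential-expression p-values; ``edge_p`` the per-edge co-expression
    p-values; ``edge_scores`` the combined S(e).
    """

    nodes: list[str]
    node_p: np.ndarray
    edges_u: np.ndarray
    edges_v: np.ndarray
    edge_p: np.ndarray
    edge_scores: np.ndarray
    combine_method: str = COMBINE_FISHER

    def __post_init__(self) -> None:
        if len(self.edges_u) != len(self.edges_v):
            raise ValueError("edge endpoint arrays differ in length")
        if np.any(self.edges_u == self.edges_v):
            raise ValueError("self-loops are not allowed")
        key = np.minimum(self.edges_u, self.edges_v) * len(self.nodes) + np.maximum(
            self.edges_u, self.edges_v)
        if len(np.unique(key)) != len(key):
            raise ValueError("duplicate edges are not allowed")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges_u)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def membership(self, genes: set[str]) -> np.ndarray:
        idx = self.node_index()
        mask = np.zeros(self.n_nodes, dtype=bool)
        for g in genes:
            if g in idx:
                mask[idx[g]] = True
        return mask

    def recompute_scores(self) -> np.ndarray:
        ps = np.column_stack([
            self.node_p[self.edges_u], self.node_p[self.edges_v], self.edge_p,
        ])
        return _combine(np.maximum(ps, _P_FLOOR), self.combine_method)

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        for i, g in enumerate(self.nodes):
            G.add_node(g, p_diff=float(self.node_p[i]))
        for u, v, p, s in zip(self.edges_u, self.edges_v, self.edge_p, self.edge_scores):
            G.add_edge(self.nodes[u], self.nodes[v], p_coexpr=float(p), score=float(s))
        return G

    def write_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def load_ppi_edges(path: str | Path) -> set[tuple[str, str]]:
    """Read an undirected PPI edge list TSV (two columns, optional header)."""
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in {"a", "protein_a", "#a"}:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                continue
            edges.add(tuple(sorted((a, b))))
    return edges


def write_ppi_edges(edges: set[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\n")


def weight_network(
    ppi_edges: set[tuple[str, str]],
    dataset: ExpressionDataset,
    stage: float,
    combine_method: str = COMBINE_FISHER,
) -> WeightedPPINetwork:
    """Map stage-wise significance onto the PPI graph.

    Node weights are the moderated-t differential-expression p-values at the
    stage; edge weights are two-sided Pearson-correlation p-values across the
    stage's samples (both arms pooled). Edges touching genes absent from the
    expression matrix are dropped (count logged); constant genes give
    p_coexpr = 1 on their edges with a warning.
    """
    measured = set(dataset.genes)
    kept = [(a, b) for a, b in ppi_edges if a in measured and b in measured]
    dropped = len(ppi_edges) - len(kept)
    if dropped:
        logger.info("dropping %d PPI edges without expression", dropped)
    if not kept:
        raise ValueError("no PPI edge has both endpoints measured")
    nodes = sorted({g for e in kept for g in e})
    node_pos = {g: i for i, g in enumerate(nodes)}

    de = moderated_t(dataset, stage)
    p_by_gene = dict(zip(de.genes, de.p))
    node_p = np.array([min(max(p_by_gene[g], _P_FLOOR), 1.0) if np.isfinite(p_by_gene[g]) else 1.0
                       for g in nodes])

    mask = dataset.sample_mask(time=stage)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"stage {stage}: need >=3 samples for co-expression, got {n}")
    X = dataset.values[:, mask]
    row_of = {g: i for i, g in enumerate(dataset.genes)}
    u_idx = np.array([node_pos[a] for a, b in kept])
    v_idx = np.array([node_pos[b] for a, b in kept])
    xu = X[[row_of[a] for a, b in kept], :]
    xv = X[[row_of[b] for a, b in kept], :]
    edge_p = _pearson_test_p(xu, xv, n)
    net = WeightedPPINetwork(
        nodes=nodes, node_p=node_p, edges_u=u_idx, edges_v=v_idx,
        edge_p=edge_p, edge_scores=np.zeros(len(kept)), combine_method=combine_method,
    )
    net.edge_scores = net.recompute_scores()
    return net


def _pearson_test_p(xu: np.ndarray, xv: np.ndarray, n: int) -> np.ndarray:
    """Vectorized two-sided Pearson-correlation test over edge pairs."""
    xu_c = xu - xu.mean(axis=1, keepdims=True)
    xv_c = xv - xv.mean(axis=1, keepdims=True)
    num = (xu_c * xv_c).sum(axis=1)
    den = np.sqrt((xu_c ** 2).sum(axis=1) * (xv_c ** 2).sum(axis=1))
    constant = den == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} edges touch constant genes; p_coexpr set to 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(constant, 0.0, num / np.where(den == 0, 1.0, den))
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(constant, 1.0, np.clip(p, _P_FLOOR, 1.0))
    return p


# --------------------------------------------------------------- overlap score


def overlap_score(
    p_i: set[str], p_j: set[str], net: WeightedPPINetwork,
) -> tuple[list[int], float]:
    """Overlap edge set O_ij and crosstalk score C for a pathway pair.

    An edge {x, y} qualifies when one endpoint lies in Pi and the other in Pj
    (in either orientation); edges inside the intersection qualify and count
    once. Returns the qualifying edge indices and the summed score.
    """
    in_i = net.membership(p_i)
    in_j = net.membership(p_j)
    u, v = net.edges_u, net.edges_v
    mask = (in_i[u] & in_j[v]) | (in_j[u] & in_i[v])
    idx = np.flatnonzero(mask)
    return idx.tolist(), float(net.edge_scores[idx].sum())


@dataclasses.dataclass
class CrosstalkResult:
    pathway_i: str
    pathway_j: str
    overlap_edges: list[int]
    c_score: float
    n_permutations: int
    p_value: float
    empty_overlap: bool = False


def permutation_pvalue(
    p_i: set[str],
    p_j: set[str],
    net: WeightedPPINetwork,
    B: int = 10_000,
    seed: int = 0,
    universe: set[str] | None = None,
    names: tuple[str, str] = ("Pi", "Pj"),
) -> CrosstalkResult:
    """Permutation significance of the crosstalk score of one pathway pair.

    ``B`` random draws of two independent gene sets of sizes |Pi ∩ network|
    and |Pj ∩ network| are taken from the sampling universe (default: all
    network nodes; pass the pathway-covered node set to condition on pathway
    membership). The reported p is the add-one estimator
    (1 + #{C_random >= C_obs}) / (B + 1). A zero observed score short-circuits
    to p = 1 with the empty-overlap flag.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    idx, c_obs = overlap_score(p_i, p_j, net)
    if c_obs == 0.0:
        return CrosstalkResult(names[0], names[1], idx, 0.0, B, 1.0, empty_overlap=True)
    in_i = net.membership(p_i)
    in_j = net.membership(p_j)
    ni, nj = int(in_i.sum()), int(in_j.sum())
    if universe is None:
        pool = np.arange(net.n_nodes)
    else:
        pool = np.flatnonzero(net.membership(universe))
    if len(pool) < max(ni, nj) + 1:
        raise ValueError("sampling universe too small for the pathway sizes")
    rng = np.random.default_rng(seed)
    c_rand = _batched_null_scores(net, pool, ni, nj, B, rng)
    n_ge = int(np.sum(c_rand >= c_obs))
    p = (1 + n_ge) / (B + 1)
    return CrosstalkResult(names[0], names[1], idx, c_obs, B, p)


def _batched_null_scores(net: WeightedPPINetwork, pool: np.ndarray, ni: int,
                         nj: int, B: int, rng: np.random.Generator,
                         batch: int = 500) -> np.ndarray:
    """Null C scores for B random same-size set pairs, in memory-bounded batches."""
    u, v, S = net.edges_u, net.edges_v, net.edge_scores
    out = np.empty(B)
    done = 0
    n_pool = len(pool)
    while done < B:
        nb = min(batch, B - done)
        in_a = np.zeros((nb, net.n_nodes), dtype=bool)
        in_b = np.zeros((nb, net.n_nodes), dtype=bool)
        # two independent uniform draws without replacement per row
        keys = rng.random((nb, n_pool)).argpartition(ni, axis=1)[:, :ni]
        rows = np.repeat(np.arange(nb), ni)
        in_a[rows, pool[keys.ravel()]] = True
        keys = rng.random((nb, n_pool)).argpartition(nj, axis=1)[:, :nj]
        rows = np.repeat(np.arange(nb), nj)
        in_b[rows, pool[keys.ravel()]] = True
        qual = (in_a[:, u] & in_b[:, v]) | (in_b[:, u] & in_a[:, v])
        out[done:done + nb] = qual @ S
        done += nb
    return out


def crosstalk_dynamics(
    pairs: list[tuple[str, str]],
    pathways: PathwaySet,
    ppi_edges: set[tuple[str, str]],
    dataset: ExpressionDataset,
    B: int = 10_000,
    seed: int = 0,
    stages: list[float] | None = None,
    universe: set[str] | None = None,
    combine_method: str = COMBINE_FISHER,
    significance: float = 0.1,
    weak_significance: float = 0.3,
) -> pd.DataFrame:
    """Stage-resolved crosstalk table for a list of pathway pairs.

    The network is re-weighted at each stage and every pair is re-scored;
    draws are seeded per (stage, pair) from the top-level seed so the table is
    reproducible and insensitive to pair order. Columns include the C score,
    the empirical p and significance flags at the strong/weak thresholds.
    """
    stages = stages if stages is not None else dataset.stages
    if not stages:
        raise ValueError("no stages available")
    missing = [s for s in stages if not dataset.sample_mask(time=s).any()]
    if missing:
        raise ValueError(f"stages missing from dataset: {missing}")
    if universe is None:
        universe = set().union(*pathways.pathways.values())
    ss = np.random.SeedSequence(seed)
    rows = []
    for si, stage in enumerate(stages):
        net = weight_network(ppi_edges, dataset, stage, combine_method=combine_method)
        for pi_name, pj_name in pairs:
            child = np.random.SeedSequence(entropy=seed, spawn_key=(si, _pair_key(pi_name, pj_name)))
            pair_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            res = permutation_pvalue(
                pathways.pathways[pi_name], pathways.pathways[pj_name], net,
                B=B, seed=pair_seed, universe=universe, names=(pi_name, pj_name),
            )
            rows.append({
                "pathway_i": pi_name, "pathway_j": pj_name, "stage": stage,
                "c_score": res.c_score, "n_overlap_edges": len(res.overlap_edges),
                "B": res.n_permutations, "p": res.p_value,
                "empty_overlap": res.empty_overlap,
                "significant": res.p_value < significance,
                "nonsignificant_weak": res.p_value > weak_significance,
            })
    _ = ss
    return pd.DataFrame(rows)


def _pair_key(a: str, b: str) -> int:
    key = "|".join(sorted((a, b)))
    h = 0
    for ch in key:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def null_calibration_pvalues(
    n_pairs: int = 200,
    B: int = 2000,
    seed: int = 0,
    n_genes: int = 300,
    pathway_size: int = 30,
    base_edge_prob: float = 0.008,
    noise_sd: float = 0.1,
    stage: float = 4.0,
) -> np.ndarray:
    """Null permutation p-values over independent synthetic replicates.

    Calibration diagnostic for the crosstalk test: each replicate draws a
    fresh expression dataset, PPI skeleton and an unrelated pathway pair
    (no planted cross-edge enrichment), then scores the pair against its own
    permutation null. Because the replicates are independent, the returned
    p-values are i.i.d. and should be approximately uniform on (0, 1] — a
    Kolmogorov-Smirnov check against uniformity is meaningful here, unlike on
    many pairs sharing one network, whose p-values are correlated.
    """
    from . import synthetic as synth

    ss = np.random.SeedSequence(seed)
    pvals = np.empty(n_pairs)
    for k, child in enumerate(ss.spawn(n_pairs)):
        s_truth, s_expr, s_ppi, s_perm = (
            int(c.generate_state(1)[0] % (2**31 - 1)) for c in child.spawn(4))
        truth = synth.generate_truth(n_genes=n_genes, n_tfs=10, targets_per_tf=5,
                                     seed=s_truth)
        dataset = synth.generate_expression(truth, noise_sd=noise_sd, seed=s_expr)
        edges, pathways, _ = synth.generate_ppi_pathways(
            n_genes=n_genes, n_pathways=2, pathway_size=pathway_size,
            n_planted_pairs=0, cross_edge_boost=1.0, seed=s_ppi,
            base_edge_prob=base_edge_prob,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = weight_network(edges, dataset, stage=stage)
        a, b = sorted(pathways.pathways)
        res = permutation_pvalue(pathways.pathways[a], pathways.pathways[b],
                                 net, B=B, seed=s_perm)
        pvals[k] = res.p_value
    return pvals
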