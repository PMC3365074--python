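"""Post-decomposition analytics on TF activities and control strengths.

Covers four analyses performed on a fitted decomposition: correlation of each
TF's inferred activity with its own expression time course, the TF x TF
activity correlation matrix, combinatorial-regulation pair calls (activity
correlation and/or protein-interaction support), and hierarchical clustering
of genes on their normalized strength rows.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .datasets import TREATED, ExpressionDataset
from .nca import NCAResult

EVIDENCE_BOTH = "both"
EVIDENCE_CORRELATION = "correlation_only"
EVIDENCE_PPI = "ppi_only"


@dataclasses.dataclass
class CombinatorialPair:
    tf_a: str
    tf_b: str
    activity_correlation: float
    ppi_supported: bool
    evidence_class: str


def tfa_expression_correlation(result: NCAResult, dataset: ExpressionDataset) -> pd.Series:
    """Pearson r of each TF's activity against its own mean expression.

    The expression series is the treated-arm replicate mean at each fitted
    condition, normalized to the time-zero value when time 0 is among the
    conditions. TFs not measured in the dataset, or fits with fewer than 3
    conditions, are reported as NaN.
    """
    out = {}
    conds = result.conditions
    enough = len(conds) >= 3
    measured = set(dataset.genes)
    times = [t for t in conds if dataset.sample_mask(t, TREATED).any()]
    for j, tf in enumerate(result.tfs):
        if not enough or tf not in measured or len(times) != len(conds):
            out[tf] = np.nan
            continue
        expr = dataset.mean_profile(TREATED, times)[dataset.gene_index(tf), :]
        if 0.0 in conds:
            expr = expr - expr[conds.index(0.0)]
        act = result.activities[j, :]
        out[tf] = _pearson(act, expr)
    return pd.Series(out, name="r")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    den = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if den == 0:
        return np.nan
    return float(np.clip((xc * yc).sum() / den, -1.0, 1.0))


def tfa_correlation_matrix(result: NCAResult) -> pd.DataFrame:
    """Symmetric TF x TF Pearson correlation of activity rows.

    Constant activity rows yield NaN rows/columns (off-diagonal); requires at
    least 3 conditions.
    """
    if len(result.conditions) < 3:
        raise ValueError("need >=3 conditions for an activity correlation matrix")
    P = result.activities
    L = P.shape[0]
    C = np.eye(L)
    for i in range(L):
        for j in range(i + 1, L):
            C[i, j] = C[j, i] = _pearson(P[i], P[j])
    return pd.DataFrame(C, index=result.tfs, columns=result.tfs)


def infer_combinatorial_pairs(
    corr: pd.DataFrame,
    ppi_edges: set[tuple[str, str]],
    r_threshold: float = 0.6,
) -> list[CombinatorialPair]:
    """Call TF pairs supported by activity correlation and/or a PPI edge.

    A pair is emitted when |r| > r_threshold or the two TFs share a
    protein-interaction edge; the evidence class records which. Pairs are
    canonicalized (tf_a < tf_b) and the output is independent of input order.
    """
    tfs = sorted(corr.index)
    ppi = {tuple(sorted(e)) for e in ppi_edges}
    pairs: list[CombinatorialPair] = []
    for i, a in enumerate(tfs):
        for b in tfs[i + 1:]:
            r = float(corr.loc[a, b])
            high_corr = np.isfinite(r) and abs(r) > r_threshold
            has_ppi = (a, b) in ppi
            if not (high_corr or has_ppi):
                continue
            cls = (EVIDENCE_BOTH if high_corr and has_ppi
                   else EVIDENCE_CORRELATION if high_corr else EVIDENCE_PPI)
            pairs.append(CombinatorialPair(a, b, r, has_ppi, cls))
    return pairs


def pairs_to_frame(pairs: list[CombinatorialPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"tf_a": p.tf_a, "tf_b": p.tf_b, "r": p.activity_correlation,
          "ppi_supported": p.ppi_supported, "evidence_class": p.evidence_class}
         for p in pairs],
        columns=["tf_a", "tf_b", "r", "ppi_supported", "evidence_class"],
    )


# ------------------------------------------------------------------ clustering


@dataclasses.dataclass
class StrengthClustering:
    genes: list[str]
    linkage_matrix: np.ndarray
    flat_clusters: dict[str, int]
    major_clusters: list[int]          # cluster labels with > major_size members
    ordered_matrix: pd.DataFrame       # strength matrix in dendrogram leaf order
    newick: str


def cluster_strengths(
    result: NCAResult,
    linkage: str = "average",
    cut_height: float | None = None,
    major_size: int = 3,
    append_expression: bool = True,
) -> StrengthClustering:
    """Hierarchically cluster genes on their (normalized) strength rows.

    Distance is Euclidean between strength rows; the flat cut defaults to half
    the maximal merge height. Clusters with more than ``major_size`` members
    are flagged as major clusters. The ordered matrix (optionally with the
    fitted log-ratio expression appended column-wise) supports heatmap export.
    """
    genes = list(result.genes)
    A = result.strengths
    if len(genes) < 2:
        return StrengthClustering(
            genes=genes, linkage_matrix=np.empty((0, 4)),
            flat_clusters={g: 1 for g in genes}, major_clusters=[],
            ordered_matrix=result.strengths_frame(), newick=f"{genes[0]};" if genes else ";",
        )
    Z = hierarchy.linkage(A, method=linkage, metric="euclidean")
    if cut_height is None:
        cut_height = float(Z[:, 2].max()) / 2.0
    labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")
    flat = dict(zip(genes, (int(x) for x in labels)))
    counts: dict[int, int] = {}
    for lab in labels:
        counts[int(lab)] = counts.get(int(lab), 0) + 1
    major = sorted(lab for lab, c in counts.items() if c > major_size)
    order = hierarchy.leaves_list(Z)
    mat = result.strengths_frame().iloc[order]
    if append_expression:
        expr = pd.DataFrame(result.log_ratios, index=result.genes,
                            columns=[f"E_{c}" for c in result.conditions]).iloc[order]
        mat = pd.concat([mat, expr], axis=1)
    return StrengthClustering(
        genes=genes, linkage_matrix=Z, flat_clusters=flat,
        major_clusters=major, ordered_matrix=mat,
        newick=_linkage_to_newick(Z, genes),
    )


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"


# -------------------------------------------------------------------- exports


def export_network(
    result: NCAResult,
    sif_path: str | Path | None = None,
    graphml_path: str | Path | None = None,
    locations: dict[str, str] | None = None,
    strength_threshold: float = 0.0,
) -> nx.DiGraph:
    """Export the fitted regulatory network as SIF and/or GraphML.

    Nodes are typed (``tf`` vs ``gene``); TF->gene edges carry the signed
    strength and its sign as attributes; optional subcellular locations are
    passed through as node attributes. Edges with |strength| at or below the
    threshold are omitted.
    """
    G = nx.DiGraph()
    tf_set = set(result.tfs)
    for g in result.genes:
        G.add_node(g, kind="tf" if g in tf_set else "gene")
    for tf in result.tfs:
        if tf not in G:
            G.add_node(tf, kind="tf")
    if locations:
        for node, loc in locations.items():
            if node in G:
                G.nodes[node]["location"] = loc
    for i, g in enumerate(result.genes):
        for j, tf in enumerate(result.tfs):
            w = float(result.strengths[i, j])
            if result.support_mask[i, j] and abs(w) > strength_threshold:
                G.add_edge(tf, g, strength=w, sign="+" if w >= 0 else "-")
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v, data in sorted(G.edges(data=True)):
                rel = "activates" if data["sign"] == "+" else "represses"
                fh.write(f"{u}\t{rel}\t{v}\n")
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    return G
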