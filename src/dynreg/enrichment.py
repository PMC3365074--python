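"""Pathway over-representation by the exact hypergeometric tail test.

Given a gene list (e.g. the selected DEGs) and a collection of pathway gene
sets over a background universe, the over-representation p-value for a pathway
with K members, a list of n genes and an overlap of k is the upper tail

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

with N the universe size. Pathways are then filtered by the overlap size and
a raw p-value threshold (no multiple-testing correction).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import pandas as pd
from scipy import stats


@dataclasses.dataclass
class PathwaySet:
    """Named gene sets over a background universe (GMT-compatible)."""

    pathways: dict[str, set[str]]
    universe: set[str]
    descriptions: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")

    def restricted_to_universe(self) -> "PathwaySet":
        """Intersect every pathway with the universe, dropping emptied ones."""
        restricted = {}
        for name, members in self.pathways.items():
            kept = members & self.universe
            if kept:
                restricted[name] = kept
        return PathwaySet(pathways=restricted, universe=set(self.universe),
                          descriptions=dict(self.descriptions))

    # ------------------------------------------------------------------- GMT

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.pathways):
                desc = self.descriptions.get(name, "na")
                members = "\t".join(sorted(self.pathways[name]))
                fh.write(f"{name}\t{desc}\t{members}\n")

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "PathwaySet":
        pathways: dict[str, set[str]] = {}
        descriptions: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT lines need name, description, genes")
                name, desc, *genes = fields
                genes = [g for g in genes if g]
                if not genes:
                    raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
                pathways[name] = set(genes)
                descriptions[name] = desc
        if universe is None:
            universe = set().union(*pathways.values())
        return cls(pathways=pathways, universe=universe, descriptions=descriptions)


def hypergeometric_enrichment(gene_list: set[str], pathways: PathwaySet) -> pd.DataFrame:
    """Exact hypergeometric upper-tail p per pathway.

    Genes outside the universe are dropped from the list with a warning.
    Columns: pathway, description, k (overlap), K (pathway size), n (list
    size), N (universe size), p.
    """
    if not pathways.universe:
        raise ValueError("empty universe")
    ps = pathways.restricted_to_universe()
    outside = set(gene_list) - ps.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the universe")
    query = set(gene_list) & ps.universe
    N = len(ps.universe)
    n = len(query)
    rows = []
    for name in sorted(ps.pathways):
        members = ps.pathways[name]
        K = len(members)
        k = len(members & query)
        # upper tail P(X >= k); sf(k-1) is exact in scipy's parametrization
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append({"pathway": name, "description": ps.descriptions.get(name, "na"),
                     "k": k, "K": K, "n": n, "N": N, "p": min(p, 1.0)})
    return pd.DataFrame(rows, columns=["pathway", "description", "k", "K", "n", "N", "p"])


def select_significant(
    results: pd.DataFrame,
    p_threshold: float = 0.1,
    min_members: int = 2,
) -> pd.DataFrame:
    """Keep pathways with at least ``min_members`` hits and p below threshold."""
    kept = results[(results["k"] >= min_members) & (results["p"] < p_threshold)]
    return kept.sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
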