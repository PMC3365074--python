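"""TF-target connectivity priors and identifiability of the bilinear model.

The connectivity prior is the zero-pattern constraint of network component
analysis: strength entries outside the supported (gene, TF) pairs are fixed at
zero. Uniqueness of the decomposition E = A P up to per-TF diagonal rescaling
requires three rank conditions on the pattern and the data:

(i)   the strength matrix A has full column rank;
(ii)  removing any one TF together with all of its target genes leaves a
      pattern that still has full column rank;
(iii) the activity matrix P has full row rank, for which the number of
      conditions must be at least the number of TFs (the part testable from
      the design alone).

Criteria (i) and (ii) are structural and are tested here on the support
pattern by generic rank: the rank of a random real matrix carried by the
pattern, replicated over several seeds. This matches the exact symbolic rank
of the pattern with probability one and is verified against a symbolic oracle
in the test suite on small patterns.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

SIGN_POS = "+"
SIGN_NEG = "-"
SIGN_UNKNOWN = "?"

PROVENANCE_PRIOR = "prior"
PROVENANCE_CLUSTERING = "clustering"

_GENERIC_RANK_SEEDS = (101, 202, 303)


@dataclasses.dataclass
class ConnectivityPrior:
    """Support set of allowed (gene, TF) regulatory pairs with optional signs.

    ``tfs`` and ``genes`` fix the column/row order of the pattern matrix;
    ``support`` holds (gene, tf) pairs; ``signs`` and ``provenance`` are
    per-pair annotations.
    """

    tfs: list[str]
    genes: list[str]
    support: set[tuple[str, str]]
    signs: dict[tuple[str, str], str] = dataclasses.field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tfs = list(self.tfs)
        self.genes = list(self.genes)
        self.support = set(self.support)
        known_tfs = set(self.tfs)
        known_genes = set(self.genes)
        for gene, tf in self.support:
            if tf not in known_tfs:
                raise ValueError(f"supported pair references unknown TF {tf!r}")
            if gene not in known_genes:
                raise ValueError(f"supported pair references unknown gene {gene!r}")

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def targets_of(self, tf: str) -> set[str]:
        return {g for g, t in self.support if t == tf}

    def pattern(self) -> np.ndarray:
        """Boolean (n_genes, n_tfs) support mask."""
        gi = {g: i for i, g in enumerate(self.genes)}
        ti = {t: j for j, t in enumerate(self.tfs)}
        mask = np.zeros((self.n_genes, self.n_tfs), dtype=bool)
        for gene, tf in self.support:
            mask[gi[gene], ti[tf]] = True
        return mask

    def drop_unregulated_genes(self) -> "ConnectivityPrior":
        """Drop genes with no supported regulator (they carry no signal)."""
        regulated = {g for g, _ in self.support}
        genes = [g for g in self.genes if g in regulated]
        return ConnectivityPrior(
            tfs=[t for t in self.tfs if self.targets_of(t)],
            genes=genes,
            support=set(self.support),
            signs=dict(self.signs),
            provenance=dict(self.provenance),
        )

    def subset_tfs(self, keep: list[str]) -> "ConnectivityPrior":
        keep_set = set(keep)
        support = {(g, t) for g, t in self.support if t in keep_set}
        regulated = {g for g, _ in support}
        return ConnectivityPrior(
            tfs=[t for t in self.tfs if t in keep_set],
            genes=[g for g in self.genes if g in regulated],
            support=support,
            signs={p: s for p, s in self.signs.items() if p in support},
            provenance={p: s for p, s in self.provenance.items() if p in support},
        )

    def merged_with(self, extra: set[tuple[str, str]],
                    signs: dict[tuple[str, str], str] | None = None) -> "ConnectivityPrior":
        """Union with additional pairs (marked as clustering-derived)."""
        signs = signs or {}
        support = set(self.support)
        new_signs = dict(self.signs)
        new_prov = dict(self.provenance)
        genes = list(self.genes)
        tfs = list(self.tfs)
        gene_set, tf_set = set(genes), set(tfs)
        for pair in sorted(extra):  # stable order: appended ids must not depend on set hashing
            gene, tf = pair
            if pair in support:
                continue
            support.add(pair)
            new_signs[pair] = signs.get(pair, SIGN_UNKNOWN)
            new_prov[pair] = PROVENANCE_CLUSTERING
            if gene not in gene_set:
                genes.append(gene)
                gene_set.add(gene)
            if tf not in tf_set:
                tfs.append(tf)
                tf_set.add(tf)
        return ConnectivityPrior(tfs=tfs, genes=genes, support=support,
                                 signs=new_signs, provenance=new_prov)

    # ------------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted(self.support)
        df = pd.DataFrame(
            {
                "tf": [t for _, t in rows],
                "target": [g for g, _ in rows],
                "sign": [self.signs.get(p, SIGN_UNKNOWN) for p in rows],
                "provenance": [self.provenance.get(p, PROVENANCE_PRIOR) for p in rows],
            }
        )
        df.to_csv(path, sep="\t", index=False)


def load_prior(path: str | Path) -> ConnectivityPrior:
    """Read a TF->target edge list TSV into a deduplicated prior.

    Columns: TF, target, optional sign (+/-/?), optional provenance. A header
    line is detected by the literal column name 'tf'. Self-regulation and
    TF-TF edges are retained. Duplicated rows collapse to one supported pair
    (the first stated sign wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    support: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], str] = {}
    provenance: dict[tuple[str, str], str] = {}
    tfs: list[str] = []
    genes: list[str] = []
    seen_tf, seen_gene = set(), set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].strip().lower() in {"tf", "#tf"}:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns, got {len(fields)}")
            tf, gene = fields[0].strip(), fields[1].strip()
            if not tf or not gene:
                raise ValueError(f"{path}:{lineno}: empty TF or target field")
            sign = fields[2].strip() if len(fields) > 2 and fields[2].strip() else SIGN_UNKNOWN
            if sign not in {SIGN_POS, SIGN_NEG, SIGN_UNKNOWN}:
                raise ValueError(f"{path}:{lineno}: bad sign {sign!r}")
            prov = fields[3].strip() if len(fields) > 3 and fields[3].strip() else PROVENANCE_PRIOR
            n_rows += 1
            pair = (gene, tf)
            if pair not in support:
                support.add(pair)
                signs[pair] = sign
                provenance[pair] = prov
            if tf not in seen_tf:
                seen_tf.add(tf)
                tfs.append(tf)
            if gene not in seen_gene:
                seen_gene.add(gene)
                genes.append(gene)
    if not support:
        raise ValueError(f"{path}: no edges found")
    logger.info("loaded prior: %d rows -> %d unique pairs, %d TFs, %d genes",
                n_rows, len(support), len(tfs), len(genes))
    return ConnectivityPrior(tfs=tfs, genes=genes, support=support,
                             signs=signs, provenance=provenance)


# ---------------------------------------------------------------- clustering


def augment_by_clustering(
    expression: ExpressionDataset,
    tfs: list[str],
    degs: list[str],
    r_threshold: float = 0.8,
    linkage: str = "average",
) -> tuple[set[tuple[str, str]], dict[tuple[str, str], str]]:
    """Propose extra (gene, TF) pairs from co-expression tree structure.

    TFs and candidate target genes are clustered together hierarchically on
    the distance 1 - |Pearson r| over all samples. A pair is proposed when the
    gene falls in the same subtree as the TF below merge height
    ``1 - r_threshold`` *and* the direct correlation satisfies
    ``|r| > r_threshold``. Returns the pairs and a sign per pair from the sign
    of the correlation.

    Genes with constant expression (undefined correlation) are excluded with
    a warning.
    """
    if expression.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation clustering")
    members = list(dict.fromkeys(list(tfs) + list(degs)))
    present = [g for g in members if g in set(expression.genes)]
    missing = set(members) - set(present)
    if missing:
        raise KeyError(f"genes absent from expression matrix: {sorted(missing)[:5]} ...")
    sub = expression.subset_genes(present)
    vals = sub.values
    sd = vals.std(axis=1)
    constant = sd == 0
    if constant.any():
        dropped = [g for g, c in zip(present, constant) if c]
        warnings.warn(f"excluding {len(dropped)} constant-expression genes from clustering")
        keep = [g for g, c in zip(present, constant) if not c]
        sub = sub.subset_genes(keep)
        vals = sub.values
        present = keep
    if len(present) < 2:
        return set(), {}
    corr = np.corrcoef(vals)
    corr = np.clip(corr, -1.0, 1.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # symmetrize away float noise
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage)
    # flat clusters below the merge-height cut: same cluster == same subtree
    labels = hierarchy.fcluster(Z, t=1.0 - r_threshold, criterion="distance")
    label_of = dict(zip(present, labels))
    tf_set = [t for t in tfs if t in label_of]
    deg_set = [g for g in degs if g in label_of]
    idx = {g: i for i, g in enumerate(present)}
    pairs: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], str] = {}
    for tf in tf_set:
        for gene in deg_set:
            if gene == tf:
                continue
            if label_of[tf] != label_of[gene]:
                continue
            r = corr[idx[tf], idx[gene]]
            if abs(r) > r_threshold:
                pairs.add((gene, tf))
                signs[(gene, tf)] = SIGN_POS if r > 0 else SIGN_NEG
    return pairs, signs


# ------------------------------------------------------------- identifiability


@dataclasses.dataclass
class IdentifiabilityReport:
    criterion_i: bool
    criterion_ii: dict[str, bool]
    criterion_iii: bool
    overall: bool
    generic_rank: int
    n_tfs: int
    n_samples: int

    def failing_tfs(self) -> list[str]:
        return [tf for tf, ok in self.criterion_ii.items() if not ok]


def _generic_rank(pattern: np.ndarray, seeds=_GENERIC_RANK_SEEDS) -> int:
    """Generic (maximal) rank of a zero-pattern via random instantiation."""
    if pattern.size == 0 or not pattern.any():
        return 0
    best = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        m = np.zeros(pattern.shape)
        m[pattern] = rng.uniform(0.5, 1.5, size=int(pattern.sum())) * rng.choice(
            [-1.0, 1.0], size=int(pattern.sum())
        )
        best = max(best, int(np.linalg.matrix_rank(m)))
    return best


def check_identifiability(prior: ConnectivityPrior, n_samples: int) -> IdentifiabilityReport:
    """Test the three rank conditions for uniqueness of the decomposition.

    Criterion (iii) is tested in its design-only necessary form:
    ``n_samples >= n_tfs``. The data-dependent part (actual row rank of the
    fitted activities) can only be checked after a fit.
    """
    if not prior.support:
        raise ValueError("empty prior")
    pattern = prior.pattern()
    L = prior.n_tfs
    rank = _generic_rank(pattern)
    crit_i = rank == L
    crit_ii: dict[str, bool] = {}
    ti = {t: j for j, t in enumerate(prior.tfs)}
    for tf in prior.tfs:
        j = ti[tf]
        target_rows = pattern[:, j]
        reduced = np.delete(pattern[~target_rows, :], j, axis=1)
        crit_ii[tf] = _generic_rank(reduced) == L - 1
    crit_iii = n_samples >= L
    overall = crit_i and all(crit_ii.values()) and crit_iii
    return IdentifiabilityReport(
        criterion_i=crit_i,
        criterion_ii=crit_ii,
        criterion_iii=crit_iii,
        overall=overall,
        generic_rank=rank,
        n_tfs=L,
        n_samples=n_samples,
    )


def reduce_to_identifiable(prior: ConnectivityPrior, n_samples: int) -> ConnectivityPrior:
    """Greedily prune TFs until the prior passes all identifiability checks.

    Each round drops one TF: first exact duplicates of another TF's target
    set (fewest targets first), then TFs implicated in a structural rank
    deficiency, and finally — when only the sample-count condition fails —
    the TF with the fewest targets. Pruning to an empty prior is an error.
    Genes left without a regulator are dropped at the end.
    """
    current = prior.drop_unregulated_genes()
    while True:
        report = check_identifiability(current, n_samples)
        if report.overall:
            return current.drop_unregulated_genes()
        victim = _pick_victim(current, report)
        remaining = [t for t in current.tfs if t != victim]
        if not remaining:
            raise ValueError("pruning removed every TF; prior cannot be made identifiable")
        logger.info("pruning TF %s (%d targets)", victim, len(current.targets_of(victim)))
        current = current.subset_tfs(remaining)


def _pick_victim(prior: ConnectivityPrior, report: IdentifiabilityReport) -> str:
    n_targets = {t: len(prior.targets_of(t)) for t in prior.tfs}
    # duplicated target sets: keep one representative, drop the smallest other
    by_targets: dict[frozenset, list[str]] = {}
    for t in prior.tfs:
        by_targets.setdefault(frozenset(prior.targets_of(t)), []).append(t)
    dup_candidates = [
        tf for group in by_targets.values() if len(group) > 1
        for tf in sorted(group, key=lambda t: (n_targets[t], t))[1:]
    ]
    if dup_candidates:
        return min(dup_candidates, key=lambda t: (n_targets[t], t))
    if not report.criterion_i or not all(report.criterion_ii.values()):
        # structural deficiency without duplicates: a redundant column exists;
        # drop the fewest-target TF among those whose removal does not lower
        # the generic rank (or among criterion-ii failures)
        pattern = prior.pattern()
        ti = {t: j for j, t in enumerate(prior.tfs)}
        redundant = []
        for tf in prior.tfs:
            reduced = np.delete(pattern, ti[tf], axis=1)
            if _generic_rank(reduced) == report.generic_rank:
                redundant.append(tf)
        pool = redundant or report.failing_tfs() or list(prior.tfs)
        return min(pool, key=lambda t: (n_targets[t], t))
    # only criterion iii fails: shrink the TF layer
    return min(prior.tfs, key=lambda t: (n_targets[t], t))
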