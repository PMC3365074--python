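"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates the four inputs of the analysis so every stage is testable without
external data: a sparse TF->gene connectivity with an identifiable pattern,
phase-patterned TF activity time courses (early/mid/late peaks over the time
course), log-linear expression with replicate noise for a treated and a
vehicle-control arm, and a protein-interaction graph with planted
cross-pathway edge enrichment plus pathway gene sets.

Ground truth is collected in :class:`SyntheticTruth` so recovery can be
scored: the true strengths and activities behind the expression matrix, the
genes whose true log-ratios clear the differential-expression definition, and
the pathway pairs with boosted cross edges.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np

from .connectivity import SIGN_NEG, SIGN_POS, ConnectivityPrior, check_identifiability
from .datasets import CONTROL, TREATED, ExpressionDataset, make_sample_id
from .enrichment import PathwaySet

PHASE_EARLY = "early"
PHASE_MID = "mid"
PHASE_LATE = "late"

# study-like defaults: a 0/4/12/24 h two-arm time course with 3 replicates
DEFAULT_TIMEPOINTS = (0.0, 4.0, 12.0, 24.0)
DEFAULT_NOISE_SD = 0.1
DEFAULT_REPLICATES = 3
DEFAULT_AMPLITUDE = 2.0
DEFAULT_PHASE_FRACTIONS = (1 / 3, 1 / 3, 1 / 3)

# a true log-ratio must clear twice the selection fold-change cut at >=2
# stages to count as a planted DEG, so planted calls are noise-robust
PLANTED_DEG_MARGIN = 2.0
_FC_CUT = np.log2(1.5)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def _tf_name(j: int) -> str:
    return f"TF{j:02d}"


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic study."""

    genes: list[str]
    tfs: list[str]
    timepoints: list[float]
    true_strengths: np.ndarray          # genes x TFs, zero off support
    true_activities: np.ndarray         # TFs x timepoints, zero at time 0
    support: set[tuple[str, str]]
    phase_labels: dict[str, str]
    planted_degs: set[str]
    planted_crosstalk_pairs: set[tuple[str, str]]
    seed: int
    prior: ConnectivityPrior | None = None

    def __post_init__(self) -> None:
        self.true_strengths = np.asarray(self.true_strengths, dtype=float)
        self.true_activities = np.asarray(self.true_activities, dtype=float)
        gi = {g: i for i, g in enumerate(self.genes)}
        ti = {t: j for j, t in enumerate(self.tfs)}
        mask = np.zeros(self.true_strengths.shape, dtype=bool)
        for gene, tf in self.support:
            mask[gi[gene], ti[tf]] = True
        if np.any(self.true_strengths[~mask] != 0):
            raise ValueError("true strengths have nonzero entries off the support")
        if 0.0 in self.timepoints:
            z = self.timepoints.index(0.0)
            if np.any(self.true_activities[:, z] != 0):
                raise ValueError("true activities must be zero at time 0")

    @property
    def log_ratio_matrix(self) -> np.ndarray:
        """Noise-free true log ratios, genes x timepoints."""
        return self.true_strengths @ self.true_activities

    def write_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.genes,
            "tfs": self.tfs,
            "timepoints": self.timepoints,
            "true_strengths": self.true_strengths.tolist(),
            "true_activities": self.true_activities.tolist(),
            "support": sorted(list(p) for p in self.support),
            "phase_labels": self.phase_labels,
            "planted_degs": sorted(self.planted_degs),
            "planted_crosstalk_pairs": sorted(list(p) for p in self.planted_crosstalk_pairs),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload) + "\n")


# ----------------------------------------------------------------- connectivity


def generate_connectivity(
    n_genes: int,
    n_tfs: int,
    targets_per_tf: int,
    seed: int,
) -> tuple[ConnectivityPrior, set[tuple[str, str]]]:
    """Random sparse TF->gene support that is identifiable by construction.

    Every TF receives one exclusive anchor target (a gene regulated by no
    other TF) plus ``targets_per_tf - 1`` draws from the shared non-anchor
    pool. Disjoint anchors make the pattern full column rank and keep it so
    after removing any TF with its targets, so the structural identifiability
    criteria hold by construction (and are asserted before returning).
    """
    if n_genes < 2 * n_tfs:
        raise ValueError(f"need n_genes >= 2*n_tfs (got {n_genes} genes for {n_tfs} TFs)")
    if targets_per_tf < 2:
        raise ValueError("targets_per_tf must be >= 2")
    if n_genes - n_tfs < targets_per_tf - 1:
        raise ValueError(
            "too few non-anchor genes: need n_genes - n_tfs >= targets_per_tf - 1"
        )
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    tfs = [_tf_name(j) for j in range(n_tfs)]
    anchor_idx = rng.choice(n_genes, size=n_tfs, replace=False)
    pool = np.setdiff1d(np.arange(n_genes), anchor_idx)
    support: set[tuple[str, str]] = set()
    for j, tf in enumerate(tfs):
        support.add((genes[anchor_idx[j]], tf))
        extra = rng.choice(pool, size=targets_per_tf - 1, replace=False)
        for gi in extra:
            support.add((genes[gi], tf))
    prior = ConnectivityPrior(tfs=tfs, genes=genes, support=support)
    report = check_identifiability(prior.drop_unregulated_genes(), n_samples=n_tfs)
    assert report.criterion_i and all(report.criterion_ii.values()), \
        "generated support unexpectedly fails identifiability"
    return prior, support


# ------------------------------------------------------------------- activities


def generate_tfa_profiles(
    n_tfs: int,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    phase_fractions: tuple[float, float, float] = DEFAULT_PHASE_FRACTIONS,
    amplitude: float = DEFAULT_AMPLITUDE,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, str]]:
    """Phase-patterned activity time courses, zero at time 0.

    Each TF is assigned an early, mid or late phase by the given fractions.
    Its activity rises from zero at time 0 to a signed peak (max |value|) at
    the first, middle or last nonzero time point and decays linearly
    afterwards. Rise curvature and decay rate vary per TF, so no two activity
    rows are proportional — same-phase TFs remain distinguishable, which keeps
    per-gene strengths identifiable for genes with two same-phase regulators.
    Peak heights are the amplitude with a modest per-TF jitter and a random
    sign. Returns the TFs x timepoints matrix and the phase labels keyed by
    generated TF name.
    """
    timepoints = tuple(float(t) for t in timepoints)
    if 0.0 not in timepoints:
        raise ValueError("timepoints must include 0")
    if abs(sum(phase_fractions) - 1.0) > 1e-9:
        raise ValueError("phase_fractions must sum to 1")
    nonzero = sorted(t for t in timepoints if t != 0)
    requested = sum(1 for f in phase_fractions if f > 0)
    if len(nonzero) < requested:
        raise ValueError(
            f"{requested} phases requested but only {len(nonzero)} nonzero timepoints"
        )
    rng = np.random.default_rng(seed)
    counts = _phase_counts(n_tfs, phase_fractions)
    phases = ([PHASE_EARLY] * counts[0] + [PHASE_MID] * counts[1] + [PHASE_LATE] * counts[2])
    rng.shuffle(phases)
    peak_time = {
        PHASE_EARLY: nonzero[0],
        PHASE_MID: nonzero[len(nonzero) // 2],
        PHASE_LATE: nonzero[-1],
    }
    order = sorted(timepoints)
    activities = np.zeros((n_tfs, len(order)))
    labels: dict[str, str] = {}
    t_arr = np.array(order)
    t_end = order[-1]
    for j in range(n_tfs):
        phase = phases[j]
        labels[_tf_name(j)] = phase
        peak = peak_time[phase]
        height = amplitude * rng.uniform(0.8, 1.2) * rng.choice([-1.0, 1.0])
        gamma = rng.uniform(0.7, 1.6)       # rise curvature, per TF
        decay = rng.uniform(0.5, 0.9)       # fraction of the peak lost by t_end
        prof = np.where(
            t_arr <= peak,
            height * (t_arr / peak) ** gamma,
            height * (1.0 - decay * (t_arr - peak) / max(t_end - peak, 1e-12)),
        )
        prof[t_arr == 0] = 0.0
        activities[j, :] = prof
    # column order must match the caller's timepoint order
    reorder = [order.index(t) for t in timepoints]
    return activities[:, reorder], labels


def _phase_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    while sum(counts) < n:
        i = int(np.argmax([r - c for r, c in zip(raw, counts)]))
        counts[i] += 1
    return counts


# -------------------------------------------------------------------- the truth


def generate_truth(
    n_genes: int = 50,
    n_tfs: int = 10,
    targets_per_tf: int = 5,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    phase_fractions: tuple[float, float, float] = DEFAULT_PHASE_FRACTIONS,
    amplitude: float = DEFAULT_AMPLITUDE,
    seed: int = 0,
) -> SyntheticTruth:
    """Sample a full ground truth: support, strengths and activities.

    Strengths on the support are signed, bounded away from zero
    (|a| in [0.5, 1.5]) so every supported edge matters. Planted DEGs are the
    regulated genes whose true log-ratio clears twice the standard
    fold-change cut at two or more nonzero timepoints.
    """
    ss = np.random.SeedSequence(seed)
    s_conn, s_act, s_str = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3))
    prior, support = generate_connectivity(n_genes, n_tfs, targets_per_tf, seed=s_conn)
    activities, phase_labels = generate_tfa_profiles(
        n_tfs, timepoints=timepoints, phase_fractions=phase_fractions,
        amplitude=amplitude, seed=s_act,
    )
    rng = np.random.default_rng(s_str)
    gi = {g: i for i, g in enumerate(prior.genes)}
    ti = {t: j for j, t in enumerate(prior.tfs)}
    strengths = np.zeros((n_genes, n_tfs))
    for gene, tf in sorted(support):  # sorted: draw order independent of set hashing
        mag = rng.uniform(0.5, 1.5)
        strengths[gi[gene], ti[tf]] = mag * rng.choice([-1.0, 1.0])
    log_ratios = strengths @ activities
    nz = [k for k, t in enumerate(timepoints) if t != 0]
    hits = (np.abs(log_ratios[:, nz]) > PLANTED_DEG_MARGIN * _FC_CUT).sum(axis=1)
    planted = {prior.genes[i] for i in range(n_genes) if hits[i] >= 2}
    return SyntheticTruth(
        genes=list(prior.genes),
        tfs=list(prior.tfs),
        timepoints=[float(t) for t in timepoints],
        true_strengths=strengths,
        true_activities=activities,
        support=support,
        phase_labels=phase_labels,
        planted_degs=planted,
        planted_crosstalk_pairs=set(),
        seed=seed,
        prior=prior,
    )


# ------------------------------------------------------------------- expression


def generate_expression(
    truth: SyntheticTruth,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    include_tf_mrna: bool = False,
    tf_mrna_coupling: float = 0.5,
) -> ExpressionDataset:
    """Replicated two-arm log2 expression generated from the truth.

    Treated-arm replicates at time t are baseline + (A P)[:, t] + Gaussian
    noise; control-arm replicates are baseline + noise (zero activities).
    Baselines are drawn once per gene, so fold changes are well defined and
    the noiseless log ratios reproduce A P exactly over the target-gene rows.

    With ``include_tf_mrna`` the matrix also carries one row per TF whose
    treated-arm mean tracks the TF's own activity with the given coupling —
    the regime where inferred activity and measured TF expression correlate.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    row_ids = list(truth.genes) + (list(truth.tfs) if include_tf_mrna else [])
    n_rows = len(row_ids)
    baseline = baseline_mean + baseline_sd * rng.standard_normal(n_rows)
    signal = truth.log_ratio_matrix
    if include_tf_mrna:
        signal = np.vstack([signal, tf_mrna_coupling * truth.true_activities])
    columns, sample_ids, times, conditions, replicates = [], [], [], [], []
    for k, t in enumerate(truth.timepoints):
        for condition in (TREATED, CONTROL):
            mean = baseline + (signal[:, k] if condition == TREATED else 0.0)
            for r in range(1, n_replicates + 1):
                noise = noise_sd * rng.standard_normal(n_rows) if noise_sd > 0 else 0.0
                columns.append(mean + noise)
                sample_ids.append(make_sample_id(t, condition, r))
                times.append(t)
                conditions.append(condition)
                replicates.append(r)
    return ExpressionDataset(
        genes=row_ids,
        samples=sample_ids,
        values=np.column_stack(columns),
        times=np.array(times),
        conditions=np.array(conditions, dtype=object),
        replicates=np.array(replicates),
    )


# ------------------------------------------------------------- PPI and pathways


def generate_ppi_pathways(
    n_genes: int,
    n_pathways: int,
    pathway_size: int,
    n_planted_pairs: int = 0,
    cross_edge_boost: float = 1.0,
    seed: int = 0,
    base_edge_prob: float = 0.005,
    disjoint_pathways: bool = False,
) -> tuple[set[tuple[str, str]], PathwaySet, set[tuple[str, str]]]:
    """Random PPI skeleton and pathway sets with optional planted crosstalk.

    Background edges are placed independently at ``base_edge_prob`` (a sparse
    rate in line with genome-scale interactomes). For each planted pathway
    pair the edge probability between the two member sets is multiplied by
    ``cross_edge_boost`` (clamped at 1 with a warning). The graph is simple.
    Pathways are uniform random gene sets, overlapping by default;
    ``disjoint_pathways`` partitions them instead (needs
    n_pathways * pathway_size <= n_genes), which makes the crosstalk score of
    a pair reflect only cross edges, never shared members. Planted pairs are
    pairs of distinct pathways, each pathway used at most once.
    """
    if cross_edge_boost < 1:
        raise ValueError("cross_edge_boost must be >= 1")
    if pathway_size > n_genes:
        raise ValueError("pathway_size exceeds the gene universe")
    if n_planted_pairs * 2 > n_pathways:
        raise ValueError("not enough pathways for the requested planted pairs")
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    if disjoint_pathways:
        if n_pathways * pathway_size > n_genes:
            raise ValueError("disjoint pathways need n_pathways*pathway_size <= n_genes")
        perm = rng.permutation(n_genes)
        members_idx = [perm[k * pathway_size:(k + 1) * pathway_size]
                       for k in range(n_pathways)]
    else:
        members_idx = [rng.choice(n_genes, size=pathway_size, replace=False)
                       for _ in range(n_pathways)]
    names = [f"PW{k:03d}" for k in range(n_pathways)]
    planted: set[tuple[str, str]] = set()
    order = rng.permutation(n_pathways)
    for k in range(n_planted_pairs):
        a, b = names[order[2 * k]], names[order[2 * k + 1]]
        planted.add(tuple(sorted((a, b))))

    prob = np.full((n_genes, n_genes), base_edge_prob)
    boosted = base_edge_prob * cross_edge_boost
    if boosted > 1.0:
        warnings.warn("boosted edge probability exceeds 1; clamped")
        boosted = 1.0
    name_pos = {nm: i for i, nm in enumerate(names)}
    for a, b in planted:
        ia, ib = members_idx[name_pos[a]], members_idx[name_pos[b]]
        prob[np.ix_(ia, ib)] = boosted
        prob[np.ix_(ib, ia)] = boosted
    draw = rng.random((n_genes, n_genes))
    upper = np.triu(np.ones((n_genes, n_genes), dtype=bool), k=1)
    adj = (draw < prob) & upper
    ui, vi = np.nonzero(adj)
    edges = {(genes[u], genes[v]) for u, v in zip(ui, vi)}
    pathways = PathwaySet(
        pathways={nm: {genes[i] for i in idx} for nm, idx in zip(names, members_idx)},
        universe=set(genes),
        descriptions={nm: "synthetic pathway" for nm in names},
    )
    return edges, pathways, planted


# ------------------------------------------------------------ DEG benchmark set


def generate_deg_benchmark(
    n_genes: int = 100,
    n_planted: int = 25,
    effect: float = 1.2,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    seed: int = 0,
) -> tuple[ExpressionDataset, set[str]]:
    """Two-arm dataset with a known set of multi-stage differential genes.

    Planted genes shift the treated arm by ``effect`` log2 units (random sign
    per gene) at every nonzero time point; the remaining genes are null at
    every stage. The default effect is roughly five noise standard deviations
    — a strong, unambiguous perturbation for benchmarking the selection rule.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [_gene_name(i) for i in range(n_genes)]
    planted_idx = rng.choice(n_genes, size=n_planted, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_planted)
    baseline = 7.0 + 1.5 * rng.standard_normal(n_genes)
    shift = np.zeros(n_genes)
    shift[planted_idx] = effect * signs
    columns, sample_ids, times, conditions, replicates = [], [], [], [], []
    for t in timepoints:
        for condition in (TREATED, CONTROL):
            mean = baseline + (shift if (condition == TREATED and t != 0) else 0.0)
            for r in range(1, n_replicates + 1):
                columns.append(mean + noise_sd * rng.standard_normal(n_genes))
                sample_ids.append(make_sample_id(t, condition, r))
                times.append(t)
                conditions.append(condition)
                replicates.append(r)
    dataset = ExpressionDataset(
        genes=genes, samples=sample_ids, values=np.column_stack(columns),
        times=np.array(times), conditions=np.array(conditions, dtype=object),
        replicates=np.array(replicates),
    )
    return dataset, {genes[i] for i in planted_idx}


# ----------------------------------------------------------------- sign helper


def support_signs(truth: SyntheticTruth) -> dict[tuple[str, str], str]:
    """Signs of the true strengths, for writing a signed prior edge list."""
    gi = {g: i for i, g in enumerate(truth.genes)}
    ti = {t: j for j, t in enumerate(truth.tfs)}
    return {
        (g, t): (SIGN_POS if truth.true_strengths[gi[g], ti[t]] >= 0 else SIGN_NEG)
        for g, t in truth.support
    }
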