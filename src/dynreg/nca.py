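"""Network component analysis: constrained bilinear decomposition E = A P.

The log-linear model of transcriptional control writes the relative log
expression of gene i at condition m as a weighted sum of latent TF activities,

    E[i, m] = sum_j A[i, j] * P[j, m],

where A (genes x TFs) carries the control strengths, constrained to be zero
outside a known connectivity support, and P (TFs x conditions) carries the
TF activity time courses. The decomposition is found by alternating least
squares on the objective ||E - A P||_F^2:

    (a) fixing P, each gene's supported strength entries solve an ordinary
        least-squares problem on the activity rows in that gene's support;
    (b) fixing A, the activities solve a full least-squares problem.

Both half-steps are exact minimizers, so the objective is non-increasing
across iterations. The fit is restarted from several random initializations
and the best final objective wins. The residual ambiguity of the model — a
per-TF rescaling A -> A X, P -> X^{-1} P with diagonal X — is resolved by an
explicit normalization convention after fitting.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from .connectivity import ConnectivityPrior, check_identifiability
from .datasets import CONTROL, TREATED, ExpressionDataset

logger = logging.getLogger(__name__)

UNIT_MAX_ACTIVITY = "unit_max_activity"
UNIT_NORM_STRENGTH = "unit_norm_strength"


@dataclasses.dataclass
class LogRatioMatrix:
    """Genes x conditions log-ratio expression (relative to a reference)."""

    genes: list[str]
    conditions: list[float]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.conditions)):
            raise ValueError("log-ratio matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("log ratios must be finite")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes,
                            columns=[str(c) for c in self.conditions])


@dataclasses.dataclass
class NCAResult:
    genes: list[str]
    tfs: list[str]
    conditions: list[float]
    strengths: np.ndarray        # genes x TFs, exactly zero off support
    activities: np.ndarray       # TFs x conditions
    support_mask: np.ndarray     # boolean genes x TFs
    objective: float             # final ||E - A P||_F^2
    n_iter: int
    restart_objectives: list[float]
    converged: bool
    log_ratios: np.ndarray       # the fitted E, kept for diagnostics/signs
    objective_trace: list[float] = dataclasses.field(default_factory=list)

    def recompute_objective(self) -> float:
        resid = self.log_ratios - self.strengths @ self.activities
        return float(np.sum(resid * resid))

    def strengths_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.strengths, index=self.genes, columns=self.tfs)

    def activities_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.activities, index=self.tfs,
                            columns=[str(c) for c in self.conditions])

    def write(self, strengths_path: str | Path, activities_path: str | Path,
              report_path: str | Path | None = None) -> None:
        sf = self.strengths_frame()
        sf.index.name = "gene"
        sf.to_csv(strengths_path, sep="\t", float_format="%.10g")
        af = self.activities_frame()
        af.index.name = "tf"
        af.to_csv(activities_path, sep="\t", float_format="%.10g")
        if report_path is not None:
            report = {
                "objective": self.objective,
                "n_iter": self.n_iter,
                "converged": self.converged,
                "restart_objectives": self.restart_objectives,
                "n_genes": len(self.genes),
                "n_tfs": len(self.tfs),
                "n_conditions": len(self.conditions),
            }
            Path(report_path).write_text(json.dumps(report, indent=2) + "\n")


# ------------------------------------------------------------------ log ratios

REFERENCE_TIME_ZERO = "time_zero"
REFERENCE_MATCHED_CONTROL = "matched_control"


def make_log_ratios(
    dataset: ExpressionDataset,
    reference: str = REFERENCE_TIME_ZERO,
) -> LogRatioMatrix:
    """Collapse replicates and express each condition relative to a reference.

    ``time_zero``: per gene, the treated-arm replicate mean at each time minus
    the treated mean at time 0 (the time-zero column is then exactly zero).
    ``matched_control``: treated mean minus the control mean at the same time.
    Values are assumed to be on the log2 scale already, so ratios are
    differences.
    """
    tps = dataset.timepoints
    if reference == REFERENCE_TIME_ZERO:
        if 0.0 not in tps:
            raise ValueError("time-zero reference requested but no time-0 samples present")
        treated = dataset.mean_profile(TREATED, tps)
        ref = treated[:, tps.index(0.0)][:, None]
        values = treated - ref
        conditions = tps
    elif reference == REFERENCE_MATCHED_CONTROL:
        conditions = [t for t in tps if dataset.sample_mask(t, CONTROL).any()]
        treated = dataset.mean_profile(TREATED, conditions)
        control = dataset.mean_profile(CONTROL, conditions)
        values = treated - control
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return LogRatioMatrix(genes=list(dataset.genes), conditions=list(conditions), values=values)


# ------------------------------------------------------------------------ fit


def _als(E: np.ndarray, mask: np.ndarray, P0: np.ndarray, tol: float,
         max_iter: int, ridge: float = 1e-10,
         ) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """One alternating-least-squares run.

    Returns (A, P, objective, iters, converged, per-iteration objectives).
    """
    n_genes, n_tfs = mask.shape
    P = P0.copy()
    A = np.zeros((n_genes, n_tfs))
    supports = [np.flatnonzero(mask[i]) for i in range(n_genes)]
    # genes grouped by support size so the per-gene OLS runs as one batched
    # normal-equation solve per group
    by_size: dict[int, list[int]] = {}
    for i, sup in enumerate(supports):
        if sup.size:
            by_size.setdefault(sup.size, []).append(i)
    groups = [
        (np.asarray(idx), np.vstack([supports[i] for i in idx]))
        for idx in (by_size[k] for k in sorted(by_size))
    ]
    prev_obj = np.inf
    obj = np.inf
    converged = False
    it = 0
    trace: list[float] = []
    for it in range(1, max_iter + 1):
        # (a) strengths: per-gene OLS on the supported activity rows
        for idx, sups in groups:
            Psub = P[sups, :]                      # (g, k, M)
            G = Psub @ Psub.transpose(0, 2, 1)     # (g, k, k)
            rhs = np.einsum("gkm,gm->gk", Psub, E[idx, :])
            try:
                coef = np.linalg.solve(G, rhs[..., None])[..., 0]
            except np.linalg.LinAlgError:
                warnings.warn("singular strength subproblem; ridge fallback used")
                G = G + ridge * np.eye(G.shape[1])[None, :, :]
                coef = np.linalg.solve(G, rhs[..., None])[..., 0]
            A[idx[:, None], sups] = coef
        # (b) activities: full least squares
        try:
            P, *_ = linalg.lstsq(A, E, check_finite=False, lapack_driver="gelsd")
        except linalg.LinAlgError:
            G = A.T @ A + ridge * np.eye(n_tfs)
            P = linalg.solve(G, A.T @ E, assume_a="pos")
            warnings.warn("singular activity subproblem; ridge fallback used")
        resid = E - A @ P
        obj = float(np.sum(resid * resid))
        trace.append(obj)
        if prev_obj < np.inf:
            denom = max(prev_obj, 1e-300)
            if (prev_obj - obj) / denom < tol:
                converged = True
                break
        prev_obj = obj
    return A, P, obj, it, converged, trace


def fit_nca(
    E: LogRatioMatrix,
    prior: ConnectivityPrior,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int = 0,
    require_identifiable: bool = True,
    init_activities: np.ndarray | None = None,
) -> NCAResult:
    """Decompose E into strengths and activities under the support constraint.

    The prior's structural identifiability (criteria i and ii) is verified
    before fitting and a failure refuses the fit with a diagnostic. The
    sample-count condition (iii) is reported as a warning only: with fewer
    conditions than TFs the decomposition is not guaranteed unique by rank
    alone, though a sparse support often pins it down in practice.

    Each restart initializes the activities from the pseudo-inverse of a
    random on-support strength matrix; the restart with the lowest final
    objective is returned. ``init_activities`` adds one warm-started run
    before the random restarts (used by the bootstrap to stabilize refits).
    """
    genes_in_prior = set(prior.genes)
    missing = [g for g in E.genes if g not in genes_in_prior]
    if missing:
        raise ValueError(
            f"{len(missing)} genes in E lack any supported regulator "
            f"(first few: {missing[:5]}); drop them before fitting"
        )
    prior = prior.subset_tfs(list(prior.tfs))
    report = check_identifiability(prior, n_samples=E.n_conditions)
    if require_identifiable and (not report.criterion_i or not all(report.criterion_ii.values())):
        bad = report.failing_tfs()
        raise ValueError(
            "prior fails structural identifiability "
            f"(criterion i: {report.criterion_i}, criterion ii failures: {bad[:5]}); "
            "use reduce_to_identifiable first"
        )
    if not report.criterion_iii:
        warnings.warn(
            f"fewer conditions ({E.n_conditions}) than TFs ({prior.n_tfs}): "
            "full row rank of the activities is not attainable; recovery relies "
            "on support sparsity"
        )
    # align rows/columns: E's gene order, prior's TF order
    gi = {g: i for i, g in enumerate(prior.genes)}
    mask_full = prior.pattern()
    rows = [gi[g] for g in E.genes]
    mask = mask_full[rows, :]
    Emat = E.values
    n_tfs = prior.n_tfs
    rng = np.random.default_rng(seed)
    best = None
    restart_objectives: list[float] = []
    # an objective this far below the data scale is numerically exact; further
    # restarts cannot improve it meaningfully
    exact_cutoff = tol * float(np.sum(Emat * Emat))
    inits: list[np.ndarray | None] = [None] * max(1, n_restarts)
    if init_activities is not None:
        inits = [np.asarray(init_activities, dtype=float)] + inits[:-1]
    for P_start in inits:
        if P_start is None:
            A0 = np.zeros(mask.shape)
            A0[mask] = rng.normal(0.0, 1.0, size=int(mask.sum()))
            P_start = np.linalg.pinv(A0) @ Emat
        A, P, obj, it, conv, trace = _als(Emat, mask, P_start, tol=tol, max_iter=max_iter)
        restart_objectives.append(obj)
        if best is None or obj < best[2]:
            best = (A, P, obj, it, conv, trace)
        if best[2] < exact_cutoff:
            break
    A, P, obj, it, conv, trace = best
    return NCAResult(
        genes=list(E.genes),
        tfs=list(prior.tfs),
        conditions=list(E.conditions),
        strengths=A,
        activities=P,
        support_mask=mask,
        objective=obj,
        n_iter=it,
        restart_objectives=restart_objectives,
        converged=conv,
        log_ratios=Emat.copy(),
        objective_trace=trace,
    )


# -------------------------------------------------------------- normalization


def normalize_result(result: NCAResult, convention: str = UNIT_MAX_ACTIVITY) -> NCAResult:
    """Resolve the diagonal scaling ambiguity A X, X^{-1} P by convention.

    ``unit_max_activity``: each TF's activity row is scaled to max |value| 1,
    with the sign chosen so the activity correlates non-negatively with the
    TF's own expression row when the TF is among the fitted genes (first
    nonzero activity entry positive otherwise). ``unit_norm_strength``: each
    TF's strength column is scaled to unit Euclidean norm, same sign rule.
    The objective is invariant. Idempotent.
    """
    P = result.activities.copy()
    A = result.strengths.copy()
    gene_row = {g: i for i, g in enumerate(result.genes)}
    scales = np.ones(len(result.tfs))
    for j, tf in enumerate(result.tfs):
        row = P[j, :]
        if np.max(np.abs(row)) == 0:
            raise ValueError(f"TF {tf!r} has an all-zero activity row; cannot normalize")
        if convention == UNIT_MAX_ACTIVITY:
            mag = np.max(np.abs(row))
        elif convention == UNIT_NORM_STRENGTH:
            norm = np.linalg.norm(A[:, j])
            if norm == 0:
                raise ValueError(f"TF {tf!r} has an all-zero strength column")
            mag = 1.0 / norm
        else:
            raise ValueError(f"unknown convention {convention!r}")
        sign = _activity_sign(row, tf, gene_row, result.log_ratios)
        scales[j] = sign / mag
        if abs(scales[j] - 1.0) < 1e-12:  # already normalized: bit-exact no-op
            scales[j] = 1.0
    # A <- A X, P <- X^{-1} P with X = diag(1/scales)
    P = P * scales[:, None]
    A = A / scales[None, :]
    out = dataclasses.replace(result, strengths=A, activities=P)
    return out


def _activity_sign(row: np.ndarray, tf: str, gene_row: dict[str, int],
                   E: np.ndarray) -> float:
    if tf in gene_row:
        expr = E[gene_row[tf], :]
        c = float(np.dot(row - row.mean(), expr - expr.mean()))
        if c != 0:
            return 1.0 if c > 0 else -1.0
    # fallback: sign of the peak entry — stable against round-off zeros
    peak = row[int(np.argmax(np.abs(row)))]
    return 1.0 if peak >= 0 else -1.0


# ------------------------------------------------------------------ bootstrap


@dataclasses.dataclass
class BootstrapSummary:
    """Per-entry percentile summaries over bootstrap refits."""

    strength_lo: np.ndarray
    strength_med: np.ndarray
    strength_hi: np.ndarray
    activity_lo: np.ndarray
    activity_med: np.ndarray
    activity_hi: np.ndarray
    n_replicates: int
    n_redraws: int


def bootstrap_nca(
    E: LogRatioMatrix,
    prior: ConnectivityPrior,
    B: int = 100,
    seed: int = 0,
    n_restarts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 1000,
    percentiles: tuple[float, float, float] = (2.5, 50.0, 97.5),
) -> BootstrapSummary:
    """Gene-resampled bootstrap of the decomposition.

    Each replicate resamples gene rows with replacement, redraws when the
    resampled support pattern loses structural identifiability, refits
    (warm-started from the full-data solution, plus random restarts), then
    maps back to the full gene set by re-solving every gene's strengths
    against the replicate's activities. All replicates are normalized with
    the unit-max-activity convention before summarizing, so the intervals
    are on a common scale. Aborts when more than half the draws have to be
    redrawn.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    gi = {g: i for i, g in enumerate(prior.genes)}
    mask_full = prior.pattern()
    rows = [gi[g] for g in E.genes]
    mask = mask_full[rows, :]
    n_genes = len(E.genes)
    full_fit = fit_nca(E, prior, n_restarts=max(3, n_restarts), tol=tol,
                       max_iter=max_iter, seed=seed,
                       require_identifiable=False)
    warm_P = full_fit.activities
    strengths = np.empty((B, n_genes, prior.n_tfs))
    activities = np.empty((B, prior.n_tfs, E.n_conditions))
    n_redraws = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n_genes, size=n_genes)
        sub_mask = mask[idx, :]
        if not _structurally_identifiable(sub_mask):
            n_redraws += 1
            if n_redraws > max(10, B) and n_redraws > 0.5 * (b + n_redraws):
                raise RuntimeError(
                    f"bootstrap redraw rate too high ({n_redraws} redraws after "
                    f"{b} accepted replicates); prior too fragile for row resampling"
                )
            continue
        sub_E = LogRatioMatrix(
            genes=[f"bs{k}" for k in range(n_genes)],
            conditions=list(E.conditions),
            values=E.values[idx, :],
        )
        sub_prior = ConnectivityPrior(
            tfs=list(prior.tfs),
            genes=sub_E.genes,
            support={(sub_E.genes[i], prior.tfs[j])
                     for i in range(n_genes) for j in np.flatnonzero(sub_mask[i])},
        )
        res = fit_nca(sub_E, sub_prior, n_restarts=n_restarts, tol=tol,
                      max_iter=max_iter, seed=int(rng.integers(0, 2**31 - 1)),
                      require_identifiable=False,
                      init_activities=warm_P[:, :])
        # map back: refit every original gene's strengths against this P
        P = res.activities
        A_full = np.zeros((n_genes, prior.n_tfs))
        for i in range(n_genes):
            sup = np.flatnonzero(mask[i])
            if sup.size:
                coef, *_ = linalg.lstsq(P[sup, :].T, E.values[i, :],
                                        check_finite=False, lapack_driver="gelsd")
                A_full[i, sup] = coef
        full = NCAResult(
            genes=list(E.genes), tfs=list(prior.tfs), conditions=list(E.conditions),
            strengths=A_full, activities=P, support_mask=mask,
            objective=float(np.sum((E.values - A_full @ P) ** 2)),
            n_iter=res.n_iter, restart_objectives=res.restart_objectives,
            converged=res.converged, log_ratios=E.values.copy(),
        )
        full = normalize_result(full, UNIT_MAX_ACTIVITY)
        strengths[b] = full.strengths
        activities[b] = full.activities
        b += 1
    lo, med, hi = percentiles
    return BootstrapSummary(
        strength_lo=np.percentile(strengths, lo, axis=0),
        strength_med=np.percentile(strengths, med, axis=0),
        strength_hi=np.percentile(strengths, hi, axis=0),
        activity_lo=np.percentile(activities, lo, axis=0),
        activity_med=np.percentile(activities, med, axis=0),
        activity_hi=np.percentile(activities, hi, axis=0),
        n_replicates=B,
        n_redraws=n_redraws,
    )


def _structurally_identifiable(mask: np.ndarray) -> bool:
    from .connectivity import _generic_rank

    L = mask.shape[1]
    if _generic_rank(mask) != L:
        return False
    for j in range(L):
        target_rows = mask[:, j]
        reduced = np.delete(mask[~target_rows, :], j, axis=1)
        if _generic_rank(reduced) != L - 1:
            return False
    return True
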