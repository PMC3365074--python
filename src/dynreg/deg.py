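"""Stage-wise differential expression with an empirical-Bayes moderated t.

Each stage (nonzero time point) compares the treated arm against the matched
control arm. Per-gene variances are shrunk toward a pooled prior variance
``s0^2`` with prior degrees of freedom ``d0``; both hyperparameters are
estimated by moment matching of the observed residual-variance distribution
against its scaled-F marginal. The moderated statistic is

    t_g = lfc_g / sqrt( s2_post_g * (1/n_t + 1/n_c) ),
    s2_post_g = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

with a two-sided p-value on d_g + d0 degrees of freedom. Setting ``d0 = 0``
recovers the ordinary two-sample pooled t-test.

A gene is called differentially expressed when it clears both a linear-scale
fold-change threshold (in either direction) and a raw p-value threshold in
more than one stage. No multiple-testing correction is applied; the selection
operates on raw p-values by design.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import CONTROL, TREATED, ExpressionDataset


@dataclasses.dataclass
class StageResult:
    """Per-gene moderated-t results at one stage."""

    stage: float
    genes: list[str]
    lfc: np.ndarray          # log2 fold change, treated minus control means
    t: np.ndarray
    p: np.ndarray            # two-sided; NaN when the gene is ineligible
    df_residual: float
    prior_df: float
    prior_var: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "stage": self.stage, "lfc": self.lfc,
             "t": self.t, "p": self.p}
        )


@dataclasses.dataclass
class DEResult:
    """Moderated-t results across all stages plus the selected gene set."""

    stages: dict[float, StageResult]
    selected_degs: set[str] = dataclasses.field(default_factory=set)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for _, s in sorted(self.stages.items())],
                         ignore_index=True)


def estimate_prior(s2: np.ndarray, df_residual: float) -> tuple[float, float]:
    """Moment-matching estimate of (prior df d0, prior variance s0^2).

    Under the hierarchical model the marginal distribution of a residual
    variance is s2 ~ s0^2 * F(d, d0). Matching the first two moments of the
    observed variances to the F moments gives a closed form:

        c = var(s2) / mean(s2)^2 = 2 (d + d0 - 2) / (d (d0 - 4)),
        d0 = (4 c d + 2 d - 4) / (c d - 2)        (valid when c d > 2),
        s0^2 = mean(s2) * (d0 - 2) / d0.

    When the observed spread is no larger than pure chi-square sampling noise
    (c d <= 2) the prior is effectively infinitely informative; d0 is capped
    at a large finite value so downstream degrees of freedom stay finite.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if s2.size < 2:
        raise ValueError("need at least 2 finite variances to estimate the prior")
    d = float(df_residual)
    m = float(np.mean(s2))
    v = float(np.var(s2, ddof=1))
    if m <= 0:
        return 1e6, max(float(np.median(s2)), 1e-12)
    c = v / (m * m)
    if c * d <= 2.0 + 1e-12:
        d0 = 1e6
    else:
        d0 = (4.0 * c * d + 2.0 * d - 4.0) / (c * d - 2.0)
        d0 = float(np.clip(d0, 0.05, 1e6))
    s0_sq = m * (d0 - 2.0) / d0 if d0 > 2.0 else m
    s0_sq = max(s0_sq, 1e-12)
    return d0, s0_sq


def _refine_prior(s2: np.ndarray, d: float, d0: float, s0_sq: float) -> tuple[float, float]:
    """One profile-likelihood polish of d0 given the moment-matched start.

    Keeps the moment estimate when optimization fails; this is a cheap
    stabilizer for small gene counts, not a full marginal-likelihood fit.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 10 or d0 >= 1e5:
        return d0, s0_sq

    def negloglik(log_d0: float) -> float:
        d0_ = np.exp(log_d0)
        s0_ = np.mean(s2) * (d0_ - 2.0) / d0_ if d0_ > 2 else np.mean(s2)
        if s0_ <= 0:
            return np.inf
        z = s2 / s0_
        return -np.sum(stats.f.logpdf(z, d, d0_) - np.log(s0_))

    try:
        res = optimize.minimize_scalar(
            negloglik, bounds=(np.log(0.05), np.log(1e6)), method="bounded"
        )
        if res.success and np.isfinite(res.fun):
            d0_new = float(np.exp(res.x))
            s0_new = float(np.mean(s2) * (d0_new - 2.0) / d0_new) if d0_new > 2 else float(np.mean(s2))
            return d0_new, max(s0_new, 1e-12)
    except Exception:
        pass
    return d0, s0_sq


def moderated_t(
    dataset: ExpressionDataset,
    stage: float,
    prior_df: float | None = None,
    prior_var: float | None = None,
) -> StageResult:
    """Moderated two-sample t of treated vs control at one stage.

    ``prior_df``/``prior_var`` override the moment-matched hyperparameters
    (``prior_df=0`` gives the ordinary pooled t-test). Requires at least two
    samples per arm at the stage.
    """
    xt = dataset.arm_values(stage, TREATED)
    xc = dataset.arm_values(stage, CONTROL)
    nt, nc = xt.shape[1], xc.shape[1]
    if nt < 2 or nc < 2:
        raise ValueError(f"stage {stage}: need >=2 samples per arm, got {nt}/{nc}")
    lfc = xt.mean(axis=1) - xc.mean(axis=1)
    d = float(nt + nc - 2)
    ss = xt.var(axis=1, ddof=1) * (nt - 1) + xc.var(axis=1, ddof=1) * (nc - 1)
    s2 = ss / d
    if prior_df is None or prior_var is None:
        d0_hat, s0_hat = estimate_prior(s2, d)
        d0_hat, s0_hat = _refine_prior(s2, d, d0_hat, s0_hat)
        d0 = d0_hat if prior_df is None else float(prior_df)
        s0_sq = s0_hat if prior_var is None else float(prior_var)
    else:
        d0, s0_sq = float(prior_df), float(prior_var)
    if d0 > 0:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    else:
        s2_post = s2.copy()
    se = np.sqrt(s2_post * (1.0 / nt + 1.0 / nc))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / se, np.where(lfc == 0, 0.0, np.inf * np.sign(lfc)))
    df_total = d + d0
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    # zero residual spread in both arms and zero lfc -> t = 0, p = 1;
    # zero spread with nonzero lfc keeps p ~ 0 via the infinite statistic
    p = np.where(np.isinf(t), 0.0, p)
    if d <= 0:
        p = np.full_like(p, np.nan)
    return StageResult(
        stage=stage, genes=list(dataset.genes), lfc=lfc, t=np.asarray(t),
        p=np.asarray(p), df_residual=d, prior_df=d0, prior_var=s0_sq,
    )


def run_all_stages(dataset: ExpressionDataset, **kwargs) -> DEResult:
    stages = dataset.stages
    if len(stages) < 2:
        raise ValueError("need at least 2 stages")
    return DEResult(stages={s: moderated_t(dataset, s, **kwargs) for s in stages})


def select_degs(
    de: DEResult,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    min_stages: int = 2,
) -> set[str]:
    """Genes passing fold change and p-value thresholds in >= min_stages stages.

    The fold-change test is two-sided on the linear scale: a gene qualifies at
    a stage when ``2**|lfc| > fc_threshold`` and ``p < p_threshold``. Genes
    with missing p-values at a stage do not qualify at that stage.
    """
    if fc_threshold < 1:
        raise ValueError("fc_threshold is a linear-scale ratio >= 1")
    n_stages = len(de.stages)
    if min_stages > n_stages:
        raise ValueError(f"min_stages={min_stages} exceeds available stages ({n_stages})")
    lfc_cut = np.log2(fc_threshold)
    counts: dict[str, int] = {}
    for res in de.stages.values():
        hits = (np.abs(res.lfc) > lfc_cut) & np.isfinite(res.p) & (res.p < p_threshold)
        for gene, h in zip(res.genes, hits):
            if h:
                counts[gene] = counts.get(gene, 0) + 1
    selected = {g for g, c in counts.items() if c >= min_stages}
    de.selected_degs = selected
    return selected
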