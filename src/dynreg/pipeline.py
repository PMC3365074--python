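"""End-to-end orchestration: simulate or load inputs, run every stage, write artifacts.

The pipeline executes, in order: differential expression and DEG selection;
connectivity assembly (prior edge list, co-expression augmentation,
identifiability pruning); the constrained decomposition with normalization and
optional bootstrap; activity analytics; pathway enrichment of the DEG list;
and stage-resolved pathway crosstalk. Every artifact is a plain-text table in
the run directory, and a single machine-readable ``summary.json`` records the
counts at each stage together with the configuration hash and seeds, so two
runs with the same configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import connectivity as conn
from . import crosstalk as xt
from . import deg as degmod
from . import enrichment as enr
from . import nca as ncamod
from . import synthetic as synth
from . import tfa as tfamod
from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All file paths, thresholds and seeds of one run."""

    expression_path: str
    prior_path: str
    ppi_path: str
    pathways_path: str

    # differential expression
    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    min_stages: int = 2

    # connectivity
    r_augment: float = 0.8
    enforce_sample_criterion: bool = False

    # decomposition
    reference: str = ncamod.REFERENCE_MATCHED_CONTROL
    n_restarts: int = 10
    tol: float = 1e-8
    max_iter: int = 2000
    bootstrap: int = 20

    # activity analytics
    r_pair: float = 0.6

    # enrichment
    enrich_p: float = 0.1
    min_members: int = 2

    # crosstalk
    crosstalk_B: int = 2000
    significance: float = 0.1
    weak_significance: float = 0.3
    crosstalk_pairs: str = "all"      # "all" or "significant"
    max_pairs: int = 50

    seed: int = 0

    def validate(self) -> None:
        for attr in ("expression_path", "prior_path", "ppi_path", "pathways_path"):
            if not Path(getattr(self, attr)).exists():
                raise FileNotFoundError(f"{attr}: {getattr(self, attr)}")
        if not (self.fc_threshold >= 1):
            raise ValueError("fc_threshold must be >= 1")
        for name in ("p_threshold", "enrich_p", "significance"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if not (0 < self.r_augment < 1) or not (0 < self.r_pair < 1):
            raise ValueError("correlation thresholds must be in (0, 1)")
        if self.min_stages < 1 or self.crosstalk_B < 1:
            raise ValueError("min_stages and crosstalk_B must be positive")
        if self.crosstalk_pairs not in {"all", "significant"}:
            raise ValueError("crosstalk_pairs must be 'all' or 'significant'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage and return the machine-readable summary.

    Stage outputs are written as they complete, so a failure partway leaves
    the finished artifacts intact; the raised error names the failing stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    seeds = _stage_seeds(config.seed)
    summary: dict = {
        "version": __version__,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "stages": {},
    }
    timings: dict[str, float] = {}

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            _write_summary(outdir, summary)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        timings[stage] = time.perf_counter() - t0
        logger.info("stage %s done in %.2fs", stage, timings[stage])
        return out

    dataset = _run("load", lambda: ExpressionDataset.from_tsv(config.expression_path))
    summary["stages"]["load"] = {
        "n_genes": dataset.n_genes, "n_samples": dataset.n_samples,
        "stages": dataset.stages,
    }

    # ---- differential expression -------------------------------------------
    def _deg():
        de = degmod.run_all_stages(dataset)
        degs = degmod.select_degs(de, config.fc_threshold, config.p_threshold,
                                  config.min_stages)
        table = de.to_frame()
        table.to_csv(outdir / "de_table.tsv", sep="\t", index=False,
                     float_format="%.6g")
        (outdir / "degs.txt").write_text("".join(f"{g}\n" for g in sorted(degs)))
        return de, degs

    de, degs = _run("deg", _deg)
    summary["stages"]["deg"] = {"n_selected": len(degs)}

    # ---- connectivity -------------------------------------------------------
    def _connectivity():
        prior = conn.load_prior(config.prior_path)
        measured = set(dataset.genes)
        tfs_measured = [t for t in prior.tfs if t in measured]
        degs_measured = [g for g in sorted(degs) if g in measured]
        added = {}
        if tfs_measured and degs_measured:
            pairs, signs = conn.augment_by_clustering(
                dataset, tfs_measured, degs_measured, r_threshold=config.r_augment)
            prior = prior.merged_with(pairs, signs)
            added = pairs
        # restrict the network to selected DEGs with at least one regulator
        keep_genes = set(degs) & set(prior.genes)
        support = {(g, t) for g, t in prior.support if g in keep_genes}
        restricted = conn.ConnectivityPrior(
            tfs=[t for t in prior.tfs if any(p[1] == t for p in support)],
            genes=[g for g in prior.genes if g in {p[0] for p in support}],
            support=support,
            signs={p: s for p, s in prior.signs.items() if p in support},
            provenance={p: s for p, s in prior.provenance.items() if p in support},
        )
        if not restricted.support:
            raise ValueError("no supported regulator targets any selected DEG")
        n_cond = len(dataset.timepoints)
        n_for_check = n_cond if config.enforce_sample_criterion else 10**9
        pruned = conn.reduce_to_identifiable(restricted, n_samples=n_for_check)
        pruned.to_tsv(outdir / "connectivity.tsv")
        report = conn.check_identifiability(pruned, n_samples=n_cond)
        return pruned, report, len(added)

    prior, ident_report, n_augmented = _run("connectivity", _connectivity)
    summary["stages"]["connectivity"] = {
        "n_tfs": prior.n_tfs, "n_genes": prior.n_genes,
        "n_support": len(prior.support), "n_augmented_pairs": n_augmented,
        "criterion_i": ident_report.criterion_i,
        "criterion_ii_failures": ident_report.failing_tfs(),
        "criterion_iii": ident_report.criterion_iii,
    }

    # ---- decomposition ------------------------------------------------------
    def _nca():
        E_full = ncamod.make_log_ratios(dataset, reference=config.reference)
        rows = [g for g in E_full.genes if g in set(prior.genes)]
        idx = [E_full.genes.index(g) for g in rows]
        E = ncamod.LogRatioMatrix(genes=rows, conditions=E_full.conditions,
                                  values=E_full.values[idx, :])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = ncamod.fit_nca(E, prior, n_restarts=config.n_restarts,
                                    tol=config.tol, max_iter=config.max_iter,
                                    seed=seeds[0])
            result = ncamod.normalize_result(result)
            result.write(outdir / "strengths.tsv", outdir / "activities.tsv",
                         outdir / "nca_report.json")
            boot = None
            boot_note = ""
            if config.bootstrap > 0:
                # row resampling can break identifiability on small supports;
                # the bootstrap is a diagnostic, so a fragile prior downgrades
                # it to "skipped" rather than failing the run
                try:
                    boot = ncamod.bootstrap_nca(E, prior, B=config.bootstrap,
                                                seed=seeds[1], n_restarts=3)
                    _write_bootstrap(outdir, result, boot)
                except RuntimeError as exc:
                    boot_note = str(exc)
                    logger.warning("bootstrap skipped: %s", exc)
        return result, boot, boot_note

    result, boot, boot_note = _run("nca", _nca)
    summary["stages"]["nca"] = {
        "objective": result.objective,
        "n_iter": result.n_iter,
        "converged": result.converged,
        "bootstrap_replicates": 0 if boot is None else boot.n_replicates,
        "bootstrap_note": boot_note,
    }

    # ---- activity analytics -------------------------------------------------
    def _tfa():
        expr_corr = tfamod.tfa_expression_correlation(result, dataset)
        expr_corr.rename_axis("tf").to_frame().to_csv(
            outdir / "tfa_expression_correlation.tsv", sep="\t", float_format="%.6g")
        corr = tfamod.tfa_correlation_matrix(result)
        corr.to_csv(outdir / "tfa_correlation_matrix.tsv", sep="\t",
                    float_format="%.6g")
        ppi_edges = xt.load_ppi_edges(config.ppi_path)
        tf_set = set(result.tfs)
        tf_ppi = {e for e in ppi_edges if e[0] in tf_set and e[1] in tf_set}
        pairs = tfamod.infer_combinatorial_pairs(corr, tf_ppi, r_threshold=config.r_pair)
        tfamod.pairs_to_frame(pairs).to_csv(outdir / "combinatorial_pairs.tsv",
                                            sep="\t", index=False, float_format="%.6g")
        clustering = tfamod.cluster_strengths(result)
        (outdir / "strength_dendrogram.nwk").write_text(clustering.newick + "\n")
        cl = clustering.flat_clusters
        with open(outdir / "strength_clusters.tsv", "w") as fh:
            fh.write("gene\tcluster\tmajor\n")
            for g in clustering.genes:
                fh.write(f"{g}\t{cl[g]}\t{int(cl[g] in clustering.major_clusters)}\n")
        tfamod.export_network(result, sif_path=outdir / "network.sif",
                              graphml_path=outdir / "network.graphml")
        return expr_corr, pairs, clustering, ppi_edges

    expr_corr, pairs, clustering, ppi_edges = _run("tfa", _tfa)
    summary["stages"]["tfa"] = {
        "n_combinatorial_pairs": len(pairs),
        "n_major_clusters": len(clustering.major_clusters),
    }

    # ---- enrichment ---------------------------------------------------------
    def _enrichment():
        pathways = enr.PathwaySet.from_gmt(config.pathways_path)
        table = enr.hypergeometric_enrichment(degs, pathways)
        table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False,
                     float_format="%.6g")
        sig = enr.select_significant(table, config.enrich_p, config.min_members)
        sig.to_csv(outdir / "enrichment_significant.tsv", sep="\t", index=False,
                   float_format="%.6g")
        return pathways, table, sig

    pathways, enrich_table, enrich_sig = _run("enrichment", _enrichment)
    summary["stages"]["enrichment"] = {
        "n_pathways": len(pathways.pathways),
        "n_significant": int(len(enrich_sig)),
    }

    # ---- crosstalk ----------------------------------------------------------
    def _crosstalk():
        if config.crosstalk_pairs == "significant":
            names = list(enrich_sig["pathway"])
        else:
            names = sorted(pathways.pathways)
        pair_list = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        pair_list = pair_list[: config.max_pairs]
        if not pair_list:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = xt.crosstalk_dynamics(
                pair_list, pathways, ppi_edges, dataset,
                B=config.crosstalk_B, seed=seeds[2],
                significance=config.significance,
                weak_significance=config.weak_significance,
            )
        table.to_csv(outdir / "crosstalk.tsv", sep="\t", index=False,
                     float_format="%.6g")
        return table

    crosstalk_table = _run("crosstalk", _crosstalk)
    summary["stages"]["crosstalk"] = {
        "n_pairs_tested": 0 if crosstalk_table is None
        else int(crosstalk_table[["pathway_i", "pathway_j"]].drop_duplicates().shape[0]),
        "n_significant_cells": 0 if crosstalk_table is None
        else int(crosstalk_table["significant"].sum()),
    }

    _write_summary(outdir, summary)
    with open(outdir / "run.log", "w") as fh:
        for stage, dt in timings.items():
            fh.write(f"{stage}\t{dt:.3f}s\n")
    return summary


def _write_summary(outdir: Path, summary: dict) -> None:
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


def _write_bootstrap(outdir: Path, result, boot) -> None:
    import pandas as pd

    rows = []
    for i, g in enumerate(result.genes):
        for j, t in enumerate(result.tfs):
            if result.support_mask[i, j]:
                rows.append({
                    "gene": g, "tf": t,
                    "lo": boot.strength_lo[i, j],
                    "median": boot.strength_med[i, j],
                    "hi": boot.strength_hi[i, j],
                })
    pd.DataFrame(rows).to_csv(outdir / "bootstrap_strengths.tsv", sep="\t",
                              index=False, float_format="%.6g")


# -------------------------------------------------------------------- simulate


def simulate_inputs(
    outdir: str | Path,
    n_genes: int = 120,
    n_tfs: int = 8,
    targets_per_tf: int = 6,
    timepoints: tuple[float, ...] = synth.DEFAULT_TIMEPOINTS,
    noise_sd: float = synth.DEFAULT_NOISE_SD,
    n_replicates: int = synth.DEFAULT_REPLICATES,
    n_pathways: int = 8,
    pathway_size: int = 15,
    n_planted_pairs: int = 2,
    cross_edge_boost: float = 20.0,
    base_edge_prob: float = 0.005,
    seed: int = 0,
) -> dict[str, Path]:
    """Write a complete, coherent input bundle for the pipeline.

    Expression (with TF mRNA rows), a signed prior edge list, a PPI edge list
    over the same gene universe and a pathway GMT, plus the ground-truth JSON
    for benchmarking. Returns the paths keyed by input kind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_truth, s_expr, s_ppi = (int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3))
    truth = synth.generate_truth(
        n_genes=n_genes, n_tfs=n_tfs, targets_per_tf=targets_per_tf,
        timepoints=timepoints, seed=s_truth,
    )
    dataset = synth.generate_expression(
        truth, noise_sd=noise_sd, n_replicates=n_replicates, seed=s_expr,
        include_tf_mrna=True,
    )
    ppi_edges, pathways, planted = synth.generate_ppi_pathways(
        n_genes=n_genes, n_pathways=n_pathways, pathway_size=pathway_size,
        n_planted_pairs=n_planted_pairs, cross_edge_boost=cross_edge_boost,
        seed=s_ppi, base_edge_prob=base_edge_prob,
    )
    truth.planted_crosstalk_pairs = planted
    paths = {
        "expression": outdir / "expression.tsv",
        "prior": outdir / "prior.tsv",
        "ppi": outdir / "ppi.tsv",
        "pathways": outdir / "pathways.gmt",
        "truth": outdir / "truth.json",
    }
    dataset.to_tsv(paths["expression"])
    assert truth.prior is not None
    truth.prior.signs.update(synth.support_signs(truth))
    truth.prior.to_tsv(paths["prior"])
    xt.write_ppi_edges(ppi_edges, paths["ppi"])
    pathways.to_gmt(paths["pathways"])
    truth.write_json(paths["truth"])
    return paths


def default_config(paths: dict[str, Path], seed: int = 0, **overrides) -> PipelineConfig:
    cfg = PipelineConfig(
        expression_path=str(paths["expression"]),
        prior_path=str(paths["prior"]),
        ppi_path=str(paths["ppi"]),
        pathways_path=str(paths["pathways"]),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
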