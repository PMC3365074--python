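import dataclasses

import numpy as np
import pytest
from scipy import optimize

from dynreg import connectivity as conn
from dynreg import nca as ncamod
from dynreg import synthetic as synth
from conftest import activity_correlations, restrict_to_prior


class TestMakeLogRatios:
    def test_time_zero_reference(self, small_truth):
        ds = synth.generate_expression(small_truth, noise_sd=0.0, seed=1)
        E = ncamod.make_log_ratios(ds, reference=ncamod.REFERENCE_TIME_ZERO)
        z = E.conditions.index(0.0)
        np.testing.assert_allclose(E.values[:, z], 0.0, atol=1e-12)
        np.testing.assert_allclose(E.values, small_truth.log_ratio_matrix, atol=1e-12)

    def test_missing_time_zero_errors(self, small_truth):
        ds = synth.generate_expression(small_truth, noise_sd=0.0, seed=1)
        keep = ds.times != 0.0
        trimmed = dataclasses.replace(
            ds,
            samples=[s for s, k in zip(ds.samples, keep) if k],
            values=ds.values[:, keep], times=ds.times[keep],
            conditions=ds.conditions[keep], replicates=ds.replicates[keep],
        )
        with pytest.raises(ValueError, match="time-zero"):
            ncamod.make_log_ratios(trimmed, reference=ncamod.REFERENCE_TIME_ZERO)
        # matched-control reference still works without a time-0 arm
        E = ncamod.make_log_ratios(trimmed, reference=ncamod.REFERENCE_MATCHED_CONTROL)
        assert E.conditions == [4.0, 12.0, 24.0]


class TestFitNca:
    def test_rank_one_exact_factorization(self):
        E = ncamod.LogRatioMatrix(genes=["g1"], conditions=[0.0, 4.0, 12.0],
                                  values=np.array([[0.0, 2.0, 4.0]]))
        prior = conn.ConnectivityPrior(tfs=["tf1"], genes=["g1"],
                                       support={("g1", "tf1")})
        res = ncamod.fit_nca(E, prior, n_restarts=2, seed=1)
        res = ncamod.normalize_result(res)
        np.testing.assert_allclose(res.strengths @ res.activities, E.values, atol=1e-10)
        np.testing.assert_allclose(res.activities[0], [0.0, 0.5, 1.0], atol=1e-10)
        assert res.strengths[0, 0] == pytest.approx(4.0, abs=1e-10)

    def test_noiseless_recovery_small(self, small_truth):
        prior = small_truth.prior.drop_unregulated_genes()
        ds = synth.generate_expression(small_truth, noise_sd=0.0, seed=2)
        E = restrict_to_prior(ds, prior)
        res = ncamod.fit_nca(E, prior, n_restarts=10, seed=3)
        assert res.objective < 1e-8 * np.sum(E.values**2)
        assert activity_correlations(res, small_truth).min() >= 0.999

    def test_objective_matches_recomputation(self, bench_noiseless_fit):
        _, _, res = bench_noiseless_fit
        assert res.objective == pytest.approx(res.recompute_objective(), abs=1e-10)

    def test_objective_trace_monotone(self, bench_noiseless_fit):
        _, _, res = bench_noiseless_fit
        trace = np.array(res.objective_trace)
        assert len(trace) >= 2
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(trace[:-1], 1.0))

    def test_off_support_exactly_zero(self, bench_noiseless_fit):
        _, _, res = bench_noiseless_fit
        assert np.all(res.strengths[~res.support_mask] == 0.0)

    def test_gene_permutation_symmetry(self, small_truth):
        prior = small_truth.prior.drop_unregulated_genes()
        ds = synth.generate_expression(small_truth, noise_sd=0.0, seed=2)
        E = restrict_to_prior(ds, prior)
        rng = np.random.default_rng(7)
        perm = rng.permutation(len(E.genes))
        E_perm = ncamod.LogRatioMatrix(
            genes=[E.genes[i] for i in perm], conditions=E.conditions,
            values=E.values[perm, :],
        )
        r1 = ncamod.normalize_result(ncamod.fit_nca(E, prior, n_restarts=8, seed=3))
        r2 = ncamod.normalize_result(ncamod.fit_nca(E_perm, prior, n_restarts=8, seed=4))
        np.testing.assert_allclose(r1.activities, r2.activities, atol=1e-6)
        s2_back = np.empty_like(r2.strengths)
        s2_back[perm, :] = r2.strengths
        np.testing.assert_allclose(r1.strengths, s2_back, atol=1e-6)

    def test_unidentifiable_prior_refused(self):
        prior = conn.ConnectivityPrior(
            tfs=["A", "B"], genes=["g1", "g2"],
            support={("g1", "A"), ("g2", "A"), ("g1", "B"), ("g2", "B")},
        )
        E = ncamod.LogRatioMatrix(genes=["g1", "g2"], conditions=[0.0, 4.0, 12.0],
                                  values=np.zeros((2, 3)))
        with pytest.raises(ValueError, match="identifiability"):
            ncamod.fit_nca(E, prior, seed=1)

    def test_uncovered_gene_refused(self, small_truth):
        prior = small_truth.prior.drop_unregulated_genes()
        ds = synth.generate_expression(small_truth, noise_sd=0.0, seed=2)
        E = ncamod.make_log_ratios(ds)  # includes unregulated genes
        if set(E.genes) == set(prior.genes):
            pytest.skip("fixture regulates every gene")
        with pytest.raises(ValueError, match="lack any supported regulator"):
            ncamod.fit_nca(E, prior, seed=1)

    def test_matches_direct_minimizer_on_tiny_instance(self):
        """ALS objective equals a brute-force minimizer started from truth."""
        truth = synth.generate_truth(n_genes=6, n_tfs=2, targets_per_tf=3,
                                     timepoints=(0.0, 4.0, 12.0, 24.0), seed=33)
        prior = truth.prior.drop_unregulated_genes()
        ds = synth.generate_expression(truth, noise_sd=0.15, seed=34)
        E = restrict_to_prior(ds, prior)
        res = ncamod.fit_nca(E, prior, n_restarts=10, seed=5)

        mask = res.support_mask
        n_sup = int(mask.sum())
        gi = {g: i for i, g in enumerate(prior.genes)}
        ti = {t: j for j, t in enumerate(prior.tfs)}
        A_true = np.zeros(mask.shape)
        for g, t in truth.support:
            if g in gi:
                A_true[gi[g], ti[t]] = truth.true_strengths[
                    truth.genes.index(g), truth.tfs.index(t)]
        P_true = truth.true_activities[[truth.tfs.index(t) for t in prior.tfs], :]

        def unpack(x):
            A = np.zeros(mask.shape)
            A[mask] = x[:n_sup]
            P = x[n_sup:].reshape(P_true.shape)
            return A, P

        def objective(x):
            A, P = unpack(x)
            return np.sum((E.values - A @ P) ** 2)

        x0 = np.concatenate([A_true[mask], P_true.ravel()])
        opt = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
        assert res.objective <= opt.fun * (1 + 1e-6) + 1e-12


class TestNormalize:
    def test_idempotent_and_objective_invariant(self, bench_noiseless_fit):
        _, _, res = bench_noiseless_fit
        once = ncamod.normalize_result(res)
        twice = ncamod.normalize_result(once)
        np.testing.assert_allclose(once.activities, twice.activities, atol=1e-12)
        np.testing.assert_allclose(once.strengths, twice.strengths, atol=1e-12)
        rel = abs(once.objective - once.recompute_objective()) / max(res.objective, 1e-300)
        assert rel < 1e-12 or once.recompute_objective() < 1e-12

    def test_unit_max_activity_convention(self, bench_noiseless_fit):
        _, _, res = bench_noiseless_fit
        out = ncamod.normalize_result(res, ncamod.UNIT_MAX_ACTIVITY)
        np.testing.assert_allclose(np.abs(out.activities).max(axis=1), 1.0, atol=1e-12)

    def test_strengths_match_truth_after_shared_normalization(
            self, bench_truth, bench_prior, bench_noiseless_fit):
        _, E, res = bench_noiseless_fit
        fitted = ncamod.normalize_result(res)
        truth_res = ncamod.NCAResult(
            genes=list(E.genes), tfs=list(bench_prior.tfs), conditions=list(E.conditions),
            strengths=np.array([[bench_truth.true_strengths[
                bench_truth.genes.index(g), bench_truth.tfs.index(t)]
                for t in bench_prior.tfs] for g in E.genes]),
            activities=bench_truth.true_activities[
                [bench_truth.tfs.index(t) for t in bench_prior.tfs], :],
            support_mask=res.support_mask, objective=0.0, n_iter=0,
            restart_objectives=[], converged=True, log_ratios=E.values,
        )
        truth_norm = ncamod.normalize_result(truth_res)
        np.testing.assert_allclose(fitted.strengths, truth_norm.strengths, atol=1e-5)

    def test_all_zero_activity_row_errors(self):
        res = ncamod.NCAResult(
            genes=["g1"], tfs=["tf1"], conditions=[0.0, 4.0],
            strengths=np.array([[1.0]]), activities=np.array([[0.0, 0.0]]),
            support_mask=np.array([[True]]), objective=0.0, n_iter=1,
            restart_objectives=[0.0], converged=True, log_ratios=np.zeros((1, 2)),
        )
        with pytest.raises(ValueError, match="all-zero activity"):
            ncamod.normalize_result(res)


class TestBootstrap:
    def test_noiseless_intervals_degenerate(self, bench_truth, bench_prior):
        ds = synth.generate_expression(bench_truth, noise_sd=0.0, seed=12)
        E = restrict_to_prior(ds, bench_prior)
        boot = ncamod.bootstrap_nca(E, bench_prior, B=20, seed=6, n_restarts=4)
        width_a = boot.activity_hi - boot.activity_lo
        assert width_a.max() < 1e-6
        width_s = boot.strength_hi - boot.strength_lo
        assert width_s.max() < 1e-6

    def test_zero_replicates_error(self, bench_prior, bench_truth):
        ds = synth.generate_expression(bench_truth, noise_sd=0.0, seed=12)
        E = restrict_to_prior(ds, bench_prior)
        with pytest.raises(ValueError, match="B"):
            ncamod.bootstrap_nca(E, bench_prior, B=0, seed=1)

    def test_seeded_reproducibility(self, bench_truth, bench_prior):
        ds = synth.generate_expression(bench_truth, noise_sd=0.1, seed=13)
        E = restrict_to_prior(ds, bench_prior)
        b1 = ncamod.bootstrap_nca(E, bench_prior, B=8, seed=9, n_restarts=2)
        b2 = ncamod.bootstrap_nca(E, bench_prior, B=8, seed=9, n_restarts=2)
        np.testing.assert_array_equal(b1.strength_med, b2.strength_med)
        np.testing.assert_array_equal(b1.activity_med, b2.activity_med)
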