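import numpy as np
import pytest
from hypothesis import settings

from dynreg import nca as ncamod
from dynreg import synthetic as synth

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")

SIX_TIMEPOINTS = (0.0, 2.0, 4.0, 8.0, 16.0, 24.0)


def restrict_to_prior(dataset, prior, reference=ncamod.REFERENCE_MATCHED_CONTROL):
    """Log-ratio matrix over the prior's regulated genes only."""
    E_full = ncamod.make_log_ratios(dataset, reference=reference)
    idx = [E_full.genes.index(g) for g in prior.genes]
    return ncamod.LogRatioMatrix(
        genes=list(prior.genes),
        conditions=E_full.conditions,
        values=E_full.values[idx, :],
    )


@pytest.fixture(scope="session")
def bench_truth():
    """The 50-gene, 10-TF, 6-condition benchmark ground truth."""
    return synth.generate_truth(
        n_genes=50, n_tfs=10, targets_per_tf=5, timepoints=SIX_TIMEPOINTS, seed=11
    )


@pytest.fixture(scope="session")
def bench_prior(bench_truth):
    return bench_truth.prior.drop_unregulated_genes()


@pytest.fixture(scope="session")
def bench_noiseless_fit(bench_truth, bench_prior):
    """Noiseless data and its fitted decomposition, shared across tests."""
    dataset = synth.generate_expression(bench_truth, noise_sd=0.0, seed=12)
    E = restrict_to_prior(dataset, bench_prior)
    result = ncamod.fit_nca(E, bench_prior, n_restarts=10, seed=3)
    return dataset, E, result


@pytest.fixture(scope="session")
def small_truth():
    """A quick 3-TF instance for cheap exactness tests."""
    return synth.generate_truth(
        n_genes=12, n_tfs=3, targets_per_tf=3, timepoints=(0.0, 4.0, 12.0, 24.0), seed=21
    )


def activity_correlations(result, truth):
    """Per-TF |r| between recovered and true activity rows."""
    out = []
    for j, tf in enumerate(result.tfs):
        k = truth.tfs.index(tf)
        r = np.corrcoef(result.activities[j], truth.true_activities[k])[0, 1]
        out.append(abs(r))
    return np.array(out)
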