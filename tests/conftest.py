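"""Shared synthetic fixtures (session-scoped; everything generated in
memory from fixed seeds)."""

import numpy as np
import pandas as pd
import pytest

import epifem as ef


@pytest.fixture(scope="session")
def sim_cfg():
    """Small discovery cohort: 300 genes, two planted modules, n=30/30."""
    return ef.SimulationConfig(
        rng_seed=7, n_genes=300, module_sizes=(15, 20), n_cases=30, n_controls=30
    )


@pytest.fixture(scope="session")
def network_truth(sim_cfg):
    return ef.simulate_network(sim_cfg)


@pytest.fixture(scope="session")
def cohort(sim_cfg, network_truth):
    net, truth = network_truth
    return ef.simulate_cohort(net, truth, sim_cfg)


@pytest.fixture(scope="session")
def gene_meth(cohort):
    return ef.summarize_promoter_methylation(cohort["beta"], cohort["annotation"])


@pytest.fixture(scope="session")
def pure_profiles(sim_cfg):
    return ef.simulate_pure_profiles(sim_cfg)


@pytest.fixture(scope="session")
def reference(pure_profiles):
    pure, labels, _ = pure_profiles
    return ef.build_reference_matrix(pure, labels, delta_thresh=0.9)


@pytest.fixture(scope="session")
def fractions(cohort, reference):
    return ef.estimate_fractions_rpc(cohort["beta"], reference)


@pytest.fixture(scope="session")
def gene_stats(gene_meth, cohort, fractions, network_truth):
    net, _ = network_truth
    stats = ef.compute_gene_stats(
        gene_meth.values, cohort["expr"], cohort["sheet"], fractions, net
    )
    return ef.add_integrated_statistic(stats)


@pytest.fixture(scope="session")
def wnet(network_truth, gene_stats):
    net, _ = network_truth
    return ef.WeightedNetwork(net, gene_stats["t_int"])


@pytest.fixture(scope="session")
def fitted(gene_meth, cohort, fractions, network_truth, sim_cfg):
    net, _ = network_truth
    model = ef.FEMAnalysis(
        gene_meth,
        cohort["expr"],
        cohort["sheet"],
        net,
        fractions,
        config=ef.SpinGlassConfig(rng_seed=7, n_seeds=50),
    )
    return model.fit()


def jaccard(a, b):
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)


def make_beta_frame(rng, n_probes=6, n_samples=4, prefix="cg"):
    vals = rng.uniform(0.05, 0.95, size=(n_probes, n_samples))
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i}" for i in range(n_probes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
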