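import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """One draw of the reference scenario (T=5, binary split at t=2,
    delta_mu=3, sigma=0.5, 500 genes, seed 1), shared across tests."""
    from drem2.regulators import feature_matrices
    from drem2.synthetic import SimScenario, simulate

    scn = SimScenario(seed=1)
    table, dyn, truth = simulate(scn)
    X = table.values[: scn.n_genes]
    feats = feature_matrices(dyn, scn.n_times)
    return {
        "scenario": scn,
        "table": table,
        "dyn": dyn,
        "truth": truth,
        "X": X,
        "features": feats,
    }


@pytest.fixture(scope="session")
def trained_default(default_sim):
    """The reference dataset fitted by greedy structure search."""
    from drem2.learning import LearnConfig, structure_search, viterbi_assign

    sim = default_sim
    model, trace = structure_search(
        sim["X"],
        sim["features"],
        LearnConfig(seed=1),
        tf_ids=sim["dyn"].tf_ids,
        gene_ids=sim["truth"]["gene_ids"],
    )
    assignment = viterbi_assign(
        model, sim["X"], sim["features"], sim["truth"]["gene_ids"]
    )
    return {"model": model, "trace": trace, "assignment": assignment, **sim}


@pytest.fixture
def rng():
    return np.random.default_rng(20120816)
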