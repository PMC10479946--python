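import numpy as np
import pandas as pd
import pytest

from fluxshift import FluxDistribution, SamplingConfig, make_scenario, toy_network


@pytest.fixture
def toy():
    return toy_network()


@pytest.fixture
def small_sampling():
    """Scaled-down sampler settings for fast, still well-mixed toy runs."""
    return SamplingConfig(n_samples=300, thinning=10, seed=1)


@pytest.fixture
def scenario():
    return make_scenario(seed=0, noise_cv=0.0)


@pytest.fixture
def empty_de():
    return pd.DataFrame({"gene": [], "log2FC": [], "FC": [], "pvalue": [], "FDR": []})


def control_reference(scenario):
    """The scenario's control flux state as a checked FluxDistribution."""
    flux = FluxDistribution(dict(scenario.v_control), scenario.model.id)
    assert flux.check_feasibility(scenario.model)
    return flux


def qp_bruteforce(spec):
    """Independent QP oracle: trust-constr (interior-point) on the same
    separable objective, a different algorithm and code path from OSQP."""
    from scipy.optimize import LinearConstraint, minimize

    n = len(spec.reaction_ids)
    S = spec.model.stoichiometric_matrix()
    lb, ub = spec.model.bounds_arrays()
    idx, w, t = spec.term_index, spec.term_weight, spec.term_target

    def f(v):
        return float(np.sum(w * (v[idx] - t) ** 2))

    def g(v):
        grad = np.zeros(n)
        np.add.at(grad, idx, 2.0 * w * (v[idx] - t))
        return grad

    x0 = np.clip(spec.v_ref, lb, ub)
    res = minimize(f, x0, jac=g, method="trust-constr",
                   constraints=[LinearConstraint(S, 0, 0)],
                   bounds=list(zip(lb, ub)),
                   options={"gtol": 1e-12, "xtol": 1e-14, "maxiter": 5000})
    return res.x, f(res.x)
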