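import pytest

from microdisk import (
    ModelParams,
    SolverOptions,
    generate_dataset,
    solve_coupled,
)

# the six built-in study cases: (alpha, gamma_E, gamma_S, q)
DEFAULT_CASES = [
    (100.0, 30.0, 30.0, 5.0),
    (50.0, 20.0, 20.0, 5.0),
    (10.0, 10.0, 10.0, 5.0),
    (100.0, 30.0, 30.0, 1.5),
    (50.0, 20.0, 20.0, 1.5),
    (10.0, 10.0, 10.0, 1.5),
]


@pytest.fixture(scope="session")
def solved_default_cases():
    """Coupled reference solutions of all six cases at n=4001 (shared)."""
    out = {}
    for alpha, g_e, g_s, q in DEFAULT_CASES:
        params = ModelParams(gamma_E=g_e, gamma_S=g_s, alpha=alpha, q=q)
        out[(alpha, g_e, g_s, q)] = solve_coupled(params, SolverOptions(n=4001))
    return out


@pytest.fixture(scope="session")
def smooth_s_dataset():
    """1143-point substrate dataset for the mild first-order case."""
    params = ModelParams(gamma_E=1.0, gamma_S=1.0, alpha=0.0, q=5.0)
    ds_S, _, prof = generate_dataset(params, 1143)
    return ds_S, prof
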