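import random

import pytest
from hypothesis import HealthCheck, settings

import procaux as px

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ex1():
    return px.example1()


@pytest.fixture(scope="session")
def ex2():
    return px.example2()


@pytest.fixture(scope="session")
def ex3():
    return px.example3()


def make_random_step(rng: random.Random, nu_ratio_one: bool = True, chain_mr: float | None = None):
    """A self-consistent single-step mass ledger for oracle tests.

    Returns (StepMassSummary, feeds, molar masses, limiting index).  The
    product molar mass is drawn below the stoichiometric reactant mass so
    the atom economy is physical (in (0, 1]); feeds are at or above the
    stoichiometric ratio so SF >= 1.
    """
    k = rng.randint(1, 4)
    nus = [rng.randint(1, 3) for _ in range(k)]
    mrs = [rng.uniform(20.0, 400.0) for _ in range(k)]
    lim = rng.randrange(k)
    if chain_mr is not None:
        mrs[lim] = chain_mr
    nu_mr = nus[lim]
    nu_p = nu_mr if nu_ratio_one else nu_mr + rng.randint(1, 2)
    n_lim = 10 ** rng.uniform(-6, 0)
    feeds = [
        n_lim * nu / nu_mr * (1.0 if i == lim else rng.uniform(1.0, 3.0))
        for i, nu in enumerate(nus)
    ]
    denom = sum(nu * mr for nu, mr in zip(nus, mrs))
    mr_p = rng.uniform(0.2, 1.0) * denom / nu_p
    sm = px.StepMassSummary(
        n_mr=feeds[lim],
        epsilon=rng.uniform(0.05, 1.0),
        nu_p=nu_p,
        nu_mr=nu_mr,
        mr_p=mr_p,
        ae=px.atom_economy(list(zip(nus, mrs)), nu_p, mr_p),
        sf=px.stoichiometric_factor(feeds, nus, mrs, lim),
        c=rng.uniform(0.0, 1.0) * n_lim,
        s=rng.uniform(0.0, 5.0) * n_lim,
    )
    return sm, feeds, mrs, lim
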