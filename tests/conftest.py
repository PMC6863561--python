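import numpy as np
import pytest

import foxdepletion as fx
from foxdepletion.inference import MCMCConfig
from foxdepletion.synthetic_data import EffortPattern, OperatingTruth


@pytest.fixture(scope="session")
def sched():
    return fx.build_weaning_schedule(fx.ConceptionModel())


@pytest.fixture(scope="session")
def standard_truth():
    """A mid-range operating truth resembling a typical study estate."""
    params = fx.ModelParams(
        N0=2.0, K=4.0, v=0.2, r=3.18, M=0.34 / 26.0, d=0.45, sigma_p=0.2
    )
    return OperatingTruth(params=params)


@pytest.fixture(scope="session")
def standard_estate(sched, standard_truth):
    """One screen-passing synthetic estate with its known trajectory."""
    effort = fx.generate_effort(
        EffortPattern(weekly_hours=(1.0, 0.7, 0.35, 1.0), years=4), seed=17
    )
    series, traj = fx.simulate_estate(standard_truth, effort, sched, seed=18)
    return series, traj


@pytest.fixture(scope="session")
def micro_cfg():
    """Tiny MCMC settings for smoke/integration tests (not convergence)."""
    return MCMCConfig(n_chains=2, burn_in=2_000, thin=5, n_recorded=300, seed=5)


@pytest.fixture(scope="session")
def standard_fit(standard_estate, sched):
    """A desk-scale converged-ish fit shared by several tests."""
    import warnings

    series, _ = standard_estate
    ps = fx.build_priors("informative")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", fx.ConvergenceWarning)
        return fx.fit(
            series, ps, sched, MCMCConfig.profile("standard", seed=9)
        )


def rng(seed=0):
    return np.random.default_rng(seed)
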