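import numpy as np
import pytest

from mosrl import models, task


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_run(rng):
    return task.generate_run(task.TaskConfig(), rng)


MOS6_MEDIAN = dict(beta=10.803, alpha_ha=0.423, alpha_psi=0.473,
                   lam_eu=1.138, lam_mo=-1.547, lam_ha=0.686)


@pytest.fixture
def mos6_median_params():
    return dict(MOS6_MEDIAN)


@pytest.fixture
def simulated_run(rng, default_run, mos6_median_params):
    spec = models.ModelSpec("MOS")
    return models.simulate(spec, mos6_median_params, default_run, rng)
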