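import numpy as np
import pytest

from acqcost.growth import logistic_model
from acqcost.types import GrowthCurve

TIME_GRID = np.arange(0.0, 24.001, 0.25)


@pytest.fixture
def time_grid():
    return TIME_GRID.copy()


def make_curve(A=1.0, mu=0.5, lam=3.0, noise_sd=0.0, seed=0,
               colony_id="c0", population="de_novo", plasmid_id="pX",
               replicate_id="rep1", times=None):
    t = TIME_GRID if times is None else np.asarray(times, float)
    v = logistic_model(t, A, mu, lam)
    if noise_sd > 0:
        v = v + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return GrowthCurve(colony_id=colony_id, population=population,
                       plasmid_id=plasmid_id, replicate_id=replicate_id,
                       times=t, values=np.clip(v, 0.0, None))


@pytest.fixture
def curve_factory():
    return make_curve


@pytest.fixture
def qc_fixture():
    """29 de novo curves with planted artifacts and their manifest.

    20 stay clean, 3 get closable 1-point spikes, 2 get 4-point spikes,
    2 never plateau, and 2 have their final density scaled x3.
    """
    from acqcost.synth import SynthConfig, gen_phenotypes, inject_artifacts, render_curves

    cfg = SynthConfig(n_colonies=29, target_cost=1.3, seed=7)
    phen = gen_phenotypes(cfg, rng=np.random.default_rng(1))
    phen = phen[phen.population == "de_novo"].reset_index(drop=True)
    curves = render_curves(phen, cfg, rng=np.random.default_rng(2))
    plan = {"spike1": 3, "spike_wide": 2, "no_plateau": 2, "size_outlier": 2}
    curves, manifest = inject_artifacts(curves, plan, rng=np.random.default_rng(3))
    return curves, manifest
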