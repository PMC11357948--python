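import numpy as np
import pytest

from qeps_puberty.model import QEPSParams, ShapeConstants
from qeps_puberty.pipeline import fit_cohort
from qeps_puberty.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def consts():
    return ShapeConstants()


@pytest.fixture
def typical_params():
    """Cohort-mean-scale individual parameters."""
    return QEPSParams(Emax=62.76, Qmax=98.51, Pmax=12.92, Etsc=1.0, Ptsc=1.0,
                      AgeP50=11.98)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_params(rng, n):
    """Random but physiologic parameter draws for property checks."""
    return [
        QEPSParams(
            Emax=rng.uniform(55, 72),
            Qmax=rng.uniform(80, 120),
            Pmax=rng.uniform(0.0, 25),
            Etsc=rng.uniform(0.7, 1.4),
            Ptsc=rng.uniform(0.6, 1.6),
            AgeP50=rng.uniform(8.5, 15.0),
        )
        for _ in range(n)
    ]


@pytest.fixture(scope="session")
def cohort_run_1990(consts):
    """Full default synthetic cohort (n=793, seed 1990), rendered with 0.3 cm
    noise and refit per subject.  Shared across tests because the fit stage
    dominates the suite's runtime."""
    config = GeneratorConfig()
    measurements, metadata, truth = generate_cohort(config, consts)
    params, fit_table = fit_cohort(measurements, consts, seed=1990)
    return {
        "config": config,
        "measurements": measurements,
        "metadata": metadata,
        "truth": truth,
        "params": params,
        "fit_table": fit_table,
    }
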