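import numpy as np
import pytest

from resinsaxs.complexes import build_agarose_strand
from resinsaxs.synthetic import gen_saxs_series, gen_toy_antibody_and_domain
from resinsaxs.transforms import InversionConfig

#: q grid reaching low enough that the structure factor dominates the lowest
#: decade (the strand form factor is flat for q*R << 1).
Q_GRID = np.logspace(np.log10(0.003), np.log10(7.0), 240)


@pytest.fixture(scope="session")
def toy_models():
    antibody, domain, truth = gen_toy_antibody_and_domain(seed=0)
    return antibody, domain, truth


@pytest.fixture(scope="session")
def strand():
    return build_agarose_strand()


@pytest.fixture(scope="session")
def synthetic_series():
    series, truth = gen_saxs_series(seed=42, q_grid=Q_GRID)
    return series, truth


@pytest.fixture(scope="session")
def inversion_config():
    return InversionConfig(r_max=20.0)
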