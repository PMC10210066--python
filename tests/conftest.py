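import numpy as np
import pytest

from zincomp import constants as C
from zincomp.synth import GroundTruth
from zincomp.system import CompetitorLigand, MultiSiteReceptor

WEAKEST_NEG_LOG_KD = -float(np.log10(C.MT2_REF32_KDS[0]))  # 7.699


@pytest.fixture
def mt2():
    """Seven-site MT2 solution model at the chromogenic working concentration."""
    return C.receptor("mt2_ref32", 1.7e-6)


@pytest.fixture
def par():
    def make(total_conc: float) -> CompetitorLigand:
        return C.competitor("PAR", total_conc)

    return make


@pytest.fixture
def noiseless_truth():
    return GroundTruth(noise_sigma=0.0, noise_floor_frac=0.0)


@pytest.fixture
def single_site():
    def make(kd: float, total_conc: float) -> MultiSiteReceptor:
        return MultiSiteReceptor(site_kds=(kd,), total_conc=total_conc)

    return make
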