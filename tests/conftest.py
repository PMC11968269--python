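import warnings

import pytest

from extruscan.annotation import LocusConfig, build_locus_annotation
from extruscan.core import ProcessivityParams

# scipy warns about near-identical replicate groups in t-tests; expected for
# degenerate fixtures
warnings.filterwarnings(
    "ignore", message="Precision loss occurred in moment calculation"
)
warnings.filterwarnings("ignore", message="Model is not converging")
warnings.filterwarnings("ignore", message="Degenerate mixture covariance")


@pytest.fixture(scope="session")
def annotation():
    """Default synthetic locus: 58 cluster genes + 2000 background genes."""
    return build_locus_annotation()


@pytest.fixture(scope="session")
def small_annotation():
    """Locus without background genes, for fast unit tests."""
    return build_locus_annotation(LocusConfig(background_genes=0))


@pytest.fixture(scope="session")
def params():
    return ProcessivityParams()


@pytest.fixture(scope="session")
def params_no_background():
    return ProcessivityParams(background_contact_scale=0.0)
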