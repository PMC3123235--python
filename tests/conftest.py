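import numpy as np
import pytest

from mtphylo.synthdata import SynthSpec, generate


@pytest.fixture(scope="session")
def defect_battery():
    """One mid-size dataset with every defect kind injected."""
    spec = SynthSpec(n_leaves=20, n_rotations=1, n_truncations=2, n_n_runs=1,
                     n_duplicates=2, n_outliers=1, n_overlong=1,
                     n_ambiguous=1, seed=7)
    return generate(spec)


@pytest.fixture(scope="session")
def clean_result():
    """Defect-free dataset with recurrent/reverting mutation disabled."""
    return generate(SynthSpec(n_leaves=12, allow_recurrent=False, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
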