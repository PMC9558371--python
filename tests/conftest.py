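import numpy as np
import pytest

from kitddg.estimators import WorkSet
from kitddg.workgen import WorkGenSpec, generate_cft_work_samples


@pytest.fixture
def cft_workset():
    """Factory for Crooks-consistent Gaussian WorkSets."""

    def make(dg_true=5.0, dissipation=2.0, n=5000, seed=1, temperature=310.0):
        return generate_cft_work_samples(
            WorkGenSpec(
                dg_true=dg_true,
                dissipation=dissipation,
                n_forward=n,
                n_reverse=n,
                temperature=temperature,
                seed=seed,
            )
        )

    return make


@pytest.fixture
def delta_workset():
    """Zero-dissipation point-mass WorkSet at a chosen dG."""

    def make(dg=5.0, n=10, temperature=310.0):
        return WorkSet(
            forward_work=np.full(n, dg),
            reverse_work=np.full(n, -dg),
            temperature=temperature,
        )

    return make
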