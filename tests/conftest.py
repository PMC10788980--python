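import numpy as np
import pytest

import cellgcn as cg


@pytest.fixture(scope="session")
def signal_dataset():
    """Default 3-condition dataset with strong planted markers."""
    return cg.generate_multicondition_dataset(cg.SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def fitted(signal_dataset):
    """Preprocessed model + fitted results on the signal dataset (shared
    across tests; training is deterministic under the fixed seed)."""
    pre = cg.standard_preprocess(signal_dataset.to_anndata())
    model = cg.ConditionGCN.from_anndata(pre)
    results = model.fit(seed=1)
    return signal_dataset, model, results


@pytest.fixture
def rng():
    return np.random.default_rng(0)
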