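import pandas as pd
import pytest

from biochromtox import datasets
from biochromtox.correlations import exclusion_subsets


@pytest.fixture(scope="session")
def descriptors():
    return datasets.load_descriptors()


@pytest.fixture(scope="session")
def endpoints():
    return datasets.load_endpoints()


@pytest.fixture(scope="session")
def reference_subsets(endpoints):
    return exclusion_subsets(endpoints, datasets.default_exclusions())


@pytest.fixture(scope="session")
def vaso_xy(descriptors, endpoints):
    """The 13 complete (chi_iam, vasodilation %) pairs."""
    xy = pd.concat(
        [descriptors.descriptors["chi_iam"], endpoints.values["vasodilation_pct"]],
        axis=1,
    ).dropna()
    return xy.iloc[:, 0].to_numpy(), xy.iloc[:, 1].to_numpy(), list(xy.index)
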