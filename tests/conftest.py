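import numpy as np
import pandas as pd
import pytest

from metcornet import ProfileMatrix, SyntheticConfig, generate_profiles


@pytest.fixture
def toy_matrix():
    """3 metabolites x 4 samples, two groups, hand-writable values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 4.0, 8.0],
         [2.0, 4.0, 8.0, 16.0],
         [5.0, 3.0, 7.0, 1.0]],
        index=["metA", "metB", "metC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    groups = pd.Series(["g1", "g1", "g2", "g2"],
                       index=values.columns, name="group")
    return ProfileMatrix(values=values, sample_groups=groups)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the 59 x 53 study design."""
    return generate_profiles(SyntheticConfig(seed=11))


def make_profile(X, groups=None, prefix="m"):
    """Wrap a raw array as a ProfileMatrix with trivial metadata."""
    X = np.asarray(X, dtype=float)
    mets = [f"{prefix}{i}" for i in range(X.shape[0])]
    samples = [f"s{j}" for j in range(X.shape[1])]
    if groups is None:
        groups = ["g"] * X.shape[1]
    return ProfileMatrix(
        values=pd.DataFrame(X, index=mets, columns=samples),
        sample_groups=pd.Series(list(groups), index=samples, name="group"),
    )
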