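import numpy as np
import pandas as pd
import pytest

from cophylochem.io_core import Tree
from cophylochem.synthetic_data import sim_bd_tree


@pytest.fixture(scope="session")
def tree8() -> Tree:
    return sim_bd_tree(8, seed=11)


@pytest.fixture(scope="session")
def tree12() -> Tree:
    return sim_bd_tree(12, seed=23)


@pytest.fixture(scope="session")
def block_chem_similarity():
    """Four chemotype guilds cutting across any phylogeny: similarity 0.8
    within a guild, 0.05 between, indexed by generic host labels.

    Discrete chemotype classes are the realistic regime for host
    defensive chemistry and keep the defense covariance structure
    distinguishable from both the identity and the all-ones matrix.
    """
    n = 20
    guild = np.arange(n) % 4
    C = np.where(np.equal.outer(guild, guild), 0.8, 0.05)
    np.fill_diagonal(C, 1.0)
    labels = [f"t{i+1}" for i in range(n)]
    return pd.DataFrame(C, index=labels, columns=labels)
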