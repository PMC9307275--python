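import warnings

import numpy as np
import pytest

import climpop


def pytest_configure(config):
    # arviz emits a refactor FutureWarning on import; keep test output clean
    warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_tree():
    return climpop.simulate_phylogeny(20, seed=7)


@pytest.fixture(scope="session")
def worked_newick(tmp_path_factory):
    """The 3-taxon tree with a hand-computable Brownian correlation."""
    p = tmp_path_factory.mktemp("trees") / "worked.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return p


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def paper_scale_layout():
    """Record layout mimicking the study's scale: 157 species, ~486 records,
    geometric record lengths in [10, 35]."""
    import pandas as pd

    rng = np.random.default_rng(42)
    rows, rid = [], 0
    for i in range(157):
        for _ in range(int(rng.integers(1, 6))):
            rid += 1
            rows.append({"record_id": f"rec_{rid:04d}",
                         "species": f"sp_{i + 1:03d}",
                         "n_years": int(min(35, 10 + rng.geometric(0.18) - 1))})
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def paper_scale_phylo():
    tree = climpop.simulate_phylogeny(157, seed=1)
    species = sorted(l.taxon.label for l in tree.leaf_node_iter())
    pc = climpop.brownian_correlation(tree, species)
    return tree, pc
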