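import numpy as np
import pandas as pd
import pytest

import microcensus as mc
from microcensus.core import AbundanceTable


@pytest.fixture
def tiny_exp():
    """3 taxa x 2 samples with taxonomy and a hand-written tree."""
    ab = AbundanceTable(np.array([[3.0, 1.0], [5.0, 0.0], [0.0, 2.0]]),
                        ["A", "B", "C"], ["S1", "S2"])
    tax = pd.DataFrame(
        {"Kingdom": ["Bacteria"] * 3,
         "Phylum": ["Bacteroidetes", "Bacteroidetes", "Firmicutes"],
         "Genus": ["g1", "g2", "g3"]},
        index=["A", "B", "C"])
    tree = mc.read_newick("((A:1,B:1):0.5,C:2);")
    return mc.build_experiment(ab, taxonomy=tax, tree=tree)


@pytest.fixture
def grouped_exp():
    """Simulated 12-taxa, 10-sample experiment with 2 groups (null)."""
    return mc.simulate_experiment(n_taxa=12, n_samples=10, n_groups=2,
                                  depth=500, seed=42)
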