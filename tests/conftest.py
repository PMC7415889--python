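import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def toy_cells():
    """Five cells at printed coordinates; cell 1 is the anchor."""
    return pd.DataFrame({
        "sample_id": ["s1"] * 5,
        "cell_id": ["c1", "c2", "c3", "c4", "c5"],
        "x": [0.0, 1.0, 0.0, 3.0, 0.5],
        "y": [0.0, 0.0, 1.0, 3.0, 0.5],
        "phenotype": ["A", "B", "B", "A", "C"],
        "is_anchor": [True, False, False, False, False],
    })


@pytest.fixture
def small_tissue():
    from celltopics.synthetic import generate_synthetic_tissue

    return generate_synthetic_tissue(
        n_cells=150, n_topics=3, n_phenotypes=8, counts_per_doc=25, seed=11
    )
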