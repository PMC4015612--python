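import numpy as np
import pandas as pd
import pytest

import hubmod as hm


def write_text(path, text):
    path.write_text(text, encoding="utf-8")
    return path


@pytest.fixture
def small_sim():
    """One dysregulated + three null modules, two conditions, seeded."""
    design = hm.two_condition_design(
        n_null=3, n_dysregulated=1, rho_null=0.3, rho_a=0.9, rho_b=0.0,
        n_partners=5, samples_per_condition=12, n_background_genes=5,
        seed=42)
    return hm.simulate_dataset(design)


@pytest.fixture
def expr_4x3():
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [0.5, np.nan, 1.5],
         [5.0, 5.5, 6.0]],
        index=["G1", "G2", "G3", "G4"],
        columns=["s1", "s2", "s3"])
    return hm.ExpressionMatrix(data)
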