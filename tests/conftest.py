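import numpy as np
import pandas as pd
import pytest

from rvbtools import GeneratorConfig

PAPER_GRID = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0)


@pytest.fixture
def noiseless_cfg():
    return GeneratorConfig(seed=0, noise_cv=0.0, n_replicates=3, time_grid=PAPER_GRID)


@pytest.fixture
def noisy_cfg():
    return GeneratorConfig(seed=11, noise_cv=0.05, n_replicates=4, time_grid=PAPER_GRID)


@pytest.fixture
def rip_abundances():
    """Abundance design with a 20-fold IP enrichment in the tagged strain."""
    rows = []
    for strain, ip_ab in (("rvb2", 20.0), ("wt", 1.0)):
        rows.append(
            dict(sample=f"{strain}_IP", fraction="IP", strain=strain,
                 target="GSY1", abundance=ip_ab)
        )
        rows.append(
            dict(sample=f"{strain}_input", fraction="input", strain=strain,
                 target="GSY1", abundance=1.0)
        )
    return pd.DataFrame(rows)
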