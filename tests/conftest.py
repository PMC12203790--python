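import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import staplecycle as sc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def uniform_design():
    """Single functional 42-mer at 10-fold excess, unit price."""
    return [
        sc.StapleSpecies(
            "f1",
            42,
            category=sc.StapleCategory.FUNCTIONAL,
            fold_excess=10.0,
            stock_conc_uM=100.0,
            price_per_equivalent=1.0,
        )
    ]


@pytest.fixture
def mixed_design():
    """Core / handle / functional / label blend mirroring a therapeutic build."""
    return [
        sc.StapleSpecies("core", 42, sc.StapleCategory.CORE, fold_excess=5.0),
        sc.StapleSpecies("handle", 58, sc.StapleCategory.HANDLE, fold_excess=10.0),
        sc.StapleSpecies(
            "cpg", 42, sc.StapleCategory.FUNCTIONAL, fold_excess=20.0, modified=True
        ),
        sc.StapleSpecies(
            "cy5",
            21,
            sc.StapleCategory.LABEL,
            fold_excess=5.0,
            modified=True,
            replenish_fraction_override=0.2,
        ),
    ]


@pytest.fixture
def half_pure_pool():
    """One species with equal full-length and truncated amounts."""
    amounts = pd.DataFrame(
        {"full_length": [5e-12], "truncated": [5e-12]},
        index=pd.Index(["s1"], name="species_id"),
    )
    return sc.PoolState(amounts=amounts, volume_ul=100.0)
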