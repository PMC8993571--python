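import numpy as np
import pandas as pd
import pytest

from grsmr import genetics
from grsmr.genetics import GenotypeMatrix, SNPSpec


@pytest.fixture(scope="session")
def panel():
    return genetics.default_panel()


@pytest.fixture
def make_matrix():
    """Build a GenotypeMatrix from a dict of rsid -> dosage list."""

    def _make(columns: dict) -> GenotypeMatrix:
        df = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()})
        df.index = pd.Index([f"s{i}" for i in range(len(df))], name="id")
        return GenotypeMatrix(df)

    return _make


@pytest.fixture
def make_snp():
    """SNPSpec factory with sensible defaults."""

    def _make(rsid="rsX", eaf=0.3, weight=0.1, trait=genetics.VITAMIN_D, **kw):
        defaults = dict(
            gene="GENE", chromosome="1", position=1000, effect_allele="G"
        )
        defaults.update(kw)
        return SNPSpec(rsid=rsid, eaf=eaf, weight=weight, trait=trait, **defaults)

    return _make
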