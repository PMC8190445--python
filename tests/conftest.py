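import numpy as np
import pandas as pd
import pytest

from rohload.roh import GenotypeMatrix


def make_genotypes(calls, spacing_cm=0.05, chromosome="1"):
    """Single-chromosome genotype matrix with uniform marker spacing."""
    calls = np.atleast_2d(np.asarray(calls, dtype=np.int8))
    m = calls.shape[1]
    markers = pd.DataFrame({
        "marker_id": [f"s{i}" for i in range(m)],
        "chromosome": chromosome,
        "cm": np.arange(m) * spacing_cm,
    })
    inds = [f"ind{i}" for i in range(calls.shape[0])]
    return GenotypeMatrix(individuals=inds, markers=markers, calls=calls)


@pytest.fixture
def genotypes_factory():
    return make_genotypes
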