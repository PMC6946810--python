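import numpy as np
import pytest

from pulmo_mr.containers import GenotypePanel


@pytest.fixture
def two_row_set():
    """The hand-checkable two-instrument set: ratios 0.3 and 0.5 with
    unit exposure effects and outcome SE 0.1 (exposure SE negligible)."""
    from pulmo_mr.containers import HarmonizedSet

    return HarmonizedSet.from_arrays(
        [1.0, 1.0], [1e-12, 1e-12], [0.3, 0.5], [0.1, 0.1]
    )


def make_panel(dosages, chrom=None, pos=None, ids=None):
    """Wrap a raw dosage matrix in a GenotypePanel with simple metadata."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    return GenotypePanel(
        variant_ids=np.array(ids if ids is not None else [f"rs{i}" for i in range(m)]),
        chrom=np.asarray(chrom if chrom is not None else np.ones(m, int)),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000),
        effect_allele=np.array(["A"] * m),
        other_allele=np.array(["G"] * m),
        dosages=dosages,
        block_id=np.zeros(m, dtype=int),
    )
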