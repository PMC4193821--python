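import numpy as np
import pytest

from triogxe import SimConfig, TrioRecord, simulate_trios


def make_trio(fid, father, mother, child, **exposures):
    """Convenience constructor from plain dosage lists."""
    return TrioRecord(fid, np.array(father, dtype=np.int8),
                      np.array(mother, dtype=np.int8),
                      np.array(child, dtype=np.int8), dict(exposures))


@pytest.fixture
def aa_x_aa_trios():
    """12 trios, all Aa x aa matings at one SNP: 9 transmit the minor allele.

    The conditional-logistic MLE on these matings has the closed form
    exp(beta) = T/U = 9/3 = 3.
    """
    trios = [make_trio(f"T{i}", [1], [0], [1]) for i in range(9)]
    trios += [make_trio(f"U{i}", [1], [0], [0]) for i in range(3)]
    return trios


@pytest.fixture
def null_panel():
    """Small multi-SNP null simulation used by IO/QC round-trip tests."""
    cfg = SimConfig(n_trios=60, maf=0.3, exposure_names=("ETS", "VIT"),
                    exposure_rates={"ETS": 0.4, "VIT": 0.2},
                    extra_null_mafs=(0.2, 0.45), seed=123)
    return simulate_trios(cfg)
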