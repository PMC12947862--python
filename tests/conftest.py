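import numpy as np
import pandas as pd
import pytest

from idrmap.csp import CSPProfile, ShiftTable


def make_shift_table(construct_id, condition, residues, dh, dn, types=None):
    n = len(residues)
    return ShiftTable(
        construct_id,
        condition,
        pd.DataFrame({
            "residue_index": residues,
            "residue_type": types if types is not None else ["A"] * n,
            "dH_ppm": dh,
            "dN_ppm": dn,
        }),
    )


@pytest.fixture
def eight_value_profile():
    """The fixed 8-value CSP fixture used for the threshold rules."""
    return CSPProfile(
        "fix", 1,
        np.array([0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.20]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
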