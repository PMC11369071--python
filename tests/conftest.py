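import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_corr_matrices():
    """A bag of random PSD correlation matrices of dims 3 and 4."""
    r = np.random.default_rng(7)
    out = []
    for d in (3, 4):
        for _ in range(6):
            A = r.normal(size=(d, d))
            C = A @ A.T
            s = np.sqrt(np.diag(C))
            out.append(C / np.outer(s, s))
    return out


@pytest.fixture(scope="session")
def small_pedigree():
    """Hand-built pedigree: one full sibship of 3, one maternal half-sib
    duo, one paternal half-sib duo, plus the parents."""
    rows = [
        # full sibs: A1, A2, A3 (mother M1, father F1)
        ("A1", "F1", "M1"), ("A2", "F1", "M1"), ("A3", "F1", "M1"),
        # maternal half sibs: B1 (M2+F2), B2 (M2+F3)
        ("B1", "F2", "M2"), ("B2", "F3", "M2"),
        # paternal half sibs: C1 (M3+F4), C2 (M4+F4)
        ("C1", "F4", "M3"), ("C2", "F4", "M4"),
    ]
    parents = [(p, None, None) for p in ("M1", "F1", "M2", "F2", "F3", "M3", "M4", "F4")]
    ped = pd.DataFrame(rows + parents, columns=["individual_id", "father_id", "mother_id"])
    ped["sex"] = 0
    is_parent = ped["father_id"].isna()
    ped["birth_year"] = np.where(is_parent, np.nan, 2000.0)
    ped["parity"] = 1
    return ped
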