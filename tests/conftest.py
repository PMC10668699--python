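import numpy as np
import pandas as pd
import pytest

from hoofgen.pedigree import Pedigree, UNKNOWN, parse_pedigree


@pytest.fixture
def founders_ped():
    """Five unrelated founders."""
    return parse_pedigree(
        pd.DataFrame(
            {"id": list("ABCDE"), "sire": ["0"] * 5, "dam": ["0"] * 5}
        )
    )


@pytest.fixture
def full_sib_ped():
    """Two founders, two full sibs, and a full-sib-mating offspring."""
    return parse_pedigree(
        pd.DataFrame(
            {
                "id": ["A", "B", "C", "D", "E"],
                "sire": ["0", "0", "A", "A", "C"],
                "dam": ["0", "0", "B", "B", "D"],
            }
        )
    )


@pytest.fixture
def half_sib_ped():
    """Shared sire, different dams; their offspring is inbred F=0.125."""
    return parse_pedigree(
        pd.DataFrame(
            {
                "id": ["S", "D1", "D2", "C1", "C2", "X"],
                "sire": ["0", "0", "0", "S", "S", "C1"],
                "dam": ["0", "0", "0", "D1", "D2", "C2"],
            }
        )
    )


def random_pedigree(rng: np.random.Generator, n: int, founder_frac: float = 0.25) -> Pedigree:
    """Random acyclic pedigree: each non-founder's parents are uniformly
    chosen among earlier animals (so single-parent and inbred loops occur)."""
    n_founders = max(2, int(n * founder_frac))
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    for i in range(n_founders, n):
        sire[i] = rng.integers(i)
        if rng.random() < 0.9:  # occasionally one unknown parent
            d = int(rng.integers(i))
            if d != sire[i]:
                dam[i] = d
    ids = np.array([f"A{i}" for i in range(n)], dtype=object)
    return Pedigree(ids=ids, sire=sire, dam=dam)
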