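import numpy as np
import pandas as pd
import pytest

from herdtrend.pedigree import Pedigree


def random_pedigree(rng: np.random.Generator, n: int, n_founders: int = None,
                    missing_rate: float = 0.0) -> Pedigree:
    """Random topologically-ordered pedigree for property tests."""
    if n_founders is None:
        n_founders = max(4, n // 5)
    ids = [f"a{i}" for i in range(n)]
    sire, dam, sex = [], [], []
    for i in range(n):
        if i < n_founders:
            sire.append(None)
            dam.append(None)
            sex.append("M" if i % 2 == 0 else "F")
        else:
            males = [j for j in range(i) if sex[j] == "M"]
            fem = [j for j in range(i) if sex[j] == "F"]
            sire.append(ids[rng.choice(males)] if rng.random() >= missing_rate else None)
            dam.append(ids[rng.choice(fem)] if rng.random() >= missing_rate else None)
            sex.append("M" if rng.random() < 0.5 else "F")
    return Pedigree.from_frame(
        pd.DataFrame({"id": ids, "sire": sire, "dam": dam, "sex": sex})
    )


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree.from_frame(
        pd.DataFrame(
            {
                "id": ["s", "d", "o"],
                "sire": [None, None, "s"],
                "dam": [None, None, "d"],
                "sex": ["M", "F", "F"],
            }
        )
    )
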