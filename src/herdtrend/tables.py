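"""Published parameter set for the Israeli Holstein breeding index (PD19).

These constants are the national first-parity REML estimates for cows born
2008--2016: the 9x9 genetic and environmental covariance matrices among the
index traits, the PD19 economic weights, and the realized genetic trends
(regression of cow EBV on birth date, per 10 years).  They parameterize the
synthetic-data generator and serve as the reference inputs for the
selection-index gain calculations.

Trait order is fixed throughout the package: milk (kg), fat (kg), protein
(kg), somatic cell score (SCS), conception status (CS, %), herd-life (days),
persistency (%), dystocia (%), stillbirth (%).
"""

from __future__ import annotations

import numpy as np

TRAITS: tuple[str, ...] = (
    "milk",
    "fat",
    "protein",
    "scs",
    "cs",
    "herd_life",
    "persistency",
    "dystocia",
    "stillbirth",
)

#: Traits for which a *negative* value is economically favorable.
NEGATIVE_FAVORABLE: frozenset[str] = frozenset({"scs", "dystocia", "stillbirth"})

#: PD19 (2019 revision) index coefficients, economic units per trait unit.
B_PD19 = np.array([0.0, 9.94, 19.88, -300.0, 26.0, 0.6, 10.0, -3.0, -6.0])

#: Genetic covariance matrix among the nine index traits (trait units squared),
#: national first-parity estimates, cows born 2008-2016.
G_2008_2016 = np.array(
    [
        [1104690.4, 18187.0, 24365.4, 109.7, -2604.3, 20562.9, 1428.5, -397.7, 13.7],
        [18187.0, 1491.4, 641.0, 1.7, -78.9, 789.7, 17.7, -0.2, 4.3],
        [24365.4, 641.0, 752.4, 3.0, -82.3, 385.9, 18.8, -8.8, 3.9],
        [109.7, 1.7, 3.0, 0.3, -1.1, -29.5, -0.2, 0.1, 0.1],
        [-2604.3, -78.9, -82.3, -1.1, 62.1, 917.6, 2.4, -10.3, -4.7],
        [20562.9, 789.7, 385.9, -29.5, 917.6, 48508.9, 521.4, -215.0, -122.3],
        [1428.5, 17.7, 18.8, -0.2, 2.4, 521.4, 34.7, -0.1, -0.3],
        [-397.7, -0.2, -8.8, 0.1, -10.3, -215.0, -0.1, 27.0, 11.2],
        [13.7, 4.3, 3.9, 0.1, -4.7, -122.3, -0.3, 11.2, 8.8],
    ]
)

#: Environmental (residual) covariance matrix, same ordering and source.
E_2008_2016 = np.array(
    [
        [1072573.5, 28444.7, 29929.6, -67.7, 2086.5, 89681.7, -481.4, -767.6, -885.6],
        [28444.7, 1488.6, 872.9, -2.2, 2.8, 2376.4, -10.0, -26.5, -26.7],
        [29929.6, 872.9, 911.2, -1.3, 43.1, 2455.3, -14.3, -22.8, -26.5],
        [-67.7, -2.2, -1.3, 0.9, 1.1, -13.4, -0.4, -0.3, -0.2],
        [2086.5, 2.8, 43.1, 1.1, 1101.3, 2098.0, -10.3, -24.7, -11.8],
        [89681.7, 2376.4, 2455.3, -13.4, 2098.0, 332822.6, 158.0, 704.8, 29.6],
        [-481.4, -10.0, -14.3, -0.4, -10.3, 158.0, 123.2, 4.3, 3.2],
        [-767.6, -26.5, -22.8, -0.3, -24.7, 704.8, 4.3, 669.1, 149.5],
        [-885.6, -26.7, -26.5, -0.2, -11.8, 29.6, 3.2, 149.5, 423.0],
    ]
)

#: Realized genetic trends over the 2008-2016 birth cohorts (trait units per
#: 10 years) with their standard errors, from the regression of cow EBV on
#: birth date in the national evaluation.
REALIZED_GAIN = np.array([699.4, 40.0, 32.5, -0.194, 1.91, 209.1, 1.00, -0.800, 0.233])
REALIZED_GAIN_SE = np.array([3.5, 0.1, 0.1, 0.002, 0.02, 0.6, 0.02, 0.014, 0.009])

#: Expected genetic trends for PD19 at selection intensity 3.02, as printed
#: in the national report (trait units per 10 years), and the genetic SDs at
#: the precision they were printed with.  Kept as reference inputs for
#: reproducing the standardized expected-vs-realized discrepancy column.
EXPECTED_GAIN = np.array([1073.4, 46.5, 33.9, -0.12, 0.3, 152.1, 2.4, -1.39, -0.34])
GENETIC_SD_PRINTED = np.array([1051.0, 38.6, 27.4, 0.55, 7.9, 220.0, 5.9, 5.2, 3.0])

#: Realized total economic gain of PD19 over the same horizon, index units.
REALIZED_TEG = 1300.7
REALIZED_TEG_SE = 3.34

#: Selection intensity calibrated so that expected economic gain matches the
#: realized gain of PD19.
INTENSITY_PD19 = 3.02


def trait_index(trait: str) -> int:
    """Position of ``trait`` in the canonical ordering."""
    try:
        return TRAITS.index(trait)
    except ValueError:
        raise KeyError(f"unknown trait {trait!r}; expected one of {TRAITS}") from None


def submatrix(m: np.ndarray, traits: list[str] | tuple[str, ...]) -> np.ndarray:
    """Sub-block of a 9x9 trait covariance matrix for the given trait subset."""
    idx = [trait_index(t) for t in traits]
    return m[np.ix_(idx, idx)]
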