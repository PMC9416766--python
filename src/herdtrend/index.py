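"""Selection-index engine.

Given economic weights ``b`` (one per trait) and the genetic (G) and
phenotypic (P = G + E) covariance matrices among the index traits, this
module computes the standard selection-index quantities for a breeding
program:

* per-trait index fractions  c_j = |b_j g_j| / sum_j |b_j g_j|,  g_j = sqrt(G_jj)
* expected correlated responses  Phi = i * bG / sqrt(b'Pb)  at selection
  intensity ``i`` (responses accrue even for traits with b_j = 0 through the
  genetic covariances)
* total expected economic gain  TEG = Phi'b
* calibration of ``i`` against a realized total gain, and the standardized
  expected-vs-realized discrepancy per trait (sign reversed for traits where
  a negative value is favorable, so positive always means "realized beat
  expectation in the desired direction").

The intensity is interpreted over whatever horizon the realized trends are
measured on (a decade for the shipped national parameter set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tables

__all__ = [
    "IndexSpec",
    "GainReport",
    "genetic_sd",
    "index_fractions",
    "expected_gains",
    "total_gain",
    "calibrate_intensity",
    "discrepancy_table",
    "gain_report",
    "pd19_spec",
]


@dataclass
class IndexSpec:
    """Named selection index: economic weights and favorable directions."""

    coefficients: np.ndarray
    traits: tuple[str, ...]
    negative_favorable: frozenset[str] = field(default_factory=frozenset)
    name: str = "index"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.traits):
            raise ValueError("one coefficient per trait required")
        if not np.any(self.coefficients):
            raise ValueError("at least one nonzero index coefficient required")

    @property
    def sign(self) -> np.ndarray:
        """+1 for traits where larger is better, -1 where smaller is better."""
        return np.array([-1.0 if t in self.negative_favorable else 1.0 for t in self.traits])


def pd19_spec() -> IndexSpec:
    """The PD19 Israeli breeding index (2019 revision)."""
    return IndexSpec(
        coefficients=tables.B_PD19.copy(),
        traits=tables.TRAITS,
        negative_favorable=tables.NEGATIVE_FAVORABLE,
        name="PD19",
    )


def genetic_sd(G: np.ndarray) -> np.ndarray:
    """Per-trait genetic standard deviations, g_j = sqrt(G_jj)."""
    diag = np.diag(np.asarray(G, dtype=float))
    if np.any(diag < 0):
        raise ValueError("negative genetic variance on the diagonal")
    return np.sqrt(diag)


def index_fractions(spec: IndexSpec, g: np.ndarray) -> np.ndarray:
    """Fraction of the index attributable to each trait (sums to 1)."""
    g = np.asarray(g, dtype=float)
    if g.shape != spec.coefficients.shape:
        raise ValueError("coefficient and SD vectors must have equal length")
    w = np.abs(spec.coefficients * g)
    total = w.sum()
    if total == 0:
        raise ValueError("all index coefficients are zero")
    return w / total


def expected_gains(intensity: float, spec: IndexSpec, G: np.ndarray, E: np.ndarray) -> np.ndarray:
    """Expected genetic change per trait under truncation selection on the index.

    Phi = i * bG / sqrt(b'Pb) with P = G + E; element j is the correlated
    response of trait j, in trait units over the horizon the intensity refers
    to.
    """
    b = spec.coefficients
    G = np.asarray(G, dtype=float)
    P = G + np.asarray(E, dtype=float)
    bpb = float(b @ P @ b)
    if bpb <= 0:
        raise ValueError("index phenotypic variance b'Pb must be positive")
    return intensity * (b @ G) / np.sqrt(bpb)


def total_gain(phi: np.ndarray, spec: IndexSpec) -> float:
    """Total expected economic gain TEG = Phi'b, in index units."""
    phi = np.asarray(phi, dtype=float)
    if phi.shape != spec.coefficients.shape:
        raise ValueError("gain vector length must match the index")
    return float(phi @ spec.coefficients)


def calibrate_intensity(
    spec: IndexSpec, G: np.ndarray, E: np.ndarray, realized_teg: float
) -> float:
    """Selection intensity that makes the expected TEG equal the realized one.

    TEG(i) = i * b'Gb / sqrt(b'Pb) is linear in i, so
    i = realized_teg * sqrt(b'Pb) / b'Gb.
    """
    b = spec.coefficients
    G = np.asarray(G, dtype=float)
    P = G + np.asarray(E, dtype=float)
    bgb = float(b @ G @ b)
    if bgb == 0:
        raise ValueError("b'Gb is zero; intensity undefined")
    return realized_teg * np.sqrt(float(b @ P @ b)) / bgb


def discrepancy_table(
    expected: np.ndarray, realized: np.ndarray, g: np.ndarray, spec: IndexSpec
) -> np.ndarray:
    """Standardized realized-minus-expected gains.

    d_j = s_j * (realized_j - expected_j) / g_j with s_j = -1 for traits where
    negative values are favorable, so a positive d_j always means the realized
    trend beat the expectation in the economically desired direction.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g == 0):
        raise ValueError("zero genetic SD; standardized discrepancy undefined")
    return spec.sign * (np.asarray(realized, float) - np.asarray(expected, float)) / g


@dataclass
class GainReport:
    """Expected-vs-realized gain summary in the national report layout."""

    spec: IndexSpec
    genetic_sd: np.ndarray
    fractions: np.ndarray
    intensity: float
    expected: np.ndarray
    realized: np.ndarray | None
    realized_se: np.ndarray | None
    discrepancy: np.ndarray | None
    teg_expected: float
    teg_realized: float | None

    def to_frame(self):
        import pandas as pd

        cols = {
            "trait": list(self.spec.traits),
            "genetic_sd": self.genetic_sd,
            "fraction_of_index": self.fractions,
            "expected_gain": self.expected,
        }
        if self.realized is not None:
            cols["realized_gain"] = self.realized
            if self.realized_se is not None:
                cols["realized_se"] = self.realized_se
            cols["std_discrepancy"] = self.discrepancy
        return pd.DataFrame(cols)


def gain_report(
    spec: IndexSpec,
    G: np.ndarray,
    E: np.ndarray,
    intensity: float | None = None,
    realized: np.ndarray | None = None,
    realized_se: np.ndarray | None = None,
    realized_teg: float | None = None,
) -> GainReport:
    """Assemble the full gain report for an index.

    Either ``intensity`` is supplied, or ``realized_teg`` (or ``realized``,
    from which the realized TEG is computed) is used to calibrate it.
    """
    g = genetic_sd(G)
    frac = index_fractions(spec, g)
    teg_real = None
    if realized is not None:
        teg_real = total_gain(realized, spec)
    if realized_teg is not None:
        teg_real = realized_teg
    if intensity is None:
        if teg_real is None:
            raise ValueError("supply an intensity or a realized gain to calibrate against")
        intensity = calibrate_intensity(spec, G, E, teg_real)
    phi = expected_gains(intensity, spec, G, E)
    disc = discrepancy_table(phi, realized, g, spec) if realized is not None else None
    return GainReport(
        spec=spec,
        genetic_sd=g,
        fractions=frac,
        intensity=intensity,
        expected=phi,
        realized=None if realized is None else np.asarray(realized, float),
        realized_se=None if realized_se is None else np.asarray(realized_se, float),
        discrepancy=disc,
        teg_expected=total_gain(phi, spec),
        teg_realized=teg_real,
    )
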