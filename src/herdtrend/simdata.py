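"""Synthetic dairy-population generator.

Generates everything the downstream analyses consume, with the statistical
structure the animal model assumes: a multi-generation pedigree with
optionally missing parents; multivariate breeding values gene-dropped with
Mendelian-sampling variances adjusted for inbreeding; multi-parity phenotype
records built from parity shifts, herd-year-season effects, breeding values
and correlated residuals, with monotone missingness from between-parity
culling; per-cow insemination sequences driven by a logistic per-service
conception model on the conception-status breeding value; and biallelic SNP
genotypes gene-dropped through the same pedigree with optional causal loci
for a protein-like and a fertility-like trait.

Default parameters are the national Israeli-Holstein parameter set
(:mod:`herdtrend.tables`): the nine index traits with the published
first-parity G and E.  All randomness flows from ``config.seed`` through
named streams (:mod:`herdtrend._streams`), so each operation is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import tables
from ._streams import stream
from .pedigree import Pedigree, UNKNOWN, compute_inbreeding
from .plink import GenotypeMatrix
from .traits import hys_classes

__all__ = [
    "SimConfig",
    "TrueValues",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_inseminations",
    "simulate_genotypes",
    "simulate_all",
    "add_genotype_missingness",
]


class ConfigError(ValueError):
    pass


def _default_G() -> np.ndarray:
    return tables.G_2008_2016.copy()


def _default_E() -> np.ndarray:
    return tables.E_2008_2016.copy()


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults describe a compact commercial population: ~10 herds recorded
    over a decade, hierarchical matings (each sire mated to several dams),
    herd-year-season SDs of about a tenth of the phenotypic SD, a mild
    positive parity trend on the production traits, a 30% per-parity culling
    hazard and a 50% per-service conception rate.
    """

    n_founders: int = 200
    n_generations: int = 3
    dams_per_sire: int = 10
    progeny_per_dam: int = 2
    n_herds: int = 10
    years_spanned: int = 10
    traits: tuple[str, ...] = tables.TRAITS
    G: np.ndarray = field(default_factory=_default_G)
    E: np.ndarray = field(default_factory=_default_E)
    hys_sd: np.ndarray | None = None
    parity_effects: np.ndarray | None = None
    n_parities: int = 3
    max_services: int = 8
    baseline_conception: float = 0.5
    missing_parent_rate: float = 0.0
    cull_hazard: float = 0.3
    n_snps: int = 2000
    n_causal: int = 50
    causal_traits: tuple[str, str] = ("protein", "cs")
    maf_range: tuple[float, float] = (0.05, 0.5)
    start_year: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        t = len(self.traits)
        if self.G.shape != (t, t) or self.E.shape != (t, t):
            raise ConfigError("G and E must be square matrices matching the trait list")
        for name, m in (("G", self.G), ("E", self.E)):
            if not np.allclose(m, m.T, rtol=0, atol=1e-8 * (1 + np.abs(m).max())):
                raise ConfigError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-6 * max(1.0, np.trace(m)):
                raise ConfigError(f"{name} must be positive semi-definite")
        if self.n_founders <= 0 or self.n_generations < 0:
            raise ConfigError("positive founder count and non-negative generations required")
        if not (0 <= self.missing_parent_rate <= 1 and 0 <= self.cull_hazard <= 1):
            raise ConfigError("probabilities must lie in [0, 1]")
        if not 0 < self.baseline_conception < 1:
            raise ConfigError("baseline conception probability must lie in (0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_causal > self.n_snps:
            raise ConfigError("n_causal cannot exceed n_snps")
        P = self.G + self.E
        if self.hys_sd is None:
            self.hys_sd = 0.1 * np.sqrt(np.diag(P))
        self.hys_sd = np.asarray(self.hys_sd, dtype=float)
        if self.parity_effects is None:
            shift = 0.1 * np.sqrt(np.diag(P))
            self.parity_effects = np.vstack(
                [k * shift for k in range(self.n_parities)]
            )
        self.parity_effects = np.atleast_2d(np.asarray(self.parity_effects, dtype=float))
        self.n_parities = self.parity_effects.shape[0]

    def trait_pos(self, trait: str) -> int:
        return self.traits.index(trait)


@dataclass
class TrueValues:
    """Ground truth for parameter-recovery tests."""

    breeding_values: pd.DataFrame  # animal x trait
    hys_effects: pd.DataFrame | None = None  # hys key x trait
    residuals: pd.DataFrame | None = None  # record x trait


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree with hierarchical matings.

    Founders are split into sires and dams at the configured mating ratio;
    each later generation mates every available sire to ``dams_per_sire``
    dams, each dam producing ``progeny_per_dam`` offspring of random sex.
    Birth years advance so the generations span ``years_spanned`` years, and
    every female is assigned a herd at birth.  A fraction
    ``missing_parent_rate`` of non-founders has its sire, dam or both
    blanked (then drawn as phantom founders by the gene-dropping step).
    """
    rng = stream(config.seed, "pedigree")
    n_sires = max(1, round(config.n_founders / (1 + config.dams_per_sire)))
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    gen_of: list[int] = []
    for i in range(config.n_founders):
        ids.append(f"A{i}")
        sire.append(UNKNOWN)
        dam.append(UNKNOWN)
        sex.append("M" if i < n_sires else "F")
        gen_of.append(0)
    prev_males = [i for i in range(config.n_founders) if sex[i] == "M"]
    prev_females = [i for i in range(config.n_founders) if sex[i] == "F"]
    counter = config.n_founders
    for g in range(1, config.n_generations + 1):
        males: list[int] = []
        females: list[int] = []
        perm = rng.permutation(prev_females)
        pos = 0
        for s in prev_males:
            mates = perm[pos : pos + config.dams_per_sire]
            pos += config.dams_per_sire
            if len(mates) == 0:
                break
            for d in mates:
                for _ in range(config.progeny_per_dam):
                    ids.append(f"A{counter}")
                    sire.append(s)
                    dam.append(int(d))
                    sx = "M" if rng.random() < 0.5 else "F"
                    sex.append(sx)
                    gen_of.append(g)
                    (males if sx == "M" else females).append(counter)
                    counter += 1
        if not males or not females:
            raise ConfigError(f"generation {g} produced a single-sex cohort; enlarge the design")
        prev_males, prev_females = males, females
    n = counter
    # blank parents on a fraction of non-founders
    if config.missing_parent_rate > 0:
        for i in range(config.n_founders, n):
            if rng.random() < config.missing_parent_rate:
                which = rng.integers(3)
                if which in (0, 2):
                    sire[i] = UNKNOWN
                if which in (1, 2):
                    dam[i] = UNKNOWN
    # birth dates: generation blocks across the configured span
    years_per_gen = config.years_spanned / max(config.n_generations, 1)
    year = config.start_year + np.array(
        [min(int(g * years_per_gen), config.years_spanned - 1) for g in gen_of]
    )
    doy = rng.integers(0, 365, n)
    birth = np.array(
        [np.datetime64(f"{y}-01-01") + np.timedelta64(int(d), "D") for y, d in zip(year, doy)],
        dtype="datetime64[D]",
    )
    herd = np.array(
        [f"H{rng.integers(config.n_herds)}" if s == "F" else "" for s in sex], dtype=object
    )
    return Pedigree(
        ids=np.array(ids, dtype=object),
        sire=np.array(sire),
        dam=np.array(dam),
        sex=np.array(sex, dtype=object),
        birth_date=birth,
        herd=herd,
    )


def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, seed: int, traits: tuple[str, ...] | None = None
) -> TrueValues:
    """Gene-drop multivariate breeding values through the pedigree.

    Founders draw N(0, G); offspring get the mid-parent mean plus a
    Mendelian-sampling deviation with covariance (1/2 - (F_s + F_d)/4) G.
    An unknown parent is replaced by a fresh phantom founder draw, so the
    unconditional variance stays G in the base generation.
    """
    G = np.asarray(G, dtype=float)
    t = G.shape[0]
    w, v = np.linalg.eigh(G)
    if w.min() < -1e-8 * max(1.0, np.trace(G)):
        raise ValueError("G must be positive semi-definite")
    L = v * np.sqrt(np.clip(w, 0, None)) @ v.T  # symmetric square root
    rng = stream(seed, "breeding_values")
    F = compute_inbreeding(ped)
    n = len(ped)
    u = np.zeros((n, t))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        us = u[s] if s != UNKNOWN else rng.standard_normal(t) @ L
        ud = u[d] if d != UNKNOWN else rng.standard_normal(t) @ L
        fs = F[s] if s != UNKNOWN else 0.0
        fd = F[d] if d != UNKNOWN else 0.0
        if s == UNKNOWN and d == UNKNOWN:
            # true founder: single draw at full variance
            u[i] = rng.standard_normal(t) @ L
            continue
        mend = 0.5 - 0.25 * (fs + fd)
        u[i] = 0.5 * (us + ud) + np.sqrt(mend) * (rng.standard_normal(t) @ L)
    labels = traits if traits is not None else tuple(f"t{j}" for j in range(t))
    return TrueValues(
        breeding_values=pd.DataFrame(u, index=ped.ids, columns=labels)
    )


def _survival_parities(ped: Pedigree, config: SimConfig) -> dict:
    """Number of parities each cow completes (shared 'survival' stream, so
    phenotype and insemination tables agree on which records exist)."""
    rng = stream(config.seed, "survival")
    out = {}
    for i in range(len(ped)):
        if ped.sex[i] != "F" or not ped.herd[i]:
            continue
        p = 1
        while p < config.n_parities and rng.random() >= config.cull_hazard:
            p += 1
        out[ped.ids[i]] = p
    return out


def _freshening_date(birth: np.datetime64, parity: int, jitter: int) -> np.datetime64:
    # first calving around 2 years, ~13-month calving interval
    return birth + np.timedelta64(730 + 395 * (parity - 1) + jitter, "D")


def simulate_phenotypes(
    ped: Pedigree, true_values: TrueValues, config: SimConfig
) -> tuple[pd.DataFrame, TrueValues]:
    """Long-format multi-parity records.

    record = parity shift + herd-year-season effect + breeding value +
    residual (covariance E across traits).  Later parities exist only while
    the cow survives the per-parity culling hazard, so missingness is
    monotone by construction.  Returns the record table and the ground truth
    augmented with the realized HYS effects and residuals.
    """
    rng = stream(config.seed, "phenotypes")
    parities = _survival_parities(ped, config)
    bv = true_values.breeding_values
    t = len(config.traits)
    Le = _sym_sqrt(config.E)
    hys_effects: dict = {}
    rows = []
    resid_rows = []
    pos = {a: i for i, a in enumerate(ped.ids)}
    for animal, n_par in parities.items():
        i = pos[animal]
        herd = ped.herd[i]
        if not herd:
            raise ValueError(f"cow {animal!r} has no herd")
        jitter = int(rng.integers(-30, 31))
        for parity in range(1, n_par + 1):
            fresh = _freshening_date(ped.birth_date[i], parity, jitter)
            hys = hys_classes(herd, fresh)
            if hys not in hys_effects:
                hys_effects[hys] = rng.standard_normal(t) * config.hys_sd
            e = rng.standard_normal(t) @ Le.T
            value = config.parity_effects[parity - 1] + hys_effects[hys] + bv.loc[animal].to_numpy() + e
            rows.append((animal, parity, fresh, "|".join(map(str, hys)), *value))
            resid_rows.append((animal, parity, *e))
    records = pd.DataFrame(
        rows, columns=["animal", "parity", "freshening_date", "hys", *config.traits]
    )
    long = records.melt(
        id_vars=["animal", "parity", "freshening_date", "hys"],
        value_vars=list(config.traits),
        var_name="trait",
        value_name="value",
    )
    truth = TrueValues(
        breeding_values=bv,
        hys_effects=pd.DataFrame.from_dict(hys_effects, orient="index", columns=config.traits),
        residuals=pd.DataFrame(
            resid_rows, columns=["animal", "parity", *config.traits]
        ),
    )
    return long, truth


def _sym_sqrt(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(np.asarray(m, dtype=float))
    return v * np.sqrt(np.clip(w, 0, None)) @ v.T


def calibrate_conception_slope(config: SimConfig) -> float:
    """Slope of the logistic per-service conception model on the CS breeding
    value, chosen so the population SD of each cow's expected conception
    status matches the genetic SD of CS.

    The expected conception status for per-service probability p (unlimited
    services) is 100 * E[1/N] = -100 p ln(p) / (1-p) for N ~ Geometric(p);
    the SD over the N(0, sigma_cs^2) breeding-value distribution is computed
    by Gauss-Hermite quadrature and matched to sigma_cs by bisection.
    """
    ci = config.trait_pos("cs")
    sigma = float(np.sqrt(config.G[ci, ci]))
    if sigma == 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(41)
    base = logit(config.baseline_conception)

    def expected_cs(p: np.ndarray) -> np.ndarray:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return np.where(p > 1 - 1e-9, 100.0, -100.0 * p * np.log(p) / (1.0 - p))

    def sd_of(k: float) -> float:
        u = sigma * nodes
        cs = expected_cs(expit(base + k * u))
        w = weights / weights.sum()
        mean = np.sum(w * cs)
        return float(np.sqrt(np.sum(w * (cs - mean) ** 2)))

    target = sigma
    hi = 1.0
    while sd_of(hi) < target and hi < 64:
        hi *= 2
    if sd_of(hi) < target:
        raise ConfigError("cannot calibrate conception slope to the requested CS variance")
    return brentq(lambda k: sd_of(k) - target, 0.0, hi, xtol=1e-8)


def simulate_inseminations(
    ped: Pedigree, true_values: TrueValues, config: SimConfig
) -> pd.DataFrame:
    """Per-cow-parity Bernoulli conception trials.

    Each service conceives with probability
    ``logistic(logit(baseline) + slope * u_cs + herd effect)``; the sequence
    stops at conception or is censored at ``max_services``.  Uses the same
    survival stream as the phenotype generator, so the set of cow-parities
    matches the record table.
    """
    rng = stream(config.seed, "inseminations")
    herd_rng = stream(config.seed, "herd_conception")
    slope = calibrate_conception_slope(config)
    ci = config.trait_pos("cs")
    parities = _survival_parities(ped, config)
    base = logit(config.baseline_conception)
    herd_shift = {f"H{h}": herd_rng.normal(0.0, 0.1) for h in range(config.n_herds)}
    bv = true_values.breeding_values
    pos = {a: i for i, a in enumerate(ped.ids)}
    rows = []
    for animal, n_par in parities.items():
        i = pos[animal]
        u_cs = float(bv.loc[animal].iloc[ci])
        p = float(expit(base + slope * u_cs + herd_shift.get(ped.herd[i], 0.0)))
        jitter = int(rng.integers(-30, 31))
        for parity in range(1, n_par + 1):
            fresh = _freshening_date(ped.birth_date[i], parity, jitter)
            for service in range(1, config.max_services + 1):
                date = fresh + np.timedelta64(60 + 21 * (service - 1), "D")
                conceived = rng.random() < p
                if conceived:
                    rows.append((animal, parity, service, date, "conceived"))
                    break
                if service == config.max_services:
                    rows.append((animal, parity, service, date, "censored"))
                else:
                    rows.append((animal, parity, service, date, "failed"))
    return pd.DataFrame(
        rows, columns=["animal", "parity", "service_no", "date", "outcome"]
    )


@dataclass
class SimGenotypes:
    genotypes: GenotypeMatrix
    founder_freq: np.ndarray
    causal_snps: np.ndarray  # indices into snp columns
    causal_effects: np.ndarray  # (n_causal, 2) allele substitution effects
    genetic_values: pd.DataFrame  # animal x causal trait pair


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> SimGenotypes:
    """Gene-drop biallelic SNPs and attach causal effects for two traits.

    Founder allele frequencies are uniform on ``maf_range``; transmission is
    Mendelian (one allele per parent, unknown parents draw from the founder
    frequency).  ``n_causal`` SNPs receive effect pairs scaled so that the
    expected causal genetic covariance under founder Hardy-Weinberg equals
    the 2x2 G-submatrix of ``causal_traits``.
    """
    rng = stream(config.seed, "genotypes")
    m = config.n_snps
    n = len(ped)
    freq = rng.uniform(*config.maf_range, size=m)
    dosage = np.zeros((n, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            dosage[i] = rng.binomial(2, freq)
            continue
        a_s = (
            rng.random(m) < dosage[s] / 2.0
            if s != UNKNOWN
            else rng.random(m) < freq
        )
        a_d = (
            rng.random(m) < dosage[d] / 2.0
            if d != UNKNOWN
            else rng.random(m) < freq
        )
        dosage[i] = a_s.astype(np.int8) + a_d.astype(np.int8)
    geno = GenotypeMatrix(
        dosage=dosage.astype(float),
        individuals=ped.ids.copy(),
        snp_ids=np.array([f"snp{j}" for j in range(m)], dtype=object),
        chrom=1 + (np.arange(m) % 29),
        pos=1000 * (1 + np.arange(m)),
    )
    if config.n_causal == 0:
        gv = np.zeros((n, 2))
        causal = np.array([], dtype=int)
        effects = np.zeros((0, 2))
    else:
        causal = np.sort(rng.choice(m, size=config.n_causal, replace=False))
        z = rng.standard_normal((config.n_causal, 2))
        het = 2.0 * freq[causal] * (1.0 - freq[causal])
        C_raw = (z * het[:, None]).T @ z
        target = tables.submatrix(config.G, list(config.causal_traits)) if tuple(
            config.traits
        ) == tables.TRAITS else config.G[np.ix_(
            [config.trait_pos(config.causal_traits[0]), config.trait_pos(config.causal_traits[1])],
            [config.trait_pos(config.causal_traits[0]), config.trait_pos(config.causal_traits[1])],
        )]
        L_t = np.linalg.cholesky(target)
        L_r = np.linalg.cholesky(C_raw)
        effects = z @ np.linalg.inv(L_r).T @ L_t.T
        centered = dosage[:, causal] - 2.0 * freq[causal]
        gv = centered @ effects
    return SimGenotypes(
        genotypes=geno,
        founder_freq=freq,
        causal_snps=causal,
        causal_effects=effects,
        genetic_values=pd.DataFrame(gv, index=ped.ids, columns=list(config.causal_traits)),
    )


def add_genotype_missingness(
    geno: GenotypeMatrix, rates: np.ndarray | float, seed: int
) -> GenotypeMatrix:
    """Mask calls at per-SNP missingness ``rates`` (for call-rate QC tests)."""
    rng = stream(seed, "genotype_missingness")
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (geno.n_snps,))
    mask = rng.random(geno.dosage.shape) < rates[None, :]
    dosage = geno.dosage.copy()
    dosage[mask] = np.nan
    return GenotypeMatrix(
        dosage=dosage,
        individuals=geno.individuals,
        snp_ids=geno.snp_ids,
        chrom=geno.chrom,
        pos=geno.pos,
    )


def simulate_all(config: SimConfig, out_dir: str | Path | None = None):
    """Run every generator stage; optionally write the CSV/PLINK bundle."""
    from .plink import write_plink

    ped = simulate_pedigree(config)
    truth = simulate_breeding_values(ped, config.G, config.seed, traits=config.traits)
    phen, truth = simulate_phenotypes(ped, truth, config)
    insem = simulate_inseminations(ped, truth, config)
    geno = simulate_genotypes(ped, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ped.to_csv(out / "pedigree.csv")
        phen.to_csv(out / "phenotypes.csv", index=False)
        insem.to_csv(out / "inseminations.csv", index=False)
        truth.breeding_values.rename_axis("animal").to_csv(out / "true_breeding_values.tsv", sep="\t")
        write_plink(geno.genotypes, str(out / "genotypes"))
    return ped, truth, phen, insem, geno
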