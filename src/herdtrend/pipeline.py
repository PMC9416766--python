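"""End-to-end pipeline: simulate -> derived traits -> evaluation -> REML ->
selection index -> GWAS, with a flat, diffable configuration.

Each stage writes plain TSV/CSV tables into the output directory and a
``manifest.json`` records the seed, package version and per-stage row
counts.  All randomness flows from the single config seed, so the same
config produces byte-identical outputs.

Periods (birth-year windows) partition the cows for variance-component
estimation, mirroring how a national data set is split into eras; each
period gets its own genetic-parameter matrix (heritabilities on the
diagonal, genetic correlations above, phenotypic correlations below).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, tables
from . import index as index_mod
from .blup import ModelSpec, build_mme, realized_trends, rebase, solve_mme
from .gwas import cross_trait_effects, ibs_kinship, null_reml, qc_filter, scan
from .pedigree import assign_groups
from .reml import TraitCovariances, parameter_table, reml_fit
from .simdata import SimConfig, simulate_all

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat pipeline configuration (loadable from a key: value YAML file)."""

    out_dir: str = "herdtrend_run"
    seed: int = 0
    run_simulate: bool = True
    run_evaluate: bool = True
    run_reml: bool = True
    run_index: bool = True
    run_gwas: bool = True
    analysis_traits: tuple[str, ...] = ("protein", "cs")
    periods: tuple[tuple[int, int], ...] = ((2000, 2004), (2005, 2009))
    base_year: int | None = None
    n_founders: int = 220
    n_generations: int = 2
    dams_per_sire: int = 10
    progeny_per_dam: int = 2
    n_herds: int = 8
    years_spanned: int = 10
    n_snps: int = 1000
    n_causal: int = 40
    reml_method: str = "em-then-ai"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "periods" in raw:
            raw["periods"] = tuple(tuple(p) for p in raw["periods"])
        if "analysis_traits" in raw:
            raw["analysis_traits"] = tuple(raw["analysis_traits"])
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            seed=self.seed,
            n_founders=self.n_founders,
            n_generations=self.n_generations,
            dams_per_sire=self.dams_per_sire,
            progeny_per_dam=self.progeny_per_dam,
            n_herds=self.n_herds,
            years_spanned=self.years_spanned,
            n_snps=self.n_snps,
            n_causal=self.n_causal,
        )


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of human-readable issues; empty iff runnable."""
    issues: list[str] = []
    if config.seed < 0:
        issues.append("seed: must be non-negative")
    for t in config.analysis_traits:
        if t not in tables.TRAITS:
            issues.append(f"analysis_traits: unknown trait {t!r}")
    spans = sorted(config.periods)
    for a, b in spans:
        if b < a:
            issues.append(f"periods: ({a}, {b}) ends before it starts")
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            issues.append(f"periods: ({a1}, {b1}) overlaps ({a2}, {b2})")
    for name in ("n_founders", "n_generations", "n_herds", "n_snps"):
        if getattr(config, name) < 0 or (name == "n_founders" and getattr(config, name) == 0):
            issues.append(f"{name}: must be positive")
    if config.reml_method not in ("em", "ai", "em-then-ai"):
        issues.append(f"reml_method: unknown method {config.reml_method!r}")
    return issues


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the manifest."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    state: dict = {}
    stage = "simulate"
    try:
        if config.run_simulate:
            scfg = config.sim_config()
            ped, truth, phen, insem, geno = simulate_all(scfg, out_dir=out / "data")
            state.update(ped=ped, truth=truth, phen=phen, insem=insem, geno=geno, scfg=scfg)
            manifest["stages"]["simulate"] = {
                "animals": len(ped),
                "phenotype_rows": len(phen),
                "insemination_rows": len(insem),
                "snps": geno.genotypes.n_snps,
            }
        if config.run_evaluate:
            stage = "evaluate"
            _stage_evaluate(config, state, out, manifest)
        if config.run_reml:
            stage = "reml"
            _stage_reml(config, state, out, manifest)
        if config.run_index:
            stage = "index"
            _stage_index(config, state, out, manifest)
        if config.run_gwas:
            stage = "gwas"
            _stage_gwas(config, state, out, manifest)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _require_sim(state: dict, what: str):
    if "ped" not in state:
        raise ValueError(f"{what} stage requires the simulate stage in this run")


def _first_parity_wide(phen: pd.DataFrame, traits) -> pd.DataFrame:
    sub = phen[(phen["parity"] == 1) & phen["trait"].isin(traits)]
    wide = sub.pivot_table(index="animal", columns="trait", values="value")[list(traits)]
    hys = sub.drop_duplicates("animal").set_index("animal")["hys"]
    wide = wide.dropna()
    wide["hys"] = hys.loc[wide.index]
    return wide.reset_index()


def _stage_evaluate(config: PipelineConfig, state: dict, out: Path, manifest: dict) -> None:
    _require_sim(state, "evaluate")
    ped, phen, scfg = state["ped"], state["phen"], state["scfg"]
    traits = list(config.analysis_traits)
    recs = _first_parity_wide(phen, traits)
    model = ModelSpec(
        traits=tuple(traits),
        G=tables.submatrix(scfg.G, traits),
        E=tables.submatrix(scfg.E, traits),
        fixed_effects=("hys",),
    )
    groups = assign_groups(ped, rule="by_sex")
    system = build_mme(recs, model, ped, groups=groups if len(groups) else None)
    sol = solve_mme(system)
    result = system.split(sol)
    birth = pd.Series(pd.to_datetime(ped.birth_date), index=ped.ids)
    base_year = config.base_year or (scfg.start_year + scfg.years_spanned // 2)
    cohort = birth.dt.year == base_year
    if cohort.sum() == 0:
        cohort = birth.dt.year == birth.dt.year.max()
    ebv = rebase(result.ebv, cohort.to_numpy())
    trends = realized_trends(ebv, birth)
    ebv.rename_axis("animal").to_csv(out / "ebv.tsv", sep="\t")
    trends.to_csv(out / "genetic_trends.tsv", sep="\t")
    state["ebv"] = ebv
    state["trends"] = trends
    manifest["stages"]["evaluate"] = {
        "records": len(recs),
        "animals_evaluated": len(ebv),
        "base_cohort_size": int(cohort.sum()),
    }


def _stage_reml(config: PipelineConfig, state: dict, out: Path, manifest: dict) -> None:
    _require_sim(state, "reml")
    ped, phen, scfg = state["ped"], state["phen"], state["scfg"]
    traits = list(config.analysis_traits)
    birth_year = pd.Series(pd.to_datetime(ped.birth_date).year, index=ped.ids)
    info = {}
    for lo, hi in config.periods:
        cows = birth_year[(birth_year >= lo) & (birth_year <= hi)].index
        sub = phen[phen["animal"].isin(cows)]
        if sub.empty:
            info[f"{lo}-{hi}"] = {"records": 0, "skipped": True}
            continue
        init = TraitCovariances(
            G=tables.submatrix(scfg.G, traits),
            E=tables.submatrix(scfg.E, traits),
            labels=tuple(traits),
        )
        fit = reml_fit(
            sub[sub["parity"] == 1],
            ped,
            traits,
            init=init,
            method=config.reml_method,
        )
        tab = parameter_table(fit.covariances)
        tab.to_csv(out / f"parameters_{lo}_{hi}.tsv", sep="\t")
        info[f"{lo}-{hi}"] = {
            "records": int(sub[sub["parity"] == 1]["animal"].nunique()),
            "converged": bool(fit.converged),
            "iterations": fit.iterations,
        }
    state["reml_info"] = info
    manifest["stages"]["reml"] = info


def _stage_index(config: PipelineConfig, state: dict, out: Path, manifest: dict) -> None:
    spec = index_mod.pd19_spec()
    report = index_mod.gain_report(
        spec,
        tables.G_2008_2016,
        tables.E_2008_2016,
        realized=tables.REALIZED_GAIN,
        realized_se=tables.REALIZED_GAIN_SE,
        realized_teg=tables.REALIZED_TEG,
    )
    frame = report.to_frame()
    frame.to_csv(out / "gain_report.tsv", sep="\t", index=False)
    manifest["stages"]["index"] = {
        "intensity": round(report.intensity, 4),
        "teg_expected": round(report.teg_expected, 2),
        "teg_realized": round(report.teg_realized, 2),
    }


def _stage_gwas(config: PipelineConfig, state: dict, out: Path, manifest: dict) -> None:
    _require_sim(state, "gwas")
    geno_all = state["geno"]
    truth = state["truth"]
    # bull-style association: genetic values of the two causal traits as response
    geno = qc_filter(geno_all.genotypes)
    K = ibs_kinship(geno)
    K = K / K.diagonal().mean()
    eig = np.linalg.eigh(K)
    results = {}
    for trait in geno_all.genetic_values.columns:
        y = geno_all.genetic_values[trait].to_numpy()
        y = y + 0.5 * y.std() * np.random.default_rng(config.seed).standard_normal(len(y))
        null = null_reml(y, K, eig=(np.clip(eig[0], 0, None), eig[1]))
        res = scan(y, geno, null=null)
        res.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
        results[trait] = res
    t1, t2 = list(results)
    r2, slope, pairs = cross_trait_effects(results[t1], results[t2])
    pd.DataFrame({"r2": [r2], "slope": [slope], "n_snps": [len(pairs)]}).to_csv(
        out / "gwas_cross_trait.tsv", sep="\t", index=False
    )
    manifest["stages"]["gwas"] = {
        "snps_tested": int((~results[t1]["p"].isna()).sum()),
        "cross_trait_r2": round(float(r2), 4),
    }
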