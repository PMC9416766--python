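"""Multi-trait individual-animal-model BLUP.

Assembles Henderson's mixed-model equations for a set of traits analyzed
jointly: fixed one-hot effects (herd-year-season, parity, ...), one additive
genetic effect per animal related through the sparse pedigree A-inverse
(optionally extended with unknown-parent group columns), and residual
covariance E.  Records may observe any subset of the traits; each record
contributes the inverse of the observed submatrix of E, the exact treatment
of missing traits in multi-trait MME.

Also provides the post-processing an evaluation pipeline needs: solving the
system (direct sparse factorization or conjugate gradients), exact
reliabilities from the inverse coefficient matrix at desk scale, rebasing to
a base cohort, combining parities into a multi-parity index, realized
genetic trends by regression of EBV on birth date, and a dense GLS oracle
used by the test-suite to validate the sparse path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import stats

from .pedigree import GroupMap, Pedigree, a_inverse

__all__ = [
    "ModelSpec",
    "MmeSystem",
    "EvaluationResult",
    "build_mme",
    "solve_mme",
    "reliability",
    "rebase",
    "combine_parities",
    "realized_trends",
    "dense_gls_blup",
]

DENSE_INVERSE_LIMIT = 4000


@dataclass
class ModelSpec:
    """Multi-trait model: trait labels, covariances, and fixed-effect columns.

    ``fixed_effects`` name columns of the record table; the first effect
    keeps all its levels, later effects drop their first level so the fixed
    design stays full rank.
    """

    traits: tuple[str, ...]
    G: np.ndarray
    E: np.ndarray
    fixed_effects: tuple[str, ...] = ("hys",)

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.G = np.asarray(self.G, float)
        self.E = np.asarray(self.E, float)
        if self.G.shape != (t, t) or self.E.shape != (t, t):
            raise ValueError("G and E must match the trait count")


@dataclass
class MmeSystem:
    C: sp.csr_matrix
    rhs: np.ndarray
    model: ModelSpec
    animal_ids: np.ndarray
    group_labels: list
    fixed_levels: dict
    n_fixed: int

    def genetic_offset(self, animal_pos: int, trait_pos: int) -> int:
        return self.n_fixed + animal_pos * len(self.model.traits) + trait_pos

    def split(self, solutions: np.ndarray) -> "EvaluationResult":
        t = len(self.model.traits)
        n = len(self.animal_ids)
        ebv = solutions[self.n_fixed : self.n_fixed + n * t].reshape(n, t)
        groups = solutions[self.n_fixed + n * t :].reshape(len(self.group_labels), t)
        fixed = {}
        for (effect, level, trait), idx in self.fixed_levels.items():
            fixed[(effect, level, trait)] = solutions[idx]
        return EvaluationResult(
            ebv=pd.DataFrame(ebv, index=self.animal_ids, columns=self.model.traits),
            fixed=fixed,
            groups=pd.DataFrame(groups, index=self.group_labels, columns=self.model.traits)
            if len(self.group_labels)
            else None,
        )


@dataclass
class EvaluationResult:
    ebv: pd.DataFrame  # animal x trait
    fixed: dict
    groups: pd.DataFrame | None = None
    reliability: pd.DataFrame | None = None


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


def _observed_pattern_inverses(E: np.ndarray):
    cache: dict[tuple[int, ...], np.ndarray] = {}

    def get(obs: tuple[int, ...]) -> np.ndarray:
        if obs not in cache:
            sub = E[np.ix_(obs, obs)]
            try:
                inv = np.linalg.inv(sub)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"residual covariance singular for observed traits {obs}"
                ) from None
            t = E.shape[0]
            W = np.zeros((t, t))
            W[np.ix_(obs, obs)] = inv
            cache[obs] = W
        return cache[obs]

    return get


def build_mme(
    records: pd.DataFrame,
    model: ModelSpec,
    ped: Pedigree,
    ainv: sp.spmatrix | None = None,
    groups: GroupMap | None = None,
) -> MmeSystem:
    """Assemble the sparse symmetric MME.

    ``records`` has one row per record: an ``animal`` column, one column per
    fixed effect named in the model, and one column per trait (NaN where the
    trait is unobserved).
    """
    t = len(model.traits)
    if ainv is None:
        ainv = a_inverse(ped, groups=groups)
    n_animals = len(ped)
    n_groups = len(groups.labels) if groups is not None else 0
    if ainv.shape[0] != n_animals + n_groups:
        raise ValueError("A-inverse dimension does not match pedigree plus groups")

    # fixed-effect equation layout
    fixed_levels: dict = {}
    n_fixed = 0
    for e_i, effect in enumerate(model.fixed_effects):
        if effect not in records.columns:
            raise ValueError(f"fixed effect column {effect!r} missing from records")
        levels = sorted(records[effect].unique())
        if e_i > 0:
            levels = levels[1:]  # reference level absorbed by the first effect
        for level in levels:
            for trait_pos in range(t):
                fixed_levels[(effect, level, model.traits[trait_pos])] = n_fixed
                n_fixed += 1
    n_eq = n_fixed + (n_animals + n_groups) * t

    animal_pos = ped.position(records["animal"].to_numpy())
    Y = records[list(model.traits)].to_numpy(dtype=float)
    rinv = _observed_pattern_inverses(model.E)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    rhs = np.zeros(n_eq)

    def fixed_cols_for(record) -> list[tuple[int, int]]:
        """(equation base index, trait stride handled by caller) per effect."""
        out = []
        for effect in model.fixed_effects:
            key0 = (effect, record[effect], model.traits[0])
            if key0 in fixed_levels:
                out.append(fixed_levels[key0])
        return out

    eff_cols = np.full((len(records), len(model.fixed_effects)), -1, dtype=int)
    for e_i, effect in enumerate(model.fixed_effects):
        col = records[effect].to_numpy()
        lut = {lvl: fixed_levels[(effect, lvl, model.traits[0])] for lvl in pd.unique(col)
               if (effect, lvl, model.traits[0]) in fixed_levels}
        eff_cols[:, e_i] = [lut.get(v, -1) for v in col]

    gen_base = n_fixed
    for k in range(len(records)):
        y = Y[k]
        obs = tuple(np.flatnonzero(~np.isnan(y)))
        if not obs:
            continue
        W = rinv(obs)
        yk = np.nan_to_num(y)
        wy = W @ yk
        bases = [b for b in eff_cols[k] if b >= 0]
        bases.append(gen_base + animal_pos[k] * t)
        for b1 in bases:
            for b2 in bases:
                for i in obs:
                    for j in obs:
                        rows.append(b1 + i)
                        cols.append(b2 + j)
                        vals.append(W[i, j])
            for i in obs:
                rhs[b1 + i] += wy[i]

    # genetic block: A-inverse (x) G-inverse
    ginv = np.linalg.inv(model.G)
    coo = sp.coo_matrix(ainv)
    for r, c, v in zip(coo.row, coo.col, coo.data):
        br, bc = gen_base + r * t, gen_base + c * t
        for i in range(t):
            for j in range(t):
                if ginv[i, j] != 0.0:
                    rows.append(br + i)
                    cols.append(bc + j)
                    vals.append(v * ginv[i, j])

    C = sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(n_eq, n_eq)))
    return MmeSystem(
        C=C,
        rhs=rhs,
        model=model,
        animal_ids=ped.ids,
        group_labels=list(groups.labels) if groups is not None else [],
        fixed_levels=fixed_levels,
        n_fixed=n_fixed,
    )


def solve_mme(
    system: MmeSystem,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> np.ndarray:
    """Solve the assembled MME; returns the stacked solution vector.

    ``direct`` uses a sparse LU factorization with a least-squares fallback
    for systems made singular by confounded group columns; ``cg`` runs
    Jacobi-preconditioned conjugate gradients and raises
    :class:`ConvergenceError` with the last residual if it stalls.
    """
    C, rhs = sp.csc_matrix(system.C), system.rhs
    rhs_norm = np.linalg.norm(rhs) or 1.0
    if method == "direct":
        try:
            sol = spla.splu(C).solve(rhs)
            if not np.all(np.isfinite(sol)):
                raise RuntimeError("singular system")
        except RuntimeError:
            sol = spla.lsmr(C, rhs, atol=1e-12, btol=1e-12, maxiter=max_iter)[0]
        return sol
    if method != "cg":
        raise ValueError(f"unknown solver {method!r}")
    diag = C.diagonal()
    diag[diag == 0] = 1.0
    M = sp.diags(1.0 / diag)
    sol, info = spla.cg(C, rhs, rtol=tol, maxiter=max_iter, M=M)
    resid = np.linalg.norm(C @ sol - rhs) / rhs_norm
    if info != 0 and resid > tol * 100:
        raise ConvergenceError(f"conjugate gradient stalled at residual {resid:.3e}", resid)
    return sol


def reliability(system: MmeSystem, animals=None, dense_limit: int = DENSE_INVERSE_LIMIT) -> pd.DataFrame:
    """Exact per-animal, per-trait reliabilities r^2 = 1 - PEV/G_tt.

    Inverts the full coefficient matrix, so it is restricted to desk-scale
    systems (raises beyond ``dense_limit`` equations).
    """
    n_eq = system.C.shape[0]
    if n_eq > dense_limit:
        raise ValueError(
            f"{n_eq} equations exceed the dense inversion limit ({dense_limit}); "
            "compute reliabilities on a subset model"
        )
    Cinv = np.linalg.pinv(system.C.toarray())
    t = len(system.model.traits)
    ids = system.animal_ids if animals is None else np.atleast_1d(animals)
    lookup = {a: i for i, a in enumerate(system.animal_ids)}
    out = np.empty((len(ids), t))
    for r, a in enumerate(ids):
        pos = lookup[a]
        for i in range(t):
            pev = Cinv[system.genetic_offset(pos, i), system.genetic_offset(pos, i)]
            out[r, i] = 1.0 - pev / system.model.G[i, i]
    return pd.DataFrame(np.clip(out, 0.0, 1.0 - 1e-12), index=ids, columns=system.model.traits)


def rebase(ebv: pd.DataFrame, cohort) -> pd.DataFrame:
    """Express EBVs relative to a base cohort (boolean mask or id list)."""
    if isinstance(cohort, (list, np.ndarray, pd.Index)) and np.asarray(cohort).dtype != bool:
        mask = ebv.index.isin(cohort)
    else:
        mask = np.asarray(cohort, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("empty base cohort")
    return ebv - ebv.loc[mask].mean(axis=0)


#: Default multi-parity combination weights for parities 1-3; the national
#: weights are not public, so these are a configurable package choice.
DEFAULT_PARITY_WEIGHTS = (0.5, 0.3, 0.2)


def combine_parities(
    parity_ebv: dict[int, pd.DataFrame] | list, weights=DEFAULT_PARITY_WEIGHTS
) -> pd.DataFrame:
    """Weighted multi-parity index; weights are normalized to sum to one."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("parity weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("at least one positive parity weight required")
    w = w / w.sum()
    frames = list(parity_ebv.values()) if isinstance(parity_ebv, dict) else list(parity_ebv)
    if len(frames) != len(w):
        raise ValueError("one weight per parity evaluation required")
    out = sum(wi * f for wi, f in zip(w, frames))
    return out


def realized_trends(ebv: pd.DataFrame, birth_dates: pd.Series, per: float = 365.25) -> pd.DataFrame:
    """Per-trait OLS slope (trait units per year) and SE of EBV on birth date.

    ``per`` rescales the slope from per-day to the reporting unit (365.25 for
    per-year trends; multiply by 10 for per-decade horizons).
    """
    dates = pd.to_datetime(birth_dates.loc[ebv.index])
    days = (dates - dates.min()).dt.days.to_numpy(dtype=float)
    if len(np.unique(days)) < 3:
        raise ValueError("at least 3 distinct birth dates required for a trend")
    rows = []
    for trait in ebv.columns:
        res = stats.linregress(days, ebv[trait].to_numpy())
        rows.append((trait, res.slope * per, res.stderr * per))
    return pd.DataFrame(rows, columns=["trait", "slope", "se"]).set_index("trait")


def dense_gls_blup(
    records: pd.DataFrame, model: ModelSpec, ped: Pedigree, A: np.ndarray
) -> EvaluationResult:
    """Reference BLUP by dense generalized least squares.

    Builds the full observation covariance V = Z(A (x) G)Z' + R explicitly
    and computes b = (X'V^-1 X)^- X'V^-1 y and u = Cov(u, y) V^-1 (y - Xb).
    Exact but O(N^3) in the observation count; used to validate the sparse
    MME on small instances.
    """
    t = len(model.traits)
    # enumerate scalar observations (record, trait)
    obs_rec: list[int] = []
    obs_trait: list[int] = []
    Y = records[list(model.traits)].to_numpy(dtype=float)
    for k in range(len(records)):
        for i in np.flatnonzero(~np.isnan(Y[k])):
            obs_rec.append(k)
            obs_trait.append(int(i))
    obs_rec_a = np.array(obs_rec)
    obs_trait_a = np.array(obs_trait)
    y = Y[obs_rec_a, obs_trait_a]
    N = len(y)
    apos = ped.position(records["animal"].to_numpy())
    a_of_obs = apos[obs_rec_a]
    V = A[np.ix_(a_of_obs, a_of_obs)] * model.G[np.ix_(obs_trait_a, obs_trait_a)]
    same_rec = obs_rec_a[:, None] == obs_rec_a[None, :]
    V = V + same_rec * model.E[np.ix_(obs_trait_a, obs_trait_a)]

    # fixed design mirroring build_mme's column layout
    fixed_levels: dict = {}
    n_fixed = 0
    for e_i, effect in enumerate(model.fixed_effects):
        levels = sorted(records[effect].unique())
        if e_i > 0:
            levels = levels[1:]
        for level in levels:
            for trait in model.traits:
                fixed_levels[(effect, level, trait)] = n_fixed
                n_fixed += 1
    X = np.zeros((N, n_fixed))
    for o in range(N):
        rec = records.iloc[obs_rec_a[o]]
        for effect in model.fixed_effects:
            key = (effect, rec[effect], model.traits[obs_trait_a[o]])
            if key in fixed_levels:
                X[o, fixed_levels[key]] = 1.0

    Vinv = np.linalg.inv(V)
    XtVi = X.T @ Vinv
    beta = np.linalg.pinv(XtVi @ X) @ (XtVi @ y)
    resid = y - X @ beta
    # Cov(u_(a,i), y_o) = A[a, a_o] G[i, trait_o]
    n = len(ped)
    Cuy = np.repeat(A[:, a_of_obs], t, axis=0) * np.tile(
        model.G[:, obs_trait_a], (n, 1)
    )
    u = (Cuy @ (Vinv @ resid)).reshape(n, t)
    fixed = {key: beta[idx] for key, idx in fixed_levels.items()}
    return EvaluationResult(
        ebv=pd.DataFrame(u, index=ped.ids, columns=model.traits), fixed=fixed
    )
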