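"""Multi-trait REML variance-component estimation for the animal model.

Model: for animal k with record vector y_k over t traits,

    y = Xb + a + e,   a ~ N(0, A (x) G),   e ~ N(0, I (x) E)

with A the pedigree numerator-relationship matrix among recorded animals.
The engine eigendecomposes A = U L U' once and rotates the data, after which
records are independent with per-record covariance V_k = l_k G + E.  Both the
restricted log-likelihood and its derivatives then cost O(n t^3) per
iteration, so desk-scale multi-trait fits run in seconds.

Updates
-------
* ``em``: classical EM-REML; monotone in the restricted likelihood.
* ``ai``: average-information (quasi-Newton) with step halving, returning
  approximate standard errors from the inverse AI matrix at convergence.
* ``em-then-ai`` (default): EM warm-up iterations followed by AI, the usual
  remedy for AI divergence far from the optimum.

G and E are floored to positive semi-definite after every update (eigenvalue
clipping at 1e-8 x trace), so derived correlations always lie in [-1, 1].

The engine requires complete records (every analyzed animal observed for
every analyzed trait), matching the complete-case edit used for the
nine-trait national analysis; animals with partial records are dropped by
the table-level wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .pedigree import Pedigree, relationship_submatrix

__all__ = [
    "TraitCovariances",
    "RemlFit",
    "reml_fit",
    "reml_fit_arrays",
    "heritability",
    "genetic_correlation",
    "environmental_correlation",
    "phenotypic_correlation",
    "parameter_table",
]

_PSD_FLOOR = 1e-8


@dataclass
class TraitCovariances:
    """Paired genetic (G) and environmental (E) covariance matrices."""

    G: np.ndarray
    E: np.ndarray
    labels: tuple[str, ...]
    se_G: np.ndarray | None = None
    se_E: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        t = len(self.labels)
        if self.G.shape != (t, t) or self.E.shape != (t, t):
            raise ValueError("G and E must be square with one row per trait label")

    @property
    def P(self) -> np.ndarray:
        """Phenotypic covariance, P = G + E."""
        return self.G + self.E

    def index(self, trait: str) -> int:
        try:
            return self.labels.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None


def _floor_psd(m: np.ndarray) -> np.ndarray:
    """Clip eigenvalues below 1e-8 x trace; keeps iterates valid covariances."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    floor = _PSD_FLOOR * max(np.trace(m), _PSD_FLOOR)
    if w[0] >= floor:
        return m
    return (v * np.maximum(w, floor)) @ v.T


def heritability(cov: TraitCovariances, trait: str) -> float:
    """h^2 = G_tt / (G_tt + E_tt)."""
    i = cov.index(trait)
    total = cov.G[i, i] + cov.E[i, i]
    if total <= 0:
        raise ValueError(f"zero total variance for trait {trait!r}")
    return float(cov.G[i, i] / total)


def _correlation(m: np.ndarray, i: int, j: int) -> float:
    denom = np.sqrt(m[i, i] * m[j, j])
    if denom == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.clip(m[i, j] / denom, -1.0, 1.0))


def genetic_correlation(cov: TraitCovariances, trait_a: str, trait_b: str) -> float:
    return _correlation(cov.G, cov.index(trait_a), cov.index(trait_b))


def environmental_correlation(cov: TraitCovariances, trait_a: str, trait_b: str) -> float:
    return _correlation(cov.E, cov.index(trait_a), cov.index(trait_b))


def phenotypic_correlation(cov: TraitCovariances, trait_a: str, trait_b: str) -> float:
    return _correlation(cov.P, cov.index(trait_a), cov.index(trait_b))


def parameter_table(cov: TraitCovariances, below: str = "phenotypic") -> pd.DataFrame:
    """Genetic-parameter matrix: heritabilities on the diagonal, genetic
    correlations above, environmental or phenotypic correlations below."""
    t = len(cov.labels)
    out = np.zeros((t, t))
    lower = environmental_correlation if below == "environmental" else phenotypic_correlation
    for i, a in enumerate(cov.labels):
        out[i, i] = heritability(cov, a)
        for j, b in enumerate(cov.labels):
            if j > i:
                out[i, j] = genetic_correlation(cov, a, b)
            elif j < i:
                out[i, j] = lower(cov, a, b)
    return pd.DataFrame(out, index=cov.labels, columns=cov.labels)


@dataclass
class RemlFit:
    covariances: TraitCovariances
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0
    method: str = "em-then-ai"
    em_iterations: int = 0


def _sym_basis(t: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(t) for j in range(i, t)]


class _Rotated:
    """Rotated-data workspace shared by likelihood, EM and AI computations.

    Pass ``eig=(eigenvalues, eigenvectors)`` of A to reuse a decomposition
    across repeated fits on the same pedigree (e.g. simulation replicates).
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, A: np.ndarray | None, eig=None) -> None:
        Y = np.atleast_2d(np.asarray(Y, float))
        if Y.ndim == 2 and Y.shape[0] < Y.shape[1] and Y.shape[0] == 1:
            Y = Y.T
        n, self.t = Y.shape
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        # drop linearly dependent fixed-effect columns (QR with pivoting)
        _, r, piv = sla.qr(X, mode="economic", pivoting=True)
        rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * max(1.0, abs(r[0, 0]))))
        X = X[:, sorted(piv[:rank])]
        self.p = X.shape[1]
        if eig is None:
            lam, U = np.linalg.eigh(np.asarray(A, float))
        else:
            lam, U = eig
        self.lam = np.clip(lam, 0.0, None)
        self.Ys = U.T @ Y
        self.Xs = U.T @ X
        self.n = n

    def evaluate(self, G: np.ndarray, E: np.ndarray):
        """Per-iteration quantities at (G, E): Vinv, GLS residual projections,
        restricted log-likelihood."""
        lam = self.lam
        t, p, Xs = self.t, self.p, self.Xs
        V = lam[:, None, None] * G + E
        Vinv = np.linalg.inv(V)
        sign, logdetV = np.linalg.slogdet(V)
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-PD record covariance")
        # M[(a,i),(b,j)] = sum_k x_ka x_kb Vinv_k[i,j]; t^2 BLAS matmuls
        M = np.empty((p, t, p, t))
        for i in range(t):
            for j in range(t):
                M[:, i, :, j] = Xs.T @ (Vinv[:, i, j, None] * Xs)
        M2 = M.reshape(p * t, p * t)
        rhs = np.einsum("ka,ki->ai", Xs, np.einsum("kij,kj->ki", Vinv, self.Ys)).reshape(-1)
        signM, logdetM = np.linalg.slogdet(M2)
        if signM <= 0:
            raise np.linalg.LinAlgError("singular fixed-effect equations")
        B = np.linalg.solve(M2, rhs).reshape(p, t)
        r = self.Ys - Xs @ B
        Py = np.einsum("kij,kj->ki", Vinv, r)
        loglik = -0.5 * (logdetV.sum() + logdetM + float(np.sum(r * Py)))
        Minv = np.linalg.inv(M2).reshape(p, t, p, t)
        # T_k = (x_k' (x) I) Minv (x_k (x) I); t^2 row-sum matmuls
        T = np.empty((self.n, t, t))
        for i in range(t):
            for j in range(t):
                T[:, i, j] = np.sum((Xs @ Minv[:, i, :, j]) * Xs, axis=1)
        W = Vinv - np.einsum("kij,kjl,klm->kim", Vinv, T, Vinv)
        return Vinv, Py, W, loglik, Minv

    def project(self, f: np.ndarray, Vinv: np.ndarray, Minv: np.ndarray) -> np.ndarray:
        """Apply the REML projection P to per-record vectors f (n, t)."""
        h = np.einsum("kij,kj->ki", Vinv, f)
        g = np.einsum("ka,ki->ai", self.Xs, h)
        w = np.einsum("aibj,bj->ai", Minv, g)
        return h - np.einsum("kij,ka,aj->ki", Vinv, self.Xs, w)


def _em_update(rot: _Rotated, G, E, Vinv, Py, W):
    lam = rot.lam[:, None, None]
    outer = Py[:, :, None] * Py[:, None, :]
    Gn = G + G @ np.mean(lam * (outer - W), axis=0) @ G
    En = E + E @ np.mean(outer - W, axis=0) @ E
    return _floor_psd(Gn), _floor_psd(En)


def _ai_update(rot: _Rotated, G, E, Vinv, Py, W, Minv):
    """One AI (average-information) Newton step; returns proposal and the AI matrix."""
    t = rot.t
    pairs = _sym_basis(t)
    m = len(pairs)
    lam = rot.lam
    scores = np.empty(2 * m)
    fvecs = np.empty((2 * m, rot.n, t))
    for idx, (i, j) in enumerate(pairs):
        S = np.zeros((t, t))
        S[i, j] = S[j, i] = 1.0
        for block, scale in ((0, lam), (1, np.ones_like(lam))):
            f = (Py @ S) * scale[:, None]
            trWS = np.einsum("kij,ji->k", W, S) @ scale
            quad = np.einsum("ki,ki->", f, Py)
            scores[block * m + idx] = 0.5 * (quad - trWS)
            fvecs[block * m + idx] = f
    Pf = np.stack([rot.project(fvecs[a], Vinv, Minv) for a in range(2 * m)])
    AI = 0.5 * np.einsum("akt,bkt->ab", fvecs, Pf)
    AI = 0.5 * (AI + AI.T)
    try:
        delta = np.linalg.solve(AI + 1e-12 * np.eye(2 * m) * max(1.0, np.trace(AI)), scores)
    except np.linalg.LinAlgError:
        return None, AI
    return delta, AI


def _pack(G, E, pairs):
    return np.array([G[i, j] for i, j in pairs] + [E[i, j] for i, j in pairs])


def _unpack(theta, pairs, t):
    G = np.zeros((t, t))
    E = np.zeros((t, t))
    m = len(pairs)
    for idx, (i, j) in enumerate(pairs):
        G[i, j] = G[j, i] = theta[idx]
        E[i, j] = E[j, i] = theta[m + idx]
    return G, E


def reml_fit_arrays(
    Y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray,
    init: TraitCovariances,
    method: str = "em-then-ai",
    tol: float = 1e-6,
    max_iter: int = 200,
    n_em: int = 10,
    eig=None,
) -> RemlFit:
    """REML fit on dense arrays: records Y (n x t), fixed design X (n x p),
    relationship matrix A (n x n) among the recorded animals.

    ``eig`` optionally supplies a precomputed eigendecomposition of A (as
    returned by ``numpy.linalg.eigh``), reused across replicate fits.
    """
    if method not in ("em", "ai", "em-then-ai"):
        raise ValueError(f"unknown REML method {method!r}")
    rot = _Rotated(Y, X, A, eig=eig)
    t = rot.t
    pairs = _sym_basis(t)
    G = _floor_psd(init.G.copy())
    E = _floor_psd(init.E.copy())
    trace: list[float] = []
    em_iters = 0
    converged = False
    AI = None
    it = 0
    for it in range(1, max_iter + 1):
        Vinv, Py, W, loglik, Minv = rot.evaluate(G, E)
        trace.append(loglik)
        use_em = method == "em" or (method == "em-then-ai" and it <= n_em)
        theta_old = _pack(G, E, pairs)
        if use_em:
            G_new, E_new = _em_update(rot, G, E, Vinv, Py, W)
            em_iters += 1
        else:
            delta, AI = _ai_update(rot, G, E, Vinv, Py, W, Minv)
            if delta is None:
                G_new, E_new = _em_update(rot, G, E, Vinv, Py, W)
            else:
                # step-halving: accept the first proposal not worse than now
                step = 1.0
                G_new = E_new = None
                for _ in range(12):
                    cand = theta_old + step * delta
                    Gc, Ec = _unpack(cand, pairs, t)
                    Gc, Ec = _floor_psd(Gc), _floor_psd(Ec)
                    try:
                        ll = rot.evaluate(Gc, Ec)[3]
                    except np.linalg.LinAlgError:
                        ll = -np.inf
                    if ll >= loglik - 1e-8 * max(1.0, abs(loglik)):
                        G_new, E_new = Gc, Ec
                        break
                    step *= 0.5
                if G_new is None:
                    G_new, E_new = _em_update(rot, G, E, Vinv, Py, W)
        theta_new = _pack(G_new, E_new, pairs)
        denom = np.maximum(np.abs(theta_old), 1e-8 * max(1.0, np.abs(theta_old).max()))
        change = np.max(np.abs(theta_new - theta_old) / denom)
        G, E = G_new, E_new
        if change < tol and (method == "em" or not use_em):
            converged = True
            break
    # final likelihood and, for AI, standard errors
    Vinv, Py, W, loglik, Minv = rot.evaluate(G, E)
    trace.append(loglik)
    se_G = se_E = None
    if method in ("ai", "em-then-ai"):
        _, AI = _ai_update(rot, G, E, Vinv, Py, W, Minv)
        try:
            C = np.linalg.inv(AI)
            ses = np.sqrt(np.clip(np.diag(C), 0.0, None))
            m = len(pairs)
            se_G = np.zeros((t, t))
            se_E = np.zeros((t, t))
            for idx, (i, j) in enumerate(pairs):
                se_G[i, j] = se_G[j, i] = ses[idx]
                se_E[i, j] = se_E[j, i] = ses[m + idx]
        except np.linalg.LinAlgError:
            pass
    cov = TraitCovariances(G=G, E=E, labels=init.labels, se_G=se_G, se_E=se_E)
    return RemlFit(
        covariances=cov,
        loglik_trace=trace,
        converged=converged,
        iterations=it,
        method=method,
        em_iterations=em_iters,
    )


def reml_fit(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    traits: list[str],
    init: TraitCovariances | None = None,
    fixed: str | None = "hys",
    method: str = "em-then-ai",
    tol: float = 1e-6,
    max_iter: int = 200,
    n_em: int = 10,
) -> RemlFit:
    """REML from a long-format phenotype table (animal, trait, value[, hys]).

    Animals missing any of the requested traits are dropped (complete-case
    analysis).  ``fixed`` names a column used as a one-hot fixed effect
    besides the overall mean; pass None for a mean-only model.
    """
    wide = phenotypes.pivot_table(index="animal", columns="trait", values="value")
    missing = [t for t in traits if t not in wide.columns]
    if missing:
        raise ValueError(f"traits absent from the data: {missing}")
    wide = wide[traits].dropna()
    animals = wide.index.to_numpy()
    if len(animals) == 0:
        raise ValueError("no complete-case records for the requested traits")
    Y = wide.to_numpy()
    if fixed is not None:
        lvl = (
            phenotypes.drop_duplicates("animal").set_index("animal")[fixed].loc[animals]
        )
        X = pd.get_dummies(lvl).to_numpy(dtype=float)
    else:
        X = np.ones((len(animals), 1))
    A = relationship_submatrix(ped, animals)
    if init is None:
        pvar = np.cov(Y.T).reshape(len(traits), len(traits))
        init = TraitCovariances(G=0.5 * pvar, E=0.5 * pvar, labels=tuple(traits))
    return reml_fit_arrays(Y, X, A, init, method=method, tol=tol, max_iter=max_iter, n_em=n_em)
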