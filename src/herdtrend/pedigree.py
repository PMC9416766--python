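"""Pedigree algebra for the animal model.

Provides the numerator-relationship machinery every pedigree-based evaluation
needs: inbreeding coefficients, the dense tabular relationship matrix A (as a
small-scale oracle), its sparse inverse by Henderson's rules with Mendelian
sampling variances adjusted for parental inbreeding, and unknown-parent
(genetic) group assignment in the Westell/Quaas-Pollak phantom-parent style.

A pedigree is stored in topological order (parents before offspring); loading
from a data frame or CSV re-sorts and validates acyclicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "Pedigree",
    "PedigreeError",
    "compute_inbreeding",
    "tabular_A",
    "a_inverse",
    "assign_groups",
    "relationship_submatrix",
]

UNKNOWN = -1  # internal index for a missing parent

DENSE_LIMIT = 2000


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, sex conflicts...)."""


@dataclass
class Pedigree:
    """Pedigree in topological order.

    Attributes
    ----------
    ids : array of animal identifiers (any hashable scalar type)
    sire, dam : integer positions into ``ids``, ``UNKNOWN`` (-1) if missing
    sex : array of "M"/"F"
    birth_date : array of ``numpy.datetime64`` (NaT allowed)
    herd : array of herd identifiers (may be empty strings for bulls)
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    birth_date: np.ndarray = field(default=None)  # type: ignore[assignment]
    herd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.birth_date is None:
            self.birth_date = np.full(n, np.datetime64("NaT"), dtype="datetime64[D]")
        if self.herd is None:
            self.herd = np.full(n, "", dtype=object)
        if len(set(map(str, self.ids))) != n:
            raise PedigreeError("duplicate animal ids")
        for p, label in ((self.sire, "sire"), (self.dam, "dam")):
            if np.any(p >= np.arange(n)):
                raise PedigreeError(f"{label} listed after offspring: pedigree not topological")
        bad_sire = [i for i in range(n) if self.sire[i] >= 0 and self.sex[self.sire[i]] != "M"]
        bad_dam = [i for i in range(n) if self.dam[i] >= 0 and self.sex[self.dam[i]] != "F"]
        if bad_sire or bad_dam:
            raise PedigreeError("sires must be male and dams female")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def position(self, ids) -> np.ndarray:
        """Positions of the given animal ids (raises on unknown id)."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in np.atleast_1d(ids)], dtype=int)
        except KeyError as exc:
            raise PedigreeError(f"unknown animal id {exc.args[0]!r}") from None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a frame with columns id, sire, dam, sex[, birth_date, herd].

        Missing parents are NaN/None/0/"" . Rows are re-sorted topologically;
        a cycle raises :class:`PedigreeError`.
        """
        df = df.copy()

        def norm(v):
            if pd.isna(v) or v in (0, "0", ""):
                return None
            return v

        ids = list(df["id"])
        parents = {a: (norm(s), norm(d)) for a, s, d in zip(ids, df["sire"], df["dam"])}
        known = set(ids)
        for a, (s, d) in parents.items():
            for p in (s, d):
                if p is not None and p not in known:
                    raise PedigreeError(f"parent {p!r} of {a!r} not in pedigree")
        order: list = []
        state: dict = {}

        def visit(a):
            # iterative DFS; recursion would overflow on deep pedigrees
            stack = [(a, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    raise PedigreeError(f"pedigree cycle involving {node!r}")
                if state.get(node) == 2:
                    continue
                state[node] = 1
                stack.append((node, True))
                for p in parents[node]:
                    if p is not None and state.get(p) != 2:
                        if state.get(p) == 1:
                            raise PedigreeError(f"pedigree cycle involving {p!r}")
                        stack.append((p, False))

        for a in ids:
            if state.get(a) != 2:
                visit(a)
        pos = {a: i for i, a in enumerate(order)}
        df = df.set_index("id").loc[order]
        sire = np.array([pos[p] if (p := norm(s)) is not None else UNKNOWN for s in df["sire"]])
        dam = np.array([pos[p] if (p := norm(d)) is not None else UNKNOWN for d in df["dam"]])
        bd = (
            pd.to_datetime(df["birth_date"]).to_numpy().astype("datetime64[D]")
            if "birth_date" in df
            else None
        )
        herd = df["herd"].to_numpy(dtype=object) if "herd" in df else None
        return cls(
            ids=np.asarray(order, dtype=object),
            sire=sire,
            dam=dam,
            sex=df["sex"].to_numpy(dtype=object),
            birth_date=bd,
            herd=herd,
        )

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        def name(p):
            return self.ids[p] if p >= 0 else ""

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": [name(p) for p in self.sire],
                "dam": [name(p) for p in self.dam],
                "sex": self.sex,
                "birth_date": pd.to_datetime(self.birth_date),
                "herd": self.herd,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo (1992) algorithm.

    Founders get F = 0.  Runs in O(n * pedigree depth) without forming A.
    """
    n = len(ped)
    f = np.zeros(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s == UNKNOWN and d == UNKNOWN:
            continue
        # accumulate row i of L (A = L D L') over ancestors, newest first;
        # parents precede offspring, so popping max index is topological
        pending = {i: 1.0}
        a_ii = 0.0
        while pending:
            j = max(pending)
            lj = pending.pop(j)
            js, jd = ped.sire[j], ped.dam[j]
            for p in (js, jd):
                if p != UNKNOWN:
                    pending[p] = pending.get(p, 0.0) + 0.5 * lj
            if js != UNKNOWN and jd != UNKNOWN:
                dj = 0.5 - 0.25 * (f[js] + f[jd])
            elif js != UNKNOWN or jd != UNKNOWN:
                dj = 0.75 - 0.25 * (f[js] if js != UNKNOWN else f[jd])
            else:
                dj = 1.0
            a_ii += lj * lj * dj
        f[i] = a_ii - 1.0
    return np.clip(f, 0.0, None)


def mendelian_variance(ped: Pedigree, inbreeding: np.ndarray | None = None) -> np.ndarray:
    """Per-animal Mendelian-sampling variance d_i (in units of the genetic variance)."""
    if inbreeding is None:
        inbreeding = compute_inbreeding(ped)
    n = len(ped)
    d = np.empty(n)
    for i in range(n):
        s, dd = ped.sire[i], ped.dam[i]
        fs = inbreeding[s] if s != UNKNOWN else None
        fd = inbreeding[dd] if dd != UNKNOWN else None
        if fs is not None and fd is not None:
            d[i] = 0.5 - 0.25 * (fs + fd)
        elif fs is not None:
            d[i] = 0.75 - 0.25 * fs
        elif fd is not None:
            d[i] = 0.75 - 0.25 * fd
        else:
            d[i] = 1.0
    return d


def tabular_A(ped: Pedigree, dense_limit: int = DENSE_LIMIT) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Intended as an exact oracle at small scale; refuses pedigrees larger than
    ``dense_limit`` animals (use the sparse paths instead).
    """
    n = len(ped)
    if n > dense_limit:
        raise PedigreeError(
            f"tabular A requested for {n} animals exceeds the dense limit "
            f"({dense_limit}); use a_inverse/relationship_submatrix instead"
        )
    a = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        asd = a[s, d] if (s != UNKNOWN and d != UNKNOWN) else 0.0
        a[i, i] = 1.0 + 0.5 * asd
        if i:
            row = np.zeros(i)
            if s != UNKNOWN:
                row += 0.5 * a[s, :i]
            if d != UNKNOWN:
                row += 0.5 * a[d, :i]
            a[i, :i] = row
            a[:i, i] = row
    return a


def a_inverse(
    ped: Pedigree,
    inbreeding: np.ndarray | None = None,
    groups: "GroupMap | None" = None,
) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    Each animal contributes alpha_i = 1/d_i to a 3x3 block over (self, sire,
    dam), with d_i the Mendelian-sampling variance adjusted for parental
    inbreeding.  When ``groups`` is given, unknown-parent slots are replaced
    by phantom-parent group columns (Westell/Quaas-Pollak); the returned
    matrix is then (n_animals + n_groups) square with group columns appended
    after the animals, and d_i is unchanged by the substitution (groups are
    population means, not individuals).
    """
    n = len(ped)
    d = mendelian_variance(ped, inbreeding)
    ngrp = len(groups.labels) if groups is not None else 0
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def parent_col(i: int, which: str) -> int | None:
        p = ped.sire[i] if which == "sire" else ped.dam[i]
        if p != UNKNOWN:
            return int(p)
        if groups is not None:
            g = groups.slot_group.get((ped.ids[i], which))
            if g is not None:
                return n + groups.labels.index(g)
        return None

    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [c for c in (parent_col(i, "sire"), parent_col(i, "dam")) if c is not None]
        rows.append(i)
        cols.append(i)
        vals.append(alpha)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * alpha, -0.5 * alpha]
        for p in parents:
            for q in parents:
                rows.append(p)
                cols.append(q)
                vals.append(0.25 * alpha)
    m = n + ngrp
    return sp.csr_matrix(sp.coo_matrix((vals, (rows, cols)), shape=(m, m)))


@dataclass
class GroupMap:
    """Assignment of unknown-parent slots to genetic groups.

    ``slot_group`` maps (animal id, "sire"|"dam") -> group label; ``labels``
    fixes the group column order.
    """

    slot_group: dict
    labels: list

    def __len__(self) -> int:
        return len(self.labels)


def assign_groups(ped: Pedigree, rule: str = "by_sex", custom=None) -> GroupMap:
    """Map every unknown-parent slot to a genetic group.

    Rules
    -----
    ``by_sex``
        Two groups at most: one absorbs all unknown *sires*, one all unknown
        *dams* (i.e., grouped by the sex of the missing parent).
    ``by_sex_and_birth_year``
        One group per (missing-parent sex, offspring birth year).
    ``custom``
        ``custom(animal_id, slot, pedigree) -> label``.
    """
    if rule not in ("by_sex", "by_sex_and_birth_year", "custom"):
        raise ValueError(f"unknown grouping rule {rule!r}")
    if rule == "custom" and custom is None:
        raise ValueError("rule 'custom' requires a callable")
    slot_group: dict = {}
    for i in range(len(ped)):
        for which, p in (("sire", ped.sire[i]), ("dam", ped.dam[i])):
            if p != UNKNOWN:
                continue
            aid = ped.ids[i]
            if rule == "by_sex":
                label = f"unknown_{which}"
            elif rule == "by_sex_and_birth_year":
                year = pd.Timestamp(ped.birth_date[i]).year if not pd.isna(ped.birth_date[i]) else "na"
                label = f"unknown_{which}_{year}"
            else:
                label = custom(aid, which, ped)
            slot_group[(aid, which)] = label
    labels = sorted(set(slot_group.values()))
    return GroupMap(slot_group=slot_group, labels=labels)


def relationship_submatrix(ped: Pedigree, ids) -> np.ndarray:
    """Dense relationship matrix among a subset of animals, via sparse A-inverse.

    Solves A^{-1} X = E_subset with a sparse LU factorization, so it scales to
    pedigrees far beyond the dense tabular limit while returning only the
    block that downstream dense methods (REML rotation, GWAS checks) need.
    """
    idx = ped.position(ids)
    ainv = sp.csc_matrix(a_inverse(ped))
    lu = spla.splu(ainv)
    rhs = np.zeros((len(ped), len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)
    sub = cols[idx, :]
    return 0.5 * (sub + sub.T)


def write_a_inverse(path, ainv: sp.spmatrix) -> None:
    """Write a sparse symmetric matrix in (row, col, value) coordinate text."""
    coo = sp.coo_matrix(ainv)
    pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(path, index=False)
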