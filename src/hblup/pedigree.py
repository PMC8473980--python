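"""Pedigree handling and pedigree-based relationship matrices.

Provides parsing/validation of multi-program pedigrees, inbreeding by the
Meuwissen & Luo traversal, the tabular numerator relationship matrix A, its
sparse inverse by Henderson's rules (with inbreeding), the partition of A
into genotyped/ungenotyped blocks, and expected founder-race fractions used
as fixed genetic-group covariates.

Individuals are namespaced as ``"<program>:<raw id>"`` so that two breeding
programs with clashing raw ids can be merged into one pedigree.  Founders
shared between programs can be collapsed through an alias table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

#: sentinel for an unknown parent after normalisation
UNKNOWN = "<UNKNOWN>"
#: race label assigned to founders without one
UNKNOWN_RACE = "UNKNOWN_RACE"

_UNKNOWN_TOKENS = {"", "0", "NA", "NAN", "NONE", ".", UNKNOWN}


def _is_unknown(token) -> bool:
    if token is None:
        return True
    if isinstance(token, float) and np.isnan(token):
        return True
    return str(token).strip().upper() in _UNKNOWN_TOKENS


@dataclass
class Pedigree:
    """Validated pedigree with parents preceding offspring.

    Attributes
    ----------
    ids
        Individual ids, in topological (parents-first) order once
        :func:`topo_sort_validate` has run.
    sire, dam
        Integer indices into ``ids`` (-1 for unknown).
    race
        Founder race/landrace label, or ``None`` for non-founders.
    program
        Breeding-program label per individual.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    race: list[str | None]
    program: list[str]
    sorted: bool = False
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=int)
        self.dam = np.asarray(self.dam, dtype=int)
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            seen: set[str] = set()
            for iid in self.ids:
                if iid in seen:
                    raise ValueError(f"duplicate id in pedigree: {iid!r}")
                seen.add(iid)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def is_founder(self, k: int) -> bool:
        return self.sire[k] < 0 and self.dam[k] < 0

    @property
    def founder_mask(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        k = self._index[iid]
        s, d = self.sire[k], self.dam[k]
        return (self.ids[s] if s >= 0 else None, self.ids[d] if d >= 0 else None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "sire": [self.ids[s] if s >= 0 else UNKNOWN for s in self.sire],
            "dam": [self.ids[d] if d >= 0 else UNKNOWN for d in self.dam],
            "race": self.race,
            "program": self.program,
        })

    def copy(self) -> "Pedigree":
        return Pedigree(list(self.ids), self.sire.copy(), self.dam.copy(),
                        list(self.race), list(self.program), self.sorted)


def _from_triples(rows: list[tuple[str, str | None, str | None, str | None]],
                  program: list[str]) -> Pedigree:
    """Build a Pedigree from (id, sire-or-None, dam-or-None, race) rows.

    Parents that never appear as a record are auto-inserted as founders with
    race ``UNKNOWN_RACE`` (with a warning).
    """
    ids = [r[0] for r in rows]
    known = set(ids)
    if len(known) != len(ids):
        seen: set[str] = set()
        for iid in ids:
            if iid in seen:
                raise ValueError(f"duplicate id in pedigree: {iid!r}")
            seen.add(iid)
    extra: list[str] = []
    extra_prog: list[str] = []
    for (iid, s, d, _), prog in zip(rows, program):
        for par in (s, d):
            if par is not None and par not in known:
                known.add(par)
                extra.append(par)
                extra_prog.append(prog)
    if extra:
        warnings.warn(
            f"{len(extra)} parents referenced but never defined; inserted as "
            f"founders with race {UNKNOWN_RACE!r} (first: {extra[0]!r})"
        )
    all_ids = extra + ids
    all_prog = extra_prog + list(program)
    index = {iid: k for k, iid in enumerate(all_ids)}
    n = len(all_ids)
    sire = np.full(n, -1, dtype=int)
    dam = np.full(n, -1, dtype=int)
    race: list[str | None] = [UNKNOWN_RACE] * len(extra) + [None] * len(ids)
    for off, (iid, s, d, r) in enumerate(rows, start=len(extra)):
        sire[off] = index[s] if s is not None else -1
        dam[off] = index[d] if d is not None else -1
        race[off] = r
    return Pedigree(all_ids, sire, dam, race, all_prog)


def read_pedigree(path, program: str, races: list[str] | None = None,
                  alias: pd.DataFrame | None = None) -> Pedigree:
    """Read a pedigree CSV (columns ``id,sire,dam,race``) for one program.

    Ids are namespaced as ``"<program>:<id>"``; unknown parents (0, empty,
    NA) are normalised to a single sentinel.  ``races``, when given, is the
    allowed race vocabulary.  ``alias`` optionally maps raw ids of this
    program to canonical (already namespaced) ids of founders shared across
    programs.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise ValueError(f"pedigree file must have columns {sorted(required)}")
    if "race" not in df.columns:
        df["race"] = None

    alias_map: dict[str, str] = {}
    if alias is not None:
        col = f"raw_id_{program}"
        if col not in alias.columns or "canonical_id" not in alias.columns:
            raise ValueError(
                "alias table needs columns canonical_id and raw_id_<program>")
        for _, arow in alias.iterrows():
            raw = arow[col]
            if not _is_unknown(raw):
                alias_map[str(raw)] = str(arow["canonical_id"])

    def ns(tok) -> str | None:
        if _is_unknown(tok):
            return None
        tok = str(tok).strip()
        if tok in alias_map:
            return alias_map[tok]
        if ":" in tok:        # already canonical ("PROG:id" or "SHARED:id")
            return tok
        return f"{program}:{tok}"

    rows: list[tuple[str, str | None, str | None, str | None]] = []
    for _, r in df.iterrows():
        iid = ns(r["id"])
        if iid is None:
            raise ValueError("pedigree contains a row with an unknown id")
        race = None if _is_unknown(r["race"]) else str(r["race"]).strip()
        if race is not None and races is not None and race not in races:
            raise ValueError(f"race {race!r} not in declared vocabulary")
        rows.append((iid, ns(r["sire"]), ns(r["dam"]), race))
    ped = _from_triples(rows, [program] * len(rows))
    return topo_sort_validate(ped)


def merge_pedigrees(*peds: Pedigree) -> Pedigree:
    """Merge program pedigrees into one, collapsing shared (aliased) ids."""
    rows: list[tuple[str, str | None, str | None, str | None]] = []
    progs: list[str] = []
    seen: dict[str, int] = {}
    for ped in peds:
        for k, iid in enumerate(ped.ids):
            s, d = ped.parents_of(iid)
            if iid in seen:
                # shared founder: keep the first definition, require founder
                if not ped.is_founder(k):
                    raise ValueError(
                        f"shared id {iid!r} is a non-founder in one program")
                continue
            seen[iid] = len(rows)
            rows.append((iid, s, d, ped.race[k]))
            progs.append(ped.program[k])
    return topo_sort_validate(_from_triples(rows, progs))


def topo_sort_validate(p: Pedigree) -> Pedigree:
    """Return the pedigree reordered so every parent precedes its offspring.

    Idempotent.  Raises ``ValueError`` listing one cycle if the pedigree is
    not acyclic.
    """
    n = p.n
    n_children = np.zeros(n, dtype=int)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for k in range(n):
        for par in (p.sire[k], p.dam[k]):
            if par >= 0:
                children[par].append(k)
                indeg[k] += 1
    del n_children
    order: list[int] = []
    stack = sorted(np.flatnonzero(indeg == 0), reverse=True)
    indeg = indeg.copy()
    while stack:
        k = stack.pop()
        order.append(k)
        for c in children[k]:
            indeg[c] -= 1
            if indeg[c] == 0:
                stack.append(c)
    if len(order) < n:
        cyc = _find_cycle(p, set(range(n)) - set(order))
        raise ValueError(f"pedigree contains an ancestry cycle: {' -> '.join(cyc)}")
    perm = np.array(order, dtype=int)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    new_ids = [p.ids[k] for k in perm]
    remap = lambda a: np.where(a[perm] >= 0, inv[np.maximum(a[perm], 0)], -1)
    return Pedigree(new_ids, remap(p.sire), remap(p.dam),
                    [p.race[k] for k in perm], [p.program[k] for k in perm],
                    sorted=True)


def _find_cycle(p: Pedigree, candidates: set[int]) -> list[str]:
    start = min(candidates)
    path, seen = [start], {start}
    k = start
    while True:
        nxt = p.sire[k] if p.sire[k] in candidates else p.dam[k]
        if nxt in seen:
            i = path.index(nxt)
            return [p.ids[j] for j in path[i:]] + [p.ids[nxt]]
        path.append(nxt)
        seen.add(nxt)
        k = nxt


def inbreeding_meuwissen_luo(p: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo ancestor traversal.

    For each individual the algorithm walks its ancestor list in decreasing
    topological index, accumulating the path coefficients L and the
    within-family (Mendelian sampling) variances D; ``F_i = Σ L_j² D_j − 1``.
    Unknown parents contribute as unrelated, non-inbred.
    """
    if not p.sorted:
        p = topo_sort_validate(p)
    n = p.n
    F = np.zeros(n)
    # F of an unknown parent enters the D rule as -1 (so founders get D=1)
    def f_of(par: int) -> float:
        return F[par] if par >= 0 else -1.0

    for i in range(n):
        s, d = p.sire[i], p.dam[i]
        if s < 0 and d < 0:
            F[i] = 0.0
            continue
        L: dict[int, float] = {i: 1.0}
        total = 0.0
        for j in range(i, -1, -1):
            lj = L.get(j)
            if lj is None:
                continue
            dj = 0.5 - 0.25 * (f_of(p.sire[j]) + f_of(p.dam[j]))
            total += lj * lj * dj
            half = 0.5 * lj
            if p.sire[j] >= 0:
                L[p.sire[j]] = L.get(p.sire[j], 0.0) + half
            if p.dam[j] >= 0:
                L[p.dam[j]] = L.get(p.dam[j], 0.0) + half
        F[i] = total - 1.0
    return F


def build_A_tabular(p: Pedigree, subset: list[str] | None = None) -> RelationshipMatrix:
    """Numerator relationship matrix A by the tabular method.

    ``a_ii = 1 + F_i`` and ``a_ij = ½(a_j,sire(i) + a_j,dam(i))``, with an
    unknown parent contributing zero.  When ``subset`` is given the full
    recursion is run and rows/columns are then selected.
    """
    if not p.sorted:
        p = topo_sort_validate(p)
    n = p.n
    A = np.zeros((n, n))
    for i in range(n):
        s, d = p.sire[i], p.dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += A[:i, s]
            if d >= 0:
                row += A[:i, d]
            row *= 0.5
            A[:i, i] = row
            A[i, :i] = row
        self_rel = 1.0
        if s >= 0 and d >= 0:
            self_rel += 0.5 * A[s, d]
        A[i, i] = self_rel
    mat = RelationshipMatrix(list(p.ids), A, "A")
    if subset is not None:
        missing = [i for i in subset if i not in p._index]
        if missing:
            raise ValueError(f"subset ids not in pedigree: {missing[:5]}")
        mat = mat.subset(list(subset), "A")
    return mat


def build_A_inverse(p: Pedigree) -> tuple[sp.csr_matrix, list[str]]:
    """Sparse A⁻¹ by Henderson's rules with inbreeding.

    The Mendelian-sampling variance of individual *i* is
    ``d_i = 0.5 − 0.25(F_s + F_d)`` with both parents known,
    ``0.75 − 0.25 F_par`` with one, and 1 with none.  Returns the CSR matrix
    in the pedigree's (sorted) id order together with that order.
    """
    if not p.sorted:
        p = topo_sort_validate(p)
    F = inbreeding_meuwissen_luo(p)
    n = p.n
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = p.sire[i], p.dam[i]
        if s >= 0 and d >= 0:
            di = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            di = 0.75 - 0.25 * F[max(s, d)]
        else:
            di = 1.0
        b = 1.0 / di
        add(i, i, b)
        for par in (s, d):
            if par >= 0:
                add(i, par, -0.5 * b)
                add(par, i, -0.5 * b)
        for p1 in (s, d):
            for p2 in (s, d):
                if p1 >= 0 and p2 >= 0:
                    add(p1, p2, 0.25 * b)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return Ainv, list(p.ids)


def partition_A(A: RelationshipMatrix, genotyped: list[str]) -> dict[str, RelationshipMatrix]:
    """Partition A into blocks by genotyping status.

    Returns ``{"A11", "A12", "A21", "A22"}`` where block 2 indexes the
    genotyped individuals (in the order given) and block 1 the rest (in A's
    order).  ``A21`` is the transpose of ``A12``.
    """
    if len(genotyped) == 0:
        raise ValueError("empty genotyped list: H is undefined without genotypes")
    gset = set(genotyped)
    missing = [g for g in genotyped if g not in A._index]
    if missing:
        raise ValueError(f"genotyped ids not in A: {missing[:5]}")
    non = [i for i in A.ids if i not in gset]
    i1 = A.indices_of(non) if non else np.array([], dtype=int)
    i2 = A.indices_of(list(genotyped))
    V = A.values
    A11 = RelationshipMatrix(non, V[np.ix_(i1, i1)], "A11")
    A22 = RelationshipMatrix(list(genotyped), V[np.ix_(i2, i2)], "A22")
    # A12 is rectangular (rows: ungenotyped, cols: genotyped)
    A12 = RelationshipMatrix.__new__(RelationshipMatrix)
    A12.ids = non
    A12.values = V[np.ix_(i1, i2)]
    A12.role = "A12"
    A12._index = {iid: k for k, iid in enumerate(non)}
    return {"A11": A11, "A12": A12, "A21": A12.values.T, "A22": A22}


@dataclass
class GroupFractionMatrix:
    """Expected founder-race proportions per individual.

    Rows sum to one; a founder's row is the indicator of its race, a
    non-founder's row is the mean of its parents' rows (an unknown parent
    counts as the ``UNKNOWN_RACE`` group).
    """

    ids: list[str]
    groups: list[str]
    values: np.ndarray

    def row(self, iid: str) -> np.ndarray:
        return self.values[self.ids.index(iid)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.groups)


def group_fraction_matrix(p: Pedigree) -> GroupFractionMatrix:
    """Race genetic-group fractions for every individual in the pedigree."""
    if not p.sorted:
        p = topo_sort_validate(p)
    groups: list[str] = []
    for k in range(p.n):
        if p.is_founder(k):
            r = p.race[k]
            if r is None:
                warnings.warn(
                    f"founder {p.ids[k]!r} has no race; assigned {UNKNOWN_RACE!r}")
                r = UNKNOWN_RACE
            if r not in groups:
                groups.append(r)
    if (UNKNOWN_RACE not in groups) and np.any(
            (~p.founder_mask) & ((p.sire < 0) | (p.dam < 0))):
        groups.append(UNKNOWN_RACE)
    gidx = {g: k for k, g in enumerate(groups)}
    n, ng = p.n, len(groups)
    Q = np.zeros((n, ng))
    unk_row = np.zeros(ng)
    if UNKNOWN_RACE in gidx:
        unk_row[gidx[UNKNOWN_RACE]] = 1.0
    for k in range(n):
        if p.is_founder(k):
            r = p.race[k] or UNKNOWN_RACE
            Q[k, gidx[r]] = 1.0
        else:
            rs = Q[p.sire[k]] if p.sire[k] >= 0 else unk_row
            rd = Q[p.dam[k]] if p.dam[k] >= 0 else unk_row
            Q[k] = 0.5 * (rs + rd)
    return GroupFractionMatrix(list(p.ids), groups, Q)
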