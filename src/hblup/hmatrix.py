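"""Assembly of the single-step relationship matrix H and its inverse.

H merges the genomic matrix of the genotyped subset into the pedigree matrix
of the whole population: the genotyped block is replaced by the blended
genomic matrix Gw and relationships involving ungenotyped individuals are
updated through the pedigree projection ``A12 A22⁻¹``.  The inverse has the
sparse form ``H⁻¹ = A⁻¹ + [0 0; 0 Gw⁻¹ − A22⁻¹]``, which is what mixed-model
software consumes.

This module also hosts the pedigree-vs-genotype conflict screen (realized G
coefficients that diverge excessively from pedigree expectations flag
identity or parentage errors) and the founder-relationship summaries by
race used to expose cryptic population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
from scipy import stats

from .pedigree import Pedigree, UNKNOWN_RACE, partition_A
from .relmat import RelationshipMatrix


def _a22_solve(A22: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        c = la.cho_factor(A22)
    except la.LinAlgError as exc:
        raise ValueError(
            "A22 is singular; check the pedigree of genotyped individuals"
        ) from exc
    return la.cho_solve(c, B)


def build_H(A: RelationshipMatrix, Gw: RelationshipMatrix,
            genotyped: list[str], form: str = "corrected") -> RelationshipMatrix:
    """Assemble H from A and the blended genomic matrix Gw.

    ``form="corrected"`` uses the additive-correction layout
    ``H11 = A11 + A12 A22⁻¹ (Gw − A22) A22⁻¹ A21``;
    ``form="direct"`` the equivalent direct layout
    ``H11 = A11 − A12 A22⁻¹ A21 + A12 A22⁻¹ Gw A22⁻¹ A21``.
    Both give the same matrix, re-sorted to A's id order.
    """
    if list(Gw.ids) != list(genotyped):
        raise ValueError("Gw must be indexed by the genotyped list, same order")
    missing = [g for g in genotyped if g not in A._index]
    if missing:
        raise ValueError(f"genotyped ids not in A: {missing[:5]}")
    blocks = partition_A(A, genotyped)
    A11, A12, A22 = blocks["A11"].values, blocks["A12"].values, blocks["A22"].values
    non = blocks["A11"].ids
    # P = A22⁻¹ A21 (projection of genotyped info onto ungenotyped ids)
    P = _a22_solve(A22, A12.T)
    GwV = Gw.values
    if form == "corrected":
        H11 = A11 + P.T @ (GwV - A22) @ P
    elif form == "direct":
        H11 = A11 - A12 @ P + P.T @ GwV @ P
    else:
        raise ValueError(f"unknown form {form!r}")
    H12 = (GwV @ P).T
    n1, n2 = len(non), len(genotyped)
    H = np.empty((n1 + n2, n1 + n2))
    H[:n1, :n1] = H11
    H[:n1, n1:] = H12
    H[n1:, :n1] = H12.T
    H[n1:, n1:] = GwV
    order = non + list(genotyped)
    mat = RelationshipMatrix(order, 0.5 * (H + H.T), "H")
    return mat.subset(list(A.ids), "H")


def build_H_inverse(Ainv: sp.spmatrix, Gw: RelationshipMatrix,
                    A22: RelationshipMatrix, genotyped: list[str],
                    ids: list[str]) -> sp.csr_matrix:
    """Sparse H⁻¹: A⁻¹ plus the genotyped-block correction Gw⁻¹ − A22⁻¹.

    ``ids`` is the id order of ``Ainv`` (the full pedigree).  The returned
    matrix is in the same order.
    """
    if list(Gw.ids) != list(genotyped) or list(A22.ids) != list(genotyped):
        raise ValueError("Gw and A22 must be indexed by the genotyped list")
    index = {iid: k for k, iid in enumerate(ids)}
    gi = np.array([index[g] for g in genotyped], dtype=int)
    try:
        cg = la.cho_factor(Gw.values)
    except la.LinAlgError as exc:
        raise ValueError(
            "Gw numerically singular after blending; increase the A22 blend "
            "weight") from exc
    Gwinv = la.cho_solve(cg, np.eye(len(genotyped)))
    A22inv = _a22_solve(A22.values, np.eye(len(genotyped)))
    corr = 0.5 * ((Gwinv - A22inv) + (Gwinv - A22inv).T)
    n = len(ids)
    rows = np.repeat(gi, len(gi))
    cols = np.tile(gi, len(gi))
    C = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    return (Ainv.tocsr() + C.tocsr()).tocsr()


@dataclass
class ConflictReport:
    """Pairs whose realized genomic relationship contradicts the pedigree."""

    pairs: pd.DataFrame  # id1, id2, expected, realized, deviation, relation_class
    threshold: float

    @property
    def n_conflicts(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def _relation_class(p: Pedigree, i: str, j: str, a: float) -> str:
    if i == j:
        return "self"
    si, di = p.parents_of(i)
    sj, dj = p.parents_of(j)
    if j in (si, di) or i in (sj, dj):
        return "parent-offspring"
    if a >= 0.25:
        return "sib"
    return "unrelated"


def detect_pedigree_conflicts(G: RelationshipMatrix, A22: RelationshipMatrix,
                              p: Pedigree, dev_threshold: float = 0.35
                              ) -> ConflictReport:
    """Flag genotyped pairs where raw G and pedigree A22 disagree strongly.

    Works on the raw (untuned) G so parent–offspring logic stays on the
    identity-by-state scale: a documented parent–offspring pair with G near
    zero, or a pedigree-unrelated pair with G ≥ 0.5, indicates a recording
    error; a diagonal deviation indicates an identity/sample swap.
    """
    if G.ids != A22.ids:
        raise ValueError("G and A22 must share ids and order")
    D = G.values - A22.values
    records = []
    n = G.n
    for i in range(n):
        for j in range(i, n):
            dev = D[i, j]
            if abs(dev) >= dev_threshold:
                id1, id2 = G.ids[i], G.ids[j]
                records.append({
                    "id1": id1, "id2": id2,
                    "expected": A22.values[i, j],
                    "realized": G.values[i, j],
                    "deviation": dev,
                    "relation_class": _relation_class(p, id1, id2,
                                                      A22.values[i, j]),
                })
    df = pd.DataFrame(records, columns=["id1", "id2", "expected", "realized",
                                        "deviation", "relation_class"])
    if len(df):
        # parent-offspring breaks first, then by deviation size
        prio = df["relation_class"].map({"parent-offspring": 0, "self": 1,
                                         "unrelated": 2, "sib": 3})
        df = (df.assign(_p=prio)
                .sort_values(["_p", "deviation"], key=abs, ascending=[True, False])
                .drop(columns="_p").reset_index(drop=True))
    return ConflictReport(pairs=df, threshold=dev_threshold)


def apply_conflict_corrections(p: Pedigree, report: ConflictReport) -> Pedigree:
    """Drop parent links contradicted by genotypes (set parent UNKNOWN).

    Only parent–offspring conflicts with a realized coefficient well below
    expectation are acted on; the corrected pedigree is re-sorted so H can
    be rebuilt on it.
    """
    ped = p.copy()
    for _, row in report.pairs.iterrows():
        if row["relation_class"] != "parent-offspring":
            continue
        if row["realized"] > row["expected"]:
            continue
        for child, parent in ((row["id1"], row["id2"]), (row["id2"], row["id1"])):
            k = ped._index.get(child)
            if k is None:
                continue
            pk = ped._index.get(parent)
            if pk is None:
                continue
            if ped.sire[k] == pk:
                ped.sire[k] = -1
            if ped.dam[k] == pk:
                ped.dam[k] = -1
    ped.sorted = False
    from .pedigree import topo_sort_validate
    return topo_sort_validate(ped)


@dataclass
class RaceRelationshipSummary:
    """Founder relationship coefficients in H summarised by race.

    ``within`` has one row per race (one-sided one-sample t-test of the mean
    pairwise coefficient against zero); ``between`` one row per race pair
    (two-sided test).  Races with fewer than two founders are reported as
    untestable.
    """

    within: pd.DataFrame
    between: pd.DataFrame

    def to_tsv(self, within_path, between_path) -> None:
        self.within.to_csv(within_path, sep="\t", index=False)
        self.between.to_csv(between_path, sep="\t", index=False)


def _tstat(vals: np.ndarray, alternative: str) -> tuple[float, float]:
    if len(vals) < 2 or float(np.std(vals, ddof=1)) < 1e-12:
        return float("nan"), float("nan")
    t, pv = stats.ttest_1samp(vals, 0.0, alternative=alternative)
    return float(t), float(pv)


def summarize_founder_relationships(H: RelationshipMatrix, p: Pedigree
                                    ) -> RaceRelationshipSummary:
    """Mean/sd/min/max founder relationship coefficients per race and pair."""
    founders = [p.ids[k] for k in range(p.n) if p.is_founder(k)]
    race_of = {p.ids[k]: (p.race[k] or UNKNOWN_RACE)
               for k in range(p.n) if p.is_founder(k)}
    races = sorted({race_of[f] for f in founders})
    by_race = {r: [f for f in founders if race_of[f] == r] for r in races}
    idx = {r: H.indices_of(by_race[r]) for r in races}

    within_rows = []
    for r in races:
        ii = idx[r]
        if len(ii) < 2:
            within_rows.append({"race": r, "n_founders": len(ii), "n_pairs": 0,
                                "mean": float("nan"), "sd": float("nan"),
                                "min": float("nan"), "max": float("nan"),
                                "t": float("nan"), "p_value": float("nan"),
                                "test": "untestable"})
            continue
        sub = H.values[np.ix_(ii, ii)]
        iu = np.triu_indices(len(ii), k=1)
        vals = sub[iu]
        t, pv = _tstat(vals, "greater")
        within_rows.append({
            "race": r, "n_founders": len(ii), "n_pairs": len(vals),
            "mean": float(np.mean(vals)), "sd": float(np.std(vals, ddof=1)),
            "min": float(np.min(vals)), "max": float(np.max(vals)),
            "t": t, "p_value": pv,
            "test": "one-sided-greater" if np.isfinite(t) else "untestable",
        })

    between_rows = []
    for a in range(len(races)):
        for b in range(a + 1, len(races)):
            ra, rb = races[a], races[b]
            vals = H.values[np.ix_(idx[ra], idx[rb])].ravel()
            t, pv = _tstat(vals, "two-sided")
            between_rows.append({
                "race1": ra, "race2": rb, "n_pairs": len(vals),
                "mean": float(np.mean(vals)) if len(vals) else float("nan"),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
                "min": float(np.min(vals)) if len(vals) else float("nan"),
                "max": float(np.max(vals)) if len(vals) else float("nan"),
                "t": t, "p_value": pv,
                "test": "two-sided" if np.isfinite(t) else "untestable",
            })
    return RaceRelationshipSummary(within=pd.DataFrame(within_rows),
                                   between=pd.DataFrame(between_rows))
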