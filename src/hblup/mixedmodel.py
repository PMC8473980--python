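"""Linear mixed models with a pluggable numerator relationship matrix.

The model is the individual-tree LMM ``y = Xb + Zu + e`` where the additive
genetic term carries a pedigree (A), genomic, or single-step (H) covariance,
optionally with an unstructured covariance across regions (the
"region-as-trait" layout: each tree is recorded in one region and regions
are tied together through the relationship matrix).  Further random terms
(full-sib family, open-pollinated family means, incomplete blocks, row
plots) are i.i.d. within level with variances that may differ across
grouping factors such as trials.

Variance components are estimated by average-information REML on the dense
phenotypic covariance ``V = Σ_i θ_i V_i``; breeding values, prediction error
variances, and accuracies come from an exact solve/inverse of Henderson's
mixed-model equations with the NRM inverse (A⁻¹ or H⁻¹).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# model specification and design
# ---------------------------------------------------------------------------

@dataclass
class NRM:
    """Numerator relationship matrix in both direct and inverse form.

    ``K`` (dense) drives REML through the phenotypic covariance; ``K_inv``
    (sparse) drives the mixed-model equations for EBVs and PEV.  Either may
    be omitted if the corresponding computation is not requested.
    """

    ids: list[str]
    K: np.ndarray | None = None
    K_inv: sp.spmatrix | None = None
    label: str = "A"

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}


@dataclass
class ModelSpec:
    """Declarative description of one mixed-model fit."""

    response: str
    nrm: NRM
    fixed: tuple[str, ...] = ("mean", "replicate", "checklot")
    random: tuple[str, ...] = ("additive", "family", "iblock", "plot")
    region_structure: str = "none"          # "none" | "unstructured"
    race_fractions: bool = False            # append group-fraction covariates
    site_specific: tuple[str, ...] = ("iblock", "plot", "residual")
    family_group_of_trial: dict | None = None  # trial -> σ²_f group label


@dataclass
class IidTerm:
    name: str
    levels: list
    rec_level: np.ndarray          # per record, -1 = term absent for record
    level_group: np.ndarray        # per level -> variance-group index
    group_names: list[str]

    @property
    def n_levels(self) -> int:
        return len(self.levels)


@dataclass
class AdditiveTerm:
    nrm: NRM
    rec_ind: np.ndarray            # per record index into nrm.ids, -1 excluded
    rec_region: np.ndarray         # per record region index (0 when no regions)
    region_names: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass
class DesignSet:
    y: np.ndarray
    X: np.ndarray
    x_names: list[str]
    additive: AdditiveTerm | None
    iid_terms: list[IidTerm]
    resid_group: np.ndarray
    resid_group_names: list[str]
    record_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.y)


def _indicator_columns(values: pd.Series, prefix: str, drop_first: bool
                       ) -> tuple[np.ndarray, list[str]]:
    levels = sorted(values.dropna().unique().tolist())
    use = levels[1:] if drop_first else levels
    cols = np.zeros((len(values), len(use)))
    for k, lev in enumerate(use):
        cols[:, k] = (values == lev).to_numpy(dtype=float)
    return cols, [f"{prefix}={lev}" for lev in use]


def family_key(sire: str | None, dam: str | None) -> str | None:
    """Unordered parent-pair key for full-sib families, OP key otherwise."""
    if sire is not None and dam is not None:
        a, b = sorted((sire, dam))
        return f"fam:{a}|{b}"
    if sire is not None or dam is not None:
        return f"op:{sire or dam}"
    return None


def build_design(ph: pd.DataFrame, spec: ModelSpec, Q=None,
                 pedigree=None, drop_confounded: bool = False) -> DesignSet:
    """Assemble response, fixed-effect matrix, and random-term maps.

    ``ph`` needs columns ``tree_id, trial, region, replicate, iblock, plot,
    entry_type, checklot_id`` plus the response column.  Family keys are the
    unordered parent pairs from ``pedigree``; open-pollinated (single known
    parent) records go to a separate family-mean factor and are excluded
    from the additive term.  With ``spec.race_fractions`` the founder-race
    fraction matrix ``Q`` is appended to X (reference race dropped).
    """
    ph = ph.reset_index(drop=True)
    if len(ph) == 0:
        raise ValueError("phenotype table has no records")
    y = ph[spec.response].to_numpy(dtype=float)
    n = len(ph)
    is_check = (ph["entry_type"] == "checklot").to_numpy()

    blocks: list[np.ndarray] = []
    names: list[str] = []
    if "mean" in spec.fixed:
        blocks.append(np.ones((n, 1)))
        names.append("mean")
    if "trial" in spec.fixed:
        cols, nm = _indicator_columns(ph["trial"], "trial",
                                      drop_first="mean" in spec.fixed)
        blocks.append(cols)
        names.extend(nm)
    if "replicate" in spec.fixed:
        for trial, sub in ph.groupby("trial"):
            reps = sorted(sub["replicate"].unique().tolist())
            if len(reps) < 2:
                continue
            for rep in reps[1:]:
                col = np.zeros((n, 1))
                col[(ph["trial"] == trial) & (ph["replicate"] == rep), 0] = 1.0
                blocks.append(col)
                names.append(f"rep[{trial}]={rep}")
    if "checklot" in spec.fixed and is_check.any():
        lots = sorted(ph.loc[is_check, "checklot_id"].dropna().unique())
        for lot in lots:
            col = np.zeros((n, 1))
            col[(ph["checklot_id"] == lot).to_numpy() & is_check, 0] = 1.0
            blocks.append(col)
            names.append(f"checklot={lot}")
    if spec.race_fractions:
        if Q is None:
            raise ValueError("race_fractions requested but no group-fraction "
                             "matrix given")
        qdf = Q.to_frame()
        frac = np.zeros((n, qdf.shape[1]))
        for i, tid in enumerate(ph["tree_id"]):
            if not is_check[i] and tid in qdf.index:
                frac[i] = qdf.loc[tid].to_numpy()
        # drop the group with the largest share in these records as reference
        ref = int(np.argmax(frac.sum(axis=0)))
        for j, grp in enumerate(qdf.columns):
            if j == ref:
                continue
            blocks.append(frac[:, [j]])
            names.append(f"race_frac={grp}")
        logger.debug("race fractions appended, reference group %s",
                     qdf.columns[ref])
    X = np.hstack(blocks) if blocks else np.ones((n, 1))
    if drop_confounded:
        X, names = _drop_confounded(X, names)
    _check_full_rank(X, names)

    # -- region layout ----------------------------------------------------
    if spec.region_structure == "unstructured":
        region_names = sorted(ph["region"].unique().tolist())
    else:
        region_names = ["_all"]
    rmap = {r: k for k, r in enumerate(region_names)}
    rec_region = (ph["region"].map(rmap).to_numpy(dtype=int)
                  if spec.region_structure == "unstructured"
                  else np.zeros(n, dtype=int))

    # -- family keys from pedigree ----------------------------------------
    fam_keys: list[str | None] = [None] * n
    if pedigree is not None:
        for i, (tid, chk) in enumerate(zip(ph["tree_id"], is_check)):
            if chk or tid not in pedigree._index:
                continue
            s, d = pedigree.parents_of(tid)
            fam_keys[i] = family_key(s, d)

    additive = None
    if "additive" in spec.random:
        rec_ind = np.full(n, -1, dtype=int)
        for i, (tid, chk) in enumerate(zip(ph["tree_id"], is_check)):
            if chk:
                continue
            if fam_keys[i] is not None and fam_keys[i].startswith("op:"):
                continue  # OP records: family mean only, no additive link
            rec_ind[i] = spec.nrm._index.get(tid, -1)
        additive = AdditiveTerm(spec.nrm, rec_ind, rec_region, region_names)

    iid_terms: list[IidTerm] = []
    group_of = spec.family_group_of_trial or {}

    def add_iid(name: str, keys: list, groups: list) -> None:
        levels = sorted({k for k in keys if k is not None})
        lmap = {k: j for j, k in enumerate(levels)}
        rec_level = np.array([lmap.get(k, -1) for k in keys], dtype=int)
        gnames = sorted({g for k, g in zip(keys, groups) if k is not None})
        gmap = {g: j for j, g in enumerate(gnames)}
        level_group = np.zeros(len(levels), dtype=int)
        for k, g in zip(keys, groups):
            if k is not None:
                level_group[lmap[k]] = gmap[g]
        if levels:
            iid_terms.append(IidTerm(name, levels, rec_level, level_group,
                                     gnames))

    trials = ph["trial"].astype(str).tolist()
    if "family" in spec.random:
        keys, groups = [], []
        for i in range(n):
            fk = fam_keys[i]
            if fk is not None and fk.startswith("fam:"):
                grp = str(group_of.get(ph.at[i, "trial"], "all"))
                reg = region_names[rec_region[i]]
                keys.append((grp, reg, fk))
                groups.append(grp)
            else:
                keys.append(None)
                groups.append(None)
        add_iid("family", keys, groups)
    if "op_family" in spec.random or "family" in spec.random:
        keys = [fk if (fk is not None and fk.startswith("op:")) else None
                for fk in fam_keys]
        add_iid("op_family", keys, ["all"] * n)
    for name in ("iblock", "plot"):
        if name not in spec.random:
            continue
        site = name in spec.site_specific
        keys, groups = [], []
        for i in range(n):
            t = trials[i]
            g = t if site else "all"
            if name == "iblock":
                keys.append((t, ph.at[i, "replicate"], ph.at[i, "iblock"]))
            else:
                keys.append((t, ph.at[i, "replicate"], ph.at[i, "iblock"],
                             ph.at[i, "plot"]))
            groups.append(g)
        add_iid(name, keys, groups)

    resid_site = "residual" in spec.site_specific
    rg_names = sorted(set(trials)) if resid_site else ["all"]
    rg_map = {g: j for j, g in enumerate(rg_names)}
    resid_group = np.array([rg_map[t if resid_site else "all"] for t in trials],
                           dtype=int)
    return DesignSet(y=y, X=X, x_names=names, additive=additive,
                     iid_terms=iid_terms, resid_group=resid_group,
                     resid_group_names=rg_names,
                     record_ids=ph["tree_id"].astype(str).tolist())


def _drop_confounded(X: np.ndarray, names: list[str]
                     ) -> tuple[np.ndarray, list[str]]:
    """Remove linearly dependent fixed-effect columns (with a warning)."""
    _, r, piv = la.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    if rank == X.shape[1]:
        return X, names
    keep = sorted(piv[:rank])
    dropped = [names[j] for j in sorted(piv[rank:])]
    warnings.warn(f"dropping confounded fixed-effect columns: {dropped}")
    return X[:, keep], [names[j] for j in keep]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.shape[1] == 0:
        return
    _, r, piv = la.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    if rank < X.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"fixed-effect matrix rank deficient after "
                         f"reference-level dropping; confounded columns: {bad}")


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Estimated (or true) variance components for one model."""

    additive: np.ndarray                 # (r, r) across-region covariance
    regions: list[str]
    iid: dict[str, np.ndarray]           # term -> per-group variances
    iid_groups: dict[str, list[str]]
    residual: np.ndarray                 # per residual-group variances
    residual_groups: list[str]

    def sigma2_a(self, region: str | None = None) -> float:
        if region is None:
            return float(np.mean(np.diag(self.additive)))
        return float(self.additive[self.regions.index(region),
                                   self.regions.index(region)])

    def r_a(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.additive))
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.additive / np.outer(d, d)

    def n_free_parameters(self) -> int:
        r = len(self.regions)
        k = r * (r + 1) // 2
        k += sum(len(v) for v in self.iid.values())
        k += len(self.residual)
        return k

    def to_dict(self) -> dict:
        out = {
            "regions": self.regions,
            "additive_covariance": self.additive.tolist(),
            "additive_correlation": self.r_a().tolist(),
            "residual": dict(zip(self.residual_groups, self.residual.tolist())),
        }
        for name, v in self.iid.items():
            out[name] = dict(zip(self.iid_groups[name], v.tolist()))
        return out


def default_start(d: DesignSet) -> VarianceComponents:
    """Heuristic starting values: equal split of the phenotypic variance."""
    vy = float(np.var(d.y)) or 1.0
    n_terms = 2 + len(d.iid_terms)  # additive + iid terms + residual
    share = vy / n_terms
    if d.additive is not None:
        r = d.additive.n_regions
        Sa = share * (0.5 * np.eye(r) + 0.5 * np.ones((r, r)))
        regions = d.additive.region_names
    else:
        Sa, regions = np.zeros((0, 0)), []
    iid = {t.name: np.full(len(t.group_names), share) for t in d.iid_terms}
    groups = {t.name: list(t.group_names) for t in d.iid_terms}
    resid = np.full(len(d.resid_group_names), share)
    return VarianceComponents(Sa, regions, iid, groups, resid,
                              list(d.resid_group_names))


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------

class _Structure:
    """Precomputed index structures for the dense-V REML iterations."""

    def __init__(self, d: DesignSet):
        self.d = d
        n = d.n
        self.n = n
        if d.additive is not None and d.additive.nrm.K is None:
            raise ValueError("REML needs the dense NRM (NRM.K)")
        if d.additive is not None:
            add = d.additive
            K = add.nrm.K
            ind = add.rec_ind
            safe = np.maximum(ind, 0)
            Krec = K[np.ix_(safe, safe)].copy()
            excl = ind < 0
            Krec[excl, :] = 0.0
            Krec[:, excl] = 0.0
            self.Krec = Krec
            self.region_idx = [np.flatnonzero(add.rec_region == r)
                               for r in range(add.n_regions)]
            self.add_basis = [(j, k) for j in range(add.n_regions)
                              for k in range(j, add.n_regions)]
        else:
            self.Krec = None
            self.add_basis = []
        # iid terms: record lists per level, level lists per group
        self.level_recs: list[list[np.ndarray]] = []
        self.group_levels: list[list[np.ndarray]] = []
        for t in d.iid_terms:
            recs = [np.flatnonzero(t.rec_level == l)
                    for l in range(t.n_levels)]
            self.level_recs.append(recs)
            self.group_levels.append(
                [np.flatnonzero(t.level_group == g)
                 for g in range(len(t.group_names))])
        self.resid_recs = [np.flatnonzero(d.resid_group == g)
                           for g in range(len(d.resid_group_names))]

    # ---- parameter packing ------------------------------------------------
    # The additive covariance uses the spherical parametrization of the
    # Cholesky factor: row i is s_i times a unit vector built from angles
    # θ ∈ (0, π).  Variances are s_i² (log scale on s_i) and every
    # correlation is strictly inside (−1, 1) once the angles are boxed, so
    # a correlation hitting ±1 becomes a clean bound instead of an
    # ill-conditioned ridge.

    ANGLE_MARGIN = 0.05

    @staticmethod
    def _row_from_spherical(s: float, th: np.ndarray) -> np.ndarray:
        i = len(th)
        row = np.zeros(i + 1)
        prod = 1.0
        for j in range(i):
            row[j] = s * prod * np.cos(th[j])
            prod *= np.sin(th[j])
        row[i] = s * prod
        return row

    def _spherical_from_row(self, row: np.ndarray) -> tuple[float, np.ndarray]:
        s = float(np.linalg.norm(row))
        i = len(row) - 1
        th = np.zeros(i)
        rem = s
        lo, hi = self.ANGLE_MARGIN, np.pi - self.ANGLE_MARGIN
        for j in range(i):
            c = row[j] / rem if rem > 0 else 0.0
            th[j] = float(np.clip(np.arccos(np.clip(c, -1.0, 1.0)), lo, hi))
            rem = rem * np.sin(th[j])
        return s, th

    def pack(self, vc: VarianceComponents, floor: float) -> np.ndarray:
        phi: list[float] = []
        if self.d.additive is not None:
            r = self.d.additive.n_regions
            Lc = la.cholesky(vc.additive + 1e-12 * np.eye(r), lower=True)
            for i in range(r):
                s, th = self._spherical_from_row(Lc[i, :i + 1])
                phi.append(np.log(max(s, np.sqrt(floor))))
                phi.extend(th)
        for t in self.d.iid_terms:
            for v in vc.iid[t.name]:
                phi.append(np.log(max(v, floor)))
        for v in vc.residual:
            phi.append(np.log(max(v, floor)))
        return np.array(phi)

    def _chol_L(self, phi: np.ndarray) -> np.ndarray:
        r = self.d.additive.n_regions
        L = np.zeros((r, r))
        pos = 0
        for i in range(r):
            s = np.exp(phi[pos])
            th = phi[pos + 1:pos + 1 + i]
            L[i, :i + 1] = self._row_from_spherical(s, th)
            pos += 1 + i
        return L

    def unpack(self, phi: np.ndarray) -> VarianceComponents:
        pos = 0
        d = self.d
        if d.additive is not None:
            L = self._chol_L(phi)
            Sa = L @ L.T
            regions = d.additive.region_names
            pos = self.n_phi_additive()
        else:
            Sa, regions = np.zeros((0, 0)), []
        iid, groups = {}, {}
        for t in d.iid_terms:
            ng = len(t.group_names)
            iid[t.name] = np.exp(phi[pos:pos + ng])
            groups[t.name] = list(t.group_names)
            pos += ng
        nr = len(d.resid_group_names)
        resid = np.exp(phi[pos:pos + nr])
        return VarianceComponents(Sa, regions, iid, groups, resid,
                                  list(d.resid_group_names))

    def n_phi_additive(self) -> int:
        if self.d.additive is None:
            return 0
        r = self.d.additive.n_regions
        return r * (r + 1) // 2

    # ---- covariance assembly ----------------------------------------------
    def build_V(self, vc: VarianceComponents) -> np.ndarray:
        d = self.d
        n = self.n
        V = np.zeros((n, n))
        if self.Krec is not None:
            reg = d.additive.rec_region
            Sexp = vc.additive[np.ix_(reg, reg)]
            V += self.Krec * Sexp
        for ti, t in enumerate(d.iid_terms):
            theta = vc.iid[t.name]
            for l, recs in enumerate(self.level_recs[ti]):
                if recs.size:
                    V[np.ix_(recs, recs)] += theta[t.level_group[l]]
        V[np.diag_indices(n)] += vc.residual[d.resid_group]
        return V

    # ---- derivative contractions -----------------------------------------
    def theta_basis_count(self) -> int:
        return (len(self.add_basis)
                + sum(len(t.group_names) for t in self.d.iid_terms)
                + len(self.d.resid_group_names))

    def trace_and_quad(self, P: np.ndarray, w: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
        """tr(P V_i) and w' V_i w for every θ-basis matrix V_i."""
        traces, quads = [], []
        if self.Krec is not None:
            for (j, k) in self.add_basis:
                rj, rk = self.region_idx[j], self.region_idx[k]
                Kb = self.Krec[np.ix_(rj, rk)]
                tr = float(np.sum(P[np.ix_(rj, rk)] * Kb))
                qd = float(w[rj] @ Kb @ w[rk])
                if j != k:
                    tr *= 2.0
                    qd *= 2.0
                traces.append(tr)
                quads.append(qd)
        for ti, t in enumerate(self.d.iid_terms):
            for levels in self.group_levels[ti]:
                tr = 0.0
                qd = 0.0
                for l in levels:
                    recs = self.level_recs[ti][l]
                    if recs.size:
                        sub = P[np.ix_(recs, recs)]
                        tr += float(sub.sum())
                        qd += float(w[recs].sum()) ** 2
                traces.append(tr)
                quads.append(qd)
        dP = np.diag(P)
        for recs in self.resid_recs:
            traces.append(float(dP[recs].sum()))
            quads.append(float((w[recs] ** 2).sum()))
        return np.array(traces), np.array(quads)

    def basis_times_vector(self, w: np.ndarray) -> np.ndarray:
        """Columns ``V_i w`` for every θ-basis matrix (for the AI matrix)."""
        cols = []
        if self.Krec is not None:
            for (j, k) in self.add_basis:
                rj, rk = self.region_idx[j], self.region_idx[k]
                Kb = self.Krec[np.ix_(rj, rk)]
                u = np.zeros(self.n)
                u[rj] += Kb @ w[rk]
                if j != k:
                    u[rk] += Kb.T @ w[rj]
                cols.append(u)
        for ti, t in enumerate(self.d.iid_terms):
            for levels in self.group_levels[ti]:
                u = np.zeros(self.n)
                for l in levels:
                    recs = self.level_recs[ti][l]
                    if recs.size:
                        u[recs] = w[recs].sum()
                cols.append(u)
        for recs in self.resid_recs:
            u = np.zeros(self.n)
            u[recs] = w[recs]
            cols.append(u)
        return np.column_stack(cols)

    def jacobian(self, phi: np.ndarray) -> np.ndarray:
        """J[i, a] = dθ_i/dφ_a mapping transformed to natural parameters."""
        n_theta = self.theta_basis_count()
        n_phi = len(phi)
        J = np.zeros((n_theta, n_phi))
        pos_t = 0
        pos_p = 0
        if self.Krec is not None:
            r = self.d.additive.n_regions
            L = self._chol_L(phi)
            a = 0
            pp = 0
            for i in range(r):
                th = phi[pp + 1:pp + 1 + i]
                row = L[i, :i + 1]
                # d/d log s_i: the whole row scales with s_i
                dL = np.zeros((r, r))
                dL[i, :i + 1] = row
                dS = dL @ L.T + L @ dL.T
                for b, (j, k) in enumerate(self.add_basis):
                    J[pos_t + b, pos_p + pp] = dS[j, k]
                # d/dθ_im
                for m in range(i):
                    drow = np.zeros(i + 1)
                    sin_m, cos_m = np.sin(th[m]), np.cos(th[m])
                    # entries before m do not involve θ_m
                    # entry m: cos θ_m factor becomes −sin θ_m
                    drow[m] = -row[m] * sin_m / cos_m if cos_m != 0.0 else \
                        -np.linalg.norm(row) * np.prod(np.sin(th[:m])) * sin_m
                    # entries after m carry a sin θ_m factor
                    drow[m + 1:] = row[m + 1:] * cos_m / sin_m
                    dL = np.zeros((r, r))
                    dL[i, :i + 1] = drow
                    dS = dL @ L.T + L @ dL.T
                    for b, (j, k) in enumerate(self.add_basis):
                        J[pos_t + b, pos_p + pp + 1 + m] = dS[j, k]
                pp += 1 + i
            pos_t += len(self.add_basis)
            pos_p += self.n_phi_additive()
        n_rest = n_theta - pos_t
        theta_rest = np.exp(phi[pos_p:pos_p + n_rest])
        for i in range(n_rest):
            J[pos_t + i, pos_p + i] = theta_rest[i]
        return J


@dataclass
class FitResult:
    """REML fit: variance components, likelihood, and (optionally) EBVs."""

    vc: VarianceComponents
    fixed_estimates: pd.Series
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    ebv: pd.DataFrame | None = None   # id, region, ebv, pev, accuracy
    gradient_norm: float = float("nan")


def _reml_loglik_parts(struct: _Structure, vc: VarianceComponents):
    d = struct.d
    V = struct.build_V(vc)
    cf = la.cho_factor(V, lower=True)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    Vi = la.cho_solve(cf, np.eye(struct.n))
    ViX = Vi @ d.X
    XtViX = d.X.T @ ViX
    cx = la.cho_factor(XtViX)
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx[0]))))
    Viy = Vi @ d.y
    beta = la.cho_solve(cx, d.X.T @ Viy)
    Py = Viy - ViX @ beta
    ll = -0.5 * (logdetV + logdetX + float(d.y @ Py))
    return ll, Vi, ViX, XtViX, cx, Py, beta


def reml_fit(d: DesignSet, start: VarianceComponents | None = None,
             max_iter: int = 200, tol: float = 1e-6,
             compute_ebv: bool = True, verbose: bool = False) -> FitResult:
    """Average-information REML with log/Cholesky parameter transforms.

    The AI step is damped (ridge added) whenever it is not positive
    definite, and halved until the restricted log-likelihood does not
    decrease.  Variances are floored at ``1e-8 ×`` the phenotypic variance
    through the log-scale bound.  Non-convergence returns a warning flag,
    not an exception.
    """
    struct = _Structure(d)
    floor = 1e-8 * (float(np.var(d.y)) or 1.0)
    vy = float(np.var(d.y)) or 1.0
    vc0 = start or default_start(d)
    phi = struct.pack(vc0, floor)
    lb = np.full_like(phi, -np.inf)
    ub = np.full_like(phi, np.inf)
    # log-scale bounds: additive diagonal & iid/residual variances; a loose
    # cap keeps exploratory steps from overflowing the covariance
    pos = 0
    if d.additive is not None:
        r = d.additive.n_regions
        margin = _Structure.ANGLE_MARGIN
        for i in range(r):
            lb[pos] = 0.5 * np.log(floor)      # log s_i
            ub[pos] = 0.5 * np.log(1e6 * vy)
            for m in range(i):
                lb[pos + 1 + m] = margin       # angles: correlations
                ub[pos + 1 + m] = np.pi - margin   # strictly inside (−1, 1)
            pos += 1 + i
    lb[pos:] = np.log(floor)
    ub[pos:] = np.log(1e6 * vy)

    ll, *state = _reml_loglik_parts(struct, struct.unpack(phi))
    converged = False
    it = 0
    flat_count = 0
    grad_norm = float("nan")
    for it in range(1, max_iter + 1):
        Vi, ViX, XtViX, cx, Py, beta = state

        def apply_P(M: np.ndarray) -> np.ndarray:
            ViM = Vi @ M
            return ViM - ViX @ la.cho_solve(cx, ViX.T @ M)

        P = Vi - ViX @ la.cho_solve(cx, ViX.T)
        traces, quads = struct.trace_and_quad(P, Py)
        g_theta = -0.5 * (traces - quads)
        W = struct.basis_times_vector(Py)
        PW = P @ W
        AI_theta = 0.5 * (W.T @ PW)
        J = struct.jacobian(phi)
        g = J.T @ g_theta
        Ahat = J.T @ AI_theta @ J
        grad_norm = float(np.max(np.abs(g)))

        # parameters pinned at the floor with an inward-pointing gradient
        # are frozen (active set); the Newton step is taken on the rest
        active = (((phi <= lb + 1e-10) & (g < 0.0))
                  | ((phi >= ub - 1e-10) & (g > 0.0)))
        free = ~active
        g_eff = np.where(active, 0.0, g)
        if not free.any():
            converged = True
            break
        step = np.zeros_like(phi)
        Af = Ahat[np.ix_(free, free)]
        gf = g[free]
        ridge = 0.0
        for _ in range(8):
            try:
                cA = la.cho_factor(Af + ridge * np.eye(len(gf)))
                step[free] = la.cho_solve(cA, gf)
                break
            except la.LinAlgError:
                ridge = max(ridge * 10.0, 1e-6 * max(np.trace(Af), 1.0))
        else:
            step[free] = gf / max(np.max(np.abs(Af)), 1.0)

        def try_step(stp):
            cand = np.clip(phi + stp, lb, ub)
            try:
                ll_c, *st_c = _reml_loglik_parts(struct, struct.unpack(cand))
            except (la.LinAlgError, ValueError):
                return None
            if np.isfinite(ll_c):
                return cand, ll_c, st_c
            return None

        def line_search(stp):
            for halving in range(25):
                hit = try_step(stp)
                if hit is not None and hit[1] >= ll - 1e-10:
                    if halving == 0:
                        # full step accepted: push further while it pays off
                        # (accelerates creep along near-singular ridges,
                        # e.g. correlations approaching the ±1 boundary)
                        best = hit
                        factor = 2.0
                        for _ in range(6):
                            more = try_step(factor * stp)
                            if more is None or more[1] <= best[1]:
                                break
                            best = more
                            factor *= 2.0
                        return best
                    return hit
                stp = 0.5 * stp
            return None

        hit = line_search(step)
        if hit is None:
            # AI direction failed (projection onto the floor can spoil it);
            # retry along the plain gradient
            scale = max(np.max(np.abs(np.diag(Ahat))), 1.0)
            hit = line_search(g_eff / scale)
        if hit is None:
            break
        phi_new, ll_new, state_new = hit
        dll = ll_new - ll
        dphi = float(np.max(np.abs(phi_new - phi)))
        phi, ll, state = phi_new, ll_new, state_new
        if verbose:
            logger.info("iter %d loglik %.6f dll %.3g dphi %.3g",
                        it, ll, dll, dphi)
        if abs(dll) < tol:
            # parameters may keep drifting along likelihood-flat directions
            # (angles of a collapsed variance row, bounded correlations);
            # three consecutive flat iterations end the fit
            flat_count += 1
        else:
            flat_count = 0
        if (abs(dll) < tol and dphi < tol) or flat_count >= 3:
            converged = True
            break
    if not converged:
        warnings.warn(f"REML did not converge in {it} iterations "
                      f"(|grad|={grad_norm:.3g})")

    vc = struct.unpack(phi)
    _, Vi, ViX, XtViX, cx, Py, beta = (ll, *state)
    fixed = pd.Series(beta, index=d.x_names)
    k = len(phi)
    aic = model_aic(ll, k)
    fit = FitResult(vc=vc, fixed_estimates=fixed, loglik=float(ll), aic=aic,
                    converged=converged, n_iter=it, gradient_norm=grad_norm)
    if compute_ebv and d.additive is not None and d.additive.nrm.K_inv is not None:
        sol = solve_mme(d, vc)
        fit.ebv = sol.ebv_table(vc)
    return fit


def model_aic(loglik: float, k: int) -> float:
    """AIC on the REML log-likelihood with k free variance parameters.

    Comparable only across fits with identical fixed effects, since REML
    likelihoods condition on the fixed-effect design.
    """
    return -2.0 * loglik + 2.0 * k


def compute_pev_accuracy(pev: np.ndarray, sigma2_a) -> np.ndarray:
    """Breeding-value accuracy ``r_i = sqrt(1 − PEV_i / σ²_a)``.

    ``sigma2_a`` may be a scalar or a per-entry array; accuracies are
    clipped to [0, 1] with a warning when PEV exceeds σ²_a.
    """
    s2 = np.asarray(sigma2_a, dtype=float)
    if np.any(s2 <= 0.0):
        raise ValueError("sigma2_a must be positive")
    ratio = 1.0 - np.asarray(pev, dtype=float) / s2
    if np.any(ratio < -1e-9):
        warnings.warn("PEV exceeds sigma2_a for some individuals; "
                      "accuracy clipped to 0")
    return np.sqrt(np.clip(ratio, 0.0, 1.0))


# ---------------------------------------------------------------------------
# mixed-model equations
# ---------------------------------------------------------------------------

@dataclass
class MMESolution:
    """Solutions and factorization of Henderson's equations."""

    design: DesignSet
    beta: pd.Series
    u_additive: np.ndarray | None     # (r, q) additive effects by region
    u_iid: dict[str, np.ndarray]
    chol: tuple
    offsets: dict[str, int]
    n_eq: int

    def pev_additive(self) -> np.ndarray:
        """Exact PEV diagonal of the additive block, shape (r, q).

        Diagonal of the inverse of the full MME coefficient matrix (times
        the implicit residual scaling already absorbed in C).
        """
        c, low = self.chol
        inv, info = la.lapack.dpotri(c, lower=low)
        if info != 0:
            raise ValueError("coefficient matrix inversion failed")
        diag = np.diag(inv)
        add = self.design.additive
        q = len(add.nrm.ids)
        r = add.n_regions
        o = self.offsets["additive"]
        return diag[o:o + r * q].reshape(r, q)

    def ebv_table(self, vc: VarianceComponents) -> pd.DataFrame:
        add = self.design.additive
        pev = self.pev_additive()
        rows = []
        for ri, region in enumerate(add.region_names):
            s2 = vc.additive[ri, ri] if vc.additive.size else float("nan")
            acc = compute_pev_accuracy(np.minimum(pev[ri], s2), s2)
            for qi, iid in enumerate(add.nrm.ids):
                rows.append((iid, region, self.u_additive[ri, qi],
                             pev[ri, qi], acc[qi]))
        return pd.DataFrame(rows, columns=["id", "region", "ebv", "pev",
                                           "accuracy"])


def solve_mme(d: DesignSet, vc: VarianceComponents) -> MMESolution:
    """Set up and solve Henderson's mixed-model equations.

    The additive block uses ``Σ_a⁻¹ ⊗ NRM⁻¹`` (region-major ordering); iid
    terms contribute ``1/θ`` diagonals; the residual is diagonal with
    per-group variances.  Returns solutions plus the Cholesky factor of the
    coefficient matrix so exact PEV diagonals can be extracted.
    """
    n = d.n
    ri = 1.0 / vc.residual[d.resid_group]

    zcols: list[sp.spmatrix] = []
    offsets: dict[str, int] = {}
    pos = 0
    if d.additive is not None:
        add = d.additive
        if add.nrm.K_inv is None:
            raise ValueError("MME needs the sparse NRM inverse (NRM.K_inv)")
        q = len(add.nrm.ids)
        r = add.n_regions
        offsets["additive"] = pos
        rows = np.flatnonzero(add.rec_ind >= 0)
        cols = add.rec_region[rows] * q + add.rec_ind[rows]
        Za = sp.coo_matrix((np.ones(len(rows)), (rows, cols)),
                           shape=(n, r * q)).tocsr()
        zcols.append(Za)
        pos += r * q
    for t in d.iid_terms:
        offsets[t.name] = pos
        rows = np.flatnonzero(t.rec_level >= 0)
        Zt = sp.coo_matrix((np.ones(len(rows)), (rows, t.rec_level[rows])),
                           shape=(n, t.n_levels)).tocsr()
        zcols.append(Zt)
        pos += t.n_levels
    Z = sp.hstack(zcols).tocsr() if zcols else sp.csr_matrix((n, 0))
    p = d.X.shape[1]
    n_eq = p + Z.shape[1]

    Xw = d.X * ri[:, None]
    C = np.zeros((n_eq, n_eq))
    C[:p, :p] = d.X.T @ Xw
    XtRZ = (Z.T @ Xw).T
    C[:p, p:] = XtRZ
    C[p:, :p] = XtRZ.T
    Zw = Z.multiply(ri[:, None]).tocsr()
    C[p:, p:] = (Z.T @ Zw).toarray()

    if d.additive is not None:
        add = d.additive
        q = len(add.nrm.ids)
        r = add.n_regions
        Sa_inv = la.inv(vc.additive)
        Kinv = add.nrm.K_inv.toarray() if sp.issparse(add.nrm.K_inv) \
            else np.asarray(add.nrm.K_inv)
        o = p + offsets["additive"]
        for a in range(r):
            for b in range(r):
                C[o + a * q:o + (a + 1) * q, o + b * q:o + (b + 1) * q] += \
                    Sa_inv[a, b] * Kinv
    for ti, t in enumerate(d.iid_terms):
        o = p + offsets[t.name]
        theta = vc.iid[t.name][t.level_group]
        C[o:o + t.n_levels, o:o + t.n_levels] += np.diag(1.0 / theta)

    rhs = np.concatenate([d.X.T @ (ri * d.y), Z.T @ (ri * d.y)])
    try:
        cf = la.cho_factor(C, lower=True)
    except la.LinAlgError as exc:
        raise ValueError("singular mixed-model coefficient matrix") from exc
    sol = la.cho_solve(cf, rhs)

    beta = pd.Series(sol[:p], index=d.x_names)
    u_add = None
    if d.additive is not None:
        q = len(d.additive.nrm.ids)
        r = d.additive.n_regions
        o = p + offsets["additive"]
        u_add = sol[o:o + r * q].reshape(r, q)
    u_iid = {}
    for t in d.iid_terms:
        o = p + offsets[t.name]
        u_iid[t.name] = sol[o:o + t.n_levels]
    # offsets stored relative to the random-effect block start for PEV
    off_abs = {k: v + p for k, v in offsets.items()}
    return MMESolution(design=d, beta=beta, u_additive=u_add, u_iid=u_iid,
                       chol=cf, offsets={k: v for k, v in off_abs.items()},
                       n_eq=n_eq)
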