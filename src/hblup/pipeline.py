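"""Two-stage analysis flow and the ABLUP/HBLUP scenario comparator.

Stage one fits each trial on its own (pedigree NRM, race genetic groups) to
produce design-adjusted phenotypes and a per-trial additive variance; each
trial is then standardized to mean zero and additive standard deviation
one.  Stage two fits multi-region models on the standardized data with an
unstructured additive covariance across regions, under four scenarios:

* ``ablup+race`` — pedigree NRM, founder-race fractions as fixed covariates
* ``ablup-race`` — pedigree NRM only
* ``hblup``      — within-program single-step H, no race groups
* ``hblup-joint``— joint H over both programs, both programs' data

Each scenario yields variance components, regional h²/d², AIC, EBVs with
prediction error variances, and mean accuracies for the individual classes
used to compare models (parents represented in the target region, parents
represented only elsewhere, genotyped individuals with/without pedigree
links, and progeny).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomic import MarkerMatrix, blend_G, compute_G_vanraden1, qc_filter, tune_G
from .hmatrix import build_H, build_H_inverse
from .mixedmodel import (FitResult, ModelSpec, NRM, VarianceComponents,
                         build_design, reml_fit)
from .pedigree import (GroupFractionMatrix, Pedigree, build_A_inverse,
                       build_A_tabular, group_fraction_matrix, partition_A)
from .relmat import RelationshipMatrix

logger = logging.getLogger(__name__)

SCENARIOS = ("ablup+race", "ablup-race", "hblup", "hblup-joint")

ACCURACY_CLASSES = ("parents_represented", "parents_correlated",
                    "genotyped_related", "genotyped_unrelated", "progeny")


# ---------------------------------------------------------------------------
# stage one: single-site adjustment and standardization
# ---------------------------------------------------------------------------

def single_site_adjust(ph: pd.DataFrame, trial: str, nrm: NRM,
                       Q: GroupFractionMatrix | None = None,
                       pedigree: Pedigree | None = None,
                       response: str = "VOL") -> tuple[pd.Series, float]:
    """Fit one trial and return design-adjusted values and σ̂²_a.

    The single-site model has fixed {mean, replicate, checklot, race
    fractions} and random {additive, family, incomplete block, plot}.
    The adjusted value subtracts the replicate estimate and the block and
    plot BLUPs: ``y_adj = y − rep − iblock − plot``.  Trials with a single
    replicate keep the mean only (with a warning).
    """
    sub = ph[ph["trial"] == trial].copy()
    if sub.empty:
        raise ValueError(f"trial {trial!r} has no records")
    if sub["replicate"].nunique() < 2:
        warnings.warn(f"trial {trial!r} has a single replicate; replicate "
                      "effects dropped")
    spec = ModelSpec(response=response, nrm=nrm,
                     fixed=("mean", "replicate", "checklot"),
                     random=("additive", "family", "iblock", "plot"),
                     region_structure="none",
                     race_fractions=Q is not None)
    d = build_design(sub, spec, Q=Q, pedigree=pedigree, drop_confounded=True)
    fit = reml_fit(d, compute_ebv=False)
    from .mixedmodel import solve_mme
    sol = solve_mme(d, fit.vc)

    y_adj = sub[response].to_numpy(dtype=float).copy()
    # subtract replicate fixed estimates
    for name, est in sol.beta.items():
        if name.startswith("rep["):
            col = d.X[:, d.x_names.index(name)]
            y_adj -= col * est
    for term_name in ("iblock", "plot"):
        for t in d.iid_terms:
            if t.name != term_name:
                continue
            u = sol.u_iid[t.name]
            has = t.rec_level >= 0
            y_adj[has] -= u[t.rec_level[has]]
    sigma2_a = fit.vc.sigma2_a()
    return pd.Series(y_adj, index=sub.index), float(sigma2_a)


def standardize_by_trial(ph: pd.DataFrame, adjusted: dict,
                         sigma2_a_by_trial: dict, response: str = "VOL",
                         floor: float = 1e-6) -> pd.DataFrame:
    """Standardize each trial to mean zero / additive SD one.

    ``adjusted`` maps trial -> Series of adjusted values (indexed by the
    phenotype-table rows); trials whose σ̂²_a sits at the variance floor are
    excluded with a warning to avoid division blow-up.
    """
    out = ph.copy()
    out[response + "_std"] = np.nan
    keep_rows = np.ones(len(out), dtype=bool)
    for trial, ser in adjusted.items():
        s2 = sigma2_a_by_trial[trial]
        rows = out.index.isin(ser.index)
        if s2 <= floor:
            warnings.warn(f"trial {trial!r} additive variance at floor; "
                          "trial excluded from standardized data")
            keep_rows &= ~rows
            continue
        vals = (ser - ser.mean()) / np.sqrt(s2)
        out.loc[ser.index, response + "_std"] = vals
    out = out[keep_rows & out[response + "_std"].notna()]
    return out


def run_stage_one(ph: pd.DataFrame, nrm: NRM, Q: GroupFractionMatrix | None,
                  pedigree: Pedigree, response: str = "VOL",
                  sigma2a_source: str = "preliminary-xsite") -> pd.DataFrame:
    """Adjust every trial, estimate per-trial σ̂²_a, standardize.

    Single-site fits supply the design-adjusted values; the σ̂²_a used for
    standardization comes, by default, from a preliminary cross-site fit of
    the adjusted values (one pooled additive variance with site-specific
    block/plot/residual variances), which is far more stable than the
    trial-by-trial estimates.  ``sigma2a_source="single-site"`` uses each
    trial's own estimate instead.
    """
    adjusted: dict[str, pd.Series] = {}
    s2a: dict[str, float] = {}
    for trial in sorted(ph["trial"].unique()):
        y_adj, s2 = single_site_adjust(ph, trial, nrm, Q=Q,
                                       pedigree=pedigree, response=response)
        adjusted[trial] = y_adj
        s2a[trial] = s2
    if sigma2a_source == "preliminary-xsite":
        ph_adj = ph.copy()
        col = response + "_adj"
        ph_adj[col] = np.nan
        for trial, ser in adjusted.items():
            ph_adj.loc[ser.index, col] = ser
        spec = ModelSpec(response=col, nrm=nrm,
                         fixed=("mean", "trial", "checklot"),
                         random=("additive", "family", "iblock", "plot"),
                         region_structure="none",
                         race_fractions=Q is not None)
        d = build_design(ph_adj, spec, Q=Q, pedigree=pedigree,
                         drop_confounded=True)
        prelim = reml_fit(d, compute_ebv=False)
        pooled = prelim.vc.sigma2_a()
        if pooled <= 1e-6:
            # pooled estimate on the boundary: fall back to the mean of the
            # informative single-site estimates rather than dropping data
            positive = [v for v in s2a.values() if v > 1e-6]
            if positive:
                warnings.warn("preliminary cross-site additive variance at "
                              "floor; using mean of single-site estimates")
                pooled = float(np.mean(positive))
        s2a = {t: pooled for t in s2a}
    elif sigma2a_source != "single-site":
        raise ValueError(f"unknown sigma2a_source {sigma2a_source!r}")
    return standardize_by_trial(ph, adjusted, s2a, response=response)


# ---------------------------------------------------------------------------
# stage two: multi-region fits and derived summaries
# ---------------------------------------------------------------------------

def fit_multiregion(ph_std: pd.DataFrame, spec: ModelSpec,
                    Q: GroupFractionMatrix | None = None,
                    pedigree: Pedigree | None = None) -> FitResult:
    """Unstructured across-region REML fit on standardized data.

    Regions with no data are simply absent from the covariance structure
    (they are reported NA downstream).  A single-region input reduces to a
    univariate fit.
    """
    d = build_design(ph_std, spec, Q=Q, pedigree=pedigree,
                     drop_confounded=True)
    return reml_fit(d)


def heritability_dominance(vc: VarianceComponents, trial_region_map: dict,
                           mode: str = "regional",
                           trait_mean: float | None = None) -> pd.DataFrame:
    """Narrow-sense heritability, dominance proportion, and CVa.

    ``h² = σ²_a / (σ²_a + σ²_f + mean_k(σ²_bk + σ²_pk + σ²_ek))`` and
    ``d² = 4σ²_f / (same denominator)``, with the mean taken over the
    region's trials (``mode="regional"``) or all trials (``mode="xsite"``).
    σ²_f is the weighted mean family variance across trial groups (weights:
    number of trials per group).  CVa = 100·σ_a/mean(trait) needs the trait
    mean on the original scale and is NaN without it.
    """
    fam = vc.iid.get("family")
    if fam is None or len(fam) == 0:
        sigma2_f_all = 0.0
    elif len(fam) == 1:
        sigma2_f_all = float(fam[0])
    else:
        # weight groups by their number of trials
        groups = vc.iid_groups["family"]
        w = np.array([sum(1 for t in trial_region_map if str(g) in str(t))
                      or 1 for g in groups], dtype=float)
        sigma2_f_all = float(np.average(fam, weights=w))

    def env_sum(trials: list[str]) -> float:
        tot = []
        for t in trials:
            s = 0.0
            for name in ("iblock", "plot"):
                if name in vc.iid:
                    gnames = vc.iid_groups[name]
                    s += vc.iid[name][gnames.index(t)] if t in gnames \
                        else float(np.mean(vc.iid[name]))
            s += (vc.residual[vc.residual_groups.index(t)]
                  if t in vc.residual_groups else float(np.mean(vc.residual)))
            tot.append(s)
        if not tot:
            raise ValueError("no trials for denominator")
        return float(np.mean(tot))

    rows = []
    if mode == "regional":
        for ri, region in enumerate(vc.regions):
            trials = [t for t, r in trial_region_map.items() if r == region]
            if not trials:
                rows.append((region, np.nan, np.nan, np.nan))
                continue
            s2a = vc.additive[ri, ri]
            denom = s2a + sigma2_f_all + env_sum(trials)
            if denom <= 0:
                raise ValueError("zero denominator in heritability")
            cva = 100.0 * np.sqrt(s2a) / trait_mean if trait_mean else np.nan
            rows.append((region, s2a / denom, 4.0 * sigma2_f_all / denom, cva))
    elif mode == "xsite":
        trials = list(trial_region_map)
        s2a = float(np.mean(np.diag(vc.additive))) if vc.additive.size else 0.0
        denom = s2a + sigma2_f_all + env_sum(trials)
        if denom <= 0:
            raise ValueError("zero denominator in heritability")
        cva = 100.0 * np.sqrt(s2a) / trait_mean if trait_mean else np.nan
        rows.append(("all", s2a / denom, 4.0 * sigma2_f_all / denom, cva))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["region", "h2", "d2", "CVa"])


# ---------------------------------------------------------------------------
# accuracy classes
# ---------------------------------------------------------------------------

def classify_individuals(pedigree: Pedigree, ph: pd.DataFrame,
                         genotyped: set, program: str | None = None
                         ) -> pd.DataFrame:
    """Assign each pedigree individual to a Fig-4-style class per region.

    * parents_represented: has progeny records in the target region
    * parents_correlated:  has progeny records, but only in other regions
    * genotyped_related:   genotyped, no progeny records, pedigree link
    * genotyped_unrelated: genotyped, no progeny records, no pedigree link
    * progeny:             has own records (and no progeny records)
    """
    recorded = set(ph.loc[ph["entry_type"] != "checklot", "tree_id"])
    regions = sorted(ph["region"].unique())
    rec_region: dict[str, set] = {}
    for tid, reg in zip(ph["tree_id"], ph["region"]):
        rec_region.setdefault(tid, set()).add(reg)

    progeny_regions: dict[str, set] = {}
    linked: set[str] = set()
    for k in range(pedigree.n):
        iid = pedigree.ids[k]
        s, d = pedigree.sire[k], pedigree.dam[k]
        if s >= 0 or d >= 0:
            linked.add(iid)
        for par in (s, d):
            if par < 0:
                continue
            linked.add(pedigree.ids[par])
            if iid in recorded:
                progeny_regions.setdefault(pedigree.ids[par], set()).update(
                    rec_region.get(iid, set()))

    rows = []
    for k in range(pedigree.n):
        iid = pedigree.ids[k]
        if program is not None and pedigree.program[k] != program:
            continue
        pr = progeny_regions.get(iid, set())
        for region in regions:
            if pr:
                cls = ("parents_represented" if region in pr
                       else "parents_correlated")
            elif iid in recorded:
                cls = "progeny"
            elif iid in genotyped:
                cls = ("genotyped_related" if iid in linked
                       else "genotyped_unrelated")
            else:
                continue
            rows.append((iid, pedigree.program[k], region, cls,
                         iid in genotyped))
    return pd.DataFrame(rows, columns=["id", "program", "region", "class",
                                       "genotyped"])


def add_total_genetic_value(fit: FitResult, Q: GroupFractionMatrix | None
                            ) -> None:
    """Append ``ebv_total`` = EBV plus estimated race-group contribution.

    Models with race fractions as fixed effects predict within-race
    deviations; total genetic merit adds the estimated group effects back,
    which is what rankings (and comparisons against simulated truth) need.
    Without race fractions the total equals the EBV.
    """
    if fit.ebv is None:
        return
    contrib = None
    if Q is not None:
        qdf = Q.to_frame()
        vals = np.zeros(len(qdf))
        any_race = False
        for name, est in fit.fixed_estimates.items():
            if name.startswith("race_frac="):
                any_race = True
                vals += qdf[name.split("=", 1)[1]].to_numpy() * est
        if any_race:
            contrib = dict(zip(qdf.index, vals))
    if contrib is None:
        fit.ebv["ebv_total"] = fit.ebv["ebv"]
    else:
        fit.ebv["ebv_total"] = (fit.ebv["ebv"]
                                + fit.ebv["id"].map(contrib).fillna(0.0))


def empirical_accuracy_by_class(fit: FitResult, classes: pd.DataFrame,
                                true_bv: pd.DataFrame,
                                min_n: int = 4) -> pd.DataFrame:
    """Correlation of (total) EBVs with simulated true breeding values.

    One row per (program, region, class) with at least ``min_n`` members
    and non-degenerate spread; this is the scale-free accuracy measure a
    simulation affords, immune to differences in σ̂²_a between models.
    """
    if fit.ebv is None:
        raise ValueError("fit has no EBV table")
    col = "ebv_total" if "ebv_total" in fit.ebv else "ebv"
    merged = classes.merge(fit.ebv, on=["id", "region"], how="inner")
    rows = []
    for (prog, region, cls), grp in merged.groupby(["program", "region",
                                                    "class"]):
        ok = [i for i in grp["id"] if i in true_bv.index]
        if len(ok) < min_n or region not in true_bv.columns:
            continue
        sub = grp[grp["id"].isin(ok)]
        tv = np.array([true_bv.at[i, region] for i in sub["id"]])
        ev = sub[col].to_numpy()
        if np.std(tv) < 1e-12 or np.std(ev) < 1e-12:
            continue
        rows.append((prog, region, cls, len(sub),
                     float(np.corrcoef(tv, ev)[0, 1])))
    return pd.DataFrame(rows, columns=["program", "region", "class", "n",
                                       "empirical_accuracy"])


def accuracy_by_class(fit: FitResult, classes: pd.DataFrame) -> pd.DataFrame:
    """Mean accuracy (and SE of the mean) per program, region, and class."""
    if fit.ebv is None:
        raise ValueError("fit has no EBV table")
    merged = classes.merge(fit.ebv, on=["id", "region"], how="inner")
    rows = []
    for (prog, region, cls), grp in merged.groupby(["program", "region",
                                                    "class"]):
        acc = grp["accuracy"].to_numpy()
        se = float(np.std(acc, ddof=1) / np.sqrt(len(acc))) if len(acc) > 1 \
            else float("nan")
        rows.append((prog, region, cls, len(acc), float(np.mean(acc)), se,
                     float(np.mean(grp["pev"]))))
    return pd.DataFrame(rows, columns=["program", "region", "class", "n",
                                       "mean_accuracy", "se", "mean_pev"])


# ---------------------------------------------------------------------------
# matrix construction helpers
# ---------------------------------------------------------------------------

@dataclass
class MatrixSet:
    """Relationship matrices for one pedigree (+ optional genomic layer)."""

    pedigree: Pedigree
    A: RelationshipMatrix
    Ainv: sp.csr_matrix
    ids: list[str]
    Q: GroupFractionMatrix
    H: RelationshipMatrix | None = None
    Hinv: sp.csr_matrix | None = None
    genotyped: list[str] = field(default_factory=list)

    def nrm(self, use_H: bool, label: str | None = None) -> NRM:
        if use_H:
            if self.H is None:
                raise ValueError("no genomic layer built for this pedigree")
            return NRM(self.ids, self.H.values, self.Hinv, label or "H")
        return NRM(self.ids, self.A.values, self.Ainv, label or "A")


def build_matrix_set(ped: Pedigree, markers: MarkerMatrix | None = None,
                     genotyped: list[str] | None = None,
                     blend_weight: float = 0.95,
                     maf_threshold: float = 0.05) -> MatrixSet:
    """Pedigree matrices, and the single-step H layer when markers given."""
    A = build_A_tabular(ped)
    Ainv, ids = build_A_inverse(ped)
    Q = group_fraction_matrix(ped)
    ms = MatrixSet(pedigree=ped, A=A, Ainv=Ainv, ids=ids, Q=Q)
    if markers is None:
        return ms
    genotyped = [g for g in (genotyped or markers.ids) if g in ped._index]
    if not genotyped:
        warnings.warn("no genotyped individuals in this pedigree; "
                      "H reduces to A")
        return ms
    mm = qc_filter(markers.subset_ids(genotyped), maf_threshold)
    G = compute_G_vanraden1(mm)
    A22 = partition_A(A, genotyped)["A22"]
    Ga, _ = tune_G(G, A22)
    Gw = blend_G(Ga, A22, blend_weight)
    ms.H = build_H(A, Gw, genotyped)
    ms.Hinv = build_H_inverse(Ainv, Gw, A22, genotyped, ids)
    ms.genotyped = genotyped
    return ms


# ---------------------------------------------------------------------------
# scenario comparison
# ---------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    """One scenario's fit plus derived summaries."""

    scenario: str
    program: str                 # program analysed ("JOINT" for the merge)
    fit: FitResult
    h2_d2: pd.DataFrame
    accuracy: pd.DataFrame       # theoretical, from PEV
    accuracy_empirical: pd.DataFrame | None = None  # vs simulated truth

    @property
    def aic(self) -> float:
        return self.fit.aic


@dataclass
class ComparisonResult:
    """All scenario fits for a dataset, keyed (scenario, program)."""

    results: dict
    stage1: dict                 # program -> standardized phenotype table

    def get(self, scenario: str, program: str) -> ScenarioResult:
        return self.results[(scenario, program)]

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for (scen, prog), res in self.results.items():
            vc = res.fit.vc
            for ri, region in enumerate(vc.regions):
                h2row = res.h2_d2[res.h2_d2["region"] == region]
                rows.append({
                    "scenario": scen, "program": prog, "region": region,
                    "sigma2_a": vc.additive[ri, ri],
                    "h2": float(h2row["h2"].iloc[0]) if len(h2row) else np.nan,
                    "d2": float(h2row["d2"].iloc[0]) if len(h2row) else np.nan,
                    "aic": res.fit.aic,
                    "loglik": res.fit.loglik,
                    "converged": res.fit.converged,
                })
        return pd.DataFrame(rows)


def scenario_compare(datasets: dict, markers: MarkerMatrix | None,
                     genotyped: dict, joint_pedigree: Pedigree | None = None,
                     response: str = "VOL",
                     scenarios: tuple = SCENARIOS,
                     blend_weight: float = 0.95,
                     true_bv: pd.DataFrame | None = None) -> ComparisonResult:
    """Run the ABLUP/HBLUP scenario set on one or two programs.

    ``datasets`` maps program -> (pedigree, phenotype table).  All
    within-program scenarios use identical phenotype rows; the joint
    scenario pools both programs on the merged pedigree and joint H.
    """
    programs = list(datasets)
    matrix_sets: dict[str, MatrixSet] = {}
    stage1: dict[str, pd.DataFrame] = {}
    for prog in programs:
        ped, ph = datasets[prog]
        ms = build_matrix_set(ped, markers, genotyped.get(prog, []),
                              blend_weight)
        matrix_sets[prog] = ms
        nrm_a = ms.nrm(use_H=False)
        stage1[prog] = run_stage_one(ph, nrm_a, ms.Q, ped, response=response)

    results: dict[tuple, ScenarioResult] = {}
    resp_std = response + "_std"

    def run_fit(prog: str, ms: MatrixSet, ph_std: pd.DataFrame,
                use_H: bool, race: bool, scen: str) -> ScenarioResult:
        nrm = ms.nrm(use_H=use_H)
        spec = ModelSpec(response=resp_std, nrm=nrm,
                         fixed=("mean", "trial", "checklot"),
                         random=("additive", "family", "iblock", "plot"),
                         region_structure="unstructured",
                         race_fractions=race)
        fit = fit_multiregion(ph_std, spec, Q=ms.Q if race else None,
                              pedigree=ms.pedigree)
        add_total_genetic_value(fit, ms.Q if race else None)
        trial_region = dict(ph_std.groupby("trial")["region"].first())
        h2d2 = heritability_dominance(fit.vc, trial_region, "regional")
        gset = set(ms.genotyped)
        cls = classify_individuals(ms.pedigree, ph_std, gset)
        acc = accuracy_by_class(fit, cls) if fit.ebv is not None else pd.DataFrame()
        emp = None
        if true_bv is not None and fit.ebv is not None:
            emp = empirical_accuracy_by_class(fit, cls, true_bv)
        return ScenarioResult(scen, prog, fit, h2d2, acc, emp)

    for prog in programs:
        ms = matrix_sets[prog]
        ph_std = stage1[prog]
        if "ablup+race" in scenarios:
            results[("ablup+race", prog)] = run_fit(prog, ms, ph_std, False,
                                                    True, "ablup+race")
        if "ablup-race" in scenarios:
            results[("ablup-race", prog)] = run_fit(prog, ms, ph_std, False,
                                                    False, "ablup-race")
        if "hblup" in scenarios:
            if ms.H is not None:
                results[("hblup", prog)] = run_fit(prog, ms, ph_std, True,
                                                   False, "hblup")
            else:
                # no genotypes: single-step degenerates exactly to ABLUP-race
                warnings.warn(f"program {prog}: no genotyped individuals; "
                              "HBLUP identical to ABLUP-race")
                results[("hblup", prog)] = run_fit(prog, ms, ph_std, False,
                                                   False, "hblup")

    if "hblup-joint" in scenarios and len(programs) > 1:
        joint_ped = joint_pedigree
        if joint_ped is None:
            from .pedigree import merge_pedigrees
            joint_ped = merge_pedigrees(*[datasets[p][0] for p in programs])
        all_g: list[str] = []
        for prog in programs:
            for iid in genotyped.get(prog, []):
                if iid not in all_g:
                    all_g.append(iid)
        cross = _cross_program_links(joint_ped, markers, all_g, programs)
        if not cross:
            warnings.warn("programs disconnected; joint EBVs not comparable")
        ms_joint = build_matrix_set(joint_ped, markers, all_g, blend_weight)
        ph_joint = pd.concat([stage1[p] for p in programs], ignore_index=True)
        results[("hblup-joint", "JOINT")] = run_fit(
            "JOINT", ms_joint, ph_joint, ms_joint.H is not None, False,
            "hblup-joint")
    return ComparisonResult(results=results, stage1=stage1)


def comparative_findings(comp: ComparisonResult, programs: list[str]
                         ) -> dict:
    """Headline comparative quantities from a scenario comparison.

    * ``delta_race_sigma2a``: mean increase in σ̂²_a when race groups are
      dropped (ABLUP−race minus ABLUP+race), over programs and regions.
    * ``acc_parents_correlated_joint`` / ``_within``: n-weighted mean
      empirical accuracy of the parents-correlated class over the
      (program, region) cells present in both the joint fit and the
      within-program single-step fits.
    """
    t = comp.summary_table()
    deltas = []
    for prog in programs:
        a = t[(t.scenario == "ablup+race") & (t.program == prog)] \
            .set_index("region")["sigma2_a"]
        b = t[(t.scenario == "ablup-race") & (t.program == prog)] \
            .set_index("region")["sigma2_a"]
        common = a.index.intersection(b.index)
        deltas.extend((b[common] - a[common]).tolist())
    out = {"delta_race_sigma2a": float(np.mean(deltas)) if deltas else np.nan}

    joint = comp.results.get(("hblup-joint", "JOINT"))
    if joint is not None and joint.accuracy_empirical is not None:
        ej = joint.accuracy_empirical
        ej = ej[ej["class"] == "parents_correlated"]
        within_rows = []
        for prog in programs:
            res = comp.results.get(("hblup", prog))
            if res is None or res.accuracy_empirical is None:
                continue
            ew = res.accuracy_empirical
            within_rows.append(ew[ew["class"] == "parents_correlated"])
        if within_rows and len(ej):
            ew = pd.concat(within_rows, ignore_index=True)
            m = ej.merge(ew, on=["program", "region", "class"],
                         suffixes=("_joint", "_within"))
            if len(m):
                w = m["n_joint"] + m["n_within"]
                out["acc_parents_correlated_joint"] = float(
                    np.average(m["empirical_accuracy_joint"], weights=w))
                out["acc_parents_correlated_within"] = float(
                    np.average(m["empirical_accuracy_within"], weights=w))
                out["n_parents_correlated_cells"] = int(len(m))
    return out


def _cross_program_links(joint_ped: Pedigree, markers: MarkerMatrix | None,
                         genotyped: list[str], programs: list[str]) -> bool:
    """True when genotypes or shared ancestors bridge the programs."""
    if markers is None or len(genotyped) < 2:
        return False
    progs = set()
    for iid in genotyped:
        k = joint_ped._index.get(iid)
        if k is not None:
            progs.add(joint_ped.program[k])
    return len(progs) > 1
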