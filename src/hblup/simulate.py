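"""Synthetic dual-program tree-breeding datasets with a truth log.

The generator emulates the structure the analysis pipeline assumes: two
breeding programs with largely disjoint multigenerational pedigrees founded
on several native races/landraces, a sparse candidate-gene marker panel on
the genotyped parents, and full-sib/half-sib/checklot trial entries spread
over three planting regions with low narrow-sense heritability and
non-trivial dominance for growth.

Race structure follows the Balding–Nichols model: race allele frequencies
are Beta draws around an ancestral frequency with a drift parameter Fst.
Marker inheritance is simulated by gene dropping (each offspring allele is
drawn uniformly from the parent's two, independently per marker — no
linkage, appropriate for a sparse candidate-gene panel).  True breeding
values are polygenic and pedigree-driven: markers inform relationships
only, mirroring how single-step models use G.

All randomness flows from one master seed; per-stage seeds are derived by
stable hashing of the stage name, so identical configurations reproduce
identical datasets byte for byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import MarkerMatrix
from .pedigree import (Pedigree, inbreeding_meuwissen_luo,
                       merge_pedigrees, topo_sort_validate, _from_triples)


def stage_seed(master: int, stage: str) -> int:
    """Derive a deterministic per-stage seed below 2³¹."""
    return (int(master) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _d(**kw):
    return field(default_factory=lambda: dict(kw))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dual-program dataset.

    Defaults are a desk-scale rendition of a pair of commercial programs:
    two programs founded on eight races (a few founders shared, plus
    cryptic duplicates and relatives only the markers can reveal), two
    full-sib generations on top of an open-pollinated first generation,
    trials in three regions with incomplete blocks and row plots, variance
    components giving h² ≈ 0.15 and d² ≈ 0.12 on the standardized scale,
    and cross-region additive correlations of 0.7.
    """

    programs: tuple[str, ...] = ("EG1", "EG2")
    races: tuple[str, ...] = ("STRZ", "FURNX", "NE_TAS", "SE_TAS", "W_TAS",
                              "KI", "W_OTW", "E_OTW")
    fst: float = 0.15
    landrace_sources: dict = field(default_factory=dict)  # race -> {src: w}
    n_markers: int = 2000
    founders_per_program: dict = _d(EG1=40, EG2=32)
    shared_founders: int = 4
    cryptic_founder_pairs: int = 4   # cross-program full-sib founder pairs
    duplicate_founders: int = 6      # same tree recorded under two ids
    op_families_per_program: dict = _d(EG1=14, EG2=12)
    op_progeny_per_family: int = 6
    fullsib_generations: int = 2
    parents_per_generation: dict = _d(EG1=16, EG2=14)
    families_per_generation: dict = _d(EG1=24, EG2=22)
    progeny_per_family: int = 20
    trials_per_family: int = 2
    home_region_bias: float = 0.6   # chance a family is tested in one region
    n_genotyped_selections: dict = _d(EG1=10, EG2=6)
    trials: dict = field(default_factory=lambda: {
        "EG1": {"WA": 2, "GT": 1},
        "EG2": {"WA": 1, "GT": 2, "GIPPS": 2},
    })
    reps_per_trial: int = 4
    iblocks_per_rep: int = 4
    checklots_per_trial: int = 2
    checklot_trees: int = 5
    sigma2_a: float = 1.0
    r_a: float = 0.7
    sigma2_f: float = 0.2
    sigma2_b: float = 0.4
    sigma2_p: float = 0.6
    sigma2_e: float = 4.47
    sigma2_race: float = 0.5
    r_race: float = 0.7          # cross-region correlation of race effects
    sigma2_trial: float = 0.25
    sigma2_checklot: float = 0.25
    genotyped_fraction: float = 0.8
    n_unrelated_genotyped: dict = _d(EG1=8, EG2=4)
    genotype_missing_rate: float = 0.02
    pedigree_error_rate: float = 0.0
    seed: int = 1

    @property
    def regions(self) -> list[str]:
        regs: list[str] = []
        for prog in self.programs:
            for r in self.trials.get(prog, {}):
                if r not in regs:
                    regs.append(r)
        return sorted(regs)

    def additive_covariance(self) -> np.ndarray:
        r = len(self.regions)
        S = np.full((r, r), self.r_a * self.sigma2_a)
        np.fill_diagonal(S, self.sigma2_a)
        return S

    def validate(self) -> None:
        if not 0.0 < self.fst < 1.0:
            # fst == 0 handled as a degenerate branch in founder alleles
            if self.fst != 0.0:
                raise ValueError("fst must be in [0, 1)")
        S = self.additive_covariance()
        if np.any(np.linalg.eigvalsh(S) < -1e-10):
            raise ValueError("additive covariance not positive semidefinite")
        for v in (self.sigma2_f, self.sigma2_b, self.sigma2_p, self.sigma2_e):
            if v < 0:
                raise ValueError("variances must be non-negative")
        if not 0.0 <= self.pedigree_error_rate < 1.0:
            raise ValueError("pedigree_error_rate must be in [0, 1)")


@dataclass
class TruthLog:
    """Ground truth of one simulated dataset, for recovery tests."""

    true_bv: pd.DataFrame            # index id, one column per region
    family_effects: pd.DataFrame     # family, region, effect
    true_pedigree: Pedigree          # pre-corruption
    injected_errors: list            # (child, true_sire, false_sire)
    race_freq: dict                  # race -> allele frequency array
    race_shift: dict                 # race -> additive mean shift
    ancestral_freq: np.ndarray

    def to_json(self, path) -> None:
        out = {
            "true_bv": self.true_bv.reset_index().to_dict(orient="list"),
            "family_effects": self.family_effects.to_dict(orient="list"),
            "injected_errors": self.injected_errors,
            "race_shift": {r: np.asarray(s).tolist()
                           for r, s in self.race_shift.items()},
            "race_freq": {r: f.tolist() for r, f in self.race_freq.items()},
            "ancestral_freq": self.ancestral_freq.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(out, fh)


def simulate_founder_alleles(cfg: SimulationConfig, rng: np.random.Generator
                             ) -> tuple[np.ndarray, dict]:
    """Ancestral and race-specific allele frequencies (Balding–Nichols).

    Race frequencies for marker j are Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst)
    draws around the ancestral p ~ Uniform(0.1, 0.9); a landrace may be a
    weighted mixture of source races.  With Fst = 0 every race equals the
    ancestral frequency.
    """
    m = cfg.n_markers
    anc = rng.uniform(0.1, 0.9, size=m)
    fst = cfg.fst
    race_freq: dict[str, np.ndarray] = {}
    primary = [r for r in cfg.races if r not in cfg.landrace_sources]
    for race in primary:
        if fst == 0.0:
            race_freq[race] = anc.copy()
        else:
            a = anc * (1.0 - fst) / fst
            b = (1.0 - anc) * (1.0 - fst) / fst
            race_freq[race] = rng.beta(a, b)
    for race, mix in cfg.landrace_sources.items():
        tot = sum(mix.values())
        f = np.zeros(m)
        for src, w in mix.items():
            f += (w / tot) * race_freq[src]
        race_freq[race] = f
    return anc, race_freq


@dataclass
class _ProgramStructure:
    pedigree: Pedigree
    generation: dict            # id -> generation index (0 = founder)
    fullsib_parents: dict       # id -> (sire, dam) for bookkeeping


def _founder_ids(cfg: SimulationConfig) -> tuple[dict, dict]:
    """Assign founder ids and races per program, with shared founders."""
    shared = [f"SHARED:F{k + 1}" for k in range(cfg.shared_founders)]
    ids: dict[str, list[str]] = {}
    race_of: dict[str, str] = {}
    races = list(cfg.races)
    for k, sid in enumerate(shared):
        race_of[sid] = races[k % len(races)]
    for prog in cfg.programs:
        n = cfg.founders_per_program[prog]
        own = [f"{prog}:F{k + 1}" for k in range(max(n - len(shared), 0))]
        for k, fid in enumerate(own):
            # skew race composition differently per program
            offset = 0 if prog == cfg.programs[0] else len(races) // 2
            race_of[fid] = races[(k + offset) % len(races)]
        ids[prog] = shared + own
    return ids, race_of


def simulate_breeding_programs(cfg: SimulationConfig
                               ) -> tuple[dict, Pedigree, dict]:
    """Build the two program pedigrees and their joint merge.

    Per program: founders → open-pollinated families (generation 1) →
    full-sib matings among selections (generations 2+).  A configurable
    number of founders is shared across programs.  Returns
    (per-program pedigrees, joint pedigree, metadata).
    """
    cfg.validate()
    rng = np.random.default_rng(stage_seed(cfg.seed, "pedigree"))
    founder_ids, race_of = _founder_ids(cfg)
    # cryptic duplicate founders: the same native tree sampled by both
    # programs under different local ids; the pedigrees never connect them,
    # only their (identical) genetics do
    duplicate_pairs: list[tuple[str, str]] = []
    if cfg.duplicate_founders > 0 and len(cfg.programs) >= 2:
        p1, p2 = cfg.programs[0], cfg.programs[1]
        own1 = [f for f in founder_ids[p1] if f.startswith(f"{p1}:")]
        own2 = [f for f in founder_ids[p2] if f.startswith(f"{p2}:")]
        by_race2: dict[str, list[str]] = {}
        for f in own2:
            by_race2.setdefault(race_of[f], []).append(f)
        for f in own1:
            if len(duplicate_pairs) >= cfg.duplicate_founders:
                break
            pool = by_race2.get(race_of[f])
            if pool:
                duplicate_pairs.append((f, pool.pop()))
    dup_members = {m for pair in duplicate_pairs for m in pair}
    peds: dict[str, Pedigree] = {}
    generation: dict[str, int] = {}
    no_record_all: list[str] = []
    for prog in cfg.programs:
        rows: list[tuple] = []
        founders = founder_ids[prog]
        for fid in founders:
            rows.append((fid, None, None, race_of[fid]))
            generation[fid] = 0
        # generation 1: open-pollinated families (dam known, sire unknown);
        # duplicated mother trees head an OP family in both programs
        n_op = cfg.op_families_per_program[prog]
        priority = dup_members | {f for f in founders
                                  if f.startswith("SHARED:")}
        first = [f for f in founders if f in priority][:n_op]
        rest = [f for f in founders if f not in priority]
        extra = max(min(n_op, len(founders)) - len(first), 0)
        op_dams = first + (list(rng.choice(rest, size=extra, replace=False))
                           if extra else [])
        gen_members: dict[int, list[str]] = {0: list(founders), 1: []}
        for fi, dam in enumerate(op_dams):
            for k in range(cfg.op_progeny_per_family):
                iid = f"{prog}:G1_{fi + 1}_{k + 1}"
                rows.append((iid, None, dam, None))
                generation[iid] = 1
                gen_members[1].append(iid)
        # generations 2+: full-sib factorial matings among a selected
        # parent pool (heavy parent reuse, as in operational programs)
        for g in range(2, 2 + cfg.fullsib_generations):
            nfam = cfg.families_per_generation[prog]
            n_par = min(cfg.parents_per_generation[prog],
                        len(gen_members[g - 1]))
            pool = sorted(rng.choice(gen_members[g - 1], size=n_par,
                                     replace=False))
            max_pairs = len(pool) * (len(pool) - 1) // 2
            if nfam > max_pairs:
                raise ValueError(
                    f"{nfam} families requested but only {max_pairs} parent "
                    f"pairs available in generation {g - 1} of {prog}")
            pairs: set[tuple[str, str]] = set()
            while len(pairs) < nfam:
                s, d = rng.choice(pool, size=2, replace=False)
                pairs.add(tuple(sorted((s, d))))
            gen_members[g] = []
            for fi, (s, d) in enumerate(sorted(pairs)):
                for k in range(cfg.progeny_per_family):
                    iid = f"{prog}:G{g}_{fi + 1}_{k + 1}"
                    rows.append((iid, s, d, None))
                    generation[iid] = g
                    gen_members[g].append(iid)
        # genotyped selections: pedigreed but never planted in a trial
        last = 1 + cfg.fullsib_generations
        sel_pairs = sorted(pairs)
        no_record: list[str] = []
        for k in range(cfg.n_genotyped_selections.get(prog, 0)):
            s, d2 = sel_pairs[k % len(sel_pairs)]
            iid = f"{prog}:SEL{k + 1}"
            rows.append((iid, s, d2, None))
            generation[iid] = last
            no_record.append(iid)
        # unpedigreed genotyped selections ("others")
        for k in range(cfg.n_unrelated_genotyped.get(prog, 0)):
            iid = f"{prog}:X{k + 1}"
            race = list(cfg.races)[k % len(cfg.races)]
            rows.append((iid, None, None, race))
            generation[iid] = 0
            no_record.append(iid)
        ped = topo_sort_validate(
            _from_triples(rows, [prog] * len(rows)))
        peds[prog] = ped
        no_record_all.extend(no_record)
    joint = merge_pedigrees(*[peds[p] for p in cfg.programs])
    meta = {"generation": generation, "race_of_founder": race_of,
            "founder_ids": founder_ids, "no_record": set(no_record_all),
            "duplicate_pairs": duplicate_pairs}
    return peds, joint, meta


def gene_drop(p: Pedigree, founder_haplotypes: dict,
              ancestral_freq: np.ndarray, rng: np.random.Generator,
              race_freq: dict | None = None) -> MarkerMatrix:
    """Drop founder alleles down the pedigree, one allele per parent.

    ``founder_haplotypes`` maps founder id -> (h1, h2) binary arrays.  An
    unknown parent's allele is drawn from a race frequency: open-pollinated
    seed is pollinated within the mother's stand, so when the known parent
    is a founder with a race label the unknown parent uses that race's
    frequency; otherwise the ancestral (base-mixture) frequency.  Returns
    0/1/2 scores for every pedigree member.
    """
    if not p.sorted:
        p = topo_sort_validate(p)
    m = len(ancestral_freq)
    h1 = np.zeros((p.n, m), dtype=np.int8)
    h2 = np.zeros((p.n, m), dtype=np.int8)
    for k in range(p.n):
        iid = p.ids[k]
        if p.is_founder(k):
            if iid in founder_haplotypes:
                h1[k], h2[k] = founder_haplotypes[iid]
            else:
                h1[k] = rng.random(m) < ancestral_freq
                h2[k] = rng.random(m) < ancestral_freq
            continue
        known = max(p.sire[k], p.dam[k])
        unk_freq = ancestral_freq
        if race_freq and known >= 0 and p.is_founder(known):
            race = p.race[known]
            if race in race_freq:
                unk_freq = race_freq[race]
        for hap, par in ((h1, p.sire[k]), (h2, p.dam[k])):
            if par < 0:
                hap[k] = rng.random(m) < unk_freq
            else:
                pick = rng.random(m) < 0.5
                hap[k] = np.where(pick, h1[par], h2[par])
    scores = (h1 + h2).astype(float)
    return MarkerMatrix(list(p.ids), [f"M{j + 1}" for j in range(m)], scores)


def _founder_haplotypes(cfg: SimulationConfig, peds: dict, race_freq: dict,
                        rng: np.random.Generator,
                        duplicate_pairs: list | None = None) -> dict:
    """Binomial founder haplotypes from race frequencies.

    ``cryptic_founder_pairs`` same-race founder pairs per program are made
    full sibs at the genotype level only (dropped from hidden common
    parents), emulating relatives unrecorded in the pedigree.
    """
    haplos: dict[str, tuple] = {}
    for prog, ped in peds.items():
        founders = [ped.ids[k] for k in range(ped.n) if ped.is_founder(k)]
        for fid in founders:
            if fid in haplos:
                continue
            k = ped.index_of(fid)
            race = ped.race[k]
            freq = race_freq.get(race)
            if freq is None:
                freq = np.mean(list(race_freq.values()), axis=0)
            haplos[fid] = (np.asarray(rng.random(len(freq)) < freq, dtype=np.int8),
                           np.asarray(rng.random(len(freq)) < freq, dtype=np.int8))
    # cryptic relatives across programs: pairs of same-race founders, one
    # per program, are regenerated as full sibs of hidden parents — the
    # pedigree records nothing, only the genotypes carry the relationship
    n_pairs = cfg.cryptic_founder_pairs
    if n_pairs > 0 and len(peds) >= 2:
        progs = sorted(peds)
        pools: dict[str, dict[str, list[str]]] = {}
        for prog in progs[:2]:
            ped = peds[prog]
            pool: dict[str, list[str]] = {}
            for k in range(ped.n):
                fid = ped.ids[k]
                if (ped.is_founder(k) and fid.startswith(f"{prog}:")
                        and not fid.split(":")[-1].startswith("X")):
                    pool.setdefault(ped.race[k], []).append(fid)
            pools[prog] = pool
        made = 0
        for race in sorted(set(pools[progs[0]]) & set(pools[progs[1]])):
            a_pool, b_pool = pools[progs[0]][race], pools[progs[1]][race]
            while a_pool and b_pool and made < n_pairs:
                a, b = a_pool.pop(), b_pool.pop()
                freq = race_freq.get(race)
                if freq is None:
                    freq = np.mean(list(race_freq.values()), axis=0)
                hidden = [(np.asarray(rng.random(len(freq)) < freq, np.int8),
                           np.asarray(rng.random(len(freq)) < freq, np.int8))
                          for _ in range(2)]
                for fid in (a, b):
                    g1 = np.where(rng.random(len(freq)) < 0.5,
                                  hidden[0][0], hidden[0][1])
                    g2 = np.where(rng.random(len(freq)) < 0.5,
                                  hidden[1][0], hidden[1][1])
                    haplos[fid] = (g1.astype(np.int8), g2.astype(np.int8))
                made += 1
    # duplicated trees carry literally the same genome in both programs
    for a, b in (duplicate_pairs or []):
        if a in haplos:
            haplos[b] = haplos[a]
    return haplos


def _simulate_true_bv(cfg: SimulationConfig, ped: Pedigree, meta: dict,
                      rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    regions = cfg.regions
    r = len(regions)
    Sa = cfg.additive_covariance()
    La = np.linalg.cholesky(Sa + 1e-12 * np.eye(r))
    # race performance interacts with region: shifts are correlated, not
    # identical, across regions
    Rrace = np.full((r, r), cfg.r_race)
    np.fill_diagonal(Rrace, 1.0)
    Lrace = np.linalg.cholesky(cfg.sigma2_race * Rrace + 1e-12 * np.eye(r))
    race_shift = {race: Lrace @ rng.standard_normal(r)
                  for race in cfg.races}
    race_shift["UNKNOWN_RACE"] = np.zeros(r)
    F = inbreeding_meuwissen_luo(ped)
    bv = np.zeros((ped.n, r))
    # founders first (so cryptic duplicates can be tied), then descendants
    for k in range(ped.n):
        if ped.is_founder(k):
            shift = race_shift.get(ped.race[k] or "UNKNOWN_RACE",
                                   np.zeros(r))
            bv[k] = shift + La @ rng.standard_normal(r)
    for a, b in meta.get("duplicate_pairs", []):
        ia, ib = ped._index.get(a), ped._index.get(b)
        if ia is not None and ib is not None:
            bv[ib] = bv[ia]
    for k in range(ped.n):
        s, d = ped.sire[k], ped.dam[k]
        if s < 0 and d < 0:
            continue
        if s >= 0 and d >= 0:
            mean = 0.5 * (bv[s] + bv[d])
            dk = 0.5 - 0.25 * (F[s] + F[d])
        else:
            # open-pollinated: the unknown parent is an unrelated tree of the
            # mother's stand, so it contributes the mother's race shift (when
            # she is a founder with a race) plus a full parental deviation
            par = max(s, d)
            shift = 0.0
            if ped.is_founder(par) and ped.race[par] in race_shift:
                shift = race_shift[ped.race[par]]
            mean = 0.5 * bv[par] + 0.5 * shift
            dk = 0.75 - 0.25 * F[par]
        bv[k] = mean + np.sqrt(dk) * (La @ rng.standard_normal(r))
    df = pd.DataFrame(bv, index=ped.ids, columns=regions)
    return df, race_shift


def simulate_phenotypes(ped: Pedigree, cfg: SimulationConfig,
                        meta: dict | None = None
                        ) -> tuple[pd.DataFrame, TruthLog]:
    """Trial records with design factors, plus the truth log.

    Each progeny is planted in exactly one trial of its own program; a
    family's progeny are spread over ``trials_per_family`` trials and form
    one row-plot per replicate.  Checklot trees carry fixed entry means and
    no pedigree link.  Phenotype = trial mean + true breeding value (in the
    trial's region) + family effect + incomplete-block + plot + residual.
    """
    if meta is None:
        meta = {"generation": {}}
    rng_bv = np.random.default_rng(stage_seed(cfg.seed, "breeding-values"))
    bv, race_shift = _simulate_true_bv(cfg, ped, meta, rng_bv)
    rng = np.random.default_rng(stage_seed(cfg.seed, "phenotypes"))
    regions = cfg.regions

    # trial network
    trials: dict[str, list[tuple[str, str]]] = {}
    trial_mean: dict[str, float] = {}
    for prog in cfg.programs:
        trials[prog] = []
        for region, cnt in cfg.trials.get(prog, {}).items():
            for t in range(cnt):
                tid = f"{prog}_{region}_T{t + 1}"
                trials[prog].append((tid, region))
                trial_mean[tid] = float(rng.normal(0.0,
                                                   np.sqrt(cfg.sigma2_trial)))

    # group progeny by family (full-sib and OP) per program
    fam_of: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    prog_of_fam: dict[str, str] = {}
    no_record = set(meta.get("no_record", set()))
    for k in range(ped.n):
        s, d = ped.sire[k], ped.dam[k]
        if s < 0 and d < 0:
            continue
        if ped.ids[k] in no_record:
            continue    # genotyped selections are never planted
        if s >= 0 and d >= 0:
            key = "fam:" + "|".join(sorted((ped.ids[s], ped.ids[d])))
        else:
            key = "op:" + ped.ids[max(s, d)]
        iid = ped.ids[k]
        fam_of[iid] = key
        members.setdefault(key, []).append(iid)
        prog_of_fam[key] = ped.program[k]

    fam_effect: dict[tuple, float] = {}
    rows = []
    blocks: dict[tuple, float] = {}
    plots: dict[tuple, float] = {}

    def block_effect(key) -> float:
        if key not in blocks:
            blocks[key] = float(rng.normal(0.0, np.sqrt(cfg.sigma2_b)))
        return blocks[key]

    def plot_effect(key) -> float:
        if key not in plots:
            plots[key] = float(rng.normal(0.0, np.sqrt(cfg.sigma2_p)))
        return plots[key]

    for fam in sorted(members):
        prog = prog_of_fam[fam]
        prog_trials = trials[prog]
        # programs deploy many family batches regionally: with probability
        # home_region_bias a family is tested only in its home region
        if rng.random() < cfg.home_region_bias:
            region_names = sorted({r for _, r in prog_trials})
            weights = np.array([sum(1 for _, r in prog_trials if r == rn)
                                for rn in region_names], dtype=float)
            home = region_names[int(rng.choice(len(region_names),
                                               p=weights / weights.sum()))]
            pool = [t for t in prog_trials if t[1] == home]
        else:
            pool = prog_trials
        k = min(cfg.trials_per_family, len(pool))
        sel = rng.choice(len(pool), size=k, replace=False)
        fam_trials = [pool[i] for i in sel]
        kids = members[fam]
        # one contiguous row-plot per family within each replicate
        fam_block: dict[tuple, int] = {}
        for i, iid in enumerate(kids):
            tid, region = fam_trials[i % len(fam_trials)]
            rep = (i // len(fam_trials)) % cfg.reps_per_trial + 1
            bk = (tid, rep)
            if bk not in fam_block:
                fam_block[bk] = int(rng.integers(1, cfg.iblocks_per_rep + 1))
            ib = fam_block[bk]
            plot_key = (tid, rep, ib, fam)
            fe_key = (fam, region)
            if fe_key not in fam_effect:
                fam_effect[fe_key] = float(
                    rng.normal(0.0, np.sqrt(cfg.sigma2_f)))
            y = (trial_mean[tid] + bv.at[iid, region] + fam_effect[fe_key]
                 + block_effect((tid, rep, ib)) + plot_effect(plot_key)
                 + float(rng.normal(0.0, np.sqrt(cfg.sigma2_e))))
            rows.append((iid, prog, tid, region, rep, ib, f"{fam}",
                         "full-sib" if fam.startswith("fam:") else "half-sib",
                         None, y))

    # checklots: unpedigreed commercial entries, fixed means
    check_mean: dict[str, float] = {}
    ck = 0
    for prog in cfg.programs:
        for tid, region in trials[prog]:
            for c in range(cfg.checklots_per_trial):
                lot = f"{prog}_CK{c + 1}"
                if lot not in check_mean:
                    check_mean[lot] = float(
                        rng.normal(0.0, np.sqrt(cfg.sigma2_checklot)))
                for t in range(cfg.checklot_trees):
                    ck += 1
                    rep = t % cfg.reps_per_trial + 1
                    ib = int(rng.integers(1, cfg.iblocks_per_rep + 1))
                    plot_key = (tid, rep, ib, f"ck:{lot}")
                    y = (trial_mean[tid] + check_mean[lot]
                         + block_effect((tid, rep, ib))
                         + plot_effect(plot_key)
                         + float(rng.normal(0.0, np.sqrt(cfg.sigma2_e))))
                    rows.append((f"CKTREE{ck}", prog, tid, region, rep, ib,
                                 f"ck:{lot}", "checklot", lot, y))

    ph = pd.DataFrame(rows, columns=["tree_id", "program", "trial", "region",
                                     "replicate", "iblock", "plot",
                                     "entry_type", "checklot_id", "VOL"])
    dup = ph.groupby("tree_id")["trial"].nunique()
    if (dup > 1).any():
        raise ValueError("a tree was assigned to more than one trial")
    fam_df = pd.DataFrame(
        [(f, r, e) for (f, r), e in fam_effect.items()],
        columns=["family", "region", "effect"])
    truth = TruthLog(true_bv=bv, family_effects=fam_df, true_pedigree=ped,
                     injected_errors=[], race_freq={}, race_shift=race_shift,
                     ancestral_freq=np.array([]))
    return ph, truth


def inject_pedigree_errors(p: Pedigree, rate: float,
                           rng: np.random.Generator) -> tuple[Pedigree, list]:
    """Replace the sire of a random fraction of non-founders.

    The false sire is a random *unrelated* earlier-born individual (zero
    pedigree relationship with the child), mimicking a recording mix-up
    with an unrelated contemporary; earlier-born keeps the pedigree
    acyclic.  Returns the corrupted pedigree and the log of
    (child, true sire, false sire) swaps.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    ped = p.copy()
    log: list[tuple[str, str, str]] = []
    if rate == 0.0:
        return ped, log
    from .pedigree import build_A_tabular
    A = build_A_tabular(p).values
    candidates = [k for k in range(ped.n) if ped.sire[k] >= 0]
    for k in candidates:
        if rng.random() >= rate:
            continue
        true_sire = ped.sire[k]
        pool = [j for j in range(k)
                if j != true_sire and j != ped.dam[k] and A[k, j] == 0.0]
        if not pool:
            continue
        false_sire = int(pool[int(rng.integers(len(pool)))])
        ped.sire[k] = false_sire
        log.append((ped.ids[k], ped.ids[true_sire], ped.ids[false_sire]))
    ped.sorted = False
    return topo_sort_validate(ped), log


@dataclass
class SyntheticDataset:
    """One simulated dual-program dataset plus ground truth."""

    cfg: SimulationConfig
    pedigrees: dict                     # program -> Pedigree (possibly corrupted)
    pedigree_joint: Pedigree            # merged (possibly corrupted)
    markers: MarkerMatrix               # genotyped individuals only, raw scores
    genotyped: dict                     # program -> list of genotyped ids
    phenotypes: pd.DataFrame
    truth: TruthLog
    meta: dict

    @property
    def genotyped_all(self) -> list[str]:
        out: list[str] = []
        for prog in self.cfg.programs:
            for iid in self.genotyped[prog]:
                if iid not in out:
                    out.append(iid)
        return out

    def write_files(self, outdir) -> None:
        """Emit the text dialects consumed by the pipeline."""
        import os
        os.makedirs(outdir, exist_ok=True)
        for prog, ped in self.pedigrees.items():
            ped.to_frame().to_csv(os.path.join(outdir, f"pedigree_{prog}.csv"),
                                  index=False)
        df = pd.DataFrame(self.markers.scores, columns=self.markers.markers)
        df.insert(0, "id", self.markers.ids)
        df.to_csv(os.path.join(outdir, "genotypes.tsv"), sep="\t", index=False,
                  na_rep="NA")
        self.phenotypes.to_csv(os.path.join(outdir, "phenotypes.csv"),
                               index=False)
        self.truth.to_json(os.path.join(outdir, "truth.json"))


def simulate_dataset(cfg: SimulationConfig | None = None) -> SyntheticDataset:
    """Run the full generator: pedigree, markers, phenotypes, truth log."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    peds, joint, meta = simulate_breeding_programs(cfg)
    rng_alleles = np.random.default_rng(stage_seed(cfg.seed, "founder-alleles"))
    anc, race_freq = simulate_founder_alleles(cfg, rng_alleles)
    rng_drop = np.random.default_rng(stage_seed(cfg.seed, "gene-drop"))
    haplos = _founder_haplotypes(cfg, peds, race_freq, rng_drop,
                                 duplicate_pairs=meta.get("duplicate_pairs"))
    full_mm = gene_drop(joint, haplos, anc, rng_drop, race_freq=race_freq)

    # genotyped set: a fraction of progeny-tested parents + the "others"
    rng_sel = np.random.default_rng(stage_seed(cfg.seed, "genotyping"))
    genotyped: dict[str, list[str]] = {}
    for prog, ped in peds.items():
        parents = sorted({ped.ids[s] for s in ped.sire if s >= 0}
                         | {ped.ids[d] for d in ped.dam if d >= 0})
        parents = [p_ for p_ in parents
                   if not joint.is_founder(joint.index_of(p_))]
        n_g = int(round(cfg.genotyped_fraction * len(parents)))
        chosen = sorted(rng_sel.choice(parents, size=n_g, replace=False)) \
            if n_g else []
        extras = [i for i in ped.ids
                  if i.split(":")[-1].startswith(("X", "SEL"))]
        genotyped[prog] = list(chosen) + extras

    all_g = []
    for prog in cfg.programs:
        for iid in genotyped[prog]:
            if iid not in all_g:
                all_g.append(iid)
    mm = full_mm.subset_ids(all_g)
    # sprinkle missingness so QC/imputation is exercised
    if cfg.genotype_missing_rate > 0:
        rng_miss = np.random.default_rng(stage_seed(cfg.seed, "missingness"))
        mask = rng_miss.random(mm.scores.shape) < cfg.genotype_missing_rate
        scores = mm.scores.copy()
        scores[mask] = np.nan
        mm = MarkerMatrix(mm.ids, mm.markers, scores)

    ph, truth = simulate_phenotypes(joint, cfg, meta)
    truth.race_freq = race_freq
    truth.ancestral_freq = anc

    peds_out, joint_out = peds, joint
    if cfg.pedigree_error_rate > 0:
        rng_err = np.random.default_rng(stage_seed(cfg.seed, "pedigree-errors"))
        joint_out, log = inject_pedigree_errors(joint, cfg.pedigree_error_rate,
                                                rng_err)
        truth.injected_errors = log
        peds_out = {}
        for prog, ped in peds.items():
            keep = set(ped.ids)
            sub_rows = []
            for k in range(joint_out.n):
                iid = joint_out.ids[k]
                if iid in keep:
                    s, d = joint_out.parents_of(iid)
                    sub_rows.append((iid, s if s in keep else None,
                                     d if d in keep else None,
                                     joint_out.race[k]))
            peds_out[prog] = topo_sort_validate(
                _from_triples(sub_rows, [prog] * len(sub_rows)))

    return SyntheticDataset(cfg=cfg, pedigrees=peds_out,
                            pedigree_joint=joint_out, markers=mm,
                            genotyped=genotyped, phenotypes=ph, truth=truth,
                            meta=meta)
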