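"""Forward-in-time simulator for a three-way pig crossbreeding scheme.

Three purebred lines (a paternal synthetic boar line S and two maternal
lines LR, LW) are derived from a common ancestral population by pure
drift, then crossed as S x (LR x LW) to produce three-way crossbreds
(CB) with recorded litter structure and known breed-of-origin of every
crossbred allele.  Phenotypes for purebred (PB) and crossbred
performance are generated from breed-specific QTL effects so that the
purebred-crossbred genetic correlation (r_pc) is directly controlled
per breed.

Divergence between the lines is pure drift (no mutation or selection):
the number of drift generations is derived from the target Weir &
Cockerham F_ST via E[F_ST] ~ 1 - (1 - 1/2Ne)^T.  Recombination follows
a uniform genetic map with Poisson crossover counts per Morgan and no
interference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PURE_BREEDS = ("S", "LR", "LW")
ORIGIN_CODES = {"S": 0, "LR": 1, "LW": 2}
ORIGIN_NAMES = {v: k for k, v in ORIGIN_CODES.items()}
UNASSIGNED = -1


@dataclass
class TraitConfig:
    """Targets for one simulated trait.

    h2_pb / h2_cb are narrow-sense heritabilities on the purebred and
    crossbred scales; rpc is the purebred-crossbred genetic correlation
    per breed-of-origin; litter_fraction is the share of phenotypic
    variance due to the common litter environment.
    """

    name: str = "ADG"
    h2_pb: float = 0.30
    h2_cb: float = 0.35
    rpc: dict = field(default_factory=lambda: {"S": 0.5, "LR": 0.3, "LW": 0.6})
    litter_fraction: float = 0.10
    covariate_slope: float = 0.3  # in phenotypic-SD units
    fixed_effect_sd: float = 0.5  # factor-level SD, phenotypic-SD units

    def validate(self) -> None:
        if not 0 < self.h2_pb < 1 or not 0 < self.h2_cb < 1:
            raise ValueError("heritabilities must be in (0, 1)")
        if not 0 <= self.litter_fraction < 1:
            raise ValueError("litter_fraction must be in [0, 1)")
        if self.h2_pb + self.litter_fraction >= 1:
            raise ValueError(f"h2_pb + litter_fraction >= 1 for trait {self.name}")
        if self.h2_cb + self.litter_fraction >= 1:
            raise ValueError(f"h2_cb + litter_fraction >= 1 for trait {self.name}")
        for b, r in self.rpc.items():
            if abs(r) > 1:
                raise ValueError(f"|rpc| > 1 for breed {b}")


@dataclass
class SimConfig:
    n_founders: int = 60            # per-breed effective size during drift
    n_generations_divergence: int | None = None  # None: derived from target_fst
    n_loci: int = 1200
    n_chromosomes: int = 3
    chromosome_length: float = 1.0  # Morgans
    target_fst: float = 0.15
    n_pb: int = 200                 # genotyped+phenotyped purebreds per breed
    n_sires_s: int = 25
    n_dams_f1: int = 60
    n_f1_grandsires: int = 10       # maternal-breed sires of the F1, per breed
    n_f1_granddams: int = 20        # maternal-breed dams of the F1, per breed
    litter_size: int = 6
    n_cb: int = 300
    n_cb_extra: int = 50            # phenotyped, not genotyped
    qtl_count: int = 200
    traits: list = field(default_factory=lambda: [TraitConfig()])
    n_farms: int = 4
    n_trials: int = 3
    seed: int = 1

    def validate(self) -> None:
        counts = [self.n_founders, self.n_loci, self.n_chromosomes, self.n_pb,
                  self.n_sires_s, self.n_dams_f1, self.litter_size, self.n_cb,
                  self.qtl_count, self.n_farms, self.n_trials]
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if self.n_cb_extra < 0:
            raise ValueError("n_cb_extra must be >= 0")
        if not 0 <= self.target_fst < 1:
            raise ValueError("target_fst must be in [0, 1)")
        if self.qtl_count > self.n_loci:
            raise ValueError("qtl_count > n_loci")
        for t in self.traits:
            t.validate()

    def drift_generations(self) -> int:
        if self.n_generations_divergence is not None:
            return self.n_generations_divergence
        if self.target_fst == 0:
            return 0
        # E[F_ST] after T generations of drift at size Ne:
        #   1 - (1 - 1/(2 Ne))^T
        per_gen = 1.0 - 1.0 / (2 * self.n_founders)
        return max(1, round(math.log(1.0 - self.target_fst) / math.log(per_gen)))


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: individuals x loci x {paternal, maternal}."""

    ids: list
    breeds: np.ndarray              # per-individual population label
    chrom: np.ndarray               # per-locus chromosome (1-based)
    pos: np.ndarray                 # per-locus genetic position (Morgans)
    haplo: np.ndarray               # (n_ind, n_loci, 2) int8 in {0, 1}

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n_ind(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.haplo.shape[1]

    def dosage(self) -> np.ndarray:
        return self.haplo.sum(axis=2).astype(np.float64)

    def row(self, ind_id) -> int:
        return self._index[ind_id]

    def subset(self, ids) -> "HaplotypePanel":
        rows = [self._index[i] for i in ids]
        return HaplotypePanel(list(ids), self.breeds[rows], self.chrom,
                              self.pos, self.haplo[rows])

    def chromosome_slices(self):
        for c in np.unique(self.chrom):
            idx = np.flatnonzero(self.chrom == c)
            yield int(c), idx[0], idx[-1] + 1


@dataclass
class TrueOrigins:
    ids: list
    codes: np.ndarray  # (n_cb, n_loci, 2) int8 with ORIGIN_CODES values

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}

    def row(self, ind_id) -> int:
        return self._index[ind_id]


def _genetic_map(config: SimConfig):
    """Evenly spaced loci on n_chromosomes of chromosome_length Morgans."""
    per_chrom = np.full(config.n_chromosomes, config.n_loci // config.n_chromosomes)
    per_chrom[: config.n_loci % config.n_chromosomes] += 1
    chrom, pos = [], []
    for c, n in enumerate(per_chrom, start=1):
        chrom.append(np.full(n, c))
        pos.append(np.linspace(0.0, config.chromosome_length, n, endpoint=False))
    return np.concatenate(chrom), np.concatenate(pos)


def _meiosis(haplo_ind, chrom, pos, length, rng, with_source=False):
    """One gamete from a diploid parent; Poisson crossovers, no interference.

    Returns the gamete and, optionally, which parental gamete (0/1) each
    allele was copied from.
    """
    n_loci = haplo_ind.shape[0]
    source = np.empty(n_loci, dtype=np.int8)
    for c in np.unique(chrom):
        sel = chrom == c
        p = pos[sel]
        n_x = rng.poisson(length)
        start = rng.integers(2)
        if n_x == 0:
            source[sel] = start
        else:
            xpos = np.sort(rng.uniform(0.0, length, n_x))
            source[sel] = (start + np.searchsorted(xpos, p, side="right")) % 2
    gamete = haplo_ind[np.arange(n_loci), source]
    if with_source:
        return gamete, source
    return gamete


def simulate_founders(config: SimConfig, rng=None):
    """Drift three purebred lines apart from a common ancestral pool.

    Returns the purebred panel (the final, pedigree-recorded generation
    of each line plus its parents), the pedigree, and the realized
    pairwise Weir-Cockerham F_ST.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    chrom, pos = _genetic_map(config)
    n_loci = config.n_loci
    p0 = rng.uniform(0.1, 0.9, n_loci)
    T = config.drift_generations()

    ids, breeds, haplos, ped_rows = [], [], [], []
    length = config.chromosome_length
    for breed in PURE_BREEDS:
        ne = config.n_founders
        pool = (rng.uniform(size=(ne, n_loci, 2)) < p0[None, :, None]).astype(np.int8)
        for _ in range(T):
            nxt = np.empty_like(pool)
            for i in range(ne):
                s, d = rng.choice(ne, size=2, replace=False)
                nxt[i, :, 0] = _meiosis(pool[s], chrom, pos, length, rng)
                nxt[i, :, 1] = _meiosis(pool[d], chrom, pos, length, rng)
            pool = nxt
        # final recorded generation: n_pb animals in full-sib litters
        n_litters = math.ceil(config.n_pb / config.litter_size)
        parents_used = {}
        k = 0
        for lit in range(n_litters):
            s, d = rng.choice(ne, size=2, replace=False)
            sid = parents_used.setdefault(("s", s), f"{breed}_F{s}")
            did = parents_used.setdefault(("d", d), f"{breed}_M{d}")
            for _ in range(config.litter_size):
                if k >= config.n_pb:
                    break
                iid = f"{breed}_{k}"
                hap = np.empty((n_loci, 2), dtype=np.int8)
                hap[:, 0] = _meiosis(pool[s], chrom, pos, length, rng)
                hap[:, 1] = _meiosis(pool[d], chrom, pos, length, rng)
                ids.append(iid)
                breeds.append(breed)
                haplos.append(hap)
                sex = "M" if k % 2 == 0 else "F"
                ped_rows.append((iid, sid, did, breed, f"{breed}_L{lit}", sex, 1))
                k += 1
        for (_, _), pid in sorted(parents_used.items(), key=lambda kv: kv[1]):
            sex = "M" if pid.split("_")[1].startswith("F") else "F"
            ped_rows.append((pid, "0", "0", breed, "0", sex, 0))

    panel = HaplotypePanel(ids, np.array(breeds, dtype=object), chrom, pos,
                           np.stack(haplos))
    pedigree = pd.DataFrame(ped_rows, columns=["id", "sire", "dam", "breed",
                                               "litter", "sex", "generation"])
    pedigree = pedigree.sort_values(["generation", "id"], kind="stable",
                                    ignore_index=True)
    fst = {}
    for i, a in enumerate(PURE_BREEDS):
        for b in PURE_BREEDS[i + 1:]:
            fst[(a, b)] = weir_cockerham_fst(panel, (a, b))
    if config.target_fst > 0 and T > 0:
        vals = [v for v in fst.values() if np.isfinite(v)]
        if vals and (min(vals) < 0.2 * config.target_fst
                     or max(vals) > 5 * config.target_fst):
            raise RuntimeError(
                f"target F_ST {config.target_fst} not reached within "
                f"{T} drift generations; achieved {fst}")
    return panel, pedigree, fst


def mate_three_way_cross(panel: HaplotypePanel, pedigree: pd.DataFrame,
                         config: SimConfig, rng=None):
    """Produce F1 (LR x LW, both directions) and CB = S sire x F1 dam.

    Breed-of-origin of every CB allele is recorded through gamete
    transmission: the paternal gamete is purebred S; the maternal gamete
    is a recombinant of the F1 dam's LR and LW gametes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    chrom, pos, length = panel.chrom, panel.pos, config.chromosome_length
    n_loci = panel.n_loci
    by_breed = {b: [i for i, br in zip(panel.ids, panel.breeds) if br == b]
                for b in PURE_BREEDS}
    sexes = dict(zip(pedigree["id"], pedigree["sex"]))

    def _pick(breed, sex, n):
        cand = [i for i in by_breed[breed] if sexes[i] == sex]
        if len(cand) == 0:
            raise ValueError(f"no {sex} {breed} parents available")
        return rng.choice(cand, size=n, replace=n > len(cand))

    # --- F1 dams ---
    # grandparents are drawn from small pools and reused, as in practice:
    # this is what gives maternal-line purebreds several F1 daughters and
    # hence informative crossbred grand-offspring groups
    n_f1 = config.n_dams_f1
    f1_ids, f1_hap, f1_src_breed, ped_rows = [], [], [], []
    ngs, ngd = config.n_f1_grandsires, config.n_f1_granddams
    lr_sires = _pick("LR", "M", ngs)
    lw_dams = _pick("LW", "F", ngd)
    lw_sires = _pick("LW", "M", ngs)
    lr_dams = _pick("LR", "F", ngd)
    for k in range(n_f1):
        j = k // 2
        if k % 2 == 0:
            sire, dam = lr_sires[j % ngs], lw_dams[j % ngd]
            sb, db = "LR", "LW"
        else:
            sire, dam = lw_sires[j % ngs], lr_dams[j % ngd]
            sb, db = "LW", "LR"
        hap = np.empty((n_loci, 2), dtype=np.int8)
        hap[:, 0] = _meiosis(panel.haplo[panel.row(sire)], chrom, pos, length, rng)
        hap[:, 1] = _meiosis(panel.haplo[panel.row(dam)], chrom, pos, length, rng)
        iid = f"F1_{k}"
        f1_ids.append(iid)
        f1_hap.append(hap)
        f1_src_breed.append((ORIGIN_CODES[sb], ORIGIN_CODES[db]))
        ped_rows.append((iid, sire, dam, "F1", f"F1_L{k}", "F", 2))

    # --- CB litters ---
    n_total = config.n_cb + config.n_cb_extra
    if config.n_sires_s * n_f1 * config.litter_size < n_total:
        raise ValueError("insufficient parents for requested number of CB")
    sires_s = _pick("S", "M", config.n_sires_s)
    cb_ids, cb_hap, cb_orig, k, lit = [], [], [], 0, 0
    while k < n_total:
        sire = sires_s[lit % config.n_sires_s]
        dam_k = int(rng.integers(n_f1))
        dam_id = f1_ids[dam_k]
        for _ in range(config.litter_size):
            if k >= n_total:
                break
            hap = np.empty((n_loci, 2), dtype=np.int8)
            orig = np.empty((n_loci, 2), dtype=np.int8)
            hap[:, 0] = _meiosis(panel.haplo[panel.row(sire)], chrom, pos, length, rng)
            orig[:, 0] = ORIGIN_CODES["S"]
            gam, src = _meiosis(f1_hap[dam_k], chrom, pos, length, rng,
                                with_source=True)
            hap[:, 1] = gam
            pat_code, mat_code = f1_src_breed[dam_k]
            orig[:, 1] = np.where(src == 0, pat_code, mat_code)
            iid = f"CB_{k}"
            cb_ids.append(iid)
            cb_hap.append(hap)
            cb_orig.append(orig)
            sex = "M" if k % 2 == 0 else "F"
            ped_rows.append((iid, sire, dam_id, "CB", f"CB_L{lit}", sex, 3))
            k += 1
        lit += 1

    all_ids = list(panel.ids) + f1_ids + cb_ids
    all_breeds = np.concatenate([panel.breeds,
                                 np.array(["F1"] * n_f1, dtype=object),
                                 np.array(["CB"] * len(cb_ids), dtype=object)])
    all_hap = np.concatenate([panel.haplo, np.stack(f1_hap), np.stack(cb_hap)])
    full_panel = HaplotypePanel(all_ids, all_breeds, chrom, pos, all_hap)
    origins = TrueOrigins(cb_ids, np.stack(cb_orig))
    ped_new = pd.DataFrame(ped_rows, columns=pedigree.columns)
    full_ped = pd.concat([pedigree, ped_new], ignore_index=True)
    return full_panel, origins, full_ped


def check_mendelian(panel: HaplotypePanel, pedigree: pd.DataFrame) -> bool:
    """Every non-founder allele must occur in the designated parent."""
    in_panel = set(panel.ids)
    for _, row in pedigree.iterrows():
        if row["id"] not in in_panel:
            continue
        child = panel.haplo[panel.row(row["id"])]
        for g, parent in enumerate((row["sire"], row["dam"])):
            if parent == "0" or parent not in in_panel:
                continue
            phap = panel.haplo[panel.row(parent)]
            ok = (child[:, g] == phap[:, 0]) | (child[:, g] == phap[:, 1])
            if not ok.all():
                return False
    return True


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class TraitTruth:
    """Generating components of one simulated trait, for recovery tests.

    K2 maps breed -> 2x2 covariance of (PB additive value, CB-performance
    additive value) realized over that breed's purebreds; these are the
    variance components of the breed-of-origin model on the scale of a
    relationship-matrix diagonal of 1.
    """

    name: str
    K2: dict
    var_cb_total: float
    var_cb_parts: dict
    litter_var: dict      # population -> sigma^2_u
    resid_var: dict       # population -> sigma^2_e
    pheno_var: dict
    qtl_loci: np.ndarray
    effects_pb: dict      # breed -> per-QTL PB effects
    effects_cb: dict      # breed -> per-QTL CB effects


def simulate_phenotypes(panel: HaplotypePanel, origins: TrueOrigins,
                        pedigree: pd.DataFrame, config: SimConfig, rng=None):
    """Generate PB and CB phenotypes from breed-specific QTL effects.

    For each breed, per-QTL (PB effect, CB effect) pairs are drawn from a
    bivariate standard normal with correlation rpc[breed].  A purebred's
    phenotype sums its dosages times its breed's PB effects; a crossbred's
    genetic value sums, over alleles, the CB effect of the allele's
    breed-of-origin.  Litter and residual variances are scaled so the
    realized heritabilities match the configured targets.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    ped = pedigree.set_index("id")
    truths = {}
    pb_rows = {b: [k for k, br in enumerate(panel.breeds) if br == b]
               for b in PURE_BREEDS}
    cb_rows = [k for k, br in enumerate(panel.breeds) if br == "CB"]
    cb_ids = [panel.ids[k] for k in cb_rows]
    dosage = panel.dosage()

    poly = dosage.std(axis=0) > 0
    if poly.sum() < config.qtl_count:
        raise ValueError("not enough polymorphic loci for requested QTL count")
    qtl = rng.choice(np.flatnonzero(poly), size=config.qtl_count, replace=False)
    qtl.sort()

    base = pd.DataFrame({
        "id": panel.ids,
        "population": ["CB" if b == "CB" else b for b in panel.breeds],
        "litter": [ped.loc[i, "litter"] for i in panel.ids],
        "sex": [ped.loc[i, "sex"] for i in panel.ids],
    })
    base["farm"] = rng.integers(config.n_farms, size=len(base))
    base["trial"] = rng.integers(config.n_trials, size=len(base))
    phenotyped = base["population"].isin(list(PURE_BREEDS) + ["CB"])
    base = base[phenotyped].reset_index(drop=True)

    out = base.copy()
    for tc in config.traits:
        eff_pb, eff_cb = {}, {}
        for b in PURE_BREEDS:
            r = tc.rpc.get(b, 0.0)
            cov = np.array([[1.0, r], [r, 1.0]])
            pair = rng.multivariate_normal(np.zeros(2), cov, size=len(qtl))
            eff_pb[b], eff_cb[b] = pair[:, 0].copy(), pair[:, 1].copy()

        tbv_pb = np.zeros(panel.n_ind)
        tbv_cb = np.zeros(panel.n_ind)
        for b in PURE_BREEDS:
            rows = pb_rows[b]
            tbv_pb[rows] = dosage[np.ix_(rows, qtl)] @ eff_pb[b]
            tbv_cb[rows] = dosage[np.ix_(rows, qtl)] @ eff_cb[b]
        parts = {b: np.zeros(len(cb_rows)) for b in PURE_BREEDS}
        for b in PURE_BREEDS:
            code = ORIGIN_CODES[b]
            for g in (0, 1):
                sel = origins.codes[:, qtl, g] == code
                alle = panel.haplo[np.ix_(cb_rows, qtl)][:, :, g]
                parts[b] += (alle * sel) @ eff_cb[b]
        cb_total = sum(parts.values())
        tbv_cb[cb_rows] = cb_total

        K2, var_parts = {}, {}
        for b in PURE_BREEDS:
            rows = pb_rows[b]
            K2[b] = np.cov(np.vstack([tbv_pb[rows], tbv_cb[rows]]))
            var_parts[b] = float(np.var(parts[b], ddof=1))
        var_cb_total = float(np.var(cb_total, ddof=1))

        litter_var, resid_var, pheno_var = {}, {}, {}
        for popn in list(PURE_BREEDS) + ["CB"]:
            if popn == "CB":
                va, h2 = var_cb_total, tc.h2_cb
            else:
                va, h2 = float(K2[popn][0, 0]), tc.h2_pb
            vp = va / h2
            vu = tc.litter_fraction * vp
            ve = vp - va - vu
            if ve <= 0:
                raise ValueError(
                    f"infeasible h2 for {popn}/{tc.name}: residual variance <= 0")
            litter_var[popn], resid_var[popn], pheno_var[popn] = vu, ve, vp

        y = np.full(len(out), np.nan)
        fix_part = np.full(len(out), np.nan)
        lit_part = np.full(len(out), np.nan)
        res_part = np.full(len(out), np.nan)
        cov_col = rng.normal(size=len(out))
        litter_effects = {}
        farm_eff = {}
        trial_eff = {}
        for k in range(len(out)):
            popn = out.loc[k, "population"]
            vp = pheno_var[popn]
            sd = math.sqrt(vp)
            if popn == "CB":
                key_t = ("trial", out.loc[k, "trial"], popn)
                key_f = ("farm_sex", out.loc[k, "farm"], out.loc[k, "sex"], popn)
                fx = trial_eff.setdefault(key_t, rng.normal(0, tc.fixed_effect_sd * sd))
                fx += farm_eff.setdefault(key_f, rng.normal(0, tc.fixed_effect_sd * sd))
            else:
                key_f = ("farm_breed_sex", out.loc[k, "farm"], popn,
                         out.loc[k, "sex"])
                fx = farm_eff.setdefault(key_f, rng.normal(0, tc.fixed_effect_sd * sd))
            lit = out.loc[k, "litter"]
            le = litter_effects.setdefault(
                lit, rng.normal(0, math.sqrt(litter_var[popn])))
            idx = panel.row(out.loc[k, "id"])
            gv = tbv_cb[idx] if popn == "CB" else tbv_pb[idx]
            res = rng.normal(0, math.sqrt(resid_var[popn]))
            fix_part[k] = fx + tc.covariate_slope * sd * cov_col[k]
            lit_part[k] = le
            res_part[k] = res
            y[k] = fix_part[k] + le + gv + res

        out[f"y_{tc.name}"] = y
        out[f"cov_{tc.name}"] = cov_col
        out[f"fix_{tc.name}"] = fix_part
        out[f"lit_{tc.name}"] = lit_part
        out[f"res_{tc.name}"] = res_part
        out[f"tbv_pb_{tc.name}"] = [tbv_pb[panel.row(i)] for i in out["id"]]
        out[f"tbv_cb_{tc.name}"] = [tbv_cb[panel.row(i)] for i in out["id"]]
        truths[tc.name] = TraitTruth(tc.name, K2, var_cb_total, var_parts,
                                     litter_var, resid_var, pheno_var, qtl,
                                     eff_pb, eff_cb)
    return out, truths


# ---------------------------------------------------------------------------
# Dataset bundle
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimConfig
    panel: HaplotypePanel          # PB + F1 + CB
    pedigree: pd.DataFrame
    origins: TrueOrigins
    phenotypes: pd.DataFrame
    truths: dict
    realized_fst: dict
    genotyped: set                 # ids with usable genotypes

    @property
    def cb_ids(self):
        return list(self.origins.ids)

    def genotyped_ids(self):
        return [i for i in self.panel.ids if i in self.genotyped]


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: founders, cross, phenotypes."""
    rng = np.random.default_rng(config.seed)
    pb_panel, pedigree, fst = simulate_founders(config, rng)
    panel, origins, pedigree = mate_three_way_cross(pb_panel, pedigree, config, rng)
    phenos, truths = simulate_phenotypes(panel, origins, pedigree, config, rng)
    # the last n_cb_extra crossbreds are phenotyped but not genotyped,
    # mirroring the extra records used only in the validation EBV step
    extra = set(origins.ids[config.n_cb:])
    genotyped = {i for i, b in zip(panel.ids, panel.breeds)
                 if b in PURE_BREEDS or (b == "CB" and i not in extra)}
    return SimulatedDataset(config, panel, pedigree, origins, phenos, truths,
                            fst, genotyped)


def simulate_hwe_population(n_ind: int, n_loci: int, seed: int = 0,
                            freq_range=(0.1, 0.9)) -> HaplotypePanel:
    """One random-mating population in Hardy-Weinberg equilibrium."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, n_loci)
    hap = (rng.uniform(size=(n_ind, n_loci, 2)) < p[None, :, None]).astype(np.int8)
    chrom = np.ones(n_loci, dtype=int)
    pos = np.linspace(0, 1, n_loci, endpoint=False)
    return HaplotypePanel([f"I{k}" for k in range(n_ind)],
                          np.array(["POP"] * n_ind, dtype=object),
                          chrom, pos, hap)


# ---------------------------------------------------------------------------
# Weir & Cockerham F_ST
# ---------------------------------------------------------------------------

def weir_cockerham_fst(panel: HaplotypePanel, breed_pair) -> float:
    """Multi-locus Weir-Cockerham theta (ratio of sums over loci).

    Returns NaN when every locus is monomorphic across both populations.
    """
    pops = []
    for b in breed_pair:
        rows = [k for k, br in enumerate(panel.breeds) if br == b]
        if len(rows) < 2:
            raise ValueError(f"need >= 2 individuals in breed {b}")
        pops.append(panel.haplo[rows])
    r = 2
    n_i = np.array([h.shape[0] for h in pops], dtype=float)  # diploids
    p_i = np.stack([h.mean(axis=(0, 2)) for h in pops])      # allele freqs
    h_i = np.stack([(h[:, :, 0] != h[:, :, 1]).mean(axis=0) for h in pops])

    nbar = n_i.mean()
    nc = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
    pbar = (n_i[:, None] * p_i).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n_i[:, None] * h_i).sum(axis=0) / (r * nbar)

    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
                       / (nbar - 1))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                               - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    denom = (a + b + c).sum()
    if denom == 0:
        warnings.warn("all loci monomorphic across both populations; "
                      "F_ST undefined")
        return float("nan")
    return float(a.sum() / denom)
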