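"""Forward-in-time, spatially explicit simulator of a small snake population.

The generative model mirrors the biology the analysis pipeline targets:

* founders scattered uniformly over a square arena, Hardy-Weinberg genotypes
  at Beta-distributed allele frequencies;
* overlapping generations with yearly reproduction: each mature female
  (optionally on a biennial schedule) first draws whether she produces any
  offspring this year (logit-linear in her true inbreeding F), then a
  negative-binomial litter, choosing a sire among males within the mating
  radius with weight exp(-d^2 / (2 r^2)) — proximity-based, nonrandom mating;
* Mendelian transmission at unlinked biallelic loci;
* natal dispersal: offspring settle at the dam's location plus Gaussian
  displacement, and occupy that single location for life (the downstream
  analysis collapses recaptures to centroids anyway);
* von Bertalanffy growth in body length (SVL), survival logit-linear in true
  pedigree F and standardized SVL — inbreeding depression on survival;
* annual surveys with imperfect detection and a trap-response shift for
  adult females captured as adults two years earlier.

The "true" inbreeding driving fitness is the pedigree-path coefficient
(kinship of the parents), maintained exactly via the recursive kinship
update as individuals are born; the genomic estimator F_grm can then be
validated against it.  Everything is driven by one seeded generator, so
runs are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class SimulationConfig:
    """Generating parameters; defaults emulate one study deme.

    Spatial units are meters, lengths cm, rates per year.  ``beta_*`` are
    logit-scale slopes; ``beta_F_survival`` < 0 and ``beta_F_zero`` > 0
    produce inbreeding depression on survival and on the probability of
    producing any offspring, respectively.
    """

    n_founders: int = 200
    n_loci: int = 1500
    founder_maf_dist: tuple = (1.5, 1.5)  # Beta(a, b) on allele frequency
    arena_size_m: float = 1500.0
    dispersal_sd_m: float = 40.0
    mating_radius_m: float = 250.0
    years: int = 12
    base_survival_logit: float = 1.1
    beta_F_survival: float = -3.0
    beta_svl_survival: float = 0.5
    base_zero_logit: float = 0.4
    beta_F_zero: float = 3.0
    litter_mean: float = 4.0
    litter_dispersion: float = 2.0
    age_maturity_yr: int = 3
    female_biennial: bool = True
    detection_prob: float = 0.35
    trap_response_delta: float = -0.8
    growth_Linf_cm: float = 66.0
    growth_K: float = 0.5
    svl_birth_cm: float = 19.0
    svl_noise_sd_cm: float = 1.0
    seed: int = 0
    site: str = "A"
    id_prefix: str = ""
    max_individuals: int = 20000
    # fixed reference used to standardize SVL inside the survival logit
    svl_ref_center_cm: float = 45.0
    svl_ref_scale_cm: float = 15.0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.dispersal_sd_m < 0:
            raise ValueError("dispersal_sd_m must be >= 0")
        if self.litter_dispersion <= 0:
            raise ValueError("litter_dispersion must be > 0")
        if not self.svl_birth_cm < self.growth_Linf_cm:
            raise ValueError("svl_birth_cm must be below growth_Linf_cm")
        if not (0 < self.detection_prob < 1):
            raise ValueError("detection_prob must be in (0, 1)")


@dataclass
class SimulatedDataset:
    """Complete truth emitted by one simulator run."""

    genotypes: GenotypeMatrix
    pedigree: Pedigree
    true_f_pedigree: pd.Series
    locations: pd.DataFrame
    captures: pd.DataFrame
    config: SimulationConfig
    extinct: bool = False
    years_completed: int = 0
    litter_sizes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def surveyed_years(self) -> dict:
        yr0 = 2000
        return {self.config.site: list(range(yr0, yr0 + self.years_completed))}


def _svl_at_age(cfg: SimulationConfig, age) -> np.ndarray:
    return cfg.growth_Linf_cm - (cfg.growth_Linf_cm - cfg.svl_birth_cm) * np.exp(
        -cfg.growth_K * np.asarray(age, dtype=float)
    )


def simulate_population(config: SimulationConfig) -> SimulatedDataset:
    """Run the forward simulation and return genotypes, pedigree, truth.

    Occasion structure within a simulated year: births, then the survey
    (newborns can be detected in their birth year), then survival to the
    next year.  Population extinction before the horizon is reported via the
    ``extinct`` flag with the partial dataset, not an exception.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    a, b = cfg.founder_maf_dist
    freqs = rng.beta(a, b, size=cfg.n_loci)
    yr0 = 2000

    # growing per-individual state
    genotypes: list[np.ndarray] = []
    dam: list[int] = []  # -1 = founder
    sire: list[int] = []
    sex: list[str] = []
    birth_year: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    fcoef: list[float] = []
    death_year: dict[int, int] = {}

    # kinship among all individuals ever created (block-grown)
    cap = max(4 * cfg.n_founders, 256)
    K = np.zeros((cap, cap))

    def grow(n_new: int) -> None:
        nonlocal K, cap
        need = len(dam) + n_new
        if need > cap:
            newcap = max(cap * 2, need)
            K2 = np.zeros((newcap, newcap))
            K2[: len(dam), : len(dam)] = K[: len(dam), : len(dam)]
            K, cap = K2, newcap

    def add_individual(d: int, s: int, g: np.ndarray, x: float, y: float, byr: int, sx: str) -> int:
        i = len(dam)
        if i + 1 > cfg.max_individuals:
            raise RuntimeError(
                f"population exceeded max_individuals={cfg.max_individuals}"
            )
        grow(1)
        if d >= 0 and s >= 0:
            row = 0.5 * (K[d, :i] + K[s, :i])
            f = K[d, s]
        else:
            row = np.zeros(i)
            f = 0.0
        K[i, :i] = row
        K[:i, i] = row
        K[i, i] = 0.5 * (1.0 + f)
        dam.append(d)
        sire.append(s)
        genotypes.append(g)
        xs.append(x)
        ys.append(y)
        birth_year.append(byr)
        sex.append(sx)
        fcoef.append(float(f))
        return i

    # founders: uniform locations, HWE genotypes, adult at year 0
    for _ in range(cfg.n_founders):
        g = rng.binomial(2, freqs).astype(np.int8)
        add_individual(
            -1,
            -1,
            g,
            float(rng.uniform(0, cfg.arena_size_m)),
            float(rng.uniform(0, cfg.arena_size_m)),
            yr0 - cfg.age_maturity_yr,
            "F" if rng.random() < 0.5 else "M",
        )

    alive = set(range(cfg.n_founders))
    captures_rows = []
    detected_adult_at: dict[int, set] = {}
    litter_rows = []
    extinct = False
    years_done = 0

    for t in range(cfg.years):
        year = yr0 + t
        if not alive:
            extinct = True
            break

        # --- reproduction ---------------------------------------------------
        live = sorted(alive)
        live_arr = np.array(live)
        ages = year - np.array([birth_year[i] for i in live])
        mature = ages >= cfg.age_maturity_yr
        sexes = np.array([sex[i] for i in live])
        males = live_arr[(sexes == "M") & mature]
        mx = np.array([xs[i] for i in males])
        my = np.array([ys[i] for i in males])
        females = live_arr[(sexes == "F") & mature]
        for f_id in females:
            age = year - birth_year[f_id]
            if cfg.female_biennial and (age - cfg.age_maturity_yr) % 2 != 0:
                continue
            if len(males) == 0:
                continue
            d2 = (mx - xs[f_id]) ** 2 + (my - ys[f_id]) ** 2
            within = d2 <= cfg.mating_radius_m**2
            if not np.any(within):
                continue
            # no-offspring draw (the zero-inflation truth)
            p_zero = _expit(cfg.base_zero_logit + cfg.beta_F_zero * fcoef[f_id])
            litter = 0
            s_id = -1
            if rng.random() >= p_zero:
                w = np.exp(-d2[within] / (2.0 * cfg.mating_radius_m**2))
                s_id = int(rng.choice(males[within], p=w / w.sum()))
                p_nb = cfg.litter_dispersion / (cfg.litter_dispersion + cfg.litter_mean)
                litter = int(rng.negative_binomial(cfg.litter_dispersion, p_nb))
                gd = genotypes[f_id]
                gs = genotypes[s_id]
                for _ in range(litter):
                    allele_d = (rng.random(cfg.n_loci) < gd / 2.0).astype(np.int8)
                    allele_s = (rng.random(cfg.n_loci) < gs / 2.0).astype(np.int8)
                    if cfg.dispersal_sd_m >= cfg.arena_size_m:
                        # global-dispersal regime: uniform resettlement (a
                        # boundary-clipped huge Gaussian would pile offspring
                        # at the arena edges instead of randomizing location)
                        ox = rng.uniform(0.0, cfg.arena_size_m)
                        oy = rng.uniform(0.0, cfg.arena_size_m)
                    elif cfg.dispersal_sd_m > 0:
                        ox = xs[f_id] + rng.normal(0.0, cfg.dispersal_sd_m)
                        oy = ys[f_id] + rng.normal(0.0, cfg.dispersal_sd_m)
                    else:
                        ox, oy = xs[f_id], ys[f_id]
                    child = add_individual(
                        int(f_id),
                        s_id,
                        (allele_d + allele_s),
                        float(np.clip(ox, 0, cfg.arena_size_m)),
                        float(np.clip(oy, 0, cfg.arena_size_m)),
                        year,
                        "F" if rng.random() < 0.5 else "M",
                    )
                    alive.add(child)
            litter_rows.append(
                {"dam": f_id, "year": year, "litter": litter, "sire": s_id}
            )

        # --- survey ----------------------------------------------------------
        for i in sorted(alive):
            age = year - birth_year[i]
            svl_true = float(_svl_at_age(cfg, age))
            logit_p = _logit(cfg.detection_prob)
            if (
                sex[i] == "F"
                and (year - 2) in detected_adult_at.get(i, set())
            ):
                logit_p += cfg.trap_response_delta
            if rng.random() < _expit(logit_p):
                svl_obs = svl_true + rng.normal(0.0, cfg.svl_noise_sd_cm)
                captures_rows.append(
                    {
                        "id": i,
                        "site": cfg.site,
                        "year": year,
                        "svl_cm": round(float(svl_obs), 2),
                        "x": xs[i],
                        "y": ys[i],
                    }
                )
                if svl_obs >= 45.0:
                    detected_adult_at.setdefault(i, set()).add(year)

        # --- survival to next year -------------------------------------------
        survivors = set()
        for i in sorted(alive):
            age = year - birth_year[i]
            svl_std = (float(_svl_at_age(cfg, age)) - cfg.svl_ref_center_cm) / cfg.svl_ref_scale_cm
            eta = (
                cfg.base_survival_logit
                + cfg.beta_F_survival * fcoef[i]
                + cfg.beta_svl_survival * svl_std
            )
            if rng.random() < _expit(eta):
                survivors.add(i)
            else:
                death_year[i] = year
        alive = survivors
        years_done = t + 1
    else:
        if not alive:
            extinct = True

    n = len(dam)
    width = max(5, len(str(n)))
    ids = np.array([f"{cfg.id_prefix}{i:0{width}d}" for i in range(n)], dtype=object)
    n_chrom = min(20, cfg.n_loci)
    chrom = np.array([f"chr{1 + l % n_chrom}" for l in range(cfg.n_loci)], dtype=object)
    pos = np.array([1 + 150_000 * (l // n_chrom) for l in range(cfg.n_loci)], dtype=int)
    gmat = GenotypeMatrix(
        individual_ids=ids,
        locus_ids=np.array([f"L{l:06d}" for l in range(cfg.n_loci)], dtype=object),
        calls=np.array(genotypes, dtype=float),
        chrom=chrom,
        pos_bp=pos,
        site_labels=np.array([cfg.site] * n, dtype=object),
    )
    ped = Pedigree(
        pd.DataFrame(
            {
                "id": ids,
                "dam": [ids[d] if d >= 0 else "" for d in dam],
                "sire": [ids[s] if s >= 0 else "" for s in sire],
                "sex": sex,
                "birth_year": birth_year,
                "byr_min": birth_year,
                "byr_max": birth_year,
                "genotyped": True,
                "dummy": False,
                "site": cfg.site,
                "death_year": [death_year.get(i, np.nan) for i in range(n)],
            }
        )
    )
    caps = pd.DataFrame(
        captures_rows, columns=["id", "site", "year", "svl_cm", "x", "y"]
    )
    if len(caps):
        caps["id"] = [ids[i] for i in caps["id"]]
    lit = pd.DataFrame(litter_rows, columns=["dam", "year", "litter", "sire"])
    if len(lit):
        lit["dam"] = [ids[i] for i in lit["dam"]]
        lit["sire"] = [ids[i] if i >= 0 else "" for i in lit["sire"]]
    return SimulatedDataset(
        genotypes=gmat,
        pedigree=ped,
        true_f_pedigree=pd.Series(fcoef, index=ids, name="true_f"),
        locations=pd.DataFrame({"x": xs, "y": ys}, index=ids),
        captures=caps,
        config=cfg,
        extinct=extinct,
        years_completed=years_done,
        litter_sizes=lit,
    )


def simulate_two_demes(
    config_a: SimulationConfig, config_b: SimulationConfig
) -> SimulatedDataset:
    """Two independent demes concatenated with their site labels.

    The demes share the locus panel size but are simulated independently (no
    migration); ids are prefixed by site to stay unique.
    """
    if config_a.n_loci != config_b.n_loci:
        raise ValueError("both demes must share n_loci")
    runs = []
    for cfg in (config_a, config_b):
        if not cfg.id_prefix:
            cfg = SimulationConfig(**{**asdict(cfg), "id_prefix": f"{cfg.site}_"})
        runs.append(simulate_population(cfg))
    da, db = runs
    ga, gb = da.genotypes, db.genotypes
    gmat = GenotypeMatrix(
        individual_ids=np.concatenate([ga.individual_ids, gb.individual_ids]),
        locus_ids=ga.locus_ids,
        calls=np.vstack([ga.calls, gb.calls]),
        chrom=ga.chrom,
        pos_bp=ga.pos_bp,
        site_labels=np.concatenate([ga.site_labels, gb.site_labels]),
    )
    ped = Pedigree(
        pd.concat([da.pedigree.table, db.pedigree.table], ignore_index=True)
    )
    return SimulatedDataset(
        genotypes=gmat,
        pedigree=ped,
        true_f_pedigree=pd.concat([da.true_f_pedigree, db.true_f_pedigree]),
        locations=pd.concat([da.locations, db.locations]),
        captures=pd.concat([da.captures, db.captures], ignore_index=True),
        config=config_a,
        extinct=da.extinct or db.extinct,
        years_completed=min(da.years_completed, db.years_completed),
        litter_sizes=pd.concat([da.litter_sizes, db.litter_sizes], ignore_index=True),
    )


def mendelian_check(genotypes: GenotypeMatrix, pedigree: Pedigree) -> pd.Series:
    """Per-trio count of loci where the offspring genotype is impossible.

    A trio is an offspring with both parents genotyped.  Phase-free rule on
    alternate-allele counts: offspring 0 is impossible if either parent is 2,
    offspring 2 if either parent is 0, offspring 1 if both parents are the
    same homozygote.  Missing calls at a locus skip that locus.
    """
    idset = set(genotypes.individual_ids)
    lookup = {v: i for i, v in enumerate(genotypes.individual_ids)}
    out = {}
    for ident in pedigree.ids:
        d, s = pedigree.dam(ident), pedigree.sire(ident)
        if ident not in idset or d not in idset or s not in idset:
            continue
        go = genotypes.calls[lookup[ident]]
        gd = genotypes.calls[lookup[d]]
        gs = genotypes.calls[lookup[s]]
        ok = ~(np.isnan(go) | np.isnan(gd) | np.isnan(gs))
        viol = (
            ((go == 0) & ((gd == 2) | (gs == 2)))
            | ((go == 2) & ((gd == 0) | (gs == 0)))
            | ((go == 1) & (((gd == 0) & (gs == 0)) | ((gd == 2) & (gs == 2))))
        )
        out[ident] = int(np.sum(viol & ok))
    return pd.Series(out, name="mendelian_violations", dtype=int)
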