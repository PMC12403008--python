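"""End-to-end orchestration: filter -> F_grm -> pedigree -> growth ->
survival -> reproduction -> spatial, with a single deterministic run report.

The pipeline consumes either file paths (012 genotypes, pedigree CSV,
captures CSV) or an in-memory simulated dataset, applies every stage with
the thresholds echoed into the report, and writes one JSON report whose
bytes depend only on the inputs and seeds (no timestamps).  A stage failure
is recorded in the report with the stage name; earlier stage results are
kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genotypes import (
    GenotypeMatrix,
    filter_genotypes,
    fgrm_per_site,
    genotype_pca,
    pairwise_pi,
    weir_cockerham_fst,
)
from .pedigree import (
    Pedigree,
    edge_effect_regression,
    fgrm_vs_pedigree_f,
    pedigree_inbreeding,
    reproductive_success,
)
from .growth import fit_fabens, occasion_svl_table
from .cjs import CJSModelSpec, build_histories, select_models
from .reproduction import inbreeding_load, zinb_candidates
from .spatial import (
    capture_centroids,
    classify_pairs,
    isolation_by_distance,
    ks_compare,
    nearby_pair_tests,
)
from .io import read_captures_csv, read_genotypes_012, read_pedigree_csv, write_report_json


DEFAULT_CJS_CANDIDATES = (
    ("site", "svl", "fgrm"),
    ("site", "svl"),
    ("svl", "fgrm"),
    ("svl",),
    (),
)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run.

    Either the three ``*_path`` fields or an in-memory dataset passed to
    :func:`run_pipeline` must be provided.  Every threshold is echoed
    verbatim into the run report.
    """

    genotypes_prefix: str | None = None
    pedigree_path: str | None = None
    captures_path: str | None = None
    surveyed_years: dict = field(default_factory=dict)
    out_dir: str | None = None
    max_locus_missing: float = 0.10
    max_indiv_missing: float = 0.20
    min_maf: float = 0.05
    het_excess_alpha: float = 0.05
    min_spacing_bp: int = 100_000
    nearby_radius_m: float = 25.0
    adult_svl_cm: float = 45.0
    reference_svl_cm: float = 52.0
    age_maturity_yr: int = 3
    seed: int = 0
    cjs_phi_candidates: tuple = DEFAULT_CJS_CANDIDATES
    cjs_p_terms: tuple = ("site", "af2")
    zinb_base_terms: tuple = ("site", "sex", "years_contributing")
    n_ibd_permutations: int = 199
    n_pca_components: int = 6


def run_pipeline(
    config: PipelineConfig,
    genotypes: GenotypeMatrix | None = None,
    pedigree: Pedigree | None = None,
    captures: pd.DataFrame | None = None,
) -> dict:
    """Execute all stages; return (and optionally write) the run report."""
    report: dict = {
        "version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "failed_stage": None,
    }

    def finish(stage: str, err: Exception) -> dict:
        report["failed_stage"] = {"stage": stage, "error": str(err)}
        _write(report, config)
        return report

    # ---- load ------------------------------------------------------------
    try:
        if genotypes is None:
            if config.genotypes_prefix is None:
                raise ValueError("config.genotypes_prefix is missing")
            genotypes = read_genotypes_012(config.genotypes_prefix)
        if pedigree is None:
            if config.pedigree_path is None:
                raise ValueError("config.pedigree_path is missing")
            pedigree = read_pedigree_csv(config.pedigree_path)
        if captures is None:
            if config.captures_path is None:
                raise ValueError("config.captures_path is missing")
            captures = read_captures_csv(config.captures_path)
        captures = captures.copy()
        captures["id"] = captures["id"].astype(str)
        surveyed = config.surveyed_years or {
            s: sorted(captures.loc[captures["site"] == s, "year"].unique().tolist())
            for s in captures["site"].unique()
        }
        surveyed = {
            s: sorted(int(y) for y in ys) for s, ys in surveyed.items()
        }
    except Exception as exc:
        return finish("load", exc)

    # ---- genotype filtering and F_grm -------------------------------------
    try:
        filtered, filt_report = filter_genotypes(
            genotypes,
            max_locus_missing=config.max_locus_missing,
            max_indiv_missing=config.max_indiv_missing,
            min_maf=config.min_maf,
            het_excess_alpha=config.het_excess_alpha,
            min_spacing_bp=config.min_spacing_bp,
            seed=config.seed,
        )
        est = fgrm_per_site(filtered)
        fgrm = est.as_series()
        report["stages"]["filter"] = {
            "steps": filt_report.to_frame(),
            "n_individuals": filtered.n_individuals,
            "n_loci": filtered.n_loci,
        }
        report["stages"]["fgrm"] = {
            "mean": float(np.nanmean(est.fgrm)),
            "min": float(np.nanmin(est.fgrm)),
            "max": float(np.nanmax(est.fgrm)),
            "frac_above_0.05": float(np.nanmean(est.fgrm > 0.05)),
        }
        if len(pd.unique(filtered.site_labels)) == 2:
            report["stages"]["fgrm"]["fst"] = weir_cockerham_fst(filtered)
        scores, varfrac = genotype_pca(
            filtered, min_maf=config.min_maf, n_components=config.n_pca_components
        )
        report["stages"]["pca"] = {"variance_fraction": varfrac}
    except Exception as exc:
        return finish("genotypes", exc)

    # ---- pedigree metrics --------------------------------------------------
    try:
        ped_f = pedigree_inbreeding(pedigree)
        rec = reproductive_success(
            pedigree, captures=captures, age_maturity=config.age_maturity_yr
        )
        rec = rec.merge(
            fgrm.rename("fgrm"), left_on="id", right_index=True, how="left"
        )
        r, df_, pval = fgrm_vs_pedigree_f(fgrm, ped_f)
        centroids = capture_centroids(captures)
        edge = {}
        for site, grp in rec.groupby("site"):
            try:
                edge[str(site)] = edge_effect_regression(grp, centroids)
            except ValueError as e:
                edge[str(site)] = {"error": str(e)}
        report["stages"]["pedigree"] = {
            "max_pedigree_f": float(ped_f.max()),
            "fgrm_vs_pedigree_f": {"r": r, "df": df_, "p": pval},
            "edge_effect": edge,
        }
    except Exception as exc:
        return finish("pedigree", exc)

    # ---- growth ------------------------------------------------------------
    try:
        sexes = pedigree.table.set_index("id")["sex"]
        cap_sex = captures.assign(sex=captures["id"].map(sexes).fillna("U"))
        fits = fit_fabens(cap_sex)
        years_all = sorted({y for ys in surveyed.values() for y in ys})
        svl_tab = occasion_svl_table(cap_sex, fits, years_all)
        fit0 = fits[()]
        report["stages"]["growth"] = {
            "linf_cm": fit0.linf,
            "k_per_yr": fit0.k,
            "residual_sd_cm": fit0.sigma,
            "n_pairs": fit0.n_pairs,
        }
    except Exception as exc:
        return finish("growth", exc)

    # ---- survival ----------------------------------------------------------
    try:
        h = build_histories(
            captures,
            surveyed,
            svl_table=svl_tab,
            fgrm=fgrm,
            sex=sexes,
            adult_svl_cm=config.adult_svl_cm,
        )
        single_site = len(pd.unique(h.site)) < 2
        p_terms = tuple(
            t for t in config.cjs_p_terms if not (single_site and t == "site")
        )
        candidates = [
            CJSModelSpec(
                phi_terms=tuple(t for t in phi if not (single_site and t == "site")),
                p_terms=p_terms,
            )
            for phi in config.cjs_phi_candidates
        ]
        # de-duplicate after site dropping
        candidates = list(dict.fromkeys(candidates))
        if len(candidates) < 2:
            candidates.append(CJSModelSpec(phi_terms=(), p_terms=p_terms))
        tab, cjs_fits = select_models(candidates, h, seed=config.seed)
        report["stages"]["survival"] = {"model_table": tab}
    except Exception as exc:
        return finish("survival", exc)

    # ---- reproduction ------------------------------------------------------
    try:
        rec_fit = rec.dropna(subset=["fgrm"]).reset_index(drop=True)
        load = inbreeding_load(rec_fit)
        base = tuple(
            t
            for t in config.zinb_base_terms
            if not (t in ("site", "sex") and rec_fit[t].nunique() < 2)
        )
        ztab, zfits = zinb_candidates(rec_fit, base_terms=base, seed=config.seed)
        report["stages"]["reproduction"] = {
            "inbreeding_load_B": load.B,
            "load_se": load.se,
            "load_n": load.n,
            "zinb_table": ztab,
        }
    except Exception as exc:
        return finish("reproduction", exc)

    # ---- spatial -----------------------------------------------------------
    try:
        spatial_out = {}
        pi = pairwise_pi(filtered)
        for site in pd.unique(pedigree.table["site"]):
            ped_site = Pedigree(
                pedigree.table[pedigree.table["site"] == site].reset_index(drop=True)
            )
            rec_site = rec[rec["site"] == site]
            cls = classify_pairs(ped_site, centroids, rec_site)
            entry: dict = {"n_pairs": int(len(cls))}
            try:
                entry["ks"] = ks_compare(cls)
            except ValueError as e:
                entry["ks"] = {"error": str(e)}
            site_ids = [
                i
                for i in pi.index
                if i in centroids.index and i in set(ped_site.table["id"])
            ]
            if len(site_ids) >= 3:
                entry["ibd"] = isolation_by_distance(
                    pi.loc[site_ids, site_ids],
                    centroids,
                    n_perm=config.n_ibd_permutations,
                    seed=config.seed,
                )
            try:
                has_off = pd.Series(
                    (rec_site["n_offspring"] > 0).to_numpy(),
                    index=rec_site["id"].to_numpy(),
                )
                entry["nearby"] = nearby_pair_tests(
                    centroids.loc[centroids.index.isin(has_off.index)],
                    fgrm,
                    has_off,
                    radius_m=config.nearby_radius_m,
                )
            except ValueError as e:
                entry["nearby"] = {"error": str(e)}
            spatial_out[str(site)] = entry
        report["stages"]["spatial"] = spatial_out
    except Exception as exc:
        return finish("spatial", exc)

    _write(report, config)
    return report


def _write(report: dict, config: PipelineConfig) -> None:
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report_json(report, out / "report.json")
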