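"""Cormack-Jolly-Seber capture-recapture models with individual covariates.

Open-population mark-recapture: conditioning on each individual's first
detection, apparent survival ``phi_t`` (interval t -> t+1) and recapture
probability ``p_t`` are modeled on the logit scale from group factors
(site, sex), static covariates (F_grm), occasion-varying covariates
(predicted body length, the two-years-after-adult-capture trap-response
indicator), and occasion factors.  The likelihood of a history with first
detection f and last detection l is

    prod_{t=f}^{l-1} phi_t  *  prod_{t=f+1}^{l} p_t^y (1-p_t)^(1-y)  *  chi_l

with the never-seen-again recursion chi_T = 1,
``chi_t = (1 - phi_t) + phi_t (1 - p_{t+1}) chi_{t+1}``.  Occasions a site
was not surveyed are handled exactly by forcing p = 0 there.

Model selection uses AICc with Akaike weights; the effective sample size is
configurable between total releases (detections that could be followed by a
re-observation) and number of individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# capture histories
# ---------------------------------------------------------------------------


@dataclass
class CaptureHistoryMatrix:
    """Individuals x occasions detections plus covariates for CJS fitting.

    ``y``: 0/1 detections; ``surveyed``: False where the individual's site ran
    no survey that year (detection structurally impossible); ``svl_std`` is the
    occasion-level standardized body length; ``af2`` flags an adult capture
    exactly two years before the occasion.  Continuous covariates are
    standardized as (x - mean) / (2 SD) so their coefficients are comparable
    with binary ones; the constants live in ``meta``.
    """

    y: np.ndarray
    surveyed: np.ndarray
    years: np.ndarray
    individual_ids: np.ndarray
    site: np.ndarray
    sex: np.ndarray
    svl_std: np.ndarray
    fgrm_std: np.ndarray
    af2: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        n, T = self.y.shape
        self.first = np.argmax(self.y, axis=1)
        lastrev = np.argmax(self.y[:, ::-1], axis=1)
        self.last = T - 1 - lastrev
        if np.any(self.y.sum(axis=1) == 0):
            raise ValueError("every retained individual needs a first detection")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]


def two_sd_standardize(x: np.ndarray):
    """Center and scale by twice the SD; returns (standardized, mean, sd)."""
    x = np.asarray(x, dtype=float)
    vals = x[~np.isnan(x)]
    mu = float(vals.mean()) if vals.size else 0.0
    sd = float(vals.std()) if vals.size else 1.0
    if sd == 0:
        sd = 1.0
    return (x - mu) / (2.0 * sd), mu, sd


def build_histories(
    captures: pd.DataFrame,
    surveyed_years: dict,
    svl_table: pd.DataFrame | None = None,
    fgrm: pd.Series | None = None,
    sex: pd.Series | None = None,
    adult_svl_cm: float = 45.0,
) -> CaptureHistoryMatrix:
    """Detection matrix + covariates from per-event capture records.

    ``surveyed_years`` maps site -> iterable of years surveyed there; the
    occasion axis is the union across sites and unsurveyed site-years become
    structural zeros.  ``svl_table`` (rows ids, columns years, cm — typically
    from the growth module) supplies the occasion-varying length; ``fgrm``
    and ``sex`` are per-id.  AFpriorcap2 at occasion t is 1 iff the
    individual was detected at t-2 with length >= ``adult_svl_cm``.
    """
    cap = captures.copy()
    cap["id"] = cap["id"].astype(str)
    # continuous occasion axis: dummy occasions fill unsurveyed gap years so
    # every interval stays annual
    allyears = {int(y) for ys in surveyed_years.values() for y in ys}
    years = list(range(min(allyears), max(allyears) + 1))
    yindex = {y: t for t, y in enumerate(years)}
    T = len(years)
    ids = list(pd.unique(cap["id"]))
    site_of = cap.groupby("id")["site"].first()
    n = len(ids)
    y = np.zeros((n, T), dtype=int)
    svl_obs = np.full((n, T), np.nan)
    for _, row in cap.iterrows():
        yr = int(row["year"])
        if yr not in yindex:
            continue
        i = ids.index(row["id"])
        y[i, yindex[yr]] = 1
        if not pd.isna(row.get("svl_cm", np.nan)):
            svl_obs[i, yindex[yr]] = float(row["svl_cm"])
    detected = y.sum(axis=1) > 0
    if not detected.all():
        warnings.warn(
            f"excluding {int(np.sum(~detected))} individual(s) with no detection",
            stacklevel=2,
        )
    keep = np.where(detected)[0]
    ids = [ids[i] for i in keep]
    y = y[keep]
    svl_obs = svl_obs[keep]
    n = len(ids)

    site = np.array([site_of.get(i, "") for i in ids], dtype=object)
    surveyed = np.ones((n, T), dtype=bool)
    for s, ys in surveyed_years.items():
        ys = {int(v) for v in ys}
        mask = site == s
        for t, yr in enumerate(years):
            if yr not in ys:
                surveyed[mask, t] = False

    # occasion-level SVL: model predictions where available, observed otherwise
    svl_raw = svl_obs.copy()
    if svl_table is not None:
        pred = svl_table.reindex(index=ids, columns=years)
        svl_raw = np.where(np.isnan(svl_obs), pred.to_numpy(dtype=float), svl_obs)

    af2 = np.zeros((n, T), dtype=float)
    af2[:, 2:] = (y[:, :-2] == 1) & (svl_raw[:, :-2] >= adult_svl_cm)

    svl_std, svl_mu, svl_sd = two_sd_standardize(svl_raw)
    svl_std = np.nan_to_num(svl_std, nan=0.0)  # mean value where unknown

    fg = np.array([np.nan if fgrm is None else fgrm.get(i, np.nan) for i in ids])
    fg_std, fg_mu, fg_sd = two_sd_standardize(fg)
    fg_std = np.nan_to_num(fg_std, nan=0.0)

    sx = np.array(
        ["U" if sex is None else str(sex.get(i, "U")) for i in ids], dtype=object
    )
    meta = {
        "svl_mean": svl_mu,
        "svl_sd": svl_sd,
        "fgrm_mean": fg_mu,
        "fgrm_sd": fg_sd,
        "adult_svl_cm": adult_svl_cm,
        "years": years,
    }
    return CaptureHistoryMatrix(
        y=y,
        surveyed=surveyed,
        years=np.array(years),
        individual_ids=np.array(ids, dtype=object),
        site=site,
        sex=sx,
        svl_std=svl_std,
        fgrm_std=fg_std,
        af2=af2,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CJSModelSpec:
    """Additive/interactive logit formulas for survival and recapture.

    Terms: "site", "sex" (factors), "svl", "fgrm" (standardized continuous),
    "year" (occasion factor), "af2"; "a*b" expands to main effects plus
    interaction, "a:b" is the interaction alone.
    """

    phi_terms: tuple = ()
    p_terms: tuple = ()

    def label(self) -> str:
        phi = " + ".join(self.phi_terms) or "1"
        p = " + ".join(self.p_terms) or "1"
        return f"phi({phi}) p({p})"


def _base_columns(h: CaptureHistoryMatrix, var: str, occ: np.ndarray):
    """Columns (name, (n, T-1) array) for one base variable on given occasions."""
    n = h.n_individuals
    m = len(occ)
    if var == "1":
        return [("(Intercept)", np.ones((n, m)))]
    if var in ("site", "sex"):
        vals = h.site if var == "site" else h.sex
        levels = sorted(pd.unique(vals))
        return [
            (f"{var}[{lev}]", np.broadcast_to((vals == lev).astype(float)[:, None], (n, m)).copy())
            for lev in levels[1:]
        ]
    if var == "fgrm":
        return [("fgrm", np.broadcast_to(h.fgrm_std[:, None], (n, m)).copy())]
    if var == "svl":
        return [("svl", h.svl_std[:, occ])]
    if var == "af2":
        return [("af2", h.af2[:, occ])]
    if var == "year":
        yrs = h.years[occ]
        return [
            (f"year[{yr}]", np.broadcast_to((yrs == yr).astype(float)[None, :], (n, m)).copy())
            for yr in yrs[1:]
        ]
    raise ValueError(f"unknown model term {var!r}")


def _design(h: CaptureHistoryMatrix, terms: tuple, kind: str):
    """Stack columns for phi (intervals, covariates at interval start) or p
    (recapture occasions 1..T-1)."""
    T = h.n_occasions
    occ = np.arange(0, T - 1) if kind == "phi" else np.arange(1, T)
    expanded: list[str] = ["1"]
    for term in terms:
        if "*" in term:
            a, b = term.split("*")
            for t in (a, b, f"{a}:{b}"):
                if t not in expanded:
                    expanded.append(t)
        elif term not in expanded:
            expanded.append(term)
    names: list[str] = []
    cols: list[np.ndarray] = []
    for term in expanded:
        if ":" in term:
            a, b = term.split(":")
            for na, ca in _base_columns(h, a, occ):
                for nb, cb in _base_columns(h, b, occ):
                    names.append(f"{na}:{nb}")
                    cols.append(ca * cb)
        else:
            for nm, c in _base_columns(h, term, occ):
                names.append(nm)
                cols.append(c)
    X = np.stack(cols, axis=2) if cols else np.zeros((h.n_individuals, T - 1, 0))
    return X, names


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _phi_p(h, X_phi, X_p, beta_phi, beta_p):
    phi = _expit(X_phi @ beta_phi)  # (n, T-1): interval t -> t+1
    p = _expit(X_p @ beta_p)  # (n, T-1): recapture at occasion t+1
    p = p * h.surveyed[:, 1:]  # unsurveyed occasions: p = 0 exactly
    return phi, p


def _loglik_from_probs(h: CaptureHistoryMatrix, phi: np.ndarray, p: np.ndarray) -> float:
    n, T = h.y.shape
    t_idx = np.arange(T - 1)[None, :]
    f = h.first[:, None]
    l = h.last[:, None]
    interval = (t_idx >= f) & (t_idx < l)  # survival f..l-1
    obs = (t_idx + 1 > f) & (t_idx + 1 <= l)  # occasions f+1..l
    yy = h.y[:, 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        log_phi = np.where(interval, np.log(np.maximum(phi, 1e-300)), 0.0)
        log_obs = np.where(
            obs,
            np.where(yy == 1, np.log(np.maximum(p, 1e-300)), np.log1p(-np.minimum(p, 1.0 - 1e-300))),
            0.0,
        )
    # chi recursion, vectorized over individuals
    chi = np.ones((n, T))
    for t in range(T - 2, -1, -1):
        chi[:, t] = (1.0 - phi[:, t]) + phi[:, t] * (1.0 - p[:, t]) * chi[:, t + 1]
    log_chi = np.log(np.maximum(chi[np.arange(n), h.last], 1e-300))
    return float(log_phi.sum() + log_obs.sum() + log_chi.sum())


def cjs_loglik(h: CaptureHistoryMatrix, spec: CJSModelSpec, beta: np.ndarray) -> float:
    """Conditional-on-first-capture CJS log-likelihood at coefficients ``beta``
    (survival block first, recapture block second)."""
    X_phi, phi_names = _design(h, spec.phi_terms, "phi")
    X_p, p_names = _design(h, spec.p_terms, "p")
    k = len(phi_names)
    beta = np.asarray(beta, dtype=float)
    if beta.size != k + len(p_names):
        raise ValueError(
            f"beta length {beta.size} != {k} phi + {len(p_names)} p coefficients"
        )
    lp_phi = X_phi @ beta[:k]
    lp_p = X_p @ beta[k:]
    if not (np.isfinite(lp_phi).all() and np.isfinite(lp_p).all()):
        raise FloatingPointError("non-finite linear predictor (check covariates)")
    phi, p = _phi_p(h, X_phi, X_p, beta[:k], beta[k:])
    return _loglik_from_probs(h, phi, p)


# ---------------------------------------------------------------------------
# fitting and selection
# ---------------------------------------------------------------------------


@dataclass
class CJSFit:
    spec: CJSModelSpec
    coef: pd.Series
    vcov: np.ndarray
    lnl: float
    k: int
    aicc: float
    n_eff: float
    converged: bool
    nonidentifiable: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)
    n_phi: int = 0

    @property
    def minus2lnl(self) -> float:
        return -2.0 * self.lnl

    def se(self) -> pd.Series:
        d = np.diag(self.vcov)
        return pd.Series(np.sqrt(np.where(d > 0, d, np.nan)), index=self.coef.index)

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.se()
        return pd.DataFrame(
            {"low": self.coef - z * se, "high": self.coef + z * se}
        )


def _numeric_hessian(fun, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    return H


def effective_sample_size(h: CaptureHistoryMatrix, convention: str = "releases") -> int:
    """AICc sample size: 'releases' counts detections eligible to be followed
    by a re-observation (detections before the final occasion); 'individuals'
    counts animals."""
    if convention == "releases":
        return int(h.y[:, :-1].sum())
    if convention == "individuals":
        return int(h.n_individuals)
    raise ValueError("convention must be 'releases' or 'individuals'")


def fit_cjs(
    h: CaptureHistoryMatrix,
    spec: CJSModelSpec,
    n_eff: str = "releases",
    n_starts: int = 3,
    seed: int = 0,
) -> CJSFit:
    """Maximum-likelihood CJS fit by multi-start quasi-Newton optimization.

    Variance from the inverse observed information (numerical Hessian);
    parameters whose information is singular are flagged, not dropped.
    """
    X_phi, phi_names = _design(h, spec.phi_terms, "phi")
    X_p, p_names = _design(h, spec.p_terms, "p")
    kphi, kp = len(phi_names), len(p_names)
    k = kphi + kp

    def nll(beta):
        phi, p = _phi_p(h, X_phi, X_p, beta[:kphi], beta[kphi:])
        return -_loglik_from_probs(h, phi, p)

    rng = np.random.default_rng(seed)
    starts = [np.zeros(k)] + [0.5 * rng.standard_normal(k) for _ in range(n_starts)]
    best = None
    for s in starts:
        res = optimize.minimize(nll, s, method="BFGS", options={"gtol": 1e-7, "maxiter": 2000})
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    lnl = -float(best.fun)
    H = _numeric_hessian(nll, best.x)
    nonident: list[str] = []
    names = [f"phi:{nm}" for nm in phi_names] + [f"p:{nm}" for nm in p_names]
    try:
        vcov = np.linalg.inv(H)
        if np.any(np.diag(vcov) <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        vcov = np.linalg.pinv(H)
        d = np.diag(vcov)
        nonident = [names[i] for i in range(k) if d[i] <= 0 or d[i] > 1e6]
    ness = effective_sample_size(h, n_eff)
    aicc = -2 * lnl + 2 * k + 2 * k * (k + 1) / max(ness - k - 1, 1)
    return CJSFit(
        spec=spec,
        coef=pd.Series(best.x, index=names),
        vcov=vcov,
        lnl=lnl,
        k=k,
        aicc=float(aicc),
        n_eff=ness,
        converged=bool(best.success),
        nonidentifiable=nonident,
        meta=dict(h.meta),
        n_phi=kphi,
    )


def select_models(
    candidates: list[CJSModelSpec],
    h: CaptureHistoryMatrix,
    n_eff: str = "releases",
    seed: int = 0,
):
    """Fit candidates, rank by AICc, and flag likely-uninformative parameters.

    Returns ``(table, fits)`` where the table mirrors the usual columns
    (delta AICc, Akaike weight, k, -2 lnL) and a non-intercept survival
    coefficient whose 85% CI covers zero raises a flag (the model is kept).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    rows = []
    fits = {}
    for spec in candidates:
        label = spec.label()
        try:
            fit = fit_cjs(h, spec, n_eff=n_eff, seed=seed)
        except Exception as exc:  # recorded, not fatal
            rows.append({"model": label, "failed": True, "error": str(exc)})
            continue
        ci85 = fit.ci(0.85)
        flagged = [
            nm
            for nm in fit.coef.index
            if nm.startswith("phi:") and nm != "phi:(Intercept)"
            and ci85.loc[nm, "low"] < 0 < ci85.loc[nm, "high"]
        ]
        fits[label] = fit
        rows.append(
            {
                "model": label,
                "aicc": fit.aicc,
                "k": fit.k,
                "minus2lnl": fit.minus2lnl,
                "failed": False,
                "uninformative_flags": ",".join(flagged),
            }
        )
    tab = pd.DataFrame(rows)
    ok = tab.get("failed", pd.Series(dtype=bool)) == False  # noqa: E712
    if ok.sum() == 0:
        raise RuntimeError("every candidate model failed to fit")
    tab.loc[ok, "delta_aicc"] = tab.loc[ok, "aicc"] - tab.loc[ok, "aicc"].min()
    rel = np.exp(-0.5 * tab.loc[ok, "delta_aicc"])
    tab.loc[ok, "weight"] = rel / rel.sum()
    tab = tab.sort_values("aicc", na_position="last").reset_index(drop=True)
    return tab, fits


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------


def predict_survival(fit: CJSFit, profile: dict, level: float = 0.95) -> dict:
    """Annual survival (with delta-method CI) for a covariate profile.

    ``profile`` uses raw units, e.g. ``{"site": "Cass", "sex": "F",
    "svl": 52.0, "fgrm": 0.1}``; continuous covariates are standardized with
    the constants stored at history-building time.
    """
    meta = fit.meta
    std = {
        "svl": lambda v: (v - meta["svl_mean"]) / (2 * meta["svl_sd"]),
        "fgrm": lambda v: (v - meta["fgrm_mean"]) / (2 * meta["fgrm_sd"]),
    }

    def column_value(name: str) -> float:
        val = 1.0
        for part in name.split(":"):
            if part == "(Intercept)":
                continue
            if "[" in part:
                var, lev = part[:-1].split("[")
                if var not in profile:
                    raise KeyError(f"profile missing factor {var!r}")
                val *= 1.0 if str(profile[var]) == lev else 0.0
            else:
                if part not in profile:
                    raise KeyError(f"profile missing covariate {part!r}")
                v = float(profile[part])
                val *= std[part](v) if part in std else v
        return val

    phi_idx = [i for i, nm in enumerate(fit.coef.index) if nm.startswith("phi:")]
    x = np.zeros(len(fit.coef))
    for i in phi_idx:
        x[i] = column_value(fit.coef.index[i][len("phi:"):])
    eta = float(x @ fit.coef.to_numpy())
    var = float(x @ fit.vcov @ x)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = np.sqrt(max(var, 0.0))
    return {
        "survival": float(_expit(eta)),
        "ci_low": float(_expit(eta - z * se)),
        "ci_high": float(_expit(eta + z * se)),
        "logit": eta,
        "se_logit": se,
    }


def simulate_histories(
    n: int,
    T: int,
    phi: float | np.ndarray,
    p: float | np.ndarray,
    seed: int = 0,
    release_occasion: int | str = "staggered",
) -> CaptureHistoryMatrix:
    """Generate simple CJS histories for calibration experiments.

    ``phi`` may be a scalar or per-individual vector of annual survival;
    likewise ``p``.  ``release_occasion`` is a fixed occasion index, or
    "staggered" for first captures spread uniformly over occasions
    0..T-2, the usual situation in a field study marking animals every year.
    """
    rng = np.random.default_rng(seed)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (n,))
    p = np.broadcast_to(np.asarray(p, dtype=float), (n,))
    y = np.zeros((n, T), dtype=int)
    if release_occasion == "staggered":
        rel = rng.integers(0, T - 1, n)
    else:
        rel = np.full(n, int(release_occasion))
    y[np.arange(n), rel] = 1
    alive = np.ones(n, dtype=bool)
    for t in range(T - 1):
        started = rel <= t
        alive &= ~started | (rng.random(n) < phi)
        y[started & alive & (rng.random(n) < p), t + 1] = 1
    return CaptureHistoryMatrix(
        y=y,
        surveyed=np.ones((n, T), dtype=bool),
        years=np.arange(2000, 2000 + T),
        individual_ids=np.array([f"s{i}" for i in range(n)], dtype=object),
        site=np.array(["A"] * n, dtype=object),
        sex=np.array(["U"] * n, dtype=object),
        svl_std=np.zeros((n, T)),
        fgrm_std=np.zeros(n),
        af2=np.zeros((n, T)),
        meta={"svl_mean": 0.0, "svl_sd": 1.0, "fgrm_mean": 0.0, "fgrm_sd": 1.0},
    )
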