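"""Von Bertalanffy growth from mark-recapture length increments.

The Fabens formulation needs no known ages: for an individual measured at
length L1 and recaptured Dt years later at L2, the expected increment is

    E[L2 - L1] = (L_inf - L1) * (1 - exp(-K * Dt))

which is fit by nonlinear least squares over first/last capture pairs
separated by at least one winter.  The fitted curve then predicts length at
any occasion (forward or backward in time) and back-calculates an age, hence
a birth year, from a single length measurement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class GrowthFit:
    """Asymptotic length L_inf (cm), growth coefficient K (1/yr), residual SD."""

    linf: float
    k: float
    sigma: float
    n_pairs: int
    group: tuple = ()

    def __post_init__(self) -> None:
        if not (self.linf > 0 and self.k > 0):
            raise ValueError("GrowthFit requires L_inf > 0 and K > 0")


@dataclass
class GrowthModelTable:
    """AICc comparison across candidate parameterizations."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    @property
    def best(self) -> str:
        return self.table.iloc[0]["model"]

    def best_fits(self) -> dict:
        return self.fits[self.best]


def capture_pairs(captures: pd.DataFrame) -> pd.DataFrame:
    """First/last capture pairs with Dt >= 1 winter and measured lengths.

    ``captures`` columns: id, year, svl_cm (day-of-year optional: when a
    ``doy`` column is present, Dt is resolved to fractional years).  Pairs
    with Dt = 0 are excluded with a warning.
    """
    cap = captures.dropna(subset=["svl_cm"]).copy()
    cap["t"] = cap["year"].astype(float)
    if "doy" in cap.columns and cap["doy"].notna().all():
        cap["t"] = cap["year"].astype(float) + cap["doy"].astype(float) / 365.25
    rows = []
    dropped = 0
    for ident, grp in cap.groupby("id"):
        grp = grp.sort_values("t")
        if len(grp) < 2:
            continue
        first, last = grp.iloc[0], grp.iloc[-1]
        dt = last["t"] - first["t"]
        if int(last["year"]) - int(first["year"]) < 1:
            dropped += 1
            continue
        rows.append(
            {
                "id": ident,
                "l1": float(first["svl_cm"]),
                "l2": float(last["svl_cm"]),
                "dt": float(dt),
                "site": first.get("site", ""),
                "sex": first.get("sex", "U"),
            }
        )
    if dropped:
        warnings.warn(
            f"excluded {dropped} recapture pair(s) not separated by a winter",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def _fabens_fit_arrays(l1, l2, dt, group_linf, group_k):
    """Least-squares Fabens fit with group-mapped L_inf and K.

    ``group_linf``/``group_k`` are integer codes mapping each pair to its
    parameter level.  Multi-start over a K grid; returns (linf[], k[], sse).
    """
    n_linf = group_linf.max() + 1
    n_k = group_k.max() + 1
    linf0 = 1.1 * l2.max()

    def resid(theta):
        linf = theta[:n_linf][group_linf]
        kk = np.exp(theta[n_linf:])[group_k]
        return (linf - l1) * (1.0 - np.exp(-kk * dt)) - (l2 - l1)

    best = None
    tried = []
    for k0 in (0.1, 0.3, 0.5, 0.7, 1.0):
        theta0 = np.concatenate([np.full(n_linf, linf0), np.full(n_k, np.log(k0))])
        tried.append(k0)
        try:
            sol = least_squares(resid, theta0, xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(sol.fun**2))
        if sol.success and (best is None or sse < best[1] - 1e-12):
            best = (sol.x, sse)
    if best is None:
        raise RuntimeError(
            f"Fabens fit failed to converge from K starts {tried}"
        )
    theta, sse = best
    return theta[:n_linf], np.exp(theta[n_linf:]), sse


def fit_fabens(
    captures: pd.DataFrame, grouping: tuple = ()
) -> dict[tuple, GrowthFit]:
    """Fit the Fabens model, optionally stratified by factors.

    ``grouping`` names capture columns (e.g. ("site",) or ("site", "sex"));
    a fully stratified fit is performed per factor-level combination.  Returns
    a dict keyed by group tuple (the empty tuple for a pooled fit).
    """
    pairs = capture_pairs(captures)
    if len(pairs) < 3:
        raise ValueError("need >= 3 usable recapture pairs")
    out: dict[tuple, GrowthFit] = {}
    if not grouping:
        groups = [((), pairs)]
    else:
        groups = [
            (key if isinstance(key, tuple) else (key,), grp)
            for key, grp in pairs.groupby(list(grouping))
        ]
    for key, grp in groups:
        if len(grp) < 3:
            raise ValueError(f"group {key} has fewer than 3 recapture pairs")
        zeros = np.zeros(len(grp), dtype=int)
        linf, kk, sse = _fabens_fit_arrays(
            grp["l1"].to_numpy(), grp["l2"].to_numpy(), grp["dt"].to_numpy(), zeros, zeros
        )
        out[key] = GrowthFit(
            linf=float(linf[0]),
            k=float(kk[0]),
            sigma=float(np.sqrt(sse / len(grp))),
            n_pairs=len(grp),
            group=key,
        )
    return out


def select_growth_models(
    captures: pd.DataFrame, factors: tuple = ("site", "sex")
) -> GrowthModelTable:
    """AICc over combinatorial {shared, per-factor, per-interaction} candidates.

    Each candidate assigns L_inf and K independently to one grouping drawn
    from: shared, each single factor, and the full interaction of ``factors``.
    Gaussian increment likelihood; AICc on the number of mean parameters + 1.
    """
    pairs = capture_pairs(captures)
    if len(pairs) < 3:
        raise ValueError("need >= 3 usable recapture pairs")
    options: dict[str, np.ndarray] = {"1": np.zeros(len(pairs), dtype=int)}
    for f in factors:
        if f in pairs.columns and pairs[f].nunique() > 1:
            options[f] = pd.factorize(pairs[f])[0]
    if len(factors) == 2 and all(f in options for f in factors):
        inter = pairs[factors[0]].astype(str) + ":" + pairs[factors[1]].astype(str)
        options["*".join(factors)] = pd.factorize(inter)[0]

    l1 = pairs["l1"].to_numpy()
    l2 = pairs["l2"].to_numpy()
    dt = pairs["dt"].to_numpy()
    n = len(pairs)
    rows = []
    fits = {}
    for g_linf, g_k in itertools.product(options, options):
        name = f"Linf({g_linf}) K({g_k})"
        try:
            linf, kk, sse = _fabens_fit_arrays(l1, l2, dt, options[g_linf], options[g_k])
        except RuntimeError:
            rows.append({"model": name, "aicc": np.nan, "k": np.nan, "failed": True})
            continue
        kpar = len(linf) + len(kk) + 1
        sigma2 = sse / n
        lnl = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        aicc = -2 * lnl + 2 * kpar + 2 * kpar * (kpar + 1) / max(n - kpar - 1, 1)
        rows.append(
            {"model": name, "aicc": aicc, "k": kpar, "lnl": lnl, "failed": False}
        )
        fits[name] = {
            "linf": linf,
            "k": kk,
            "sigma": float(np.sqrt(sigma2)),
            "group_linf": g_linf,
            "group_k": g_k,
        }
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    rel = np.exp(-0.5 * tab["delta_aicc"])
    tab["weight"] = rel / rel.sum()
    return GrowthModelTable(table=tab, fits=fits)


def predict_svl(fit: GrowthFit, svl_at: float, t_from: float, t_to: float) -> float:
    """Project a length along the fitted curve from t_from to t_to.

    ``L(t_to) = L_inf - (L_inf - L(t_from)) * exp(-K (t_to - t_from))``;
    exact inversion going backward.  A length at or above the asymptote is
    returned unchanged for forward prediction (no shrinkage).
    """
    dt = t_to - t_from
    if svl_at >= fit.linf and dt >= 0:
        warnings.warn(
            "length at/above the asymptote: returned unchanged", stacklevel=2
        )
        return float(svl_at)
    return float(fit.linf - (fit.linf - svl_at) * np.exp(-fit.k * dt))


def back_calculate_birth_year(
    fit: GrowthFit,
    svl: float,
    capture_year: int,
    svl_birth: float = 19.0,
    max_age: float = 30.0,
):
    """Estimate birth year (with +/- 2 y bounds) from a single length.

    ``age = -(1/K) ln((L_inf - svl) / (L_inf - svl_birth))``; an individual
    at or beyond the asymptote gets the configurable maximum age.
    Returns (birth_year, byr_min, byr_max).
    """
    if svl_birth >= fit.linf:
        raise ValueError("svl_birth must be below L_inf")
    if svl >= fit.linf:
        warnings.warn("length at/above asymptote: using max_age", stacklevel=2)
        age = max_age
    else:
        age = -np.log((fit.linf - svl) / (fit.linf - svl_birth)) / fit.k
        age = max(0.0, min(age, max_age))
    byr = int(capture_year - round(age))
    return byr, byr - 2, byr + 2


def occasion_svl_table(
    captures: pd.DataFrame, fits: dict[tuple, GrowthFit], years, grouping: tuple = ()
) -> pd.DataFrame:
    """Predicted length for every individual at every occasion year.

    Anchored at each individual's first measured capture and projected with
    its group's fit (pooled fit when ``grouping`` is empty).  Rows = ids,
    columns = years.
    """
    years = list(years)
    cap = captures.dropna(subset=["svl_cm"]).sort_values("year")
    rows = {}
    for ident, grp in cap.groupby("id"):
        first = grp.iloc[0]
        key = tuple(first[f] for f in grouping) if grouping else ()
        fit = fits.get(key) or fits.get(())
        if fit is None:
            continue
        rows[ident] = [
            predict_svl(fit, float(first["svl_cm"]), float(first["year"]), float(y))
            for y in years
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=years)
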