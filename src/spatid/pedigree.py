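"""Pedigree container, kinship/inbreeding, and reproductive-success extraction.

Kinship follows the classical recursion on a parent-before-offspring ordering:
``k(i,i) = (1 + F_i)/2`` with ``F_i = k(dam_i, sire_i)``, and
``k(i,j) = (k(dam_i, j) + k(sire_i, j))/2`` for j not a descendant of i;
founders (and unknown parents) are unrelated and non-inbred.  Pedigree
inbreeding of an individual is exactly the kinship of its parents.

Reproductive success is the number of pedigree children, with a correction
for captive-born offspring: a child born in captivity counts toward its
mother's output only if it was encountered in the field after birth or left
descendants of its own in the pedigree (evidence it survived to adulthood).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

UNKNOWN = ""  # sentinel for an unknown parent


@dataclass
class Pedigree:
    """Parent-offspring links with sex, birth-year bounds and status flags.

    ``table`` columns: id, dam, sire, sex ('F'/'M'/'U'), birth_year, byr_min,
    byr_max, genotyped (bool), dummy (bool), site.  Unknown parents are the
    empty string.  Construction validates referential integrity, parent sex
    and acyclicity.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col, default in (
            ("dam", UNKNOWN),
            ("sire", UNKNOWN),
            ("sex", "U"),
            ("birth_year", np.nan),
            ("byr_min", np.nan),
            ("byr_max", np.nan),
            ("genotyped", True),
            ("dummy", False),
            ("site", ""),
        ):
            if col not in t.columns:
                t[col] = default
        t["id"] = t["id"].astype(str)
        t["dam"] = t["dam"].fillna(UNKNOWN).astype(str)
        t["sire"] = t["sire"].fillna(UNKNOWN).astype(str)
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate pedigree ids: {dups[:5]}")
        self.table = t.reset_index(drop=True)
        ids = set(t["id"])
        sex = dict(zip(t["id"], t["sex"]))
        for col, want in (("dam", "F"), ("sire", "M")):
            parents = set(t[col]) - {UNKNOWN}
            missing = parents - ids
            if missing:
                raise ValueError(f"{col} ids not present as records: {sorted(missing)[:5]}")
            bad = [p for p in parents if sex.get(p, "U") not in (want, "U")]
            if bad:
                raise ValueError(f"{col} ids with wrong sex: {bad[:5]}")
        self._dam = dict(zip(t["id"], t["dam"]))
        self._sire = dict(zip(t["id"], t["sire"]))
        self._order = self._topological_order()

    # -- structure ----------------------------------------------------------

    def _topological_order(self) -> list[str]:
        """Parents-before-offspring order; raises naming a cycle if one exists."""
        ids = list(self.table["id"])
        state: dict[str, int] = {}
        order: list[str] = []
        for start in ids:
            if state.get(start) == 2:
                continue
            stack = [(start, False)]
            path: list[str] = []
            while stack:
                node, done = stack.pop()
                if done:
                    state[node] = 2
                    order.append(node)
                    path.pop()
                    continue
                if state.get(node) == 2:
                    continue
                if state.get(node) == 1:
                    cyc = path[path.index(node):] + [node]
                    raise ValueError(f"pedigree cycle detected: {' -> '.join(cyc)}")
                state[node] = 1
                path.append(node)
                stack.append((node, True))
                for par in (self._dam[node], self._sire[node]):
                    if par != UNKNOWN and state.get(par) != 2:
                        stack.append((par, False))
            # path bookkeeping above keeps `path` as the grey (in-progress) chain
        return order

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def dam(self, i: str) -> str:
        return self._dam[i]

    def sire(self, i: str) -> str:
        return self._sire[i]

    def children(self) -> dict[str, list[str]]:
        """parent id -> list of child ids (via either link)."""
        out: dict[str, list[str]] = {}
        for cid in self.table["id"]:
            for par in (self._dam[cid], self._sire[cid]):
                if par != UNKNOWN:
                    out.setdefault(par, []).append(cid)
        return out


# ---------------------------------------------------------------------------
# kinship and inbreeding
# ---------------------------------------------------------------------------


def kinship_matrix(p: Pedigree, ids=None) -> pd.DataFrame:
    """Pairwise kinship coefficients by the tabular recursion.

    Computes the full matrix over all pedigree members in topological order,
    then returns the (symmetric) submatrix for ``ids`` (default: everyone).
    """
    order = p._order
    pos = {v: i for i, v in enumerate(order)}
    n = len(order)
    K = np.zeros((n, n))
    for i, ident in enumerate(order):
        d, s = p.dam(ident), p.sire(ident)
        kd = K[pos[d], :i] if d != UNKNOWN else 0.0
        ks = K[pos[s], :i] if s != UNKNOWN else 0.0
        if i > 0:
            row = 0.5 * (np.asarray(kd) + np.asarray(ks))
            K[i, :i] = row
            K[:i, i] = row
        f = K[pos[d], pos[s]] if d != UNKNOWN and s != UNKNOWN else 0.0
        K[i, i] = 0.5 * (1.0 + f)
    df = pd.DataFrame(K, index=order, columns=order)
    if ids is None:
        ids = p.ids
    else:
        ids = [str(i) for i in ids]
        unknown = set(ids) - set(order)
        if unknown:
            raise KeyError(f"ids not in pedigree: {sorted(unknown)[:5]}")
    return df.loc[ids, ids]


def pedigree_inbreeding(p: Pedigree) -> pd.Series:
    """Per-individual inbreeding coefficient F = kinship(dam, sire).

    Individuals with any unknown parent get F = 0 (parents treated as
    unrelated founders).
    """
    K = kinship_matrix(p)
    out = {}
    for ident in p.ids:
        d, s = p.dam(ident), p.sire(ident)
        out[ident] = float(K.loc[d, s]) if d != UNKNOWN and s != UNKNOWN else 0.0
    return pd.Series(out, name="pedigree_f")


# ---------------------------------------------------------------------------
# reproductive success
# ---------------------------------------------------------------------------


def reproductive_success(
    p: Pedigree,
    captures: pd.DataFrame | None = None,
    lab_born: set | None = None,
    age_maturity: int = 3,
    study_years: tuple[int, int] | None = None,
    include_dummy_offspring: bool = True,
) -> pd.DataFrame:
    """Per-individual offspring counts and contribution years.

    ``captures`` needs columns id, year (used for "recaptured after birth"
    and last-known-alive).  ``lab_born`` ids are captive-born offspring: one
    counts toward its *mother* only if it has a field capture after its birth
    year or has descendants in the pedigree.  ``years_contributing`` counts
    calendar years y in the study window with
    ``birth_year + age_maturity <= y <= last year known alive`` where the
    last-alive year is the latest of last capture and last child's birth year.
    """
    lab_born = {str(i) for i in (lab_born or set())}
    unknown_lab = lab_born - set(p.ids)
    if unknown_lab:
        warnings.warn(
            f"lab-born ids absent from pedigree ignored: {sorted(unknown_lab)[:5]}",
            stacklevel=2,
        )
    t = p.table.set_index("id")
    child_map = p.children()
    cap_years: dict[str, list[int]] = {}
    if captures is not None and len(captures):
        for ident, grp in captures.groupby(captures["id"].astype(str)):
            cap_years[ident] = sorted(int(y) for y in grp["year"])

    def _has_descendants(ident: str) -> bool:
        stack = list(child_map.get(ident, []))
        return len(stack) > 0

    def _lab_born_counts(ident: str) -> bool:
        """Captive-born child passes if re-encountered after birth or has its own descendants."""
        byr = t.loc[ident, "birth_year"]
        years = cap_years.get(ident, [])
        recaptured = (
            any((pd.isna(byr) or y > byr) for y in years) if years else False
        )
        return recaptured or _has_descendants(ident)

    rows = []
    study_lo = study_hi = None
    if study_years is not None:
        study_lo, study_hi = study_years
    elif cap_years:
        allyears = [y for ys in cap_years.values() for y in ys]
        study_lo, study_hi = min(allyears), max(allyears)

    for ident in p.ids:
        kids = child_map.get(ident, [])
        if not include_dummy_offspring:
            kids = [k for k in kids if not bool(t.loc[k, "dummy"])]
        n_off = 0
        for k in kids:
            if k in lab_born and t.loc[k, "dam"] == ident and not _lab_born_counts(k):
                continue
            n_off += 1
        byr = t.loc[ident, "birth_year"]
        last_alive = -np.inf
        if cap_years.get(ident):
            last_alive = max(last_alive, max(cap_years[ident]))
        kid_byrs = [t.loc[k, "birth_year"] for k in child_map.get(ident, [])]
        kid_byrs = [b for b in kid_byrs if not pd.isna(b)]
        if kid_byrs:
            last_alive = max(last_alive, max(kid_byrs))
        if study_lo is None or pd.isna(byr) or not np.isfinite(last_alive):
            years_contrib = 0
        else:
            lo = max(study_lo, int(byr) + age_maturity)
            hi = min(study_hi, int(last_alive))
            years_contrib = max(0, hi - lo + 1)
        rows.append(
            {
                "id": ident,
                "sex": t.loc[ident, "sex"],
                "site": t.loc[ident, "site"],
                "n_offspring": int(n_off),
                "years_contributing": int(years_contrib),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# concordance and edge effects
# ---------------------------------------------------------------------------


def fgrm_vs_pedigree_f(fgrm: pd.Series, ped_f: pd.Series):
    """Pearson correlation between genomic and pedigree inbreeding.

    Returns ``(r, df, p)`` with df = n - 2 over the shared ids.
    """
    shared = fgrm.index.intersection(ped_f.index)
    x = fgrm.loc[shared].astype(float)
    y = ped_f.loc[shared].astype(float)
    ok = ~(x.isna() | y.isna())
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 shared ids")
    if x.max() - x.min() == 0 or y.max() - y.min() == 0:
        raise ValueError("zero variance in one of the inbreeding vectors")
    r, pval = stats.pearsonr(x, y)
    return float(r), int(len(x) - 2), float(pval)


def edge_effect_regression(rec: pd.DataFrame, centroids: pd.DataFrame):
    """OLS of offspring count on distance from the site's central point.

    The central point is the centroid of individual centroids.  Returns a
    dict with slope, se, r_squared, f_stat, p, n.
    """
    import statsmodels.api as sm

    merged = rec.merge(centroids, left_on="id", right_index=True, how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 individuals with coordinates")
    cx, cy = merged["x"].mean(), merged["y"].mean()
    dist = np.hypot(merged["x"] - cx, merged["y"] - cy)
    X = sm.add_constant(np.asarray(dist))
    fit = sm.OLS(np.asarray(merged["n_offspring"], dtype=float), X).fit()
    return {
        "slope": float(fit.params[1]),
        "se": float(fit.bse[1]),
        "r_squared": float(fit.rsquared_adj),
        "f_stat": float(fit.fvalue),
        "p": float(fit.f_pvalue),
        "n": int(len(merged)),
    }
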