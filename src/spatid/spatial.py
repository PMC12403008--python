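"""Spatial kinship structure: centroids, distance classes, KS tests, IBD.

Limited dispersal leaves a footprint: close kin live closer together than
unrelated animals, and genetic similarity decays with distance (isolation by
distance).  This module collapses recaptures to per-individual centroids,
classifies pairs of individuals by pedigree relationship, compares the
distance distributions of related classes against unrelated-without-offspring
pairs with (Bonferroni-corrected) Kolmogorov-Smirnov tests, measures
isolation by distance as a Spearman correlation with a location-permutation
p-value, and runs the nearby-pair t tests that guard the inbreeding-
depression models against spatial confounding.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import UNKNOWN, Pedigree, kinship_matrix

RELATED_CLASSES = ("dam_offspring", "sire_offspring", "parent_pair")


def capture_centroids(captures: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each individual's capture coordinates.

    Individuals captured once keep that location; rows with missing
    coordinates are dropped (the individual is excluded, with a warning, if
    none remain).  Returns a DataFrame indexed by id with columns x, y.
    """
    cap = captures.copy()
    cap["id"] = cap["id"].astype(str)
    ok = cap[["x", "y"]].notna().all(axis=1)
    dropped_ids = set(cap.loc[~ok, "id"]) - set(cap.loc[ok, "id"])
    if dropped_ids:
        warnings.warn(
            f"excluding {len(dropped_ids)} individual(s) with no usable coordinates",
            stacklevel=2,
        )
    cent = cap.loc[ok].groupby("id")[["x", "y"]].mean()
    return cent


def classify_pairs(
    p: Pedigree, centroids: pd.DataFrame, rec: pd.DataFrame
) -> pd.DataFrame:
    """Pairs of individuals labeled by relationship class with distances.

    Classes, mutually exclusive in priority order: dam_offspring,
    sire_offspring, parent_pair (a dam-sire pair sharing at least one
    pedigree child), and unrelated_no_offspring (pedigree kinship exactly 0,
    neither member has offspring).  Distances are Euclidean on centroids;
    pairs lacking a centroid are skipped.
    """
    have = set(centroids.index.astype(str))
    n_off = dict(zip(rec["id"].astype(str), rec["n_offspring"]))

    def dist(a: str, b: str) -> float:
        pa, pb = centroids.loc[a], centroids.loc[b]
        return float(np.hypot(pa["x"] - pb["x"], pa["y"] - pb["y"]))

    rows = []
    seen: set[frozenset] = set()

    def add(a: str, b: str, cls: str) -> None:
        key = frozenset((a, b))
        if a == b or key in seen or a not in have or b not in have:
            return
        seen.add(key)
        rows.append({"id1": a, "id2": b, "class": cls, "distance_m": dist(a, b)})

    parent_pairs = set()
    for ident in p.ids:
        d, s = p.dam(ident), p.sire(ident)
        if d != UNKNOWN:
            add(d, ident, "dam_offspring")
        if s != UNKNOWN:
            add(s, ident, "sire_offspring")
        if d != UNKNOWN and s != UNKNOWN:
            parent_pairs.add((d, s))
    for d, s in sorted(parent_pairs):
        add(d, s, "parent_pair")

    no_off = [
        i for i in p.ids if n_off.get(i, 0) == 0 and i in have
    ]
    if no_off:
        K = kinship_matrix(p, no_off).to_numpy()
        for (ai, a), (bi, b) in combinations(enumerate(no_off), 2):
            if K[ai, bi] == 0.0:
                add(a, b, "unrelated_no_offspring")
    return pd.DataFrame(rows)


def ks_compare(classes: pd.DataFrame, n_comparisons: int | None = None) -> pd.DataFrame:
    """Two-sample KS of each related class's distances vs the unrelated class.

    The Bonferroni adjustment multiplies each p by ``n_comparisons`` (default:
    the number of tests actually run), capping at 1.  Empty classes are
    skipped with a warning.
    """
    ref = classes.loc[classes["class"] == "unrelated_no_offspring", "distance_m"]
    if len(ref) < 2:
        raise ValueError("unrelated_no_offspring reference class has fewer than 2 pairs")
    rows = []
    for cls in RELATED_CLASSES:
        vals = classes.loc[classes["class"] == cls, "distance_m"]
        if len(vals) < 2:
            warnings.warn(f"class {cls} has <2 pairs; skipped", stacklevel=2)
            continue
        res = stats.ks_2samp(vals, ref)
        rows.append(
            {"class": cls, "n": len(vals), "n_ref": len(ref), "D": res.statistic, "p": res.pvalue}
        )
    out = pd.DataFrame(rows)
    m = n_comparisons if n_comparisons is not None else len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    return out


def isolation_by_distance(
    pi: pd.DataFrame, centroids: pd.DataFrame, n_perm: int = 999, seed: int = 0
) -> dict:
    """Spearman correlation of pairwise genetic mismatch with distance.

    Mantel-style significance: individual locations are permuted ``n_perm``
    times (seeded) and the one-sided p is the fraction of permuted
    correlations at least as large as observed.
    """
    shared = [i for i in pi.index if i in centroids.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 individuals with both genotypes and locations")
    P = pi.loc[shared, shared].to_numpy()
    xy = centroids.loc[shared, ["x", "y"]].to_numpy()
    D = np.hypot(
        xy[:, [0]] - xy[:, 0][None, :], xy[:, [1]] - xy[:, 1][None, :]
    )
    iu = np.triu_indices(len(shared), k=1)
    pvec = P[iu]
    ok = ~np.isnan(pvec)
    if np.std(D[iu][ok]) == 0:
        raise ValueError("constant pairwise distances")
    rho = stats.spearmanr(pvec[ok], D[iu][ok]).statistic
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(shared))
        Dp = D[np.ix_(perm, perm)][iu]
        r = stats.spearmanr(pvec[ok], Dp[ok]).statistic
        if r >= rho:
            count += 1
    return {
        "rho": float(rho),
        "p": float((count + 1) / (n_perm + 1)),
        "n_individuals": len(shared),
        "n_perm": n_perm,
    }


def _ttest(a, b, pooled: bool) -> dict:
    res = stats.ttest_ind(a, b, equal_var=pooled)
    df = (len(a) + len(b) - 2) if pooled else float(res.df)
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def nearby_pair_tests(
    centroids: pd.DataFrame,
    fgrm: pd.Series,
    has_offspring: pd.Series,
    radius_m: float = 25.0,
) -> dict:
    """F_grm contrasts among pairs of individuals within ``radius_m``.

    Builds unordered pairs of individuals whose centroids are within the
    radius, splits them into (no-offspring, parent) and (no-offspring,
    no-offspring) pairs, and reports:

    a. two-sample t (pooled df, Welch also reported) comparing the F_grm of
       the no-offspring members against their nearby parents;
    b. two-sample t comparing no-offspring members of mixed pairs against
       members of no-offspring pairs;
    c. Welch two-sample t comparing the within-pair F_grm differences of the
       two pair types.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    ids = [
        i
        for i in centroids.index.astype(str)
        if i in fgrm.index and not pd.isna(fgrm.get(i)) and i in has_offspring.index
    ]
    xy = centroids.loc[ids, ["x", "y"]].to_numpy()
    n = len(ids)
    D = np.hypot(xy[:, [0]] - xy[:, 0][None, :], xy[:, [1]] - xy[:, 1][None, :])
    f = fgrm.loc[ids].to_numpy(dtype=float)
    par = has_offspring.loc[ids].to_numpy(dtype=bool)
    np_pairs = []  # (F_no_offspring, F_parent)
    nn_pairs = []  # (F_a, F_b), both no offspring
    iu, ju = np.where(np.triu(D <= radius_m, k=1))
    for i, j in zip(iu, ju):
        if par[i] and not par[j]:
            np_pairs.append((f[j], f[i]))
        elif par[j] and not par[i]:
            np_pairs.append((f[i], f[j]))
        elif not par[i] and not par[j]:
            nn_pairs.append((f[i], f[j]))
    if not np_pairs or not nn_pairs:
        raise ValueError("no usable pairs within the radius")
    np_pairs = np.array(np_pairs)
    nn_pairs = np.array(nn_pairs)
    out = {
        "n_pairs_no_offspring_parent": int(len(np_pairs)),
        "n_pairs_no_offspring_no_offspring": int(len(nn_pairs)),
        "a_vs_nearby_parents": _ttest(np_pairs[:, 0], np_pairs[:, 1], pooled=True),
        "a_vs_nearby_parents_welch": _ttest(np_pairs[:, 0], np_pairs[:, 1], pooled=False),
        "b_vs_nearby_no_offspring": _ttest(
            np_pairs[:, 0], nn_pairs.ravel(), pooled=True
        ),
        "c_pair_differences_welch": _ttest(
            np_pairs[:, 0] - np_pairs[:, 1],
            nn_pairs[:, 0] - nn_pairs[:, 1],
            pooled=False,
        ),
    }
    return out
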