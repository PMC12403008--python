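"""Genotype-matrix container and population-genomic summaries.

The central container is :class:`GenotypeMatrix`: an individuals x loci matrix
of alternate-allele counts (0/1/2, NaN = missing call) with per-locus genomic
coordinates and a per-individual deme ("site") label.  On top of it this
module implements

* per-locus allele frequencies on an explicit reference sample,
* the genomic inbreeding coefficient ``F_grm`` (diagonal of a genomic
  relationship matrix, von-Wright-scaled so outbred = 0),
* the standard locus/individual quality filters (missingness, heterozygote
  excess, MAF, physical spacing),
* pairwise nucleotide mismatch (pi) between individuals,
* principal components of the genotype matrix,
* Weir & Cockerham's two-population F_ST,
* replicate-concordance genotyping-error rate with a jackknife CI, and
* the linkage-disequilibrium (r^2) effective-population-size estimator.

All estimators treat missing calls by pairwise/casewise deletion unless
documented otherwise; nothing here imputes except the PCA (per-locus mean
fill, the standard choice for genotype PCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x loci alternate-allele counts with coordinates.

    Parameters
    ----------
    individual_ids : sequence of str
        Row labels, unique.
    locus_ids : sequence of str
        Column labels, unique.
    calls : ndarray of shape (n_individuals, n_loci)
        Values in {0, 1, 2} counting alternate-allele copies; NaN = missing.
    chrom, pos_bp : per-locus chromosome name and 1-based position.
    site_labels : per-individual deme label.
    """

    individual_ids: np.ndarray
    locus_ids: np.ndarray
    calls: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    site_labels: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=int)
        self.site_labels = np.asarray(self.site_labels, dtype=object)
        n, L = self.calls.shape
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls rows")
        if len(self.locus_ids) != L or len(self.chrom) != L or len(self.pos_bp) != L:
            raise ValueError("locus metadata length does not match calls columns")
        if len(self.site_labels) != n:
            raise ValueError("site_labels length does not match calls rows")
        if len(set(self.locus_ids)) != L:
            raise ValueError("locus_ids must be unique")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual_ids must be unique")
        ok = np.isnan(self.calls) | np.isin(self.calls, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or NaN")
        if np.any(self.pos_bp < 1):
            raise ValueError("pos_bp must be >= 1")

    # -- basic views --------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def individual_index(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown individual id {exc}") from None

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.individual_ids[index],
            self.locus_ids,
            self.calls[index],
            self.chrom,
            self.pos_bp,
            self.site_labels[index],
        )

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.individual_ids,
            self.locus_ids[index],
            self.calls[:, index],
            self.chrom[index],
            self.pos_bp[index],
            self.site_labels,
        )

    def subset_ids(self, ids) -> "GenotypeMatrix":
        return self.take_individuals(self.individual_index(ids))


@dataclass
class AlleleFrequencies:
    """Per-locus alternate-allele frequency and non-missing genotype count."""

    freq: np.ndarray
    n_called: np.ndarray
    locus_ids: np.ndarray

    def __post_init__(self) -> None:
        with np.errstate(invalid="ignore"):
            bad = (self.freq < 0) | (self.freq > 1)
        if np.any(bad & ~np.isnan(self.freq)):
            raise ValueError("allele frequencies must lie in [0, 1]")


@dataclass
class InbreedingEstimates:
    """Per-individual F_grm with the count of loci each estimate used."""

    individual_ids: np.ndarray
    fgrm: np.ndarray
    n_loci_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.individual_ids, "fgrm": self.fgrm, "n_loci": self.n_loci_used}
        )

    def as_series(self) -> pd.Series:
        return pd.Series(self.fgrm, index=self.individual_ids, name="fgrm")


# ---------------------------------------------------------------------------
# allele frequencies and F_grm
# ---------------------------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix, subset=None) -> AlleleFrequencies:
    """Alternate-allele frequency per locus on a reference sample.

    ``subset`` is an iterable of individual ids (default: everyone).  Loci
    with zero non-missing calls in the subset get frequency NaN.
    """
    if subset is None:
        calls = g.calls
    else:
        subset = list(subset)
        if len(subset) == 0:
            raise ValueError("reference subset is empty")
        calls = g.calls[g.individual_index(subset)]
    n_called = np.sum(~np.isnan(calls), axis=0)
    alt = np.nansum(calls, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
    return AlleleFrequencies(freq=freq, n_called=n_called, locus_ids=g.locus_ids)


def compute_fgrm(g: GenotypeMatrix, freqs: AlleleFrequencies) -> InbreedingEstimates:
    """Genomic inbreeding from the diagonal of the genomic relationship matrix.

    For individual j with genotype ``x_i`` (copies of the alternate allele) at
    locus i and reference frequency ``p_i``::

        F_grm = (1/L) * sum_i [x_i^2 - (1 + 2 p_i) x_i + 2 p_i^2]
                              / (2 p_i (1 - p_i))

    where L counts the loci actually summed for that individual: loci with a
    missing call, a missing frequency, or a monomorphic reference frequency
    (p_i = 0 or 1, undefined denominator) are dropped per individual.  Under
    Hardy-Weinberg proportions at the reference frequencies every per-locus
    term has expectation zero, so outbred individuals score near 0; negative
    values indicate an excess of heterozygosity.
    """
    if not np.array_equal(freqs.locus_ids, g.locus_ids):
        raise ValueError("frequency locus_ids do not match genotype locus_ids")
    p = freqs.freq
    x = g.calls
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 2.0 * p * (1.0 - p)
        term = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / denom
    usable = ~np.isnan(x) & ~np.isnan(p) & (p > 0.0) & (p < 1.0)
    term = np.where(usable, term, 0.0)
    L = usable.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fgrm = np.where(L > 0, term.sum(axis=1) / L, np.nan)
    if np.any(L == 0):
        warnings.warn(
            f"{int(np.sum(L == 0))} individual(s) had zero usable loci; F_grm set to NaN",
            stacklevel=2,
        )
    return InbreedingEstimates(
        individual_ids=g.individual_ids, fgrm=fgrm, n_loci_used=L
    )


def fgrm_per_site(g: GenotypeMatrix) -> InbreedingEstimates:
    """F_grm with the reference allele frequencies computed per deme.

    Mirrors estimating inbreeding "for individuals in each population
    separately": each individual's reference sample is every individual
    sharing its site label.
    """
    fgrm = np.full(g.n_individuals, np.nan)
    nloc = np.zeros(g.n_individuals, dtype=int)
    for site in pd.unique(g.site_labels):
        idx = np.where(g.site_labels == site)[0]
        sub = g.take_individuals(idx)
        est = compute_fgrm(sub, allele_frequencies(sub))
        fgrm[idx] = est.fgrm
        nloc[idx] = est.n_loci_used
    return InbreedingEstimates(g.individual_ids, fgrm, nloc)


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def _hwe_het_excess_pvalue(n_het: int, n_alt: int, n: int) -> float:
    """Exact one-sided (toward heterozygote excess) Hardy-Weinberg test.

    Conditional distribution of the heterozygote count given the minor-allele
    count ``n_alt`` among ``n`` diploids; p-value sums the probabilities of
    heterozygote counts >= observed (same parity as n_alt).
    """
    n_rare = min(n_alt, 2 * n - n_alt)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    n_aa = (n_rare - hets) // 2
    n_bb = n - hets - n_aa
    # log P(h | n_rare, n) up to a constant
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(n_aa + 1)
        - gammaln(hets + 1)
        - gammaln(n_bb + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    return float(prob[hets >= n_het].sum())


@dataclass
class FilterReport:
    """Loci/individuals removed at each filtering step, in application order."""

    steps: list = field(default_factory=list)

    def add(self, step: str, removed: int, kept: int) -> None:
        self.steps.append({"step": step, "removed": int(removed), "kept": int(kept)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def filter_genotypes(
    g: GenotypeMatrix,
    max_locus_missing: float = 0.10,
    max_indiv_missing: float = 0.20,
    min_maf: float = 0.05,
    het_excess_alpha: float = 0.05,
    min_spacing_bp: int = 100_000,
    seed: int = 0,
    het_test_per_site: bool = False,
):
    """Quality filters applied in a fixed order, with a per-step report.

    Order: locus missingness, individual missingness, heterozygote-excess
    exact test (one-sided), minor-allele frequency, then physical spacing
    thinning that keeps one randomly chosen locus per ``min_spacing_bp``
    window on each chromosome (seeded, hence reproducible and idempotent).

    Returns ``(filtered GenotypeMatrix, FilterReport)``.
    """
    report = FilterReport()
    out = g

    # 1. locus missingness
    miss = np.mean(np.isnan(out.calls), axis=0)
    keep = miss <= max_locus_missing
    report.add("locus_missingness", np.sum(~keep), np.sum(keep))
    out = out.take_loci(np.where(keep)[0])
    if out.n_loci == 0:
        raise ValueError("all loci removed at step locus_missingness")

    # 2. individual missingness
    imiss = np.mean(np.isnan(out.calls), axis=1)
    ikeep = imiss <= max_indiv_missing
    report.add("individual_missingness", np.sum(~ikeep), np.sum(ikeep))
    out = out.take_individuals(np.where(ikeep)[0])
    if out.n_individuals == 0:
        raise ValueError("all individuals removed at step individual_missingness")

    # 3. heterozygote-excess exact test
    if het_excess_alpha > 0.0:
        groups = (
            [np.where(out.site_labels == s)[0] for s in pd.unique(out.site_labels)]
            if het_test_per_site
            else [np.arange(out.n_individuals)]
        )
        keep = np.ones(out.n_loci, dtype=bool)
        for l in range(out.n_loci):
            for idx in groups:
                col = out.calls[idx, l]
                col = col[~np.isnan(col)]
                if col.size == 0:
                    continue
                p = _hwe_het_excess_pvalue(
                    int(np.sum(col == 1)), int(np.sum(col)), int(col.size)
                )
                if p < het_excess_alpha:
                    keep[l] = False
                    break
        report.add("het_excess", np.sum(~keep), np.sum(keep))
        out = out.take_loci(np.where(keep)[0])
        if out.n_loci == 0:
            raise ValueError("all loci removed at step het_excess")

    # 4. minor allele frequency
    freq = allele_frequencies(out).freq
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
        keep = maf >= min_maf
    keep &= ~np.isnan(freq)
    report.add("maf", np.sum(~keep), np.sum(keep))
    out = out.take_loci(np.where(keep)[0])
    if out.n_loci == 0:
        raise ValueError("all loci removed at step maf")

    # 5. spacing thinning
    if min_spacing_bp > 0:
        rng = np.random.default_rng(seed)
        keep_idx = []
        for ch in pd.unique(out.chrom):
            idx = np.where(out.chrom == ch)[0]
            # random candidate order, greedy acceptance at >= min_spacing_bp
            order = idx[rng.permutation(len(idx))]
            accepted_pos: list[int] = []
            accepted: list[int] = []
            for j in order:
                pos = out.pos_bp[j]
                if all(abs(pos - q) >= min_spacing_bp for q in accepted_pos):
                    accepted.append(j)
                    accepted_pos.append(pos)
            keep_idx.extend(accepted)
        keep_idx = sorted(keep_idx)
        report.add("spacing", out.n_loci - len(keep_idx), len(keep_idx))
        out = out.take_loci(keep_idx)
        if out.n_loci == 0:
            raise ValueError("all loci removed at step spacing")

    return out, report


# ---------------------------------------------------------------------------
# pairwise pi
# ---------------------------------------------------------------------------


def pairwise_pi(g: GenotypeMatrix) -> pd.DataFrame:
    """Mean per-locus probability of allelic mismatch between individuals.

    For a pair (i, j) and dosage fractions ``a = call/2``, each locus
    contributes ``a_i (1 - a_j) + (1 - a_i) a_j`` — the probability that one
    allele drawn from each individual differs — averaged over loci called in
    both.  Diagonal entries are NaN; pairs sharing no called loci are NaN.
    """
    if g.n_individuals < 2:
        raise ValueError("pairwise_pi needs at least two individuals")
    mask = ~np.isnan(g.calls)
    a = np.where(mask, g.calls / 2.0, 0.0)
    m = mask.astype(float)
    num = a @ (m - a).T + (m - a) @ a.T
    den = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(pi, np.nan)
    return pd.DataFrame(pi, index=g.individual_ids, columns=g.individual_ids)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def genotype_pca(
    g: GenotypeMatrix, min_maf: float = 0.0, n_components: int = 10, scale: bool = False
):
    """Principal components of the genotype matrix.

    Missing calls are filled with the per-locus mean, columns centered and
    (optionally) scaled by sqrt(2 p (1-p)).  Scores come from the SVD of the
    centered matrix; each component's sign is fixed by making its
    largest-magnitude locus loading positive, so repeated runs are identical.

    Returns ``(scores DataFrame indexed by individual, variance_fraction)``.
    """
    if g.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    freq = allele_frequencies(g).freq
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    keep = ~np.isnan(freq) & (maf >= min_maf) if min_maf > 0 else ~np.isnan(freq)
    X = g.calls[:, keep]
    p = freq[keep]
    colmean = 2.0 * p
    X = np.where(np.isnan(X), colmean, X) - colmean
    if scale:
        sd = np.sqrt(np.maximum(2.0 * p * (1.0 - p), 1e-12))
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    # deterministic sign: largest-|loading| positive per component
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U[:, :k] * S[:k]
    total = np.sum(X * X)
    varfrac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=g.individual_ids, columns=cols), varfrac


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def weir_cockerham_fst(g: GenotypeMatrix) -> float:
    """Weir & Cockerham's variance-components F_ST for the two demes.

    Multi-locus ratio of sums of the a (among-population), b (among
    individuals within populations) and c (within-individual) components.
    Returns NaN when every locus is monomorphic.
    """
    sites = pd.unique(g.site_labels)
    if len(sites) != 2:
        raise ValueError("weir_cockerham_fst expects exactly two site labels")
    r = 2
    idx = [np.where(g.site_labels == s)[0] for s in sites]
    A = B = C = 0.0
    any_poly = False
    for l in range(g.n_loci):
        n_i, p_i, h_i = [], [], []
        for ind in idx:
            col = g.calls[ind, l]
            col = col[~np.isnan(col)]
            if col.size == 0:
                break
            n_i.append(col.size)
            p_i.append(np.mean(col) / 2.0)
            h_i.append(np.mean(col == 1))
        else:
            n_i = np.array(n_i, dtype=float)
            p_i = np.array(p_i)
            h_i = np.array(h_i)
            nbar = n_i.mean()
            if nbar <= 1:
                continue
            pbar = np.sum(n_i * p_i) / (r * nbar)
            if pbar <= 0.0 or pbar >= 1.0:
                continue
            any_poly = True
            nc = (r * nbar - np.sum(n_i**2) / (r * nbar)) / (r - 1)
            s2 = np.sum(n_i * (p_i - pbar) ** 2) / ((r - 1) * nbar)
            hbar = np.sum(n_i * h_i) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
            A += a
            B += b
            C += c
    if not any_poly or (A + B + C) == 0.0:
        return float("nan")
    return float(A / (A + B + C))


# ---------------------------------------------------------------------------
# replicate genotyping error
# ---------------------------------------------------------------------------


@dataclass
class ErrorRateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_discordant: int
    n_compared: int


def replicate_error_rate(g: GenotypeMatrix, replicate_pairs) -> ErrorRateEstimate:
    """Genotype discordance between technical replicates.

    ``replicate_pairs`` is a sequence of (id_a, id_b).  The rate pools
    discordant over compared calls across pairs; the 95% CI comes from a
    leave-one-pair-out jackknife.
    """
    pairs = list(replicate_pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two replicate pairs for a jackknife CI")
    disc = np.zeros(len(pairs))
    comp = np.zeros(len(pairs))
    for k, (a, b) in enumerate(pairs):
        ia, ib = g.individual_index([a, b])
        ca, cb = g.calls[ia], g.calls[ib]
        ok = ~np.isnan(ca) & ~np.isnan(cb)
        comp[k] = ok.sum()
        disc[k] = np.sum(ca[ok] != cb[ok])
    total = comp.sum()
    if total == 0:
        raise ValueError("zero compared calls across replicate pairs")
    rate = disc.sum() / total
    # leave-one-pair-out pseudo-estimates
    theta = np.array(
        [
            (disc.sum() - disc[k]) / (comp.sum() - comp[k])
            if (comp.sum() - comp[k]) > 0
            else np.nan
            for k in range(len(pairs))
        ]
    )
    theta = theta[~np.isnan(theta)]
    npairs = len(theta)
    tbar = theta.mean()
    se = np.sqrt((npairs - 1) / npairs * np.sum((theta - tbar) ** 2))
    return ErrorRateEstimate(
        rate=float(rate),
        ci_low=float(max(0.0, rate - 1.96 * se)),
        ci_high=float(rate + 1.96 * se),
        n_discordant=int(disc.sum()),
        n_compared=int(total),
    )


# ---------------------------------------------------------------------------
# LD-based effective population size
# ---------------------------------------------------------------------------


@dataclass
class NeEstimate:
    ne: float
    ci_low: float
    ci_high: float
    r2_mean: float
    r2_drift: float
    n_pairs: int
    sample_size: int


def _ld_ne_point(calls: np.ndarray, pair_ok: np.ndarray) -> tuple[float, float, float]:
    """(mean r2, drift r2, Ne) for a complete-ish 012 matrix."""
    S, L = calls.shape
    colmean = np.nanmean(calls, axis=0)
    X = np.where(np.isnan(calls), colmean, calls)
    sd = X.std(axis=0)
    ok = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - X.mean(axis=0)) / np.where(ok, sd, 1.0)
    R = (Z.T @ Z) / S
    r2 = R**2
    use = pair_ok & np.outer(ok, ok)
    iu = np.triu_indices(L, k=1)
    vals = r2[iu][use[iu]]
    if vals.size == 0:
        raise ValueError("no eligible unlinked locus pairs for LD-Ne")
    r2_mean = float(vals.mean())
    # Waples bias-corrected transform (random mating), regime by sample size
    if S >= 30:
        expected = 1.0 / S + 3.19 / S**2
        r2p = r2_mean - expected
        disc = 1.0 / 9.0 - 2.76 * r2p
        if r2p <= 0 or disc < 0:
            return r2_mean, r2p, float("inf")
        ne = (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2p)
    else:
        expected = 0.0018 + 0.907 / S + 4.44 / S**2
        r2p = r2_mean - expected
        disc = 0.308**2 - 2.08 * r2p
        if r2p <= 0 or disc < 0:
            return r2_mean, r2p, float("inf")
        ne = (0.308 + np.sqrt(disc)) / (2.0 * r2p)
    return r2_mean, r2p, float(ne)


def ld_ne(
    g: GenotypeMatrix,
    cohort,
    min_maf: float = 0.05,
    unlinked_min_bp: int = 100_000,
) -> NeEstimate:
    """Linkage-disequilibrium effective population size for a cohort.

    Computes the mean squared genotypic (composite) correlation r^2 over
    locus pairs on different chromosomes or >= ``unlinked_min_bp`` apart,
    subtracts the sample-size expectation, and applies the bias-corrected
    random-mating transform to Ne.  The 95% CI is a leave-one-individual-out
    jackknife on Ne; a non-positive drift component reports Ne = inf.
    """
    cohort = list(cohort)
    if len(cohort) < 10:
        raise ValueError("cohort must contain at least 10 individuals")
    sub = g.subset_ids(cohort)
    freq = allele_frequencies(sub).freq
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    keep = ~np.isnan(freq) & (maf >= min_maf)
    sub = sub.take_loci(np.where(keep)[0])
    if sub.n_loci < 2:
        raise ValueError("fewer than 2 usable loci after the MAF cutoff")
    diff_chrom = sub.chrom[:, None] != sub.chrom[None, :]
    far_apart = np.abs(sub.pos_bp[:, None] - sub.pos_bp[None, :]) >= unlinked_min_bp
    pair_ok = diff_chrom | far_apart
    iu = np.triu_indices(sub.n_loci, k=1)
    n_pairs = int(pair_ok[iu].sum())
    if n_pairs == 0:
        raise ValueError("no eligible unlinked locus pairs after the spacing rule")

    r2_mean, r2p, ne = _ld_ne_point(sub.calls, pair_ok)
    # jackknife over individuals
    jn = []
    for i in range(sub.n_individuals):
        idx = np.delete(np.arange(sub.n_individuals), i)
        try:
            jn.append(_ld_ne_point(sub.calls[idx], pair_ok)[2])
        except ValueError:
            continue
    jn = np.array(jn)
    finite = jn[np.isfinite(jn)]
    if np.isfinite(ne) and len(finite) == len(jn) and len(jn) > 1:
        npts = len(jn)
        se = np.sqrt((npts - 1) / npts * np.sum((jn - jn.mean()) ** 2))
        lo, hi = ne - 1.96 * se, ne + 1.96 * se
    else:
        lo, hi = float("nan"), float("inf")
    return NeEstimate(
        ne=float(ne),
        ci_low=float(lo),
        ci_high=float(hi),
        r2_mean=r2_mean,
        r2_drift=r2p,
        n_pairs=n_pairs,
        sample_size=sub.n_individuals,
    )
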