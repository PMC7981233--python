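"""Genotype summary statistics, equilibrium tests, pairwise kinship and
isolation-by-distance machinery for codominant microsatellite data.

The kinship estimator is the Loiselle et al. (1995) correlation-type
coefficient: for individuals *i*, *j* with allele dosages (0, 1/2 or 1) at
locus *l*,

    k_ij = sum_l sum_a [ (p_ia - pbar_a)(p_ja - pbar_a) + pbar_a(1-pbar_a)/(n_l-1) ]
           -----------------------------------------------------------------------
                      sum_l sum_a pbar_a (1 - pbar_a)

where ``pbar_a`` is the reference-sample frequency of allele *a* and ``n_l``
the number of reference *gene copies* (2 x genotyped individuals) at locus
*l*; the added term is the small-sample bias correction.  Expected values: 0.25 for parent-offspring
and full sibs, 0.125 for half sibs, ~0 for unrelated pairs; the estimator is
slightly negatively biased when the dyad is part of its own reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import ttest_1samp

from .io import GenotypeTable
from .spatial import DistanceMatrix, HomeRange

__all__ = [
    "LocusSummary",
    "KinshipMatrix",
    "Autocorrelogram",
    "MantelResult",
    "locus_summaries",
    "hwe_exact_test",
    "ld_permutation_test",
    "holm_bonferroni",
    "loiselle_kinship",
    "autocorrelogram",
    "mantel_test",
    "neighbor_relatedness_contrast",
    "neighbor_contrast_test",
]


# ---------------------------------------------------------------------------
# Locus summaries
# ---------------------------------------------------------------------------


@dataclass
class LocusSummary:
    locus: str
    n_alleles: int
    allele_freqs: dict[int, float]
    Ho: float
    He: float
    sample_n: int
    hwe_p: float | None = None


def locus_summaries(
    genotypes: GenotypeTable, ids: Sequence[str] | None = None
) -> list[LocusSummary]:
    """Per-locus allele frequencies, observed and unbiased expected heterozygosity.

    He uses Nei's small-sample correction (2n/(2n-1)) * (1 - sum p^2) with n the
    number of genotyped individuals.
    """
    ids = list(genotypes.ids if ids is None else ids)
    out = []
    for locus in genotypes.loci:
        pairs = [genotypes.get(i, locus) for i in ids]
        pairs = [p for p in pairs if p is not None]
        n = len(pairs)
        if n < 2:
            raise ValueError(f"locus {locus}: fewer than 2 genotyped individuals")
        alleles = np.array([a for p in pairs for a in p])
        uniq, counts = np.unique(alleles, return_counts=True)
        freqs = counts / counts.sum()
        ho = sum(1 for a, b in pairs if a != b) / n
        if len(uniq) == 1:
            he = 0.0
        else:
            he = (2 * n / (2 * n - 1)) * (1.0 - float(np.sum(freqs**2)))
        out.append(
            LocusSummary(
                locus=locus,
                n_alleles=len(uniq),
                allele_freqs={int(a): float(f) for a, f in zip(uniq, freqs)},
                Ho=ho,
                He=he,
                sample_n=n,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Hardy-Weinberg Monte-Carlo exact test
# ---------------------------------------------------------------------------


def _genotype_log_weight(codes: np.ndarray, n_het: int) -> float:
    """Log of the permutation-null weight of a genotype configuration.

    Conditional on allele counts, P(configuration) is proportional to
    2^heterozygotes / prod(genotype count factorials); constant factors cancel
    in comparisons.
    """
    _, cnt = np.unique(codes, return_counts=True)
    return n_het * np.log(2.0) - float(gammaln(cnt + 1).sum())


def hwe_exact_test(
    genotype_pairs: Sequence[tuple[int, int]],
    n_mc: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Monte-Carlo exact test of Hardy-Weinberg proportions at one locus.

    Under the null, the observed alleles are randomly paired into genotypes.
    The p-value is the probability of a configuration as or less probable than
    the observed one, estimated from ``n_mc`` random pairings (with the +1
    correction so p is never 0).
    """
    rng = np.random.default_rng() if rng is None else rng
    pairs = [p for p in genotype_pairs if p is not None]
    if not pairs:
        raise ValueError("all genotypes missing at locus")
    alleles = np.array([a for p in pairs for a in p])
    uniq = np.unique(alleles)
    if len(uniq) < 2:
        raise ValueError("monomorphic locus: HWE test undefined")
    k = len(uniq)
    relabel = {a: i for i, a in enumerate(uniq)}
    arr = np.array([relabel[a] for a in alleles])
    n = len(pairs)
    obs_codes = np.array([relabel[a] * k + relabel[b] for a, b in pairs])
    obs_het = sum(1 for a, b in pairs if a != b)
    t_obs = _genotype_log_weight(obs_codes, obs_het)
    hits = 0
    work = arr.copy()
    for _ in range(n_mc):
        rng.shuffle(work)
        mat = work.reshape(n, 2)
        lo = mat.min(axis=1)
        hi = mat.max(axis=1)
        codes = lo * k + hi
        t = _genotype_log_weight(codes, int((lo != hi).sum()))
        if t <= t_obs + 1e-9:
            hits += 1
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# Linkage-disequilibrium permutation test
# ---------------------------------------------------------------------------


def _g_statistic(codes_i: np.ndarray, codes_j: np.ndarray) -> float:
    """G (log-likelihood ratio) statistic of the two-way genotype table."""
    _, inv_i = np.unique(codes_i, return_inverse=True)
    _, inv_j = np.unique(codes_j, return_inverse=True)
    ni, nj = inv_i.max() + 1, inv_j.max() + 1
    obs = np.bincount(inv_i * nj + inv_j, minlength=ni * nj).reshape(ni, nj).astype(float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


def ld_permutation_test(
    genotypes: GenotypeTable,
    locus_i: str,
    locus_j: str,
    n_perm: int = 1_000,
    rng: np.random.Generator | None = None,
    min_shared: int = 10,
) -> float | None:
    """Permutation test of genotypic association between two loci.

    Statistic: G of the two-locus genotype contingency table; null built by
    permuting one locus's genotypes across individuals.  Returns None when
    fewer than ``min_shared`` individuals are genotyped at both loci.
    """
    rng = np.random.default_rng() if rng is None else rng
    shared = [
        i
        for i in genotypes.ids
        if genotypes.get(i, locus_i) is not None and genotypes.get(i, locus_j) is not None
    ]
    if len(shared) < min_shared:
        return None
    gi = [genotypes.get(i, locus_i) for i in shared]
    gj = [genotypes.get(i, locus_j) for i in shared]
    code = {g: c for c, g in enumerate(sorted(set(gi) | set(gj)))}
    ci = np.array([code[g] for g in gi])
    cj = np.array([code[g] for g in gj])
    g_obs = _g_statistic(ci, cj)
    hits = 0
    work = cj.copy()
    for _ in range(n_perm):
        rng.shuffle(work)
        if _g_statistic(ci, work) >= g_obs - 1e-9:
            hits += 1
    return (hits + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Holm-Bonferroni sequential correction
# ---------------------------------------------------------------------------


def holm_bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Sequentially rejective Bonferroni correction.

    Sort p ascending; reject p_(i) while p_(i) <= alpha/(m-i+1), stop at the
    first failure.  With m = 8 tests the first threshold is alpha/8 (~0.0065
    at the conventional 5% level, the usual choice for an eight-locus HWE
    battery).  Returns a boolean rejection flag per input position.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0,1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if p[idx] <= alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# Loiselle kinship
# ---------------------------------------------------------------------------


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray  # NaN on the diagonal and for dyads with no shared locus
    reference: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self._index = {i: k for k, i in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self._index[i] for i in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.reference)


def _dosage_matrix(
    genotypes: GenotypeTable, ids: Sequence[str], locus: str
) -> tuple[np.ndarray, np.ndarray]:
    """Rows = individuals, cols = alleles observed at the locus; NaN when missing."""
    pairs = [genotypes.get(i, locus) for i in ids]
    alleles = sorted({a for p in pairs if p is not None for a in p})
    a_index = {a: i for i, a in enumerate(alleles)}
    X = np.full((len(ids), len(alleles)), np.nan)
    for r, p in enumerate(pairs):
        if p is not None:
            X[r] = 0.0
            X[r, a_index[p[0]]] += 0.5
            X[r, a_index[p[1]]] += 0.5
    return X, np.array([p is not None for p in pairs])


def loiselle_kinship(
    genotypes: GenotypeTable,
    ids: Sequence[str] | None = None,
    reference_ids: Sequence[str] | None = None,
) -> KinshipMatrix:
    """Pairwise Loiselle kinship matrix.

    ``reference_ids`` define the allele-frequency baseline (default: ``ids``
    themselves); a minimum of 10 reference individuals is required.  Dyads
    sharing no co-genotyped locus get NaN.
    """
    ids = list(genotypes.ids if ids is None else ids)
    reference_ids = ids if reference_ids is None else list(reference_ids)
    if len(reference_ids) < 10:
        raise ValueError("need >= 10 reference individuals for allele frequencies")
    n = len(ids)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for locus in genotypes.loci:
        Xref, okref = _dosage_matrix(genotypes, reference_ids, locus)
        n_l = int(okref.sum())
        if n_l < 2:
            continue
        pbar = np.nanmean(Xref, axis=0)  # reference allele frequencies
        d_l = float(np.sum(pbar * (1 - pbar)))
        if d_l <= 0:
            continue
        c_l = d_l / (2 * n_l - 1)  # bias correction; n counted in gene copies
        X, ok = _dosage_matrix(genotypes, ids, locus)
        # align allele columns with reference frequencies
        ref_alleles = sorted(
            {a for i in reference_ids for p in [genotypes.get(i, locus)] if p for a in p}
        )
        tgt_alleles = sorted(
            {a for i in ids for p in [genotypes.get(i, locus)] if p for a in p}
        )
        # build dosage over the union so columns line up
        union = sorted(set(ref_alleles) | set(tgt_alleles))
        u_index = {a: i for i, a in enumerate(union)}
        Xu = np.zeros((n, len(union)))
        Xu[~ok] = np.nan
        for col, a in enumerate(tgt_alleles):
            Xu[:, u_index[a]] = X[:, col]
        pbar_u = np.zeros(len(union))
        for col, a in enumerate(ref_alleles):
            pbar_u[u_index[a]] = pbar[col]
        centred = np.where(np.isnan(Xu), 0.0, Xu - pbar_u)
        both = np.outer(ok, ok)
        num += np.where(both, centred @ centred.T + c_l, 0.0)
        den += np.where(both, d_l, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(k, np.nan)
    return KinshipMatrix(ids, k, reference=f"{len(reference_ids)} reference individuals")


# ---------------------------------------------------------------------------
# Spatial autocorrelogram
# ---------------------------------------------------------------------------


@dataclass
class Autocorrelogram:
    cohort_label: str
    class_bounds: list[tuple[float, float]]
    mean_kinship: list[float]
    envelope_lo: list[float]
    envelope_hi: list[float]
    n_pairs: list[int]

    def significant_classes(self) -> list[int]:
        return [
            c
            for c, m in enumerate(self.mean_kinship)
            if m < self.envelope_lo[c] or m > self.envelope_hi[c]
        ]


def autocorrelogram(
    kinship: KinshipMatrix,
    dmat: DistanceMatrix,
    n_classes: int = 5,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    cohort_label: str = "",
) -> Autocorrelogram:
    """Distance-class spatial autocorrelogram of pairwise kinship.

    Classes are equal-frequency (quantile) bins of the pairwise distances.
    The null envelope (2.5%/97.5%) per class comes from permuting the
    individuals among their occupied spatial positions.
    """
    if list(kinship.ids) != list(dmat.ids):
        raise ValueError("kinship and distance matrices must share ids in order")
    rng = np.random.default_rng() if rng is None else rng
    n = len(kinship.ids)
    iu = np.triu_indices(n, k=1)
    d = dmat.values[iu]
    k = kinship.values[iu]
    valid = ~np.isnan(k)
    n_dyads = int(valid.sum())
    while n_classes > 1 and n_dyads < n_classes:
        n_classes -= 1
    qs = np.quantile(d, np.linspace(0, 1, n_classes + 1))
    qs[-1] = np.nextafter(qs[-1], np.inf)
    cls = np.clip(np.searchsorted(qs, d, side="right") - 1, 0, n_classes - 1)
    bounds = [(float(qs[c]), float(qs[c + 1])) for c in range(n_classes)]

    def class_means(kv: np.ndarray) -> np.ndarray:
        out = np.empty(n_classes)
        for c in range(n_classes):
            sel = (cls == c) & ~np.isnan(kv)
            out[c] = np.nan if not sel.any() else float(kv[sel].mean())
        return out

    obs = class_means(k)
    n_pairs = [int(((cls == c) & valid).sum()) for c in range(n_classes)]
    perm_means = np.empty((n_perm, n_classes))
    for b in range(n_perm):
        perm = rng.permutation(n)
        kv = kinship.values[np.ix_(perm, perm)][iu]
        perm_means[b] = class_means(kv)
    lo = np.nanpercentile(perm_means, 2.5, axis=0)
    hi = np.nanpercentile(perm_means, 97.5, axis=0)
    return Autocorrelogram(
        cohort_label=cohort_label,
        class_bounds=bounds,
        mean_kinship=[float(x) for x in obs],
        envelope_lo=[float(x) for x in lo],
        envelope_hi=[float(x) for x in hi],
        n_pairs=n_pairs,
    )


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    permutations: int
    description: str = ""


def mantel_test(
    matrix_a: np.ndarray,
    matrix_b: np.ndarray,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
    description: str = "",
) -> MantelResult:
    """Mantel permutation test between two symmetric distance-like matrices.

    r is the Pearson correlation of the off-diagonal elements; the null is
    built by jointly permuting rows and columns of ``matrix_b``; the p-value
    carries the +1 correction in numerator and denominator.
    """
    rng = np.random.default_rng() if rng is None else rng
    A = np.asarray(matrix_a, float)
    B = np.asarray(matrix_b, float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    a = A[iu]
    if a.std() == 0 or B[iu].std() == 0:
        raise ValueError("constant matrix: Mantel r undefined")
    a = (a - a.mean()) / a.std()

    def corr(Bm: np.ndarray) -> float:
        b = Bm[iu]
        return float(np.mean(a * (b - b.mean()) / b.std()))

    r_obs = corr(B)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(B[np.ix_(perm, perm)])
        if alternative == "greater":
            hits += r_p >= r_obs - 1e-12
        elif alternative == "less":
            hits += r_p <= r_obs + 1e-12
        else:
            hits += abs(r_p) >= abs(r_obs) - 1e-12
    return MantelResult(
        r=r_obs, p=(hits + 1) / (n_perm + 1), permutations=n_perm, description=description
    )


# ---------------------------------------------------------------------------
# Neighbour relatedness contrast
# ---------------------------------------------------------------------------


@dataclass
class NeighborContrast:
    focal_id: str
    cohort_label: str
    neighbor_ids: list[str]
    mean_k_neighbors: float
    mean_k_others: float
    difference: float  # neighbors minus others


def neighbor_relatedness_contrast(
    focal_id: str,
    cohort_males: dict[str, int],
    kinship: KinshipMatrix,
    home_ranges: dict[str, HomeRange],
    habitat_bushes: dict[int, "object"],
    cohort_label: str = "",
    exclude_ids: set[str] | None = None,
) -> NeighborContrast | None:
    """Mean kinship of a focal male to its spatial neighbours vs the rest.

    Neighbours are cohort males captured in any bush whose polygon intersects
    the focal's home-range polygon.  Returns None (flagged, excluded from
    tests) when the focal has no neighbours or no scorable dyads.
    """
    hr = home_ranges.get(focal_id)
    if hr is None:
        return None
    exclude_ids = exclude_ids or set()
    neighbors, others = [], []
    for other, bush in cohort_males.items():
        if other == focal_id or other in exclude_ids:
            continue
        poly = habitat_bushes[bush]
        (neighbors if poly.intersects(hr.polygon) else others).append(other)
    k_n = [kinship.get(focal_id, o) for o in neighbors if not np.isnan(kinship.get(focal_id, o))]
    k_o = [kinship.get(focal_id, o) for o in others if not np.isnan(kinship.get(focal_id, o))]
    if not k_n or not k_o:
        return None
    mn, mo = float(np.mean(k_n)), float(np.mean(k_o))
    return NeighborContrast(
        focal_id=focal_id,
        cohort_label=cohort_label,
        neighbor_ids=neighbors,
        mean_k_neighbors=mn,
        mean_k_others=mo,
        difference=mn - mo,
    )


def neighbor_contrast_test(
    contrasts: Sequence[NeighborContrast],
    kinship: KinshipMatrix,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> dict:
    """Cohort-level test of the neighbour-vs-others kinship differences.

    Reports the one-sample t-test on the per-focal differences (the classical
    analysis, which ignores dyad non-independence) alongside a permutation
    test in which each focal's neighbour labels are reshuffled among its
    scored partners — the recommended inference.
    """
    rng = np.random.default_rng() if rng is None else rng
    diffs = np.array([c.difference for c in contrasts])
    if len(diffs) < 2:
        return {"n": len(diffs), "t": np.nan, "t_p": np.nan, "perm_p": np.nan,
                "mean_difference": float(diffs.mean()) if len(diffs) else np.nan}
    t_stat, t_p = ttest_1samp(diffs, 0.0)
    obs = float(diffs.mean())
    hits = 0
    per_focal = []
    for c in contrasts:
        row = kinship.values[kinship._index[c.focal_id]]
        ks = row[~np.isnan(row)]
        per_focal.append((ks, len(c.neighbor_ids)))
    for _ in range(n_perm):
        sim = []
        for ks, n_nb in per_focal:
            n_nb = min(n_nb, len(ks) - 1) or 1
            perm = rng.permutation(len(ks))
            sim.append(ks[perm[:n_nb]].mean() - ks[perm[n_nb:]].mean())
        if abs(np.mean(sim)) >= abs(obs) - 1e-12:
            hits += 1
    return {
        "n": len(diffs),
        "mean_difference": obs,
        "t": float(t_stat),
        "t_p": float(t_p),
        "perm_p": (hits + 1) / (n_perm + 1),
    }
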