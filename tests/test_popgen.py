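"""Summary statistics, equilibrium tests, kinship, autocorrelograms, Mantel."""

import math

import numpy as np
import pytest
from scipy.special import gammaln

from anole_spatgen.io import GenotypeTable
from anole_spatgen.popgen import (
    autocorrelogram,
    holm_bonferroni,
    hwe_exact_test,
    ld_permutation_test,
    locus_summaries,
    loiselle_kinship,
    mantel_test,
    neighbor_contrast_test,
    neighbor_relatedness_contrast,
)
from anole_spatgen.simulate import mendelian_offspring
from anole_spatgen.spatial import DistanceMatrix


def _table(pairs_by_ind, locus="L1"):
    return GenotypeTable([locus], {k: {locus: v} for k, v in pairs_by_ind.items()})


class TestLocusSummaries:
    def test_two_heterozygotes(self):
        t = _table({"a": (1, 2), "b": (1, 2)})
        (s,) = locus_summaries(t)
        assert s.allele_freqs == {1: 0.5, 2: 0.5}
        assert s.Ho == 1.0
        assert s.n_alleles == 2

    def test_monomorphic(self):
        t = _table({"a": (1, 1), "b": (1, 1), "c": (1, 1)})
        (s,) = locus_summaries(t)
        assert s.Ho == 0.0 and s.He == 0.0 and s.n_alleles == 1

    def test_unbiased_he_matches_direct_formula(self, rng):
        pairs = {f"i{k}": tuple(sorted(rng.integers(1, 8, size=2))) for k in range(50)}
        t = _table(pairs)
        (s,) = locus_summaries(t)
        alleles = [a for p in pairs.values() for a in p]
        freqs = np.bincount(alleles) / len(alleles)
        n = 50
        expected = (2 * n / (2 * n - 1)) * (1 - np.sum(freqs**2))
        assert s.He == pytest.approx(expected, abs=1e-12)
        assert np.isclose(sum(s.allele_freqs.values()), 1.0, atol=1e-9)


class TestHWE:
    def test_perfect_proportions_not_rejected(self, rng):
        pairs = [(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25
        assert hwe_exact_test(pairs, n_mc=2000, rng=rng) >= 0.99

    def test_heterozygote_deficit_rejected(self, rng):
        pairs = [(1, 1)] * 50 + [(2, 2)] * 50
        assert hwe_exact_test(pairs, n_mc=2000, rng=rng) < 0.001

    def test_monte_carlo_matches_enumeration(self, rng):
        """Biallelic sample of 10: the exact p enumerates every heterozygote
        count consistent with the allele counts."""
        pairs = [(1, 1)] * 4 + [(1, 2)] * 2 + [(2, 2)] * 4
        n = len(pairs)
        n1 = sum(p.count(1) for p in pairs)
        n2 = 2 * n - n1

        def log_prob(h):  # exact conditional probability of h heterozygotes
            n11 = (n1 - h) // 2
            n22 = (n2 - h) // 2
            return (
                gammaln(n + 1) - gammaln(n11 + 1) - gammaln(h + 1) - gammaln(n22 + 1)
                + h * math.log(2) + gammaln(n1 + 1) + gammaln(n2 + 1) - gammaln(2 * n + 1)
            )
        hs = [h for h in range(min(n1, n2) + 1) if (n1 - h) % 2 == 0 and (n2 - h) % 2 == 0]
        probs = {h: math.exp(log_prob(h)) for h in hs}
        assert sum(probs.values()) == pytest.approx(1.0, abs=1e-9)
        obs = probs[2]
        exact_p = sum(p for p in probs.values() if p <= obs + 1e-12)
        n_mc = 20_000
        mc_p = hwe_exact_test(pairs, n_mc=n_mc, rng=rng)
        se = math.sqrt(exact_p * (1 - exact_p) / n_mc)
        assert abs(mc_p - exact_p) < 3 * se + 2 / n_mc


class TestLD:
    def test_perfect_association_rejected(self, rng):
        calls = {}
        for i in range(50):
            g = tuple(sorted(rng.integers(1, 5, size=2)))
            calls[f"i{i}"] = {"L1": g, "L2": g}
        t = GenotypeTable(["L1", "L2"], calls)
        p = ld_permutation_test(t, "L1", "L2", n_perm=1000, rng=rng)
        assert p <= 0.001 + 1e-9

    def test_insufficient_overlap_skipped(self, rng):
        calls = {f"i{k}": {"L1": (1, 2), "L2": None} for k in range(20)}
        t = GenotypeTable(["L1", "L2"], calls)
        assert ld_permutation_test(t, "L1", "L2", rng=rng) is None


class TestHolm:
    def test_single_small_p_rejected(self):
        assert holm_bonferroni([0.004], alpha=0.0065).tolist() == [True]

    def test_all_ones_kept(self):
        assert not holm_bonferroni([1.0] * 8).any()

    def test_matches_stepwise_reference(self, rng):
        """Flags agree with an independently coded sequential rule."""
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            flags = holm_bonferroni(p, alpha=0.05)
            order = np.argsort(p, kind="stable")
            ref = np.zeros(len(p), dtype=bool)
            for i, idx in enumerate(order, start=1):
                if p[idx] <= 0.05 / (len(p) - i + 1):
                    ref[idx] = True
                else:
                    break
            assert flags.tolist() == ref.tolist()


def _random_genotypes(rng, n_ind, n_loci=8, k=20, prefix="i"):
    pools = [list(range(100, 100 + 2 * k, 2)) for _ in range(n_loci)]
    freqs = [rng.dirichlet(np.ones(k)) for _ in range(n_loci)]
    loci = [f"L{j}" for j in range(n_loci)]

    def draw():
        gt = []
        for pool, f in zip(pools, freqs):
            a, b = rng.choice(k, size=2, p=f)
            gt.append((min(pool[a], pool[b]), max(pool[a], pool[b])))
        return gt

    calls = {f"{prefix}{j}": dict(zip(loci, draw())) for j in range(n_ind)}
    return GenotypeTable(loci, calls), draw, loci


class TestLoiselleKinship:
    def test_identical_genotypes_rare_alleles_positive(self, rng):
        # 2 identical individuals carrying alleles rare in the reference
        t, draw, loci = _random_genotypes(rng, 30)
        rare = dict(zip(loci, [(999, 999)] * len(loci)))
        t.calls["x"] = dict(rare)
        t.calls["y"] = dict(rare)
        kin = loiselle_kinship(t, ids=["x", "y"], reference_ids=list(t.calls))
        assert kin.get("x", "y") > 0

    def test_reference_sample_mean_slightly_negative(self, rng):
        """Within its own reference sample the estimator averages just below
        zero over all dyads — its documented finite-sample property."""
        t, _, _ = _random_genotypes(rng, 10)
        kin = loiselle_kinship(t)
        iu = np.triu_indices(10, k=1)
        mean = np.nanmean(kin.values[iu])
        assert -0.2 < mean < 0.0

    def test_pedigree_dyad_expectations(self, rng):
        t, draw, loci = _random_genotypes(rng, 100, prefix="R")
        for j in range(150):
            p1, p2 = draw(), draw()
            t.calls[f"P{j}"] = dict(zip(loci, p1))
            t.calls[f"Oa{j}"] = dict(zip(loci, mendelian_offspring(p1, p2, rng)))
            t.calls[f"Un{j}"] = dict(zip(loci, draw()))
        kin = loiselle_kinship(
            t, ids=list(t.calls), reference_ids=[f"R{j}" for j in range(100)]
        )
        po = np.mean([kin.get(f"P{j}", f"Oa{j}") for j in range(150)])
        un = np.mean([kin.get(f"P{j}", f"Un{j}") for j in range(150)])
        assert po == pytest.approx(0.25, abs=0.03)
        assert un == pytest.approx(0.0, abs=0.03)

    def test_symmetry_and_locus_order_invariance(self, rng):
        t, _, loci = _random_genotypes(rng, 12)
        kin = loiselle_kinship(t)
        assert np.allclose(kin.values, kin.values.T, equal_nan=True)
        rev = GenotypeTable(loci[::-1], {i: dict(c) for i, c in t.calls.items()})
        kin2 = loiselle_kinship(rev)
        assert np.allclose(kin.values, kin2.values, equal_nan=True)

    def test_no_shared_locus_gives_nan(self):
        t = GenotypeTable(
            ["L1", "L2"],
            {"a": {"L1": (1, 2), "L2": None}, "b": {"L1": None, "L2": (1, 2)},
             **{f"r{k}": {"L1": (1, 2), "L2": (1, 2)} for k in range(10)}},
        )
        kin = loiselle_kinship(t)
        assert math.isnan(kin.get("a", "b"))


class TestAutocorrelogram:
    def _dist(self, n, rng):
        pts = rng.uniform(0, 100, size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return DistanceMatrix([f"i{k}" for k in range(n)], d, "euclidean")

    def test_zero_kinship_inside_envelope(self, rng):
        from anole_spatgen.popgen import KinshipMatrix

        n = 20
        d = self._dist(n, rng)
        kin = KinshipMatrix(d.ids, np.zeros((n, n)))
        ac = autocorrelogram(kin, d, n_perm=99, rng=rng)
        assert all(m == 0 for m in ac.mean_kinship)
        assert ac.significant_classes() == []

    def test_clustered_clones_flag_first_class(self, rng):
        from anole_spatgen.popgen import KinshipMatrix

        n = 25
        pts = np.vstack([rng.uniform(0, 5, size=(5, 2)), rng.uniform(40, 100, size=(20, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = [f"i{k}" for k in range(n)]
        kv = np.zeros((n, n))
        kv[:5, :5] = 0.5  # the tight cluster is a clonal family
        np.fill_diagonal(kv, np.nan)
        ac = autocorrelogram(
            KinshipMatrix(ids, kv), DistanceMatrix(ids, d, "euclidean"),
            n_perm=199, rng=rng,
        )
        assert 0 in ac.significant_classes()
        assert ac.mean_kinship[0] > ac.envelope_hi[0]

    def test_weighted_class_means_recover_overall_mean(self, rng):
        from anole_spatgen.popgen import KinshipMatrix

        n = 30
        d = self._dist(n, rng)
        kv = rng.normal(0, 0.1, size=(n, n))
        kv = (kv + kv.T) / 2
        np.fill_diagonal(kv, np.nan)
        kin = KinshipMatrix(d.ids, kv)
        ac = autocorrelogram(kin, d, n_perm=9, rng=rng)
        weighted = np.sum(np.array(ac.mean_kinship) * np.array(ac.n_pairs)) / sum(ac.n_pairs)
        iu = np.triu_indices(n, k=1)
        assert weighted == pytest.approx(np.nanmean(kv[iu]), abs=1e-12)
        assert sum(ac.n_pairs) == n * (n - 1) // 2


class TestMantel:
    def _sym(self, n, rng):
        m = rng.uniform(size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return m

    def test_self_comparison_r1_smallest_p(self, rng):
        a = self._sym(12, rng)
        res = mantel_test(a, a.copy(), n_perm=199, rng=rng)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 200)

    def test_enumeration_oracle_n4(self, rng):
        """The permutation p at n=4 agrees with complete 4! enumeration."""
        from itertools import permutations

        a, b = self._sym(4, rng), self._sym(4, rng)
        iu = np.triu_indices(4, k=1)
        av = (a[iu] - a[iu].mean()) / a[iu].std()

        def corr(mat):
            v = mat[iu]
            return np.mean(av * (v - v.mean()) / v.std())

        r_obs = corr(b)
        rs = [corr(b[np.ix_(p, p)]) for p in permutations(range(4))]
        exact = np.mean([r >= r_obs - 1e-12 for r in rs])
        n_perm = 4999
        res = mantel_test(a, b, n_perm=n_perm, rng=rng)
        se = math.sqrt(exact * (1 - exact) / n_perm)
        assert abs(res.p - exact) < 3 * se + 2 / n_perm

    def test_agrees_with_skbio(self, rng):
        """Independent cross-check against scikit-bio's Mantel implementation."""
        from skbio.stats.distance import DistanceMatrix as SkbioDM, mantel

        a, b = self._sym(15, rng), self._sym(15, rng)
        r_sk, p_sk, _ = mantel(
            SkbioDM(a), SkbioDM(b), method="pearson", permutations=999,
            alternative="greater",
        )
        res = mantel_test(a, b, n_perm=999, rng=rng)
        assert res.r == pytest.approx(r_sk, abs=1e-9)
        assert abs(res.p - p_sk) < 0.06

    def test_constant_matrix_flagged(self, rng):
        a = np.zeros((5, 5))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(a, self._sym(5, rng), rng=rng)

    def test_relabeling_invariance(self, rng):
        a, b = self._sym(10, rng), self._sym(10, rng)
        perm = rng.permutation(10)
        r1 = mantel_test(a, b, n_perm=9, rng=np.random.default_rng(1)).r
        r2 = mantel_test(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)],
                         n_perm=9, rng=np.random.default_rng(1)).r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestNeighborContrast:
    def test_zero_kinship_zero_difference(self, rng, square_park):
        from anole_spatgen.popgen import KinshipMatrix
        from anole_spatgen.spatial import HomeRange

        ids = ["f", "n1", "o1", "o2"]
        kv = np.zeros((4, 4))
        np.fill_diagonal(kv, np.nan)
        kin = KinshipMatrix(ids, kv)
        hr = HomeRange("f", [1], square_park.bushes[1], 12.0, 1)
        males = {"f": 1, "n1": 1, "o1": 3, "o2": 4}
        c = neighbor_relatedness_contrast(
            "f", males, kin, {"f": hr}, square_park.bushes
        )
        assert c.difference == 0.0
        assert c.neighbor_ids == ["n1"]

    def test_true_son_neighbor_positive_difference(self, rng, square_park):
        """A focal whose only neighbour is his own son shows a neighbour mean
        near the parent-offspring expectation, above the population mean."""
        t, draw, loci = _random_genotypes(rng, 60, prefix="R")
        p1, p2 = draw(), draw()
        t.calls["dad"] = dict(zip(loci, p1))
        t.calls["son"] = dict(zip(loci, mendelian_offspring(p1, p2, rng)))
        kin = loiselle_kinship(
            t, ids=["dad", "son"] + [f"R{j}" for j in range(20)],
            reference_ids=[f"R{j}" for j in range(60)],
        )
        from anole_spatgen.spatial import HomeRange

        hr = HomeRange("dad", [1], square_park.bushes[1], 12.0, 1)
        males = {"dad": 1, "son": 1, **{f"R{j}": 3 + (j % 2) for j in range(20)}}
        c = neighbor_relatedness_contrast("dad", males, kin, {"dad": hr},
                                          square_park.bushes)
        assert c.mean_k_neighbors > c.mean_k_others
        assert c.mean_k_neighbors == pytest.approx(0.25, abs=0.15)

    def test_cohort_test_outputs(self, rng, square_park):
        from anole_spatgen.popgen import KinshipMatrix

        n = 12
        ids = [f"i{k}" for k in range(n)]
        kv = rng.normal(0, 0.05, size=(n, n))
        kv = (kv + kv.T) / 2
        np.fill_diagonal(kv, np.nan)
        kin = KinshipMatrix(ids, kv)
        from anole_spatgen.spatial import HomeRange

        contrasts = []
        for f in ids[:4]:
            hr = HomeRange(f, [1], square_park.bushes[1], 12.0, 1)
            males = {i: (1 if k < 6 else 3) for k, i in enumerate(ids)}
            c = neighbor_relatedness_contrast(f, males, kin, {f: hr},
                                              square_park.bushes)
            contrasts.append(c)
        out = neighbor_contrast_test(contrasts, kin, n_perm=99, rng=rng)
        assert 0 < out["perm_p"] <= 1
        assert out["n"] == 4
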