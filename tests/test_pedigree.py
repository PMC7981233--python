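"""Parentage likelihood, sequential consensus procedure, pedigree F."""

import math

import numpy as np
import pytest

from anole_spatgen.io import CohortKey, GenotypeTable, PedigreeLink
from anole_spatgen.pedigree import (
    ParentageConfig,
    assign_parents,
    inbreeding_coefficient,
    inbreeding_trajectory,
    pedigree_kinship,
    sequential_pedigree,
    transmission_likelihood,
)
from anole_spatgen.simulate import mendelian_offspring


def _freqs(k=6):
    return [{a: 1.0 / k for a in range(1, k + 1)}]


class TestTransmissionLikelihood:
    def test_mendelian_exclusion_at_zero_error(self):
        ll = transmission_likelihood([(1, 1)], [(2, 2)], None, _freqs(), 0.0)
        assert ll == -math.inf

    def test_certain_trio_likelihood_one(self):
        ll = transmission_likelihood([(1, 2)], [(1, 1)], [(2, 2)], _freqs(), 0.0)
        assert ll == pytest.approx(0.0)  # log 1

    def test_matches_exhaustive_enumeration(self, rng):
        """Single-locus likelihood equals a brute-force sum over every true
        offspring genotype and per-allele error outcome."""
        k = 4
        freqs = {a: f for a, f in zip(range(1, k + 1), (0.4, 0.3, 0.2, 0.1))}
        eps = 0.05

        def e(obs, true):
            return 1 - eps if obs == true else eps / (k - 1)

        def p_obs(obs, true_pair):
            (x, y), (a, b) = obs, true_pair
            tot = e(x, a) * e(y, b)
            if x != y:
                tot += e(y, a) * e(x, b)
            return tot

        for _ in range(20):
            off = tuple(sorted(rng.integers(1, k + 1, size=2)))
            cand = tuple(sorted(rng.integers(1, k + 1, size=2)))
            other = tuple(sorted(rng.integers(1, k + 1, size=2)))
            # trio: enumerate the four equally likely transmitted pairs
            brute = 0.0
            for a in cand:
                for b in other:
                    brute += 0.25 * p_obs(off, (a, b))
            ll = transmission_likelihood([off], [cand], [other], [freqs], eps)
            assert ll == pytest.approx(math.log(brute), abs=1e-12)
            # pair with unknown second parent: integrate over the pool
            brute2 = 0.0
            for a in cand:
                for b, fb in freqs.items():
                    brute2 += 0.5 * fb * p_obs(off, (a, b))
            ll2 = transmission_likelihood([off], [cand], None, [freqs], eps)
            assert ll2 == pytest.approx(math.log(brute2), abs=1e-12)

    def test_no_shared_loci_raises(self):
        with pytest.raises(ValueError):
            transmission_likelihood([None], [(1, 1)], None, _freqs(), 0.0)


def _sim_genotypes(rng, n_loci=8, k=20):
    pools = [list(range(100, 100 + 2 * k, 2)) for _ in range(n_loci)]
    freqs = [rng.dirichlet(np.ones(k)) for _ in range(n_loci)]
    loci = [f"L{j}" for j in range(n_loci)]

    def draw():
        gt = []
        for pool, f in zip(pools, freqs):
            a, b = rng.choice(k, size=2, p=f)
            gt.append((min(pool[a], pool[b]), max(pool[a], pool[b])))
        return gt

    return loci, draw


class TestAssignParents:
    def test_lone_true_sire_high_support(self, rng):
        loci, draw = _sim_genotypes(rng)
        sire, dam = draw(), draw()
        off = mendelian_offspring(sire, dam, rng)
        calls = {"off": dict(zip(loci, off)), "sire": dict(zip(loci, sire))}
        for j in range(30):
            calls[f"bg{j}"] = dict(zip(loci, draw()))
        t = GenotypeTable(loci, calls)
        links = assign_parents(["off"], ["sire"], [], t, ParentageConfig(), rng=rng)
        assert [l.parent_id for l in links] == ["sire"]
        assert links[0].support > 0.95

    def test_no_candidates_empty(self, rng):
        loci, draw = _sim_genotypes(rng)
        t = GenotypeTable(loci, {"off": dict(zip(loci, draw()))})
        assert assign_parents(["off"], [], [], t, ParentageConfig(), rng=rng) == []

    def test_recovery_among_many_candidates(self, rng):
        """True sires recovered from 30 candidates for >=80% of offspring."""
        loci, draw = _sim_genotypes(rng)
        sires = {f"s{j}": draw() for j in range(30)}
        dams = {f"d{j}": draw() for j in range(30)}
        calls = {i: dict(zip(loci, g)) for i, g in {**sires, **dams}.items()}
        truth = {}
        for j in range(40):
            s, d = f"s{j % 30}", f"d{(j * 7) % 30}"
            off = mendelian_offspring(sires[s], dams[d], rng)
            calls[f"o{j}"] = dict(zip(loci, off))
            truth[f"o{j}"] = s
        t = GenotypeTable(loci, calls)
        links = assign_parents(
            [f"o{j}" for j in range(40)], list(sires), list(dams), t,
            ParentageConfig(), rng=rng,
        )
        sire_links = {l.offspring_id: l.parent_id for l in links if l.parent_role == "sire"}
        hits = sum(sire_links.get(o) == s for o, s in truth.items())
        assert hits / 40 >= 0.8

    def test_exclusion_consistency_zero_error(self, rng):
        """With eps=0 every accepted link is Mendel-compatible at all loci."""
        loci, draw = _sim_genotypes(rng, n_loci=5, k=8)
        calls = {}
        for j in range(15):
            calls[f"s{j}"] = dict(zip(loci, draw()))
            calls[f"o{j}"] = dict(zip(loci, draw()))  # unrelated "offspring"
        t = GenotypeTable(loci, calls)
        cfg = ParentageConfig(error_rate=0.0)
        links = assign_parents(
            [f"o{j}" for j in range(15)], [f"s{j}" for j in range(15)], [], t, cfg,
            rng=rng,
        )
        for l in links:
            for loc in loci:
                og, pg = t.get(l.offspring_id, loc), t.get(l.parent_id, loc)
                assert set(og) & set(pg), "accepted link violates Mendelian sharing"


def _cohorts(labels):
    out = {}
    for lab, ids in labels.items():
        season = "spring" if lab[0] == "S" else "fall"
        out[CohortKey.of(int(lab[1:]), season)] = ids
    return dict(sorted(out.items()))


class TestSequential:
    def test_single_founder_cohort_empty(self, rng):
        loci, draw = _sim_genotypes(rng, n_loci=4, k=6)
        ids = [f"f{j}" for j in range(8)]
        t = GenotypeTable(loci, {i: dict(zip(loci, draw())) for i in ids})
        sexes = {i: ("M" if j % 2 else "F") for j, i in enumerate(ids)}
        res = sequential_pedigree(
            _cohorts({"S2010": ids}), sexes, t, ParentageConfig(n_replicates=2),
            seeds=[1, 2],
        )
        # founders may only be linked to one another; the engine must not
        # fabricate confident links among unrelated founders
        assert len(res.consensus) <= 1

    def test_replicates_identical_and_consensus_idempotent(self, sim_full_capture):
        from anole_spatgen.io import cohort_members

        res = sim_full_capture
        members = cohort_members(res.records)
        out = sequential_pedigree(
            members, res.truth.sexes, res.genotypes,
            ParentageConfig(n_replicates=3), seeds=[5, 6, 7],
        )
        keys = [
            {(l.offspring_id, l.parent_id, l.parent_role) for l in rep}
            for rep in out.replicates
        ]
        assert keys[0] == keys[1] == keys[2]  # deterministic engine
        assert {(l.offspring_id, l.parent_id, l.parent_role) for l in out.consensus} == keys[0]

    def test_consensus_subset_of_each_replicate(self, sim_small):
        from anole_spatgen.io import cohort_members

        members = cohort_members(sim_small.records)
        out = sequential_pedigree(
            members, sim_small.truth.sexes, sim_small.genotypes,
            ParentageConfig(n_replicates=2), seeds=[1, 2],
        )
        cons = {(l.offspring_id, l.parent_id, l.parent_role) for l in out.consensus}
        for rep in out.replicates:
            assert cons <= {(l.offspring_id, l.parent_id, l.parent_role) for l in rep}

    def test_nonchronological_order_rejected(self, rng):
        loci, draw = _sim_genotypes(rng, n_loci=2, k=4)
        t = GenotypeTable(loci, {"a": dict(zip(loci, draw()))})
        cohorts = {
            CohortKey.of(2011, "spring"): ["a"],
            CohortKey.of(2010, "spring"): ["a"],
        }
        with pytest.raises(ValueError, match="chronological"):
            sequential_pedigree(cohorts, {"a": "M"}, t, ParentageConfig(), seeds=[1, 2, 3])


def _oracle_f(parents, ind):
    """Wright's path-counting inbreeding coefficient: sum over common
    ancestors and disjoint ancestor paths of (1/2)^(n1+n2+1) (1 + F_A)."""

    def ancestors_paths(x):
        # all paths (as tuples of ids, starting at x) to every ancestor
        paths = {x: [(x,)]}
        stack = [(x, (x,))]
        while stack:
            cur, path = stack.pop()
            for p in parents.get(cur, (None, None)):
                if p is not None:
                    paths.setdefault(p, []).append(path + (p,))
                    stack.append((p, path + (p,)))
        return paths

    def f_of(x):
        s, d = parents.get(x, (None, None))
        if s is None or d is None:
            return 0.0
        return kinship_paths(s, d)

    def kinship_paths(a, b):
        pa, pb = ancestors_paths(a), ancestors_paths(b)
        tot = 0.0
        for anc in set(pa) & set(pb):
            for path1 in pa[anc]:
                for path2 in pb[anc]:
                    if set(path1) & set(path2) != {anc}:
                        continue  # paths must share only the common ancestor
                    n1, n2 = len(path1) - 1, len(path2) - 1
                    tot += 0.5 ** (n1 + n2 + 1) * (1 + f_of(anc))
        return tot

    return f_of(ind)


class TestInbreeding:
    def test_full_sib_mating(self):
        ped = {"sire": ("gs", "gd"), "dam": ("gs", "gd"), "kid": ("sire", "dam")}
        assert inbreeding_coefficient(ped, "kid") == pytest.approx(0.25)

    def test_father_daughter_mating(self):
        ped = {"daughter": ("dad", "mom"), "kid": ("dad", "daughter")}
        assert inbreeding_coefficient(ped, "kid") == pytest.approx(0.25)

    def test_first_cousins(self):
        ped = {
            "p1": ("gs", "gd"), "p2": ("gs", "gd"),
            "c1": ("p1", "u1"), "c2": ("p2", "u2"),
            "kid": ("c1", "c2"),
        }
        assert inbreeding_coefficient(ped, "kid") == pytest.approx(0.0625)

    def test_unknown_parent_zero(self):
        assert inbreeding_coefficient({"kid": ("dad", None)}, "kid") == 0.0
        assert inbreeding_coefficient({}, "kid") == 0.0

    def test_matches_path_counting_oracle(self, rng):
        """Random 4-generation pedigrees: the tabular recursion agrees with
        Wright's path-counting formula."""
        for trial in range(10):
            r = np.random.default_rng(trial)
            gen = [[f"g0_{j}" for j in range(6)]]
            parents = {}
            for g in range(1, 4):
                layer = []
                for j in range(6):
                    s, d = r.choice(gen[g - 1], size=2, replace=False)
                    ind = f"g{g}_{j}"
                    parents[ind] = (str(s), str(d))
                    layer.append(ind)
                gen.append(layer)
            for ind in gen[3]:
                assert inbreeding_coefficient(parents, ind) == pytest.approx(
                    _oracle_f(parents, ind), abs=1e-12
                )

    def test_kinship_symmetry(self):
        ped = {"a": ("s", "d"), "b": ("s", "d")}
        assert pedigree_kinship(ped, "a", "b") == pedigree_kinship(ped, "b", "a")

    def test_cycle_raises(self):
        ped = {"a": ("b", "x"), "b": ("a", "y")}
        with pytest.raises(ValueError, match="cycle"):
            inbreeding_coefficient(ped, "a")


class TestTrajectory:
    def test_no_parents_all_zero(self):
        snaps = [("S2010", []), ("F2010", [])]
        out = inbreeding_trajectory(snaps)
        assert [o["mean_F"] for o in out] == [0.0, 0.0]

    def test_repeated_full_sib_matings_nondecreasing(self):
        links = []
        prev = ("f0a", "f0b")
        snaps = []
        for g in range(1, 5):
            a, b = f"g{g}a", f"g{g}b"
            for kid in (a, b):
                links.append(PedigreeLink(kid, prev[0], "sire", 1.0, 3))
                links.append(PedigreeLink(kid, prev[1], "dam", 1.0, 3))
            prev = (a, b)
            snaps.append((f"step{g}", list(links)))
        out = inbreeding_trajectory(snaps)
        means = [o["mean_F"] for o in out]
        assert all(b >= a for a, b in zip(means, means[1:]))
        # cumulative mean over the sib-line F sequence 0, 1/4, 3/8, 1/2
        assert means[-1] == pytest.approx((0 + 0.25 + 0.375 + 0.5) / 4, abs=1e-9)
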