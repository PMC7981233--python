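"""Likelihood-based parentage assignment and pedigree inbreeding coefficients.

The assignment engine is a categorical-allocation likelihood over parent
configurations: an offspring's genotype arises by Mendelian transmission from
a candidate sire and/or dam (population allele frequencies stand in for an
unsampled parent), and each observed offspring allele is independently
mistyped with probability epsilon (replaced by a uniformly drawn different
allele of the locus).  Candidate parent genotypes are taken at face value.

For each offspring the four configurations {no parent, sire only, dam only,
sire+dam} are weighted by a prior on a true parent being present in the
candidate set (``p_parent_sampled``) and the best configuration is retained
when a likelihood-ratio test against the configuration without that parent
is significant.

The engine runs under a sequential cohort-stacking procedure: cohorts are
added one at a time, earlier assignments become fixed priors, the whole
procedure is run in replicate, and only links recovered in every replicate
enter the consensus pedigree.

Pedigree inbreeding coefficients use the recursive tabular method: F of an
individual equals the pedigree kinship of its two parents, with unknown
parents treated as unrelated founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .io import CohortKey, GenotypeTable, PedigreeLink

__all__ = [
    "ParentageConfig",
    "transmission_likelihood",
    "assign_parents",
    "sequential_pedigree",
    "SequentialResult",
    "inbreeding_coefficient",
    "pedigree_kinship",
    "inbreeding_trajectory",
]


@dataclass
class ParentageConfig:
    error_rate: float = 0.01
    p_parent_sampled: float = 0.5
    retention_alpha: float = 0.05  # LRT p-value below which a link is retained
    n_replicates: int = 3
    allow_inbreeding: bool = True
    max_missing: float = 0.5  # offspring with more missing loci are skipped
    tie_break: str = "refuse"  # "refuse" (deterministic) or "random"
    pair_top_k: int = 5  # joint sire-dam search over the K best of each sex

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error_rate must be in [0,1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


# ---------------------------------------------------------------------------
# Per-locus likelihood machinery
# ---------------------------------------------------------------------------


def _error_matrix(k: int, eps: float) -> np.ndarray:
    """E[obs, true]: per-allele mistyping kernel over a pool of k alleles."""
    if k == 1:
        return np.ones((1, 1))
    E = np.full((k, k), eps / (k - 1))
    np.fill_diagonal(E, 1.0 - eps)
    return E


def _obs_given_true(E: np.ndarray, x: int, y: int) -> np.ndarray:
    """M[a,b] = P(observe unordered {x,y} | true ordered genotype (a,b))."""
    M = np.outer(E[x], E[y])
    if x != y:
        M = M + np.outer(E[y], E[x])
    return M


def transmission_likelihood(
    offspring_gt: Sequence[tuple[int, int] | None],
    candidate_gt: Sequence[tuple[int, int] | None],
    other_parent_gt: Sequence[tuple[int, int] | None] | None,
    allele_freqs: Sequence[Mapping[int, float]],
    epsilon: float,
) -> float:
    """Summed log-likelihood of the offspring genotype given a candidate parent.

    ``other_parent_gt`` may be None (unknown: its allele is drawn from the
    population frequencies).  Loci missing in the offspring or candidate are
    skipped.  Returns -inf on a Mendelian exclusion when epsilon == 0.
    """
    total = 0.0
    n_used = 0
    for l, off in enumerate(offspring_gt):
        cand = candidate_gt[l]
        if off is None or cand is None:
            continue
        freqs = allele_freqs[l]
        pool = sorted(freqs)
        idx = {a: i for i, a in enumerate(pool)}
        k = len(pool)
        p = np.array([freqs[a] for a in pool])
        E = _error_matrix(k, epsilon)
        M = _obs_given_true(E, idx[off[0]], idx[off[1]])
        u, v = idx[cand[0]], idx[cand[1]]
        other = other_parent_gt[l] if other_parent_gt is not None else None
        if other is None:
            h = M @ p
            lik = 0.5 * (h[u] + h[v])
        else:
            w, z = idx[other[0]], idx[other[1]]
            lik = 0.25 * (M[u, w] + M[u, z] + M[v, w] + M[v, z])
        with np.errstate(divide="ignore"):
            total += float(np.log(lik))
        n_used += 1
    if n_used == 0:
        raise ValueError("no co-genotyped loci between offspring and candidate")
    return total


class _LocusContext:
    """Precomputed per-locus arrays shared across offspring and candidates."""

    def __init__(self, genotypes: GenotypeTable, reference_ids: Sequence[str], eps: float):
        self.loci = genotypes.loci
        self.pools: list[list[int]] = []
        self.freqs: list[np.ndarray] = []
        self.E: list[np.ndarray] = []
        self.index: list[dict[int, int]] = []
        for locus in self.loci:
            counts: dict[int, int] = {}
            for i in reference_ids:
                pair = genotypes.get(i, locus)
                if pair is not None:
                    for a in pair:
                        counts[a] = counts.get(a, 0) + 1
            pool = sorted(counts)
            tot = sum(counts.values())
            self.pools.append(pool)
            self.freqs.append(np.array([counts[a] / tot for a in pool]))
            self.E.append(_error_matrix(len(pool), eps))
            self.index.append({a: i for i, a in enumerate(pool)})

    def gt_indices(self, genotypes: GenotypeTable, ind: str, l: int) -> tuple[int, int] | None:
        pair = genotypes.get(ind, self.loci[l])
        if pair is None:
            return None
        idx = self.index[l]
        if pair[0] not in idx or pair[1] not in idx:
            return None  # allele unseen in reference; treat as missing
        return (idx[pair[0]], idx[pair[1]])


@dataclass
class _Assignment:
    offspring_id: str
    sire_id: str | None
    dam_id: str | None
    sire_support: float
    dam_support: float
    sire_lrt_p: float
    dam_lrt_p: float


def _single_parent_loglik(
    ctx: _LocusContext,
    genotypes: GenotypeTable,
    offspring_id: str,
    candidates: Sequence[str],
) -> tuple[np.ndarray, float, list]:
    """Log-likelihood per candidate as sole sampled parent, plus the
    no-sampled-parent log-likelihood; also returns per-locus M matrices."""
    n_cand = len(candidates)
    logL = np.zeros(n_cand)
    logL0 = 0.0
    Ms = []
    for l in range(len(ctx.loci)):
        off = ctx.gt_indices(genotypes, offspring_id, l)
        if off is None:
            Ms.append(None)
            continue
        p = ctx.freqs[l]
        M = _obs_given_true(ctx.E[l], off[0], off[1])
        Ms.append(M)
        h = M @ p
        L0 = float(p @ h)
        logL0 += np.log(L0)
        with np.errstate(divide="ignore"):
            for c, cand in enumerate(candidates):
                g = ctx.gt_indices(genotypes, cand, l)
                lik = L0 if g is None else 0.5 * (h[g[0]] + h[g[1]])
                logL[c] += np.log(lik)
    return logL, logL0, Ms


def assign_parents(
    offspring_ids: Sequence[str],
    candidate_sires: Sequence[str],
    candidate_dams: Sequence[str],
    genotypes: GenotypeTable,
    config: ParentageConfig,
    rng: np.random.Generator | None = None,
    reference_ids: Sequence[str] | None = None,
) -> list[PedigreeLink]:
    """Best sire-dam configuration per offspring under the allocation likelihood.

    Ties between equally likely candidates are refused (no link) unless
    ``config.tie_break == 'random'``, in which case the replicate rng decides.
    """
    rng = np.random.default_rng() if rng is None else rng
    if reference_ids is None:
        reference_ids = list(genotypes.ids)  # whole-table allele frequencies
    ctx = _LocusContext(genotypes, reference_ids, config.error_rate)
    pi = config.p_parent_sampled
    links: list[PedigreeLink] = []
    for off in offspring_ids:
        if off not in genotypes.calls or genotypes.missing_fraction(off) > config.max_missing:
            continue
        sires = [s for s in candidate_sires if s != off]
        dams = [d for d in candidate_dams if d != off]
        if not sires and not dams:
            continue
        logLs, logL0, Ms = _single_parent_loglik(ctx, genotypes, off, sires)
        logLd, _, _ = _single_parent_loglik(ctx, genotypes, off, dams)

        def best(cands: list[str], logs: np.ndarray) -> str | None:
            if not cands:
                return None
            order = np.argsort(-logs, kind="stable")
            if not np.isfinite(logs[order[0]]):
                return None  # every candidate Mendelian-excluded
            if len(order) > 1 and logs[order[0]] - logs[order[1]] < 1e-9:
                if config.tie_break == "random":
                    tied = [i for i in order if logs[order[0]] - logs[i] < 1e-9]
                    return cands[int(rng.choice(tied))]
                return None
            return cands[int(order[0])]

        def joint_loglik(sire: str, dam: str) -> float:
            total = 0.0
            for l, M in enumerate(Ms):
                if M is None:
                    continue
                p = ctx.freqs[l]
                gs = ctx.gt_indices(genotypes, sire, l)
                gd = ctx.gt_indices(genotypes, dam, l)
                h = M @ p
                if gs is None and gd is None:
                    lik = float(p @ h)
                elif gs is None:
                    lik = 0.5 * (h[gd[0]] + h[gd[1]])
                elif gd is None:
                    lik = 0.5 * (h[gs[0]] + h[gs[1]])
                else:
                    lik = 0.25 * (
                        M[gs[0], gd[0]] + M[gs[0], gd[1]] + M[gs[1], gd[0]] + M[gs[1], gd[1]]
                    )
                with np.errstate(divide="ignore"):
                    total += float(np.log(lik))
            return total

        s1 = best(sires, logLs)
        d1 = best(dams, logLd)
        logL10 = logLs[sires.index(s1)] if s1 else -np.inf
        logL01 = logLd[dams.index(d1)] if d1 else -np.inf
        # joint search over the K most likely candidates of each sex: the true
        # trio often dominates even when a relative wins the marginal ranking
        K = config.pair_top_k
        top_s = [sires[i] for i in np.argsort(-logLs, kind="stable")[:K]
                 if np.isfinite(logLs[i])] if sires else []
        top_d = [dams[i] for i in np.argsort(-logLd, kind="stable")[:K]
                 if np.isfinite(logLd[i])] if dams else []
        pair = None
        logL11 = -np.inf
        if top_s and top_d:
            scored = sorted(
                ((joint_loglik(s, d), s, d) for s in top_s for d in top_d),
                key=lambda x: -x[0],
            )
            if len(scored) == 1 or scored[0][0] - scored[1][0] >= 1e-9:
                logL11, *pair = scored[0]
                pair = tuple(pair)
            elif config.tie_break == "random":
                tied = [x for x in scored if scored[0][0] - x[0] < 1e-9]
                logL11, *pair = tied[int(rng.integers(len(tied)))]
                pair = tuple(pair)
        # posterior-style weights over the four configurations
        logw = np.array(
            [
                np.log((1 - pi) ** 2) + logL0,
                np.log(pi * (1 - pi)) + logL10 if s1 else -np.inf,
                np.log((1 - pi) * pi) + logL01 if d1 else -np.inf,
                2 * np.log(pi) + logL11 if pair else -np.inf,
            ]
        )
        if not np.isfinite(logw).any():
            continue
        w = np.exp(logw - logw[np.isfinite(logw)].max())
        w[~np.isfinite(logw)] = 0.0
        w /= w.sum()
        map_cfg = int(np.argmax(w))
        sire_support = float(w[1] + w[3])
        dam_support = float(w[2] + w[3])
        if map_cfg == 3:
            s_hat, d_hat = pair
            lr_s = max(0.0, 2.0 * (logL11 - logLd[dams.index(d_hat)]))
            lr_d = max(0.0, 2.0 * (logL11 - logLs[sires.index(s_hat)]))
            if float(chi2.sf(lr_s, df=1)) < config.retention_alpha:
                links.append(PedigreeLink(off, s_hat, "sire", round(sire_support, 6), 0))
            if float(chi2.sf(lr_d, df=1)) < config.retention_alpha:
                links.append(PedigreeLink(off, d_hat, "dam", round(dam_support, 6), 0))
        elif map_cfg == 1 and s1:
            lr = max(0.0, 2.0 * (logL10 - logL0))
            if float(chi2.sf(lr, df=1)) < config.retention_alpha:
                links.append(PedigreeLink(off, s1, "sire", round(sire_support, 6), 0))
        elif map_cfg == 2 and d1:
            lr = max(0.0, 2.0 * (logL01 - logL0))
            if float(chi2.sf(lr, df=1)) < config.retention_alpha:
                links.append(PedigreeLink(off, d1, "dam", round(dam_support, 6), 0))
    return links


# ---------------------------------------------------------------------------
# Sequential cohort stacking with replicate consensus
# ---------------------------------------------------------------------------


@dataclass
class SequentialResult:
    consensus: list[PedigreeLink]
    replicates: list[list[PedigreeLink]]
    step_snapshots: list[tuple[str, list[PedigreeLink]]]  # consensus links after each cohort


def sequential_pedigree(
    cohort_members: Mapping[CohortKey, Sequence[str]],
    sexes: Mapping[str, str],
    genotypes: GenotypeTable,
    config: ParentageConfig,
    seeds: Sequence[int] | None = None,
) -> SequentialResult:
    """Run the stepwise cohort-stacking parentage procedure in replicate.

    At step k the candidate parents are all individuals first seen in cohorts
    1..k (males as sires, females as dams) and the offspring are the cohort-k
    newcomers; accepted links are fixed and never revised.  Links present in
    every replicate form the consensus.
    """
    cohorts = list(cohort_members)
    if cohorts != sorted(cohorts):
        raise ValueError("cohorts must be supplied in chronological order")
    if seeds is None:
        seeds = list(range(1, config.n_replicates + 1))
    if len(seeds) != config.n_replicates:
        raise ValueError("need one seed per replicate")
    first_cohort: dict[str, CohortKey] = {}
    for ck in cohorts:
        for ind in cohort_members[ck]:
            first_cohort.setdefault(ind, ck)

    replicate_links: list[list[PedigreeLink]] = []
    replicate_steps: list[list[tuple[str, list[PedigreeLink]]]] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        accepted: list[PedigreeLink] = []
        have_parent: set[tuple[str, str]] = set()
        steps: list[tuple[str, list[PedigreeLink]]] = []
        for k, ck in enumerate(cohorts):
            newcomers = [i for i in cohort_members[ck] if first_cohort[i] == ck]
            offspring = [
                i
                for i in newcomers
                if (i, "sire") not in have_parent or (i, "dam") not in have_parent
            ]
            seen = [i for c in cohorts[: k + 1] for i in cohort_members[c]]
            seen = sorted(set(seen))
            sires = [i for i in seen if sexes.get(i) == "M" and i in genotypes.calls]
            dams = [i for i in seen if sexes.get(i) == "F" and i in genotypes.calls]
            new_links = assign_parents(
                offspring, sires, dams, genotypes, config, rng=rng, reference_ids=seen
            )
            parent_of: dict[str, set[str]] = {}
            for l in accepted:
                parent_of.setdefault(l.offspring_id, set()).add(l.parent_id)

            def is_ancestor(anc: str, ind: str) -> bool:
                stack = [ind]
                seen_ids: set[str] = set()
                while stack:
                    cur = stack.pop()
                    if cur == anc:
                        return True
                    if cur in seen_ids:
                        continue
                    seen_ids.add(cur)
                    stack.extend(parent_of.get(cur, ()))
                return False

            for link in new_links:
                key = (link.offspring_id, link.parent_role)
                # same-cohort candidates can produce reciprocal assignments;
                # refuse any link that would close a parentage cycle
                if key not in have_parent and not is_ancestor(
                    link.offspring_id, link.parent_id
                ):
                    have_parent.add(key)
                    accepted.append(link)
                    parent_of.setdefault(link.offspring_id, set()).add(link.parent_id)
            steps.append((ck.label, list(accepted)))
        replicate_links.append(accepted)
        replicate_steps.append(steps)

    keysets = [
        {(l.offspring_id, l.parent_id, l.parent_role) for l in rep} for rep in replicate_links
    ]
    common = set.intersection(*keysets)
    by_key: dict[tuple, list[PedigreeLink]] = {}
    for rep in replicate_links:
        for l in rep:
            by_key.setdefault((l.offspring_id, l.parent_id, l.parent_role), []).append(l)
    consensus = [
        PedigreeLink(
            k[0],
            k[1],
            k[2],
            round(float(np.mean([l.support for l in by_key[k]])), 6),
            len(seeds),
        )
        for k in sorted(common)
    ]
    # per-step consensus snapshots (intersection of replicate snapshots)
    snapshots: list[tuple[str, list[PedigreeLink]]] = []
    for s in range(len(cohorts)):
        keys = set.intersection(
            *[
                {(l.offspring_id, l.parent_id, l.parent_role) for l in rep[s][1]}
                for rep in replicate_steps
            ]
        )
        snap = [l for l in consensus if (l.offspring_id, l.parent_id, l.parent_role) in keys]
        snapshots.append((cohorts[s].label, snap))
    return SequentialResult(consensus, replicate_links, snapshots)


# ---------------------------------------------------------------------------
# Pedigree inbreeding
# ---------------------------------------------------------------------------


def _parent_map(links: Sequence[PedigreeLink]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for l in links:
        out.setdefault(l.offspring_id, {})[l.parent_role] = l.parent_id
    return out


def pedigree_kinship(
    links: Sequence[PedigreeLink] | Mapping[str, tuple[str | None, str | None]],
    a: str,
    b: str,
) -> float:
    """Pedigree kinship f(a, b) by the recursive tabular method."""
    if isinstance(links, Mapping):
        parents = {k: {"sire": v[0], "dam": v[1]} for k, v in links.items()}
        parents = {
            k: {r: p for r, p in d.items() if p is not None} for k, d in parents.items()
        }
    else:
        parents = _parent_map(links)

    depth_memo: dict[str, int] = {}
    in_progress: set[str] = set()

    def depth(x: str) -> int:
        if x not in depth_memo:
            if x in in_progress:
                raise ValueError(f"pedigree cycle through {x}")
            in_progress.add(x)
            ps = parents.get(x, {})
            depth_memo[x] = 1 + max((depth(p) for p in ps.values()), default=-1)
            in_progress.discard(x)
        return depth_memo[x]

    memo: dict[tuple[str, str], float] = {}

    def f(x: str, y: str) -> float:
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        if x == y:
            ps = parents.get(x, {})
            val = 0.5 * (1.0 + (f(ps["sire"], ps["dam"]) if len(ps) == 2 else 0.0))
        else:
            # recurse through the parents of the later-generation individual
            if depth(x) < depth(y):
                x, y = y, x
            ps = parents.get(x, {})
            if not ps:
                val = 0.0
            else:
                val = 0.5 * sum(f(p, y) for p in ps.values())
                # an individual with a single known parent: the unknown parent
                # is an unrelated founder and contributes 0
        memo[key] = val
        return val

    return f(a, b)


def inbreeding_coefficient(
    links: Sequence[PedigreeLink] | Mapping[str, tuple[str | None, str | None]],
    individual_id: str,
) -> float:
    """F = pedigree kinship of the individual's two parents (0 if either unknown)."""
    if isinstance(links, Mapping):
        sire, dam = links.get(individual_id, (None, None))
    else:
        pm = _parent_map(links).get(individual_id, {})
        sire, dam = pm.get("sire"), pm.get("dam")
    if sire is None or dam is None:
        return 0.0
    return pedigree_kinship(links, sire, dam)


def inbreeding_trajectory(
    step_snapshots: Sequence[tuple[str, Sequence[PedigreeLink]]],
) -> list[dict]:
    """Mean pedigree F (over individuals with both parents assigned) after each
    sequential cohort step."""
    out = []
    for label, links in step_snapshots:
        pm = _parent_map(links)
        full = [i for i, d in pm.items() if "sire" in d and "dam" in d]
        fs = [inbreeding_coefficient(list(links), i) for i in full]
        out.append(
            {
                "cohort": label,
                "n_with_parents": len(full),
                "mean_F": float(np.mean(fs)) if fs else 0.0,
                "sd_F": float(np.std(fs, ddof=1)) if len(fs) > 1 else 0.0,
            }
        )
    return out
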