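"""Individual-based simulator of a fenced-park lizard population.

The model emulates a one-hectare urban park whose perimeter fence is fringed
by discrete bushes — the only usable habitat.  Males come in two size morphs
split at 64 mm SVL: heavyweights defend exactly one bush each (contested
bushes go to the larger male), lightweights roam as non-territorial sneakers.
Mating is polygynous: a female's offspring is sired by her bush's resident
heavyweight with probability ``p_resident_sire``, otherwise by a random
lightweight.  Offspring recruit one season after birth at the dam's bush;
sons disperse (leave the natal bush, and by default avoid their sire's entire
occupied range) while daughters tend to be philopatric.  Microsatellite
genotypes follow Mendelian inheritance from true parental genotypes, with an
independent per-allele mistyping probability applied to the *observed* table.

Every run emits the three analysis inputs (capture CSV, GenePop genotypes,
habitat GeoJSON) plus a ground-truth set (pedigree, natal bushes, per-season
occupancy, morph history) for parameter-recovery testing.

Demographic rates (survival, recruitment, growth, maturity) are model
assumptions chosen to produce roughly 850 unique captured individuals over
ten seasonal cohorts; see docs/methods.md.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon, box
from shapely.ops import unary_union

from .io import (
    CaptureRecord,
    CohortKey,
    GenotypeTable,
    HabitatMap,
    write_capture_table,
    write_genotypes,
    write_habitat,
)

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimResult",
    "generate_habitat",
    "mendelian_offspring",
    "apply_genotyping_error",
    "simulate_population",
    "write_outputs",
]


@dataclass
class SimConfig:
    # habitat
    park_width: float = 100.0  # m; one-hectare square park
    park_height: float = 100.0
    n_bushes: int = 38
    bush_depth: float = 2.0  # m into the park from the fence
    bush_length_range: tuple[float, float] = (4.0, 8.0)  # m along the fence
    # genetics
    n_loci: int = 8
    alleles_per_locus: tuple[int, int] = (13, 33)
    genotyping_error: float = 0.01
    # demography & behaviour
    founder_n: int = 110
    n_cohorts: int = 10
    start_year: int = 2010
    capture_prob: float = 0.55
    p_female_philopatry: float = 0.8
    p_male_natal_stay: float = 0.0
    # seasonal within-park movement (heavyweights hold their territory and
    # never roam; females and sneaker lightweights shift between nearby bushes)
    p_female_move: float = 0.25
    p_male_move: float = 0.15
    move_k_nearest: int = 4
    # female-defence polygyny: a moving female heads for the nearest bush held
    # by a resident heavyweight with this probability
    hw_preference: float = 0.7
    male_avoids_sire_range: bool = True
    p_resident_sire: float = 0.8
    survival_prob: float = 0.65
    recruits_per_female: float = 2.1  # Poisson mean per mature female per season
    female_maturity_svl: float = 42.0
    recruit_svl_range: tuple[float, float] = (28.0, 38.0)
    growth_mean: float = 10.0  # SVL increment per season, mm
    growth_sd: float = 2.0
    svl_asymptote_male: float = 78.0
    svl_asymptote_female: float = 72.0
    founder_svl_range: tuple[float, float] = (35.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "capture_prob",
            "p_female_philopatry",
            "p_male_natal_stay",
            "p_resident_sire",
            "survival_prob",
            "genotyping_error",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_bushes < 2:
            raise ValueError("need at least 2 bushes")


@dataclass
class TruthSet:
    """Ground truth emitted alongside the observable outputs."""

    pedigree: dict[str, tuple[str | None, str | None]]  # id -> (sire, dam)
    natal_bush: dict[str, int]
    bush_by_season: dict[str, dict[str, int]]  # id -> cohort label -> bush
    svl_by_season: dict[str, dict[str, float]]
    sexes: dict[str, str]
    territory_by_season: dict[str, dict[str, int]]  # cohort label -> hw id -> bush

    def true_sire(self, ind: str) -> str | None:
        return self.pedigree.get(ind, (None, None))[0]

    def true_dam(self, ind: str) -> str | None:
        return self.pedigree.get(ind, (None, None))[1]


@dataclass
class SimResult:
    config: SimConfig
    habitat: HabitatMap
    records: list[CaptureRecord]
    genotypes: GenotypeTable  # observed (error-perturbed) calls, captured ids only
    truth: TruthSet
    allele_pools: list[list[int]]
    cohorts: list[CohortKey]


# ---------------------------------------------------------------------------
# Habitat generation
# ---------------------------------------------------------------------------


def generate_habitat(config: SimConfig, seed: int | None = None) -> HabitatMap:
    """Place rectangular bushes of fixed depth along the park fence.

    Bushes are distributed over the four walls with random lengths and gaps;
    corners are kept clear so bushes on adjacent walls never overlap.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    W, H = config.park_width, config.park_height
    d = config.bush_depth
    margin = d + 0.5  # keep corners clear
    walls = [W, H, W, H]  # south, east, north, west
    capacity = [w - 2 * margin for w in walls]
    cursor = [margin] * 4
    lengths = rng.uniform(*config.bush_length_range, size=config.n_bushes)
    if lengths.sum() > sum(capacity):
        raise ValueError(
            f"total bush length {lengths.sum():.0f} m exceeds usable perimeter "
            f"{sum(capacity):.0f} m"
        )
    bushes: dict[int, Polygon] = {}
    for i, length in enumerate(lengths, start=1):
        remaining = [walls[w] - margin - cursor[w] for w in range(4)]
        w = int(np.argmax(remaining))
        if remaining[w] < length:
            raise ValueError(f"cannot fit bush {i} of length {length:.1f} m")
        max_gap = min(2.0, max(0.0, remaining[w] - length))
        gap = float(rng.uniform(0.2, max(0.3, max_gap)))
        gap = min(gap, max(0.0, remaining[w] - length))
        s = cursor[w] + gap
        if w == 0:  # south wall
            poly = box(s, 0.0, s + length, d)
        elif w == 1:  # east wall
            poly = box(W - d, s, W, s + length)
        elif w == 2:  # north wall
            poly = box(s, H - d, s + length, H)
        else:  # west wall
            poly = box(0.0, s, d, s + length)
        cursor[w] = s + length
        bushes[i] = poly
    fence = LineString([(0, 0), (W, 0), (W, H), (0, H), (0, 0)])
    return HabitatMap(bushes, fence)


# ---------------------------------------------------------------------------
# Genetics
# ---------------------------------------------------------------------------


def mendelian_offspring(
    sire_gt: Sequence[tuple[int, int] | None],
    dam_gt: Sequence[tuple[int, int] | None],
    rng: np.random.Generator,
) -> list[tuple[int, int] | None]:
    """One uniformly chosen allele from each parent, independently per locus.

    A locus missing in either parent yields a missing offspring locus.
    """
    out: list[tuple[int, int] | None] = []
    for sg, dg in zip(sire_gt, dam_gt):
        if sg is None or dg is None:
            out.append(None)
        else:
            a = sg[int(rng.integers(2))]
            b = dg[int(rng.integers(2))]
            out.append((min(a, b), max(a, b)))
    return out


def apply_genotyping_error(
    genotype: Sequence[tuple[int, int] | None],
    allele_pools: Sequence[Sequence[int]],
    epsilon: float,
    rng: np.random.Generator,
) -> list[tuple[int, int] | None]:
    """Each allele call is independently replaced, with probability epsilon,
    by a uniformly drawn *different* allele from that locus's pool."""
    out: list[tuple[int, int] | None] = []
    for gt, pool in zip(genotype, allele_pools):
        if gt is None:
            out.append(None)
            continue
        obs = []
        for a in gt:
            if epsilon > 0 and rng.random() < epsilon and len(pool) > 1:
                others = [x for x in pool if x != a]
                obs.append(int(others[int(rng.integers(len(others)))]))
            else:
                obs.append(int(a))
        out.append((min(obs), max(obs)))
    return out


def _founder_allele_pools(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[list[int]], list[np.ndarray]]:
    """Allele size pools and symmetric-Dirichlet founder frequencies per locus."""
    pools, freqs = [], []
    lo, hi = config.alleles_per_locus
    for _ in range(config.n_loci):
        k = int(rng.integers(lo, hi + 1))
        sizes = list(range(100, 100 + 2 * k, 2))  # even 3-digit sizes, microsat-style
        pools.append(sizes)
        freqs.append(rng.dirichlet(np.ones(k)))
    return pools, freqs


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


@dataclass
class _Lizard:
    id: str
    sex: str
    svl: float
    bush: int
    genotype: list  # true genotype
    sire: str | None = None
    dam: str | None = None
    natal_bush: int | None = None
    occupied: set = field(default_factory=set)


def _forbidden_for_male(
    habitat: HabitatMap, sire: _Lizard | None, avoid: bool
) -> set[int]:
    """Bushes a dispersing male avoids: everything intersecting the hull of
    his sire's occupied bushes (strict paternal-range avoidance)."""
    if sire is None or not avoid or not sire.occupied:
        return set()
    hull = unary_union([habitat.bushes[b] for b in sire.occupied]).convex_hull
    return {b for b, poly in habitat.bushes.items() if poly.intersects(hull)}


def _male_move_ok(
    habitat: HabitatMap,
    male: _Lizard,
    candidate: int,
    sons: Mapping[str, "_Lizard"],
    avoid: bool,
) -> bool:
    """Male kin exclusion is mutual: a male may not move such that the hull of
    his occupied bushes comes to cover a bush any of his sons has used."""
    if not avoid or not sons:
        return True
    hull = unary_union(
        [habitat.bushes[b] for b in (male.occupied | {candidate})]
    ).convex_hull
    for son in sons.values():
        for b in son.occupied:
            if habitat.bushes[b].intersects(hull):
                return False
    return True


def simulate_population(config: SimConfig) -> SimResult:
    """Run the seasonal individual-based model and return observables + truth."""
    rng = np.random.default_rng(config.seed)
    habitat = generate_habitat(config, seed=config.seed)
    bush_ids = habitat.bush_ids
    cents = {b: np.array(habitat.centroid(b)) for b in bush_ids}
    pools, founder_freqs = _founder_allele_pools(config, rng)

    def draw_founder_genotype() -> list:
        gt = []
        for pool, fr in zip(pools, founder_freqs):
            a, b = rng.choice(len(pool), size=2, p=fr)
            a, b = pool[int(a)], pool[int(b)]
            gt.append((min(a, b), max(a, b)))
        return gt

    next_id = [0]

    def new_id() -> str:
        next_id[0] += 1
        return f"A{next_id[0]:04d}"

    alive: dict[str, _Lizard] = {}
    for _ in range(config.founder_n):
        liz = _Lizard(
            id=new_id(),
            sex="M" if rng.random() < 0.5 else "F",
            svl=float(rng.uniform(*config.founder_svl_range)),
            bush=int(rng.choice(bush_ids)),
            genotype=draw_founder_genotype(),
        )
        alive[liz.id] = liz

    truth = TruthSet({}, {}, {}, {}, {}, {})
    all_lizards: dict[str, _Lizard] = dict(alive)
    sons_of: dict[str, dict[str, _Lizard]] = {}
    records: list[CaptureRecord] = []
    cohorts: list[CohortKey] = []
    cohort = CohortKey(config.start_year, 0)

    prev_claimed: dict[int, str] = {}
    for step in range(config.n_cohorts):
        if not alive:
            raise RuntimeError(f"population extinct before cohort {step} ({cohort.label})")
        cohorts.append(cohort)
        # keep occupancy histories current before anyone moves this season:
        # male kin-exclusion checks below rely on up-to-date sets
        for liz in alive.values():
            liz.occupied.add(liz.bush)
        # --- seasonal movement of females and lightweight males ---
        for liz in sorted(alive.values(), key=lambda l: l.id):
            is_hw = liz.sex == "M" and liz.svl >= 64.0
            if is_hw:
                continue  # heavyweights keep their territory bush
            p_move = config.p_female_move if liz.sex == "F" else config.p_male_move
            if rng.random() < p_move:
                here = cents[liz.bush]
                ranked = sorted(
                    (b for b in bush_ids if b != liz.bush),
                    key=lambda b: (float(np.linalg.norm(cents[b] - here)), b),
                )
                options = ranked[: config.move_k_nearest]
                if (
                    liz.sex == "F"
                    and prev_claimed
                    and rng.random() < config.hw_preference
                ):
                    held = [b for b in ranked if b in prev_claimed]
                    if held:
                        options = [held[0]]
                if liz.sex == "M":
                    sire = all_lizards.get(liz.sire) if liz.sire else None
                    forbidden = _forbidden_for_male(
                        habitat, sire, config.male_avoids_sire_range
                    )
                    options = [
                        b
                        for b in options
                        if b not in forbidden
                        and _male_move_ok(
                            habitat,
                            liz,
                            b,
                            sons_of.get(liz.id, {}),
                            config.male_avoids_sire_range,
                        )
                    ]
                if options:
                    liz.bush = int(options[int(rng.integers(len(options)))])
                    liz.occupied.add(liz.bush)
        # --- territory assignment: heavyweights claim one bush each ---
        heavies = sorted(
            (l for l in alive.values() if l.sex == "M" and l.svl >= 64.0),
            key=lambda l: (-l.svl, l.id),
        )
        claimed: dict[int, str] = {}
        for hw in heavies:
            if hw.bush not in claimed:
                claimed[hw.bush] = hw.id
            else:
                # displaced: nearest unclaimed bush, honouring male kin exclusion
                sire = all_lizards.get(hw.sire) if hw.sire else None
                forbidden = _forbidden_for_male(habitat, sire, config.male_avoids_sire_range)
                options = [
                    b
                    for b in bush_ids
                    if b not in claimed
                    and b not in forbidden
                    and _male_move_ok(
                        habitat, hw, b, sons_of.get(hw.id, {}), config.male_avoids_sire_range
                    )
                ]
                if options:
                    here = cents[hw.bush]
                    options.sort(key=lambda b: (float(np.linalg.norm(cents[b] - here)), b))
                    hw.bush = options[0]
                    hw.occupied.add(hw.bush)
                    claimed[hw.bush] = hw.id
                # else: shares the bush (stays put rather than violate exclusion)
        truth.territory_by_season[cohort.label] = {v: k for k, v in claimed.items()}
        prev_claimed = dict(claimed)
        for liz in alive.values():
            liz.occupied.add(liz.bush)
            truth.bush_by_season.setdefault(liz.id, {})[cohort.label] = liz.bush
            truth.svl_by_season.setdefault(liz.id, {})[cohort.label] = round(liz.svl, 2)

        # --- capture sampling ---
        for liz in sorted(alive.values(), key=lambda l: l.id):
            if rng.random() < config.capture_prob:
                mass = 4e-5 * liz.svl**2.7 * float(rng.uniform(0.9, 1.1))
                records.append(
                    CaptureRecord(
                        individual_id=liz.id,
                        cohort=cohort,
                        sex=liz.sex,
                        svl=round(min(liz.svl, 80.0), 2),
                        mass=round(mass, 2),
                        bush_id=liz.bush,
                    )
                )

        last = step == config.n_cohorts - 1
        # --- mating (recruits appear next season) ---
        newborns: list[_Lizard] = []
        if not last:
            resident = {bush: hw_id for bush, hw_id in claimed.items()}
            males = [l for l in alive.values() if l.sex == "M"]
            lightweights = [l for l in males if l.svl < 64.0]
            females = [
                l
                for l in alive.values()
                if l.sex == "F" and l.svl >= config.female_maturity_svl
            ]
            for dam in sorted(females, key=lambda l: l.id):
                n_off = int(rng.poisson(config.recruits_per_female))
                for _ in range(n_off):
                    sire: _Lizard | None = None
                    if dam.bush in resident and rng.random() < config.p_resident_sire:
                        sire = alive[resident[dam.bush]]
                    elif lightweights:
                        sire = lightweights[int(rng.integers(len(lightweights)))]
                    elif males:
                        sire = males[int(rng.integers(len(males)))]
                    if sire is None:
                        continue
                    kid = _Lizard(
                        id=new_id(),
                        sex="M" if rng.random() < 0.5 else "F",
                        svl=float(rng.uniform(*config.recruit_svl_range)),
                        bush=dam.bush,
                        genotype=mendelian_offspring(sire.genotype, dam.genotype, rng),
                        sire=sire.id,
                        dam=dam.id,
                        natal_bush=dam.bush,
                    )
                    newborns.append(kid)

        # --- survival and growth ---
        survivors: dict[str, _Lizard] = {}
        for liz in alive.values():
            if rng.random() < config.survival_prob:
                inc = max(0.0, float(rng.normal(config.growth_mean, config.growth_sd)))
                cap = (
                    config.svl_asymptote_male
                    if liz.sex == "M"
                    else config.svl_asymptote_female
                )
                liz.svl = min(liz.svl + inc, cap)
                survivors[liz.id] = liz
        alive = survivors

        # --- recruitment with sex-biased dispersal ---
        for kid in newborns:
            truth.pedigree[kid.id] = (kid.sire, kid.dam)
            truth.natal_bush[kid.id] = kid.natal_bush
            stay_p = (
                config.p_male_natal_stay if kid.sex == "M" else config.p_female_philopatry
            )
            if rng.random() >= stay_p:
                if kid.sex == "M":
                    sire = all_lizards.get(kid.sire) if kid.sire else None
                    forbidden = _forbidden_for_male(
                        habitat, sire, config.male_avoids_sire_range
                    )
                    forbidden.add(kid.natal_bush)
                else:
                    forbidden = {kid.natal_bush}
                options = [b for b in bush_ids if b not in forbidden]
                if options:
                    kid.bush = int(options[int(rng.integers(len(options)))])
            alive[kid.id] = kid
            all_lizards[kid.id] = kid
            if kid.sex == "M" and kid.sire:
                sons_of.setdefault(kid.sire, {})[kid.id] = kid
        cohort = cohort.next()

    for liz in all_lizards.values():
        truth.sexes[liz.id] = liz.sex

    # --- observed genotype table for captured individuals ---
    captured_ids = sorted({r.individual_id for r in records})
    loci = [f"L{i + 1:02d}" for i in range(config.n_loci)]
    calls = {}
    for ind in captured_ids:
        obs = apply_genotyping_error(
            all_lizards[ind].genotype, pools, config.genotyping_error, rng
        )
        calls[ind] = dict(zip(loci, obs))
    genotypes = GenotypeTable(loci, calls)

    return SimResult(
        config=config,
        habitat=habitat,
        records=records,
        genotypes=genotypes,
        truth=truth,
        allele_pools=[list(p) for p in pools],
        cohorts=cohorts,
    )


def write_outputs(result: SimResult, out_dir: str | Path) -> dict[str, Path]:
    """Write capture.csv, genotypes.gen, habitat.geojson and the truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "captures": out / "capture.csv",
        "genotypes": out / "genotypes.gen",
        "habitat": out / "habitat.geojson",
        "truth_pedigree": out / "truth_pedigree.csv",
        "truth_ranges": out / "truth_ranges.csv",
    }
    write_capture_table(result.records, paths["captures"])
    write_genotypes(result.genotypes, paths["genotypes"], format="genepop")
    write_habitat(result.habitat, paths["habitat"])
    with open(paths["truth_pedigree"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "sire_id", "dam_id", "natal_bush"])
        for ind, (sire, dam) in sorted(result.truth.pedigree.items()):
            w.writerow([ind, sire or "", dam or "", result.truth.natal_bush.get(ind, "")])
    with open(paths["truth_ranges"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "cohort", "bush_id", "svl_mm"])
        for ind, by_season in sorted(result.truth.bush_by_season.items()):
            for label, bush in by_season.items():
                w.writerow([ind, label, bush, result.truth.svl_by_season[ind][label]])
    return paths
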