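"""End-to-end hypothesis tests on a park dataset (real or simulated).

H1: home-range area differs between the sexes (linear model of log area on sex).
H2: home-range area scales with body size (Pearson r of log area vs max SVL).
H3: male spatial distancing is structured by size morph (linear model of the
    per-male average distance d' on morph and cohort, per-cohort pairwise
    rank-sum tests between morph pair classes, Mantel tests of |dSVL| vs
    geographic distance).
H4: offspring are captured inside a parent's home range (per parent-role
    inside/outside x offspring-sex tables with Yates-corrected chi-square).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    CaptureRecord,
    GenotypeTable,
    HabitatMap,
    Individual,
    PedigreeLink,
    build_individuals,
    classify_morph,
    cohort_members,
)
from .pedigree import ParentageConfig, inbreeding_trajectory, sequential_pedigree
from .popgen import (
    autocorrelogram,
    holm_bonferroni,
    hwe_exact_test,
    locus_summaries,
    loiselle_kinship,
    mantel_test,
)
from .spatial import (
    DistanceMatrix,
    HomeRange,
    average_distance,
    bush_distance_matrix,
    home_ranges,
    individual_distance_matrix,
)

__all__ = [
    "yates_chi_square",
    "h1_home_range_by_sex",
    "h2_size_range_correlation",
    "h3_distancing",
    "h4_inheritance",
    "run_all",
    "render_markdown",
]


def yates_chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    statistic = sum over cells of (max(0, |O-E| - 0.5))^2 / E; p from the
    chi-square distribution with 1 df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables")
    total = obs.sum()
    if total == 0:
        raise ValueError("empty table")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(exp == 0):
        return math.nan, math.nan
    stat = float(np.sum(np.maximum(np.abs(obs - exp) - 0.5, 0.0) ** 2 / exp))
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# H1 / H2
# ---------------------------------------------------------------------------


def h1_home_range_by_sex(
    ranges: Mapping[str, HomeRange], sexes: Mapping[str, str]
) -> dict:
    """Linear model of log home-range area on sex."""
    import statsmodels.formula.api as smf

    rows = [
        {"id": i, "log_area": math.log(hr.area), "area": hr.area, "sex": sexes[i]}
        for i, hr in ranges.items()
    ]
    df = pd.DataFrame(rows)
    counts = df["sex"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 individuals of each sex")
    fit = smf.ols("log_area ~ C(sex)", data=df).fit()
    return {
        "n_male": int(counts.get("M", 0)),
        "n_female": int(counts.get("F", 0)),
        "mean_area_male": float(df.loc[df.sex == "M", "area"].mean()),
        "mean_area_female": float(df.loc[df.sex == "F", "area"].mean()),
        "F": float(fit.fvalue),
        "df": (int(fit.df_model), int(fit.df_resid)),
        "p": float(fit.f_pvalue),
    }


def h2_size_range_correlation(
    ranges: Mapping[str, HomeRange],
    individuals: Mapping[str, Individual],
    subset: str = "all",
) -> dict:
    """Pearson correlation of log home-range area with maximum recorded SVL."""
    ids = [
        i
        for i in ranges
        if subset == "all" or individuals[i].sex == {"male": "M", "female": "F"}[subset]
    ]
    if len(ids) < 3:
        return {"subset": subset, "n": len(ids), "r": math.nan, "p": math.nan,
                "flag": "n < 3"}
    x = np.array([individuals[i].max_svl for i in ids])
    y = np.array([math.log(ranges[i].area) for i in ids])
    if np.std(x) == 0 or np.std(y) == 0:
        return {"subset": subset, "n": len(ids), "r": math.nan, "p": math.nan,
                "flag": "constant variable"}
    r, p = stats.pearsonr(x, y)
    return {"subset": subset, "n": len(ids), "r": float(r), "p": float(p)}


# ---------------------------------------------------------------------------
# H3: spatial distancing of male size morphs
# ---------------------------------------------------------------------------


def _male_table(records: Sequence[CaptureRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.individual_id,
            "cohort": r.cohort.label,
            "cohort_key": r.cohort,
            "bush": r.bush_id,
            "svl": r.svl,
            "morph": classify_morph(r.svl),
        }
        for r in records
        if r.sex == "M"
    ]
    return pd.DataFrame(rows)


def h3_distancing(
    records: Sequence[CaptureRecord],
    habitat: HabitatMap,
    dmat: DistanceMatrix | None = None,
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> dict:
    """Morph-structured male spatial distancing.

    Per cohort and focal male, computes the mean distance d' to all other
    males, and the pair-class means (LW-LW, HW-HW, LW-HW).  Fits a linear
    model of d' on morph + cohort, adds male density only if a partial-F test
    improves the fit, runs per-cohort pairwise rank-sum tests between pair
    classes (Holm-corrected), and Mantel tests of |dSVL| vs distance.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    rng = np.random.default_rng() if rng is None else rng
    if dmat is None:
        dmat = bush_distance_matrix(habitat, metric="perimeter")
    males = _male_table(records)
    if males.empty:
        return {"flag": "no male records"}
    per_male_rows = []
    pairwise: dict[str, dict] = {}
    mantel: dict[str, dict] = {}
    for cohort, grp in males.groupby("cohort", sort=False):
        ids = grp["id"].tolist()
        if len(ids) < 2:
            continue
        pos = dict(zip(grp["id"], grp["bush"]))
        morph = dict(zip(grp["id"], grp["morph"]))
        svl = dict(zip(grp["id"], grp["svl"]))
        lows = [i for i in ids if morph[i] == "lightweight"]
        highs = [i for i in ids if morph[i] == "heavyweight"]
        for i in ids:
            ad = average_distance(i, pos, dmat, cohort_label=cohort)
            same = lows if morph[i] == "lightweight" else highs
            cross = highs if morph[i] == "lightweight" else lows
            d_same = (
                float(np.mean([dmat.get(pos[i], pos[j]) for j in same if j != i]))
                if len(same) > 1
                else math.nan
            )
            d_cross = (
                float(np.mean([dmat.get(pos[i], pos[j]) for j in cross]))
                if cross
                else math.nan
            )
            per_male_rows.append(
                {
                    "id": i,
                    "cohort": cohort,
                    "morph": morph[i],
                    "d_prime": ad.d_prime,
                    "d_same_morph": d_same,
                    "d_cross_morph": d_cross,
                    "density": len(ids),
                }
            )
        # per-cohort pairwise rank-sum tests between the three pair classes
        ll = [r["d_same_morph"] for r in per_male_rows
              if r["cohort"] == cohort and r["morph"] == "lightweight"
              and not math.isnan(r["d_same_morph"])]
        hh = [r["d_same_morph"] for r in per_male_rows
              if r["cohort"] == cohort and r["morph"] == "heavyweight"
              and not math.isnan(r["d_same_morph"])]
        lh = [r["d_cross_morph"] for r in per_male_rows
              if r["cohort"] == cohort and r["morph"] == "lightweight"
              and not math.isnan(r["d_cross_morph"])]
        comps, ps = [], []
        for name, a, b in (("HH_vs_LL", hh, ll), ("LH_vs_LL", lh, ll), ("HH_vs_LH", hh, lh)):
            if len(a) >= 2 and len(b) >= 2:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                comps.append(name)
                ps.append(p)
        flags = holm_bonferroni(ps) if ps else []
        pairwise[cohort] = {
            n: {"p": float(p), "significant": bool(f)}
            for n, p, f in zip(comps, ps, flags)
        }
        # Mantel: |dSVL| vs geographic distance, within cohort
        def _mantel_for(sub_ids: list[str], label: str) -> None:
            if len(sub_ids) < 4:
                return
            sub_pos = {i: pos[i] for i in sub_ids}
            gdist = individual_distance_matrix(sub_pos, dmat)
            sv = np.array([svl[i] for i in sub_ids])
            size_diff = np.abs(sv[:, None] - sv[None, :])
            if size_diff.std() == 0 or gdist.values.std() == 0:
                return
            res = mantel_test(
                size_diff, gdist.values, n_perm=n_perm, rng=rng,
                alternative="greater", description=f"{cohort}:{label}",
            )
            mantel.setdefault(cohort, {})[label] = {"r": res.r, "p": res.p}

        _mantel_for(ids, "all_males")
        _mantel_for(highs, "heavyweights")
        _mantel_for(lows, "lightweights")

    df = pd.DataFrame(per_male_rows)
    out: dict = {"per_male": df, "pairwise_by_cohort": pairwise, "mantel_by_cohort": mantel}
    if df["d_prime"].std() == 0:
        out["model"] = {"flag": "degenerate: all d' identical"}
        return out
    if df["cohort"].nunique() > 1 and df["morph"].nunique() > 1:
        base = smf.ols("d_prime ~ C(morph) + C(cohort)", data=df).fit()
        aug = smf.ols("d_prime ~ C(morph) + C(cohort) + density", data=df).fit()
        try:
            cmp_tab = sm.stats.anova_lm(base, aug)
            density_p = float(cmp_tab["Pr(>F)"].iloc[1])
        except Exception:
            density_p = math.nan
        use_density = bool(density_p < 0.05) if not math.isnan(density_p) else False
        fit = aug if use_density else base
        anova = sm.stats.anova_lm(fit, typ=2)
        out["model"] = {
            "r2": float(fit.rsquared),
            "F": float(fit.fvalue),
            "df": (int(fit.df_model), int(fit.df_resid)),
            "p": float(fit.f_pvalue),
            "morph_p": float(anova.loc["C(morph)", "PR(>F)"]),
            "cohort_p": float(anova.loc["C(cohort)", "PR(>F)"]),
            "density_partial_F_p": density_p,
            "density_retained": use_density,
        }
    else:
        out["model"] = {"flag": "needs >=2 cohorts and both morphs"}
    # pair-class grand means, as in a pooled summary table
    out["class_means"] = {
        "LW_LW": float(df.loc[df.morph == "lightweight", "d_same_morph"].mean()),
        "HW_HW": float(df.loc[df.morph == "heavyweight", "d_same_morph"].mean()),
        "LW_HW": float(df.loc[df.morph == "lightweight", "d_cross_morph"].mean()),
    }
    return out


# ---------------------------------------------------------------------------
# H4: home-range inheritance
# ---------------------------------------------------------------------------


@dataclass
class InheritanceRecord:
    offspring_id: str
    parent_id: str
    parent_role: str
    offspring_sex: str
    offspring_capture_bushes: list[int]
    inside_parent_range: bool


def h4_inheritance(
    links: Sequence[PedigreeLink],
    ranges: Mapping[str, HomeRange],
    individuals: Mapping[str, Individual],
    habitat: HabitatMap,
) -> dict:
    """Offspring presence inside the parent's home range, by parent role and sex.

    An offspring is 'inside' iff any of its capture bushes intersects the
    parent's home-range polygon.  Emits per-offspring counts, per-parent
    averaged percentages, and a Yates-corrected chi-square on the 2x2
    inside/outside x offspring-sex table for each parent role; Fisher's exact
    test is added as a robustness check when any expected cell is below 5.
    """
    dyads: list[InheritanceRecord] = []
    for link in links:
        parent_hr = ranges.get(link.parent_id)
        off = individuals.get(link.offspring_id)
        if parent_hr is None or off is None or not off.records:
            continue
        bushes = off.capture_bushes
        inside = any(habitat.bushes[b].intersects(parent_hr.polygon) for b in bushes)
        dyads.append(
            InheritanceRecord(
                offspring_id=link.offspring_id,
                parent_id=link.parent_id,
                parent_role=link.parent_role,
                offspring_sex=off.sex,
                offspring_capture_bushes=bushes,
                inside_parent_range=inside,
            )
        )
    out: dict = {"n_dyads": len(dyads), "records": dyads, "by_role": {}}
    for role in ("sire", "dam"):
        sub = [d for d in dyads if d.parent_role == role]
        if not sub:
            out["by_role"][role] = {"flag": "not evaluable"}
            continue
        cells = {}
        for sex in ("M", "F"):
            group = [d for d in sub if d.offspring_sex == sex]
            n_in = sum(d.inside_parent_range for d in group)
            cells[sex] = {
                "n": len(group),
                "inside": n_in,
                "outside": len(group) - n_in,
                "pct_inside": 100.0 * n_in / len(group) if group else math.nan,
            }
        # per-parent averaged percentages (alternative tabulation)
        per_parent: dict[str, dict[str, list[bool]]] = {}
        for d in sub:
            per_parent.setdefault(d.parent_id, {}).setdefault(d.offspring_sex, []).append(
                d.inside_parent_range
            )
        avg_pct = {}
        for sex in ("M", "F"):
            vals = [
                100.0 * np.mean(v[sex]) for v in per_parent.values() if v.get(sex)
            ]
            avg_pct[sex] = float(np.mean(vals)) if vals else math.nan
        table = np.array(
            [
                [cells["M"]["inside"], cells["M"]["outside"]],
                [cells["F"]["inside"], cells["F"]["outside"]],
            ]
        )
        entry: dict = {
            "n_parents": len(per_parent),
            "cells": cells,
            "per_parent_mean_pct_inside": avg_pct,
            "table": table.tolist(),
        }
        if table.sum() > 0 and table.sum(axis=1).min() > 0 and table.sum(axis=0).min() >= 0:
            try:
                chi2_stat, chi2_p = yates_chi_square(table)
                entry["yates_chi2"] = chi2_stat
                entry["yates_p"] = chi2_p
                exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
                if (exp < 5).any():
                    odds, fp = stats.fisher_exact(table)
                    entry["fisher_p"] = float(fp)
            except ValueError:
                entry["flag"] = "not evaluable"
        else:
            entry["flag"] = "not evaluable"
        out["by_role"][role] = entry
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class AnalysisReport:
    provenance: dict
    stages: dict = field(default_factory=dict)  # stage -> "ok" | "skipped" | "failed: ..."
    qc: dict | None = None
    h1: dict | None = None
    h2: dict | None = None
    h3: dict | None = None
    h4: dict | None = None
    ibd: dict | None = None
    inbreeding: list | None = None


def run_all(
    records: Sequence[CaptureRecord],
    habitat: HabitatMap,
    genotypes: GenotypeTable | None = None,
    seed: int = 1,
    metric: str = "perimeter",
    n_perm: int = 199,
    hwe_n_mc: int = 2000,
    parentage: ParentageConfig | None = None,
    pedigree_links: Sequence[PedigreeLink] | None = None,
) -> AnalysisReport:
    """Run QC, spatial, kinship/IBD, parentage and H1-H4 on one dataset.

    Stages that cannot run (e.g. no genotype table) are marked skipped and
    downstream dependents skipped too; a precomputed pedigree can be supplied
    to bypass inference.
    """
    rng = np.random.default_rng(seed)
    report = AnalysisReport(
        provenance={"seed": seed, "metric": metric, "n_perm": n_perm, "n_records": len(records)}
    )
    individuals = build_individuals(records)
    sexes = {i: ind.sex for i, ind in individuals.items()}
    ranges = home_ranges(individuals.values(), habitat)
    dmat = bush_distance_matrix(habitat, metric=metric)
    members = cohort_members(records)

    # --- QC ---
    if genotypes is not None:
        try:
            summaries = locus_summaries(genotypes)
            hwe_ps = []
            for s in summaries:
                pairs = [genotypes.get(i, s.locus) for i in genotypes.ids]
                try:
                    p = hwe_exact_test(pairs, n_mc=hwe_n_mc, rng=rng)
                except ValueError:
                    p = math.nan
                s.hwe_p = p
                hwe_ps.append(p)
            valid = [p for p in hwe_ps if not math.isnan(p)]
            flags = holm_bonferroni(valid) if valid else []
            report.qc = {
                "loci": [
                    {
                        "locus": s.locus,
                        "n_alleles": s.n_alleles,
                        "Ho": s.Ho,
                        "He": s.He,
                        "n": s.sample_n,
                        "hwe_p": s.hwe_p,
                    }
                    for s in summaries
                ],
                "mean_Ho": float(np.mean([s.Ho for s in summaries])),
                "mean_He": float(np.mean([s.He for s in summaries])),
                "hwe_holm_rejections": int(np.sum(flags)) if len(flags) else 0,
            }
            report.stages["qc"] = "ok"
        except Exception as exc:  # pragma: no cover - defensive
            report.stages["qc"] = f"failed: {exc}"
    else:
        report.stages["qc"] = "skipped: no genotypes"

    # --- H1 / H2 ---
    try:
        report.h1 = h1_home_range_by_sex(ranges, sexes)
        report.stages["h1"] = "ok"
    except Exception as exc:
        report.stages["h1"] = f"failed: {exc}"
    try:
        report.h2 = {
            s: h2_size_range_correlation(ranges, individuals, s)
            for s in ("all", "male", "female")
        }
        report.stages["h2"] = "ok"
    except Exception as exc:
        report.stages["h2"] = f"failed: {exc}"

    # --- H3 ---
    try:
        h3 = h3_distancing(records, habitat, dmat=dmat, n_perm=n_perm, rng=rng)
        h3 = {k: v for k, v in h3.items() if k != "per_male"} | {
            "n_males_scored": int(len(h3["per_male"])) if "per_male" in h3 else 0
        }
        report.h3 = h3
        report.stages["h3"] = "ok"
    except Exception as exc:
        report.stages["h3"] = f"failed: {exc}"

    # --- kinship / IBD ---
    if genotypes is not None and report.stages.get("qc") == "ok":
        try:
            ibd: dict = {"cohorts": {}}
            for ck, ids in members.items():
                gen_ids = [i for i in ids if i in genotypes.calls]
                if len(gen_ids) < 10:
                    continue
                kin = loiselle_kinship(genotypes, ids=gen_ids)
                pos = {}
                for i in gen_ids:
                    rec = individuals[i].record_at(ck)
                    if rec is not None:
                        pos[i] = rec.bush_id
                kin = kin.submatrix(list(pos))
                gdist = individual_distance_matrix(pos, dmat)
                ac = autocorrelogram(
                    kin, gdist, n_perm=n_perm, rng=rng, cohort_label=ck.label
                )
                kv = kin.values.copy()
                entry = {
                    "n": len(pos),
                    "autocorrelogram": {
                        "bounds": ac.class_bounds,
                        "mean_kinship": ac.mean_kinship,
                        "envelope_lo": ac.envelope_lo,
                        "envelope_hi": ac.envelope_hi,
                        "n_pairs": ac.n_pairs,
                        "significant_classes": ac.significant_classes(),
                    },
                }
                if not np.all(np.isnan(kv)):
                    kin_for_mantel = np.nan_to_num(kv, nan=0.0)
                    np.fill_diagonal(kin_for_mantel, 0.0)
                    if kin_for_mantel.std() > 0 and gdist.values.std() > 0:
                        mres = mantel_test(
                            kin_for_mantel,
                            gdist.values,
                            n_perm=n_perm,
                            rng=rng,
                            alternative="less",
                            description=f"IBD {ck.label}",
                        )
                        entry["mantel"] = {"r": mres.r, "p": mres.p}
                ibd["cohorts"][ck.label] = entry
            report.ibd = ibd
            report.stages["ibd"] = "ok"
        except Exception as exc:
            report.stages["ibd"] = f"failed: {exc}"
    else:
        report.stages["ibd"] = "skipped: no genotypes"

    # --- parentage + H4 + inbreeding ---
    links = list(pedigree_links) if pedigree_links is not None else None
    if links is None and genotypes is not None:
        try:
            cfg = parentage or ParentageConfig()
            seq = sequential_pedigree(
                members,
                sexes,
                genotypes,
                cfg,
                seeds=[int(seed) + r for r in range(cfg.n_replicates)],
            )
            links = seq.consensus
            report.inbreeding = inbreeding_trajectory(seq.step_snapshots)
            report.stages["pedigree"] = "ok"
        except Exception as exc:
            report.stages["pedigree"] = f"failed: {exc}"
            links = None
    elif links is not None:
        report.stages["pedigree"] = "ok (supplied)"
    else:
        report.stages["pedigree"] = "skipped: no genotypes"

    if links is not None:
        try:
            report.h4 = h4_inheritance(links, ranges, individuals, habitat)
            report.h4["records"] = [
                {
                    "offspring_id": d.offspring_id,
                    "parent_id": d.parent_id,
                    "parent_role": d.parent_role,
                    "offspring_sex": d.offspring_sex,
                    "inside": d.inside_parent_range,
                }
                for d in report.h4["records"]
            ]
            report.stages["h4"] = "ok"
        except Exception as exc:
            report.stages["h4"] = f"failed: {exc}"
    else:
        report.stages["h4"] = "skipped: no pedigree"
    return report


def render_markdown(report: AnalysisReport) -> str:
    """Deterministic markdown rendering of an analysis report."""

    def fmt(obj) -> str:
        return json.dumps(obj, indent=1, sort_keys=True, default=str)

    lines = ["# Park analysis report", "", "## Provenance", fmt(report.provenance), ""]
    lines += ["## Stages", fmt(report.stages), ""]
    for name in ("qc", "h1", "h2", "h3", "ibd", "h4", "inbreeding"):
        val = getattr(report, name)
        if val is not None:
            lines += [f"## {name.upper()}", fmt(val), ""]
    return "\n".join(lines)
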