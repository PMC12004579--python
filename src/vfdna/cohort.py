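"""Cohort-level orchestration and statistics.

Runs every per-sample stage (Gαq composition and triage, BSE mutation
calls, power-gated 3p/8q copy-number calls, subtype inference) over a
cohort bundle, then computes the cohort summaries: triage tallies,
concordance with the matched primary tumour, clinicopathological
association tests (Mann-Whitney, Fisher, Spearman) and melanoma-related
survival (Kaplan-Meier with log-rank).

Accounting rules for concordance mirror the per-sample bookkeeping:
BSE concordance counts only samples whose mutation was actually measured
(not-measured variants are excluded from the denominator), and
copy-number concordance counts only samples that passed the 80%
sensitivity gate.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .bse import DETECTED, NOT_DETECTED, NOT_MEASURED, BseAssayResult, dropoff_call, not_measured, targeted_bse_call
from .cna import CopyNumberResult, SnpContext, call_cna, choose_method, cn_classic, cn_snp
from .composition import SampleComposition, Triage, compose_multi_driver, compose_sample
from .ddpcr import VolumePlan, estimate_concentration, merge_wells
from .io import RunConfig, wells_from_frame
from .power import SimScenario, power_gate, sample_power
from .subtype import NOT_INFERABLE, infer_subtype
from .synthetic import CohortBundle

log = logging.getLogger("vfdna")

TRIAGE_ORDER = ["vfDNA-/UM-", "vfDNA+/UM-", "vfDNA+/UM+"]


def _sample_plan(row: pd.Series, base: VolumePlan) -> VolumePlan:
    kwargs = {}
    v = row.get("vitreous_input_ul")
    if v is not None and not pd.isna(v):
        kwargs["vitreous_input_ul"] = float(v)
    else:
        log.warning(
            "sample %s: vitreous input volume missing; assuming %s µL",
            row.get("sample_id"), base.vitreous_input_ul,
        )
    e = row.get("elution_ul")
    if e is not None and not pd.isna(e):
        kwargs["elution_ul"] = float(e)
    return VolumePlan(
        vitreous_input_ul=kwargs.get("vitreous_input_ul", base.vitreous_input_ul),
        elution_ul=kwargs.get("elution_ul", base.elution_ul),
        dna_per_reaction_ul=base.dna_per_reaction_ul,
        reaction_ul=base.reaction_ul,
        droplet_volume_nl=base.droplet_volume_nl,
    )


def _driver_composition(
    sid: str,
    row: pd.Series,
    wells: Dict,
    plan: VolumePlan,
    cfg: RunConfig,
) -> Optional[SampleComposition]:
    pairs = []
    for gene_col, assay_col in (
        ("driver_gene", "driver_assay_id"),
        ("driver2_gene", "driver2_assay_id"),
    ):
        assay = row.get(assay_col)
        if not assay or pd.isna(assay):
            continue
        ws = wells.get((sid, str(assay)))
        if not ws:
            continue
        merged = merge_wells(ws)
        kw = dict(
            plan=plan, ci_level=cfg.ci_level,
            min_droplets=cfg.min_droplets, min_positives=cfg.min_positives,
        )
        mut = estimate_concentration(merged, "mutant", species="mutant", **kw)
        wt = estimate_concentration(merged, "wildtype", species="wildtype", **kw)
        pairs.append((mut, wt))
    if not pairs:
        return None
    return compose_multi_driver(sid, pairs)


def _bse_result(
    sid: str, row: pd.Series, wells: Dict, comp: SampleComposition, cfg: RunConfig
) -> Optional[BseAssayResult]:
    gene = row.get("bse_gene")
    if not gene or pd.isna(gene):
        return None
    if comp.triage != Triage.VFDNA_POS_UM_POS:
        return None  # BSE analysis is only attempted on UM+ samples
    assay_id = row.get("bse_assay_id")
    if not assay_id or pd.isna(assay_id):
        return not_measured(sid, str(gene))
    ws = wells.get((sid, str(assay_id)))
    if not ws:
        return not_measured(sid, str(gene))
    kind = row.get("bse_assay_kind", "targeted_duplex")
    kw = dict(min_droplets=cfg.min_droplets, min_positives=cfg.min_positives)
    if kind == "drop_off":
        return dropoff_call(ws, sid, str(gene), **kw)
    return targeted_bse_call(ws, sid, str(gene), **kw)


def _cna_for_chromosome(
    sid: str,
    chrom: str,
    comp: SampleComposition,
    wells: Dict,
    geno: pd.DataFrame,
    plan: VolumePlan,
    cfg: RunConfig,
    n_sims: int,
    seed,
) -> Tuple[CopyNumberResult, float, bool, str]:
    contexts = [
        SnpContext(
            snp_id=str(r.snp_id),
            chromosome=str(r.chromosome),
            stable_variant=str(getattr(r, "stable_variant", "var2")),
            genotyped_heterozygous=bool(r.heterozygous),
        )
        for r in geno.itertuples()
        if r.sample_id == sid
    ]
    classic_ok = (sid, f"classic_{chrom}") in wells
    method, ctx = choose_method(contexts, chrom, classic_available=classic_ok)
    # the preferred SNP is only usable if its wells were actually measured
    if method == "snp" and ctx is not None and (sid, ctx.snp_id) not in wells:
        if classic_ok:
            method, ctx = "classic", None
        elif comp.total_vfdna == 0:
            pass  # vfDNA-negative samples carry no CNA wells at all
    if method == "no_call":
        return (
            CopyNumberResult(sid, chrom, "none", None, None, None, "no_call",
                             powered=False),
            0.0, False, "none",
        )

    scenario = SimScenario.loss() if chrom == "3p" else SimScenario.gain()
    report = sample_power(
        comp, scenario, method, chrom,
        n_droplets=cfg.droplets_merged, n_sims=n_sims, rng_seed=seed,
        power_threshold=cfg.power_threshold,
    )
    powered = power_gate(report, cfg.power_threshold)

    kw = dict(plan=plan, ci_level=cfg.ci_level,
              min_droplets=cfg.min_droplets, min_positives=cfg.min_positives)
    if method == "snp" and ctx is not None and (sid, ctx.snp_id) in wells:
        merged = merge_wells(wells[(sid, ctx.snp_id)])
        var1 = estimate_concentration(merged, "var1", species="var1", **kw)
        var2 = estimate_concentration(merged, "var2", species="var2", **kw)
        result = cn_snp(var1, var2, sid, chrom, ci_level=cfg.ci_level)
    elif classic_ok:
        merged = merge_wells(wells[(sid, f"classic_{chrom}")])
        target = estimate_concentration(merged, "target", species="target", **kw)
        ref = estimate_concentration(merged, "reference", species="reference", **kw)
        result = cn_classic(target, ref, sid, chrom, ci_level=cfg.ci_level)
    else:
        result = CopyNumberResult(sid, chrom, method, None, None, None,
                                  "no_call", powered=powered)
        return result, report.sensitivity, powered, method
    result = call_cna(result, powered)
    if not powered:
        log.info("sample %s chr%s: underpowered (sensitivity %.2f); no call",
                 sid, chrom, report.sensitivity)
    return result, report.sensitivity, powered, method


def run_pipeline(
    bundle: CohortBundle,
    config: Optional[RunConfig] = None,
    rng_seed: int = 0,
    n_sims: Optional[int] = None,
) -> pd.DataFrame:
    """Run every analysis stage over a cohort bundle.

    Returns one row per sample with composition, BSE, copy-number, power
    and subtype results alongside the pass-through tumour-truth and
    clinicopathological columns of the sample sheet.
    """
    cfg = config or RunConfig()
    n_sims = n_sims or cfg.max_sims
    wells = wells_from_frame(bundle.wells)
    geno = bundle.genotypes
    ss = np.random.SeedSequence(rng_seed)
    records: List[dict] = []

    for idx, row in bundle.samples.iterrows():
        sid = str(row["sample_id"])
        plan = _sample_plan(row, cfg.volume_plan)
        child = ss.spawn(1)[0]
        comp = _driver_composition(sid, row, wells, plan, cfg)
        if comp is None:
            log.warning("sample %s: no driver wells found; skipped", sid)
            continue

        bse_res = _bse_result(sid, row, wells, comp, cfg)
        seeds = child.spawn(2)
        cn3p, sens3p, pow3p, meth3p = _cna_for_chromosome(
            sid, "3p", comp, wells, geno, plan, cfg, n_sims, seeds[0]
        )
        cn8q, sens8q, pow8q, meth8q = _cna_for_chromosome(
            sid, "8q", comp, wells, geno, plan, cfg, n_sims, seeds[1]
        )
        bse_list = [bse_res] if bse_res is not None else []
        sub = infer_subtype(sid, bse_list, [cn3p, cn8q])

        rec = {
            "sample_id": sid,
            "triage": comp.triage.value,
            "total_vfdna": comp.total_vfdna,
            "melanoma_fraction": comp.melanoma_fraction,
            "melanoma_fraction_raw": comp.melanoma_fraction_raw,
            "mut_conc": comp.mut_conc.copies_per_ul_vitreous,
            "wt_conc": comp.wt_conc.copies_per_ul_vitreous,
            "nonmelanoma_conc": comp.nonmelanoma_conc,
            "mut_positives": comp.mut_conc.positive_droplets,
            "wt_positives": comp.wt_conc.positive_droplets,
            "bse_gene": row.get("bse_gene", ""),
            "bse_status": bse_res.status if bse_res else "",
            "bse_mut_droplets": bse_res.mutant_positive_droplets if bse_res else 0,
            "cn3p_method": meth3p,
            "cn3p_value": cn3p.cn_value,
            "cn3p_lo": cn3p.ci99_low,
            "cn3p_hi": cn3p.ci99_high,
            "cn3p_call": cn3p.call,
            "sens3p": sens3p,
            "powered3p": pow3p,
            "cn8q_method": meth8q,
            "cn8q_value": cn8q.cn_value,
            "cn8q_lo": cn8q.ci99_low,
            "cn8q_hi": cn8q.ci99_high,
            "cn8q_call": cn8q.call,
            "sens8q": sens8q,
            "powered8q": pow8q,
            "subtype": sub.subtype,
            "subtype_evidence": "; ".join(sub.evidence),
            "chr8q_status": sub.chr8q_status,
        }
        for col in (
            "tumor_3p", "tumor_3p_clonality", "tumor_8q", "tumor_8q_clonality",
            "tumor_subtype", "prominence_mm", "largest_basal_diameter_mm",
            "bruch_breach", "survival_years", "melanoma_death",
        ):
            if col in row.index:
                rec[col] = row[col]
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# summaries


def cohort_summary(records: pd.DataFrame) -> Dict[str, object]:
    """Triage tallies, concordance accounting and headline medians."""
    n = len(records)
    out: Dict[str, object] = {"n_samples": n}
    for label in TRIAGE_ORDER:
        k = int((records["triage"] == label).sum())
        out[f"triage[{label}]"] = k
        out[f"triage_pct[{label}]"] = round(100.0 * k / n) if n else 0.0

    um = records[records["triage"] == "vfDNA+/UM+"]
    out["n_um_pos"] = len(um)
    if len(um):
        out["median_total_vfdna_um_pos"] = float(um["total_vfdna"].median())
        out["median_fraction_pct_um_pos"] = float(
            (um["melanoma_fraction"].astype(float) * 100).median()
        )

    measured = um[um["bse_status"].isin([DETECTED, NOT_DETECTED])]
    out["bse_measured"] = len(measured)
    out["bse_concordant"] = int((measured["bse_status"] == DETECTED).sum())
    for gene in ("BAP1", "SF3B1", "EIF1AX"):
        g = measured[measured["bse_gene"] == gene]
        out[f"bse[{gene}]"] = f"{int((g['bse_status'] == DETECTED).sum())}/{len(g)}"

    for chrom in ("3p", "8q"):
        pcol, ccol, tcol = f"powered{chrom}", f"cn{chrom}_call", f"tumor_{chrom}"
        powered = um[um[pcol] == True]  # noqa: E712
        out[f"powered_{chrom}"] = len(powered)
        out[f"underpowered_{chrom}"] = int(len(um) - len(powered))
        if tcol in records.columns and len(powered):
            truth_alt = "loss" if chrom == "3p" else "gain"
            match = (
                ((powered[tcol] == truth_alt) & (powered[ccol] == truth_alt))
                | ((powered[tcol] == "normal") & (powered[ccol] == "no_change"))
            )
            out[f"cna_concordant_{chrom}"] = int(match.sum())
            out[f"cna_analysed_{chrom}"] = int(len(powered))

    out["subtype_inferred"] = int((records["subtype"] != NOT_INFERABLE).sum())
    return out


def association_tests(records: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Mann-Whitney, Fisher and Spearman association tests."""
    rows: List[dict] = []
    pos = records[records["triage"] == "vfDNA+/UM+"]
    neg = records[records["triage"] == "vfDNA+/UM-"]

    def mwu(name, a, b):
        a, b = pd.Series(a).dropna(), pd.Series(b).dropna()
        if len(a) < 3 or len(b) < 3:
            rows.append({"test": name, "statistic": np.nan, "p_value": np.nan,
                         "note": "skipped: insufficient group sizes"})
            return
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append({"test": name, "statistic": float(stat), "p_value": float(p),
                     "note": f"n={len(a)} vs n={len(b)}; "
                             f"median {a.median():.1f} vs {b.median():.1f}"})

    if "prominence_mm" in records.columns:
        mwu("prominence UM+ vs UM- (Mann-Whitney U)",
            pos["prominence_mm"], neg["prominence_mm"])
    if "largest_basal_diameter_mm" in records.columns:
        mwu("largest basal diameter UM+ vs UM- (Mann-Whitney U)",
            pos["largest_basal_diameter_mm"], neg["largest_basal_diameter_mm"])
    mwu("non-melanoma vfDNA UM+ vs UM- (Mann-Whitney U)",
        pos["nonmelanoma_conc"], neg["nonmelanoma_conc"])

    def fisher(name, a_bool, b_bool):
        a_bool, b_bool = pd.Series(a_bool).dropna(), pd.Series(b_bool).dropna()
        if len(a_bool) < 3 or len(b_bool) < 3:
            rows.append({"test": name, "statistic": np.nan, "p_value": np.nan,
                         "note": "skipped: insufficient group sizes"})
            return
        table = [
            [int(a_bool.sum()), int((~a_bool.astype(bool)).sum())],
            [int(b_bool.sum()), int((~b_bool.astype(bool)).sum())],
        ]
        odds, p = stats.fisher_exact(table)
        rows.append({"test": name, "statistic": float(odds), "p_value": float(p),
                     "note": f"table={table}"})

    if "bruch_breach" in records.columns:
        fisher("Bruch's membrane breach UM+ vs UM- (Fisher)",
               pos["bruch_breach"], neg["bruch_breach"])
    if "tumor_subtype" in records.columns:
        fisher("poor-prognosis tumour subtype UM+ vs UM- (Fisher)",
               pos["tumor_subtype"] == "poor_prognosis",
               neg["tumor_subtype"] == "poor_prognosis")

    if "prominence_mm" in records.columns and len(pos) >= 3:
        rho, p = stats.spearmanr(pos["mut_conc"], pos["prominence_mm"])
        rows.append({"test": "mutant vfDNA conc vs prominence (Spearman)",
                     "statistic": float(rho), "p_value": float(p),
                     "note": f"n={len(pos)}"})
    return pd.DataFrame(rows, columns=["test", "statistic", "p_value", "note"])


def survival_analysis(
    records: pd.DataFrame,
    group_col: str = "subtype",
    include_not_inferable: bool = False,
) -> Dict[str, object]:
    """Kaplan-Meier per group with median survival and a log-rank test.

    Medians are NaN when the curve never crosses 0.5 (median not
    reached).  Records missing survival fields are excluded listwise.
    """
    df = records.dropna(subset=["survival_years", "melanoma_death", group_col])
    if not include_not_inferable and group_col == "subtype":
        df = df[df[group_col] != NOT_INFERABLE]
    out: Dict[str, object] = {"groups": {}}
    kmf = KaplanMeierFitter()
    for g, grp in df.groupby(group_col):
        kmf.fit(grp["survival_years"], grp["melanoma_death"].astype(bool))
        med = kmf.median_survival_time_
        out["groups"][str(g)] = {
            "n": int(len(grp)),
            "events": int(grp["melanoma_death"].astype(bool).sum()),
            "median_survival_years": (
                float(round(med, 1)) if np.isfinite(med) else None
            ),
        }
    if df[group_col].nunique() >= 2:
        res = multivariate_logrank_test(
            df["survival_years"], df[group_col], df["melanoma_death"].astype(bool)
        )
        out["logrank_statistic"] = float(res.test_statistic)
        out["logrank_p"] = float(res.p_value)
    else:
        out["logrank_p"] = None
        out["note"] = "log-rank skipped: fewer than two groups"
    return out


def reproduce_published_cohort(table_path) -> Dict[str, object]:
    """Deterministic re-analysis of a per-sample clinical summary table.

    The table (TSV) must follow the per-sample record schema produced by
    :func:`run_pipeline` (triage, composition, BSE status, power flags,
    copy-number calls, subtype, tumour truth, survival).  Returns the
    headline cohort numbers: triage tallies, medians, concordance counts,
    power-gate counts, subtype-inferred count, the Spearman correlation
    of mutant concentration with prominence, and the poor-prognosis
    Kaplan-Meier median.
    """
    records = pd.read_csv(table_path, sep="\t")
    summary = cohort_summary(records)
    assoc = association_tests(records)
    surv = survival_analysis(records, group_col="subtype")
    rho_row = assoc[assoc["test"].str.contains("Spearman")]
    summary["spearman_rho_mut_conc_prominence"] = (
        float(rho_row["statistic"].iloc[0]) if len(rho_row) else None
    )
    poor = surv["groups"].get("poor_prognosis", {})
    summary["km_median_poor_prognosis_years"] = poor.get("median_survival_years")
    summary["logrank_p"] = surv.get("logrank_p")
    return summary
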