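"""Synthetic vitreous-fluid cohorts with known ground truth.

Real vitreous-fluid droplet data cannot be redistributed, so every
pipeline stage is exercised on simulated cohorts that emulate the
structure of a per-sample clinical summary table: total vfDNA
concentrations spanning ~1-5,600 haploid copies/µL vitreous,
melanoma-cell fractions from 0 to 95%, a Gαq driver plus optional BSE
mutation and optional (sub)clonal 3p-loss / 8q-gain genotypes, tumour
prominence correlated with the mutant-DNA concentration, and
subtype-dependent survival.  Droplet counts for every assay are drawn
from the same Poisson-occupancy model the power simulator uses, so the
generator doubles as the ground-truth oracle for parameter-recovery
tests.

All distributional choices live in :class:`GeneratorConfig`; the default
instance (also returned by :func:`paperlike_preset`) approximates the
published cohort-level summaries (triage mix 2/18/45 of 65, concentration
ranges and medians, assay availability, heterogeneity rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .assays import AssayDef, AssayRegistry, SNP_PANEL, default_mutation_panel
from .ddpcr import VolumePlan
from .power import SimScenario, expected_lambdas, simulate_experiment

GAQ_DRIVERS = (
    ("GNAQ", "p.Q209P"),
    ("GNAQ", "p.Q209L"),
    ("GNA11", "p.Q209L"),
    ("GNA11", "p.R183H"),
    ("CYSLTR2", "p.L129Q"),
    ("PLCB4", "p.D630N"),
)
GAQ_WEIGHTS = (0.25, 0.20, 0.40, 0.05, 0.05, 0.05)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with study-like defaults."""

    n_samples: int = 65
    # triage mix: no DNA / DNA without tumour DNA / tumour DNA present
    triage_probs: Tuple[float, float, float] = (2 / 65, 18 / 65, 45 / 65)
    # copies/µL vitreous, log-uniform over the printed cohort ranges
    total_conc_range_um_pos: Tuple[float, float] = (2.6, 5585.3)
    total_conc_range_um_neg: Tuple[float, float] = (1.1, 1588.4)
    # melanoma-cell fraction for UM+ samples: log-normal with the cohort
    # median, clipped to the printed range; set fraction_median to None
    # for a plain log-uniform over fraction_range
    fraction_range: Tuple[float, float] = (0.0003, 0.95)
    fraction_median: Optional[float] = 0.155
    fraction_sigma_ln: float = 2.0
    # tumour molecular subtype mix (BAP1-driven / SF3B1 / EIF1AX)
    subtype_probs: Tuple[float, float, float] = (0.55, 0.25, 0.20)
    p_8q_gain: Dict[str, float] = field(
        default_factory=lambda: {"bap1": 0.80, "sf3b1": 0.85, "eif1ax": 0.05}
    )
    p_subclonal: float = 0.10
    subclonal_range: Tuple[float, float] = (0.2, 0.6)
    # probability the tumour's BSE variant has a covering assay
    p_assay: Dict[str, float] = field(
        default_factory=lambda: {"BAP1": 0.20, "SF3B1": 0.80, "EIF1AX": 1.0}
    )
    # probability a heterozygous SNP is available per chromosome
    p_het_snp: Dict[str, float] = field(
        default_factory=lambda: {"3p": 0.90, "8q": 0.65}
    )
    p_two_driver_discordant: float = 0.02
    wells_per_assay: int = 3
    droplets_per_well: int = 15_000
    # prominence (mm) = intercept + slope*log10(mutant conc + 1) + noise
    prominence_intercept: float = 5.5
    prominence_slope: float = 1.8
    prominence_sd: float = 3.0
    diameter_mean_mm: float = 12.0
    diameter_sd_mm: float = 3.0
    p_bruch_breach: float = 0.5
    # melanoma-related survival: exponential, medians in years
    survival_median_poor: float = 5.8
    survival_median_better: float = 25.0
    censor_range_years: Tuple[float, float] = (2.0, 15.0)
    volume_plan: VolumePlan = field(default_factory=VolumePlan)

    def validate(self) -> None:
        bad = []
        for name in ("triage_probs", "subtype_probs"):
            if abs(sum(getattr(self, name)) - 1.0) > 1e-9:
                bad.append(f"{name} must sum to 1")
        for name in ("total_conc_range_um_pos", "total_conc_range_um_neg",
                     "fraction_range", "subclonal_range", "censor_range_years"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                bad.append(f"{name} must satisfy 0 < low <= high")
        if not self.fraction_range[1] <= 0.95:
            bad.append("fraction_range upper bound capped at 0.95")
        if self.n_samples < 1:
            bad.append("n_samples must be >= 1")
        if self.wells_per_assay not in (1, 2, 3):
            bad.append("wells_per_assay must be 1-3")
        if bad:
            raise ValueError("invalid generator config: " + "; ".join(bad))


def paperlike_preset() -> GeneratorConfig:
    """Named preset approximating the published cohort distributions."""
    return GeneratorConfig()


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: truth, droplet counts and sheets."""

    truth: pd.DataFrame
    wells: pd.DataFrame
    samples: pd.DataFrame
    genotypes: pd.DataFrame
    panel: AssayRegistry
    config: GeneratorConfig


def _loguniform(rng, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _sanitize(variant: str) -> str:
    return variant.replace("p.", "").replace(" ", "").replace(".", "")


def _cn_scenario(cn: int, clonality: float) -> SimScenario:
    if cn == 1:
        return SimScenario.loss(clonality)
    if cn == 3:
        return SimScenario.gain(clonality)
    return SimScenario.null()


def _sim_wells(
    rng, lambdas, assay_id, n_wells, droplets, sample_id, rows
) -> None:
    for w in range(n_wells):
        wc = simulate_experiment(
            lambdas, droplets, rng, well_id=f"{sample_id}-{assay_id}-w{w + 1}",
            assay_id=assay_id,
        )
        for ch, k in wc.positives_by_channel.items():
            rows.append(
                {
                    "Well": wc.well_id,
                    "Sample": sample_id,
                    "Assay": assay_id,
                    "Channel": ch,
                    "Positives": k,
                    "AcceptedDroplets": wc.accepted_droplets,
                    "DoublePositives": wc.double_positives,
                }
            )


def _sim_dropoff_wells(
    rng, lam_mut, lam_wt, assay_id, n_wells, droplets, sample_id, rows
) -> None:
    """Drop-off geometry: the reference probe sees every allele, the
    drop-off probe only wild-type alleles, so droplets split into
    (empty, mutant-only, any-wild-type) and the any-wild-type cluster is
    the double-positive one."""
    p_wt = -np.expm1(-lam_wt)
    p_mut_only = -np.expm1(-lam_mut) * np.exp(-lam_wt)
    p_none = 1.0 - p_wt - p_mut_only
    for w in range(n_wells):
        none, mut_only, wt_any = rng.multinomial(
            droplets, [p_none, p_mut_only, p_wt]
        )
        well_id = f"{sample_id}-{assay_id}-w{w + 1}"
        for ch, k in (
            ("reference", int(mut_only + wt_any)),
            ("dropoff", int(wt_any)),
        ):
            rows.append(
                {
                    "Well": well_id,
                    "Sample": sample_id,
                    "Assay": assay_id,
                    "Channel": ch,
                    "Positives": k,
                    "AcceptedDroplets": droplets,
                    "DoublePositives": int(wt_any),
                }
            )


def generate_cohort(
    n: Optional[int] = None,
    config: Optional[GeneratorConfig] = None,
    rng_seed=0,
) -> CohortBundle:
    """Draw a full synthetic cohort with droplet-level data.

    Every registered assay of every sample is simulated as
    ``wells_per_assay`` wells of ``droplets_per_well`` droplets through
    the Poisson-occupancy droplet model, and all ground truth is recorded
    for parameter-recovery testing.
    """
    config = config or paperlike_preset()
    config.validate()
    n = int(n) if n is not None else config.n_samples
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    plan = config.volume_plan
    lam_per_conc = plan.droplet_volume_ul / plan.vitreous_scale

    subtype_names = ("bap1", "sf3b1", "eif1ax")
    bap1_variants: List[str] = []
    truth_rows, sample_rows, geno_rows = [], [], []
    well_rows: List[dict] = []

    for i in range(n):
        sid = f"syn-{i + 1:03d}"
        triage = rng.choice(3, p=config.triage_probs)  # 0 neg/neg, 1 +/-, 2 +/+
        subtype = subtype_names[rng.choice(3, p=config.subtype_probs)]
        driver_idx = rng.choice(len(GAQ_DRIVERS), p=GAQ_WEIGHTS)
        driver_gene, driver_variant = GAQ_DRIVERS[driver_idx]

        if triage == 0:
            total = 0.0
        elif triage == 1:
            total = _loguniform(rng, *config.total_conc_range_um_neg)
        else:
            total = _loguniform(rng, *config.total_conc_range_um_pos)
        if triage != 2:
            frac = 0.0
        elif config.fraction_median is not None:
            frac = float(
                np.clip(
                    np.exp(rng.normal(np.log(config.fraction_median),
                                      config.fraction_sigma_ln)),
                    *config.fraction_range,
                )
            )
        else:
            frac = _loguniform(rng, *config.fraction_range)

        # tumour genotype truth
        if subtype == "bap1":
            cn3p, bse_gene = 1, "BAP1"
        elif subtype == "sf3b1":
            cn3p, bse_gene = 2, "SF3B1"
        else:
            cn3p, bse_gene = 2, "EIF1AX"
        cn8q = 3 if rng.random() < config.p_8q_gain[subtype] else 2

        def _clon():
            if rng.random() < config.p_subclonal:
                return float(rng.uniform(*config.subclonal_range))
            return 1.0

        q3p = _clon() if cn3p != 2 else 1.0
        q8q = _clon() if cn8q != 2 else 1.0

        # BSE variant and assay coverage
        assay_avail = rng.random() < config.p_assay[bse_gene]
        if bse_gene == "EIF1AX":
            exon = 1 if rng.random() < 0.4 else 2
            bse_variant = f"exon {exon}"
            bse_assay_id = f"EIF1AX_ex{exon}_dropoff"
            bse_kind = "drop_off"
        elif bse_gene == "SF3B1":
            if assay_avail:
                bse_variant = "p.R625H" if rng.random() < 0.5 else "p.R625C"
                bse_assay_id = "SF3B1_R625_targeted"
            else:
                bse_variant = "p.K666T"  # non-hotspot, no covering assay
                bse_assay_id = ""
            bse_kind = "targeted_duplex"
        else:  # BAP1: private truncating variants, mostly uncovered
            pos = int(rng.integers(10, 700))
            bse_variant = f"p.L{pos}fs"
            if assay_avail:
                bap1_variants.append(bse_variant)
                bse_assay_id = f"BAP1_custom_{len(bap1_variants)}"
            else:
                bse_assay_id = ""
            bse_kind = "targeted_duplex"

        # heterozygous SNP availability per chromosome
        snp_ids = {}
        for chrom in ("3p", "8q"):
            if rng.random() < config.p_het_snp[chrom]:
                snp = SNP_PANEL[chrom][rng.integers(len(SNP_PANEL[chrom]))]
                snp_ids[chrom] = snp
                geno_rows.append(
                    {
                        "sample_id": sid,
                        "snp_id": snp,
                        "chromosome": chrom,
                        "heterozygous": True,
                        "stable_variant": "var2",
                    }
                )
            else:
                snp_ids[chrom] = ""

        # clinic
        mut_conc = total * frac / 2.0
        prominence = max(
            0.5,
            config.prominence_intercept
            + config.prominence_slope * np.log10(mut_conc + 1.0)
            + rng.normal(0.0, config.prominence_sd),
        )
        diameter = max(5.0, rng.normal(config.diameter_mean_mm, config.diameter_sd_mm))
        bruch = bool(rng.random() < config.p_bruch_breach)
        median = (
            config.survival_median_poor
            if subtype == "bap1"
            else config.survival_median_better
        )
        t_death = float(rng.exponential(median / np.log(2.0)))
        censor = float(rng.uniform(*config.censor_range_years))
        surv_t = min(t_death, censor)
        death = t_death <= censor

        # droplet-level simulation
        lam_total = total * lam_per_conc
        lam_mut = lam_total * frac / 2.0
        lam_wt = lam_total - lam_mut
        droplets = config.droplets_per_well
        n_wells = config.wells_per_assay

        two_driver = (
            triage == 1 and rng.random() < config.p_two_driver_discordant
        )
        driver_assay = f"{driver_gene}_{_sanitize(driver_variant)}"
        _sim_wells(
            rng, {"mutant": lam_mut, "wildtype": lam_wt},
            driver_assay, n_wells, droplets, sid, well_rows,
        )
        driver2_gene = driver2_variant = ""
        driver2_assay = ""
        if two_driver:
            driver2_gene, driver2_variant = ("PLCB4", "p.D630N")
            if (driver2_gene, driver2_variant) == (driver_gene, driver_variant):
                driver2_gene, driver2_variant = ("GNA11", "p.R183H")
            driver2_assay = f"{driver2_gene}_{_sanitize(driver2_variant)}"
            _sim_wells(
                rng, {"mutant": 0.0, "wildtype": lam_wt},
                driver2_assay, n_wells, droplets, sid, well_rows,
            )

        if triage == 2 and assay_avail:
            if bse_kind == "drop_off":
                _sim_dropoff_wells(
                    rng, lam_mut, lam_wt, bse_assay_id, n_wells, droplets,
                    sid, well_rows,
                )
            else:
                _sim_wells(
                    rng, {"mutant": lam_mut, "wildtype": lam_wt},
                    bse_assay_id, n_wells, droplets, sid, well_rows,
                )

        if total > 0:
            for chrom, cn, q in (("3p", cn3p, q3p), ("8q", cn8q, q8q)):
                scen = _cn_scenario(cn, q)
                lams = expected_lambdas(lam_total, frac, scen, "classic")
                _sim_wells(
                    rng, lams, f"classic_{chrom}", n_wells, droplets, sid,
                    well_rows,
                )
                if snp_ids[chrom]:
                    lams = expected_lambdas(lam_total, frac, scen, "snp")
                    _sim_wells(
                        rng, lams, snp_ids[chrom], n_wells, droplets, sid,
                        well_rows,
                    )

        triage_label = ("vfDNA-/UM-", "vfDNA+/UM-", "vfDNA+/UM+")[triage]
        subtype_dichotomy = (
            "poor_prognosis" if subtype == "bap1" else "better_prognosis"
        )
        truth_rows.append(
            {
                "sample_id": sid,
                "triage_true": triage_label,
                "total_conc_true": total,
                "fraction_true": frac,
                "mut_conc_true": mut_conc,
                "subtype_true": subtype_dichotomy,
                "subtype_class": subtype,
                "cn3p_true": cn3p,
                "clonality_3p": q3p,
                "cn8q_true": cn8q,
                "clonality_8q": q8q,
                "bse_gene": bse_gene,
                "bse_variant": bse_variant,
                "bse_assay_available": assay_avail,
            }
        )
        sample_rows.append(
            {
                "sample_id": sid,
                "driver_gene": driver_gene,
                "driver_variant": driver_variant,
                "driver_assay_id": driver_assay,
                "driver2_gene": driver2_gene,
                "driver2_variant": driver2_variant,
                "driver2_assay_id": driver2_assay,
                "bse_gene": bse_gene,
                "bse_variant": bse_variant,
                "bse_assay_id": bse_assay_id,
                "bse_assay_kind": bse_kind,
                "vitreous_input_ul": plan.vitreous_input_ul,
                "elution_ul": plan.elution_ul,
                "tumor_3p": "loss" if cn3p == 1 else "normal",
                "tumor_3p_clonality": q3p,
                "tumor_8q": "gain" if cn8q == 3 else "normal",
                "tumor_8q_clonality": q8q,
                "tumor_subtype": subtype_dichotomy,
                "prominence_mm": round(float(prominence), 2),
                "largest_basal_diameter_mm": round(float(diameter), 2),
                "bruch_breach": bruch,
                "survival_years": round(surv_t, 3),
                "melanoma_death": death,
            }
        )

    panel = default_mutation_panel(bap1_variants)
    return CohortBundle(
        truth=pd.DataFrame(truth_rows),
        wells=pd.DataFrame(well_rows),
        samples=pd.DataFrame(sample_rows),
        genotypes=pd.DataFrame(
            geno_rows,
            columns=["sample_id", "snp_id", "chromosome", "heterozygous",
                     "stable_variant"],
        ),
        panel=panel,
        config=config,
    )
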