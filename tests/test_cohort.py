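"""Cohort orchestration: pipeline records, concordance accounting,
association tests and survival analysis."""

import numpy as np
import pandas as pd
import pytest

from vfdna.cohort import (
    association_tests,
    cohort_summary,
    run_pipeline,
    survival_analysis,
)
from vfdna.io import RunConfig


class TestPipeline:
    def test_one_record_per_sample(self, small_bundle, small_records):
        assert len(small_records) == len(small_bundle.samples)
        assert small_records["sample_id"].is_unique

    def test_triage_matches_truth_mostly(self, small_bundle, small_records):
        """Detectability-based triage recovers the generating class for
        nearly all samples (borderline low-fraction samples may flip)."""
        df = small_records.merge(small_bundle.truth, on="sample_id")
        agree = (df["triage"] == df["triage_true"]).mean()
        assert agree >= 0.85

    def test_underpowered_samples_never_called(self, small_records):
        for chrom in ("3p", "8q"):
            gated = small_records[~small_records[f"powered{chrom}"].astype(bool)]
            assert (gated[f"cn{chrom}_call"] == "no_call").all()

    def test_deterministic_given_seed(self, small_bundle, small_records):
        again = run_pipeline(small_bundle, RunConfig(), rng_seed=7, n_sims=200)
        pd.testing.assert_frame_equal(small_records, again)


def _records_for_accounting():
    """Hand-built records exercising the concordance denominators."""
    base = {
        "total_vfdna": 100.0, "melanoma_fraction": 0.2,
        "melanoma_fraction_raw": 0.2, "mut_conc": 10.0, "wt_conc": 90.0,
        "nonmelanoma_conc": 80.0, "mut_positives": 50, "wt_positives": 450,
        "cn3p_method": "snp", "cn3p_value": 1.8, "cn3p_lo": 1.6,
        "cn3p_hi": 1.95, "sens3p": 0.9,
        "cn8q_method": "snp", "cn8q_value": 2.0, "cn8q_lo": 1.9,
        "cn8q_hi": 2.1, "sens8q": 0.9,
        "subtype_evidence": "", "chr8q_status": "no_call",
        "bse_mut_droplets": 0,
    }
    rows = [
        # measured & concordant BSE; powered concordant 3p loss
        dict(base, sample_id="s1", triage="vfDNA+/UM+", bse_gene="SF3B1",
             bse_status="detected", powered3p=True, cn3p_call="loss",
             tumor_3p="loss", powered8q=False, cn8q_call="no_call",
             tumor_8q="gain", subtype="poor_prognosis"),
        # not measured: excluded from BSE denominator; underpowered 3p
        dict(base, sample_id="s2", triage="vfDNA+/UM+", bse_gene="BAP1",
             bse_status="not_measured", powered3p=False, cn3p_call="no_call",
             tumor_3p="loss", powered8q=True, cn8q_call="gain",
             tumor_8q="gain", subtype="not_inferable"),
        # measured, discordant BSE; powered discordant 3p
        dict(base, sample_id="s3", triage="vfDNA+/UM+", bse_gene="SF3B1",
             bse_status="not_detected", powered3p=True, cn3p_call="no_change",
             tumor_3p="loss", powered8q=True, cn8q_call="no_change",
             tumor_8q="normal", subtype="better_prognosis"),
        # UM- sample: outside every concordance denominator
        dict(base, sample_id="s4", triage="vfDNA+/UM-", bse_gene="BAP1",
             bse_status="", powered3p=False, cn3p_call="no_call",
             tumor_3p="loss", powered8q=False, cn8q_call="no_call",
             tumor_8q="normal", subtype="not_inferable"),
    ]
    return pd.DataFrame(rows)


class TestSummaryAccounting:
    def test_bse_denominator_excludes_not_measured(self):
        s = cohort_summary(_records_for_accounting())
        assert s["bse_measured"] == 2
        assert s["bse_concordant"] == 1
        assert s["bse[SF3B1]"] == "1/2"
        assert s["bse[BAP1]"] == "0/0"

    def test_cna_concordance_counts_only_powered(self):
        s = cohort_summary(_records_for_accounting())
        assert s["powered_3p"] == 2 and s["underpowered_3p"] == 1
        assert s["cna_concordant_3p"] == 1  # s1 yes, s3 no, s2 not counted
        assert s["powered_8q"] == 2
        assert s["cna_concordant_8q"] == 2  # s2 gain/gain, s3 normal/no_change

    def test_triage_tallies(self):
        s = cohort_summary(_records_for_accounting())
        assert s["triage[vfDNA+/UM+]"] == 3
        assert s["triage[vfDNA+/UM-]"] == 1
        assert s["subtype_inferred"] == 2

    def test_percentages_recompute_from_counts(self, small_records):
        s = cohort_summary(small_records)
        n = s["n_samples"]
        for label in ("vfDNA-/UM-", "vfDNA+/UM-", "vfDNA+/UM+"):
            assert s[f"triage_pct[{label}]"] == round(100 * s[f"triage[{label}]"] / n)


class TestAssociations:
    def test_identical_groups_give_p_one(self):
        df = _records_for_accounting()
        df = pd.concat([df] * 3, ignore_index=True)
        df["sample_id"] = [f"s{i}" for i in range(len(df))]
        df["prominence_mm"] = 5.0
        df["largest_basal_diameter_mm"] = 10.0
        df["bruch_breach"] = True
        out = association_tests(df)
        prom = out[out["test"].str.startswith("prominence")]
        assert prom["p_value"].iloc[0] == pytest.approx(1.0)

    def test_monotone_pairs_give_spearman_one(self):
        df = _records_for_accounting()
        df = pd.concat([df] * 3, ignore_index=True)
        df = df[df["triage"] == "vfDNA+/UM+"].reset_index(drop=True)
        df["mut_conc"] = np.arange(len(df), dtype=float)
        df["prominence_mm"] = df["mut_conc"] ** 2 + 1  # monotone transform
        out = association_tests(df)
        rho = out[out["test"].str.contains("Spearman")]["statistic"].iloc[0]
        assert rho == pytest.approx(1.0)

    def test_small_groups_skipped_with_note(self):
        df = _records_for_accounting()
        df["prominence_mm"] = 5.0
        out = association_tests(df)
        prom = out[out["test"].str.startswith("prominence")]
        assert "skipped" in prom["note"].iloc[0]
        assert np.isnan(prom["p_value"].iloc[0])


class TestSurvival:
    @staticmethod
    def _surv_df(times, events, groups):
        return pd.DataFrame({
            "survival_years": times,
            "melanoma_death": events,
            "subtype": groups,
        })

    def test_no_events_median_undefined(self):
        df = self._surv_df([1, 2, 3, 4], [False] * 4,
                           ["poor_prognosis"] * 2 + ["better_prognosis"] * 2)
        out = survival_analysis(df)
        for g in out["groups"].values():
            assert g["median_survival_years"] is None

    def test_point_mass_median(self):
        df = self._surv_df([5.8] * 5 + [9.0] * 5, [True] * 10,
                           ["poor_prognosis"] * 5 + ["better_prognosis"] * 5)
        out = survival_analysis(df)
        assert out["groups"]["poor_prognosis"]["median_survival_years"] == 5.8
        assert out["logrank_p"] < 0.05

    def test_single_group_skips_logrank(self):
        df = self._surv_df([1, 2, 3], [True, True, False], ["poor_prognosis"] * 3)
        out = survival_analysis(df)
        assert out["logrank_p"] is None
        assert "skipped" in out["note"]

    def test_subtype_dependent_survival_detected(self, rng):
        """Exponential survival with a 4x hazard ratio: the log-rank test
        flags the difference in most replicate cohorts (power check)."""
        hits = 0
        n_sims = 60
        for _ in range(n_sims):
            n = 30
            grp = np.r_[np.zeros(n // 2), np.ones(n // 2)]
            scale = np.where(grp == 0, 5.8, 23.2) / np.log(2)
            t_death = rng.exponential(scale)
            censor = rng.uniform(2, 15, size=n)
            df = self._surv_df(
                np.minimum(t_death, censor), t_death <= censor,
                np.where(grp == 0, "poor_prognosis", "better_prognosis"),
            )
            out = survival_analysis(df)
            hits += out["logrank_p"] < 0.05
        assert hits / n_sims >= 0.6

    def test_missing_survival_excluded_listwise(self):
        df = self._surv_df([1, 2, np.nan, 4], [True, True, True, False],
                           ["poor_prognosis"] * 2 + ["better_prognosis"] * 2)
        out = survival_analysis(df)
        assert out["groups"]["better_prognosis"]["n"] == 1
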