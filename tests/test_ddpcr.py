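"""Partition statistics: Poisson MLE, merging, QC and interval coverage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vfdna.ddpcr import (
    ConcentrationEstimate,
    VolumePlan,
    WellCounts,
    estimate_concentration,
    merge_wells,
    qc_well,
)


def well(k, n=15_000, assay="a", well_id="w", channel="mutant"):
    return WellCounts(well_id, assay, n, {channel: k})


class TestEstimate:
    @pytest.mark.parametrize(
        "k, n, lam_expected, detectable",
        [
            (0, 15_000, 0.0, False),
            (round(15_000 * (1 - math.exp(-1))), 15_000, 1.0, True),
            (1500, 15_000, -math.log(0.9), True),
        ],
    )
    def test_poisson_inversion(self, k, n, lam_expected, detectable):
        est = estimate_concentration(well(k, n), "mutant")
        assert est.lambda_hat == pytest.approx(lam_expected, abs=2e-4)
        assert est.detectable is detectable

    def test_concentration_units(self):
        """k=1500 of 15,000 droplets at 0.85 nL is ~123.95 copies/µL
        reaction; the vitreous-scale factor is applied exactly."""
        plan = VolumePlan()
        est = estimate_concentration(well(1500), "mutant", plan=plan)
        assert est.copies_per_ul_reaction == pytest.approx(123.9535, abs=1e-3)
        assert est.copies_per_ul_vitreous / est.copies_per_ul_reaction == (
            pytest.approx(plan.vitreous_scale, rel=1e-12)
        )

    def test_ci_brackets_point_estimate(self):
        est = estimate_concentration(well(37), "mutant")
        assert est.ci_low <= est.copies_per_ul_reaction <= est.ci_high

    def test_saturation_flagged(self):
        with pytest.warns(RuntimeWarning, match="saturated"):
            est = estimate_concentration(well(15_000), "mutant")
        assert est.saturated
        assert math.isfinite(est.lambda_hat)

    def test_qc_fail_still_estimates(self):
        est = estimate_concentration(well(50, n=5000), "mutant")
        assert not est.qc_pass and not est.detectable
        assert "qc_fail" in est.flags
        assert est.lambda_hat > 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            WellCounts("w", "a", 100, {"mutant": 101})
        with pytest.raises(ValueError):
            WellCounts("w", "a", 0, {"mutant": 0})


class TestQc:
    @pytest.mark.parametrize("n, ok", [(10_000, True), (9_999, False), (45_000, True)])
    def test_boundary_inclusive(self, n, ok):
        assert qc_well(well(0, n)) is ok


class TestMerge:
    def test_single_well_identity(self):
        w = well(7)
        m = merge_wells([w])
        assert m.accepted_droplets == w.accepted_droplets
        assert m.positives_by_channel == w.positives_by_channel

    def test_three_experiments_merge_to_45000(self):
        wells = [well(1, well_id=f"w{i}") for i in range(3)]
        m = merge_wells(wells)
        assert m.accepted_droplets == 45_000
        assert m.positives_by_channel["mutant"] == 3

    def test_merge_rescues_detectability(self):
        """Three wells of one positive each: none detectable alone, the
        merge is (>= 3-droplet rule applied after pooling)."""
        singles = [
            estimate_concentration(well(1, well_id=f"w{i}"), "mutant")
            for i in range(3)
        ]
        assert not any(e.detectable for e in singles)
        merged = estimate_concentration(
            merge_wells([well(1, well_id=f"w{i}") for i in range(3)]), "mutant"
        )
        assert merged.detectable

    def test_mixed_assays_rejected(self):
        with pytest.raises(ValueError, match="different assays"):
            merge_wells([well(1, assay="a"), well(1, assay="b")])

    @given(
        ks=st.lists(st.integers(0, 500), min_size=2, max_size=4),
        order=st.randoms(use_true_random=False),
    )
    @settings(max_examples=40, deadline=None)
    def test_merge_order_invariant(self, ks, order):
        wells = [well(k, n=2000, well_id=f"w{i}") for i, k in enumerate(ks)]
        shuffled = list(wells)
        order.shuffle(shuffled)
        a, b = merge_wells(wells), merge_wells(shuffled)
        assert a.accepted_droplets == b.accepted_droplets
        assert a.positives_by_channel == b.positives_by_channel


@given(n=st.integers(100, 50_000), k=st.integers(0, 99))
@settings(max_examples=60, deadline=None)
def test_lambda_strictly_increasing_in_k(n, k):
    k = min(k, n - 1)
    lo = estimate_concentration(well(k, n), "mutant").lambda_hat
    hi = estimate_concentration(well(k + 1, n), "mutant").lambda_hat
    assert hi > lo
    assert estimate_concentration(well(0, n), "mutant").lambda_hat == 0.0


def brute_force_pooled_mle(wells, lo=1e-8, hi=10.0, rounds=6, grid=4001):
    """Independent oracle: grid search over the pooled log-likelihood."""

    def nll(lam):
        total = 0.0
        for w in wells:
            k = w.positives_by_channel["mutant"]
            n = w.accepted_droplets
            p = -math.expm1(-lam)
            if k > 0:
                total -= k * math.log(p)
            total += (n - k) * lam
        return total

    for _ in range(rounds):
        xs = np.linspace(lo, hi, grid)
        vals = [nll(x) for x in xs]
        i = int(np.argmin(vals))
        lo, hi = xs[max(0, i - 1)], xs[min(grid - 1, i + 1)]
    return 0.5 * (lo + hi)


def test_merged_estimate_matches_joint_likelihood(rng):
    """Estimating on pooled counts equals the joint-likelihood MLE."""
    for _ in range(10):
        wells = []
        for i in range(int(rng.integers(1, 4))):
            n = int(rng.integers(200, 3000))
            k = int(rng.integers(1, n // 2))
            wells.append(well(k, n, well_id=f"w{i}"))
        est = estimate_concentration(merge_wells(wells), "mutant")
        oracle = brute_force_pooled_mle(wells)
        assert est.lambda_hat == pytest.approx(oracle, rel=1e-6)


@pytest.mark.parametrize("lam", [0.01, 0.1, 1.0])
def test_ci99_coverage(lam, rng):
    """The 99% interval should contain the true concentration in at
    least 97.5% of 2,000 simulated wells."""
    n = 15_000
    plan = VolumePlan()
    true_conc = lam / plan.droplet_volume_ul
    ks = rng.binomial(n, 1 - math.exp(-lam), size=2000)
    hit = 0
    for k in ks:
        est = estimate_concentration(well(int(k), n), "mutant", plan=plan)
        hit += est.ci_low <= true_conc <= est.ci_high
    assert hit / 2000 >= 0.975
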