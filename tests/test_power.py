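"""In-silico power simulation: expected occupancies, droplet model,
sensitivity estimates and the 80% gate."""

import numpy as np
import pytest

from vfdna.power import (
    DROPLETS_MERGED,
    DROPLETS_SINGLE,
    PowerReport,
    SimScenario,
    expected_lambdas,
    power_gate,
    sensitivity,
    simulate_cn_calls,
    simulate_experiment,
)


class TestScenario:
    def test_copy_numbers_fixed_per_scenario(self):
        assert SimScenario.loss().tumour_copy_number == 1
        assert SimScenario.gain().tumour_copy_number == 3
        with pytest.raises(ValueError):
            SimScenario("loss", 2)
        with pytest.raises(ValueError):
            SimScenario("gain", 3, clonality=0.0)

    def test_effective_cn_attenuated_by_clonality(self):
        assert SimScenario.loss(0.4).effective_copy_number == pytest.approx(1.6)
        assert SimScenario.gain(0.5).effective_copy_number == pytest.approx(2.5)


class TestExpectedLambdas:
    def test_no_tumour_dna_implies_diploid(self):
        for method in ("classic", "snp"):
            lams = expected_lambdas(0.4, 0.0, SimScenario.loss(), method)
            if method == "classic":
                assert lams["target"] == pytest.approx(lams["reference"])
            else:
                assert lams["var1"] == pytest.approx(lams["var2"])

    def test_pure_tumour_full_loss_removes_var1(self):
        lams = expected_lambdas(0.4, 1.0, SimScenario.loss(), "snp")
        assert lams["var1"] == 0.0
        assert lams["var2"] == pytest.approx(0.2)

    @pytest.mark.parametrize("method", ["classic", "snp"])
    def test_half_fraction_gain_implies_cn_2_5(self, method):
        """f=0.5 clonal gain: implied copy number 2 + f = 2.5 for both
        estimator parameterisations."""
        lams = expected_lambdas(0.4, 0.5, SimScenario.gain(), method)
        if method == "classic":
            implied = 2 * lams["target"] / lams["reference"]
        else:
            implied = 1 + lams["var1"] / lams["var2"]
        assert implied == pytest.approx(2.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_lambdas(-1.0, 0.5, SimScenario.loss(), "snp")
        with pytest.raises(ValueError):
            expected_lambdas(1.0, 1.5, SimScenario.loss(), "snp")


class TestDropletModel:
    def test_zero_lambda_all_negative(self):
        wc = simulate_experiment({"a": 0.0, "b": 0.0}, 15_000, 1)
        assert all(v == 0 for v in wc.positives_by_channel.values())
        assert wc.double_positives == 0

    def test_occupancy_matches_poisson_expectation(self, rng):
        """lambda = 1 gives ~(1 - e^-1) positive droplets, within 4 SD."""
        n = 15_000
        wc = simulate_experiment({"a": 1.0, "b": 0.01}, n, rng)
        p = 1 - np.exp(-1)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(wc.positives_by_channel["a"] - n * p) < 4 * sd

    def test_double_positives_consistent(self, rng):
        wc = simulate_experiment({"a": 0.5, "b": 0.3}, 10_000, rng)
        assert wc.double_positives <= min(wc.positives_by_channel.values())

    def test_fixed_seed_reproducible(self):
        a = simulate_experiment({"a": 0.2, "b": 0.1}, 15_000, 42)
        b = simulate_experiment({"a": 0.2, "b": 0.1}, 15_000, 42)
        assert a.positives_by_channel == b.positives_by_channel
        assert a.double_positives == b.double_positives


class TestSensitivity:
    def test_null_scenario_false_positive_rate(self):
        """At copy number 2 the detection rate is the type-I error of the
        nominal 99% interval."""
        rep = sensitivity(0.5, 0.5, SimScenario.null(), "snp",
                          n_droplets=DROPLETS_MERGED, n_sims=1000, rng_seed=3)
        assert rep.sensitivity <= 0.015

    def test_asymptotic_regime_near_one(self):
        rep = sensitivity(2.0, 0.9, SimScenario.loss(), "snp",
                          n_droplets=DROPLETS_MERGED, n_sims=500, rng_seed=3)
        assert rep.sensitivity >= 0.99

    def test_scarce_sample_underpowered(self):
        """Tiny melanoma fraction at low input: even 45,000 droplets stay
        below the 80% gate."""
        rep = sensitivity(0.01, 0.005, SimScenario.loss(), "snp",
                          n_droplets=DROPLETS_MERGED, n_sims=500, rng_seed=3)
        assert rep.sensitivity < 0.80
        assert not rep.powered

    def test_zero_dna_gives_zero_sensitivity(self):
        rep = sensitivity(0.0, 0.5, SimScenario.loss(), "snp", rng_seed=0)
        assert rep.sensitivity == 0.0 and not rep.powered and rep.n_sims == 0

    def test_single_experiment_not_more_sensitive_than_merge(self):
        single = sensitivity(0.1, 0.25, SimScenario.loss(), "snp",
                             n_droplets=DROPLETS_SINGLE, n_sims=500, rng_seed=5)
        merged = sensitivity(0.1, 0.25, SimScenario.loss(), "snp",
                             n_droplets=DROPLETS_MERGED, n_sims=500, rng_seed=5)
        se = np.sqrt(0.25 / 500)
        assert single.sensitivity <= merged.sensitivity + 3 * se

    def test_monotone_in_fraction(self):
        vals = [
            sensitivity(0.2, f, SimScenario.loss(), "snp",
                        n_droplets=DROPLETS_MERGED, n_sims=400,
                        rng_seed=9).sensitivity
            for f in (0.05, 0.15, 0.4)
        ]
        se = np.sqrt(0.25 / 400)
        assert vals[0] <= vals[1] + 3 * se <= vals[2] + 6 * se

    def test_reports_reproducible(self):
        kw = dict(n_droplets=DROPLETS_MERGED, n_sims=300, rng_seed=11,
                  sample_id="s", chromosome="3p")
        a = sensitivity(0.1, 0.3, SimScenario.loss(), "snp", **kw)
        b = sensitivity(0.1, 0.3, SimScenario.loss(), "snp", **kw)
        assert a == b

    def test_sims_capped_at_1000(self):
        with pytest.raises(ValueError):
            sensitivity(0.1, 0.3, SimScenario.loss(), "snp", n_sims=2000)


class TestGate:
    @pytest.mark.parametrize("s, powered", [(0.79, False), (0.80, True), (0.999, True)])
    def test_boundary(self, s, powered):
        rep = PowerReport("s", "3p", "snp", "loss", DROPLETS_MERGED, 1000, s, s >= 0.8)
        assert power_gate(rep) is powered


def test_direction_match_required(rng):
    """A loss scenario is only 'detected' by loss calls: with a strong
    gain signal, loss-direction detections are absent."""
    lams = expected_lambdas(1.0, 0.8, SimScenario.gain(), "snp")
    calls = simulate_cn_calls(lams, "snp", DROPLETS_MERGED, 300, rng)
    assert (calls == "gain").mean() > 0.9
    assert (calls == "loss").sum() == 0
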