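"""In-silico digital PCR simulation and per-sample power prediction.

Whether a copy-number alteration is detectable in a vitreous-fluid sample
depends on how much DNA the sample holds and what fraction of it is
melanoma-cell derived.  Before spending precious material on copy-number
wells, the pipeline simulates the planned experiment: droplet counts are
drawn from the Poisson-occupancy model at the concentrations implied by
the sample's own Gαq mutant/wild-type measurements, assuming a clonal
loss (copy number 1) or gain (copy number 3) in the melanoma-cell
population.  The sensitivity is the fraction of simulated experiments in
which the 99%-CI caller detects the alteration in the correct direction.
A configuration is *underpowered* when sensitivity stays below 80% even
at 45,000 droplets (a merge of three 15,000-droplet experiments); such
samples receive no copy-number call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .cna import classify_cn, ratio_interval
from .composition import SampleComposition
from .ddpcr import VolumePlan, WellCounts

DROPLETS_SINGLE = 15_000
DROPLETS_MERGED = 45_000
DEFAULT_N_SIMS = 1_000
POWER_THRESHOLD = 0.80


@dataclass(frozen=True)
class SimScenario:
    """A copy-number scenario to probe: loss (1 copy), gain (3 copies) or
    null (2 copies), present in ``clonality`` of the tumour cells."""

    scenario: str  # "loss" | "gain" | "null"
    tumour_copy_number: float
    clonality: float = 1.0

    _EXPECTED_CN = {"loss": 1, "gain": 3, "null": 2}

    def __post_init__(self) -> None:
        if self.scenario not in self._EXPECTED_CN:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.tumour_copy_number != self._EXPECTED_CN[self.scenario]:
            raise ValueError(
                f"{self.scenario} scenario implies tumour copy number "
                f"{self._EXPECTED_CN[self.scenario]}, got {self.tumour_copy_number}"
            )
        if not 0 < self.clonality <= 1:
            raise ValueError("clonality must be in (0, 1]")

    @classmethod
    def loss(cls, clonality: float = 1.0) -> "SimScenario":
        return cls("loss", 1, clonality)

    @classmethod
    def gain(cls, clonality: float = 1.0) -> "SimScenario":
        return cls("gain", 3, clonality)

    @classmethod
    def null(cls) -> "SimScenario":
        return cls("null", 2, 1.0)

    @property
    def effective_copy_number(self) -> float:
        """Bulk tumour-cell copy number, attenuated by subclonality."""
        return 2.0 + self.clonality * (self.tumour_copy_number - 2.0)


@dataclass(frozen=True)
class PowerReport:
    sample_id: str
    chromosome: str
    method: str
    scenario: str
    droplets_tested: int
    n_sims: int
    sensitivity: float
    powered: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")


def expected_lambdas(
    total_lambda: float,
    fraction: float,
    scenario: SimScenario,
    method: str,
) -> Dict[str, float]:
    """Per-species mean molecules per droplet for a simulated experiment.

    ``total_lambda`` is the total vfDNA concentration expressed as mean
    haploid genome-equivalents (Gαq mutant + wild-type alleles) per
    droplet; ``fraction`` the melanoma-cell-derived share.  With
    c_eff = 2 + clonality*(tumour_cn - 2):

    * classic: reference carries 2 copies/genome in every cell
      (lambda_ref = T) while the target averages (1-f)*2 + f*c_eff
      copies/genome;
    * SNP: the stable allele var2 is haploid in every cell
      (lambda_var2 = T/2) while var1 is haploid in normal cells and
      (c_eff - 1)-ploid in altered tumour cells.
    """
    if total_lambda < 0:
        raise ValueError("total_lambda must be >= 0")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    c_eff = scenario.effective_copy_number
    if method == "classic":
        return {
            "target": total_lambda * ((1 - fraction) * 2 + fraction * c_eff) / 2.0,
            "reference": total_lambda,
        }
    if method == "snp":
        half = total_lambda / 2.0
        return {
            "var1": half * ((1 - fraction) + fraction * (c_eff - 1)),
            "var2": half,
        }
    raise ValueError(f"unknown method {method!r}")


def simulate_experiment(
    lambdas: Dict[str, float],
    n_droplets: int,
    rng,
    well_id: str = "sim",
    assay_id: str = "sim",
) -> WellCounts:
    """Draw one in-silico well: independent Poisson occupancy per species,
    a channel positive iff it received >= 1 molecule of its species.

    For two-species assays the four droplet clusters (empty / single
    positives / double positive) are drawn jointly so the
    double-positive count is consistent with the marginals.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    for sp, lam in lambdas.items():
        if lam < 0:
            raise ValueError(f"negative lambda for species {sp!r}")
    species = list(lambdas)
    if len(species) == 2:
        s1, s2 = species
        p1 = -np.expm1(-lambdas[s1])
        p2 = -np.expm1(-lambdas[s2])
        probs = [(1 - p1) * (1 - p2), p1 * (1 - p2), (1 - p1) * p2, p1 * p2]
        none, only1, only2, both = rng.multinomial(n_droplets, probs)
        positives = {s1: int(only1 + both), s2: int(only2 + both)}
        doubles: Optional[int] = int(both)
    else:
        positives = {
            sp: int(rng.binomial(n_droplets, -np.expm1(-lam)))
            for sp, lam in lambdas.items()
        }
        doubles = None
    return WellCounts(
        well_id=well_id,
        assay_id=assay_id,
        accepted_droplets=n_droplets,
        positives_by_channel=positives,
        double_positives=doubles,
    )


def _lambda_draws(lam: float, n_droplets: int, n_sims: int, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised Poisson-MLE draws: (lambda_hat, se_lambda) per replicate."""
    p = -np.expm1(-lam)
    k = rng.binomial(n_droplets, p, size=n_sims).astype(float)
    k[k == n_droplets] = n_droplets - 0.5  # saturation continuity correction
    phat = k / n_droplets
    lam_hat = -np.log1p(-phat)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(
            (phat > 0) & (phat < 1),
            np.sqrt(phat / ((1.0 - phat) * n_droplets)),
            0.0,
        )
    return lam_hat, se


def simulate_cn_calls(
    lambdas: Dict[str, float],
    method: str,
    n_droplets: int,
    n_sims: int,
    rng,
    ci_level: float = 0.99,
) -> np.ndarray:
    """Array of copy-number call labels over ``n_sims`` simulated
    experiments, using the same ratio-CI machinery as the real caller."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if method == "classic":
        num_lam, den_lam = lambdas["target"], lambdas["reference"]
        scale, offset = 2.0, 0.0
    else:
        num_lam, den_lam = lambdas["var1"], lambdas["var2"]
        scale, offset = 1.0, 1.0
    lam1, se1 = _lambda_draws(num_lam, n_droplets, n_sims, rng)
    lam2, se2 = _lambda_draws(den_lam, n_droplets, n_sims, rng)
    floor_lam = -np.log1p(-0.5 / n_droplets)
    p0 = 0.5 / n_droplets
    floor_se = np.sqrt(p0 / ((1 - p0) * n_droplets))
    r, lo, hi = ratio_interval(
        lam1, se1, lam2, se2, ci_level=ci_level,
        lam_floor=floor_lam, se_floor=floor_se,
    )
    cn = offset + scale * r
    return classify_cn(cn, offset + scale * lo, offset + scale * hi)


def sensitivity(
    total_lambda: float,
    fraction: float,
    scenario: SimScenario,
    method: str,
    n_droplets: int = DROPLETS_MERGED,
    n_sims: int = DEFAULT_N_SIMS,
    rng_seed=None,
    sample_id: str = "",
    chromosome: str = "",
    ci_level: float = 0.99,
    early_stop: bool = False,
    power_threshold: float = POWER_THRESHOLD,
) -> PowerReport:
    """Fraction of simulated experiments detecting the scenario's
    alteration in the correct direction.

    For the null scenario the returned value is the false-positive rate
    (any loss or gain call).  With ``early_stop`` the simulation runs in
    batches and stops once the Wilson 99% bound on the sensitivity lies
    decisively on one side of the power threshold.
    """
    if n_sims > DEFAULT_N_SIMS:
        raise ValueError(f"n_sims capped at {DEFAULT_N_SIMS}")
    rng = np.random.default_rng(rng_seed)
    if total_lambda <= 0 or (scenario.scenario != "null" and fraction <= 0):
        return PowerReport(
            sample_id, chromosome, method, scenario.scenario,
            n_droplets, 0, 0.0, False,
        )
    lams = expected_lambdas(total_lambda, fraction, scenario, method)
    if scenario.scenario == "null":
        want = ("loss", "gain")
    else:
        want = (scenario.scenario,)

    hits = 0
    done = 0
    batch = 200 if early_stop else n_sims
    while done < n_sims:
        m = min(batch, n_sims - done)
        calls = simulate_cn_calls(lams, method, n_droplets, m, rng, ci_level)
        hits += int(np.isin(calls, want).sum())
        done += m
        if early_stop and done < n_sims:
            lo, hi = _wilson(hits, done, z=2.576)
            if lo > power_threshold or hi < power_threshold:
                break
    sens = hits / done
    return PowerReport(
        sample_id, chromosome, method, scenario.scenario,
        n_droplets, done, sens, sens >= power_threshold,
    )


def _wilson(k: int, n: int, z: float) -> Tuple[float, float]:
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return centre - half, centre + half


def composition_lambdas(
    comp: SampleComposition, plan: Optional[VolumePlan] = None
) -> Tuple[float, float]:
    """(total_lambda, fraction) implied by a sample's Gαq measurements."""
    lam_m = comp.mut_conc.lambda_hat
    lam_w = comp.wt_conc.lambda_hat
    total = lam_m + lam_w
    frac = 0.0 if total == 0 else min(1.0, 2.0 * lam_m / total)
    return total, frac


def sample_power(
    comp: SampleComposition,
    scenario: SimScenario,
    method: str,
    chromosome: str,
    n_droplets: int = DROPLETS_MERGED,
    n_sims: int = DEFAULT_N_SIMS,
    rng_seed=None,
    **kwargs,
) -> PowerReport:
    """Power report for one sample, driven by its own composition."""
    total, frac = composition_lambdas(comp)
    return sensitivity(
        total, frac, scenario, method,
        n_droplets=n_droplets, n_sims=n_sims, rng_seed=rng_seed,
        sample_id=comp.sample_id, chromosome=chromosome, **kwargs,
    )


def power_gate(report: PowerReport, threshold: float = POWER_THRESHOLD) -> bool:
    """Powered iff sensitivity >= threshold (exactly 80% counts as
    powered; 'underpowered' is strictly below)."""
    return report.sensitivity >= threshold


def sensitivity_curve(
    total_lambda: float,
    fraction: float,
    scenario: SimScenario,
    method: str,
    droplet_grid: Sequence[int],
    n_sims: int = 500,
    rng_seed=None,
) -> "list[tuple[int, float]]":
    """(droplets, sensitivity) pairs for plotting a power curve."""
    rng = np.random.default_rng(rng_seed)
    out = []
    for n in droplet_grid:
        rep = sensitivity(
            total_lambda, fraction, scenario, method,
            n_droplets=int(n), n_sims=n_sims, rng_seed=rng,
        )
        out.append((int(n), rep.sensitivity))
    return out
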