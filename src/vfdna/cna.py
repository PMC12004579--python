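"""Chromosome 3p / 8q copy-number estimation and calling.

Two estimators are supported, both producing a copy-number value on the
scale where 2 means unaltered:

* classic:   cn = 2 * [target] / [reference]   (target PPARG on 3p or
  PTK2 on 8q against a stable reference gene TERT or TTC5);
* SNP-based: cn = 1 + [var1] / [var2]          (allelic imbalance of a
  heterozygous germline SNP, var2 assumed haploid-stable).

The 99% confidence interval comes from the delta method on the
log-ratio of the two Poisson concentration estimates; an alteration is
called only when the point estimate departs from 2 *and* the interval
excludes 2.  Calls are additionally gated by the in-silico power analysis
(:mod:`vfdna.power`): an underpowered sample gets ``no_call`` regardless
of its interval.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm

from .ddpcr import ConcentrationEstimate

CLASSIC_TARGET_GENES = {"PPARG": "3p", "PTK2": "8q"}
CLASSIC_REFERENCE_GENES = {"TERT": "5p", "TTC5": "14q"}


@dataclass(frozen=True)
class SnpContext:
    """One germline SNP usable for allelic-imbalance copy-number calls."""

    snp_id: str
    chromosome: str  # "3p" | "8q"
    stable_variant: str = "var2"
    genotyped_heterozygous: bool = False
    expected_droplet_count: float = 0.0  # for choosing among several SNPs

    @property
    def usable(self) -> bool:
        return self.genotyped_heterozygous


@dataclass(frozen=True)
class CopyNumberResult:
    sample_id: str
    chromosome: str
    method: str  # "classic" | "snp"
    cn_value: Optional[float]
    ci99_low: Optional[float]
    ci99_high: Optional[float]
    call: str  # "loss" | "gain" | "no_change" | "no_call"
    powered: Optional[bool] = None
    flags: tuple = ()


def ratio_interval(
    lam1, se1, lam2, se2, ci_level: float = 0.99, lam_floor=None, se_floor=None
):
    """Delta-method CI for the ratio ``lam1/lam2`` on the log scale.

    Works element-wise on numpy arrays.  ``SE(log R)^2 = (se1/lam1)^2 +
    (se2/lam2)^2``; the interval is ``exp(log R +/- z*SE)``.  A zero
    numerator yields a lower bound of 0 and an upper bound computed with
    the continuity floor (``lam_floor``/``se_floor``, typically the
    lambda-equivalent of half a positive droplet) so that an empty channel
    still produces a finite, conservative upper limit.
    """
    lam1 = np.asarray(lam1, dtype=float)
    se1 = np.asarray(se1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    se2 = np.asarray(se2, dtype=float)
    z = norm.ppf(0.5 + ci_level / 2.0)

    if lam_floor is None:
        lam_floor = np.where(lam1 > 0, lam1, np.nan)
    if se_floor is None:
        se_floor = se1

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lam2 > 0, lam1 / lam2, np.nan)
        lam1_eff = np.where(lam1 > 0, lam1, lam_floor)
        se1_eff = np.where(lam1 > 0, se1, se_floor)
        log_se = np.sqrt(
            (se1_eff / lam1_eff) ** 2 + np.where(lam2 > 0, (se2 / lam2) ** 2, np.nan)
        )
        ratio_eff = np.where(lam2 > 0, lam1_eff / lam2, np.nan)
        hi = ratio_eff * np.exp(z * log_se)
        lo = np.where(lam1 > 0, ratio_eff * np.exp(-z * log_se), 0.0)
    return ratio, lo, hi


def classify_cn(cn, lo, hi):
    """Copy-number call from the point estimate and its 99% interval.

    loss: cn < 2 and the whole interval below 2; gain: cn > 2 and the
    whole interval above 2; otherwise no change.  NaNs (failed ratio)
    yield ``no_call``.  Vectorised: returns an object array of labels for
    array input, a single label for scalars.
    """
    cn = np.asarray(cn, dtype=float)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    out = np.full(cn.shape, "no_change", dtype=object)
    out[np.isnan(cn) | np.isnan(lo) | np.isnan(hi)] = "no_call"
    with np.errstate(invalid="ignore"):
        out[(cn < 2) & (hi < 2)] = "loss"
        out[(cn > 2) & (lo > 2)] = "gain"
    if out.shape == ():
        return out[()]
    return out


def _half_droplet_floor(est: ConcentrationEstimate) -> Tuple[float, float]:
    n = est.accepted_droplets
    lam = -np.log1p(-0.5 / n)
    p = 0.5 / n
    se = np.sqrt(p / ((1 - p) * n))
    return lam, se


def _ratio_result(
    sample_id: str,
    chromosome: str,
    method: str,
    num: ConcentrationEstimate,
    den: ConcentrationEstimate,
    scale: float,
    offset: float,
    ci_level: float,
) -> CopyNumberResult:
    flags: List[str] = []
    if den.lambda_hat <= 0:
        return CopyNumberResult(
            sample_id, chromosome, method, None, None, None, "no_call",
            flags=("denominator_zero",),
        )
    lam_floor, se_floor = _half_droplet_floor(num)
    r, lo, hi = ratio_interval(
        num.lambda_hat, num.se_lambda, den.lambda_hat, den.se_lambda,
        ci_level=ci_level, lam_floor=lam_floor, se_floor=se_floor,
    )
    if num.lambda_hat <= 0:
        flags.append("numerator_zero")
    if not (num.qc_pass and den.qc_pass):
        flags.append("qc_fail")
    cn = offset + scale * float(r)
    cn_lo = offset + scale * float(lo)
    cn_hi = offset + scale * float(hi)
    call = "no_call" if "qc_fail" in flags else str(classify_cn(cn, cn_lo, cn_hi))
    return CopyNumberResult(
        sample_id, chromosome, method, cn, cn_lo, cn_hi, call, flags=tuple(flags)
    )


def cn_classic(
    target: ConcentrationEstimate,
    reference: ConcentrationEstimate,
    sample_id: str = "",
    chromosome: str = "",
    ci_level: float = 0.99,
) -> CopyNumberResult:
    """Classic copy number ``2*[target]/[reference]`` with 99% CI."""
    return _ratio_result(
        sample_id, chromosome, "classic", target, reference, 2.0, 0.0, ci_level
    )


def cn_snp(
    var1: ConcentrationEstimate,
    var2: ConcentrationEstimate,
    sample_id: str = "",
    chromosome: str = "",
    ci_level: float = 0.99,
) -> CopyNumberResult:
    """SNP-based copy number ``1 + [var1]/[var2]`` with 99% CI.

    ``var2`` is the allele assumed copy-number stable (haploid); its
    concentration in the denominator anchors the scale.
    """
    return _ratio_result(
        sample_id, chromosome, "snp", var1, var2, 1.0, 1.0, ci_level
    )


def call_cna(result: CopyNumberResult, powered: bool) -> CopyNumberResult:
    """Apply the power gate: an underpowered sample is never called."""
    if not powered:
        return replace(result, call="no_call", powered=False)
    return replace(result, powered=True)


def choose_method(
    contexts: Sequence[SnpContext],
    chromosome: str,
    classic_available: bool = True,
) -> Tuple[str, Optional[SnpContext]]:
    """Prefer the SNP-based estimator whenever a heterozygous SNP exists.

    Among several usable SNPs on the chromosome, the one with the highest
    expected droplet count is used (merging across distinct loci is not
    attempted).  Falls back to the classic estimator, else ``no_call``.
    """
    usable = [
        c for c in contexts if c.chromosome == chromosome and c.usable
    ]
    if usable:
        best = max(usable, key=lambda c: c.expected_droplet_count)
        return "snp", best
    if classic_available:
        return "classic", None
    return "no_call", None
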