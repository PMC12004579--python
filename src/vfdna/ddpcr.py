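"""Partition-level statistics for droplet digital PCR.

A droplet digital PCR experiment partitions a reaction into ~15,000-20,000
nanolitre droplets; after end-point PCR each droplet is classified as
positive or negative for each fluorescence channel.  Under random (Poisson)
partitioning of target molecules, the mean occupancy per droplet is
recovered from the fraction of negative droplets:

    lambda_hat = -ln(1 - k/N)

for ``k`` positive droplets out of ``N`` accepted.  This module converts
droplet counts into absolute concentrations (copies/µL of PCR reaction and
of the original vitreous-fluid specimen), attaches delta-method confidence
intervals, merges replicate wells, and applies the two quality rules used
throughout the pipeline: a well needs at least 10,000 accepted droplets to
pass QC, and a target needs at least 3 positive droplets (after merging)
to count as detectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

from scipy.stats import norm

DEFAULT_MIN_DROPLETS = 10_000
DEFAULT_MIN_POSITIVES = 3
DEFAULT_CI_LEVEL = 0.99

#: droplets with an estimated positive fraction above this are outside the
#: reliable dynamic range of the assay (near-saturation)
DYNAMIC_RANGE_CEILING = 0.999


@dataclass(frozen=True)
class VolumePlan:
    """Volumes linking one PCR well back to the vitreous-fluid specimen.

    Defaults follow the wet-lab workflow this pipeline models: DNA from
    100-200 µL vitreous fluid (150 µL assumed when unrecorded) eluted in
    35 µL, of which 3.5 µL enters a 22 µL reaction partitioned into
    0.85 nL droplets.
    """

    vitreous_input_ul: float = 150.0
    elution_ul: float = 35.0
    dna_per_reaction_ul: float = 3.5
    reaction_ul: float = 22.0
    droplet_volume_nl: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "vitreous_input_ul",
            "elution_ul",
            "dna_per_reaction_ul",
            "reaction_ul",
            "droplet_volume_nl",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"VolumePlan.{name} must be strictly positive")
        if self.dna_per_reaction_ul > self.elution_ul:
            raise ValueError("dna_per_reaction_ul cannot exceed elution_ul")

    @property
    def droplet_volume_ul(self) -> float:
        return self.droplet_volume_nl / 1000.0

    @property
    def vitreous_scale(self) -> float:
        """Factor converting copies/µL reaction to copies/µL vitreous."""
        return (self.reaction_ul / self.dna_per_reaction_ul) * (
            self.elution_ul / self.vitreous_input_ul
        )


@dataclass
class WellCounts:
    """Classified droplet counts for one well (or a merge of wells).

    ``positives_by_channel`` holds the total positive droplets per channel,
    *including* double positives; ``double_positives`` counts droplets
    positive in both channels (None when the export did not record them).
    """

    well_id: str
    assay_id: str
    accepted_droplets: int
    positives_by_channel: Dict[str, int]
    double_positives: Optional[int] = None

    def __post_init__(self) -> None:
        if self.accepted_droplets <= 0:
            raise ValueError("accepted_droplets must be > 0")
        for ch, k in self.positives_by_channel.items():
            if not 0 <= k <= self.accepted_droplets:
                raise ValueError(
                    f"positives in channel {ch!r} ({k}) outside "
                    f"[0, {self.accepted_droplets}]"
                )
        if self.double_positives is not None:
            if self.double_positives < 0:
                raise ValueError("double_positives must be >= 0")
            if self.positives_by_channel and self.double_positives > min(
                self.positives_by_channel.values()
            ):
                raise ValueError(
                    "double_positives cannot exceed the smallest channel count"
                )

    def positives(self, channel: str) -> int:
        try:
            return self.positives_by_channel[channel]
        except KeyError:
            raise KeyError(
                f"channel {channel!r} not present in well {self.well_id!r} "
                f"(has {sorted(self.positives_by_channel)})"
            ) from None


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Poisson-MLE concentration with delta-method confidence interval.

    ``ci_low``/``ci_high`` are in copies/µL reaction, the same scale as
    ``copies_per_ul_reaction``.  ``detectable`` is True iff the well(s)
    carried at least ``min_positives`` positive droplets and passed the
    accepted-droplet QC.
    """

    species: str
    lambda_hat: float
    se_lambda: float
    copies_per_ul_reaction: float
    copies_per_ul_vitreous: float
    ci_low: float
    ci_high: float
    positive_droplets: int
    accepted_droplets: int
    detectable: bool
    qc_pass: bool
    saturated: bool = False
    flags: tuple = ()


def qc_well(counts: WellCounts, min_droplets: int = DEFAULT_MIN_DROPLETS) -> bool:
    """True iff the well passes the accepted-droplet quality control.

    The boundary is inclusive: exactly ``min_droplets`` accepted droplets
    passes.
    """
    return counts.accepted_droplets >= min_droplets


def lambda_from_counts(k: float, n: int) -> float:
    """Poisson occupancy MLE ``-ln(1 - k/n)`` (k may be fractional after
    the saturation continuity correction)."""
    if not 0 <= k <= n:
        raise ValueError("positives must lie in [0, accepted_droplets]")
    return -math.log1p(-k / n)


def estimate_concentration(
    counts: WellCounts,
    channel: str,
    plan: Optional[VolumePlan] = None,
    ci_level: float = DEFAULT_CI_LEVEL,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    species: Optional[str] = None,
) -> ConcentrationEstimate:
    """Estimate the concentration of the species read in ``channel``.

    The MLE is ``lambda_hat = -ln(1 - k/N)``; its standard error comes
    from the delta method on the binomial positive fraction,
    ``SE = sqrt(p(1-p)/N) / (1-p)``, with a symmetric normal interval
    floored at zero.  A saturated well (k = N) is handled with the
    continuity correction k -> N - 0.5 and flagged.
    """
    if plan is None:
        plan = VolumePlan()
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    n = counts.accepted_droplets
    k = counts.positives(channel)

    flags: List[str] = []
    saturated = k == n
    k_eff: float = n - 0.5 if saturated else float(k)
    if saturated:
        flags.append("saturated")
        warnings.warn(
            f"well {counts.well_id!r} channel {channel!r} is saturated "
            "(all droplets positive); continuity-corrected estimate returned",
            RuntimeWarning,
            stacklevel=2,
        )

    p_hat = k_eff / n
    lam = -math.log1p(-p_hat)
    se = math.sqrt(p_hat / ((1.0 - p_hat) * n)) if 0 < p_hat < 1 else 0.0
    if p_hat > DYNAMIC_RANGE_CEILING:
        flags.append("above_dynamic_range")

    z = norm.ppf(0.5 + ci_level / 2.0)
    vol = plan.droplet_volume_ul
    conc = lam / vol
    ci_low = max(0.0, (lam - z * se)) / vol
    ci_high = (lam + z * se) / vol

    qc = qc_well(counts, min_droplets)
    if not qc:
        flags.append("qc_fail")

    return ConcentrationEstimate(
        species=species or channel,
        lambda_hat=lam,
        se_lambda=se,
        copies_per_ul_reaction=conc,
        copies_per_ul_vitreous=conc * plan.vitreous_scale,
        ci_low=ci_low,
        ci_high=ci_high,
        positive_droplets=k,
        accepted_droplets=n,
        detectable=(k >= min_positives) and qc,
        qc_pass=qc,
        saturated=saturated,
        flags=tuple(flags),
    )


def merge_wells(wells: Sequence[WellCounts]) -> WellCounts:
    """Pool replicate wells of the same assay into one combined count.

    Droplet and positive counts are summed channel-wise; estimating on the
    merged counts equals the joint maximum-likelihood estimate over the
    replicates, so merging first and estimating second is exact.
    """
    if not wells:
        raise ValueError("merge_wells requires at least one well")
    assay_ids = {w.assay_id for w in wells}
    if len(assay_ids) > 1:
        raise ValueError(f"cannot merge wells from different assays: {sorted(assay_ids)}")
    if len(wells) == 1:
        return replace(wells[0])

    channels = set()
    for w in wells:
        channels.update(w.positives_by_channel)
    merged_pos = {
        ch: sum(w.positives_by_channel.get(ch, 0) for w in wells) for ch in channels
    }
    doubles: Optional[int]
    if any(w.double_positives is None for w in wells):
        doubles = None
    else:
        doubles = sum(w.double_positives for w in wells)  # type: ignore[misc]
    return WellCounts(
        well_id="+".join(w.well_id for w in wells),
        assay_id=wells[0].assay_id,
        accepted_droplets=sum(w.accepted_droplets for w in wells),
        positives_by_channel=merged_pos,
        double_positives=doubles,
    )
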