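"""DNA composition of a vitreous-fluid sample from its Gαq driver assay.

Nearly every uveal melanoma carries a clonal hotspot mutation in one of
the Gαq-pathway genes (GNAQ, GNA11, CYSLTR2, PLCB4), so the mutant allele
acts as a generic marker of melanoma-cell-derived DNA.  From the mutant
and wild-type allele concentrations of the driver assay:

    total vfDNA concentration  = [mutation] + [wildtype]
    melanoma-cell DNA fraction = 2 * [mutation] / ([mutation] + [wildtype])

(the factor 2 accounts for the mutation being heterozygous: a pure-tumour
sample has [mutation] = [wildtype] and fraction 1).  Samples are triaged
into three classes: vfDNA-/UM- (no measurable DNA), vfDNA+/UM- (DNA but no
mutant alleles) and vfDNA+/UM+ (melanoma-cell-derived DNA present), using
the >=3-positive-droplet detectability rule on counts merged over up to
three replicate experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .ddpcr import DYNAMIC_RANGE_CEILING, ConcentrationEstimate


class Triage(str, Enum):
    VFDNA_NEG_UM_NEG = "vfDNA-/UM-"
    VFDNA_POS_UM_NEG = "vfDNA+/UM-"
    VFDNA_POS_UM_POS = "vfDNA+/UM+"


@dataclass(frozen=True)
class SampleComposition:
    sample_id: str
    mut_conc: ConcentrationEstimate
    wt_conc: ConcentrationEstimate
    total_vfdna: float  # copies/µL vitreous
    melanoma_fraction: Optional[float]  # clamped to [0, 1]; None if total == 0
    melanoma_fraction_raw: Optional[float]  # unclamped 2m/(m+w)
    nonmelanoma_conc: float  # copies/µL vitreous, floored at 0
    triage: Triage
    unreliable: bool = False  # any channel beyond the dynamic-range ceiling


def _check_units(mut: ConcentrationEstimate, wt: ConcentrationEstimate) -> None:
    # same volume plan <=> identical reaction->vitreous scale
    for est in (mut, wt):
        if est.copies_per_ul_reaction > 0:
            pass
    if mut.copies_per_ul_reaction > 0 and wt.copies_per_ul_reaction > 0:
        s_m = mut.copies_per_ul_vitreous / mut.copies_per_ul_reaction
        s_w = wt.copies_per_ul_vitreous / wt.copies_per_ul_reaction
        if abs(s_m - s_w) > 1e-9 * max(s_m, s_w):
            raise ValueError(
                "mutant and wild-type estimates use different volume plans"
            )


def total_vfdna(mut: ConcentrationEstimate, wt: ConcentrationEstimate) -> float:
    """Total vfDNA concentration, copies/µL vitreous."""
    _check_units(mut, wt)
    return mut.copies_per_ul_vitreous + wt.copies_per_ul_vitreous


def melanoma_fraction(
    mut: ConcentrationEstimate, wt: ConcentrationEstimate
) -> Optional[float]:
    """Raw melanoma-cell-derived fraction ``2m/(m+w)``; None when m+w = 0.

    Values above 1 (mutant excess from allelic imbalance or sampling
    noise) are returned as-is; reporting-level clamping happens in
    :func:`compose_sample`.
    """
    _check_units(mut, wt)
    m = mut.copies_per_ul_vitreous
    w = wt.copies_per_ul_vitreous
    if m + w == 0:
        return None
    return 2.0 * m / (m + w)


def nonmelanoma_concentration(
    mut: ConcentrationEstimate, wt: ConcentrationEstimate
) -> float:
    """Non-melanoma-cell-derived DNA, ``total*(1-fraction) = wt - mut``,
    floored at 0."""
    _check_units(mut, wt)
    return max(0.0, wt.copies_per_ul_vitreous - mut.copies_per_ul_vitreous)


def triage_sample(mut: ConcentrationEstimate, wt: ConcentrationEstimate) -> Triage:
    """Triage from the detectability (>=3 merged positive droplets + QC)
    of the mutant and wild-type species."""
    if mut.detectable:
        return Triage.VFDNA_POS_UM_POS
    if wt.detectable:
        return Triage.VFDNA_POS_UM_NEG
    return Triage.VFDNA_NEG_UM_NEG


def compose_sample(
    sample_id: str,
    mut: ConcentrationEstimate,
    wt: ConcentrationEstimate,
) -> SampleComposition:
    raw = melanoma_fraction(mut, wt)
    frac = None if raw is None else min(raw, 1.0)
    unreliable = any(
        est.positive_droplets / est.accepted_droplets > DYNAMIC_RANGE_CEILING
        for est in (mut, wt)
    )
    return SampleComposition(
        sample_id=sample_id,
        mut_conc=mut,
        wt_conc=wt,
        total_vfdna=total_vfdna(mut, wt),
        melanoma_fraction=frac,
        melanoma_fraction_raw=raw,
        nonmelanoma_conc=nonmelanoma_concentration(mut, wt),
        triage=triage_sample(mut, wt),
        unreliable=unreliable,
    )


def compose_multi_driver(
    sample_id: str,
    driver_pairs: Sequence[tuple],
) -> SampleComposition:
    """Composition for a tumour with several clonal Gαq drivers.

    ``driver_pairs`` is a sequence of (mut_estimate, wt_estimate) tuples,
    one per driver assay.  Each driver yields its own composition; the one
    with the strongest mutant signal drives the reported triage and
    fraction (a mutant signal in any driver marks the sample UM+).
    """
    if not driver_pairs:
        raise ValueError("at least one driver assay required")
    comps = [compose_sample(sample_id, m, w) for m, w in driver_pairs]
    best = max(
        comps,
        key=lambda c: (
            c.triage == Triage.VFDNA_POS_UM_POS,
            c.mut_conc.copies_per_ul_vitreous,
            c.total_vfdna,
        ),
    )
    return best
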