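"""Qualitative calling of secondary (BSE) driver mutations.

BAP1, SF3B1 and EIF1AX mutations define the prognostic subtypes of uveal
melanoma.  In vitreous-fluid DNA they are interpreted qualitatively —
'detected' or 'not detected' — because even a handful of mutant molecules
proves the mutation's presence.  Two assay designs are supported:

* targeted duplex: a mutant-specific probe; mutant evidence is the
  mutant-channel positive count;
* drop-off: a reference probe binds every allele while a second probe
  spanning the mutation site fails on mutant molecules, so mutant
  molecules show up as droplets positive in the reference channel only
  (the 'blue' cluster in two-dimensional plots).  Wild-type molecules
  co-encapsulated with mutant ones land in the double-positive cluster
  and are not mutant evidence.

Either way a mutation is 'detected' when >= 3 mutant-evidence droplets
accumulate over the merged replicate wells (up to three) and QC passes.
A variant with no covering assay in the panel is 'not measured'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .assays import AssayRegistry, assay_availability
from .ddpcr import (
    DEFAULT_MIN_DROPLETS,
    DEFAULT_MIN_POSITIVES,
    WellCounts,
    merge_wells,
    qc_well,
)

DETECTED = "detected"
NOT_DETECTED = "not_detected"
NOT_MEASURED = "not_measured"

BSE_GENES = ("BAP1", "SF3B1", "EIF1AX")


@dataclass(frozen=True)
class BseAssayResult:
    sample_id: str
    gene: str
    assay_kind: str  # "targeted_duplex" | "drop_off" | "none"
    status: str  # detected | not_detected | not_measured
    mutant_positive_droplets: int = 0
    merged_experiments: int = 0
    qc_pass: bool = True

    def __post_init__(self) -> None:
        if self.status == DETECTED and self.mutant_positive_droplets < DEFAULT_MIN_POSITIVES:
            raise ValueError(
                "a 'detected' call requires at least "
                f"{DEFAULT_MIN_POSITIVES} mutant-evidence droplets"
            )


def _merged(wells: Sequence[WellCounts]) -> WellCounts:
    if isinstance(wells, WellCounts):
        return wells
    return merge_wells(list(wells))


def dropoff_call(
    wells,
    sample_id: str,
    gene: str,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    reference_channel: Optional[str] = None,
) -> BseAssayResult:
    """Call a drop-off assay from its cluster counts.

    Mutant evidence is the reference-only ('blue') cluster: reference
    channel positives minus double positives.  Wells lacking the
    double-positive accounting cannot be interpreted and are rejected.
    """
    n_wells = 1 if isinstance(wells, WellCounts) else len(wells)
    merged = _merged(wells)
    if merged.double_positives is None:
        raise ValueError(
            f"drop-off call for {sample_id}/{gene} needs double-positive counts"
        )
    if reference_channel is None:
        channels = sorted(merged.positives_by_channel)
        reference_channel = (
            "reference" if "reference" in channels else channels[0]
        )
    blue = merged.positives(reference_channel) - merged.double_positives
    if blue < 0:
        raise ValueError("reference-channel count below double-positive count")
    qc = qc_well(merged, min_droplets)
    status = DETECTED if (blue >= min_positives and qc) else NOT_DETECTED
    return BseAssayResult(
        sample_id=sample_id,
        gene=gene,
        assay_kind="drop_off",
        status=status,
        mutant_positive_droplets=blue,
        merged_experiments=n_wells,
        qc_pass=qc,
    )


def targeted_bse_call(
    wells,
    sample_id: str,
    gene: str,
    min_droplets: int = DEFAULT_MIN_DROPLETS,
    min_positives: int = DEFAULT_MIN_POSITIVES,
    mutant_channel: str = "mutant",
) -> BseAssayResult:
    """Call a targeted duplex assay: detected iff >= 3 merged
    mutant-channel positives with QC pass."""
    n_wells = 1 if isinstance(wells, WellCounts) else len(wells)
    merged = _merged(wells)
    k = merged.positives(mutant_channel)
    qc = qc_well(merged, min_droplets)
    status = DETECTED if (k >= min_positives and qc) else NOT_DETECTED
    return BseAssayResult(
        sample_id=sample_id,
        gene=gene,
        assay_kind="targeted_duplex",
        status=status,
        mutant_positive_droplets=k,
        merged_experiments=n_wells,
        qc_pass=qc,
    )


def not_measured(sample_id: str, gene: str) -> BseAssayResult:
    """Placeholder for a tumour variant with no covering assay."""
    return BseAssayResult(
        sample_id=sample_id,
        gene=gene,
        assay_kind="none",
        status=NOT_MEASURED,
    )


def call_bse(
    sample_id: str,
    gene: str,
    variant: str,
    wells,
    panel: AssayRegistry,
    assay_kind: Optional[str] = None,
    **kwargs,
) -> BseAssayResult:
    """Availability-aware dispatch: not_measured when the panel has no
    covering assay (or the variant string cannot be parsed), else the
    kind-appropriate call."""
    try:
        available = assay_availability(gene, variant, panel)
    except ValueError as exc:
        warnings.warn(
            f"{sample_id}/{gene}: {exc}; recording as not measured",
            RuntimeWarning,
            stacklevel=2,
        )
        return not_measured(sample_id, gene)
    if not available or wells is None:
        return not_measured(sample_id, gene)
    if assay_kind is None:
        assay_kind = "drop_off" if gene == "EIF1AX" else "targeted_duplex"
    if assay_kind == "drop_off":
        return dropoff_call(wells, sample_id, gene, **kwargs)
    return targeted_bse_call(wells, sample_id, gene, **kwargs)
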