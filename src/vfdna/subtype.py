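"""Molecular-subtype inference from combined mutation and copy-number calls.

Uveal melanomas split into a poor-prognosis group (BAP1 mutation and/or
monosomy 3p) and a better-prognosis group (EIF1AX or SF3B1 mutation
and/or disomy 3p).  From vitreous-fluid measurements the subtype is
inferable when the evidence supports one side:

* positive evidence (a detected mutation, a called 3p loss) is always
  usable;
* negative evidence (3p 'no change') is usable only when the sample was
  statistically powered to detect a loss — an unpowered absence proves
  nothing.

Chromosome 8q status is carried along as an annotation but does not by
itself assign a subtype.  Conflicting evidence (e.g. an EIF1AX mutation
together with a powered 3p loss) resolves to poor prognosis with a
warning, the conservative direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

from .bse import DETECTED, BseAssayResult
from .cna import CopyNumberResult

POOR = "poor_prognosis"
BETTER = "better_prognosis"
NOT_INFERABLE = "not_inferable"


@dataclass(frozen=True)
class SubtypeCall:
    sample_id: str
    subtype: str
    evidence: Tuple[str, ...] = ()
    chr8q_status: str = "no_call"
    conflict: bool = False

    def __post_init__(self) -> None:
        if self.subtype not in (POOR, BETTER, NOT_INFERABLE):
            raise ValueError(f"unknown subtype {self.subtype!r}")
        if self.subtype != NOT_INFERABLE and not self.evidence:
            raise ValueError("an inferred subtype requires evidence")


def infer_subtype(
    sample_id: str,
    bse_results: Sequence[BseAssayResult],
    cna_results: Sequence[CopyNumberResult],
) -> SubtypeCall:
    """Combine power-gated copy-number calls and BSE mutation calls."""
    poor_ev: List[str] = []
    better_ev: List[str] = []

    for r in bse_results:
        if r.status != DETECTED:
            continue
        if r.gene == "BAP1":
            poor_ev.append("BAP1 mutation detected")
        elif r.gene in ("SF3B1", "EIF1AX"):
            better_ev.append(f"{r.gene} mutation detected")

    chr8q = "no_call"
    for r in cna_results:
        if r.chromosome == "8q":
            chr8q = r.call
        elif r.chromosome == "3p":
            if r.call == "loss":
                poor_ev.append(f"chromosome 3p loss ({r.method})")
            elif r.call == "no_change" and r.powered:
                better_ev.append(f"powered chromosome 3p disomy ({r.method})")

    conflict = bool(poor_ev) and bool(better_ev)
    if conflict:
        warnings.warn(
            f"{sample_id}: conflicting subtype evidence "
            f"(poor: {poor_ev}; better: {better_ev}); "
            "resolving to poor prognosis",
            RuntimeWarning,
            stacklevel=2,
        )
    if poor_ev:
        return SubtypeCall(sample_id, POOR, tuple(poor_ev + better_ev), chr8q, conflict)
    if better_ev:
        return SubtypeCall(sample_id, BETTER, tuple(better_ev), chr8q, conflict)
    return SubtypeCall(sample_id, NOT_INFERABLE, (), chr8q, False)
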