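"""Assay definitions and the variant-coverage registry.

Assays are abstract here: no primer or probe sequences, only the mapping
from fluorescence channels to molecular species and, for the mutation
assays, which variants of a gene they cover.  Four kinds exist:

* ``targeted_duplex`` — mutant and wild-type probes in one well
  (channels: mutant, wildtype);
* ``drop_off`` — a reference probe binding all alleles plus a drop-off
  probe that fails on mutant molecules (channels: reference, dropoff);
* ``cna_classic`` — a chromosomal target plus a stable reference gene
  (channels: target, reference);
* ``cna_snp`` — the two alleles of a heterozygous germline SNP
  (channels: var1, var2).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

REQUIRED_SPECIES = {
    "targeted_duplex": {"mutant", "wildtype"},
    "drop_off": {"reference", "dropoff"},
    "cna_classic": {"target", "reference"},
    "cna_snp": {"var1", "var2"},
}

#: heterozygous germline SNPs usable for allelic-imbalance copy-number calls
SNP_PANEL = {
    "3p": ("rs6617", "rs6976", "rs9586", "rs1989839", "rs1062633", "rs2236947"),
    "8q": ("rs7018178", "rs7843014"),
}

#: classic copy-number targets and the stable reference genes
CLASSIC_TARGETS = {"3p": "PPARG", "8q": "PTK2"}
CLASSIC_REFERENCES = ("TERT", "TTC5")  # 5p preferred, 14q fallback


@dataclass(frozen=True)
class AssayDef:
    """One digital PCR assay: what it measures and through which channels."""

    assay_id: str
    assay_kind: str
    channel_map: Dict[str, str] = field(default_factory=dict)
    gene: Optional[str] = None
    covered_variants: Tuple[str, ...] = ()
    covered_exons: Tuple[int, ...] = ()
    anneal_temp: Optional[float] = None  # °C, metadata only

    def __post_init__(self) -> None:
        if self.assay_kind not in REQUIRED_SPECIES:
            raise ValueError(f"unknown assay_kind {self.assay_kind!r}")
        species = set(self.channel_map.values())
        if species != REQUIRED_SPECIES[self.assay_kind]:
            raise ValueError(
                f"assay {self.assay_id!r} ({self.assay_kind}) must map channels to "
                f"{sorted(REQUIRED_SPECIES[self.assay_kind])}, got {sorted(species)}"
            )


class AssayRegistry:
    """Panel of assays keyed by id, with variant-coverage lookup."""

    def __init__(self, assays: Iterable[AssayDef] = ()) -> None:
        self._assays: Dict[str, AssayDef] = {}
        for a in assays:
            self.add(a)

    def add(self, assay: AssayDef) -> None:
        if assay.assay_id in self._assays:
            raise ValueError(f"duplicate assay_id {assay.assay_id!r}")
        self._assays[assay.assay_id] = assay

    def __contains__(self, assay_id: str) -> bool:
        return assay_id in self._assays

    def __getitem__(self, assay_id: str) -> AssayDef:
        return self._assays[assay_id]

    def __iter__(self):
        return iter(self._assays.values())

    def __len__(self) -> int:
        return len(self._assays)

    def assays_for_gene(self, gene: str) -> List[AssayDef]:
        return [a for a in self._assays.values() if a.gene == gene]


_PROTEIN_RE = re.compile(r"^p\.?([A-Za-z])(\d+)([A-Za-z*]+|fs.*|del.*|ins.*)$")
_EXON_RE = re.compile(r"^(?:exon|ex)\s*(\d+)", re.IGNORECASE)


def parse_variant(variant: str) -> Dict[str, object]:
    """Parse a protein-change (``p.R625H``) or exon (``exon 2``) notation.

    Returns a dict with ``kind`` ('protein' or 'exon') plus the parsed
    fields; raises ValueError for anything else.
    """
    v = variant.strip()
    m = _PROTEIN_RE.match(v)
    if m:
        return {
            "kind": "protein",
            "ref": m.group(1).upper(),
            "pos": int(m.group(2)),
            "alt": m.group(3),
            "norm": f"p.{m.group(1).upper()}{m.group(2)}{m.group(3)}",
        }
    m = _EXON_RE.match(v)
    if m:
        return {"kind": "exon", "exon": int(m.group(1))}
    raise ValueError(f"cannot parse variant notation {variant!r}")


def assay_availability(gene: str, variant: str, panel: AssayRegistry) -> bool:
    """Does any registered assay cover this tumour's variant?

    A drop-off assay covers every variant within its exons; a targeted
    assay covers only its listed protein changes.  An unparseable variant
    string raises ValueError (cohort-level callers downgrade this to a
    'not measured' status).
    """
    parsed = parse_variant(variant)
    for assay in panel.assays_for_gene(gene):
        if parsed["kind"] == "exon":
            if parsed["exon"] in assay.covered_exons:
                return True
        else:
            if assay.covered_exons:
                # drop-off assays cover any point change in their exons; a
                # protein position cannot be mapped to an exon without
                # transcript structure, so coverage requires an explicit list
                # unless the assay covers the whole gene hotspot region.
                pass
            norm = parsed["norm"]
            for cov in assay.covered_variants:
                if _variant_matches(norm, cov):
                    return True
    return False


def _variant_matches(norm: str, covered: str) -> bool:
    """Match ``p.R625H`` against covered entries like ``p.R625C/H`` or
    ``p.R625*`` (any substitution at the position)."""
    try:
        p = parse_variant(norm)
    except ValueError:
        return False
    covered = covered.strip()
    m = re.match(r"^p\.?([A-Za-z])(\d+)(.*)$", covered)
    if not m:
        return False
    if p["ref"] != m.group(1).upper() or p["pos"] != int(m.group(2)):
        return False
    alts = m.group(3)
    if alts in ("", "*"):
        return True
    return str(p["alt"]) in alts.split("/")


def default_mutation_panel(extra_bap1_variants: Iterable[str] = ()) -> AssayRegistry:
    """The study-style mutation panel.

    EIF1AX exon 1 and exon 2 drop-off assays cover every mutation in those
    exons; SF3B1 is covered at the p.R625 hotspot (C/H); BAP1 mutations are
    scattered and essentially private, so BAP1 is covered only for variants
    registered explicitly via ``extra_bap1_variants``.
    """
    reg = AssayRegistry(
        [
            AssayDef(
                "EIF1AX_ex1_dropoff",
                "drop_off",
                {"FAM": "reference", "HEX": "dropoff"},
                gene="EIF1AX",
                covered_exons=(1,),
            ),
            AssayDef(
                "EIF1AX_ex2_dropoff",
                "drop_off",
                {"FAM": "reference", "HEX": "dropoff"},
                gene="EIF1AX",
                covered_exons=(2,),
            ),
            AssayDef(
                "SF3B1_R625_targeted",
                "targeted_duplex",
                {"FAM": "mutant", "HEX": "wildtype"},
                gene="SF3B1",
                covered_variants=("p.R625C/H",),
            ),
        ]
    )
    for i, v in enumerate(extra_bap1_variants):
        reg.add(
            AssayDef(
                f"BAP1_custom_{i + 1}",
                "targeted_duplex",
                {"FAM": "mutant", "HEX": "wildtype"},
                gene="BAP1",
                covered_variants=(v,),
            )
        )
    return reg
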