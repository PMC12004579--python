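"""Readers, writers and run configuration.

Tabular conventions: well-count tables are CSV in a QuantaSoft-export-like
dialect (one row per well and channel; comma or semicolon delimiter
autodetected; extra columns ignored); all other sheets and reports are
UTF-8 tab-separated with '.' as decimal separator.  Assay registries and
run configuration are YAML.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import pandas as pd
import yaml

from .assays import AssayDef, AssayRegistry
from .ddpcr import (
    DEFAULT_CI_LEVEL,
    DEFAULT_MIN_DROPLETS,
    DEFAULT_MIN_POSITIVES,
    ConcentrationEstimate,
    VolumePlan,
    WellCounts,
)
from .power import DEFAULT_N_SIMS, DROPLETS_MERGED, DROPLETS_SINGLE, POWER_THRESHOLD
from .synthetic import CohortBundle, GeneratorConfig

WELL_COLUMNS = [
    "Well", "Sample", "Assay", "Channel", "Positives", "AcceptedDroplets",
    "DoublePositives",
]


@dataclass
class RunConfig:
    """Thresholds and paths for one pipeline run.

    Threshold defaults are the analysis constants used throughout:
    10,000-droplet QC minimum, 3-droplet detectability, 99% confidence
    level, 80% sensitivity gate, 15,000/45,000 simulated droplets and at
    most 1,000 simulations per condition.
    """

    wells_path: Optional[str] = None
    samples_path: Optional[str] = None
    genotypes_path: Optional[str] = None
    registry_path: Optional[str] = None
    min_droplets: int = DEFAULT_MIN_DROPLETS
    min_positives: int = DEFAULT_MIN_POSITIVES
    ci_level: float = DEFAULT_CI_LEVEL
    power_threshold: float = POWER_THRESHOLD
    droplets_single: int = DROPLETS_SINGLE
    droplets_merged: int = DROPLETS_MERGED
    max_sims: int = DEFAULT_N_SIMS
    seed: int = 0
    volume_plan: VolumePlan = field(default_factory=VolumePlan)

    def __post_init__(self) -> None:
        for name in ("min_droplets", "min_positives", "droplets_single",
                     "droplets_merged", "max_sims"):
            if getattr(self, name) <= 0:
                raise ValueError(f"RunConfig.{name} must be positive")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.power_threshold <= 1:
            raise ValueError("power_threshold must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "volume_plan" in raw:
            raw["volume_plan"] = VolumePlan(**raw["volume_plan"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# well-count tables


def read_well_table(path) -> pd.DataFrame:
    """Read a well-count CSV, autodetecting comma/semicolon delimiters.

    Accepts either a Positives or a Negatives column (Positives wins);
    extra columns are ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    if "Positives" not in df.columns:
        if "Negatives" in df.columns and "AcceptedDroplets" in df.columns:
            df["Positives"] = df["AcceptedDroplets"] - df["Negatives"]
        else:
            raise ValueError(
                f"{path}: need a Positives (or Negatives) column; "
                f"found {list(df.columns)}"
            )
    missing = [c for c in WELL_COLUMNS if c not in df.columns and c != "DoublePositives"]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "DoublePositives" not in df.columns:
        df["DoublePositives"] = pd.NA
    return df[WELL_COLUMNS].copy()


def wells_from_frame(df: pd.DataFrame) -> Dict[Tuple[str, str], List[WellCounts]]:
    """Group a well table into WellCounts keyed by (sample, assay)."""
    out: Dict[Tuple[str, str], List[WellCounts]] = {}
    for (sample, assay, well), grp in df.groupby(
        ["Sample", "Assay", "Well"], sort=True
    ):
        accepted = grp["AcceptedDroplets"].unique()
        if len(accepted) != 1:
            raise ValueError(
                f"inconsistent AcceptedDroplets for well {well!r}"
            )
        doubles = grp["DoublePositives"].dropna().unique()
        wc = WellCounts(
            well_id=str(well),
            assay_id=str(assay),
            accepted_droplets=int(accepted[0]),
            positives_by_channel={
                str(r.Channel): int(r.Positives) for r in grp.itertuples()
            },
            double_positives=int(doubles[0]) if len(doubles) else None,
        )
        out.setdefault((str(sample), str(assay)), []).append(wc)
    return out


def write_well_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sheets


SAMPLE_SHEET_STR_COLS = (
    "sample_id", "driver_gene", "driver_variant", "driver_assay_id",
    "driver2_gene", "driver2_variant", "driver2_assay_id",
    "bse_gene", "bse_variant", "bse_assay_id", "bse_assay_kind",
    "tumor_3p", "tumor_8q", "tumor_subtype",
)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: sample sheet needs a sample_id column")
    for col in SAMPLE_SHEET_STR_COLS:
        # empty strings survive the TSV round trip as NaN; restore them
        if col in df.columns:
            df[col] = df[col].fillna("").astype(str)
    return df


def read_genotype_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "snp_id", "chromosome", "heterozygous"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: genotype sheet missing {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# assay registry


def registry_to_yaml(registry: AssayRegistry, path) -> None:
    entries = []
    for a in registry:
        entries.append(
            {
                "assay_id": a.assay_id,
                "assay_kind": a.assay_kind,
                "gene": a.gene,
                "channel_map": dict(a.channel_map),
                "covered_variants": list(a.covered_variants),
                "covered_exons": list(a.covered_exons),
                "anneal_temp": a.anneal_temp,
            }
        )
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def registry_from_yaml(path) -> AssayRegistry:
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    reg = AssayRegistry()
    for e in entries:
        reg.add(
            AssayDef(
                assay_id=e["assay_id"],
                assay_kind=e["assay_kind"],
                channel_map=dict(e.get("channel_map") or {}),
                gene=e.get("gene"),
                covered_variants=tuple(e.get("covered_variants") or ()),
                covered_exons=tuple(e.get("covered_exons") or ()),
                anneal_temp=e.get("anneal_temp"),
            )
        )
    return reg


# ---------------------------------------------------------------------------
# cohort bundles


def write_bundle(bundle: CohortBundle, outdir) -> Path:
    """Write a synthetic cohort as a ready-to-run fixture directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_well_table(bundle.wells, outdir / "wells.csv")
    write_tsv(bundle.samples, outdir / "samples.tsv")
    write_tsv(bundle.genotypes, outdir / "genotypes.tsv")
    write_tsv(bundle.truth, outdir / "truth.tsv")
    registry_to_yaml(bundle.panel, outdir / "registry.yaml")
    return outdir


def read_bundle(indir) -> CohortBundle:
    indir = Path(indir)
    truth_path = indir / "truth.tsv"
    return CohortBundle(
        truth=pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame(),
        wells=read_well_table(indir / "wells.csv"),
        samples=read_sample_sheet(indir / "samples.tsv"),
        genotypes=read_genotype_sheet(indir / "genotypes.tsv"),
        panel=registry_from_yaml(indir / "registry.yaml"),
        config=GeneratorConfig(),
    )


# ---------------------------------------------------------------------------
# estimates


def estimates_to_frame(estimates: List[ConcentrationEstimate]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(e) for e in estimates])


def estimates_to_json(estimates: List[ConcentrationEstimate], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            [dataclasses.asdict(e) for e in estimates], fh, indent=2, default=str
        )
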