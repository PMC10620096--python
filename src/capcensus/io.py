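"""Shared data model and table IO.

Every table moving through the pipeline is tab-separated UTF-8 with a "."
decimal and the protein (or peptide) identifier in the first column.  Missing
intensities are empty cells and are held as missing (NaN), never as zero:
a reporter-ion zero is a measurement, an empty cell is the absence of one.

All downstream stages consume the containers defined here; no stage reads
files directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("capcensus")

#: Controlled subcellular-compartment vocabulary.
COMPARTMENTS = (
    "cytosol",
    "nucleus",
    "ER",
    "Golgi",
    "mitochondria",
    "plasma membrane",
    "endosome",
    "lysosome",
    "other",
)

GOLGI_CLASSES = ("membrane", "associated", "not_golgi")

#: Default known-autophagy-fluxer panel used to seed the consensus profile
#: (validated receptors/substrates plus two ATG8 orthologues).
DEFAULT_KNOWN_FLUXERS = (
    "TEX264",
    "CCPG1",
    "CALCOCO1",
    "SQSTM1",
    "MAP1LC3B",
    "GABARAPL2",
)

DESIGN_COLUMNS = ("channel_id", "genotype", "treatment", "replicate", "experiment_id")

ANNOTATION_COLUMNS = (
    "compartment",
    "golgi_class",
    "tm_count",
    "known_fluxer",
    "histone",
    "molar_mass",
)


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-design table (channel -> genotype/treatment/replicate)."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    design = design.copy()
    design["replicate"] = design["replicate"].astype(int)
    if (design["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive integers")
    if design["channel_id"].duplicated().any():
        dup = design.loc[design["channel_id"].duplicated(), "channel_id"].tolist()
        raise ValueError(f"duplicate channel_id in design: {dup}")
    return design


@dataclass
class QuantExperiment:
    """A protein x TMT-channel relative-intensity matrix plus its design.

    ``intensity`` is indexed by protein ID with one column per channel;
    ``design`` maps each channel to (genotype, treatment, replicate,
    experiment_id).  ``normalized``/``log2`` record the processing state so
    each stage can enforce its preconditions.
    """

    intensity: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False
    log2: bool = False

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        if self.intensity.index.duplicated().any():
            dup = self.intensity.index[self.intensity.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein IDs: {dup}")
        chans = set(self.intensity.columns)
        design_chans = set(self.design["channel_id"])
        missing = chans - design_chans
        if missing:
            raise ValueError(
                f"channel(s) missing from design: {sorted(missing)}"
            )
        extra = design_chans - chans
        if extra:
            raise ValueError(f"design channel(s) absent from table: {sorted(extra)}")
        vals = self.intensity.to_numpy(dtype=float)
        if not self.log2 and np.nanmin(vals, initial=np.inf) < 0:
            raise ValueError("negative intensities are not allowed before log2")

    @property
    def proteins(self) -> pd.Index:
        return self.intensity.index

    @property
    def channels(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def experiment_id(self) -> str:
        return str(self.design["experiment_id"].iloc[0])

    def channels_for(self, genotype: str, treatment: str) -> list[str]:
        d = self.design
        sel = (d["genotype"] == genotype) & (d["treatment"] == treatment)
        return d.loc[sel, "channel_id"].tolist()

    def conditions(self) -> list[tuple[str, str]]:
        """Unique (genotype, treatment) pairs in design order."""
        pairs = self.design[["genotype", "treatment"]].drop_duplicates()
        return list(pairs.itertuples(index=False, name=None))

    def with_intensity(self, intensity: pd.DataFrame, **flags) -> "QuantExperiment":
        return replace(self, intensity=intensity, **flags)


@dataclass
class ZScoreMatrix:
    """Per-protein standardized profile (the observed values of the RMSE fit).

    Each complete row has mean 0 and sample SD 1 across the experiment's
    channels; standardization is within one experiment (one TMT plex).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    source_experiment_id: str = ""

    def channels_for(self, genotype: str, treatment: str) -> list[str]:
        d = self.design
        sel = (d["genotype"] == genotype) & (d["treatment"] == treatment)
        return d.loc[sel, "channel_id"].tolist()

    def conditions(self) -> list[tuple[str, str]]:
        pairs = self.design[["genotype", "treatment"]].drop_duplicates()
        return list(pairs.itertuples(index=False, name=None))


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t", dtype={"channel_id": str}))


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_quant_table(path, design_path) -> QuantExperiment:
    """Read a protein x channel TSV plus its design file.

    The header row names the channels and the first column holds protein IDs.
    Empty cells become missing values; any other non-numeric entry is a hard
    error naming the offending column.
    """
    design = read_design(design_path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for col in raw.columns:
        try:
            raw[col] = pd.to_numeric(raw[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric entry in channel {col!r}: {exc}") from exc
    return QuantExperiment(intensity=raw.astype(float), design=design)


def write_quant_table(exp: QuantExperiment, path, design_path=None) -> None:
    out = exp.intensity.copy()
    out.index.name = out.index.name or "protein_id"
    out.to_csv(path, sep="\t")
    if design_path is not None:
        write_design(exp.design, design_path)


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {"true": True, "false": False, "1": True, "0": False,
               "yes": True, "no": False}
    return series.astype(str).str.strip().str.lower().map(mapping).astype(bool)


def validate_annotations(
    ann: pd.DataFrame, aliases: dict[str, str] | None = None
) -> pd.DataFrame:
    """Enforce the annotation invariants; map unknown compartments to "other".

    ``aliases`` optionally maps free-text compartment labels onto the
    controlled vocabulary before the unknown->other fallback applies.
    """
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    ann = ann.copy()
    if ann.index.duplicated().any():
        raise ValueError("duplicate protein IDs in annotation table")
    if aliases:
        ann["compartment"] = ann["compartment"].replace(aliases)
    unknown = ~ann["compartment"].isin(COMPARTMENTS)
    if unknown.any():
        labels = sorted(ann.loc[unknown, "compartment"].unique())
        logger.warning(
            "mapping %d unknown compartment label(s) to 'other': %s",
            int(unknown.sum()), labels,
        )
        ann.loc[unknown, "compartment"] = "other"
        # a demoted label can no longer carry a Golgi class
        ann.loc[unknown, "golgi_class"] = "not_golgi"
    bad_class = ~ann["golgi_class"].isin(GOLGI_CLASSES)
    if bad_class.any():
        raise ValueError(
            f"unknown golgi_class: {sorted(ann.loc[bad_class, 'golgi_class'].unique())}"
        )
    for col in ("known_fluxer", "histone"):
        ann[col] = _as_bool(ann[col])
    ann["tm_count"] = ann["tm_count"].astype(int)
    if (ann["tm_count"] < 0).any():
        raise ValueError("tm_count must be non-negative")

    is_golgi = ann["compartment"] == "Golgi"
    not_golgi_class = ann["golgi_class"] == "not_golgi"
    if (is_golgi & not_golgi_class).any() or ((~is_golgi) & (~not_golgi_class)).any():
        bad = ann.index[(is_golgi == not_golgi_class)].tolist()
        raise ValueError(
            f"golgi_class must be not_golgi exactly for non-Golgi proteins: {bad}"
        )
    assoc = ann["golgi_class"] == "associated"
    if (ann.loc[assoc, "tm_count"] != 0).any():
        bad = ann.index[assoc & (ann["tm_count"] != 0)].tolist()
        raise ValueError(f"Golgi-associated proteins cannot have TM segments: {bad}")
    hist = ann["histone"]
    if ann.loc[hist, "molar_mass"].isna().any():
        bad = ann.index[hist & ann["molar_mass"].isna()].tolist()
        raise ValueError(f"histone rows require a molar mass: {bad}")
    mm = ann["molar_mass"]
    if (mm.dropna() <= 0).any():
        raise ValueError("molar_mass must be positive (g/mol)")
    return ann


def read_annotations(path, aliases: dict[str, str] | None = None) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    return validate_annotations(ann, aliases=aliases)


def write_annotations(ann: pd.DataFrame, path) -> None:
    out = ann.copy()
    out.index.name = out.index.name or "protein_id"
    out.to_csv(path, sep="\t")


def validate_peptides(pep: pd.DataFrame, channels: list[str] | None = None) -> pd.DataFrame:
    for col in ("peptide_id", "protein_id", "ms1_area"):
        if col not in pep.columns:
            raise ValueError(f"peptide table missing column {col!r}")
    if pep["peptide_id"].duplicated().any():
        raise ValueError("each peptide must map to exactly one protein (duplicate peptide_id)")
    if (pep["ms1_area"] < 0).any():
        raise ValueError("ms1_area must be non-negative")
    if channels is not None:
        missing = set(channels) - set(pep.columns)
        if missing:
            raise ValueError(f"peptide table missing reporter channels: {sorted(missing)}")
    return pep


def read_peptides(path, channels: list[str] | None = None) -> pd.DataFrame:
    return validate_peptides(pd.read_csv(path, sep="\t"), channels=channels)


def write_peptides(pep: pd.DataFrame, path) -> None:
    pep.to_csv(path, sep="\t", index=False)
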