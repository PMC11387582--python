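"""Core in-memory containers for the pipeline.

The central object is :class:`IntensityMatrix`, a proteins x samples grid of
log2 label-free quantification (LFQ) abundances with an explicit missingness
mask.  Zeros in raw LFQ exports mean "not quantified", never "absent at zero
copies", so missing cells are carried as NaN and excluded from every
statistic unless a stage explicitly imputes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["IntensityMatrix", "read_intensity_tsv", "read_metadata_tsv"]

#: canonical metadata columns (one row per sample)
METADATA_COLUMNS = [
    "sample_id",
    "patient_id",
    "subtype",
    "timepoint",
    "age_years",
    "sex",
    "smn2_copies",
    "bmi_group",
    "motor_score",
    "responder",
]

SUBTYPES = ("SMA1", "SMA2", "SMA3")
TIMEPOINTS = ("T0", "T302")


@dataclass
class IntensityMatrix:
    """Proteins x samples log2-abundance grid with missingness as NaN.

    Parameters
    ----------
    values
        DataFrame indexed by unique protein IDs with unique sample-ID
        columns.  Finite entries are log2 abundances; NaN means the protein
        was not quantified in that sample.
    """

    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate protein IDs in intensity matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in intensity matrix")
        self.values = self.values.astype(float)

    @property
    def protein_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean observed-ness grid (True = quantified)."""
        return self.values.notna()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[:, list(sample_ids)])

    def subset_proteins(self, protein_ids) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(protein_ids)])

    def to_raw_frame(self) -> pd.DataFrame:
        """Back-transform to a raw-scale table with zeros for missing cells."""
        raw = np.exp2(self.values)
        return raw.fillna(0.0)

    def write_tsv(self, path: str | Path, raw_scale: bool = False) -> None:
        frame = self.to_raw_frame() if raw_scale else self.values
        frame.to_csv(path, sep="\t", index_label="protein_id")


def read_intensity_tsv(path: str | Path) -> pd.DataFrame:
    """Read a raw intensity TSV (proteins x samples, zeros = missing)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.index.has_duplicates:
        raise ValueError(f"duplicate protein IDs in {path}")
    return frame.astype(float)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "patient_id", "subtype", "timepoint"} - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing required columns: {sorted(missing)}")
    return meta
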