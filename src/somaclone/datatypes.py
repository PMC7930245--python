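"""Core data containers shared by every pipeline stage.

The pipeline's common currency is a :class:`VariantTable`: a sites x samples
matrix of (alt read count, total depth) pairs plus per-site annotations.
Sample-level metadata (tissue, sex, matched-reference status) lives in
:class:`SampleMeta` and drives the sex-aware depth thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOME = "autosome"

#: site annotation columns every VariantTable carries
SITE_COLUMNS = ("chrom", "pos", "ref", "alt", "chrom_class")


def chrom_class(chrom: str) -> str:
    """Classify a chromosome name as ``autosome``, ``X`` or ``Y``."""
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    if c in ("X", "x"):
        return "X"
    if c in ("Y", "y"):
        return "Y"
    return AUTOSOME


class VariantTable:
    """Sites x samples matrix of alt counts and depths with site annotations.

    Parameters
    ----------
    sites:
        DataFrame indexed by mutation id with columns ``chrom`` (str),
        ``pos`` (1-based int), ``ref``, ``alt`` (single bases) and
        optionally ``chrom_class`` (derived from ``chrom`` when absent).
    alt, depth:
        Integer DataFrames (sites x samples) sharing the site index; the
        alt-count matrix must be cell-wise bounded by the depth matrix.
    """

    def __init__(self, sites: pd.DataFrame, alt: pd.DataFrame, depth: pd.DataFrame):
        sites = sites.copy()
        if "chrom_class" not in sites.columns:
            sites["chrom_class"] = [chrom_class(c) for c in sites["chrom"]]
        if not (sites.index.equals(alt.index) and sites.index.equals(depth.index)):
            raise ValueError("sites, alt and depth must share one index")
        if list(alt.columns) != list(depth.columns):
            raise ValueError("alt and depth must share sample columns")
        key = sites[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate site {dup}")
        alt = alt.astype(np.int64)
        depth = depth.astype(np.int64)
        if (alt.to_numpy() < 0).any() or (depth.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (alt.to_numpy() > depth.to_numpy()).any():
            raise ValueError("alt count exceeds depth")
        self.sites = sites
        self.alt = alt
        self.depth = depth

    # -- basic views -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.alt.columns)

    @property
    def site_ids(self) -> pd.Index:
        return self.sites.index

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def vaf(self) -> pd.DataFrame:
        """Naive per-cell variant allele fraction; 0 where depth is 0."""
        d = self.depth.to_numpy().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(d > 0, self.alt.to_numpy() / np.maximum(d, 1), 0.0)
        return pd.DataFrame(v, index=self.site_ids, columns=self.samples)

    def subset(self, ids) -> "VariantTable":
        """Return a new table restricted to ``ids`` (index labels or bool mask)."""
        return VariantTable(self.sites.loc[ids], self.alt.loc[ids], self.depth.loc[ids])

    def equals(self, other: "VariantTable") -> bool:
        return (
            self.sites.equals(other.sites)
            and self.alt.equals(other.alt)
            and self.depth.equals(other.depth)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"VariantTable({self.n_sites} sites x {len(self.samples)} samples)"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    tissue: str
    is_matched_reference: bool = False
    sex: str = "female"


@dataclass
class SampleMeta:
    """Per-sample metadata for one patient.

    All samples belong to a single patient, so ``sex`` must be uniform.
    """

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self):
        if not self.samples:
            raise ValueError("at least one sample is required")
        sexes = {s.sex for s in self.samples}
        if not sexes <= {"male", "female"}:
            raise ValueError(f"unknown sex value(s): {sexes}")
        if len(sexes) != 1:
            raise ValueError("sex must be uniform within one patient")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")

    @property
    def sex(self) -> str:
        return self.samples[0].sex

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def matched_reference_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.is_matched_reference]

    def tissue_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.tissue
        raise KeyError(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "tissue": [s.tissue for s in self.samples],
                "is_matched_reference": [s.is_matched_reference for s in self.samples],
                "sex": [s.sex for s in self.samples],
            }
        ).set_index("sample_id")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleMeta":
        frame = frame.reset_index() if frame.index.name == "sample_id" else frame
        return cls(
            [
                Sample(
                    sample_id=str(r["sample_id"]),
                    tissue=str(r["tissue"]),
                    is_matched_reference=bool(r["is_matched_reference"]),
                    sex=str(r["sex"]),
                )
                for _, r in frame.iterrows()
            ]
        )
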