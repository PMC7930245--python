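"""Reading and writing the pipeline's standard formats.

Variant tables travel either as a TSV dialect (site annotations followed by
``<sample>:alt`` / ``<sample>:dp`` column pairs) or as a multi-sample VCF
with per-sample AD/DP FORMAT fields (read through cyvcf2; coordinates stay
1-based). Sample metadata is a TSV; exclusion regions are BED, 0-based
half-open, converted on read.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import Sample, SampleMeta, VariantTable, chrom_class


class FormatError(ValueError):
    """Malformed input file; the message names the offending record."""


# ---------------------------------------------------------------------------
# TSV variant tables

_SITE_COLS = ["mutation_id", "chrom", "pos", "ref", "alt", "chrom_class"]


def write_variant_tsv(table: VariantTable, path) -> None:
    out = table.sites.copy()
    for s in table.samples:
        out[f"{s}:alt"] = table.alt[s]
        out[f"{s}:dp"] = table.depth[s]
    out.index.name = "mutation_id"
    out.to_csv(path, sep="\t")


def read_variant_tsv(path) -> VariantTable:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _SITE_COLS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    sample_cols = [c for c in raw.columns if c.endswith(":alt")]
    samples = [c[:-4] for c in sample_cols]
    if not samples:
        raise FormatError(f"{path}: no '<sample>:alt' columns found")
    for s in samples:
        if f"{s}:dp" not in raw.columns:
            raise FormatError(f"{path}: sample {s} lacks a depth column '{s}:dp'")

    def to_int(col: str) -> np.ndarray:
        vals = np.empty(len(raw), dtype=np.int64)
        for i, v in enumerate(raw[col]):
            try:
                vals[i] = int(v)
            except (TypeError, ValueError):
                # +2: one for the header row, one for 1-based numbering
                raise FormatError(
                    f"{path}: line {i + 2}: non-integer value {v!r} in column {col}"
                ) from None
        return vals

    sites = pd.DataFrame(
        {
            "chrom": raw["chrom"].astype(str).to_numpy(),
            "pos": to_int("pos"),
            "ref": raw["ref"].astype(str).to_numpy(),
            "alt": raw["alt"].astype(str).to_numpy(),
            "chrom_class": raw["chrom_class"].astype(str).to_numpy(),
        },
        index=pd.Index(raw["mutation_id"], name="mutation_id"),
    )
    alt = pd.DataFrame(
        {s: to_int(f"{s}:alt") for s in samples}, index=sites.index
    )
    depth = pd.DataFrame(
        {s: to_int(f"{s}:dp") for s in samples}, index=sites.index
    )
    try:
        return VariantTable(sites, alt, depth)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""


def write_vcf(table: VariantTable, path) -> None:
    """Write a minimal multi-sample VCF with per-sample AD and DP."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in pd.unique(table.sites["chrom"]):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        alt = table.alt.to_numpy()
        depth = table.depth.to_numpy()
        for i, (mid, row) in enumerate(table.sites.iterrows()):
            cells = [
                f"{depth[i, j] - alt[i, j]},{alt[i, j]}:{depth[i, j]}"
                for j in range(alt.shape[1])
            ]
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{mid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tAD:DP\t" + "\t".join(cells) + "\n"
            )


def read_vcf(path, apply_caller_filters: bool = True) -> VariantTable:
    """Read a multi-sample VCF with AD (and optionally DP) FORMAT fields.

    When ``apply_caller_filters`` is set, records carrying the upstream
    caller's alignment annotations are screened as a pass-through:
    ASMD < 140 or CLPM != 0 drops the record. These flags are never
    computed here — they require read alignments.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    alt_rows, dp_rows = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(f"{path}: {rec.CHROM}:{rec.POS}: expected one ALT allele")
        if apply_caller_filters:
            asmd = rec.INFO.get("ASMD")
            clpm = rec.INFO.get("CLPM")
            if (asmd is not None and asmd < 140) or (clpm is not None and clpm != 0):
                continue
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(
                f"{path}: {rec.CHROM}:{rec.POS}: record lacks the AD FORMAT field"
            )
        ad = np.asarray(ad, dtype=np.int64)
        ad[ad < 0] = 0  # htslib encodes missing values as negative
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        depth = (
            np.asarray(dp, dtype=np.int64).reshape(-1)
            if dp is not None
            else ad.sum(axis=1)
        )
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        alt_rows.append(ad[:, 1])
        dp_rows.append(np.maximum(depth, ad[:, 1]))
    if not ids:
        raise FormatError(f"{path}: no usable records")
    index = pd.Index(ids, name="mutation_id")
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "ref": refs,
            "alt": alts,
            "chrom_class": [chrom_class(c) for c in chroms],
        },
        index=index,
    )
    return VariantTable(
        sites,
        pd.DataFrame(np.stack(alt_rows), index=index, columns=samples),
        pd.DataFrame(np.stack(dp_rows), index=index, columns=samples),
    )


# ---------------------------------------------------------------------------
# sample metadata, BED exclusions

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no"}


def write_sample_meta(meta: SampleMeta, path) -> None:
    meta.to_frame().to_csv(path, sep="\t")


def read_sample_meta(path) -> SampleMeta:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample_id", "tissue", "is_matched_reference", "sex"}
    if not need <= set(raw.columns):
        raise FormatError(f"{path}: need columns {sorted(need)}")
    samples = []
    for i, r in raw.iterrows():
        flag = str(r["is_matched_reference"]).strip().lower()
        if flag not in _TRUTHY | _FALSY:
            raise FormatError(
                f"{path}: line {i + 2}: bad is_matched_reference value {flag!r}"
            )
        samples.append(
            Sample(
                sample_id=r["sample_id"],
                tissue=r["tissue"],
                is_matched_reference=flag in _TRUTHY,
                sex=str(r["sex"]).strip().lower(),
            )
        )
    try:
        return SampleMeta(samples)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e


def read_bed(path) -> list[tuple[str, int, int]]:
    """Read exclusion regions; BED is 0-based half-open."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: need chrom, start, end")
            try:
                regions.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
    return regions


def exclude_regions(table: VariantTable, regions: list[tuple[str, int, int]]) -> VariantTable:
    """Drop sites falling inside any region (1-based site vs 0-based BED)."""
    if not regions:
        return table
    drop = np.zeros(table.n_sites, dtype=bool)
    chrom = table.sites["chrom"].to_numpy()
    pos0 = table.sites["pos"].to_numpy() - 1  # convert to 0-based
    for c, start, end in regions:
        drop |= (chrom == c) & (pos0 >= start) & (pos0 < end)
    return table.subset(~drop)


def read_variant_input(path, format: str | None = None) -> VariantTable:
    """Dispatch on format ('vcf' or 'tsv'; guessed from the suffix)."""
    if format is None:
        format = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        return read_variant_tsv(path)
    raise ValueError(f"unknown variant-table format {format!r}")
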