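"""Reading, validation and representation of MPRA count data.

A count table is a TSV with columns ``variant_id  allele  barcode``
followed by one integer column per sequencing sample.  Each sample is
either a DNA (plasmid library) or RNA (transcribed output) sample; the
mapping is supplied as a two-column TSV (``sample_id  DNA|RNA``) or as a
dict.  Barcode rows act as replicates: a variant needs at least one
barcode per allele to be analyzable, and rows of variants violating
this are dropped with a warning.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .nb import VariantData

logger = logging.getLogger(__name__)

META_COLUMNS = ["variant_id", "allele", "barcode"]
ALLELES = ("ref", "alt")


class CountTableError(ValueError):
    """Malformed or invalid count-table input."""


@dataclass
class CountTable:
    """Barcode-by-sample count matrix with variant/allele metadata.

    ``frame`` holds the metadata columns plus one integer column per
    sample; ``sample_types`` maps sample_id -> "DNA" | "RNA".
    """

    frame: pd.DataFrame
    sample_types: pd.Series

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_types.index)

    @property
    def dna_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_types[s] == "DNA"]

    @property
    def rna_ids(self) -> list[str]:
        return [s for s in self.sample_ids if self.sample_types[s] == "RNA"]

    @property
    def variant_ids(self) -> list[str]:
        return sorted(self.frame["variant_id"].unique())

    @property
    def n_barcodes(self) -> int:
        return len(self.frame)

    def counts(self, sample_ids=None) -> np.ndarray:
        ids = sample_ids if sample_ids is not None else self.sample_ids
        return self.frame[ids].to_numpy(dtype=float)

    def variant_data(self, variant_id: str, depths: pd.Series) -> VariantData:
        """Extract one variant's counts and depth factors for model fitting."""
        rows = self.frame[self.frame["variant_id"] == variant_id]
        if rows.empty:
            raise KeyError(f"unknown variant {variant_id!r}")
        return VariantData(
            variant_id=variant_id,
            dna=rows[self.dna_ids].to_numpy(dtype=float),
            rna=rows[self.rna_ids].to_numpy(dtype=float),
            alt=(rows["allele"] == "alt").to_numpy(),
            d_dna=depths[self.dna_ids].to_numpy(dtype=float),
            d_rna=depths[self.rna_ids].to_numpy(dtype=float),
        )

    def iter_variant_data(self, depths: pd.Series):
        groups = self.frame.groupby("variant_id").indices
        dna = self.frame[self.dna_ids].to_numpy(dtype=float)
        rna = self.frame[self.rna_ids].to_numpy(dtype=float)
        alt = (self.frame["allele"] == "alt").to_numpy()
        d_dna = depths[self.dna_ids].to_numpy(dtype=float)
        d_rna = depths[self.rna_ids].to_numpy(dtype=float)
        for vid in self.variant_ids:
            rows = groups[vid]
            yield VariantData(
                variant_id=vid, dna=dna[rows], rna=rna[rows], alt=alt[rows],
                d_dna=d_dna, d_rna=d_rna,
            )


def validate_count_table(
    frame: pd.DataFrame, sample_types: pd.Series | dict
) -> tuple[CountTable, int]:
    """Validate a raw frame; returns the table plus the number of dropped rows.

    Enforces: integer non-negative counts, unique barcodes, >=1 DNA and
    >=2 RNA samples, and >=1 barcode per allele per variant (variants
    violating the last rule are dropped, not fatal).
    """
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise CountTableError(f"missing required columns: {missing}")
    sample_types = pd.Series(dict(sample_types), dtype=object)
    bad_types = sorted(set(sample_types) - {"DNA", "RNA"})
    if bad_types:
        raise CountTableError(f"sample types must be DNA or RNA, got {bad_types}")
    sample_ids = [c for c in frame.columns if c not in META_COLUMNS]
    unknown = [s for s in sample_ids if s not in sample_types.index]
    if unknown:
        raise CountTableError(f"samples without a DNA/RNA type: {unknown}")
    sample_types = sample_types.loc[sample_ids]
    if (sample_types == "DNA").sum() < 1 or (sample_types == "RNA").sum() < 2:
        raise CountTableError("need at least 1 DNA and 2 RNA samples")

    bad_allele = ~frame["allele"].isin(ALLELES)
    if bad_allele.any():
        raise CountTableError(
            f"allele must be one of {ALLELES}; offending rows: {list(frame.index[bad_allele][:5])}"
        )
    for col in sample_ids:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals != np.floor(vals))
        if bad.any():
            row = frame.index[bad][0]
            raise CountTableError(
                f"non-integer or negative count in column {col!r}, row {row}: {frame.loc[row, col]!r}"
            )
    frame = frame.copy()
    frame[sample_ids] = frame[sample_ids].astype(np.int64)

    dup = frame["barcode"].duplicated()
    if dup.any():
        raise CountTableError(f"duplicate barcodes: {sorted(frame['barcode'][dup].unique()[:5])}")

    # Allele-pair completeness: every retained variant has ref and alt barcodes.
    per_variant = frame.groupby("variant_id")["allele"].agg(lambda a: set(a))
    incomplete = per_variant.index[per_variant.apply(lambda s: len(s) < 2)]
    n_dropped = 0
    if len(incomplete):
        mask = frame["variant_id"].isin(incomplete)
        n_dropped = int(mask.sum())
        warnings.warn(
            f"dropping {n_dropped} barcode rows from {len(incomplete)} variants "
            f"missing one allele (e.g. {list(incomplete[:3])})",
            stacklevel=2,
        )
        frame = frame[~mask]
    if frame.empty:
        raise CountTableError("no variants with both alleles present")
    return CountTable(frame.reset_index(drop=True), sample_types), n_dropped


def read_count_table(
    path, sample_types: dict | pd.Series | None = None, sample_map_path=None
) -> tuple[CountTable, int]:
    """Read a TSV count table; sample types from a map file or dict."""
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in META_COLUMNS})
    if sample_types is None:
        if sample_map_path is None:
            raise CountTableError("provide sample_types or sample_map_path")
        sm = pd.read_csv(sample_map_path, sep="\t", header=None, names=["sample_id", "type"])
        sample_types = pd.Series(sm["type"].values, index=sm["sample_id"].astype(str))
    return validate_count_table(frame, sample_types)


def write_count_table(table: CountTable, path, sample_map_path=None) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
    if sample_map_path is not None:
        table.sample_types.rename("type").to_csv(
            sample_map_path, sep="\t", header=False
        )


def compute_depth_factors(table: CountTable) -> pd.Series:
    """Per-sample depth factors, normalized to geometric mean 1 within each sample type.

    d_s = (column total of sample s) / geomean(column totals of same-type samples),
    so a depth-1 sample is the "average" sample of its type and the DNA->RNA
    scale difference is absorbed by the allele-level transcription parameters.
    """
    totals = table.frame[table.sample_ids].sum(axis=0).astype(float)
    if (totals <= 0).any():
        zeroed = list(totals.index[totals <= 0])
        raise CountTableError(f"samples with zero total counts: {zeroed}; remove them first")
    d = pd.Series(index=totals.index, dtype=float)
    for stype in ("DNA", "RNA"):
        ids = [s for s in table.sample_ids if table.sample_types[s] == stype]
        if ids:
            gm = np.exp(np.mean(np.log(totals[ids])))
            d[ids] = totals[ids] / gm
    return d


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTable:
    """Per-variant annotations: one categorical label or >=1 continuous columns."""

    frame: pd.DataFrame            # indexed by variant_id
    kind: str                      # "categorical" | "continuous"

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def values_for(self, variant_ids) -> np.ndarray:
        return self.frame.reindex(variant_ids).to_numpy()


def read_annotations(path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t", dtype={"variant_id": str})
    if "variant_id" not in frame.columns or frame.shape[1] < 2:
        raise CountTableError("annotation file needs variant_id plus >=1 value column")
    if frame["variant_id"].duplicated().any():
        dups = frame["variant_id"][frame["variant_id"].duplicated()].tolist()[:5]
        raise CountTableError(f"duplicate variant_id rows in annotations: {dups}")
    frame = frame.set_index("variant_id")
    numeric = frame.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    if numeric.notna().all().all():
        frame = numeric.astype(float)
        if not np.isfinite(frame.to_numpy()).all():
            raise CountTableError("continuous annotations must be finite")
        kind = "continuous"
    else:
        if frame.shape[1] != 1:
            raise CountTableError("categorical annotations must be a single label column")
        kind = "categorical"
    return AnnotationTable(frame, kind)


# ---------------------------------------------------------------------------
# Barcode counting from FASTQ
# ---------------------------------------------------------------------------

def count_barcodes(
    fastq_paths,
    barcode_map: dict,
    offset: int = 0,
    length: int | None = None,
) -> tuple[Counter, int, int]:
    """Exact-match barcode counting for one sequencing sample.

    The barcode is taken from each read at ``[offset, offset+length)``
    (0-based, half-open).  Reads shorter than ``offset + length`` are
    skipped and tallied separately.  Returns (counts per barcode,
    n_unmatched, n_too_short).
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if length is None:
        lengths = {len(b) for b in barcode_map}
        if len(lengths) != 1:
            raise ValueError("barcode_map has mixed lengths; pass length explicitly")
        length = lengths.pop()
    counts: Counter = Counter({bc: 0 for bc in barcode_map})
    n_unmatched = 0
    n_short = 0
    for path in fastq_paths:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                seq = str(rec.seq)
                if len(seq) < offset + length:
                    n_short += 1
                    continue
                bc = seq[offset : offset + length]
                if bc in counts:
                    counts[bc] += 1
                else:
                    n_unmatched += 1
    return counts, n_unmatched, n_short
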