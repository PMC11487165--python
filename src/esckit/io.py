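"""Domain containers and on-disk formats.

Every analysis module consumes only the in-memory types defined here:

* :class:`ExpressionMatrix` -- genes x samples log-scale normalized expression.
* :class:`GeneSetCollection` -- named gene sets (GMT convention).
* :class:`MutationTable` -- per-sample somatic mutation records with a closed
  variant-class vocabulary and optional ref/alt read counts.
* :class:`CopyNumberSegmentTable` -- per-sample segments with absolute copy
  values plus a per-sample mean ploidy.
* :class:`SampleSheet` -- per-sample cohort metadata (labels, survival,
  purity, IHC counts, arbitrary covariates).
* :class:`TileFeatureTable` -- per-tile numeric image features with
  slide/patient/group metadata.

All tabular formats are plain TSV.  Readers validate on load and never
silently drop rows; writers round-trip through the matching reader.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "MutationTable",
    "CopyNumberSegmentTable",
    "SampleSheet",
    "TileFeatureTable",
    "VARIANT_CLASSES",
    "VARIANT_CLASS_SYNONYMS",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_mutations",
    "write_mutations",
    "read_segments",
    "write_segments",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_tiles",
    "write_tiles",
]


class FormatError(ValueError):
    """A file violated its format contract (bad cell, duplicate id, ...)."""


# ---------------------------------------------------------------------------
# Expression


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale normalized expression.

    The package assumes values arrive already normalized and log-transformed;
    nothing here re-normalizes.  Missing or non-finite entries are rejected.
    """

    frame: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        idx, cols = self.frame.index, self.frame.columns
        if idx.duplicated().any():
            dupes = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if cols.duplicated().any():
            dupes = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        values = self.frame.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise FormatError(
                f"non-finite expression value at gene "
                f"{idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.frame.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.frame.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(self.frame.loc[genes])


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (header = sample ids, first column = gene ids)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    # Reparse strictly: any cell that failed numeric conversion -> error with location.
    try:
        numeric = frame.astype(float)
    except (ValueError, TypeError):
        for j, col in enumerate(frame.columns):
            converted = pd.to_numeric(frame[col], errors="coerce")
            bad = converted.isna() & frame[col].notna()
            if bad.any():
                row = frame.index[bad.argmax()]
                raise FormatError(
                    f"{path}: non-numeric cell at gene {row!r}, sample {col!r}"
                ) from None
        raise
    if numeric.isna().any().any():
        mask = numeric.isna()
        i = int(np.argwhere(mask.to_numpy())[0][0])
        j = int(np.argwhere(mask.to_numpy())[0][1])
        raise FormatError(
            f"{path}: missing value at gene {numeric.index[i]!r}, "
            f"sample {numeric.columns[j]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.frame.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Ordered mapping of set name -> :class:`GeneSet` (GMT semantics)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise FormatError(f"key {name!r} != set name {gs.name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def add(self, gs: GeneSet) -> None:
        if gs.name in self.sets:
            raise FormatError(f"duplicate gene set name {gs.name!r}")
        self.sets[gs.name] = gs

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with *universe*, dropping (with a warning) sets
        left empty."""
        universe = frozenset(universe)
        out = GeneSetCollection()
        for gs in self:
            genes = gs.genes & universe
            if genes:
                out.add(GeneSet(gs.name, gs.description, genes))
            else:
                warnings.warn(
                    f"gene set {gs.name!r} is disjoint from the universe; dropped",
                    stacklevel=2,
                )
        return out

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        coll = cls()
        for name, genes in d.items():
            coll.add(GeneSet(name, "", frozenset(genes)))
        return coll


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate gene entries within a line are deduplicated; duplicate set names
    and lines with fewer than three fields are errors.
    """
    path = Path(path)
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} field(s), "
                    "expected >= 3 (name, description, genes...)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in coll:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            coll.add(GeneSet(name, desc, frozenset(genes)))
    if len(coll) == 0:
        warnings.warn(f"{path}: GMT file contains no gene sets", stacklevel=2)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in coll:
            genes = "\t".join(sorted(gs.genes))
            fh.write(f"{gs.name}\t{gs.description}\t{genes}\n")


# ---------------------------------------------------------------------------
# Mutations

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift",
    "splice_site",
    "inframe_indel",
    "synonymous",
    "other",
)

#: Documented synonym map for MAF-style variant classifications (GDC dialect
#: and common lowercase spellings) onto the internal closed vocabulary.
VARIANT_CLASS_SYNONYMS: dict[str, str] = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "stop_gained": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
    "frameshift_variant": "frameshift",
    "splice_site": "splice_site",
    "splice_region": "splice_site",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "in_frame_del": "inframe_indel",
    "in_frame_ins": "inframe_indel",
    "inframe_indel": "inframe_indel",
    "silent": "synonymous",
    "synonymous": "synonymous",
    "synonymous_variant": "synonymous",
    "nonstop_mutation": "other",
    "translation_start_site": "other",
    "3'utr": "other",
    "5'utr": "other",
    "intron": "other",
    "igr": "other",
    "rna": "other",
    "other": "other",
}

#: classes treated as functionally relevant ("non-silent"): everything except
#: synonymous and other.
NON_SILENT_CLASSES = frozenset(VARIANT_CLASSES) - {"synonymous", "other"}

# Accepted column-name synonyms for MAF-like TSV input.
_MUT_COLUMN_SYNONYMS = {
    "sample": "sample",
    "tumor_sample_barcode": "sample",
    "sample_id": "sample",
    "gene": "gene",
    "hugo_symbol": "gene",
    "gene_id": "gene",
    "variant_class": "variant_class",
    "variant_classification": "variant_class",
    "t_ref_count": "ref_count",
    "ref_count": "ref_count",
    "t_alt_count": "alt_count",
    "alt_count": "alt_count",
    "deleterious": "deleterious",
}


@dataclass
class MutationTable:
    """Somatic mutation records, one row per mutation.

    Columns: ``sample``, ``gene``, ``variant_class`` (closed vocabulary),
    optional ``ref_count``/``alt_count`` (non-negative; NaN when absent) and
    optional ``deleterious`` (externally annotated 0/1).  A record's VAF is
    ``alt / (ref + alt)``, defined only when the read depth is positive.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample", "gene", "variant_class"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"mutation table missing columns: {sorted(missing)}")
        bad = ~self.frame["variant_class"].isin(VARIANT_CLASSES)
        if bad.any():
            raise FormatError(
                f"unknown variant_class values {sorted(self.frame.loc[bad, 'variant_class'].unique())}; "
                f"accepted: {list(VARIANT_CLASSES)}"
            )
        for col in ("ref_count", "alt_count"):
            if col not in self.frame.columns:
                self.frame[col] = np.nan
            vals = self.frame[col]
            if (vals.dropna() < 0).any():
                raise FormatError(f"negative {col} in mutation table")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def samples(self) -> list[str]:
        return sorted(self.frame["sample"].unique())

    def non_silent_mask(self) -> pd.Series:
        return self.frame["variant_class"].isin(NON_SILENT_CLASSES)

    def vaf(self) -> pd.Series:
        """Per-record VAF = alt/(ref+alt); NaN where depth is zero or missing."""
        depth = self.frame["ref_count"] + self.frame["alt_count"]
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.frame["alt_count"] / depth
        return v.where(depth > 0)

    def for_sample(self, sample: str) -> "MutationTable":
        return MutationTable(self.frame[self.frame["sample"] == sample].copy())


def read_mutations(path: str | Path) -> MutationTable:
    """Read a MAF-like mutation TSV.

    Column names are mapped through a documented synonym table (GDC-style
    ``Tumor_Sample_Barcode``/``Hugo_Symbol``/``Variant_Classification`` or
    lowercase internal names); variant-class strings likewise.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    rename = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _MUT_COLUMN_SYNONYMS:
            rename[col] = _MUT_COLUMN_SYNONYMS[key]
    frame = raw.rename(columns=rename)
    required = {"sample", "gene", "variant_class"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    mapped = frame["variant_class"].str.strip().str.lower().map(VARIANT_CLASS_SYNONYMS)
    unknown = frame.loc[mapped.isna(), "variant_class"].unique().tolist()
    if unknown:
        raise FormatError(
            f"{path}: unknown variant_class values {unknown[:5]}; accepted "
            f"vocabulary (after synonym mapping): {list(VARIANT_CLASSES)}"
        )
    frame["variant_class"] = mapped
    for col in ("ref_count", "alt_count"):
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="raise")
        else:
            frame[col] = np.nan
    keep = ["sample", "gene", "variant_class", "ref_count", "alt_count"]
    if "deleterious" in frame.columns:
        frame["deleterious"] = pd.to_numeric(frame["deleterious"], errors="raise")
        keep.append("deleterious")
    return MutationTable(frame[keep])


def write_mutations(muts: MutationTable, path: str | Path) -> None:
    muts.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Copy-number segments


@dataclass
class CopyNumberSegmentTable:
    """Per-sample copy-number segments (1-based inclusive coordinates) plus a
    per-sample mean ploidy.
    """

    frame: pd.DataFrame  # columns: sample, chrom, start, end, copy_value
    mean_ploidy: pd.Series  # index = sample id

    def __post_init__(self) -> None:
        required = {"sample", "chrom", "start", "end", "copy_value"}
        missing = required - set(self.frame.columns)
        if missing:
            raise FormatError(f"segment table missing columns: {sorted(missing)}")
        if (self.frame["start"] >= self.frame["end"]).any():
            raise FormatError("segment with start >= end")
        if (self.frame["copy_value"] <= 0).any():
            raise FormatError("segment copy_value must be > 0")
        have = set(self.frame["sample"].unique())
        no_ploidy = have - set(self.mean_ploidy.index)
        if no_ploidy:
            raise FormatError(f"samples without mean_ploidy: {sorted(no_ploidy)[:5]}")
        if (self.mean_ploidy <= 0).any():
            raise FormatError("mean_ploidy must be > 0")

    def to_half_open(self) -> pd.DataFrame:
        """Return the segments converted to 0-based half-open coordinates."""
        out = self.frame.copy()
        out["start"] = out["start"] - 1
        return out


def read_segments(path: str | Path) -> CopyNumberSegmentTable:
    """Read a segment TSV with columns sample, chrom, start, end, copy_value,
    mean_ploidy (ploidy repeated per sample)."""
    frame = pd.read_csv(path, sep="\t")
    if "mean_ploidy" not in frame.columns:
        raise FormatError(f"{path}: missing mean_ploidy column")
    ploidy = frame.groupby("sample")["mean_ploidy"].first()
    inconsistent = frame.groupby("sample")["mean_ploidy"].nunique() > 1
    if inconsistent.any():
        raise FormatError(
            f"{path}: inconsistent mean_ploidy within sample(s) "
            f"{list(inconsistent[inconsistent].index)[:5]}"
        )
    return CopyNumberSegmentTable(
        frame.drop(columns="mean_ploidy"), ploidy.astype(float)
    )


def write_segments(segs: CopyNumberSegmentTable, path: str | Path) -> None:
    out = segs.frame.copy()
    out["mean_ploidy"] = out["sample"].map(segs.mean_ploidy)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sample sheet


@dataclass
class SampleSheet:
    """Per-sample cohort metadata.

    Recognized columns (all optional except the unique sample index):
    ``subtype``, ``immune_cluster``, ``time`` (days), ``event`` (0/1),
    ``purity`` in [0, 1], ``ihc_<marker>`` counts, and arbitrary covariates.
    """

    frame: pd.DataFrame  # index = sample id

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        if "event" in self.frame.columns:
            ev = self.frame["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise FormatError("event column must be 0/1")
        if "time" in self.frame.columns:
            t = self.frame["time"].dropna()
            if (t < 0).any():
                raise FormatError("negative survival time")
        if "purity" in self.frame.columns:
            p = self.frame["purity"].dropna()
            if ((p < 0) | (p > 1)).any():
                raise FormatError("purity outside [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def survival(self) -> pd.DataFrame:
        """Return the (time, event) columns, rows with either missing dropped."""
        if not {"time", "event"} <= set(self.frame.columns):
            raise KeyError("sample sheet has no survival columns (time, event)")
        return self.frame[["time", "event"]].dropna()


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.frame.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Tile features


@dataclass
class TileFeatureTable:
    """Per-tile image-derived numeric features with slide/patient metadata.

    ``meta`` carries tile_id, slide_id, patient_id, optional group label and
    background_fraction; ``features`` is the aligned tiles x features block.
    Feature extraction itself (the CNN stage) is upstream of this contract.
    """

    meta: pd.DataFrame  # columns: tile_id, slide_id, patient_id, [group], background_fraction
    features: pd.DataFrame  # index aligned with meta, columns = feature names

    def __post_init__(self) -> None:
        required = {"tile_id", "slide_id", "patient_id", "background_fraction"}
        missing = required - set(self.meta.columns)
        if missing:
            raise FormatError(f"tile table missing meta columns: {sorted(missing)}")
        if len(self.meta) != len(self.features):
            raise FormatError("tile meta and feature blocks differ in length")
        if self.features.columns.duplicated().any():
            raise FormatError("duplicate feature names")
        bf = self.meta["background_fraction"]
        if ((bf < 0) | (bf > 1)).any():
            raise FormatError("background_fraction outside [0, 1]")
        if not np.isfinite(self.features.to_numpy()).all():
            raise FormatError("non-finite tile feature values")
        self.meta = self.meta.reset_index(drop=True)
        self.features = self.features.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.meta)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def select_rows(self, mask) -> "TileFeatureTable":
        return TileFeatureTable(
            self.meta.loc[mask].copy(), self.features.loc[mask].copy()
        )


def read_tiles(path: str | Path) -> TileFeatureTable:
    frame = pd.read_csv(path, sep="\t")
    meta_cols = [
        c
        for c in ("tile_id", "slide_id", "patient_id", "group", "background_fraction")
        if c in frame.columns
    ]
    feature_cols = [c for c in frame.columns if c not in meta_cols]
    return TileFeatureTable(frame[meta_cols], frame[feature_cols].astype(float))


def write_tiles(tiles: TileFeatureTable, path: str | Path) -> None:
    pd.concat([tiles.meta, tiles.features], axis=1).to_csv(path, sep="\t", index=False)
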