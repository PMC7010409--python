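"""Reading, validating and writing SEG-style segment tables and annotations.

The canonical in-memory container is a :class:`SampleTable`: a pandas
DataFrame of segments (one row per copy-number segment, 1-based inclusive
coordinates) plus a per-sample annotation frame. Input follows the common
segmentation-output convention with mandatory columns ``ID``, ``chr``,
``loc.start``, ``loc.end`` and ``seg.mean`` (case-insensitive), and optional
``purity`` and ``BAF`` columns. Any further column is collapsed into a
per-sample annotation variable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

#: canonical name -> accepted (lower-cased) header aliases
_HEADER_ALIASES = {
    "sample_id": ("id", "sample", "sample_id", "sampleid"),
    "chrom": ("chr", "chrom", "chromosome"),
    "start": ("loc.start", "start", "loc_start"),
    "end": ("loc.end", "end", "loc_end"),
    "seg_mean": ("seg.mean", "seg_mean", "segmean", "log2ratio"),
    "purity": ("purity",),
    "baf": ("baf",),
}
MANDATORY = ("sample_id", "chrom", "start", "end", "seg_mean")
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "seg_mean", "purity", "baf"]

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y"}


@dataclass
class SampleTable:
    """Segments of a cohort plus per-sample annotations.

    ``segments`` columns: sample_id, chrom, start, end, seg_mean, purity, baf
    (purity/baf are NaN when absent). ``annotations`` is indexed by sample_id.
    """

    segments: pd.DataFrame
    annotations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(index=pd.Index([], name="sample_id"))
    )

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.segments["sample_id"]))

    def __len__(self) -> int:
        return len(self.segments)

    def per_sample(self):
        """Iterate (sample_id, segment frame) in input order."""
        for sid, sub in self.segments.groupby("sample_id", sort=False):
            yield sid, sub

    def with_segments(self, segments: pd.DataFrame) -> "SampleTable":
        return SampleTable(segments.reset_index(drop=True), self.annotations)


def normalize_chrom(value) -> str | None:
    """Normalize a chromosome label to ``chr``-prefixed form.

    Returns None for mitochondrial contigs (rejected upstream with a warning)
    and raises for anything else unrecognized.
    """
    name = str(value).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() in {"M", "MT"}:
        return None
    if name.upper() in {"X", "Y"}:
        return "chr" + name.upper()
    if name in _VALID_CHROMS:
        return "chr" + name
    raise ValidationError(f"unrecognized chromosome name {value!r}")


def _match_headers(columns) -> dict[str, str]:
    lower = {str(c).strip().lower(): c for c in columns}
    mapping = {}
    for canon, aliases in _HEADER_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                mapping[canon] = lower[alias]
                break
    missing = [c for c in MANDATORY if c not in mapping]
    if missing:
        raise SchemaError(
            "missing mandatory column(s): "
            + ", ".join(missing)
            + f" (found headers: {list(columns)})"
        )
    return mapping


def _check_numeric(series: pd.Series, name: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0])
        raise ParseError(
            f"non-numeric {name} value {series.iloc[row]!r} at row {row}"
        )
    return out


def validate_no_overlaps(segments: pd.DataFrame) -> None:
    """Raise :class:`ValidationError` if any sample has overlapping segments
    on one chromosome (1-based inclusive coordinates)."""
    offenders = []
    for (sid, chrom), sub in segments.groupby(["sample_id", "chrom"], sort=False):
        sub = sub.sort_values("start")
        prev_end = sub["end"].values[:-1]
        nxt_start = sub["start"].values[1:]
        bad = nxt_start <= prev_end
        if bad.any():
            for i in np.flatnonzero(bad):
                offenders.append(
                    f"{sid} {chrom}:{sub['start'].values[i]}-{prev_end[i]} overlaps "
                    f"{chrom}:{nxt_start[i]}-{sub['end'].values[i + 1]}"
                )
    if offenders:
        raise ValidationError(
            "overlapping segments within a sample/chromosome: "
            + "; ".join(offenders[:10])
        )


def _collapse_per_sample(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    """Collapse per-segment annotation columns to one value per sample
    (first value wins; inconsistencies warn)."""
    records = {}
    for sid, sub in df.groupby("sample_id", sort=False):
        row = {}
        for col in cols:
            vals = sub[col].dropna().unique()
            if len(vals) > 1:
                warnings.warn(
                    f"annotation {col!r} is inconsistent across segments of "
                    f"sample {sid}; keeping first value {vals[0]!r}",
                    stacklevel=3,
                )
            row[col] = vals[0] if len(vals) else np.nan
        records[sid] = row
    ann = pd.DataFrame.from_dict(records, orient="index")
    ann.index.name = "sample_id"
    # type numeric columns when every non-missing value parses as a number
    for col in ann.columns:
        coerced = pd.to_numeric(ann[col], errors="coerce")
        if coerced.notna().equals(ann[col].notna()):
            ann[col] = coerced
    return ann


def read_segments(path, dialect: str | None = None) -> SampleTable:
    """Read a SEG-style TSV/CSV segment table.

    Parameters
    ----------
    path : str or Path
        Input file with headers ID, chr, loc.start, loc.end, seg.mean and
        optional purity/BAF plus annotation columns.
    dialect : {"tsv", "csv"}, optional
        Field separator; inferred from the file extension (default tab).
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise SchemaError(f"unknown dialect {dialect!r} (use 'tsv' or 'csv')")
    raw = pd.read_csv(path, sep="\t" if dialect == "tsv" else ",", dtype=object)
    mapping = _match_headers(raw.columns)
    df = pd.DataFrame({canon: raw[orig] for canon, orig in mapping.items()})

    df["sample_id"] = df["sample_id"].astype(str)
    chroms = df["chrom"].map(normalize_chrom)
    if chroms.isna().any():
        n = int(chroms.isna().sum())
        warnings.warn(
            f"dropping {n} mitochondrial segment(s); chrM is not scored",
            stacklevel=2,
        )
    df["chrom"] = chroms
    df = df[df["chrom"].notna()].reset_index(drop=True)

    for col in ("start", "end", "seg_mean"):
        df[col] = _check_numeric(df[col], col)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["seg_mean"] = df["seg_mean"].astype(float)
    if not np.isfinite(df["seg_mean"]).all():
        row = int(np.flatnonzero(~np.isfinite(df["seg_mean"].values))[0])
        raise ParseError(f"non-finite seg.mean at row {row}")
    if (df["start"] < 1).any() or (df["end"] < df["start"]).any():
        raise ValidationError("coordinates must satisfy 1 <= start <= end")

    for col in ("purity", "baf"):
        if col in df.columns:
            df[col] = _check_numeric(df[col], col).astype(float)
        else:
            df[col] = np.nan
    pur = df["purity"].dropna()
    if ((pur <= 0) | (pur > 1)).any():
        raise ValidationError("purity values must lie in (0, 1]")
    baf = df["baf"].dropna()
    if ((baf < 0) | (baf > 1)).any():
        raise ValidationError("BAF values must lie in [0, 1]")
    if (baf > 0.5).any():
        # raw B-allele frequencies: fold to deviation from the 0.5 band
        df["baf"] = (df["baf"] - 0.5).abs()

    df = df.sort_values(["sample_id", "chrom", "start"], kind="stable").reset_index(
        drop=True
    )
    validate_no_overlaps(df)

    extra = [c for c in raw.columns if c not in mapping.values()]
    if extra:
        ann_src = raw[extra].copy()
        ann_src["sample_id"] = raw[mapping["sample_id"]].astype(str)
        annotations = _collapse_per_sample(ann_src, extra)
    else:
        annotations = pd.DataFrame(index=pd.Index(df["sample_id"].unique(),
                                                  name="sample_id"))
    return SampleTable(df[SEGMENT_COLUMNS], annotations)


def write_segments(table: SampleTable, path) -> None:
    """Write segments back out as a SEG-style TSV (mandatory fields exact)."""
    df = table.segments
    out = pd.DataFrame(
        {
            "ID": df["sample_id"],
            "chr": df["chrom"],
            "loc.start": df["start"],
            "loc.end": df["end"],
            "seg.mean": df["seg_mean"].map(repr),
        }
    )
    for col, name in (("purity", "purity"), ("baf", "BAF")):
        if df[col].notna().any():
            out[name] = df[col]
    out.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    """Read a per-sample annotation table (first column = sample id).

    Variables are typed numeric when every non-missing value parses as a
    number, categorical (string) otherwise.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        raw = pd.read_csv(path, sep=sep, dtype=object)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"no samples in annotation file {path}") from None
    if raw.empty:
        raise SchemaError(f"no samples in annotation file {path}")
    sid_col = raw.columns[0]
    ids = raw[sid_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicated sample_id {dup!r} in annotation file")
    ann = raw.drop(columns=[sid_col])
    ann.index = pd.Index(ids, name="sample_id")
    for col in ann.columns:
        coerced = pd.to_numeric(ann[col], errors="coerce")
        if coerced.notna().equals(ann[col].notna()):
            ann[col] = coerced
    return ann


def attach_annotations(table: SampleTable, annotations: pd.DataFrame) -> SampleTable:
    """Merge an external annotation frame into a SampleTable.

    Annotated samples absent from the segment table are reported via warning.
    """
    known = set(table.samples)
    orphan = [s for s in annotations.index if s not in known]
    if orphan:
        warnings.warn(
            f"{len(orphan)} annotated sample(s) have no segments: "
            + ", ".join(map(str, orphan[:5])),
            stacklevel=2,
        )
    merged = table.annotations.join(annotations, how="outer")
    return SampleTable(table.segments, merged)
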