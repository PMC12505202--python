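"""MADC (missing allele discovery counts) read-count I/O.

The MADC dialect is a plain CSV with one row per discovered microhaplotype:

    AlleleID,CloneID,AlleleSequence,<sample_1>,...,<sample_n>

``AlleleID`` is ``<locus_id>|<class>`` where class is ``Ref`` (exact
reference match), ``Alt`` (one variant at the target SNP) or ``Other_k``
(additional off-target variants).  Only the Ref and Alt microhaplotypes are
used for genotyping; Other rows are tallied in the parse report and
otherwise ignored.

Sample sheets are TSV with columns
``sample_id, group, nominal_ploidy, parent1, parent2``; marker tables are
TSV with columns ``locus_id, chrom, pos, ref, alt, flags``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_AMPLICON_LEN = 81

_LOCUS_POS_RE = re.compile(r"^(?P<chrom>.+?)[_:](?P<pos>\d+)$")


@dataclass(frozen=True)
class MarkerDef:
    """A target SNP locus on the panel."""

    locus_id: str
    chrom: str = ""
    pos: int = 0
    ref_allele: str = "N"
    alt_allele: str = "N"
    flags: frozenset = field(default_factory=frozenset)
    amplicon_len: int = DEFAULT_AMPLICON_LEN

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"{self.locus_id}: pos must be >= 1 (or 0 for unknown)")


@dataclass
class ParseReport:
    """Bookkeeping from a MADC parse."""

    n_loci: int = 0
    n_samples: int = 0
    n_other_rows: int = 0
    other_counts_total: int = 0
    loci_missing_alt: list = field(default_factory=list)
    warnings: list = field(default_factory=list)


class CountMatrix:
    """Per-locus, per-sample Ref/Alt read counts.

    Both matrices are loci x samples integer DataFrames sharing a locus_id
    index and sample_id columns.
    """

    def __init__(self, ref: pd.DataFrame, alt: pd.DataFrame):
        if not ref.index.equals(alt.index) or not ref.columns.equals(alt.columns):
            raise ValueError("ref and alt matrices must share index and columns")
        if (ref.to_numpy() < 0).any() or (alt.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        self.ref = ref
        self.alt = alt

    @property
    def loci(self) -> pd.Index:
        return self.ref.index

    @property
    def samples(self) -> pd.Index:
        return self.ref.columns

    @property
    def shape(self):
        return self.ref.shape

    def total(self) -> pd.DataFrame:
        """Ref + Alt depth per cell (Other microhaplotypes excluded)."""
        return self.ref + self.alt

    def subset(self, loci=None, samples=None) -> "CountMatrix":
        ref, alt = self.ref, self.alt
        if loci is not None:
            ref, alt = ref.loc[loci], alt.loc[loci]
        if samples is not None:
            ref, alt = ref[samples], alt[samples]
        return CountMatrix(ref.copy(), alt.copy())

    def alt_fraction(self, min_reads: int = 1) -> pd.DataFrame:
        """Alt / (Ref+Alt), NaN where depth < min_reads."""
        tot = self.total().to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.alt.to_numpy(dtype=float) / tot
        frac[tot < min_reads] = np.nan
        return pd.DataFrame(frac, index=self.loci, columns=self.samples)

    def __eq__(self, other):
        return (isinstance(other, CountMatrix)
                and self.ref.equals(other.ref) and self.alt.equals(other.alt))


# ---------------------------------------------------------------------------
# sample sheets and marker tables

SHEET_COLUMNS = ["sample_id", "group", "nominal_ploidy", "parent1", "parent2"]
_VALID_PLOIDIES = {1, 2, 3, 4, 6}


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, unique ids and legal ploidies; returns a copy
    indexed by sample_id."""
    df = sheet.copy()
    if df.index.name != "sample_id":
        if "sample_id" not in df.columns:
            raise ValueError("sample sheet needs a sample_id column")
        df = df.set_index("sample_id")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dup}")
    for col in ("group", "nominal_ploidy"):
        if col not in df.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    bad = set(df["nominal_ploidy"]) - _VALID_PLOIDIES
    if bad:
        raise ValueError(f"unsupported nominal_ploidy values: {sorted(bad)}")
    for col in ("parent1", "parent2"):
        if col not in df.columns:
            df[col] = ""
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, keep_default_na=False)
    df["nominal_ploidy"] = df["nominal_ploidy"].astype(int)
    return validate_sample_sheet(df)


def write_sample_sheet(path, sheet: pd.DataFrame) -> None:
    validate_sample_sheet(sheet).reset_index().to_csv(path, sep="\t", index=False)


def total_gametes(sheet: pd.DataFrame) -> int:
    """Total gamete count G = sum of nominal ploidies; a singleton allele has
    frequency 1/G in the panel."""
    return int(sheet["nominal_ploidy"].sum())


def markers_to_frame(markers) -> pd.DataFrame:
    rows = [{"locus_id": m.locus_id, "chrom": m.chrom, "pos": m.pos,
             "ref": m.ref_allele, "alt": m.alt_allele,
             "flags": ";".join(sorted(m.flags))} for m in markers]
    return pd.DataFrame(rows).set_index("locus_id")


def read_marker_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        flags = frozenset(f for f in str(row.get("flags", "")).split(";") if f)
        out.append(MarkerDef(row["locus_id"], row.get("chrom", ""),
                             int(row["pos"]), row.get("ref", "N"),
                             row.get("alt", "N"), flags))
    return out


def write_marker_table(path, markers) -> None:
    markers_to_frame(markers).reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MADC parsing


def _marker_from_id(locus_id: str) -> MarkerDef:
    m = _LOCUS_POS_RE.match(locus_id)
    if m:
        return MarkerDef(locus_id, m.group("chrom"), int(m.group("pos")))
    return MarkerDef(locus_id)


def read_madc(path, sheet: pd.DataFrame, markers=None):
    """Parse a MADC CSV into (markers, CountMatrix, ParseReport).

    Ref/Alt microhaplotype rows populate the count matrix; Other rows are
    tallied in the report only.  A locus with no Alt row gets zero alt
    counts (no Alt observations) and a warning.  Duplicate Ref or Alt rows
    for a locus are a hard error, as is a sample column absent from the
    sample sheet.
    """
    sheet = validate_sample_sheet(sheet)
    df = pd.read_csv(path, dtype={"AlleleID": str, "CloneID": str,
                                  "AlleleSequence": str})
    meta_cols = ["AlleleID", "CloneID", "AlleleSequence"]
    for col in meta_cols[:1]:
        if col not in df.columns:
            raise ValueError(f"not a MADC file: missing column {col!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    unknown = [c for c in sample_cols if c not in sheet.index]
    if unknown:
        raise ValueError(f"samples in MADC file absent from sample sheet: {unknown}")

    parts = df["AlleleID"].str.rsplit("|", n=1, expand=True)
    if parts.shape[1] != 2 or parts[1].isna().any():
        bad = df["AlleleID"][parts.shape[1] != 2 or parts[1].isna()]
        raise ValueError("malformed AlleleID (expected '<locus>|<class>')")
    df["_locus"] = parts[0]
    df["_class"] = parts[1]

    report = ParseReport(n_samples=len(sample_cols))
    locus_order = df["_locus"].drop_duplicates().tolist()
    counts = df[sample_cols].to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError("non-numeric count cells in MADC file")
    if (counts < 0).any():
        raise ValueError("negative count cells in MADC file")

    ref_rows, alt_rows = {}, {}
    for i, (locus, cls) in enumerate(zip(df["_locus"], df["_class"])):
        if cls == "Ref":
            if locus in ref_rows:
                raise ValueError(f"duplicate Ref row for locus {locus}")
            ref_rows[locus] = counts[i]
        elif cls == "Alt":
            if locus in alt_rows:
                raise ValueError(f"duplicate Alt row for locus {locus}")
            alt_rows[locus] = counts[i]
        elif cls.startswith("Other"):
            report.n_other_rows += 1
            report.other_counts_total += int(counts[i].sum())
        else:
            raise ValueError(f"unknown microhaplotype class {cls!r} for {locus}")

    zeros = np.zeros(len(sample_cols), dtype=int)
    ref = np.vstack([ref_rows.get(l, zeros) for l in locus_order])
    alt = np.vstack([alt_rows.get(l, zeros) for l in locus_order])
    for locus in locus_order:
        if locus not in alt_rows:
            report.loci_missing_alt.append(locus)
            msg = f"locus {locus} has no Alt microhaplotype row; alt counts set to 0"
            report.warnings.append(msg)
            warnings.warn(msg)

    report.n_loci = len(locus_order)
    idx = pd.Index(locus_order, name="locus_id")
    cm = CountMatrix(pd.DataFrame(ref.astype(int), index=idx, columns=sample_cols),
                     pd.DataFrame(alt.astype(int), index=idx, columns=sample_cols))

    if markers is not None:
        by_id = {m.locus_id: m for m in markers}
        marker_list = [by_id.get(l, _marker_from_id(l)) for l in locus_order]
    else:
        marker_list = [_marker_from_id(l) for l in locus_order]
    return marker_list, cm, report


def write_madc(path, markers, counts: CountMatrix, sequences=None) -> None:
    """Write Ref/Alt rows in the MADC dialect (round-trips read_madc)."""
    seqs = sequences or {}
    rows = []
    for m in markers:
        base = seqs.get(m.locus_id, "N" * m.amplicon_len)
        rows.append([f"{m.locus_id}|Ref", m.locus_id, base]
                    + counts.ref.loc[m.locus_id].tolist())
        rows.append([f"{m.locus_id}|Alt", m.locus_id, base]
                    + counts.alt.loc[m.locus_id].tolist())
    header = ["AlleleID", "CloneID", "AlleleSequence"] + list(counts.samples)
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# target-SNP deduplication


def dedup_window(markers, window_bp: int = 15):
    """Retain one target SNP per window_bp window along each chromosome.

    Greedy left-to-right scan in ascending position (ties broken by
    locus_id): a marker is removed when its position lies within window_bp
    (inclusive) of the last kept marker on the same chromosome.  Partially
    overlapping microhaplotypes therefore never both survive.

    Returns (kept, removed), a partition of the input in original order.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    for m in markers:
        if m.pos is None or m.pos < 1:
            raise ValueError(f"marker {m.locus_id} lacks a position")
    keep_ids = set()
    by_chrom = {}
    for m in markers:
        by_chrom.setdefault(m.chrom, []).append(m)
    for chrom_markers in by_chrom.values():
        chrom_markers.sort(key=lambda m: (m.pos, m.locus_id))
        last_kept = None
        for m in chrom_markers:
            if last_kept is None or m.pos - last_kept > window_bp:
                keep_ids.add(m.locus_id)
                last_kept = m.pos
    kept = [m for m in markers if m.locus_id in keep_ids]
    removed = [m for m in markers if m.locus_id not in keep_ids]
    return kept, removed
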