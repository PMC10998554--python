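"""Readers and writers for single-cell V(D)J contig tables and feature-barcode matrices.

Two contig dialects are supported: the Cell Ranger ``filtered_contig_annotations.csv``
layout (``tenx_csv``) and a flat AIRR Rearrangement TSV (``airr_tsv``).  Feature
counts travel as MatrixMarket coordinate files with sidecar ``features.tsv`` /
``barcodes.tsv``, following the 10x convention of features-by-cells orientation
on disk; in memory counts are indexed (cell, feature).

Both writers are deterministic: identical inputs produce identical bytes, and
``read ∘ write`` is the identity on record fields.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("nanotcr")

PMHC_BARCODE = "pmhc_barcode"
SECRETION_BARCODE = "secretion_barcode"
FEATURE_CLASSES = (PMHC_BARCODE, SECRETION_BARCODE)
TR_LOCI = ("TRA", "TRB")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """An in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainRecord:
    """One assembled TCR contig for one cell.

    ``locus`` is normally TRA or TRB; records with other loci (e.g. IGH from a
    contaminating B cell) are retained on read and flagged for exclusion by
    :func:`nanotcr.clonotypes.filter_chains`.
    """

    cell_barcode: str
    contig_id: str
    locus: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    reads: int
    umis: int
    d_gene: str = ""
    c_gene: str = ""
    productive: bool = True
    full_length: bool = True
    high_confidence: bool = True
    is_cell: bool = True
    length: int = 0
    raw_clonotype_id: str = ""

    def validate(self) -> None:
        if self.locus not in TR_LOCI:
            raise ValidationError(f"locus must be TRA or TRB, got {self.locus!r}")
        if self.reads < 0 or self.umis < 0:
            raise ValidationError("reads and umis must be nonnegative")
        if self.reads and self.umis > self.reads:
            raise ValidationError(
                f"{self.contig_id}: umis ({self.umis}) exceed reads ({self.reads})"
            )
        if self.productive:
            n = len(self.cdr3_nt)
            if n == 0 or n % 3:
                raise ValidationError(
                    f"{self.contig_id}: productive CDR3 nt length {n} not a positive multiple of 3"
                )
            if len(self.cdr3_aa) != n // 3:
                raise ValidationError(
                    f"{self.contig_id}: CDR3 aa length {len(self.cdr3_aa)} != nt length {n}/3"
                )


class Feature(NamedTuple):
    feature_id: str
    feature_class: str
    display_label: str


@dataclass
class FeatureCounts:
    """Per-cell counts over a registry of pMHC-identity and secretion features."""

    cell_barcodes: list[str]
    features: list[Feature]
    counts: np.ndarray  # (n_cells, n_features), nonnegative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.cell_barcodes), len(self.features)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_barcodes)} cells x {len(self.features)} features"
            )
        if (self.counts < 0).any():
            raise ValidationError("counts must be nonnegative")
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValidationError("cell barcodes must be unique")
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValidationError("feature ids must be unique")
        for f in self.features:
            if f.feature_class not in FEATURE_CLASSES:
                raise ValidationError(f"unknown feature class {f.feature_class!r}")
        self._cell_index = {b: i for i, b in enumerate(self.cell_barcodes)}
        self._feature_index = {f.feature_id: j for j, f in enumerate(self.features)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_barcodes)

    def __contains__(self, cell_barcode: str) -> bool:
        return cell_barcode in self._cell_index

    def count(self, cell_barcode: str, feature_id: str) -> int:
        return int(self.counts[self._cell_index[cell_barcode], self._feature_index[feature_id]])

    def features_of_class(self, feature_class: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == feature_class]

    def class_counts(self, cell_barcode: str, feature_class: str) -> dict[str, int]:
        """Counts for one cell restricted to one feature class."""
        if cell_barcode not in self._cell_index:
            raise KeyError(f"unknown cell barcode {cell_barcode!r}")
        row = self.counts[self._cell_index[cell_barcode]]
        return {
            f.feature_id: int(row[j])
            for j, f in enumerate(self.features)
            if f.feature_class == feature_class
        }


# ---------------------------------------------------------------------------
# Contig tables
# ---------------------------------------------------------------------------

TENX_COLUMNS = [
    "barcode", "is_cell", "contig_id", "high_confidence", "length", "chain",
    "v_gene", "d_gene", "j_gene", "c_gene", "full_length", "productive",
    "cdr3", "cdr3_nt", "reads", "umis", "raw_clonotype_id",
]

AIRR_COLUMNS = [
    "cell_id", "sequence_id", "locus", "v_call", "d_call", "j_call", "c_call",
    "junction_aa", "junction", "productive", "complete_vdj", "consensus_count",
    "duplicate_count", "high_confidence", "is_cell",
]

_TRUE = {"True", "TRUE", "true", "T"}
_FALSE = {"False", "FALSE", "false", "F", ""}


def _parse_bool(value: str, column: str, line: int) -> bool:
    if value in _TRUE:
        return True
    if value in _FALSE:
        return False
    raise FormatError(f"line {line}: unparsable boolean {value!r} in column {column}")


def _parse_int(value: str, column: str, line: int) -> int:
    try:
        return int(value) if value else 0
    except ValueError:
        raise FormatError(f"line {line}: unparsable integer {value!r} in column {column}") from None


def read_contig_table(path: str | Path, dialect: str = "tenx_csv") -> list[ChainRecord]:
    """Read a contig annotation table into :class:`ChainRecord` rows.

    Rows whose locus is outside {TRA, TRB} are retained (their ``locus`` field
    carries the original value) and are removed later by ``filter_chains``.
    """
    if dialect not in ("tenx_csv", "airr_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "tenx_csv" else "\t"
    required = TENX_COLUMNS if dialect == "tenx_csv" else AIRR_COLUMNS
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s): {', '.join(extra)}", stacklevel=2)

    records: list[ChainRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        r = row._asdict()
        if dialect == "tenx_csv":
            rec = ChainRecord(
                cell_barcode=r["barcode"],
                contig_id=r["contig_id"],
                locus=r["chain"],
                v_gene=r["v_gene"],
                d_gene=r["d_gene"],
                j_gene=r["j_gene"],
                c_gene=r["c_gene"],
                cdr3_aa=r["cdr3"],
                cdr3_nt=r["cdr3_nt"],
                reads=_parse_int(r["reads"], "reads", line),
                umis=_parse_int(r["umis"], "umis", line),
                productive=_parse_bool(r["productive"], "productive", line),
                full_length=_parse_bool(r["full_length"], "full_length", line),
                high_confidence=_parse_bool(r["high_confidence"], "high_confidence", line),
                is_cell=_parse_bool(r["is_cell"], "is_cell", line),
                length=_parse_int(r["length"], "length", line),
                raw_clonotype_id=r["raw_clonotype_id"],
            )
        else:
            rec = ChainRecord(
                cell_barcode=r["cell_id"],
                contig_id=r["sequence_id"],
                locus=r["locus"],
                v_gene=r["v_call"],
                d_gene=r["d_call"],
                j_gene=r["j_call"],
                c_gene=r["c_call"],
                cdr3_aa=r["junction_aa"],
                cdr3_nt=r["junction"],
                reads=_parse_int(r["consensus_count"], "consensus_count", line),
                umis=_parse_int(r["duplicate_count"], "duplicate_count", line),
                productive=_parse_bool(r["productive"], "productive", line),
                full_length=_parse_bool(r["complete_vdj"], "complete_vdj", line),
                high_confidence=_parse_bool(r["high_confidence"], "high_confidence", line),
                is_cell=_parse_bool(r["is_cell"], "is_cell", line),
            )
        records.append(rec)
    return records


def _bool_str(value: bool, dialect: str) -> str:
    if dialect == "airr_tsv":
        return "T" if value else "F"
    return "True" if value else "False"


def write_contig_table(records: Sequence[ChainRecord], path: str | Path,
                       dialect: str = "tenx_csv") -> None:
    """Write records in the given dialect with a fixed column order (byte-stable)."""
    if dialect not in ("tenx_csv", "airr_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "," if dialect == "tenx_csv" else "\t"
    columns = TENX_COLUMNS if dialect == "tenx_csv" else AIRR_COLUMNS
    rows = []
    for rec in records:
        if dialect == "tenx_csv":
            rows.append({
                "barcode": rec.cell_barcode, "is_cell": _bool_str(rec.is_cell, dialect),
                "contig_id": rec.contig_id,
                "high_confidence": _bool_str(rec.high_confidence, dialect),
                "length": rec.length, "chain": rec.locus, "v_gene": rec.v_gene,
                "d_gene": rec.d_gene, "j_gene": rec.j_gene, "c_gene": rec.c_gene,
                "full_length": _bool_str(rec.full_length, dialect),
                "productive": _bool_str(rec.productive, dialect),
                "cdr3": rec.cdr3_aa, "cdr3_nt": rec.cdr3_nt,
                "reads": rec.reads, "umis": rec.umis,
                "raw_clonotype_id": rec.raw_clonotype_id,
            })
        else:
            rows.append({
                "cell_id": rec.cell_barcode, "sequence_id": rec.contig_id,
                "locus": rec.locus, "v_call": rec.v_gene, "d_call": rec.d_gene,
                "j_call": rec.j_gene, "c_call": rec.c_gene,
                "junction_aa": rec.cdr3_aa, "junction": rec.cdr3_nt,
                "productive": _bool_str(rec.productive, dialect),
                "complete_vdj": _bool_str(rec.full_length, dialect),
                "consensus_count": rec.reads, "duplicate_count": rec.umis,
                "high_confidence": _bool_str(rec.high_confidence, dialect),
                "is_cell": _bool_str(rec.is_cell, dialect),
            })
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Feature matrices
# ---------------------------------------------------------------------------

def read_feature_matrix(mtx_path: str | Path, features_path: str | Path,
                        barcodes_path: str | Path,
                        class_map: Mapping[str, str] | None = None) -> FeatureCounts:
    """Read a 10x-style feature-barcode triplet into :class:`FeatureCounts`.

    The MTX file is features-by-cells (10x convention).  Feature class comes
    from a third column of ``features.tsv`` when present, otherwise from
    ``class_map`` (feature_id -> class); one of the two must assign a class to
    every feature.
    """
    matrix = scipy.sparse.coo_matrix(scipy.io.mmread(str(mtx_path)))
    feat_df = pd.read_csv(features_path, sep="\t", header=None, dtype=str,
                          keep_default_na=False)
    if feat_df.shape[1] < 2:
        raise FormatError(f"{features_path}: expected >=2 tab-separated columns")
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str,
                           keep_default_na=False)[0].tolist()
    n_features, n_cells = matrix.shape
    if n_features != len(feat_df):
        raise FormatError(
            f"matrix has {n_features} features but features.tsv has {len(feat_df)} rows")
    if n_cells != len(barcodes):
        raise FormatError(
            f"matrix has {n_cells} cells but barcodes.tsv has {len(barcodes)} rows")

    features = []
    for _, row in feat_df.iterrows():
        fid, label = row[0], row[1]
        if feat_df.shape[1] >= 3 and row[2]:
            fclass = row[2]
        elif class_map and fid in class_map:
            fclass = class_map[fid]
        else:
            raise FormatError(
                f"feature {fid!r}: no class column and no class_map entry")
        if fclass not in FEATURE_CLASSES:
            raise FormatError(f"feature {fid!r}: unknown class {fclass!r}")
        features.append(Feature(fid, fclass, label))

    counts = np.asarray(matrix.T.todense(), dtype=np.int64)
    return FeatureCounts(cell_barcodes=barcodes, features=features, counts=counts)


def write_feature_matrix(fc: FeatureCounts, dir_path: str | Path) -> None:
    """Write ``matrix.mtx``, ``features.tsv`` (3 columns incl. class) and
    ``barcodes.tsv`` under ``dir_path``.  Deterministic byte output."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(fc.counts.T)  # features x cells on disk
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, sparse, field="integer")
    (dir_path / "matrix.mtx").write_bytes(buf.getvalue())
    with open(dir_path / "features.tsv", "w", newline="\n") as fh:
        for f in fc.features:
            fh.write(f"{f.feature_id}\t{f.display_label}\t{f.feature_class}\n")
    with open(dir_path / "barcodes.tsv", "w", newline="\n") as fh:
        for b in fc.cell_barcodes:
            fh.write(b + "\n")


def read_feature_matrix_dir(dir_path: str | Path,
                            class_map: Mapping[str, str] | None = None) -> FeatureCounts:
    """Convenience wrapper for a directory written by :func:`write_feature_matrix`."""
    dir_path = Path(dir_path)
    return read_feature_matrix(dir_path / "matrix.mtx", dir_path / "features.tsv",
                               dir_path / "barcodes.tsv", class_map=class_map)
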