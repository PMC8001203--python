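"""Readers and writers for the formats the pipeline touches.

Genotypes come in as a minimal VCF (GT-only FORMAT, biallelic) or as a
samples x variants CSV/TSV of {0,1,2,NA} codes; the clinical table is a
CSV with a documented closed-vocabulary schema.  Readers reject malformed
input with a location-bearing message — there is no silent coercion.
Writers are deterministic: fixed column order, fixed float formatting, no
timestamps.

VCF genotype codes count the ALT allele; reorientation to the minor allele
happens exactly once, in :meth:`cypgx.genetics.GenotypeMatrix.orient_minor`.
"""

from __future__ import annotations

import csv
import dataclasses
import difflib
import io as _io
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .genetics import MISSING, GenotypeMatrix

THERAPIES = ("nact", "adjuvant_cytotoxic", "hormonal_only", "none")
SUBTYPES = ("LumA", "LumB", "HER2", "TNBC")
RESPONSES = ("good", "poor")
FUNCTIONAL_CLASSES = (
    "intronic", "exonic", "UTR3", "UTR5", "upstream", "downstream",
    "intergenic", "splicing",
)
CODING_CONSEQUENCES = (
    "non-synonymous SNV", "synonymous SNV", "stop-gain",
    "frameshift deletion", "frameshift insertion",
    "non-frameshift deletion", "unknown",
)

CLINICAL_COLUMNS = (
    "sample_id", "response", "dfs_months", "dfs_event", "therapy", "subtype",
    "tumor_size", "grade", "node_positive", "er_positive",
)

_MISSING_MARKERS = {"", "NA", "na", "NaN", "nan", "./.", None}

__all__ = [
    "VariantAnnotation",
    "ClinicalRecord",
    "read_genotypes_vcf",
    "read_genotypes_table",
    "write_genotypes_table",
    "write_genotypes_vcf",
    "read_clinical",
    "write_clinical",
    "read_annotations",
    "write_report",
    "SchemaError",
]


class SchemaError(ValueError):
    """Malformed or out-of-vocabulary input; the message carries the location."""


@dataclass(frozen=True)
class VariantAnnotation:
    variant_id: str
    gene: str
    functional_class: str
    coding_consequence: str | None = None
    novel: bool = False

    def __post_init__(self):
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise SchemaError(
                f"unknown functional class {self.functional_class!r} for "
                f"{self.variant_id}{_suggest(self.functional_class, FUNCTIONAL_CLASSES)}"
            )
        if (self.functional_class == "exonic") != (self.coding_consequence is not None):
            raise SchemaError(
                f"{self.variant_id}: coding consequence must be present iff the "
                f"variant is exonic (class={self.functional_class!r})"
            )
        if self.coding_consequence is not None and self.coding_consequence not in CODING_CONSEQUENCES:
            raise SchemaError(
                f"unknown coding consequence {self.coding_consequence!r} for "
                f"{self.variant_id}{_suggest(self.coding_consequence, CODING_CONSEQUENCES)}"
            )


@dataclass
class ClinicalRecord:
    """One patient's clinical row.

    ``response`` is defined only for NACT-treated patients (good = CR/PR,
    poor = SD/PD) and is None otherwise.  DFS is months from surgery to
    first relapse; ``dfs_event`` 1 = relapse observed, 0 = censored.
    """

    sample_id: str
    response: str | None = None
    dfs_months: float | None = None
    dfs_event: int | None = None
    therapy: str = "none"
    subtype: str | None = None
    tumor_size: float | None = None
    grade: int | None = None
    node_positive: int | None = None
    er_positive: int | None = None
    extras: dict | None = None

    def __post_init__(self):
        if self.response is not None and self.response not in RESPONSES:
            raise SchemaError(
                f"{self.sample_id}: unknown response {self.response!r}"
                f"{_suggest(self.response, RESPONSES)}"
            )
        if self.therapy not in THERAPIES:
            raise SchemaError(
                f"{self.sample_id}: unknown therapy {self.therapy!r}"
                f"{_suggest(self.therapy, THERAPIES)}"
            )
        if self.subtype is not None and self.subtype not in SUBTYPES:
            raise SchemaError(
                f"{self.sample_id}: unknown subtype {self.subtype!r}"
                f"{_suggest(self.subtype, SUBTYPES)}"
            )
        if self.dfs_months is not None and self.dfs_months <= 0:
            raise SchemaError(f"{self.sample_id}: dfs_months must be positive")
        if self.dfs_event is not None and self.dfs_months is None:
            raise SchemaError(f"{self.sample_id}: dfs_event given without dfs_months")
        if self.dfs_event is not None and self.dfs_event not in (0, 1):
            raise SchemaError(f"{self.sample_id}: dfs_event must be 0 or 1")


def _suggest(value, vocabulary) -> str:
    close = difflib.get_close_matches(str(value), vocabulary, n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a biallelic GT-only VCF into a genotype matrix (ALT-count codes).

    Multi-allelic records and records without GT are rejected with the
    variant's position; 1-based coordinates are kept as metadata.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    metadata: dict[str, dict] = {}
    for i, rec in enumerate(vcf, start=1):
        where = f"record {i} at {rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise SchemaError(f"{where}: multi-allelic record (ALT={rec.ALT}); split upstream")
        if "GT" not in (rec.FORMAT or []):
            raise SchemaError(f"{where}: no GT in FORMAT")
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in metadata:
            raise SchemaError(f"{where}: duplicate variant id {vid!r}")
        col = np.full(len(samples), MISSING, dtype=np.int8)
        for s, gt in enumerate(rec.genotypes):  # [allele_a, allele_b, phased]
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            col[s] = a + b
        variant_ids.append(vid)
        columns.append(col)
        metadata[vid] = {"chrom": rec.CHROM, "pos": rec.POS, "ref": rec.REF, "alt": rec.ALT[0]}
    if not variant_ids:
        raise SchemaError(f"{path}: no variant records")
    values = np.column_stack(columns)
    return GenotypeMatrix(samples, variant_ids, values, metadata=metadata)


def write_genotypes_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT-only FORMAT (codes count ALT)."""
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids),
    ]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    for j, vid in enumerate(matrix.variant_ids):
        meta = matrix.metadata.get(vid, {})
        chrom = str(meta.get("chrom", "1"))
        pos = str(meta.get("pos", j + 1))
        ref = str(meta.get("ref", "A"))
        alt = str(meta.get("alt", "G"))
        gts = "\t".join(gt_strings[int(v)] for v in matrix.values[:, j])
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_genotypes_table(path: str | Path) -> GenotypeMatrix:
    """Samples-in-rows, variants-in-columns table of {0,1,2,NA} codes."""
    text = Path(path).read_text()
    if not text.strip():
        raise SchemaError(f"{path}: empty file")
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(_io.StringIO(text), delimiter=delim))
    header = rows[0]
    if len(header) < 2:
        raise SchemaError(f"{path}: header needs a sample column plus >=1 variant")
    variant_ids = header[1:]
    sample_ids, data = [], []
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SchemaError(f"{path} line {r}: {len(row)} fields, expected {len(header)}")
        sample_ids.append(row[0])
        codes = []
        for c, cell in enumerate(row[1:], start=2):
            cell = cell.strip()
            if cell in _MISSING_MARKERS:
                codes.append(MISSING)
            elif cell in ("0", "1", "2"):
                codes.append(int(cell))
            else:
                raise SchemaError(
                    f"{path} line {r}, column {header[c - 1]!r}: invalid genotype {cell!r}"
                )
        data.append(codes)
    if not data:
        raise SchemaError(f"{path}: no sample rows")
    return GenotypeMatrix(sample_ids, variant_ids, np.array(data, dtype=np.int8))


def write_genotypes_table(matrix: GenotypeMatrix, path: str | Path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        w.writerow(["sample_id"] + list(matrix.variant_ids))
        for i, sid in enumerate(matrix.sample_ids):
            w.writerow([sid] + ["NA" if v == MISSING else str(int(v)) for v in matrix.values[i]])


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def _parse_cell(value, kind, sample_id, column):
    if value in _MISSING_MARKERS:
        return None
    try:
        return kind(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{sample_id}: invalid {column} value {value!r}") from None


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the clinical CSV; unknown columns are preserved under extras."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise SchemaError(f"{path}: missing required sample_id column")
        extras_cols = [c for c in reader.fieldnames if c not in CLINICAL_COLUMNS]
        records = []
        for r, row in enumerate(reader, start=2):
            sid = row.get("sample_id", "")
            if not sid:
                raise SchemaError(f"{path} line {r}: empty sample_id")
            norm = {
                k: (None if (v is None or v.strip() in _MISSING_MARKERS) else v.strip())
                for k, v in row.items()
            }
            records.append(
                ClinicalRecord(
                    sample_id=sid,
                    response=norm.get("response"),
                    dfs_months=_parse_cell(norm.get("dfs_months"), float, sid, "dfs_months"),
                    dfs_event=_parse_cell(norm.get("dfs_event"), int, sid, "dfs_event"),
                    therapy=norm.get("therapy") or "none",
                    subtype=norm.get("subtype"),
                    tumor_size=_parse_cell(norm.get("tumor_size"), float, sid, "tumor_size"),
                    grade=_parse_cell(norm.get("grade"), int, sid, "grade"),
                    node_positive=_parse_cell(norm.get("node_positive"), int, sid, "node_positive"),
                    er_positive=_parse_cell(norm.get("er_positive"), int, sid, "er_positive"),
                    extras={c: norm.get(c) for c in extras_cols} if extras_cols else None,
                )
            )
    if len({r.sample_id for r in records}) != len(records):
        raise SchemaError(f"{path}: duplicate sample ids")
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        if math.isnan(value):
            return ""
        return f"{value:.6g}"
    return str(value)


def write_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CLINICAL_COLUMNS)
        for rec in records:
            w.writerow([_fmt(getattr(rec, c)) for c in CLINICAL_COLUMNS])


def read_annotations(path: str | Path) -> list[VariantAnnotation]:
    """Annotation CSV: variant_id, gene, functional_class[, coding_consequence, novel]."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            cc = row.get("coding_consequence") or None
            out.append(
                VariantAnnotation(
                    variant_id=row["variant_id"],
                    gene=row["gene"],
                    functional_class=row["functional_class"],
                    coding_consequence=cc if cc not in _MISSING_MARKERS else None,
                    novel=row.get("novel", "0") in ("1", "true", "True"),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = "1"


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            return None
        return float(f"{v:.6g}")
    return obj


def write_report(results, path: str | Path, fmt: str = "tsv") -> None:
    """Write analysis results deterministically as TSV or JSON.

    TSV expects a list of flat dicts (or dataclasses); column order is the
    first row's key order, floats are printed to 6 significant digits.
    JSON nests arbitrarily and carries a schema version.
    """
    if fmt == "json":
        payload = {"schema_version": REPORT_SCHEMA_VERSION, "results": _to_plain(results)}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return
    if fmt != "tsv":
        raise ValueError(f"unknown report format {fmt!r}")
    rows = [_to_plain(r) for r in results]
    rows = [r for r in rows if isinstance(r, dict)]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if not rows:
            w.writerow(["empty"])
            return
        cols = list(rows[0].keys())
        w.writerow(cols)
        for r in rows:
            w.writerow([_fmt(r.get(c)) if not isinstance(r.get(c), str) else r.get(c) for c in cols])


def read_report_tsv(path: str | Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
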