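"""Readers and writers for the tabular formats the pipeline touches.

All TSVs are tab-delimited, UTF-8, '.' decimal, with a mandatory header row
(BLAST outfmt-6, which has no header, is the one exception).  Readers never
silently coerce: every dropped row is counted and reported through the module
logger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import typing
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple, Type

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    PROTEIN_EVALUE_MAX,
    AbundanceMatrix,
    Contig,
    HostPrediction,
    MappingRecord,
    NucHit,
    OrfCall,
    ProteinHit,
    QualityRecord,
    RrnaHit,
    ToolCall,
    ValidationError,
    validate_design,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed row; the message names the file and line number."""


# ---------------------------------------------------------------------------
# sequence / evidence readers
# ---------------------------------------------------------------------------

def read_contigs(path) -> List[Contig]:
    """Read contigs from FASTA; a ``circular=1``/"circular" tag in the
    description marks circular contigs."""
    contigs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        circular = "circular" in rec.description.lower()
        seq = str(rec.seq)
        contigs.append(Contig(rec.id, len(seq), circular=circular, sequence=seq))
    return contigs


def write_contigs(contigs: Iterable[Contig], path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            tag = " circular" if c.circular else ""
            seq = c.sequence if c.sequence is not None else "N" * c.length
            fh.write(f">{c.id}{tag}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_nuc_hits(path, evalue_max: float) -> List[NucHit]:
    """Parse BLAST outfmt-6 (12 tab-separated columns, no header).

    Rows with e-value above ``evalue_max`` are dropped and counted.  Hits
    reported with q_start > q_end (minus-strand convention of some producers)
    are normalised by swapping, since triage only uses query-interval
    coverage.
    """
    hits: List[NucHit] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                ident = float(fields[2])
                q_start = int(fields[6])
                q_end = int(fields[7])
                e_value = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if e_value > evalue_max:
                dropped += 1
                continue
            if q_start > q_end:
                q_start, q_end = q_end, q_start
            hits.append(
                NucHit(fields[0], fields[1], ident, q_start, q_end, e_value, bitscore)
            )
    logger.info(
        "read_nuc_hits(%s): kept %d rows, dropped %d above e-value %.3g",
        path, len(hits), dropped, evalue_max,
    )
    return hits


def write_nuc_hits(hits: Iterable[NucHit], path) -> None:
    """Write hits back to outfmt-6 (unused standard columns are zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            length = h.q_end - h.q_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, repr(float(h.pct_identity)),
                        str(length), "0", "0", str(int(h.q_start)), str(int(h.q_end)),
                        "0", "0", repr(float(h.e_value)), repr(float(h.bitscore)),
                    ]
                )
                + "\n"
            )


def read_orfs(path) -> List[OrfCall]:
    """Read CDS features from GFF3 (1-based inclusive coordinates).

    orf_id comes from the ID attribute; a CDS without one is an error.
    """
    orfs: List[OrfCall] = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF columns")
            if fields[2] != "CDS":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start > end:
                raise ParseError(f"{path}:{lineno}: start {start} > end {end}")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ParseError(f"{path}:{lineno}: CDS without ID attribute")
            key = (fields[0], attrs["ID"])
            if key in seen:
                raise ParseError(f"{path}:{lineno}: duplicate ORF id {attrs['ID']!r}")
            seen.add(key)
            orfs.append(OrfCall(fields[0], attrs["ID"], start, end, fields[6]))
    return orfs


def write_orfs(orfs: Iterable[OrfCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            fh.write(
                f"{o.contig_id}\tprodigal\tCDS\t{o.start}\t{o.end}\t.\t"
                f"{o.strand}\t0\tID={o.orf_id}\n"
            )


def read_protein_hits(path) -> List[ProteinHit]:
    """Read a protein/HMM hit table (columns: orf_id, database, e_value).

    Rows failing their database's e-value cut-off (1e-10 for refseq_viral,
    1e-5 for the HMM databases) are dropped and counted.
    """
    df = _read_tsv(path, ["orf_id", "database", "e_value"])
    hits: List[ProteinHit] = []
    dropped = 0
    for row in df.itertuples(index=False):
        cutoff = PROTEIN_EVALUE_MAX.get(row.database)
        if cutoff is None:
            raise ParseError(f"{path}: unknown protein database {row.database!r}")
        ev = float(row.e_value)
        if ev > cutoff:
            dropped += 1
            continue
        hits.append(ProteinHit(row.orf_id, row.database, ev))
    logger.info("read_protein_hits(%s): kept %d, dropped %d", path, len(hits), dropped)
    return hits


def read_tool_calls(path) -> List[ToolCall]:
    df = _read_tsv(path, ["contig_id", "tool", "positive"])
    calls = []
    seen = set()
    for row in df.itertuples(index=False):
        key = (row.contig_id, row.tool)
        if key in seen:
            raise ValidationError(f"duplicate tool call for {key}")
        seen.add(key)
        score = getattr(row, "score", None)
        if score is not None and pd.isna(score):
            score = None
        calls.append(ToolCall(row.contig_id, row.tool, _parse_bool(row.positive), score))
    return calls


def read_quality_table(path) -> List[QualityRecord]:
    """Read a CheckV-style quality summary.

    Missing completeness ("NA"/empty) is encoded as absent, never as 0.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"contig_id": str})
    # accept both the CheckV column name and our own record field name
    df = df.rename(columns={"viral_gene_count": "viral_genes"})
    missing = [
        c for c in ("contig_id", "completeness", "gene_count", "viral_genes", "provirus")
        if c not in df.columns
    ]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        comp = None if pd.isna(row.completeness) else float(row.completeness)
        rs = getattr(row, "region_start", None)
        re_ = getattr(row, "region_end", None)
        rs = None if rs is None or pd.isna(rs) else int(rs)
        re_ = None if re_ is None or pd.isna(re_) else int(re_)
        records.append(
            QualityRecord(
                row.contig_id, comp, int(row.gene_count), int(row.viral_genes),
                _parse_bool(row.provirus), rs, re_,
            )
        )
    return records


def read_rrna_hits(path) -> List[RrnaHit]:
    df = _read_tsv(path, ["contig_id"])
    type_col = "rrna_type" if "rrna_type" in df.columns else None
    return [
        RrnaHit(r.contig_id, getattr(r, "rrna_type", "unknown") if type_col else "unknown")
        for r in df.itertuples(index=False)
    ]


def read_host_predictions(path) -> List[HostPrediction]:
    df = _read_tsv(path, ["contig_id"])
    preds = []
    for row in df.itertuples(index=False):
        def _opt(name):
            v = getattr(row, name, None)
            return None if v is None or pd.isna(v) or v == "" else v
        conf = _opt("confidence")
        preds.append(
            HostPrediction(
                row.contig_id, _opt("host_phylum"), _opt("host_order"),
                _opt("host_family"), None if conf is None else float(conf),
            )
        )
    return preds


# ---------------------------------------------------------------------------
# mapping / counts
# ---------------------------------------------------------------------------

def read_mapping(path) -> List[MappingRecord]:
    df = _read_tsv(path, ["contig_id", "sample_id", "mapped_reads", "breadth"])
    return [
        MappingRecord(r.contig_id, r.sample_id, int(r.mapped_reads), float(r.breadth))
        for r in df.itertuples(index=False)
    ]


def mapping_to_frame(records: Sequence[MappingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [r.contig_id for r in records],
            "sample_id": [r.sample_id for r in records],
            "mapped_reads": [r.mapped_reads for r in records],
            "breadth": [r.breadth for r in records],
        }
    )


def read_depth_table(path, contig_lengths: dict) -> pd.DataFrame:
    """Derive breadth from a per-base depth TSV (contig_id, sample_id, pos, depth).

    breadth = (#positions with depth >= 1) / contig length.  Returns a frame
    with contig_id, sample_id, breadth.
    """
    df = _read_tsv(path, ["contig_id", "sample_id", "pos", "depth"])
    covered = (
        df[df["depth"] >= 1]
        .groupby(["contig_id", "sample_id"])["pos"]
        .nunique()
        .rename("covered")
        .reset_index()
    )
    covered["breadth"] = [
        c / contig_lengths[cid] for cid, c in zip(covered["contig_id"], covered["covered"])
    ]
    return covered[["contig_id", "sample_id", "breadth"]]


def read_design(path) -> pd.DataFrame:
    df = _read_tsv(
        path, ["sample_id", "group", "subject_id", "timepoint", "total_mapped_reads"]
    )
    df["timepoint"] = df["timepoint"].astype(str)
    df["subject_id"] = df["subject_id"].astype(str)
    return validate_design(df)


def read_counts_and_design(counts_path, design_path) -> Tuple[AbundanceMatrix, pd.DataFrame]:
    """Read a features x samples count matrix plus its design table.

    The matrix's sample columns must all appear in the design; columns are
    reordered to design order (design samples missing from the matrix are
    reported and skipped).
    """
    design = read_design(design_path)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    extra = [s for s in counts.columns if s not in design.index]
    if extra:
        raise ValidationError(
            f"samples in count matrix absent from design: {extra}"
        )
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValidationError("negative count in matrix")
    if not np.allclose(arr, np.round(arr)):
        raise ValidationError("counts must be integers")
    missing = [s for s in design.index if s not in counts.columns]
    if missing:
        logger.warning("design samples missing from count matrix: %s", missing)
    order = [s for s in design.index if s in counts.columns]
    counts = counts[order].astype(np.int64)
    return AbundanceMatrix(counts, "count"), design.loc[order]


def write_matrix(matrix: AbundanceMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format="%.12g", index_label="feature_id")


def read_matrix(path, scale: str) -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index.name = None
    return AbundanceMatrix(df, scale)


# ---------------------------------------------------------------------------
# generic dataclass record tables
# ---------------------------------------------------------------------------

def write_records(records: Sequence, path) -> None:
    """Write homogeneous dataclass records to TSV.

    Floats are rendered in their shortest exact decimal form so
    reader(writer(x)) == x.  Callers with empty data should use
    :func:`write_empty` with the record type, which writes a header-only file.
    """
    if not records:
        raise ValueError("write_records needs at least one record; use write_empty")
    cls = type(records[0])
    if not dataclasses.is_dataclass(cls):
        raise TypeError("records must be dataclasses")
    if any(type(r) is not cls for r in records):
        raise TypeError("records must be homogeneous")
    names = [f.name for f in dataclasses.fields(cls)]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for r in records:
            fh.write("\t".join(_render(getattr(r, n)) for n in names) + "\n")


def write_empty(cls: Type, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(f.name for f in dataclasses.fields(cls)) + "\n")


def read_records(path, cls: Type) -> List:
    """Read a TSV written by :func:`write_records` back into dataclasses."""
    hints = typing.get_type_hints(cls)
    fields = dataclasses.fields(cls)
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [f.name for f in fields]
        if header != expected:
            raise ParseError(f"{path}: header {header} != fields {expected}")
        for lineno, line in enumerate(fh, start=2):
            vals = line.rstrip("\n").split("\t")
            if len(vals) != len(fields):
                raise ParseError(f"{path}:{lineno}: wrong column count")
            kwargs = {
                f.name: _unrender(v, hints[f.name]) for f, v in zip(fields, vals)
            }
            out.append(cls(**kwargs))
    return out


def write_manifest(path, **params) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                     dtype={c: str for c in ("contig_id", "sample_id", "orf_id")})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "yes", "1"):
        return True
    if s in ("false", "no", "0"):
        return False
    raise ParseError(f"cannot parse boolean {value!r}")


def _render(value) -> str:
    if value is None:
        return ""
    if isinstance(value, (bool, np.bool_)):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(float(value))  # shortest exact round-trip form
    if isinstance(value, np.integer):
        return str(int(value))
    return str(value)


def _unrender(text: str, hint):
    origin = typing.get_origin(hint)
    if origin is typing.Union:  # Optional[...]
        args = [a for a in typing.get_args(hint) if a is not type(None)]
        if text == "":
            return None
        return _unrender(text, args[0])
    if hint is bool:
        return _parse_bool(text)
    if hint is int:
        return int(text)
    if hint is float:
        return float(text)
    return text
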