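"""Domain types shared by every pipeline stage.

Coordinate convention: all genomic intervals are 1-based inclusive, so an
interval spans ``end - start + 1`` bases.  This matches both interval formats
the pipeline consumes (BLAST outfmt-6 and GFF3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

GROUPS = ("Ctr", "CtrStress", "FVTStress")

#: per-database e-value cut-offs for protein homology evidence
PROTEIN_EVALUE_MAX = {"refseq_viral": 1e-10, "phrogs": 1e-5, "ipf": 1e-5}

TOOLS = ("virsorter2", "deepvirfinder", "vrca_circular")


class ValidationError(ValueError):
    """A record violated a domain invariant."""


@dataclass(frozen=True)
class Contig:
    """An assembled sequence entering triage."""

    id: str
    length: int
    circular: bool = False
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValidationError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValidationError(
                f"contig {self.id}: sequence length {len(self.sequence)} "
                f"!= length field {self.length}"
            )


@dataclass(frozen=True)
class NucHit:
    """One nucleotide alignment hit (BLAST outfmt-6 row), query-side interval."""

    query_id: str
    subject_id: str
    pct_identity: float
    q_start: int
    q_end: int
    e_value: float
    bitscore: float

    def __post_init__(self):
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.pct_identity} outside [0, 100]"
            )
        if not (1 <= self.q_start <= self.q_end):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: bad interval "
                f"{self.q_start}..{self.q_end}"
            )
        if self.e_value < 0:
            raise ValidationError("e_value must be nonnegative")


@dataclass(frozen=True)
class OrfCall:
    contig_id: str
    orf_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValidationError(
                f"ORF {self.orf_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"ORF {self.orf_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ProteinHit:
    orf_id: str
    database: str
    e_value: float

    def __post_init__(self):
        if self.database not in PROTEIN_EVALUE_MAX:
            raise ValidationError(f"unknown protein database {self.database!r}")
        if self.e_value > PROTEIN_EVALUE_MAX[self.database]:
            raise ValidationError(
                f"hit on {self.orf_id}: e-value {self.e_value} fails the "
                f"{self.database} cut-off {PROTEIN_EVALUE_MAX[self.database]}"
            )


@dataclass(frozen=True)
class ToolCall:
    """Boolean call from a standalone viral identification tool."""

    contig_id: str
    tool: str
    positive: bool
    score: Optional[float] = None

    def __post_init__(self):
        if self.tool not in TOOLS:
            raise ValidationError(f"unknown tool {self.tool!r}")


@dataclass(frozen=True)
class QualityRecord:
    """CheckV-style quality summary for one contig.

    ``completeness`` is None when CheckV could not estimate it; an unknown
    completeness fails any threshold test downstream (conservative).
    """

    contig_id: str
    completeness: Optional[float]
    gene_count: int
    viral_gene_count: int
    provirus: bool = False
    region_start: Optional[int] = None
    region_end: Optional[int] = None

    def __post_init__(self):
        if self.viral_gene_count > self.gene_count:
            raise ValidationError(
                f"{self.contig_id}: viral_gene_count {self.viral_gene_count} "
                f"> gene_count {self.gene_count}"
            )
        if self.provirus:
            if self.region_start is None or self.region_end is None:
                raise ValidationError(
                    f"{self.contig_id}: provirus without trim coordinates"
                )
            if self.region_start > self.region_end:
                raise ValidationError(
                    f"{self.contig_id}: region_start > region_end"
                )


@dataclass(frozen=True)
class RrnaHit:
    contig_id: str
    rrna_type: str = "unknown"

    def __post_init__(self):
        if not self.contig_id:
            raise ValidationError("rRNA hit with empty contig_id")


@dataclass(frozen=True)
class MappingRecord:
    """Per-contig, per-sample read count with breadth of coverage."""

    contig_id: str
    sample_id: str
    mapped_reads: int
    breadth: float

    def __post_init__(self):
        if not (0.0 <= self.breadth <= 1.0):
            raise ValidationError(
                f"{self.contig_id}/{self.sample_id}: breadth {self.breadth} "
                "outside [0, 1]"
            )
        if self.mapped_reads < 0:
            raise ValidationError("mapped_reads must be nonnegative")
        if self.mapped_reads == 0 and self.breadth != 0.0:
            raise ValidationError(
                f"{self.contig_id}/{self.sample_id}: zero reads with "
                f"nonzero breadth {self.breadth}"
            )


@dataclass(frozen=True)
class HostPrediction:
    contig_id: str
    host_phylum: Optional[str] = None
    host_order: Optional[str] = None
    host_family: Optional[str] = None
    confidence: Optional[float] = None

    def __post_init__(self):
        if self.host_phylum is None and self.host_order is None and self.host_family is None:
            raise ValidationError(
                f"{self.contig_id}: host prediction with no taxon rank"
            )


DESIGN_COLUMNS = ("sample_id", "group", "subject_id", "timepoint", "total_mapped_reads")


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample design table (sample -> group/subject/timepoint).

    Returns a copy indexed by ``sample_id`` with columns
    group, subject_id, timepoint, total_mapped_reads.
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValidationError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in design: {dup!r}")
    bad = set(design["group"]) - set(GROUPS)
    if bad:
        raise ValidationError(f"unknown groups in design: {sorted(bad)}")
    if (design["total_mapped_reads"] <= 0).any():
        raise ValidationError("total_mapped_reads must be positive")
    out = design.copy()
    out["total_mapped_reads"] = out["total_mapped_reads"].astype(np.int64)
    return out.set_index("sample_id", drop=False)


class AbundanceMatrix:
    """Features x samples abundance matrix with an explicit scale.

    scale is one of {"count", "relative", "absolute", "clr", "log"}.  Relative
    columns sum to 1 (or 0 for an all-zero sample); clr columns sum to 0.
    ``feature_lengths`` (bp) travels with count/relative scales for
    length-aware operations.
    """

    #: "log" is unconstrained log-scale data (e.g. log expression); the other
    #: scales carry the validation documented above
    SCALES = ("count", "relative", "absolute", "clr", "log")

    def __init__(
        self,
        values: pd.DataFrame,
        scale: str,
        feature_lengths: Optional[pd.Series] = None,
    ):
        if scale not in self.SCALES:
            raise ValidationError(f"unknown scale {scale!r}")
        if values.index.duplicated().any():
            raise ValidationError("duplicate feature ids")
        if values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if scale in ("count", "relative", "absolute"):
            arr = values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise ValidationError(f"negative values on {scale} scale")
        if scale == "relative":
            sums = values.sum(axis=0).to_numpy(dtype=float)
            ok = np.isclose(sums, 1.0, atol=1e-12) | (sums == 0.0)
            if not ok.all():
                raise ValidationError("relative columns must sum to 1 (or 0)")
        if scale == "clr":
            sums = values.sum(axis=0).to_numpy(dtype=float)
            if not np.allclose(sums, 0.0, atol=1e-9):
                raise ValidationError("clr columns must sum to 0")
        if feature_lengths is not None:
            feature_lengths = feature_lengths.reindex(values.index)
            if feature_lengths.isna().any():
                missing = feature_lengths.index[feature_lengths.isna()][0]
                raise ValidationError(f"missing feature length for {missing!r}")
        self.values = values
        self.scale = scale
        self.feature_lengths = feature_lengths

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    def subset_features(self, feature_ids: Sequence[str]) -> "AbundanceMatrix":
        lengths = None
        if self.feature_lengths is not None:
            lengths = self.feature_lengths.loc[list(feature_ids)]
        return AbundanceMatrix(self.values.loc[list(feature_ids)], self.scale, lengths)

    def __repr__(self):
        return (
            f"AbundanceMatrix({len(self.feature_ids)} features x "
            f"{len(self.sample_ids)} samples, scale={self.scale!r})"
        )
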