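"""Seeded generators for every input the pipeline consumes.

Two families of fixtures are produced, both pure functions of (parameters,
seed):

* evidence bundles — contigs plus nucleotide/protein/tool/rRNA/quality
  evidence tables where each contig's viral status is planted through
  exactly one evidence route (or through none), including contigs sitting
  exactly on each decision boundary.  Running triage on a bundle must
  reproduce the planted truth.
* count studies — the three-group design (control, stressed, stressed +
  faecal virome transplant) with repeated timepoints, compositional counts
  drawn logistic-normal-multinomially, planted stress-depletion and
  FVT-restoration effects on the log scale, one spike-in feature of known
  absolute amount, and per-record breadth values that exercise the 75%
  spurious-mapping filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import io as svio
from .model import (
    GROUPS,
    AbundanceMatrix,
    Contig,
    MappingRecord,
    NucHit,
    OrfCall,
    ProteinHit,
    QualityRecord,
    RrnaHit,
    ToolCall,
    validate_design,
)

ROUTES = ("nucleotide", "protein", "virsorter2", "deepvirfinder", "circular")


@dataclass(frozen=True)
class TriageTruth:
    contig_id: str
    is_viral: bool
    planted_route: str  # one of ROUTES or "none"
    boundary_case: bool
    quant_included: bool


@dataclass(frozen=True)
class StudyTruth:
    feature_id: str
    feature_class: str  # restored | stress_only | null | spike
    stress_effect: float
    fvt_effect: float


@dataclass
class EvidenceBundle:
    contigs: List[Contig]
    nuc_hits: List[NucHit]
    orfs: List[OrfCall]
    protein_hits: List[ProteinHit]
    tool_calls: List[ToolCall]
    rrna_hits: List[RrnaHit]
    quality: List[QualityRecord]
    truth: List[TriageTruth]
    params: dict = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    design: pd.DataFrame
    counts: AbundanceMatrix
    mapping: List[MappingRecord]
    latent_log: pd.DataFrame  # features x samples latent log-abundance
    truth: List[StudyTruth]
    feature_lengths: pd.Series
    spike_feature_id: str
    absolute_truth: pd.DataFrame  # planted absolute abundances
    spurious_cells: Set[Tuple[str, str]]
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# evidence bundles
# ---------------------------------------------------------------------------

def _disjoint_intervals(rng, length: int, covered: int, k: int = 3):
    """k disjoint 1-based intervals totalling exactly ``covered`` positions."""
    k = min(k, covered)
    cuts = np.sort(rng.choice(np.arange(1, covered), size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
    parts = np.diff(np.concatenate(([0], cuts, [covered])))
    free = length - covered
    gap_cuts = np.sort(rng.integers(0, free + 1, size=k))
    ivs = []
    pos = 1
    for part, gap in zip(parts, np.diff(np.concatenate(([0], gap_cuts)))):
        pos += gap
        ivs.append((pos, pos + int(part) - 1))
        pos += int(part)
    return ivs


def _nuc_hits_for(rng, contig: Contig, covered: int, identity_low=False) -> List[NucHit]:
    ident_range = (30.0, 49.0) if identity_low else (55.0, 99.0)
    hits = []
    for s, e in _disjoint_intervals(rng, contig.length, covered):
        hits.append(
            NucHit(
                contig.id, f"db{rng.integers(1, 500)}",
                float(rng.uniform(*ident_range)), s, e,
                float(10 ** rng.uniform(-50, -11)), float(rng.uniform(100, 900)),
            )
        )
    return hits


def _orfs_for(rng, contig: Contig, n_orfs: int) -> List[OrfCall]:
    orfs = []
    span = contig.length // max(n_orfs, 1)
    for k in range(n_orfs):
        start = k * span + 1
        end = min(start + max(span - rng.integers(1, 30), 3) - 1, contig.length)
        strand = "+" if rng.random() < 0.5 else "-"
        orfs.append(OrfCall(contig.id, f"{contig.id}_orf{k + 1}", start, int(end), strand))
    return orfs


def _protein_hits_for(rng, orfs: Sequence[OrfCall], n_hit: int) -> List[ProteinHit]:
    chosen = rng.choice(len(orfs), size=n_hit, replace=False)
    hits = []
    for j in chosen:
        db = ("refseq_viral", "phrogs", "ipf")[rng.integers(0, 3)]
        emax = 1e-10 if db == "refseq_viral" else 1e-5
        hits.append(ProteinHit(orfs[j].orf_id, db, float(emax * 10 ** -rng.uniform(1, 30))))
        if rng.random() < 0.3:  # a second database hitting the same ORF
            db2 = "phrogs" if db != "phrogs" else "ipf"
            hits.append(ProteinHit(orfs[j].orf_id, db2, float(1e-5 * 10 ** -rng.uniform(1, 20))))
    return hits


def _quality_for(rng, contig: Contig, quant_pass: bool, boundary: bool,
                 provirus_region: Optional[Tuple[int, int]] = None) -> QualityRecord:
    genes = int(rng.integers(10, 60))
    if quant_pass:
        completeness = 50.0 if boundary else float(rng.uniform(55.0, 99.0))
        if boundary:
            genes = 10 * int(rng.integers(1, 6))
            viral = genes // 10  # exactly 10% of genes
        else:
            viral = int(rng.integers(int(np.ceil(genes / 10)), genes + 1))
    else:
        mode = rng.integers(0, 3)
        if mode == 0:  # completeness failure
            completeness = float(rng.uniform(5.0, 49.9))
            viral = int(rng.integers(max(1, (genes + 9) // 10), genes + 1))
        elif mode == 1:  # no viral genes
            completeness = float(rng.uniform(55.0, 99.0))
            viral = 0
        else:  # viral-gene fraction below 10%
            genes = max(genes, 21)
            completeness = float(rng.uniform(55.0, 99.0))
            viral = max(1, (genes - 1) // 10 - 1)
            while 10 * viral >= genes:
                viral -= 1
            viral = max(viral, 0)
            if viral == 0 and 10 * 1 < genes:
                viral = 1
    provirus = provirus_region is not None
    rs, re_ = provirus_region if provirus else (None, None)
    return QualityRecord(contig.id, completeness, genes, viral, provirus, rs, re_)


def simulate_evidence_bundle(
    n_contigs: int = 200,
    viral_fraction: float = 0.3,
    boundary_fraction: float = 0.1,
    seed: int = 0,
) -> EvidenceBundle:
    """Contigs plus evidence tables with planted triage ground truth.

    Planted-viral contigs satisfy exactly one route; negatives sit strictly
    below every threshold.  A ``boundary_fraction`` of contigs is planted
    exactly at a decision boundary (85% coverage, 2-of-4 ORFs, completeness
    50.0, 10% viral genes, 3000 bp effective length).  A few negatives carry
    positive evidence vetoed by an rRNA hit, and a few lose their viral call
    because the provirus trim brings them under 3 kb.
    """
    rng = np.random.default_rng(seed)
    n_viral = round(n_contigs * viral_fraction)
    n_boundary = round(n_contigs * boundary_fraction)

    contigs: List[Contig] = []
    nuc_hits: List[NucHit] = []
    orfs: List[OrfCall] = []
    protein_hits: List[ProteinHit] = []
    tool_calls: List[ToolCall] = []
    rrna_hits: List[RrnaHit] = []
    quality: List[QualityRecord] = []
    truth: List[TriageTruth] = []

    n_rrna_veto = max(2, n_contigs // 40)
    n_provirus_drop = max(2, n_contigs // 40)

    for i in range(n_contigs):
        cid = f"c{i:04d}"
        viral = i < n_viral
        boundary = viral and i < min(n_boundary, n_viral)
        route = ROUTES[i % len(ROUTES)] if viral else "none"
        # lengths multiple of 20 keep the 85% boundary exact
        length = int(rng.integers(160, 500)) * 20
        circular = viral and route == "circular" and rng.random() < 0.5
        contig = Contig(cid, length, circular=circular)
        contigs.append(contig)

        n_orfs = int(rng.integers(6, 16))
        contig_orfs = _orfs_for(rng, contig, 4 if (viral and route == "protein" and boundary) else n_orfs)
        orfs.extend(contig_orfs)

        # --- evidence per route ------------------------------------------
        if viral and route == "nucleotide":
            covered = (85 * length) // 100 if boundary else int(length * rng.uniform(0.88, 0.98))
            nuc_hits.extend(_nuc_hits_for(rng, contig, covered))
        elif rng.random() < 0.5:
            # sub-threshold nucleotide noise on other contigs
            covered = int(length * rng.uniform(0.2, 0.8))
            if covered * 100 >= 85 * length:
                covered = (85 * length) // 100 - 1
            if rng.random() < 0.5:
                nuc_hits.extend(_nuc_hits_for(rng, contig, covered))
            else:  # high coverage but identity < 50
                nuc_hits.extend(
                    _nuc_hits_for(rng, contig, int(length * 0.95), identity_low=True)
                )

        if viral and route == "protein":
            total = len(contig_orfs)
            n_hit = 2 if boundary else int(rng.integers((total + 1) // 2, total + 1))
            n_hit = max(n_hit, 2)
            protein_hits.extend(_protein_hits_for(rng, contig_orfs, n_hit))
        elif len(contig_orfs) >= 5 and rng.random() < 0.4:
            # sub-threshold protein noise: either 1 ORF or < 50% of ORFs
            total = len(contig_orfs)
            n_hit = 1 if rng.random() < 0.5 else max(1, (total - 1) // 2 - (total % 2 == 0))
            while 2 * n_hit >= total and n_hit >= 2:
                n_hit -= 1
            protein_hits.extend(_protein_hits_for(rng, contig_orfs, max(n_hit, 1)))

        for tool, r in (("virsorter2", "virsorter2"), ("deepvirfinder", "deepvirfinder"),
                        ("vrca_circular", "circular")):
            positive = viral and route == r
            if positive or rng.random() < 0.5:
                score = float(rng.uniform(0.9, 1.0)) if positive else float(rng.uniform(0.0, 0.4))
                tool_calls.append(ToolCall(cid, tool, positive, score))

        # --- provirus / quality ------------------------------------------
        provirus_region = None
        effective = length
        if viral and (rng.random() < 0.25 or (boundary and route == "virsorter2")):
            eff = 3000 if boundary and route in ("virsorter2", "deepvirfinder") else int(
                rng.integers(3000, max(length - 200, 3001))
            )
            eff = min(eff, length - 100)
            if eff >= 3000:
                start = int(rng.integers(1, length - eff + 1))
                provirus_region = (start, start + eff - 1)
                effective = eff
        quant_pass = viral and rng.random() < 0.6
        quality.append(
            _quality_for(rng, contig, quant_pass, boundary and quant_pass, provirus_region)
        )

        truth.append(
            TriageTruth(cid, viral, route, bool(boundary), bool(viral and quant_pass))
        )

    # --- rRNA-vetoed contigs: positive tool evidence, killed by rRNA -----
    for k in range(n_rrna_veto):
        cid = f"r{k:03d}"
        length = int(rng.integers(160, 500)) * 20
        contig = Contig(cid, length)
        contigs.append(contig)
        orfs.extend(_orfs_for(rng, contig, int(rng.integers(6, 16))))
        tool_calls.append(ToolCall(cid, "virsorter2", True, float(rng.uniform(0.9, 1.0))))
        rrna_hits.append(RrnaHit(cid, ("5S", "16S", "23S")[int(rng.integers(0, 3))]))
        quality.append(_quality_for(rng, contig, False, False))
        truth.append(TriageTruth(cid, False, "none", False, False))

    # --- provirus-trim drops: viral evidence, trimmed under 3 kb ---------
    for k in range(n_provirus_drop):
        cid = f"p{k:03d}"
        length = int(rng.integers(160, 500)) * 20
        contig = Contig(cid, length)
        contigs.append(contig)
        orfs.extend(_orfs_for(rng, contig, int(rng.integers(6, 16))))
        tool_calls.append(ToolCall(cid, "deepvirfinder", True, float(rng.uniform(0.9, 1.0))))
        eff = 2999 if k == 0 else int(rng.integers(500, 3000))
        start = int(rng.integers(1, length - eff + 1))
        quality.append(
            QualityRecord(cid, float(rng.uniform(55, 95)), 20, 10, True, start, start + eff - 1)
        )
        truth.append(TriageTruth(cid, False, "none", k == 0, False))

    return EvidenceBundle(
        contigs, nuc_hits, orfs, protein_hits, tool_calls, rrna_hits, quality, truth,
        params=dict(n_contigs=n_contigs, viral_fraction=viral_fraction,
                    boundary_fraction=boundary_fraction, seed=seed),
    )


def simulate_homology_clusters(
    n_clusters: int = 10,
    cluster_size: int = 4,
    n_singletons: int = 20,
    seed: int = 0,
) -> Tuple[List[Contig], List[NucHit]]:
    """Contigs in fully connected homology clusters plus singletons.

    Every within-cluster pair shares >= 90% identity over >= 90% of the
    shorter member; between-cluster and singleton hits stay strictly below
    one of the two thresholds.  Only the longest member of each cluster
    should survive deduplication.
    """
    rng = np.random.default_rng(seed)
    contigs: List[Contig] = []
    hits: List[NucHit] = []
    for c in range(n_clusters):
        # distinct lengths within the cluster so 'longest member' is unique
        lengths = sorted(rng.choice(np.arange(3000, 9000), size=cluster_size, replace=False))
        members = [
            Contig(f"cl{c:02d}m{j}", int(lengths[j])) for j in range(cluster_size)
        ]
        contigs.extend(members)
        for a in range(cluster_size):
            for b in range(a + 1, cluster_size):
                short, long_ = members[a], members[b]
                covered = int(np.ceil(0.9 * short.length)) + int(
                    rng.integers(0, short.length - int(np.ceil(0.9 * short.length)) + 1)
                )
                for s, e in _disjoint_intervals(rng, short.length, covered, k=2):
                    hits.append(
                        NucHit(short.id, long_.id, float(rng.uniform(91, 99.9)),
                               s, e, 1e-30, 500.0)
                    )
    for k in range(n_singletons):
        contigs.append(Contig(f"s{k:03d}", int(rng.integers(3000, 9000))))
    # sub-threshold noise hits between random contigs
    ids = [c.id for c in contigs]
    lengths = {c.id: c.length for c in contigs}
    for _ in range(n_singletons):
        a, b = rng.choice(len(ids), size=2, replace=False)
        qid = ids[a] if lengths[ids[a]] <= lengths[ids[b]] else ids[b]
        covered = int(lengths[qid] * rng.uniform(0.1, 0.5))
        if rng.random() < 0.5:  # low identity, high coverage
            ident, covered = float(rng.uniform(60, 89.9)), int(lengths[qid] * 0.95)
        else:  # good identity, low coverage
            ident = float(rng.uniform(91, 99))
        for s, e in _disjoint_intervals(rng, lengths[qid], max(covered, 10), k=2):
            hits.append(NucHit(qid, ids[b] if qid == ids[a] else ids[a], ident, s, e, 1e-25, 300.0))
    return contigs, hits


# ---------------------------------------------------------------------------
# count studies
# ---------------------------------------------------------------------------

def simulate_count_study(
    n_features: int = 300,
    n_per_group: Sequence[int] = (10, 10, 9),
    n_restored: int = 30,
    n_stress_only: int = 0,
    effect_size: float = 1.5,
    subject_sd: float = 0.0,
    residual_sd: float = 1.0,
    library_size: int = 100_000,
    timepoints: Sequence[str] = ("T1",),
    spike_absolute: float = 1e6,
    breadth_spurious_fraction: float = 0.1,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> SimulatedStudy:
    """Three-group compositional count study with planted restoration effects.

    Latent per-sample log-abundances are Gaussian around per-feature
    baselines; stressed samples are shifted by the (signed) stress effect on
    restored and stress_only features, and virome-treated samples shift back
    on restored features.  With several timepoints the first is a pre-stress
    baseline (no group effects) and subjects carry feature-specific random
    intercepts of SD ``subject_sd`` shared across their timepoints.  Counts
    are multinomial
    at ``library_size`` with cell probabilities proportional to absolute
    abundance x contig length; the spike feature sits at a constant absolute
    amount in every sample.  A fraction of (feature, sample) mapping records
    is planted with breadth < 0.75 to exercise the spurious-count filter.
    """
    if n_restored + n_stress_only > n_features - 1:
        raise ValueError("too many affected features")
    rng = np.random.default_rng(seed)
    groups = list(GROUPS)
    n_by_group = dict(zip(groups, n_per_group))
    timepoints = [str(t) for t in timepoints]

    # subjects and samples
    subjects = []
    for g in groups:
        for k in range(n_by_group[g]):
            subjects.append((f"{g}_s{k:02d}", g))
    rows = []
    for sid, g in subjects:
        for t in timepoints:
            rows.append(
                dict(sample_id=f"{sid}_{t}", group=g, subject_id=sid,
                     timepoint=t, total_mapped_reads=int(library_size))
            )
    design = validate_design(pd.DataFrame(rows))

    # features: f0000.. with the spike last
    feature_ids = [f"f{i:04d}" for i in range(n_features - 1)] + ["spike_Q33"]
    classes = (
        ["restored"] * n_restored
        + ["stress_only"] * n_stress_only
        + ["null"] * (n_features - 1 - n_restored - n_stress_only)
    )
    rng.shuffle(classes)
    classes.append("spike")
    baseline = rng.normal(0.0, baseline_sd, size=n_features)
    baseline[-1] = 2.0  # spike kept comfortably abundant
    signs = rng.choice([-1.0, 1.0], size=n_features)
    stress_eff = np.array(
        [effect_size * s if c in ("restored", "stress_only") else 0.0
         for c, s in zip(classes, signs)]
    )
    fvt_eff = np.array(
        [-e if c == "restored" else 0.0 for c, e in zip(classes, stress_eff)]
    )
    truth = [
        StudyTruth(fid, c, float(se), float(fe))
        for fid, c, se, fe in zip(feature_ids, classes, stress_eff, fvt_eff)
    ]

    # feature-specific subject intercepts (a constant-across-features offset
    # would be removed by the clr transform and carry no information)
    subj_offset = {
        sid: rng.normal(0.0, subject_sd, size=n_features) for sid, _ in subjects
    }
    lengths = pd.Series(
        rng.integers(3000, 15001, size=n_features), index=feature_ids, name="length"
    )

    sample_ids = list(design.index)
    latent = np.empty((n_features, len(sample_ids)))
    spike_ix = n_features - 1
    for j, sid in enumerate(sample_ids):
        g = design.loc[sid, "group"]
        t = design.loc[sid, "timepoint"]
        post = len(timepoints) == 1 or t != timepoints[0]
        x = baseline + rng.normal(0.0, residual_sd, size=n_features)
        x += subj_offset[design.loc[sid, "subject_id"]]
        if post and g == "CtrStress":
            x += stress_eff
        elif post and g == "FVTStress":
            x += stress_eff + fvt_eff
        x[spike_ix] = baseline[spike_ix]  # spike: fixed absolute amount
        latent[:, j] = x

    # absolute abundance anchored to the spike
    absolute = spike_absolute * np.exp(latent - latent[spike_ix][None, :])
    probs = absolute * lengths.to_numpy(dtype=float)[:, None]
    probs /= probs.sum(axis=0, keepdims=True)
    counts = np.column_stack(
        [rng.multinomial(int(library_size), probs[:, j]) for j in range(len(sample_ids))]
    )

    # breadth: high for genuine signal, planted low for spurious cells
    spurious: Set[Tuple[str, str]] = set()
    mapping: List[MappingRecord] = []
    for i, fid in enumerate(feature_ids):
        for j, sid in enumerate(sample_ids):
            reads = int(counts[i, j])
            if reads == 0:
                mapping.append(MappingRecord(fid, sid, 0, 0.0))
                continue
            if fid != "spike_Q33" and rng.random() < breadth_spurious_fraction:
                breadth = float(rng.uniform(0.05, 0.7499))
                spurious.add((fid, sid))
            else:
                breadth = float(rng.uniform(0.80, 1.0))
            mapping.append(MappingRecord(fid, sid, reads, breadth))

    counts_df = pd.DataFrame(counts, index=feature_ids, columns=sample_ids)
    return SimulatedStudy(
        design=design,
        counts=AbundanceMatrix(counts_df, "count", lengths),
        mapping=mapping,
        latent_log=pd.DataFrame(latent, index=feature_ids, columns=sample_ids),
        truth=truth,
        feature_lengths=lengths,
        spike_feature_id="spike_Q33",
        absolute_truth=pd.DataFrame(absolute, index=feature_ids, columns=sample_ids),
        spurious_cells=spurious,
        params=dict(
            n_features=n_features, n_per_group=list(n_per_group),
            n_restored=n_restored, n_stress_only=n_stress_only,
            effect_size=effect_size, subject_sd=subject_sd,
            residual_sd=residual_sd, library_size=library_size,
            timepoints=timepoints, spike_absolute=spike_absolute,
            breadth_spurious_fraction=breadth_spurious_fraction, seed=seed,
        ),
    )


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixture_bundle(bundle, directory, force: bool = False) -> None:
    """Write a simulated bundle/study to standard-format files + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True)")

    if isinstance(bundle, EvidenceBundle):
        svio.write_contigs(bundle.contigs, directory / "contigs.fasta")
        svio.write_nuc_hits(bundle.nuc_hits, directory / "nuc_hits.tsv")
        svio.write_orfs(bundle.orfs, directory / "orfs.gff3")
        _write_or_empty(bundle.protein_hits, ProteinHit, directory / "protein_hits.tsv")
        _write_or_empty(bundle.tool_calls, ToolCall, directory / "tool_calls.tsv")
        _write_or_empty(bundle.rrna_hits, RrnaHit, directory / "rrna_hits.tsv")
        _write_or_empty(bundle.quality, QualityRecord, directory / "quality.tsv")
        _write_or_empty(bundle.truth, TriageTruth, directory / "triage_truth.tsv")
    elif isinstance(bundle, SimulatedStudy):
        svio.write_matrix(bundle.counts, directory / "counts.tsv")
        bundle.design.to_csv(directory / "design.tsv", sep="\t", index=False)
        _write_or_empty(bundle.mapping, MappingRecord, directory / "mapping.tsv")
        _write_or_empty(bundle.truth, StudyTruth, directory / "study_truth.tsv")
        bundle.feature_lengths.rename("length").to_frame().to_csv(
            directory / "feature_lengths.tsv", sep="\t", index_label="feature_id"
        )
    else:
        raise TypeError(f"cannot write {type(bundle).__name__}")
    svio.write_manifest(directory / "manifest.json", **bundle.params)


def _write_or_empty(records, cls, path):
    if records:
        svio.write_records(records, path)
    else:
        svio.write_empty(cls, path)
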