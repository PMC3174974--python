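"""Seven-type CISD classification from motif arrangement, fused domains
and taxonomy.

Decision order (architecture beats taxonomy):

1. two motif-bearing CDGSH hits with inter-motif spacing inside the
   configured tandem range → type 6; type 5 if a C-terminal glutamate
   synthase FMN-binding fusion follows;
2. a DUF1271 segment anywhere → type 7 (subtypes DC / DCC / CDC from the
   linear order of DUF1271 and CISD segments);
3. a single motif → taxon default (eukaryote→1, apicomplexa→2, archaea→3,
   bacteria→4), optionally overridden by a homology call against
   per-type seed alignments (bacterial type-3 members and the 2a/2b split
   have no architectural signature);
4. otherwise orphan.

A hit counts as motif-bearing when strict or his-to-cys (a degenerate
motif that may still hold a cluster); fully disrupted windows do not
define architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .io import SequenceRecord
from .motif import MotifHit

SEGMENT_KINDS = ("CISD_motif", "DUF1271", "FMN_binding", "other")
TAXA = ("eukaryote", "apicomplexa", "archaea", "bacteria", "unknown")

DEFAULT_SPACING_RANGE = (5, 40)  # residues between motif end and next start


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class Segment:
    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ClassificationError(f"unknown segment kind: {self.kind!r}")
        if self.end < self.start:
            raise ClassificationError(f"segment end {self.end} < start {self.start}")


@dataclass
class ArchitectureAnnotation:
    """Ordered, non-overlapping domain segments along one sequence."""

    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: s.start)
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start <= a.end:
                raise ClassificationError(
                    f"overlapping segments: {a} and {b}")

    def of_kind(self, kind: str) -> list[Segment]:
        return [s for s in self.segments if s.kind == kind]


@dataclass(frozen=True)
class TypeCall:
    cisd_type: str
    subtype7: str = "none"
    evidence: tuple[str, ...] = ()
    confidence: str = "architectural"  # architectural | taxonomic | homology

    def __post_init__(self) -> None:
        if (self.subtype7 != "none") != (self.cisd_type == "7"):
            raise ClassificationError(
                f"subtype7={self.subtype7!r} inconsistent with type {self.cisd_type!r}")
        if not self.evidence:
            raise ClassificationError("TypeCall requires at least one evidence rule id")


def _motif_bearing(motifs: Sequence[MotifHit]) -> list[MotifHit]:
    return sorted((m for m in motifs if m.status in ("strict", "his_to_cys")),
                  key=lambda m: m.start)


def _subtype7_from_pattern(pattern: str) -> str:
    if pattern.count("D") != 1 or not 1 <= pattern.count("C") <= 2:
        raise ClassificationError(
            f"type-7 architecture needs one DUF1271 and 1-2 CISD motifs, got {pattern!r}")
    if pattern in ("DC", "DCC", "CDC"):
        return pattern
    raise ClassificationError(f"unrecognised type-7 segment order {pattern!r}")


def assign_subtype7(arch: ArchitectureAnnotation,
                    extra_motifs: Sequence[tuple[int, int]] = ()) -> str:
    """DC / DCC / CDC from the linear DUF1271 (D) and CISD-motif (C) order.

    ``extra_motifs`` adds scanned motif intervals not present in the
    annotation.
    """
    marks = [(s.start, "D" if s.kind == "DUF1271" else "C")
             for s in arch.segments if s.kind in ("DUF1271", "CISD_motif")]
    annotated = [(s.start, s.end) for s in arch.of_kind("CISD_motif")]
    for start, end in extra_motifs:
        if not any(s <= end and start <= e for s, e in annotated):
            marks.append((start, "C"))
    pattern = "".join(m for _, m in sorted(marks))
    return _subtype7_from_pattern(pattern)


def _seed_identity(seq: str, seed: SequenceRecord) -> float:
    """Ungapped percent identity of a global alignment against one seed."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    target = seed.ungapped
    if not seq or not target:
        return 0.0
    aln = aligner.align(seq, target)[0]
    matches = sum(
        1
        for (qs, qe), (ts, te) in zip(*aln.aligned)
        for q, t in zip(seq[qs:qe], target[ts:te])
        if q == t
    )
    return 100.0 * matches / max(len(seq), len(target))


def homology_call(seq: SequenceRecord,
                  seeds: Mapping[str, Sequence[SequenceRecord]]) -> tuple[str | None, float]:
    """Winner-takes-all nearest-seed type label by percent identity.

    Returns (type label, best identity); ties return (None, identity) and
    leave the taxonomic default standing.
    """
    best: dict[str, float] = {}
    for label, records in seeds.items():
        if records:
            best[label] = max(_seed_identity(seq.ungapped, r) for r in records)
    if not best:
        return None, 0.0
    top = max(best.values())
    winners = [k for k, v in best.items() if abs(v - top) < 1e-9]
    if len(winners) != 1:
        return None, top
    return winners[0], top


def assign_type(motifs: Sequence[MotifHit],
                arch: ArchitectureAnnotation | None = None,
                taxon: str = "unknown",
                spacing_range: tuple[int, int] = DEFAULT_SPACING_RANGE,
                seeds: Mapping[str, Sequence[SequenceRecord]] | None = None,
                sequence: SequenceRecord | None = None) -> TypeCall:
    """Classify one sequence; see module docstring for the decision order."""
    if taxon not in TAXA:
        raise ClassificationError(f"unknown taxon: {taxon!r}")
    arch = arch or ArchitectureAnnotation()
    bearing = _motif_bearing(motifs)
    evidence: list[str] = []

    # annotated CISD-motif segments are architectural evidence in their own
    # right (a fully disrupted motif no longer scans, but its annotation
    # still defines the domain arrangement)
    intervals = [(m.start, m.end) for m in bearing]
    for seg in arch.of_kind("CISD_motif"):
        if not any(s <= seg.end and seg.start <= e for s, e in intervals):
            intervals.append((seg.start, seg.end))
            evidence.append("arch_motif")
    intervals.sort()

    if not intervals:
        return TypeCall("orphan", evidence=("no_motif",), confidence="architectural")

    # tandem motifs → type 6, or 5 with a C-terminal FMN-binding fusion
    if len(intervals) >= 2:
        lo, hi = spacing_range
        for (_, a_end), (b_start, b_end) in zip(intervals, intervals[1:]):
            spacing = b_start - a_end - 1
            if lo <= spacing <= hi:
                evidence.append(f"tandem_spacing:{spacing}")
                fmn = arch.of_kind("FMN_binding")
                if fmn and fmn[-1].start > b_end:
                    evidence.append("fmn_fusion")
                    return TypeCall("5", evidence=tuple(evidence))
                return TypeCall("6", evidence=tuple(evidence))

    if arch.of_kind("DUF1271"):
        sub = assign_subtype7(arch, extra_motifs=intervals)
        return TypeCall("7", subtype7=sub,
                        evidence=("duf1271_fusion", f"subtype:{sub}"))

    # single motif: taxonomy default with optional homology override
    defaults = {"eukaryote": "1", "apicomplexa": "2", "archaea": "3", "bacteria": "4"}
    default = defaults.get(taxon)
    if seeds and sequence is not None:
        label, ident = homology_call(sequence, seeds)
        if label is not None:
            return TypeCall(label, evidence=(f"seed_identity:{label}:{ident:.1f}",),
                            confidence="homology")
        evidence.append("seed_identity_tie")
    if default is None:
        evidence.append("unknown_taxon")
        return TypeCall("orphan", evidence=tuple(evidence), confidence="taxonomic")
    evidence.append(f"single_motif_taxon:{taxon}")
    return TypeCall(default, evidence=tuple(evidence), confidence="taxonomic")


def column_conservation(alignment: Sequence[SequenceRecord], column: int,
                        residue_set: set[str] | frozenset[str]) -> float:
    """Fraction of non-gap rows whose residue at a 1-based alignment column
    belongs to ``residue_set``."""
    if not alignment:
        raise ClassificationError("empty alignment")
    width = len(alignment[0].residues)
    for rec in alignment:
        if len(rec.residues) != width:
            raise ClassificationError(
                f"ragged alignment: {rec.id!r} has length {len(rec.residues)} != {width}")
    if not 1 <= column <= width:
        raise ClassificationError(f"column {column} outside alignment width {width}")
    residues = [rec.residues[column - 1] for rec in alignment]
    non_gap = [r for r in residues if r != "-"]
    if not non_gap:
        return 0.0
    upper = {r.upper() for r in residue_set}
    return sum(1 for r in non_gap if r in upper) / len(non_gap)
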