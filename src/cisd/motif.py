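"""CDGSH and P-motif scanning.

The CDGSH motif is the 17-residue consensus [ΦCXCXX(S/T)XXXPΦCDG(S/T/A)H]
(Φ hydrophobic, X any); its positions 2, 4, 13 (cysteines) and 17
(histidine) ligate the [2Fe-2S] cluster.  Scanning distinguishes

* ``strict`` hits — every constrained position satisfied;
* ``his_to_cys`` hits — the single deviation is the terminal histidine
  ligand replaced by cysteine, a substitution that can still bind a
  cluster;
* ``disrupted`` hits — any other constrained-position substitution
  (e.g. Cys→Ser, His→Gly/Ser/Gln/Asn), up to ``max_mismatch`` of them.

The P motif [GPΦXΦ] supplies the lid-proline that caps a bridging sulfide
of the cluster; it is scanned strictly.

All positions are reported 1-based in ungapped sequence coordinates, so
scanning is invariant to alignment gaps in the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import SequenceRecord

#: Default hydrophobic (Φ) residue set; observed Φ occupants include W, F, A, L.
DEFAULT_HYDROPHOBIC = frozenset("ACFILMPVWY")

#: Offsets (0-based within the 17-mer) of the four cluster ligands.
LIGAND_OFFSETS = (1, 3, 12, 16)

MOTIF_LENGTH = 17
PMOTIF_LENGTH = 5


@dataclass(frozen=True)
class MotifSpec:
    """Positional rules of the 17-residue CDGSH consensus.

    Constrained positions (1-based within the motif): 1=Φ, 2=C, 4=C,
    7=S/T, 11=P, 12=Φ, 13=C, 14=D, 15=G, 16=S/T/A, 17=H.  Positions
    3, 5, 6, 8, 9, 10 are unconstrained (X).
    """

    hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC

    def allowed(self, position: int) -> frozenset[str] | None:
        """Allowed residues at 1-based motif position, or None if free."""
        phi = self.hydrophobic_set
        table: dict[int, frozenset[str]] = {
            1: phi, 2: frozenset("C"), 4: frozenset("C"),
            7: frozenset("ST"), 11: frozenset("P"), 12: phi,
            13: frozenset("C"), 14: frozenset("D"), 15: frozenset("G"),
            16: frozenset("STA"), 17: frozenset("H"),
        }
        return table.get(position)

    @property
    def constrained_positions(self) -> tuple[int, ...]:
        return (1, 2, 4, 7, 11, 12, 13, 14, 15, 16, 17)


@dataclass(frozen=True)
class MotifHit:
    """One motif match in ungapped 1-based coordinates."""

    record_id: str
    start: int
    window: str
    status: str  # strict | his_to_cys | disrupted | pmotif
    mismatches: tuple[tuple[int, str], ...] = ()
    ligand_positions: tuple[int, ...] = ()
    lid_p: bool = field(default=False)

    @property
    def end(self) -> int:
        return self.start + len(self.window) - 1


def _assess_window(window: str, spec: MotifSpec) -> list[tuple[int, str]]:
    """Mismatches at constrained positions; 'U'/'X' never satisfy a constraint."""
    mismatches = []
    for pos in spec.constrained_positions:
        residue = window[pos - 1]
        allowed = spec.allowed(pos)
        if residue in ("U", "X") or residue not in allowed:
            mismatches.append((pos, residue))
    return mismatches


def scan_cdgsh(seq: SequenceRecord, spec: MotifSpec | None = None,
               max_mismatch: int = 0) -> list[MotifHit]:
    """Scan a sequence for CDGSH motifs allowing up to ``max_mismatch``
    constrained-position substitutions.

    A strict hit suppresses any relaxed hit that shares its third-cysteine
    (C13) position, so a degenerate window overlapping an intact motif is
    not double-reported.  Hits are sorted by start.
    """
    if spec is None:
        spec = MotifSpec()
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    residues = seq.ungapped
    hits: list[MotifHit] = []
    for i in range(len(residues) - MOTIF_LENGTH + 1):
        window = residues[i:i + MOTIF_LENGTH]
        mismatches = _assess_window(window, spec)
        if len(mismatches) > max_mismatch:
            continue
        start = i + 1
        if not mismatches:
            status = "strict"
        elif len(mismatches) == 1 and mismatches[0][0] == 17 and mismatches[0][1] == "C":
            status = "his_to_cys"
        else:
            status = "disrupted"
        hits.append(MotifHit(
            record_id=seq.id,
            start=start,
            window=window,
            status=status,
            mismatches=tuple(mismatches),
            ligand_positions=tuple(start + off for off in LIGAND_OFFSETS),
            lid_p=window[10] == "P",
        ))
    strict_c13 = {h.ligand_positions[2] for h in hits if h.status == "strict"}
    hits = [h for h in hits
            if h.status == "strict" or h.ligand_positions[2] not in strict_c13]
    hits.sort(key=lambda h: h.start)
    return hits


def scan_pmotif(seq: SequenceRecord,
                hydrophobic_set: frozenset[str] = DEFAULT_HYDROPHOBIC) -> list[MotifHit]:
    """Scan for the 5-residue P motif [GPΦXΦ] (strict matching only)."""
    residues = seq.ungapped
    hits = []
    for i in range(len(residues) - PMOTIF_LENGTH + 1):
        w = residues[i:i + PMOTIF_LENGTH]
        if (w[0] == "G" and w[1] == "P"
                and w[2] in hydrophobic_set and w[2] not in "UX"
                and w[4] in hydrophobic_set and w[4] not in "UX"):
            hits.append(MotifHit(
                record_id=seq.id, start=i + 1, window=w, status="pmotif",
                ligand_positions=(), lid_p=True,
            ))
    return hits
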