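"""Ground-truth synthetic data for every pipeline stage.

Two generators:

* :func:`gen_sequences` plants intact or degenerate CDGSH motifs (plus
  fusion-domain architecture and taxonomy labels) into random background
  sequences, emitting a truth table so scanner recall and classifier
  accuracy are measurable exactly.  Degenerate motifs use the
  substitutions observed in real tandem-motif domains: His17→Cys (may
  still bind a cluster) or a disrupting change (Cys→Ser; His→Gly, Ser,
  Gln or Asn).
* :func:`gen_dimer` builds a two-module coordinate set from an idealized
  17-Cα + [2Fe-2S] template at an exactly controlled cluster
  center-to-center distance, inter-module shift angle and (optionally)
  perfect two-fold symmetry, with Gaussian coordinate noise added last.

Both are deterministic for a fixed seed.  Default type proportions follow
the observed species distribution across the seven types; background
residue frequencies are uniform (no downstream claim depends on
composition).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .classify import ArchitectureAnnotation, Segment
from .io import Atom, RecordMeta, Residue, SequenceRecord, StructureModel, compose_record_name
from .motif import DEFAULT_HYDROPHOBIC, MOTIF_LENGTH

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default mix: proportional to the observed species counts per type.
DEFAULT_TYPE_MIX: dict[str, float] = {
    "1": 98, "2": 9, "3": 18, "4": 103, "5": 32, "6": 128, "7": 53, "orphan": 18,
}

DEFAULT_TANDEM_SPACING = (15, 25)  # residues between tandem motifs (about 20)

_TAXON_FOR_TYPE = {
    "1": ("eukaryote",), "2": ("apicomplexa",), "3": ("archaea",),
    "4": ("bacteria",), "5": ("bacteria",), "6": ("eukaryote", "bacteria"),
    "7": ("archaea", "bacteria"), "orphan": ("bacteria", "archaea", "eukaryote"),
}
_PHYLA_FOR_TAXON = {
    "eukaryote": ("Chor", "Arth", "Stre", "Nema", "Prot"),
    "apicomplexa": ("Prot",),
    "archaea": ("Eury", "Cren"),
    "bacteria": ("Apro", "Bpro", "Gpro", "Acti", "Firm", "Bact", "Cyan"),
}
_SUBTYPE7_WEIGHTS = {"DC": 14, "DCC": 8, "CDC": 31}  # observed species counts

DISRUPTING_SUBS = {
    "C": ("S",),            # Cys -> Ser at a cysteine ligand position
    "H": ("G", "S", "Q", "N"),  # His -> Gly/Ser/Gln/Asn at position 17
}


@dataclass
class SeqTruth:
    record_id: str
    cisd_type: str
    subtype7: str
    taxon: str
    motif_starts: tuple[int, ...]
    motif_statuses: tuple[str, ...]
    architecture: ArchitectureAnnotation


@dataclass
class SyntheticSequences:
    records: list[SequenceRecord]
    truth: list[SeqTruth]
    metas: list[RecordMeta] = field(default_factory=list)

    @property
    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "record_id": t.record_id,
                "cisd_type": t.cisd_type,
                "subtype7": t.subtype7,
                "taxon": t.taxon,
                "motif_starts": ";".join(map(str, t.motif_starts)),
                "motif_statuses": ";".join(t.motif_statuses),
            }
            for t in self.truth
        ])

    def architecture_of(self, record_id: str) -> ArchitectureAnnotation:
        for t in self.truth:
            if t.record_id == record_id:
                return t.architecture
        raise KeyError(record_id)


def _sample_motif(rng: np.random.Generator) -> str:
    """One intact 17-residue CDGSH instance drawn from the consensus."""
    phi = sorted(DEFAULT_HYDROPHOBIC)
    window = []
    for pos in range(1, MOTIF_LENGTH + 1):
        if pos in (1, 12):
            window.append(phi[rng.integers(len(phi))])
        elif pos in (2, 4, 13):
            window.append("C")
        elif pos == 7:
            window.append("ST"[rng.integers(2)])
        elif pos == 11:
            window.append("P")
        elif pos == 14:
            window.append("D")
        elif pos == 15:
            window.append("G")
        elif pos == 16:
            window.append("STA"[rng.integers(3)])
        elif pos == 17:
            window.append("H")
        else:
            window.append(AMINO_ACIDS[rng.integers(20)])
    return "".join(window)


def _degenerate(window: str, rng: np.random.Generator) -> tuple[str, str]:
    """Apply one degeneracy edit; returns (window, status)."""
    if rng.random() < 0.5:
        return window[:16] + "C", "his_to_cys"
    if rng.random() < 0.5:  # hit a cysteine ligand
        pos = int(rng.choice([2, 4, 13]))
        sub = DISRUPTING_SUBS["C"][rng.integers(len(DISRUPTING_SUBS["C"]))]
    else:  # hit the histidine
        pos, subs = 17, DISRUPTING_SUBS["H"]
        sub = subs[rng.integers(len(subs))]
    return window[:pos - 1] + sub + window[pos:], "disrupted"


def _background(n: int, rng: np.random.Generator,
                freqs: Mapping[str, float] | None = None) -> str:
    if freqs is None:
        idx = rng.integers(0, 20, size=n)
        return "".join(AMINO_ACIDS[i] for i in idx)
    letters = sorted(freqs)
    p = np.array([freqs[a] for a in letters], dtype=float)
    p /= p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def gen_sequences(n: int, type_mix: Mapping[str, float] | None = None,
                  degeneracy_rate: float = 0.17, seed: int = 0,
                  tandem_spacing: tuple[int, int] = DEFAULT_TANDEM_SPACING,
                  background_freqs: Mapping[str, float] | None = None
                  ) -> SyntheticSequences:
    """Generate ``n`` labelled sequences with planted motifs and architecture.

    ``degeneracy_rate`` is the probability that one of the two motifs of a
    tandem-motif (type 5/6) sequence carries a degeneracy edit; the
    observed fraction in the real tandem-motif families is 17%.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not 0.0 <= degeneracy_rate <= 1.0:
        raise ValueError("degeneracy_rate must be in [0, 1]")
    lo, hi = tandem_spacing
    if lo < 1 or hi < lo:
        raise ValueError(f"bad tandem spacing range {tandem_spacing}")
    mix = dict(type_mix or DEFAULT_TYPE_MIX)
    labels = sorted(mix)
    weights = np.array([mix[k] for k in labels], dtype=float)
    if (weights < 0).any() or weights.sum() == 0:
        raise ValueError("type_mix weights must be non-negative and not all zero")
    weights /= weights.sum()

    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    truths: list[SeqTruth] = []
    metas: list[RecordMeta] = []
    for idx in range(n):
        cisd_type = labels[rng.choice(len(labels), p=weights)]
        taxa = _TAXON_FOR_TYPE[cisd_type]
        taxon = taxa[rng.integers(len(taxa))]
        phyla = _PHYLA_FOR_TAXON[taxon]
        phylum = phyla[rng.integers(len(phyla))]

        segments: list[Segment] = []
        starts: list[int] = []
        statuses: list[str] = []
        subtype7 = "none"
        degenerate = False

        def plant(seq: str, window: str, status: str) -> str:
            starts.append(len(seq) + 1)
            statuses.append(status)
            segments.append(Segment("CISD_motif", len(seq) + 1, len(seq) + MOTIF_LENGTH))
            return seq + window

        seq = _background(int(rng.integers(20, 41)), rng, background_freqs)
        if cisd_type in ("1", "2", "3", "4"):
            seq = plant(seq, _sample_motif(rng), "strict")
        elif cisd_type in ("5", "6"):
            w1, w2 = _sample_motif(rng), _sample_motif(rng)
            s1 = s2 = "strict"
            if rng.random() < degeneracy_rate:
                degenerate = True
                edited, status = _degenerate(_sample_motif(rng), rng)
                if rng.random() < 0.5:
                    w1, s1 = edited, status
                else:
                    w2, s2 = edited, status
            seq = plant(seq, w1, s1)
            spacing = int(rng.integers(lo, hi + 1))
            seq += _background(spacing, rng, background_freqs)
            seq = plant(seq, w2, s2)
            if cisd_type == "5":
                fmn_len = int(rng.integers(150, 201))
                fmn_start = len(seq) + 6
                seq += _background(5 + fmn_len, rng, background_freqs)
                segments.append(Segment("FMN_binding", fmn_start, fmn_start + fmn_len - 1))
        elif cisd_type == "7":
            subs = sorted(_SUBTYPE7_WEIGHTS)
            p7 = np.array([_SUBTYPE7_WEIGHTS[s] for s in subs], dtype=float)
            subtype7 = subs[rng.choice(len(subs), p=p7 / p7.sum())]
            duf_len = int(rng.integers(60, 91))
            wide = int(rng.integers(50, 71))  # keeps type-7 CISDs out of tandem range

            def plant_duf(seq: str) -> str:
                segments.append(Segment("DUF1271", len(seq) + 1, len(seq) + duf_len))
                return seq + _background(duf_len, rng, background_freqs)

            if subtype7 == "DC":
                seq = plant_duf(seq)
                seq += _background(10, rng, background_freqs)
                seq = plant(seq, _sample_motif(rng), "strict")
            elif subtype7 == "DCC":
                seq = plant_duf(seq)
                seq += _background(10, rng, background_freqs)
                seq = plant(seq, _sample_motif(rng), "strict")
                seq += _background(wide, rng, background_freqs)
                seq = plant(seq, _sample_motif(rng), "strict")
            else:  # CDC
                seq = plant(seq, _sample_motif(rng), "strict")
                seq += _background(10, rng, background_freqs)
                seq = plant_duf(seq)
                seq += _background(10, rng, background_freqs)
                seq = plant(seq, _sample_motif(rng), "strict")
        seq += _background(int(rng.integers(15, 31)), rng, background_freqs)

        meta = RecordMeta(
            cisd_type=cisd_type,
            phylum_abbrev=phylum,
            genus_initial=chr(ord("A") + int(rng.integers(26))),
            species=f"sp{idx:04d}",
            genebank_id=f"SYN_{idx:06d}",
            subtype7=subtype7,
            degenerate_flag=degenerate,
            eukaryote_prefix=(cisd_type in ("5", "6") and taxon == "eukaryote"),
        )
        name = compose_record_name(meta)
        records.append(SequenceRecord(id=name, residues=seq, meta=meta))
        metas.append(meta)
        truths.append(SeqTruth(
            record_id=name, cisd_type=cisd_type, subtype7=subtype7, taxon=taxon,
            motif_starts=tuple(starts), motif_statuses=tuple(statuses),
            architecture=ArchitectureAnnotation(segments),
        ))
    return SyntheticSequences(records=records, truth=truths, metas=metas)


# ---------------------------------------------------------------------------
# Genome sets for profiling

def gen_genome_set(n_genera: int, genomes_per_genus: int, retention_p: float,
                   seed: int = 0):
    """Genome set with planted per-genus CISD retention probability.

    Returns ``(positives, genome_set)`` as lists of
    :class:`cisd.profile.SpeciesKey`; each genus keeps at least one
    positive species so every genus qualifies for the loss statistic.
    """
    from .profile import SpeciesKey

    rng = np.random.default_rng(seed)
    genome_set, positives = [], []
    for g in range(n_genera):
        genus = f"genus{g:03d}"
        keys = [SpeciesKey("bacteria", "gpro", genus, f"sp{s:03d}")
                for s in range(genomes_per_genus)]
        genome_set.extend(keys)
        pos = [k for k in keys if rng.random() < retention_p]
        if not pos:
            pos = [keys[int(rng.integers(len(keys)))]]
        positives.extend(pos)
    return positives, genome_set


# ---------------------------------------------------------------------------
# Dimeric coordinate sets

@dataclass(frozen=True)
class DimerParams:
    center_distance: float = 15.0
    shift_angle: float = 0.0
    symmetric: bool = False
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.center_distance <= 0:
            raise ValueError("center_distance must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.symmetric and abs(self.shift_angle) > 1e-12:
            raise ValueError(
                "a symmetric (two-fold) placement requires shift_angle = 0")


def load_template() -> tuple[np.ndarray, np.ndarray]:
    """Bundled idealized module template: (17 Cα, 4 cluster atoms FE,FE,S,S),
    translated so the cluster centroid sits at the origin."""
    ca, cluster = [], []
    with resources.files("cisd.data").joinpath("module_template.csv").open() as fh:
        rows = [r for r in csv.reader(fh)
                if r and not r[0].startswith("#") and r[0] != "kind"]
    for kind, _idx, x, y, z in rows:
        (ca if kind == "CA" else cluster).append([float(x), float(y), float(z)])
    ca = np.asarray(ca)
    cluster = np.asarray(cluster)
    shift = cluster.mean(axis=0)
    return ca - shift, cluster - shift


_TEMPLATE_RESNAMES = ["LEU", "CYS", "ALA", "CYS", "ALA", "ALA", "SER", "ALA",
                      "ALA", "ALA", "PRO", "LEU", "CYS", "ASP", "GLY", "SER", "HIS"]
_LIGAND_ATOM_FOR = {"CYS": "SG", "HIS": "NE2"}
_LIGAND_POSITIONS = (2, 4, 13, 17)  # 1-based within the module


def _module_residues(chain: str, ca: np.ndarray, cluster: np.ndarray
                     ) -> tuple[list[Residue], Residue]:
    """Residues (with ligand pseudo-atoms) and the FES het-group for one module."""
    fe = cluster[:2]
    residues = []
    for i, name in enumerate(_TEMPLATE_RESNAMES):
        atoms = [Atom("CA", "C", tuple(ca[i]))]
        if (i + 1) in _LIGAND_POSITIONS:
            # ligand pseudo-atom 2.3 Å out from the nearest Fe toward the Cα
            nearest = fe[np.argmin(np.linalg.norm(fe - ca[i], axis=1))]
            direction = ca[i] - nearest
            direction /= np.linalg.norm(direction)
            pos = nearest + 2.3 * direction
            aname = _LIGAND_ATOM_FOR[name]
            atoms.append(Atom(aname, "N" if aname == "NE2" else "S", tuple(pos)))
        residues.append(Residue(chain, i + 1, "", name, atoms))
    fes = Residue(chain, 101, "", "FES", [
        Atom("FE1", "FE", tuple(cluster[0])),
        Atom("FE2", "FE", tuple(cluster[1])),
        Atom("S1", "S", tuple(cluster[2])),
        Atom("S2", "S", tuple(cluster[3])),
    ])
    return residues, fes


def gen_dimer(params: DimerParams,
              template: tuple[np.ndarray, np.ndarray] | None = None) -> StructureModel:
    """Two-module coordinate set with exactly realized geometry.

    Chain A is the template module with its cluster centroid at the
    origin.  Chain B is a rigid copy: first the two-fold placement (180°
    rotation about z through the interface midpoint) that puts its cluster
    centroid at ``center_distance`` along x, then a rotation of the whole
    copy about z through the origin by ``shift_angle`` (the angle
    recovered by :func:`cisd.struct.intermodule_angle` against the
    unshifted reference).  Gaussian noise of ``noise_sigma`` Å is added
    last to every coordinate.
    """
    ca, cluster = load_template() if template is None else template
    if ca.shape != (17, 3) or cluster.shape != (4, 3):
        raise ValueError("template must be 17 Cα + 4 cluster atoms")

    d = params.center_distance
    p = np.array([d / 2.0, 0.0, 0.0])
    flip = np.diag([-1.0, -1.0, 1.0])  # 180° about z

    def place(q: np.ndarray) -> np.ndarray:
        out = (q - p) @ flip.T + p
        if params.shift_angle:
            th = np.radians(params.shift_angle)
            rot = np.array([[np.cos(th), -np.sin(th), 0.0],
                            [np.sin(th), np.cos(th), 0.0],
                            [0.0, 0.0, 1.0]])
            out = out @ rot.T
        return out

    ca_b, cluster_b = place(ca), place(cluster)

    rng = np.random.default_rng(params.seed)
    if params.noise_sigma > 0:
        ca = ca + rng.normal(0, params.noise_sigma, ca.shape)
        cluster = cluster + rng.normal(0, params.noise_sigma, cluster.shape)
        ca_b = ca_b + rng.normal(0, params.noise_sigma, ca_b.shape)
        cluster_b = cluster_b + rng.normal(0, params.noise_sigma, cluster_b.shape)

    res_a, fes_a = _module_residues("A", ca, cluster)
    res_b, fes_b = _module_residues("B", ca_b, cluster_b)
    return StructureModel(name="synthetic_dimer", polymer=res_a + res_b,
                          het_groups=[fes_a, fes_b], waters=[])
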