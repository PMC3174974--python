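"""Readers, writers and naming conventions.

Sequence collections are plain or gap-aligned FASTA.  Record names follow the
underscore-joined convention used throughout the supplementary sequence sets:

    [e]Type<T>[<subtype7>][<copy>]['] _ <PhylumAbbrev> _ <GenusInitial> _ <species> _ <GenBankID>

e.g. ``Type6_Apro_M_magneticum_YP_423370``.  A leading ``e`` marks a
eukaryotic member of the tandem-motif families, a trailing prime marks a
degenerate CDGSH motif, and type-7 names carry the DC/DCC/CDC subtype.
GenBank identifiers may themselves contain underscores, so the id is the
re-joined tail after the first four fields.

Structures are read from PDB or mmCIF through :mod:`gemmi` into a flat
:class:`StructureModel` that keeps author residue numbering, resolves
altlocs by occupancy, strips hydrogens, and separates polymer residues from
het-groups (e.g. FES clusters) and waters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class DialectError(FormatError):
    """Raised when a structure file extension is not recognised."""


class RecordNameError(ValueError):
    """Raised when a record name does not follow the naming convention."""


ALLOWED_RESIDUE_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYXUBZ-")

#: Controlled vocabulary of phylum / class abbreviations used in record names.
PHYLUM_ABBREVS = {
    # eukaryotes
    "Arth": "Arthropoda", "Baci": "Bacillariophyta", "Cnid": "Cnidaria",
    "Chor": "Chordata", "Chlp": "Chlorophyta", "Echi": "Echinodermata",
    "Nema": "Nematoda", "Phae": "Phaeophyceae", "Plac": "Placozoa",
    "Plat": "Platyhelminthes", "Stre": "Streptophyta", "Prot": "Protist",
    # bacteria
    "Acid": "Acidobacteria", "Acti": "Actinobacteria",
    "Apro": "Alphaproteobacteria", "Aqui": "Aquificae",
    "Bact": "Bacteroidetes", "Bpro": "Betaproteobacteria",
    "Chlf": "Chloroflexi", "Chlo": "Chlorobi", "Cyan": "Cyanobacteria",
    "Dein": "Deinococcus-Thermus", "Dpro": "Deltaproteobacteria",
    "Epro": "Epsilonproteobacteria", "Firm": "Firmicutes",
    "Fuso": "Fusobacteria", "Gpro": "Gammaproteobacteria",
    "Nitro": "Nitrospirae", "Plan": "Planctomycetes",
    "Spir": "Spirochaetes", "Verr": "Verrucomicrobia",
    "Zpro": "Zetaproteobacteria",
    # archaea
    "Eury": "Euryarchaeota", "Cren": "Crenarchaeota",
}

_EUKARYOTE_ABBREVS = frozenset({
    "Arth", "Baci", "Cnid", "Chor", "Chlp", "Echi", "Nema", "Phae",
    "Plac", "Plat", "Stre", "Prot",
})
_ARCHAEA_ABBREVS = frozenset({"Eury", "Cren"})

CISD_TYPES = ("1", "2", "2a", "2b", "3", "4", "5", "6", "7", "orphan")
SUBTYPES7 = ("DC", "DCC", "CDC", "none")


def superkingdom_of(phylum_abbrev: str) -> str:
    if phylum_abbrev in _EUKARYOTE_ABBREVS:
        return "Eukaryota"
    if phylum_abbrev in _ARCHAEA_ABBREVS:
        return "Archaea"
    if phylum_abbrev in PHYLUM_ABBREVS:
        return "Bacteria"
    raise RecordNameError(f"unknown phylum abbreviation: {phylum_abbrev!r}")


@dataclass(frozen=True)
class RecordMeta:
    """Metadata parsed from an underscore-joined supplementary record name."""

    cisd_type: str
    phylum_abbrev: str
    genus_initial: str
    species: str
    genebank_id: str
    subtype7: str = "none"
    subtype7_copy: int | None = None
    degenerate_flag: bool = False
    eukaryote_prefix: bool = False

    def __post_init__(self) -> None:
        if self.cisd_type not in CISD_TYPES:
            raise RecordNameError(f"unknown CISD type: {self.cisd_type!r}")
        if self.subtype7 not in SUBTYPES7:
            raise RecordNameError(f"unknown type-7 subtype: {self.subtype7!r}")
        if (self.subtype7 != "none") != (self.cisd_type == "7"):
            raise RecordNameError(
                f"subtype7={self.subtype7!r} inconsistent with type {self.cisd_type!r}")
        if self.phylum_abbrev not in PHYLUM_ABBREVS:
            raise RecordNameError(f"unknown phylum abbreviation: {self.phylum_abbrev!r}")

    @property
    def superkingdom(self) -> str:
        return superkingdom_of(self.phylum_abbrev)


@dataclass
class SequenceRecord:
    """One protein sequence, possibly gap-aligned, with optional parsed metadata."""

    id: str
    residues: str
    description: str = ""
    meta: RecordMeta | None = None

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - ALLOWED_RESIDUE_LETTERS
        if bad:
            raise FormatError(
                f"record {self.id!r}: residue letters {sorted(bad)} not allowed")
        self.residues = self.residues.upper()

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def with_meta(self) -> "SequenceRecord":
        """Return a copy whose ``meta`` is parsed from the record id."""
        return replace(self, meta=parse_record_name(self.id))


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read plain or gap-aligned FASTA, preserving record order and gaps."""
    path = Path(path)
    text = path.read_text()
    if ">" not in text:
        raise FormatError(f"{path}: not FASTA (no '>' header found)")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq)
        if not residues.replace("-", ""):
            raise FormatError(f"{path}: record {rec.id!r} has no residues")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# Record names

_TYPE_TOKEN_RE = re.compile(
    r"^(?P<euk>e?)Type(?P<type>2a|2b|[1-7])(?P<sub>DCC|CDC|DC)?(?P<copy>[12])?(?P<prime>'?)$"
)
_ORPHAN_TOKEN_RE = re.compile(r"^(?P<euk>e?)(Orphan|TypeO)(?P<prime>'?)$", re.IGNORECASE)


def parse_record_name(name: str) -> RecordMeta:
    """Parse an underscore-joined record name into :class:`RecordMeta`.

    Splitting is positional left-to-right: the first four underscore fields
    are type, phylum, genus initial and species; everything after is
    re-joined as the GenBank id (ids such as ``YP_423370`` contain
    underscores themselves).
    """
    tokens = name.split("_")
    if len(tokens) < 5:
        raise RecordNameError(
            f"{name!r}: expected >= 5 underscore-joined fields, got {len(tokens)}")
    type_tok, phylum, genus, species = tokens[:4]
    genebank_id = "_".join(tokens[4:])
    m = _TYPE_TOKEN_RE.match(type_tok)
    if m:
        cisd_type = m.group("type")
        subtype7 = m.group("sub") or "none"
        copy = int(m.group("copy")) if m.group("copy") else None
        if cisd_type != "7" and subtype7 != "none":
            raise RecordNameError(f"{name!r}: subtype on non-type-7 token {type_tok!r}")
    else:
        mo = _ORPHAN_TOKEN_RE.match(type_tok)
        if not mo:
            raise RecordNameError(f"{name!r}: unrecognised type token {type_tok!r}")
        m, cisd_type, subtype7, copy = mo, "orphan", "none", None
    if phylum not in PHYLUM_ABBREVS:
        raise RecordNameError(f"{name!r}: unknown phylum token {phylum!r}")
    if not (len(genus) == 1 and genus.isalpha()):
        raise RecordNameError(f"{name!r}: genus-initial token {genus!r} is not one letter")
    if not genebank_id:
        raise RecordNameError(f"{name!r}: empty GenBank id")
    return RecordMeta(
        cisd_type=cisd_type,
        phylum_abbrev=phylum,
        genus_initial=genus,
        species=species,
        genebank_id=genebank_id,
        subtype7=subtype7,
        subtype7_copy=copy,
        degenerate_flag=m.group("prime") == "'",
        eukaryote_prefix=m.group("euk") == "e",
    )


def compose_record_name(meta: RecordMeta) -> str:
    """Inverse of :func:`parse_record_name`."""
    if meta.cisd_type == "orphan":
        tok = "Orphan"
    else:
        tok = f"Type{meta.cisd_type}"
        if meta.subtype7 != "none":
            tok += meta.subtype7
        if meta.subtype7_copy is not None:
            tok += str(meta.subtype7_copy)
    if meta.degenerate_flag:
        tok += "'"
    if meta.eukaryote_prefix:
        tok = "e" + tok
    return "_".join([tok, meta.phylum_abbrev, meta.genus_initial,
                     meta.species, meta.genebank_id])


# ---------------------------------------------------------------------------
# Structures

WATER_NAMES = frozenset({"HOH", "WAT"})

_STANDARD_AA = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "SEC", "MSE",
})


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)


@dataclass
class Residue:
    chain: str
    seqnum: int
    icode: str
    name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seqnum, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES


@dataclass
class StructureModel:
    """Flat coordinate model: polymer residues, het-groups and waters."""

    name: str
    polymer: list[Residue]
    het_groups: list[Residue]
    waters: list[Residue]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.polymer + self.het_groups + self.waters:
            seen.setdefault(r.chain, None)
        return list(seen)

    @property
    def residues(self) -> list[Residue]:
        return self.polymer + self.het_groups + self.waters

    def polymer_chain(self, chain: str) -> list[Residue]:
        return [r for r in self.polymer if r.chain == chain]

    def atom_count(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def find_residue(self, chain: str, seqnum: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.key == (chain, seqnum, icode):
                return r
        return None

    def subset_chains(self, chains: Sequence[str], include_het: bool = True) -> "StructureModel":
        keep = set(chains)
        return StructureModel(
            name=self.name,
            polymer=[r for r in self.polymer if r.chain in keep],
            het_groups=[r for r in self.het_groups if r.chain in keep] if include_het else [],
            waters=[],
        )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one atom per name: highest occupancy, first wins on ties."""
    best: dict[str, Atom] = {}
    for a in atoms:
        prev = best.get(a.name)
        if prev is None or a.occupancy > prev.occupancy + 1e-12:
            best[a.name] = a
    return list(best.values())


def read_structure(path: str | Path, altloc_policy: str = "occupancy") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens are stripped; altlocs collapse to the highest-occupancy copy
    (first on ties); residues keep author numbering and insertion codes.
    """
    path = Path(path)
    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy: {altloc_policy!r}")
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        fmt = gemmi.CoorFormat.Pdb
    elif suffix in {".cif", ".mmcif"}:
        fmt = gemmi.CoorFormat.Mmcif
    else:
        raise DialectError(f"{path}: unrecognised structure extension {suffix!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse structure: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise FormatError(f"{path}: structure has no models")
    model = st[0]

    polymer: list[Residue] = []
    hets: list[Residue] = []
    waters: list[Residue] = []
    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                if at.element.is_hydrogen:
                    continue
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    xyz=(at.pos.x, at.pos.y, at.pos.z),
                    occupancy=at.occ,
                    altloc=at.altloc or "",
                ))
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            for a in atoms:
                if not np.all(np.isfinite(a.coord)):
                    raise FormatError(f"{path}: non-finite coordinates in {res.name}")
            residue = Residue(
                chain=chain.name,
                seqnum=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                name=res.name.strip(),
                atoms=atoms,
            )
            if residue.is_water:
                waters.append(residue)
            elif residue.name in _STANDARD_AA:
                polymer.append(residue)
            else:
                hets.append(residue)
    model_out = StructureModel(name=path.stem, polymer=polymer,
                               het_groups=hets, waters=waters)
    if model_out.atom_count() == 0:
        raise FormatError(f"{path}: structure contains no atoms")
    return model_out


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a :class:`StructureModel` as PDB or mmCIF (by extension)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = model.name
    gmodel = gemmi.Model("1")
    by_chain: dict[str, list[Residue]] = {}
    for r in model.residues:
        by_chain.setdefault(r.chain, []).append(r)
    for chain_name, residues in by_chain.items():
        chain = gemmi.Chain(chain_name)
        for r in residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seqnum, r.icode or " ")
            gres.het_flag = "H" if (r.is_water or r.name not in _STANDARD_AA) else "A"
            for a in r.atoms:
                gat = gemmi.Atom()
                gat.name = a.name
                gat.element = gemmi.Element(a.element)
                gat.pos = gemmi.Position(*a.xyz)
                gat.occ = a.occupancy
                gres.add_atom(gat)
            chain.add_residue(gres)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    suffix = path.suffix.lower()
    if suffix in {".pdb", ".ent"}:
        st.write_pdb(str(path))
    elif suffix in {".cif", ".mmcif"}:
        st.make_mmcif_document().write_file(str(path))
    else:
        raise DialectError(f"{path}: unrecognised structure extension {suffix!r}")


def expand_symmetry_mate(path: str | Path, contact_cutoff: float = 5.0,
                         ) -> tuple[StructureModel, str]:
    """Build the crystallographic dimer for a monomer-in-ASU crystal.

    Applies every spacegroup operator (with unit-cell translations in
    {-1,0,1}³) to the deposited coordinates and keeps the image making the
    largest number of polymer-atom contacts within ``contact_cutoff`` of
    the original — the crystallographic dimer interface.  The mate's
    chains are renamed by suffixing ``*``.  Returns ``(model, operator
    triplet used)``.
    """
    path = Path(path)
    base = read_structure(path)
    st = gemmi.read_structure(str(path))
    cell = st.cell
    if cell.volume < 1000.0:  # placeholder 1 Å cells carry no lattice
        raise FormatError(f"{path}: no usable unit cell for symmetry expansion")
    try:
        ops = gemmi.SpaceGroup(st.spacegroup_hm).operations()
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: no usable spacegroup: {exc}") from exc

    base_coords = np.array([a.coord for r in base.polymer for a in r.atoms])
    from scipy.spatial import cKDTree

    tree = cKDTree(base_coords)

    def transform(op, shift, xyz):
        frac = cell.fractionalize(gemmi.Position(*xyz))
        fx, fy, fz = op.apply_to_xyz([frac.x, frac.y, frac.z])
        pos = cell.orthogonalize(gemmi.Fractional(fx + shift[0], fy + shift[1],
                                                  fz + shift[2]))
        return (pos.x, pos.y, pos.z)

    best = None
    for op in ops:
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                for sz in (-1, 0, 1):
                    if op.triplet() == "x,y,z" and (sx, sy, sz) == (0, 0, 0):
                        continue
                    moved = np.array([transform(op, (sx, sy, sz), xyz)
                                      for xyz in base_coords])
                    # identity images (pure lattice translations far away) score 0
                    contacts = sum(len(tree.query_ball_point(p, contact_cutoff))
                                   for p in moved)
                    min_d = tree.query(moved)[0].min()
                    if min_d < 1.0:  # overlapping image, not a mate
                        continue
                    if best is None or contacts > best[0]:
                        best = (contacts, op, (sx, sy, sz))
    if best is None or best[0] == 0:
        raise FormatError(f"{path}: no symmetry mate in contact found")
    _, op, shift = best

    def clone(res: Residue) -> Residue:
        return Residue(
            chain=res.chain + "*", seqnum=res.seqnum, icode=res.icode, name=res.name,
            atoms=[Atom(a.name, a.element, transform(op, shift, a.xyz),
                        a.occupancy, a.altloc) for a in res.atoms],
        )

    mate_polymer = [clone(r) for r in base.polymer]
    mate_het = [clone(r) for r in base.het_groups]
    merged = StructureModel(
        name=base.name + "+mate",
        polymer=base.polymer + mate_polymer,
        het_groups=base.het_groups + mate_het,
        waters=base.waters,
    )
    return merged, f"{op.triplet()} +{shift}"


# ---------------------------------------------------------------------------
# TSV helpers (single-header, tab-delimited reports)

def write_tsv(rows: Iterable[dict], path: str | Path, columns: Sequence[str]) -> None:
    import pandas as pd

    df = pd.DataFrame(list(rows), columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
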