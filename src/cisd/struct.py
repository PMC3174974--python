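"""Structural geometry of iron-sulfur binding modules.

A [2Fe-2S] cluster is a rhombus of two irons and two bridging sulfides.
In CISDs it is held by an *iron-sulfur binding module*: the 17 Cα of one
CDGSH motif plus the cluster, ligated by the side chains of Cys at motif
positions 2, 4 and 13 and His (Nδ1/Nε2) at position 17.  This module
implements the quantitative comparisons between such modules:

* cluster detection and ligand assignment from coordinates;
* module extraction anchored on the first cysteine ligand (motif
  position 2), window Cα[C2-1 … C2+15];
* least-squares rigid superposition (Kabsch) and RMSD;
* inter-cluster center-to-center distance and the shift angle of the
  partner cluster after aligning one module between two structures;
* Shrake-Rupley solvent-accessible surface area and interface burial;
* heavy-atom hydrogen-bond and close-contact detection;
* internal pseudo-dyad measurement for tandem-motif structures.

All quantities are invariant under global rigid motion of the input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .io import Atom, Residue, StructureModel

FE_LIGAND_CUTOFF = 3.0  # Å, Fe to Cys Sγ / His Nδ1,Nε2 heavy atom
CLUSTER_ASSEMBLY_CUTOFF = 3.5  # Å, Fe-S within an assembled cluster
HBOND_DMAX = 3.5  # Å, donor N/O to acceptor N/O
SASA_PROBE = 1.4  # Å, water probe
SASA_NPOINTS = 960

_CLUSTER_RESNAMES = frozenset({"FES", "FE2", "2FE", "FS2"})


class StructError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Superposition

def superpose(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares rigid superposition of A onto B.

    Correspondence is positional.  Returns ``(R, t, rmsd)`` with a proper
    rotation (det R = +1) such that ``A @ R.T + t`` best fits ``B``.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise StructError(f"point sets must share shape (n,3); got {A.shape} vs {B.shape}")
    if len(A) < 3:
        raise StructError("need at least 3 points for a rigid superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def apply_transform(points: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.asarray(points, dtype=float) @ np.asarray(R).T + np.asarray(t)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of a proper rotation matrix, degrees in [0, 180].

    Uses atan2 of the skew-symmetric part against the trace, which stays
    well-conditioned at 0° and 180° where arccos is not.
    """
    v = 0.5 * np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(v)
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arctan2(s, c)))


# ---------------------------------------------------------------------------
# Clusters and modules

@dataclass
class FeSCluster:
    """A [2Fe-2S] cluster: 2 Fe + 2 inorganic S atoms with their residue."""

    residue: Residue | None
    fe_atoms: list[Atom]
    s_atoms: list[Atom]
    chain: str

    def __post_init__(self) -> None:
        if len(self.fe_atoms) != 2 or len(self.s_atoms) != 2:
            raise StructError(
                f"cluster needs 2 Fe + 2 S, got {len(self.fe_atoms)} Fe, {len(self.s_atoms)} S")
        coords = self.coords
        dists = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        if dists.max() >= 5.0:
            raise StructError(f"cluster atoms too far apart ({dists.max():.2f} Å)")

    @property
    def atoms(self) -> list[Atom]:
        return self.fe_atoms + self.s_atoms

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


@dataclass
class IronSulfurModule:
    """17 ordered motif Cα plus the bound cluster."""

    cluster: FeSCluster
    ligand_residues: list[Residue]
    ca_residues: list[Residue]
    ca_segment: np.ndarray  # (17, 3)

    def __post_init__(self) -> None:
        self.ca_segment = np.asarray(self.ca_segment, dtype=float)
        if self.ca_segment.shape != (17, 3):
            raise StructError(f"ca_segment must be (17,3), got {self.ca_segment.shape}")

    @property
    def chain(self) -> str:
        return self.ca_residues[0].chain

    @property
    def anchor(self) -> Residue:
        """Residue at motif position 2 (first Cys ligand)."""
        return self.ca_residues[1]

    @property
    def all_coords(self) -> np.ndarray:
        """17 Cα followed by the 4 cluster atoms (21, 3)."""
        return np.vstack([self.ca_segment, self.cluster.coords])


@dataclass
class GeometryReport:
    """Derived structural quantities for one model (optionally vs a reference)."""

    model: str
    n_clusters: int = 0
    n_waters: int = 0
    ligands: list[tuple[str, tuple[int, ...], str]] = field(default_factory=list)
    module_rmsd_max: float = float("nan")
    center_distance: float = float("nan")
    shift_angle: float = float("nan")
    dyad_rmsd: float = float("nan")
    dyad_rotation: float = float("nan")
    buried_area: dict[str, float] = field(default_factory=dict)
    n_hbonds: int = 0


def find_clusters(model: StructureModel) -> list[FeSCluster]:
    """[2Fe-2S] clusters from FES-type het-groups, else assembled from free
    Fe and inorganic S atoms within 3.5 Å."""
    clusters: list[FeSCluster] = []
    leftover_fe: list[tuple[Residue, Atom]] = []
    leftover_s: list[tuple[Residue, Atom]] = []
    for res in model.het_groups:
        fe = [a for a in res.atoms if a.element.upper() == "FE"]
        s = [a for a in res.atoms if a.element.upper() == "S"]
        if res.name in _CLUSTER_RESNAMES and len(fe) == 2 and len(s) == 2:
            clusters.append(FeSCluster(res, fe, s, res.chain))
        else:
            leftover_fe.extend((res, a) for a in fe)
            leftover_s.extend((res, a) for a in s)
    # assemble clusters from loose ions
    used_s: set[int] = set()
    fe_pool = list(leftover_fe)
    while len(fe_pool) >= 2:
        res0, fe0 = fe_pool[0]
        partner_idx = None
        for j in range(1, len(fe_pool)):
            if np.linalg.norm(fe0.coord - fe_pool[j][1].coord) < 2 * CLUSTER_ASSEMBLY_CUTOFF:
                partner_idx = j
                break
        if partner_idx is None:
            warnings.warn(f"{model.name}: lone Fe atom without cluster partner", stacklevel=2)
            fe_pool.pop(0)
            continue
        fe_pair = [fe0, fe_pool[partner_idx][1]]
        s_near = [
            (k, a) for k, (_, a) in enumerate(leftover_s)
            if k not in used_s and all(
                np.linalg.norm(a.coord - f.coord) < CLUSTER_ASSEMBLY_CUTOFF for f in fe_pair)
        ]
        if len(s_near) < 2:
            warnings.warn(f"{model.name}: Fe pair without 2 bridging sulfides, excluded",
                          stacklevel=2)
            fe_pool.pop(partner_idx)
            fe_pool.pop(0)
            continue
        s_near.sort(key=lambda ka: min(
            np.linalg.norm(ka[1].coord - f.coord) for f in fe_pair))
        picked = s_near[:2]
        used_s.update(k for k, _ in picked)
        clusters.append(FeSCluster(res0, fe_pair, [a for _, a in picked], res0.chain))
        fe_pool.pop(partner_idx)
        fe_pool.pop(0)
    if fe_pool:
        warnings.warn(f"{model.name}: lone Fe atom without cluster partner", stacklevel=2)
    clusters.sort(key=lambda c: (c.chain, c.residue.seqnum if c.residue else 0))
    return clusters


_LIGAND_ATOMS = {"CYS": ("SG",), "HIS": ("ND1", "NE2"), "SEC": ("SE",)}


def assign_ligands(model: StructureModel, cluster: FeSCluster,
                   cutoff: float = FE_LIGAND_CUTOFF) -> list[tuple[Residue, Atom]]:
    """Protein residues coordinating the cluster irons.

    Matches Cys Sγ and His Nδ1/Nε2 within ``cutoff`` of either Fe; unique
    residues sorted by sequence position.  More than four candidates keeps
    the four nearest with a warning; none within 10 Å of any candidate
    warns and returns empty.
    """
    fe_coords = np.array([a.coord for a in cluster.fe_atoms])
    found: dict[tuple, tuple[Residue, Atom, float]] = {}
    for res in model.polymer:
        for atom_name in _LIGAND_ATOMS.get(res.name, ()):
            atom = res.atom(atom_name)
            if atom is None:
                continue
            d = float(np.linalg.norm(fe_coords - atom.coord, axis=1).min())
            if d <= cutoff:
                prev = found.get(res.key)
                if prev is None or d < prev[2]:
                    found[res.key] = (res, atom, d)
    entries = sorted(found.values(), key=lambda e: e[2])
    if len(entries) > 4:
        warnings.warn(
            f"{model.name}: {len(entries)} candidate ligands, keeping 4 nearest",
            stacklevel=2)
        entries = entries[:4]
    if not entries:
        warnings.warn(f"{model.name}: no protein ligand within {cutoff} Å of cluster",
                      stacklevel=2)
    entries.sort(key=lambda e: (e[0].chain, e[0].seqnum, e[0].icode))
    return [(res, atom) for res, atom, _ in entries]


def coordination_class(ligands: Sequence[tuple[Residue, Atom]]) -> str:
    """e.g. '3Cys1His' for the canonical CISD ligation."""
    counts: dict[str, int] = {}
    for res, _ in ligands:
        label = res.name.capitalize()
        counts[label] = counts.get(label, 0) + 1
    return "".join(f"{n}{name}" for name, n in sorted(counts.items(), key=lambda kv: -kv[1]))


def extract_module(model: StructureModel, cluster: FeSCluster,
                   cutoff: float = FE_LIGAND_CUTOFF) -> IronSulfurModule:
    """Extract the 17-Cα iron-sulfur binding module anchored on the first
    cysteine ligand (motif position 2); window C2-1 … C2+15."""
    ligands = assign_ligands(model, cluster, cutoff)
    cys = [res for res, _ in ligands if res.name in ("CYS", "SEC")]
    if not cys:
        raise StructError(f"{model.name}: cluster has no cysteine ligand to anchor on")
    anchor = min(cys, key=lambda r: r.seqnum)
    chain = anchor.chain
    wanted = list(range(anchor.seqnum - 1, anchor.seqnum + 16))
    by_num = {r.seqnum: r for r in model.polymer_chain(chain) if not r.icode}
    missing = [n for n in wanted if n not in by_num or by_num[n].atom("CA") is None]
    if missing:
        raise StructError(
            f"{model.name}: chain {chain} missing Cα for residues {missing} "
            f"inside motif window {wanted[0]}-{wanted[-1]}")
    ca_residues = [by_num[n] for n in wanted]
    ca = np.array([r.atom("CA").coord for r in ca_residues])
    return IronSulfurModule(cluster=cluster, ligand_residues=[r for r, _ in ligands],
                            ca_residues=ca_residues, ca_segment=ca)


def extract_all_modules(model: StructureModel,
                        cutoff: float = FE_LIGAND_CUTOFF) -> list[IronSulfurModule]:
    return [extract_module(model, c, cutoff) for c in find_clusters(model)]


# ---------------------------------------------------------------------------
# Inter-module geometry

def cluster_distance(c1: FeSCluster, c2: FeSCluster) -> float:
    """Center-to-center distance between two 4-atom cluster centroids, Å."""
    return float(np.linalg.norm(c1.centroid - c2.centroid))


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = np.dot(v1, v2) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def intermodule_angle(ref: StructureModel | Sequence[IronSulfurModule],
                      target: StructureModel | Sequence[IronSulfurModule]) -> float:
    """Shift angle of the partner cluster between two dual-module structures.

    One target module is superposed onto one reference module (best of the
    up-to-four pairings by 17-Cα rmsd).  The angle is measured at the
    aligned cluster centroid, between the vector to the reference partner
    centroid and the vector to the transformed target partner centroid.
    """
    ref_mods = extract_all_modules(ref) if isinstance(ref, StructureModel) else list(ref)
    tgt_mods = extract_all_modules(target) if isinstance(target, StructureModel) else list(target)
    if len(ref_mods) != 2 or len(tgt_mods) != 2:
        raise StructError(
            f"need exactly 2 modules per structure, got {len(ref_mods)} and {len(tgt_mods)}")
    best = None
    for i, tm in enumerate(tgt_mods):
        for j, rm in enumerate(ref_mods):
            R, t, rmsd = superpose(tm.ca_segment, rm.ca_segment)
            # tolerance keeps the pairing deterministic when modules are
            # exactly congruent (idealized templates)
            if best is None or rmsd < best[0] - 1e-9:
                best = (rmsd, R, t, i, j)
    _, R, t, i, j = best
    vertex = ref_mods[j].cluster.centroid
    ref_partner = ref_mods[1 - j].cluster.centroid
    tgt_partner = apply_transform(tgt_mods[1 - i].cluster.centroid[None, :], R, t)[0]
    return _angle_deg(ref_partner - vertex, tgt_partner - vertex)


def pseudo_dyad(model: StructureModel | Sequence[IronSulfurModule]) -> tuple[float, float]:
    """Internal two-fold symmetry between the two iron-sulfur modules.

    Superposes module 1 (17 Cα + 4 cluster atoms) onto module 2 and
    returns ``(rmsd, rotation angle in degrees)``; a perfect dyad gives
    rmsd 0 and 180°.
    """
    mods = extract_all_modules(model) if isinstance(model, StructureModel) else list(model)
    if len(mods) != 2:
        raise StructError(f"pseudo-dyad needs exactly 2 modules, got {len(mods)}")
    R, _, rmsd = superpose(mods[0].all_coords, mods[1].all_coords)
    return rmsd, rotation_angle(R)


# ---------------------------------------------------------------------------
# Solvent accessible surface area (Shrake-Rupley)

def _load_radii() -> dict[str, float]:
    with resources.files("cisd.data").joinpath("vdw_radii.json").open() as fh:
        return {k.upper(): float(v) for k, v in json.load(fh)["radii"].items()}


VDW_RADII = _load_radii()


def _sphere_points(n: int) -> np.ndarray:
    """n quasi-uniform unit-sphere points (Fibonacci spiral quadrature)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def sasa(model: StructureModel, probe: float = SASA_PROBE,
         n_points: int = SASA_NPOINTS, include_het: bool = True,
         default_radius: float | None = None) -> dict[tuple, float]:
    """Per-atom solvent-accessible surface area, Å².

    Shrake-Rupley quadrature with ``n_points`` per atom and the bundled
    Bondi van-der-Waals radius table (metadata: ``cisd.struct.VDW_RADII``).
    Waters are excluded; het groups (clusters) included by default.
    Unknown elements raise unless ``default_radius`` is given.
    Keys are ``(chain, seqnum, icode, atom name)``.
    """
    residues = list(model.polymer) + (list(model.het_groups) if include_het else [])
    atoms: list[tuple[Residue, Atom]] = [(r, a) for r in residues for a in r.atoms]
    if not atoms:
        return {}
    radii = np.empty(len(atoms))
    for i, (_, a) in enumerate(atoms):
        r = VDW_RADII.get(a.element.upper(), default_radius)
        if r is None:
            raise StructError(f"no van-der-Waals radius for element {a.element!r}")
        radii[i] = r + probe
    coords = np.array([a.coord for _, a in atoms])
    points = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas: dict[tuple, float] = {}
    for i, (res, atom) in enumerate(atoms):
        sphere = coords[i] + radii[i] * points
        neighbours = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(sphere - coords[j], axis=1)
            accessible &= d >= radii[j]
            if not accessible.any():
                break
        frac = accessible.sum() / n_points
        areas[(*res.key, atom.name)] = float(4.0 * np.pi * radii[i] ** 2 * frac)
    return areas


def buried_area(model: StructureModel, chainA: str, chainB: str,
                probe: float = SASA_PROBE, n_points: int = SASA_NPOINTS,
                include_het: bool = True) -> tuple[float, float]:
    """Interface burial per chain: SASA(chain alone) - SASA(chain in complex)."""
    chains = set(model.chains)
    for c in (chainA, chainB):
        if c not in chains:
            raise StructError(f"{model.name}: chain {c!r} not present (have {sorted(chains)})")
    complex_model = model.subset_chains([chainA, chainB], include_het=include_het)
    complex_sasa = sasa(complex_model, probe, n_points, include_het)
    out = []
    for c in (chainA, chainB):
        alone = sasa(model.subset_chains([c], include_het=include_het),
                     probe, n_points, include_het)
        in_complex = sum(v for k, v in complex_sasa.items() if k[0] == c)
        out.append(sum(alone.values()) - in_complex)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Hydrogen bonds and contacts

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomContact:
    res1: tuple[str, int, str, str]  # chain, seqnum, icode, resname
    atom1: str
    res2: tuple[str, int, str, str]
    atom2: str
    distance: float


def _res_tag(r: Residue) -> tuple[str, int, str, str]:
    return (r.chain, r.seqnum, r.icode, r.name)


def _adjacent_backbone(r1: Residue, a1: Atom, r2: Residue, a2: Atom) -> bool:
    # peptide-adjacent backbone N/O pairs are through-bond neighbours, not H-bonds
    return (r1.chain == r2.chain and abs(r1.seqnum - r2.seqnum) == 1
            and a1.name in BACKBONE_ATOMS and a2.name in BACKBONE_ATOMS)


def detect_hbonds(model: StructureModel, d_max: float = HBOND_DMAX,
                  selection: Callable[[Residue, Atom], bool] | None = None
                  ) -> list[AtomContact]:
    """Heavy-atom hydrogen bonds: N/O…N/O pairs within ``d_max``, not in the
    same residue and not through-bond neighbours; sorted by distance."""
    candidates: list[tuple[Residue, Atom]] = []
    for res in model.polymer:
        for atom in res.atoms:
            if atom.element.upper() in ("N", "O"):
                if selection is None or selection(res, atom):
                    candidates.append((res, atom))
    if not candidates:
        return []
    coords = np.array([a.coord for _, a in candidates])
    tree = cKDTree(coords)
    bonds = []
    for i, j in sorted(tree.query_pairs(d_max)):
        r1, a1 = candidates[i]
        r2, a2 = candidates[j]
        if r1.key == r2.key:
            continue
        if _adjacent_backbone(r1, a1, r2, a2):
            continue
        d = float(np.linalg.norm(a1.coord - a2.coord))
        bonds.append(AtomContact(_res_tag(r1), a1.name, _res_tag(r2), a2.name, d))
    bonds.sort(key=lambda b: b.distance)
    return bonds


def close_contacts(model: StructureModel, chainA: str, chainB: str, d_max: float,
                   atom_filter: Callable[[Residue, Atom], bool] | None = None
                   ) -> list[AtomContact]:
    """All inter-chain atom pairs within ``d_max``, optionally filtered
    (e.g. backbone only); sorted by distance."""
    def pick(chain: str) -> list[tuple[Residue, Atom]]:
        out = []
        for res in model.polymer + model.het_groups:
            if res.chain != chain:
                continue
            for atom in res.atoms:
                if atom_filter is None or atom_filter(res, atom):
                    out.append((res, atom))
        return out

    A, B = pick(chainA), pick(chainB)
    if not A or not B:
        return []
    tree = cKDTree(np.array([a.coord for _, a in B]))
    contacts = []
    for rA, aA in A:
        for j in tree.query_ball_point(aA.coord, d_max):
            rB, aB = B[j]
            d = float(np.linalg.norm(aA.coord - aB.coord))
            contacts.append(AtomContact(_res_tag(rA), aA.name, _res_tag(rB), aB.name, d))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def count_waters(model: StructureModel) -> int:
    return len(model.waters)


# ---------------------------------------------------------------------------
# Aggregate report

def analyze(model: StructureModel, ref: StructureModel | None = None,
            sasa_points: int = SASA_NPOINTS) -> GeometryReport:
    """Full geometry report for one structure (shift angle needs ``ref``)."""
    report = GeometryReport(model=model.name)
    report.n_waters = count_waters(model)
    clusters = find_clusters(model)
    report.n_clusters = len(clusters)
    modules = []
    for c in clusters:
        ligs = assign_ligands(model, c)
        report.ligands.append((
            c.chain, tuple(r.seqnum for r, _ in ligs), coordination_class(ligs)))
        try:
            modules.append(extract_module(model, c))
        except StructError:
            pass
    if len(modules) >= 2:
        report.center_distance = cluster_distance(modules[0].cluster, modules[1].cluster)
        rmsds = [superpose(a.ca_segment, b.ca_segment)[2]
                 for i, a in enumerate(modules) for b in modules[i + 1:]]
        report.module_rmsd_max = max(rmsds)
        if len(modules) == 2:
            report.dyad_rmsd, report.dyad_rotation = pseudo_dyad(modules)
            if ref is not None:
                report.shift_angle = intermodule_angle(ref, modules)
    chains = [c for c in model.chains if model.polymer_chain(c)]
    if len(chains) == 2:
        a, b = buried_area(model, chains[0], chains[1], n_points=sasa_points)
        report.buried_area = {chains[0]: a, chains[1]: b}
    report.n_hbonds = len(detect_hbonds(model))
    return report
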