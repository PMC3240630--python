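"""Structure I/O and geometric analysis of models and ensembles.

Covers the quantities used to characterise docking models and NMR
ensembles of small helical domains: helix axes and interhelical angles,
Kabsch superposition and pairwise-RMSD clustering, centres of mass and
radii of gyration, numerical solvent-accessible surface area and buried
interface area, inter-chain contact/clash screening, assembly of larger
complexes by superposition, and peptide molecular mass.

Coordinates are in Angstrom, masses in Dalton; PDB files are parsed with
gemmi into a light array-based :class:`StructureModel`.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio.SeqUtils import molecular_weight
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Chothia-style heavy-atom van der Waals radii (A)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20, "P": 1.80}


@dataclass
class StructureModel:
    """Flat atom table for one structural model."""

    serial: np.ndarray        # int
    name: np.ndarray          # str, e.g. "CA"
    element: np.ndarray       # str, e.g. "C"
    resnum: np.ndarray        # int
    restype: np.ndarray       # str, 3-letter
    chain: np.ndarray         # str
    xyz: np.ndarray           # (n, 3) float, A
    mass: np.ndarray          # float, Da
    model_id: int = 1

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def mask(self, chain=None, residues=None, atoms=None, heavy=False) -> np.ndarray:
        m = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            chains = [chain] if isinstance(chain, str) else list(chain)
            m &= np.isin(self.chain, chains)
        if residues is not None:
            m &= np.isin(self.resnum, np.asarray(list(residues)))
        if atoms is not None:
            m &= np.isin(self.name, list(atoms))
        if heavy:
            m &= self.element != "H"
        return m

    def select(self, **kwargs) -> "StructureModel":
        m = self.mask(**kwargs)
        return StructureModel(
            serial=self.serial[m],
            name=self.name[m],
            element=self.element[m],
            resnum=self.resnum[m],
            restype=self.restype[m],
            chain=self.chain[m],
            xyz=self.xyz[m],
            mass=self.mass[m],
            model_id=self.model_id,
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        return replace(self, xyz=self.xyz @ np.asarray(rotation).T + np.asarray(translation))

    def with_chain(self, chain_id: str) -> "StructureModel":
        return replace(self, chain=np.full(self.n_atoms, chain_id, dtype=object))

    def chains(self) -> list[str]:
        seen = []
        for c in self.chain:
            if c not in seen:
                seen.append(c)
        return seen


def merge_models(models) -> StructureModel:
    """Concatenate atom tables; chain ids must already be unique."""
    models = list(models)
    chains = [c for m in models for c in m.chains()]
    if len(chains) != len(set(chains)):
        raise ValueError(f"overlapping chain ids when merging: {chains}")
    return StructureModel(
        serial=np.arange(1, sum(m.n_atoms for m in models) + 1),
        name=np.concatenate([m.name for m in models]),
        element=np.concatenate([m.element for m in models]),
        resnum=np.concatenate([m.resnum for m in models]),
        restype=np.concatenate([m.restype for m in models]),
        chain=np.concatenate([m.chain for m in models]),
        xyz=np.vstack([m.xyz for m in models]),
        mass=np.concatenate([m.mass for m in models]),
        model_id=models[0].model_id,
    )


def _element_of(atom_name: str, element: str) -> str:
    if element and element.strip():
        return element.strip().capitalize()
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "C"


def _from_gemmi_model(gmodel, model_id: int) -> StructureModel:
    serial, name, element, resnum, restype, chain, xyz, mass = [], [], [], [], [], [], [], []
    for gchain in gmodel:
        for res in gchain:
            for atom in res:
                serial.append(atom.serial)
                name.append(atom.name)
                el = atom.element.name if atom.element and atom.element.name != "X" else ""
                el = _element_of(atom.name, el)
                element.append(el)
                resnum.append(res.seqid.num)
                restype.append(res.name)
                chain.append(gchain.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                mass.append(gemmi.Element(el).weight)
    return StructureModel(
        serial=np.asarray(serial, dtype=int),
        name=np.asarray(name, dtype=object),
        element=np.asarray(element, dtype=object),
        resnum=np.asarray(resnum, dtype=int),
        restype=np.asarray(restype, dtype=object),
        chain=np.asarray(chain, dtype=object),
        xyz=np.asarray(xyz, dtype=float),
        mass=np.asarray(mass, dtype=float),
        model_id=model_id,
    )


def read_structure(source, model: int | str = "all"):
    """Parse a PDB stream or path.

    ``model='all'`` returns a list of :class:`StructureModel` (multi-model
    NMR ensembles preserved); an integer returns that single model
    (1-based, PDB MODEL numbering).
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"PDB parse error: {exc}") from exc
    st.setup_entities()
    models = [_from_gemmi_model(gm, i + 1) for i, gm in enumerate(st)]
    if not models or all(m.n_atoms == 0 for m in models):
        raise ValueError("no atoms parsed from PDB input")
    if model == "all":
        return models
    idx = int(model) - 1
    if not (0 <= idx < len(models)):
        raise ValueError(f"model {model} not in ensemble of {len(models)}")
    return models[idx]


def write_structure(models, out) -> None:
    """Write one or more models as plain PDB text."""
    if isinstance(models, StructureModel):
        models = [models]
    if isinstance(out, (str, bytes, os.PathLike)):
        with open(out, "w") as fh:
            write_structure(models, fh)
            return
    multi = len(models) > 1
    for i, m in enumerate(models, start=1):
        if multi:
            out.write(f"MODEL     {i:4d}\n")
        serial = 0
        for j in range(m.n_atoms):
            serial += 1
            name = m.name[j]
            pad = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = m.xyz[j]
            out.write(
                f"ATOM  {serial:5d} {pad:<4s} {m.restype[j]:>3s} {m.chain[j][:1]}"
                f"{m.resnum[j]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {m.element[j]:>2s}\n"
            )
        out.write("TER\n")
        if multi:
            out.write("ENDMDL\n")
    out.write("END\n")


# ---------------------------------------------------------------------------
# helix axes


@dataclass
class HelixAxis:
    anchor: np.ndarray       # point on the axis
    direction: np.ndarray    # unit vector, oriented N->C
    residue_range: tuple[int, int]
    fit_rms: float           # rms scatter of CA radial distances, A


def _ca_trace(model: StructureModel, residues, chain=None) -> np.ndarray:
    sub = model.select(residues=residues, atoms=["CA"], chain=chain)
    order = np.argsort(sub.resnum)
    return sub.xyz[order]


def helix_axis(model: StructureModel, residues, chain=None) -> HelixAxis:
    """Fit the axis of a helical segment through its CA atoms.

    Local axis directions are taken from consecutive CA quadruplets via
    the bisector construction (the two bisectors at the inner residues are
    both perpendicular to the local axis, so their cross product gives its
    direction); the segment axis is the mean local direction anchored at
    the CA centroid.  This is exact on ideal helices down to 5 residues
    (e.g. a 3-10 turn), where a straight-line fit through the CAs is
    biased by the incomplete final turn; 4-residue segments fall back to
    the best-fit line.  The direction is oriented from the N- to the
    C-terminal end.
    """
    residues = list(residues)
    ca = _ca_trace(model, residues, chain=chain)
    n = len(ca)
    if n < 4:
        raise ValueError(f"need >= 4 CA atoms to fit a helix axis, got {n}")
    nc = ca[-1] - ca[0]
    if n >= 5:
        dirs = []
        for i in range(n - 3):
            r = ca[i : i + 4]
            b1 = _bisector(r[0], r[1], r[2])
            b2 = _bisector(r[1], r[2], r[3])
            d = np.cross(b1, b2)
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                continue
            d /= norm
            if np.dot(d, r[3] - r[0]) < 0:
                d = -d
            dirs.append(d)
        direction = np.mean(dirs, axis=0)
        direction /= np.linalg.norm(direction)
    else:
        centered = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        direction = vt[0]
    if np.dot(direction, nc) < 0:
        direction = -direction
    # anchor on the axis: least-squares circle centre of the CAs projected
    # onto the plane normal to the axis (the centroid is biased off-axis
    # for non-integer numbers of turns)
    u = _any_perpendicular(direction)
    v = np.cross(direction, u)
    centroid = ca.mean(axis=0)
    p2 = np.column_stack([(ca - centroid) @ u, (ca - centroid) @ v])
    A = np.column_stack([2.0 * p2, np.ones(n)])
    b = np.sum(p2**2, axis=1)
    (cx, cy, _), *_ = np.linalg.lstsq(A, b, rcond=None)
    anchor = centroid + cx * u + cy * v
    radial = ca - anchor
    radial -= np.outer(radial @ direction, direction)
    r = np.linalg.norm(radial, axis=1)
    return HelixAxis(
        anchor=anchor,
        direction=direction,
        residue_range=(min(residues), max(residues)),
        fit_rms=float(np.std(r)),
    )


def _any_perpendicular(d: np.ndarray) -> np.ndarray:
    probe = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, probe)
    return u / np.linalg.norm(u)


def _bisector(a, b, c):
    u = (a - b) / np.linalg.norm(a - b)
    v = (c - b) / np.linalg.norm(c - b)
    w = u + v
    return w / np.linalg.norm(w)


def interhelical_angle(a: HelixAxis, b: HelixAxis, directed: bool = True) -> float:
    """Angle between two helix axes in degrees.

    With ``directed=True`` (default) the N->C orientation is respected and
    the angle spans [0, 180] degrees, so parallel and antiparallel packing
    are distinguished; ``directed=False`` folds to [0, 90].
    """
    cosang = float(np.clip(np.dot(a.direction, b.direction), -1.0, 1.0))
    ang = float(np.degrees(np.arccos(cosang)))
    return ang if directed else min(ang, 180.0 - ang)


# ---------------------------------------------------------------------------
# superposition, RMSD, clustering


def kabsch_superpose(mobile: StructureModel, target: StructureModel, selection: dict | None = None):
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns ``(rotation, translation, rmsd)`` with the convention
    ``x @ rotation.T + translation``; a proper rotation is enforced (no
    reflection).  Atom counts in the two selections must match.
    """
    selection = selection or {}
    X = mobile.select(**selection).xyz
    Y = target.select(**selection).xyz
    if len(X) != len(Y):
        raise ValueError(f"selection size mismatch: {len(X)} vs {len(Y)} atoms")
    if len(X) < 3:
        raise ValueError("need at least 3 atoms to superpose")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    U, _, Vt = np.linalg.svd(X0.T @ Y0)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = yc - R @ xc
    rmsd = float(np.sqrt(np.mean(np.sum((X0 @ R.T - Y0) ** 2, axis=1))))
    return R, t, rmsd


def pairwise_rmsd_matrix(ensemble, selection: dict | None = None) -> np.ndarray:
    """Symmetric matrix of pairwise superposed RMSDs over an ensemble."""
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ValueError("need at least two models")
    n = len(ensemble)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(ensemble[i], ensemble[j], selection)
            mat[i, j] = mat[j, i] = rmsd
    return mat


def cluster_models(matrix: np.ndarray, cutoff: float = 5.0) -> list[list[int]]:
    """Greedy neighbour-count clustering of an RMSD matrix.

    Repeatedly takes the unassigned model with the most unassigned
    neighbours within ``cutoff`` as a cluster centre, assigns it and its
    neighbours, and iterates; clusters come out ordered by size
    (singletons allowed).  The result partitions the ensemble exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")
    n = matrix.shape[0]
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        counts = {
            i: sum(1 for j in unassigned if j != i and matrix[i, j] <= cutoff)
            for i in unassigned
        }
        centre = min(unassigned, key=lambda i: (-counts[i], i))
        members = sorted({centre} | {j for j in unassigned if matrix[centre, j] <= cutoff})
        clusters.append(members)
        unassigned -= set(members)
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


# ---------------------------------------------------------------------------
# mass-weighted geometry


def center_of_mass(model: StructureModel, selection: dict | None = None) -> np.ndarray:
    sub = model.select(**(selection or {}))
    if sub.n_atoms == 0:
        raise ValueError("empty selection")
    return np.average(sub.xyz, axis=0, weights=sub.mass)


def com_distance(model: StructureModel, sel_a: dict, sel_b: dict) -> float:
    return float(np.linalg.norm(center_of_mass(model, sel_a) - center_of_mass(model, sel_b)))


def radius_of_gyration(model: StructureModel, selection: dict | None = None) -> float:
    """Mass-weighted radius of gyration (A) over the selected atoms."""
    sub = model.select(**(selection or {}))
    if sub.n_atoms == 0:
        raise ValueError("empty selection")
    com = np.average(sub.xyz, axis=0, weights=sub.mass)
    return float(np.sqrt(np.average(np.sum((sub.xyz - com) ** 2, axis=1), weights=sub.mass)))


# ---------------------------------------------------------------------------
# surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(model: StructureModel, probe: float = 1.4, points: int = 960):
    """Shrake-Rupley solvent-accessible surface area.

    Each heavy atom is covered with a deterministic quasi-uniform point
    set on its solvent-expanded sphere; points falling inside any
    neighbouring expanded sphere are occluded.  Returns
    ``(per_atom, total)`` in A^2.
    """
    sub = model.select(heavy=True)
    if sub.n_atoms == 0:
        raise ValueError("no heavy atoms")
    radii = np.empty(sub.n_atoms)
    for i, el in enumerate(sub.element):
        if el not in VDW_RADII:
            raise ValueError(f"no van der Waals radius for element {el!r} (atom {sub.name[i]} {sub.resnum[i]})")
        radii[i] = VDW_RADII[el]
    expanded = radii + probe
    unit = _sphere_points(points)
    tree = cKDTree(sub.xyz)
    per_atom = np.zeros(sub.n_atoms)
    rmax = expanded.max()
    for i in range(sub.n_atoms):
        neigh = [j for j in tree.query_ball_point(sub.xyz[i], expanded[i] + rmax) if j != i]
        pts = sub.xyz[i] + expanded[i] * unit
        free = np.ones(points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - sub.xyz[j]) ** 2, axis=1)
            free &= d2 > expanded[j] ** 2
        per_atom[i] = free.mean() * 4.0 * np.pi * expanded[i] ** 2
    return per_atom, float(per_atom.sum())


def buried_surface(A: StructureModel, B: StructureModel, probe: float = 1.4, points: int = 960) -> float:
    """Interface area buried on complexation: SASA(A) + SASA(B) - SASA(AB)."""
    shared = set(A.chains()) & set(B.chains())
    if shared:
        raise ValueError(f"chains {sorted(shared)} present in both molecules")
    _, sa = sasa(A, probe, points)
    _, sb = sasa(B, probe, points)
    _, sab = sasa(merge_models([A, B]), probe, points)
    return float(sa + sb - sab)


# ---------------------------------------------------------------------------
# contacts and clashes


@dataclass
class ClashReport:
    contacts: list[tuple[int, int, float]]   # (atom index in A, atom index in B, distance)
    clashes: list[tuple[int, int, float]]
    severe: bool

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def n_clashes(self) -> int:
        return len(self.clashes)


def clash_report(
    A: StructureModel,
    B: StructureModel,
    contact_cutoff: float = 4.0,
    clash_cutoff: float = 2.5,
    severe_threshold: int = 10,
) -> ClashReport:
    """Inter-chain heavy-atom pairs below the contact and clash cutoffs.

    The ``severe`` verdict fires when the clash-pair count exceeds
    ``severe_threshold``, the screening criterion for sterically
    infeasible arrangements of docked subunits.
    """
    a = A.select(heavy=True)
    b = B.select(heavy=True)
    tree = cKDTree(b.xyz)
    contacts, clashes = [], []
    for i, pos in enumerate(a.xyz):
        for j in tree.query_ball_point(pos, contact_cutoff):
            d = float(np.linalg.norm(pos - b.xyz[j]))
            contacts.append((i, j, d))
            if d < clash_cutoff:
                clashes.append((i, j, d))
    return ClashReport(contacts=contacts, clashes=clashes, severe=len(clashes) > severe_threshold)


# ---------------------------------------------------------------------------
# assembly by superposition


def _superpose_matched(mobile: StructureModel, target: StructureModel, atoms=BACKBONE_ATOMS):
    """Kabsch fit on the (residue, atom-name) pairs common to both chains,
    ordered identically on each side."""

    def keyed(model):
        sub = model.select(atoms=list(atoms))
        return {(int(r), str(n)): x for r, n, x in zip(sub.resnum, sub.name, sub.xyz)}

    ka, kb = keyed(mobile), keyed(target)
    shared = sorted(set(ka) & set(kb))
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared backbone atoms between receptor and protomer")
    X = np.array([ka[k] for k in shared])
    Y = np.array([kb[k] for k in shared])
    fake = dict(
        serial=np.arange(len(shared)),
        name=np.array([k[1] for k in shared], dtype=object),
        element=np.full(len(shared), "C", dtype=object),
        resnum=np.array([k[0] for k in shared]),
        restype=np.full(len(shared), "GLY", dtype=object),
        chain=np.full(len(shared), "A", dtype=object),
        mass=np.ones(len(shared)),
    )
    return kabsch_superpose(
        StructureModel(xyz=X, **fake), StructureModel(xyz=Y, **fake), selection=None
    )


def build_assembly(
    dimer: StructureModel,
    complex_AB: StructureModel,
    receptor_chain: str,
    ligand_chains,
    protomer_chains=None,
    selection_atoms=BACKBONE_ATOMS,
) -> StructureModel:
    """Decorate each protomer of a homodimer with the ligand of a complex.

    The receptor chain of ``complex_AB`` is superposed (Kabsch, backbone
    atoms of shared residues) onto each protomer chain of ``dimer`` in
    turn, and the ligand chains are transplanted with fresh chain ids.
    Returns dimer plus 2x ligand chains merged into one model.
    """
    protomer_chains = list(protomer_chains) if protomer_chains is not None else dimer.chains()
    ligand_chains = list(ligand_chains)
    receptor = complex_AB.select(chain=receptor_chain)
    if receptor.n_atoms == 0:
        raise ValueError(f"receptor chain {receptor_chain!r} not found in complex")
    used = list(dimer.chains())
    alphabet = [c for c in "CDEFGHIJKLMNOPQRSTUVWXYZAB" if c not in used]
    pieces = [dimer]
    rmsds = []
    for prot in protomer_chains:
        prot_model = dimer.select(chain=prot)
        R, t, rmsd = _superpose_matched(receptor, prot_model, selection_atoms)
        rmsds.append(rmsd)
        for lig in ligand_chains:
            lig_model = complex_AB.select(chain=lig)
            if lig_model.n_atoms == 0:
                raise ValueError(f"ligand chain {lig!r} not found in complex")
            new_id = alphabet.pop(0)
            pieces.append(lig_model.transformed(R, t).with_chain(new_id))
    logger.info("assembly superposition RMSDs: %s", [f"{r:.3f}" for r in rmsds])
    return merge_models(pieces)


# ---------------------------------------------------------------------------
# sequence mass


def molecular_mass(sequence: str) -> float:
    """Average-isotope mass of a peptide chain in kDa (residues + one water)."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return float(molecular_weight(sequence.upper(), seq_type="protein")) / 1000.0
    except ValueError as exc:
        raise ValueError(f"invalid amino-acid sequence: {exc}") from exc
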