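"""Structure data model, PDB I/O and exact geometry primitives.

The in-memory model is a minimal chain -> residue -> atom hierarchy with
coordinates in Angstrom.  Parsing goes through gemmi; the policies layered
on top (ATOM records only, altloc resolved to highest occupancy then
alphabetical, standard residues only, first MODEL by default) are the
package's own.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np

from .constants import (
    AA3_TO_1,
    BACKBONE_ATOMS,
    CHAIN_BREAK_CN,
    CHI_ATOMS,
    DEFAULT_RADIUS,
    ELEMENT_RADII,
    STANDARD_AA,
)
from .errors import EmptyStructureError, GeometryError, PDBError, SuperpositionError


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "C"


@dataclasses.dataclass
class Atom:
    """A heavy atom: PDB name, element, coordinate (A), occupancy."""

    name: str
    coord: np.ndarray
    element: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"bad coordinate for atom {self.name}: {self.coord}")
        if not self.element:
            self.element = _element_from_name(self.name)

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def radius(self) -> float:
        return ELEMENT_RADII.get(self.element, DEFAULT_RADIUS)


@dataclasses.dataclass
class Residue:
    """One standard amino-acid residue.

    ``seq_index`` preserves the author numbering from the source file;
    ``index`` is the package's 0-based contiguous per-chain index and is
    what all the math uses.
    """

    aa: str
    chain_id: str
    seq_index: int
    index: int = 0
    atoms: dict[str, Atom] = dataclasses.field(default_factory=dict)

    def add_atom(self, atom: Atom) -> None:
        # at most one atom per name (altlocs resolved upstream)
        if atom.name not in self.atoms:
            self.atoms[atom.name] = atom

    def get(self, name: str) -> Optional[Atom]:
        return self.atoms.get(name)

    def coord(self, name: str) -> Optional[np.ndarray]:
        atom = self.atoms.get(name)
        return None if atom is None else atom.coord

    @property
    def is_complete(self) -> bool:
        """Backbone N, CA, C all present."""
        return all(n in self.atoms for n in ("N", "CA", "C"))

    @property
    def one_letter(self) -> str:
        return AA3_TO_1[self.aa]


class Structure:
    """Ordered chains of residues; the substrate of all feature code."""

    def __init__(self, id: str, chains: Optional[dict[str, list[Residue]]] = None):
        self.id = id
        self.chains: dict[str, list[Residue]] = chains or {}
        self._reindex()

    def _reindex(self) -> None:
        for residues in self.chains.values():
            for i, res in enumerate(residues):
                res.index = i

    def add_residue(self, residue: Residue) -> None:
        self.chains.setdefault(residue.chain_id, []).append(residue)
        chain = self.chains[residue.chain_id]
        residue.index = len(chain) - 1

    @property
    def residues(self) -> list[Residue]:
        return [r for residues in self.chains.values() for r in residues]

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for res in self.residues:
            for atom in res.atoms.values():
                yield res, atom

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates of residues that have one, in residue order."""
        return np.array([r.coord("CA") for r in self.residues
                         if r.coord("CA") is not None], dtype=float)

    def copy(self, id: Optional[str] = None) -> "Structure":
        chains: dict[str, list[Residue]] = {}
        for cid, residues in self.chains.items():
            chains[cid] = [
                Residue(
                    aa=r.aa, chain_id=r.chain_id, seq_index=r.seq_index,
                    index=r.index,
                    atoms={n: Atom(a.name, a.coord.copy(), a.element, a.occupancy)
                           for n, a in r.atoms.items()},
                )
                for r in residues
            ]
        return Structure(id if id is not None else self.id, chains)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """A copy with every coordinate mapped to R @ x + t."""
        out = self.copy()
        for _, atom in out.atoms():
            atom.coord = rotation @ atom.coord + translation
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Structure {self.id}: {len(self.chains)} chain(s), {self.n_residues} residues>"


# ---------------------------------------------------------------------------
# PDB I/O


def read_pdb(
    path: str | Path,
    model_index: int = 0,
    chain_filter: Optional[Sequence[str]] = None,
    length_filter: bool = False,
) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Only ATOM records of standard amino acids are kept; HETATM (waters,
    ligands, modified residues) are dropped.  Alternate locations are
    resolved to the highest-occupancy conformer, ties broken by altloc
    letter.  By default only the first MODEL is read.

    Parameters
    ----------
    model_index:
        0-based MODEL to read from multi-model files.
    chain_filter:
        If given, keep only these chain identifiers.
    length_filter:
        If True, reject structures outside 50..1000 residues (the dataset
        curation window for reference sets).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise PDBError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no coordinate models")
    if model_index >= len(st):
        raise PDBError(f"{path}: model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    out = Structure(id=path.stem)
    for chain in model:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if res.het_flag != "A" or res.name not in STANDARD_AA:
                continue
            residue = Residue(aa=res.name, chain_id=chain.name,
                              seq_index=res.seqid.num)
            # group by atom name, resolve altlocs
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            for name, variants in by_name.items():
                best = min(variants, key=lambda a: (-a.occ, a.altloc or "~"))
                el = best.element.name.upper() if best.element else ""
                residue.add_atom(Atom(name=name,
                                      coord=np.array([best.pos.x, best.pos.y, best.pos.z]),
                                      element=el or _element_from_name(name),
                                      occupancy=best.occ))
            if residue.atoms:
                out.add_residue(residue)

    if out.n_residues == 0:
        raise EmptyStructureError(f"{path}: no standard amino-acid residues")
    if length_filter and not (50 <= out.n_residues <= 1000):
        raise PDBError(
            f"{path}: {out.n_residues} residues outside the 50..1000 window")
    return out


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-column ATOM records, one TER per chain, END."""
    if structure.n_residues == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    lines: list[str] = []
    serial = 1
    for chain_id, residues in structure.chains.items():
        last = None
        for res in residues:
            for atom in res.atoms.values():
                # column-aligned atom name: 1-char elements start in col 14
                if len(atom.name) < 4 and len(atom.element) == 1:
                    name_field = f" {atom.name:<3s}"
                else:
                    name_field = f"{atom.name:<4s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name_field} {res.aa:<3s} {chain_id[:1]:1s}"
                    f"{res.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
                )
                serial += 1
            last = res
        if last is not None:
            lines.append(
                f"TER   {serial:5d}      {last.aa:<3s} {chain_id[:1]:1s}{last.seq_index:4d}")
            serial += 1
    lines.append("END")
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise PDBError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Geometry primitives


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    cis (p1, p4 eclipsed) = 0; trans = 180.  Range (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b0 = p2 - p1
    b1 = p3 - p2
    b2 = p4 - p3
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1_norm = np.linalg.norm(b1)
    if b1_norm < 1e-9 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise GeometryError("degenerate dihedral (collinear or coincident points)")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b1 / b1_norm))
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


@dataclasses.dataclass
class BackboneTorsions:
    phi: Optional[float]
    psi: Optional[float]
    omega: Optional[float]


def backbone_dihedrals(structure: Structure) -> list[BackboneTorsions]:
    """Per-residue (phi, psi, omega), ``None`` where undefined.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    omega(i) = CA(i-1)-C(i-1)-N(i)-CA(i).  Chain termini and chain breaks
    (peptide C-N distance > 2.5 A) leave the cross-boundary angles
    undefined; no error is raised.
    """
    result: list[BackboneTorsions] = []
    for residues in structure.chains.values():
        n = len(residues)
        for i, res in enumerate(residues):
            phi = psi = omega = None
            N, CA, C = res.coord("N"), res.coord("CA"), res.coord("C")
            if N is not None and CA is not None and C is not None:
                prev = residues[i - 1] if i > 0 else None
                nxt = residues[i + 1] if i < n - 1 else None
                prev_ok = (
                    prev is not None and prev.coord("C") is not None
                    and np.linalg.norm(prev.coord("C") - N) <= CHAIN_BREAK_CN
                )
                next_ok = (
                    nxt is not None and nxt.coord("N") is not None
                    and nxt.coord("CA") is not None
                    and np.linalg.norm(C - nxt.coord("N")) <= CHAIN_BREAK_CN
                )
                try:
                    if prev_ok:
                        phi = dihedral(prev.coord("C"), N, CA, C)
                        if prev.coord("CA") is not None:
                            omega = dihedral(prev.coord("CA"), prev.coord("C"), N, CA)
                    if next_ok:
                        psi = dihedral(N, CA, C, nxt.coord("N"))
                except GeometryError:
                    pass
            result.append(BackboneTorsions(phi, psi, omega))
    return result


def side_chain_chis(residue: Residue) -> list[float]:
    """Chi angles (degrees) for one residue; missing atoms truncate the list."""
    chis: list[float] = []
    for quad in CHI_ATOMS.get(residue.aa, []):
        coords = [residue.coord(name) for name in quad]
        if any(c is None for c in coords):
            break
        try:
            chis.append(dihedral(*coords))
        except GeometryError:
            break
    return chis


@dataclasses.dataclass
class Superposition:
    """Least-squares rigid map x -> R @ x + t of set A onto set B."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Kabsch superposition of paired point sets (reflections excluded)."""
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise SuperpositionError(f"paired Nx3 arrays required, got {A.shape} / {B.shape}")
    n = A.shape[0]
    if n < 3:
        raise SuperpositionError(f"at least 3 points required, got {n}")
    ca = A.mean(axis=0)
    cb = B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A @ R.T + t - B
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return Superposition(rotation=R, translation=t, rmsd=rmsd, n_atoms=n)
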