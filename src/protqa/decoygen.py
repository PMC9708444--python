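"""Synthetic natives, graded decoys, and feature-table test substrates.

The generator stands in for a downloaded decoy archive: it builds ideal
native backbones from torsion angles (helix, strand, coil segments),
perturbs them at calibrated noise levels so the resulting decoys span the
quality bands of real predicted models (GDT-TS around 0.8, around 0.5 and
below 0.3), and labels every decoy by actually computing GDT-TS against
its native.  All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import (
    AA1_TO_3,
    CA_C_O_ANGLE,
    CA_CB_LENGTH,
    CB_CB_X_ANGLE,
    CHI1_STUB,
    CHI1_STUB_LENGTH,
    CHI1_STUB_LENGTH_DEFAULT,
    C_N_CA_CB_TORSION,
    IDEAL_BOND_ANGLES,
    IDEAL_BOND_LENGTHS,
    MODAL_CHI1,
    MODAL_CHI1_DEFAULT,
    N_CA_CB_ANGLE,
)
from .gdt import gdt_ts
from .structure import Atom, Residue, Structure, backbone_dihedrals

HELIX = (-57.0, -47.0)
STRAND = (-120.0, 130.0)
# cartesian noise levels (A): spans GDT-TS from ~1.0 down to ~0.1
DEFAULT_NOISE_GRID = (0.2, 0.5, 1.0, 2.0, 4.0, 8.0)
# dihedral noise levels (degrees): same quality span but with intact
# chains and ideal covalent geometry, like real predicted models
DEFAULT_DIHEDRAL_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 40.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given three predecessors: |c-d| = bond,
    angle(b,c,d) = angle_deg, torsion(a,b,c,d) = torsion_deg (NeRF)."""
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(theta),
                        bond * np.sin(theta) * np.cos(chi),
                        bond * np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclasses.dataclass
class NoiseSpec:
    """How to degrade a native into a decoy.

    mode 'cartesian': i.i.d. Gaussian displacement of every atom,
    sigma in Angstrom.  mode 'dihedral': Gaussian noise on phi/psi
    (sigma in degrees) followed by a rebuild from ideal geometry.
    mode 'fragment': swap two torsion windows of ``fragment_len`` and
    rebuild.  The seed is mandatory; generation is bit-reproducible.
    """

    mode: str = "cartesian"
    sigma: float = 1.0
    fragment_len: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("cartesian", "dihedral", "fragment"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def build_chain(
    sequence: str,
    phi_psi: tuple[float, float] | Sequence[tuple[float, float]],
    chi1: Optional[Sequence[Optional[float]]] = None,
    structure_id: str = "built",
    chain_id: str = "A",
) -> Structure:
    """Build a full backbone (N, CA, C, O) plus CB and a one-atom chi1 stub
    from ideal covalent geometry by sequential torsion placement.

    ``phi_psi`` is either one (phi, psi) pair applied to every residue or a
    per-residue sequence; omega is fixed trans (180 degrees).  ``chi1``
    optionally sets the chi1 torsion per residue (default: a coarse modal
    value per residue type).
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    for ch in sequence:
        if ch not in AA1_TO_3:
            raise ValueError(f"invalid residue code {ch!r}")
    if isinstance(phi_psi, tuple) and np.isscalar(phi_psi[0]):
        angles = [(float(phi_psi[0]), float(phi_psi[1]))] * n
    else:
        angles = [(float(p), float(s)) for p, s in phi_psi]
        if len(angles) != n:
            raise ValueError("phi_psi length mismatch")

    b_nca = IDEAL_BOND_LENGTHS[("N", "CA")]
    b_cac = IDEAL_BOND_LENGTHS[("CA", "C")]
    b_cn = IDEAL_BOND_LENGTHS[("C", "N")]
    b_co = IDEAL_BOND_LENGTHS[("C", "O")]
    a_ncac = IDEAL_BOND_ANGLES[("N", "CA", "C")]
    a_cacn = IDEAL_BOND_ANGLES[("CA", "C", "N")]
    a_cnca = IDEAL_BOND_ANGLES[("C", "N", "CA")]

    # first residue in a canonical frame
    N0 = np.zeros(3)
    CA0 = np.array([b_nca, 0.0, 0.0])
    ang = np.radians(180.0 - a_ncac)
    C0 = CA0 + b_cac * np.array([np.cos(ang), np.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": N0, "CA": CA0, "C": C0}]
    for i in range(1, n):
        prev = backbone[-1]
        psi_prev = angles[i - 1][1]
        Ni = place_atom(prev["N"], prev["CA"], prev["C"], b_cn, a_cacn, psi_prev)
        CAi = place_atom(prev["CA"], prev["C"], Ni, b_nca, a_cnca, 180.0)  # omega
        Ci = place_atom(prev["C"], Ni, CAi, b_cac, a_ncac, angles[i][0])
        backbone.append({"N": Ni, "CA": CAi, "C": Ci})

    st = Structure(id=structure_id)
    for i, one in enumerate(sequence):
        aa = AA1_TO_3[one]
        res = Residue(aa=aa, chain_id=chain_id, seq_index=i + 1)
        bb = backbone[i]
        res.add_atom(Atom("N", bb["N"], "N"))
        res.add_atom(Atom("CA", bb["CA"], "C"))
        res.add_atom(Atom("C", bb["C"], "C"))
        # carbonyl O anti to the next amide nitrogen: torsion psi + 180
        psi = angles[i][1]
        O = place_atom(bb["N"], bb["CA"], bb["C"], b_co, CA_C_O_ANGLE, psi + 180.0)
        res.add_atom(Atom("O", O, "O"))
        if aa != "GLY":
            CB = place_atom(bb["C"], bb["N"], bb["CA"], CA_CB_LENGTH,
                            N_CA_CB_ANGLE, C_N_CA_CB_TORSION)
            res.add_atom(Atom("CB", CB, "C"))
            stub = CHI1_STUB.get(aa)
            if stub is not None and aa != "ALA":
                chi = None if chi1 is None else chi1[i]
                if chi is None:
                    chi = MODAL_CHI1.get(aa, MODAL_CHI1_DEFAULT)
                length = CHI1_STUB_LENGTH.get(aa, CHI1_STUB_LENGTH_DEFAULT)
                X = place_atom(bb["N"], bb["CA"], CB, length, CB_CB_X_ANGLE, chi)
                res.add_atom(Atom(stub, X, "S" if stub.startswith("S")
                                  else ("O" if stub.startswith("O") else "C")))
        st.add_residue(res)
    return st


def _native_torsions(native: Structure) -> list[tuple[float, float]]:
    torsions = backbone_dihedrals(native)
    out = []
    for tor in torsions:
        out.append((tor.phi if tor.phi is not None else 180.0,
                    tor.psi if tor.psi is not None else 180.0))
    return out


def _native_chi1(native: Structure) -> list[Optional[float]]:
    from .structure import side_chain_chis
    out: list[Optional[float]] = []
    for res in native.residues:
        chis = side_chain_chis(res)
        out.append(chis[0] if chis else None)
    return out


def perturb(native: Structure, spec: NoiseSpec) -> Structure:
    """A decoy of ``native`` under the given noise specification."""
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "cartesian":
        decoy = native.copy(id=f"{native.id}_d{spec.seed}")
        for _, atom in decoy.atoms():
            atom.coord = atom.coord + rng.normal(0.0, spec.sigma, 3)
        return decoy

    angles = _native_torsions(native)
    if spec.mode == "dihedral":
        angles = [
            (_wrap(p + rng.normal(0.0, spec.sigma)),
             _wrap(s + rng.normal(0.0, spec.sigma)))
            for p, s in angles]
    else:  # fragment
        n = len(angles)
        L = min(spec.fragment_len, max(1, n // 2))
        if n >= 2 * L:
            i = int(rng.integers(0, n - 2 * L + 1))
            j = int(rng.integers(i + L, n - L + 1))
            angles[i:i + L], angles[j:j + L] = angles[j:j + L], angles[i:i + L]
    return build_chain(native.sequence, angles, chi1=_native_chi1(native),
                       structure_id=f"{native.id}_d{spec.seed}")


def _wrap(angle: float) -> float:
    angle = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if angle == -180.0 else angle


# ---------------------------------------------------------------------------
# Benchmark generation


@dataclasses.dataclass
class DecoyRecord:
    model_id: str
    structure: Structure
    observed_gdt: float
    sigma: float


@dataclasses.dataclass
class SyntheticBenchmark:
    """Named natives plus labelled decoy sets, CASP-benchmark shaped."""

    natives: dict[str, Structure]
    decoys: dict[str, list[DecoyRecord]]
    seed: int

    def manifest(self) -> pd.DataFrame:
        rows = []
        for target_id in self.natives:
            for rec in self.decoys[target_id]:
                rows.append({"target_id": target_id, "model_id": rec.model_id,
                             "sigma": rec.sigma, "observed_gdt": rec.observed_gdt})
        return pd.DataFrame(rows)

    def to_directory(self, path: str | Path) -> Path:
        """Write natives/decoys as PDB files plus a manifest TSV."""
        from .structure import write_pdb
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for target_id, native in self.natives.items():
            tdir = path / target_id
            tdir.mkdir(exist_ok=True)
            write_pdb(native, tdir / "native.pdb")
            for rec in self.decoys[target_id]:
                write_pdb(rec.structure, tdir / f"{rec.model_id}.pdb")
                rows.append({
                    "target_id": target_id, "model_id": rec.model_id,
                    "path": str(tdir / f"{rec.model_id}.pdb"),
                    "sigma": rec.sigma, "observed_gdt": rec.observed_gdt})
        pd.DataFrame(rows).to_csv(path / "manifest.tsv", sep="\t", index=False)
        return path / "manifest.tsv"


def _random_topology(length: int, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Per-residue torsions from random helix/strand/coil segments."""
    angles: list[tuple[float, float]] = []
    while len(angles) < length:
        kind = rng.choice(["H", "E", "C"], p=[0.45, 0.3, 0.25])
        seg = int(rng.integers(6, 16)) if kind != "C" else int(rng.integers(3, 8))
        for _ in range(min(seg, length - len(angles))):
            if kind == "H":
                angles.append(HELIX)
            elif kind == "E":
                angles.append(STRAND)
            else:
                angles.append((float(rng.uniform(-150.0, -60.0)),
                               float(rng.uniform(-60.0, 170.0))))
    return angles


def make_native(length: int, seed: int, structure_id: str = "native") -> Structure:
    """One synthetic native with mixed helix/strand/coil topology."""
    rng = np.random.default_rng(seed)
    aa_pool = list("ACDEFGHIKLMNPQRSTVWY")
    sequence = "".join(rng.choice(aa_pool) for _ in range(length))
    return build_chain(sequence, _random_topology(length, rng),
                       structure_id=structure_id)


def generate_benchmark(
    n_targets: int,
    decoys_per_target: int,
    noise_grid: Optional[Sequence[float]] = None,
    seed: int = 0,
    length_range: tuple[int, int] = (50, 120),
    mode: str = "dihedral",
) -> SyntheticBenchmark:
    """A reduced-scale CASP-style benchmark with computed GDT-TS labels.

    Decoys are distributed round-robin over the noise grid so each target
    spans the full quality range (GDT-TS bands ~0.8 / ~0.5 / <0.3); every
    label is computed by the GDT module, never assumed.  The default
    dihedral mode degrades models the way real predictions degrade —
    wrong torsions on intact, ideal-geometry chains; cartesian mode
    shatters covalent geometry instead.
    """
    if n_targets < 2:
        raise ValueError("need at least 2 targets")
    if noise_grid is None:
        noise_grid = DEFAULT_DIHEDRAL_GRID if mode == "dihedral" else DEFAULT_NOISE_GRID
    rng = np.random.default_rng(seed)
    natives: dict[str, Structure] = {}
    decoys: dict[str, list[DecoyRecord]] = {}
    for t in range(n_targets):
        target_id = f"T{t:03d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        native = make_native(length, seed=int(rng.integers(2 ** 31)),
                             structure_id=target_id)
        natives[target_id] = native
        records = []
        for k in range(decoys_per_target):
            sigma = float(noise_grid[k % len(noise_grid)])
            spec = NoiseSpec(mode=mode, sigma=sigma,
                             seed=int(rng.integers(2 ** 31)))
            decoy = perturb(native, spec)
            decoy.id = f"{target_id}_m{k:03d}"
            observed = gdt_ts(decoy, native).gdt_ts
            records.append(DecoyRecord(model_id=decoy.id, structure=decoy,
                                       observed_gdt=observed, sigma=sigma))
        decoys[target_id] = records
    return SyntheticBenchmark(natives=natives, decoys=decoys, seed=seed)


# ---------------------------------------------------------------------------
# Feature-table substrate for model training tests


_MAPPINGS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "mean3": lambda X: X[:, :3].mean(axis=1),
    "linear": lambda X: X @ np.linspace(0.3, -0.3, X.shape[1]) + 0.5,
}


def synthetic_feature_table(
    n: int,
    mapping: str | Callable[[np.ndarray], np.ndarray] = "mean3",
    noise_sd: float = 0.02,
    seed: int = 0,
    n_features: int = 19,
) -> tuple[np.ndarray, np.ndarray]:
    """(features, targets) with a known ground-truth mapping plus noise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    fn = _MAPPINGS[mapping] if isinstance(mapping, str) else mapping
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, (n, n_features))
    y = np.clip(fn(X) + rng.normal(0.0, noise_sd, n), 0.0, 1.0)
    return X, y
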