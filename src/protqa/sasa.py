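"""Solvent-accessible surface area (Shrake-Rupley) and relative accessibility.

Atom SASA uses a deterministic golden-spiral point distribution on each
atom's solvent-expanded sphere; a point is exposed when it lies outside
every neighbouring atom's expanded sphere.  Residue relative accessibility
(rSASA) divides the residue's atom-SASA sum by its Gly-X-Gly theoretical
maximum and is discretised into buried (< 0.1), intermediate (0.1-0.4) and
exposed (> 0.4) classes.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .constants import DEFAULT_RADIUS, ELEMENT_RADII, MAX_ASA
from .structure import Structure

ACC_CLASSES = ("buried", "intermediate", "exposed")
BURIED_MAX = 0.1
EXPOSED_MIN = 0.4


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral (Fibonacci) unit-sphere points."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Coordinates in a deterministic principal-axes frame.

    The sphere point lattice is fixed in space, so raw Shrake-Rupley output
    depends slightly on molecular orientation.  Expressing the structure in
    its own canonical frame first makes the computation rigid-motion
    invariant (axis signs fixed by the third moment of the projections,
    falling back to the first atom's projection; handedness by construction).
    """
    center = coords.mean(axis=0)
    c = coords - center
    if len(coords) < 2:
        return c
    _, V = np.linalg.eigh(c.T @ c)
    V = V[:, ::-1]  # principal axes, descending variance
    axes = []
    for k in range(2):
        v = V[:, k]
        proj = c @ v
        s = float((proj ** 3).sum())
        if abs(s) < 1e-9:
            s = float(proj[0])
        if s < 0:
            v = -v
        axes.append(v)
    axes.append(np.cross(axes[0], axes[1]))
    return c @ np.column_stack(axes)


def compute_sasa(
    structure: Structure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA in A^2, in structure atom-iteration order."""
    atoms = [atom for _, atom in structure.atoms()]
    coords = _canonical_frame(np.array([a.coord for a in atoms], dtype=float))
    radii = np.empty(len(atoms))
    for k, atom in enumerate(atoms):
        if atom.element not in ELEMENT_RADII:
            warnings.warn(
                f"unknown element {atom.element!r} for atom {atom.name}; "
                f"using default radius {DEFAULT_RADIUS} A")
        radii[k] = ELEMENT_RADII.get(atom.element, DEFAULT_RADIUS)

    expanded = radii + probe
    unit = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    neighbors: list[list[int]] = [[] for _ in range(len(atoms))]
    for i, j in tree.query_pairs(2.0 * expanded.max()):
        # occlusion is only possible within the sum of expanded radii
        if np.dot(coords[i] - coords[j], coords[i] - coords[j]) \
                < (expanded[i] + expanded[j]) ** 2:
            neighbors[i].append(j)
            neighbors[j].append(i)
    sasa = np.empty(len(atoms))
    for k in range(len(atoms)):
        neigh = neighbors[k]
        if neigh:
            pts = coords[k] + expanded[k] * unit
            nc = coords[neigh]
            nr = expanded[neigh]
            d2 = cdist(pts, nc, "sqeuclidean")
            frac = float((~(d2 < nr * nr).any(axis=1)).mean())
        else:
            frac = 1.0
        sasa[k] = frac * 4.0 * np.pi * expanded[k] ** 2
    return sasa


@dataclasses.dataclass
class AccessibilityProfile:
    """Per-residue relative SASA and its discretised class (0/1/2)."""

    rsasa: np.ndarray
    classes: np.ndarray  # int codes into ACC_CLASSES

    def class_names(self) -> list[str]:
        return [ACC_CLASSES[c] for c in self.classes]


def classify_rsasa(rsasa: np.ndarray) -> np.ndarray:
    classes = np.ones(len(rsasa), dtype=int)
    classes[rsasa < BURIED_MAX] = 0
    classes[rsasa > EXPOSED_MIN] = 2
    return classes


def accessibility_profile(
    structure: Structure,
    probe: float = 1.4,
    n_sphere_points: int = 960,
    atom_sasa: np.ndarray | None = None,
) -> AccessibilityProfile:
    """Residue rSASA profile; pass ``atom_sasa`` to reuse a previous pass."""
    if atom_sasa is None:
        atom_sasa = compute_sasa(structure, probe, n_sphere_points)
    rsasa = np.empty(structure.n_residues)
    k = 0
    for i, res in enumerate(structure.residues):
        total = float(atom_sasa[k:k + len(res.atoms)].sum())
        k += len(res.atoms)
        rsasa[i] = total / MAX_ASA[res.aa]
    return AccessibilityProfile(rsasa=rsasa, classes=classify_rsasa(rsasa))
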