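"""The 19-component structure quality descriptor.

Layout (fixed order):

====  =======================  ===================================================
f01   dihedral_pref_aa         mean (phi,psi) log-odds, amino-acid context
f02   dihedral_pref_ss         mean (phi,psi) log-odds, secondary-structure context
f03   dihedral_pref_aa_ss      mean (phi,psi) log-odds, joint context
f04   acc_pref_aa              mean rSASA-class log-odds, amino-acid context
f05   acc_pref_ss              mean rSASA-class log-odds, secondary-structure context
f06   acc_pref_aa_ss           mean rSASA-class log-odds, joint context
f07   acc_modal_aa             fraction of residues in their aa-modal rSASA class
f08   acc_modal_ss             fraction in their ss-modal rSASA class
f09   acc_modal_aa_ss          fraction in their (aa,ss)-modal rSASA class
f10   ss_fitness               sequence-to-secondary-structure fitness, (0, 1]
f11   profitfun_avg            arithmetic mean of f01..f10
f12   rotamer_outlier_frac     fraction of rotameric residues at rare chi bins
f13   rotamer_favored_frac     fraction of rotameric residues at common chi bins
f14   ca_geometry_outlier_pct  % residues with aberrant CA-CA virtual geometry
f15   clash_score              serious steric overlaps per 100 residues
f16   molprobity_composite     log-combination of clash/rotamer/Ramachandran terms
f17   gscore_dihedral          dihedral normality (log-odds, Procheck-style)
f18   gscore_covalent          covalent-geometry normality (mean -z^2/2)
f19   gscore_overall           (f17 + f18) / 2
====  =======================  ===================================================

Features that are undefined for a structure (e.g. rotamer fractions of a
poly-glycine chain) are encoded as 0 and flagged in ``valid``.
"""

from __future__ import annotations

import dataclasses
import math
from collections import deque
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    CHAIN_BREAK_CN,
    IDEAL_BOND_ANGLES,
    IDEAL_BOND_LENGTHS,
    SIGMA_BOND_ANGLE,
    SIGMA_BOND_LENGTH,
)
from .sasa import AccessibilityProfile, accessibility_profile, compute_sasa  # noqa: F401
from .secstruct import assign_secondary_structure  # noqa: F401 (module surface)
from .structure import (
    BackboneTorsions,
    Residue,
    Structure,
    backbone_dihedrals,
    side_chain_chis,
)
from .tables import SS_CLASSES, PreferenceTables, chi_bin

FEATURE_NAMES = (
    "dihedral_pref_aa", "dihedral_pref_ss", "dihedral_pref_aa_ss",
    "acc_pref_aa", "acc_pref_ss", "acc_pref_aa_ss",
    "acc_modal_aa", "acc_modal_ss", "acc_modal_aa_ss",
    "ss_fitness", "profitfun_avg",
    "rotamer_outlier_frac", "rotamer_favored_frac",
    "ca_geometry_outlier_pct", "clash_score", "molprobity_composite",
    "gscore_dihedral", "gscore_covalent", "gscore_overall",
)

ROTAMER_FAVORED_MIN = 0.02
ROTAMER_OUTLIER_MAX = 0.005
CA_DIST_TRANS = (3.6, 4.0)
CA_DIST_CISPRO = (2.8, 3.2)
CA_ANGLE_WINDOW = (75.0, 150.0)


@dataclasses.dataclass
class FeatureVector:
    """Ordered 19-component descriptor of one model structure."""

    values: np.ndarray
    valid: np.ndarray
    structure_id: str = ""

    names = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        assert self.values.shape == (19,) and self.valid.shape == (19,)

    def __len__(self) -> int:
        return 19

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


# ---------------------------------------------------------------------------
# ProFitFun-style statistical preference features (f01-f11)


def profitfun_features(
    structure: Structure,
    tables: PreferenceTables,
    torsions: Optional[list[BackboneTorsions]] = None,
    ss: Optional[str] = None,
    acc: Optional[AccessibilityProfile] = None,
) -> np.ndarray:
    """f01..f11; precomputed torsions/ss/accessibility may be passed in."""
    if torsions is None:
        torsions = backbone_dihedrals(structure)
    if ss is None:
        ss = assign_secondary_structure(structure)
    if acc is None:
        acc = accessibility_profile(structure)

    d_aa, d_ss, d_aa_ss = [], [], []
    a_aa, a_ss, a_aa_ss = [], [], []
    m_aa, m_ss, m_aa_ss = [], [], []
    fitness = []
    ss_index = {s: k for k, s in enumerate(SS_CLASSES)}
    for i, res in enumerate(structure.residues):
        aa, s = res.aa, ss[i]
        tor = torsions[i]
        if tor.phi is not None and tor.psi is not None:
            d_aa.append(tables.dihedral_logodds(aa, tor.phi, tor.psi))
            d_ss.append(tables.dihedral_logodds(s, tor.phi, tor.psi))
            d_aa_ss.append(tables.dihedral_logodds((aa, s), tor.phi, tor.psi))
        c = int(acc.classes[i])
        a_aa.append(tables.acc_logodds(aa, c))
        a_ss.append(tables.acc_logodds(s, c))
        a_aa_ss.append(tables.acc_logodds((aa, s), c))
        m_aa.append(c == tables.acc_modal_class(aa))
        m_ss.append(c == tables.acc_modal_class(s))
        m_aa_ss.append(c == tables.acc_modal_class((aa, s)))
        prop = tables.ss_propensity[aa]
        fitness.append(math.log(prop[ss_index[s]] / prop.max()))

    def mean(xs):
        return float(np.mean(xs)) if xs else 0.0

    f = np.empty(11)
    f[0], f[1], f[2] = mean(d_aa), mean(d_ss), mean(d_aa_ss)
    f[3], f[4], f[5] = mean(a_aa), mean(a_ss), mean(a_aa_ss)
    f[6], f[7], f[8] = mean(m_aa), mean(m_ss), mean(m_aa_ss)
    f[9] = math.exp(mean(fitness))
    f[10] = float(np.mean(f[:10]))
    return f


# ---------------------------------------------------------------------------
# Stereochemistry features (f12-f16)


def _bond_graph(structure: Structure) -> tuple[list, dict[int, set[int]]]:
    """Covalent bond graph over heavy atoms.

    Bonds are inferred geometrically but only allowed within a residue or
    between sequence-adjacent residues of the same chain, so that sterically
    clashing atoms far apart in sequence are never treated as bonded.
    """
    atoms = []  # (residue_pos, chain_id, res_index, atom)
    for pos, (res, atom) in enumerate(structure.atoms()):
        atoms.append((res, atom))
    coords = np.array([a.coord for _, a in atoms])
    adj: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(2.1):
        ri, ai = atoms[i]
        rj, aj = atoms[j]
        same = ri is rj
        adjacent = (ri.chain_id == rj.chain_id
                    and abs(ri.index - rj.index) == 1)
        if not (same or adjacent):
            continue
        limit = 2.1 if "S" in (ai.element, aj.element) else 1.9
        if np.linalg.norm(ai.coord - aj.coord) < limit:
            adj[i].add(j)
            adj[j].add(i)
    return atoms, adj


def _within_bond_separation(adj: dict[int, set[int]], i: int, j: int,
                            max_sep: int = 3) -> bool:
    """True if atoms i, j are within ``max_sep`` covalent bonds."""
    seen = {i}
    frontier = deque([(i, 0)])
    while frontier:
        node, depth = frontier.popleft()
        if depth == max_sep:
            continue
        for nb in adj[node]:
            if nb == j:
                return True
            if nb not in seen:
                seen.add(nb)
                frontier.append((nb, depth + 1))
    return False


def clash_score(
    structure: Structure,
    overlap_threshold: float = 0.4,
    per_1000_atoms: bool = False,
) -> float:
    """Serious steric overlaps per 100 residues (f15).

    A clash is a non-bonded atom pair (more than 3 covalent bonds apart)
    whose distance is below r_i + r_j - overlap_threshold.  The optional
    ``per_1000_atoms`` switch reports the MolProbity-style normalisation
    instead of the per-100-residues default.
    """
    atoms, adj = _bond_graph(structure)
    if len(atoms) < 2:
        return 0.0
    coords = np.array([a.coord for _, a in atoms])
    radii = np.array([a.radius for _, a in atoms])
    tree = cKDTree(coords)
    max_clash_dist = 2.0 * radii.max() - overlap_threshold
    clashes = 0
    for i, j in tree.query_pairs(max_clash_dist):
        if np.linalg.norm(coords[i] - coords[j]) >= radii[i] + radii[j] - overlap_threshold:
            continue
        if _within_bond_separation(adj, i, j):
            continue
        clashes += 1
    if per_1000_atoms:
        return 1000.0 * clashes / len(atoms)
    return 100.0 * clashes / structure.n_residues


def rotamer_features(structure: Structure, tables: PreferenceTables) -> tuple[float, float, bool]:
    """(f12 outlier fraction, f13 favored fraction, defined flag).

    A residue is favored when its chi-bin combination has reference
    frequency >= 2 %, an outlier below 0.5 %.  GLY/ALA and residues with
    no measurable chi are excluded from the denominator.
    """
    n_rot = 0
    outliers = 0
    favored = 0
    for res in structure.residues:
        chis = side_chain_chis(res)
        if not chis:
            continue
        n_rot += 1
        freq = tables.rotamers.frequency(res.aa, tuple(chi_bin(x) for x in chis))
        if freq < ROTAMER_OUTLIER_MAX:
            outliers += 1
        if freq >= ROTAMER_FAVORED_MIN:
            favored += 1
    if n_rot == 0:
        return 0.0, 0.0, False
    return outliers / n_rot, favored / n_rot, True


def ca_geometry_outliers(structure: Structure) -> float:
    """Percentage of interior residues with aberrant CA virtual geometry (f14)."""
    outliers = 0
    evaluable = 0
    for residues in structure.chains.values():
        for i in range(1, len(residues) - 1):
            prev_ca = residues[i - 1].coord("CA")
            ca = residues[i].coord("CA")
            next_ca = residues[i + 1].coord("CA")
            if prev_ca is None or ca is None or next_ca is None:
                continue
            evaluable += 1
            d = float(np.linalg.norm(next_ca - ca))
            window = (CA_DIST_CISPRO if residues[i + 1].aa == "PRO"
                      and d < 3.4 else CA_DIST_TRANS)
            dist_ok = window[0] <= d <= window[1]
            v1 = prev_ca - ca
            v2 = next_ca - ca
            cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            ang_ok = CA_ANGLE_WINDOW[0] <= ang <= CA_ANGLE_WINDOW[1]
            if not (dist_ok and ang_ok):
                outliers += 1
    if evaluable == 0:
        return 0.0
    return 100.0 * outliers / evaluable


def rama_favored_pct(
    structure: Structure,
    tables: PreferenceTables,
    torsions: Optional[list[BackboneTorsions]] = None,
) -> float:
    """% of scored residues inside the bins holding the top 98 % of the
    context-free Ramachandran mass."""
    if torsions is None:
        torsions = backbone_dihedrals(structure)
    mask = tables.favored_dihedral_mask()
    n = 0
    fav = 0
    from .tables import dihedral_bin
    for tor in torsions:
        if tor.phi is None or tor.psi is None:
            continue
        n += 1
        i, j = dihedral_bin(tor.phi, tor.psi, tables.bin_width)
        if mask[i, j]:
            fav += 1
    return 100.0 * fav / n if n else 100.0


def molprobity_composite(f15: float, f12: float, rama_favored: float) -> float:
    """Composite stereochemistry score (f16); higher is worse.

    A MolProbity-style log combination of the clash score, the rotamer
    outlier percentage and the Ramachandran-favored percentage.
    """
    return (0.426 * math.log(1.0 + f15)
            + 0.33 * math.log(1.0 + max(0.0, 100.0 * f12 - 1.0))
            + 0.25 * math.log(1.0 + max(0.0, (100.0 - rama_favored) - 2.0))
            + 0.5)


# ---------------------------------------------------------------------------
# Procheck-style G-scores (f17-f19)


def g_scores(
    structure: Structure,
    tables: PreferenceTables,
    torsions: Optional[list[BackboneTorsions]] = None,
) -> tuple[float, float, float]:
    """(f17 dihedral G-score, f18 covalent G-score, f19 overall).

    f17 averages, over residues, the (phi,psi) log-odds in amino-acid
    context plus the chi-bin log-odds against a uniform chi background.
    f18 averages -z^2/2 over backbone bond lengths and angles against the
    ideal-geometry constants; an exactly ideal chain scores 0.
    """
    if torsions is None:
        torsions = backbone_dihedrals(structure)

    per_res = []
    for i, res in enumerate(structure.residues):
        tor = torsions[i]
        terms = []
        if tor.phi is not None and tor.psi is not None:
            terms.append(tables.dihedral_logodds(res.aa, tor.phi, tor.psi))
        chis = side_chain_chis(res)
        if chis:
            bins = tuple(chi_bin(x) for x in chis)
            freq = tables.rotamers.frequency(res.aa, bins)
            terms.append(math.log(freq * (3 ** len(bins))))
        if terms:
            per_res.append(float(np.sum(terms)))
    f17 = float(np.mean(per_res)) if per_res else 0.0

    zs = []
    for residues in structure.chains.values():
        for i, res in enumerate(residues):
            N, CA, C, O = (res.coord(x) for x in ("N", "CA", "C", "O"))
            if N is None or CA is None or C is None:
                continue
            zs.append((np.linalg.norm(CA - N) - IDEAL_BOND_LENGTHS[("N", "CA")])
                      / SIGMA_BOND_LENGTH)
            zs.append((np.linalg.norm(C - CA) - IDEAL_BOND_LENGTHS[("CA", "C")])
                      / SIGMA_BOND_LENGTH)
            if O is not None:
                zs.append((np.linalg.norm(O - C) - IDEAL_BOND_LENGTHS[("C", "O")])
                          / SIGMA_BOND_LENGTH)
            zs.append((_angle(N, CA, C) - IDEAL_BOND_ANGLES[("N", "CA", "C")])
                      / SIGMA_BOND_ANGLE)
            if i + 1 < len(residues):
                nxt = residues[i + 1]
                Nn, CAn = nxt.coord("N"), nxt.coord("CA")
                if Nn is not None and np.linalg.norm(Nn - C) <= CHAIN_BREAK_CN:
                    zs.append((np.linalg.norm(Nn - C) - IDEAL_BOND_LENGTHS[("C", "N")])
                              / SIGMA_BOND_LENGTH)
                    zs.append((_angle(CA, C, Nn) - IDEAL_BOND_ANGLES[("CA", "C", "N")])
                              / SIGMA_BOND_ANGLE)
                    if CAn is not None:
                        zs.append((_angle(C, Nn, CAn) - IDEAL_BOND_ANGLES[("C", "N", "CA")])
                                  / SIGMA_BOND_ANGLE)
    f18 = float(np.mean([-0.5 * z * z for z in zs])) if zs else 0.0
    f19 = 0.5 * f17 + 0.5 * f18
    return f17, f18, f19


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1 = a - b
    v2 = c - b
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Assembly


def extract_features(structure: Structure, tables: PreferenceTables) -> FeatureVector:
    """Assemble the full 19-component :class:`FeatureVector`."""
    torsions = backbone_dihedrals(structure)
    ss = assign_secondary_structure(structure)
    acc = accessibility_profile(structure)

    values = np.zeros(19)
    valid = np.ones(19, dtype=bool)
    values[0:11] = profitfun_features(structure, tables, torsions, ss, acc)
    f12, f13, rot_defined = rotamer_features(structure, tables)
    values[11], values[12] = f12, f13
    valid[11] = valid[12] = rot_defined
    values[13] = ca_geometry_outliers(structure)
    values[14] = clash_score(structure)
    rama = rama_favored_pct(structure, tables, torsions)
    values[15] = molprobity_composite(values[14], f12, rama)
    values[16], values[17], values[18] = g_scores(structure, tables, torsions)
    return FeatureVector(values=values, valid=valid, structure_id=structure.id)
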