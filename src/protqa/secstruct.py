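"""Secondary-structure assignment (H / E / C) from backbone geometry.

A reduced Kabsch-Sander scheme: an ideal amide hydrogen is rebuilt from the
backbone (1.0 A from N, anti-parallel to the preceding carbonyl), hydrogen
bonds are scored with the classic electrostatic energy

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

and accepted when E < -0.5.  Consecutive i -> i+4 turns give helix (H),
ladder patterns give strand (E), everything else is coil (C).  Residues
with incomplete backbones are coil.
"""

from __future__ import annotations

import numpy as np

from .constants import CHAIN_BREAK_CN
from .structure import Structure

_HB_ENERGY_CUTOFF = -0.5
_Q = 0.084 * 332.0
_CA_PREFILTER = 9.0  # A; CA pairs farther than this cannot H-bond


def _chain_arrays(residues):
    n = len(residues)
    N = np.full((n, 3), np.nan)
    CA = np.full((n, 3), np.nan)
    C = np.full((n, 3), np.nan)
    O = np.full((n, 3), np.nan)
    for i, r in enumerate(residues):
        for name, arr in (("N", N), ("CA", CA), ("C", C), ("O", O)):
            c = r.coord(name)
            if c is not None:
                arr[i] = c
    return N, CA, C, O


def _hbond_matrix(residues) -> np.ndarray:
    """hb[i, j]: carbonyl of residue i accepts the amide H of residue j."""
    n = len(residues)
    N, CA, C, O = _chain_arrays(residues)

    # ideal amide H on the donor nitrogen; PRO and chain starts cannot donate
    H = np.full((n, 3), np.nan)
    for j in range(1, n):
        if residues[j].aa == "PRO":
            continue
        if residues[j].chain_id != residues[j - 1].chain_id:
            continue
        if np.isnan(N[j]).any() or np.isnan(C[j - 1]).any() or np.isnan(O[j - 1]).any():
            continue
        if np.linalg.norm(C[j - 1] - N[j]) > CHAIN_BREAK_CN:
            continue
        d = C[j - 1] - O[j - 1]
        nd = np.linalg.norm(d)
        if nd > 1e-6:
            H[j] = N[j] + d / nd

    donor_ok = ~np.isnan(H[:, 0])
    acceptor_ok = ~(np.isnan(C[:, 0]) | np.isnan(O[:, 0]))

    def dmat(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))

    with np.errstate(invalid="ignore", divide="ignore"):
        r_on = dmat(O, N)
        r_ch = dmat(C, H)
        r_oh = dmat(O, H)
        r_cn = dmat(C, N)
        energy = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
        r_min = np.fmin(np.fmin(r_on, r_ch), np.fmin(r_oh, r_cn))
        ca_far = dmat(CA, CA) > _CA_PREFILTER

    idx = np.arange(n)
    hb = (energy < _HB_ENERGY_CUTOFF)
    hb &= acceptor_ok[:, None] & donor_ok[None, :]
    hb &= np.abs(idx[:, None] - idx[None, :]) >= 2
    hb &= r_min >= 0.5          # clashing geometry is not a hydrogen bond
    hb &= ~np.isnan(energy)
    hb &= ~ca_far               # nan CA distances compare False, kept out by the nan-energy mask
    return hb


def assign_secondary_structure(structure: Structure) -> str:
    """Per-residue H/E/C string over the flattened residue list.

    Helices are intra-chain (i -> i+4 turn ladders); bridge partners may
    sit on different chains, so inter-chain sheets are recognised.
    """
    residues = structure.residues
    n = len(residues)
    hb = _hbond_matrix(residues)
    ss = np.full(n, "C", dtype="<U1")

    def same_chain(i: int, j: int) -> bool:
        return residues[i].chain_id == residues[j].chain_id

    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if hb[i, i + 4] and same_chain(i, i + 4):
            turn4[i] = True
    for i in range(n - 1):
        if turn4[i] and turn4[i + 1]:
            ss[i + 1:i + 5] = "H"

    def _hb(i: int, j: int) -> bool:
        return 0 <= i < n and 0 <= j < n and hb[i, j]

    for i in range(n):
        for j in range(i + 3, n):
            anti = (_hb(i, j) and _hb(j, i)) or \
                   (_hb(i - 1, j + 1) and _hb(j - 1, i + 1))
            para = (_hb(i - 1, j) and _hb(j, i + 1)) or \
                   (_hb(j - 1, i) and _hb(i, j + 1))
            if anti or para:
                if ss[i] != "H":
                    ss[i] = "E"
                if ss[j] != "H":
                    ss[j] = "E"
    return "".join(ss)
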