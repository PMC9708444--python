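"""Statistical preference tables learned from a reference structure set.

Counts of (phi, psi) bins and of relative-accessibility classes are
accumulated per amino acid, per secondary-structure class and per
(aa, ss) pair, converted to pseudocounted probabilities, and scored as
log-odds against the context-free background:

    L(b | context) = ln P(b | context) / P(b)

A secondary-structure propensity table P(ss | aa) and a rotamer table
(chi angles binned at 120 degrees into gauche+/trans/gauche-) come from
the same pass over the reference set.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .constants import STANDARD_AA
from .errors import TableError
from .sasa import accessibility_profile
from .secstruct import assign_secondary_structure
from .structure import Structure, backbone_dihedrals, side_chain_chis

SS_CLASSES = ("H", "E", "C")
N_ACC = 3
AA_ORDER = tuple(sorted(STANDARD_AA))

_FORMAT = "protqa-tables-1"


def dihedral_bin(phi: float, psi: float, bin_width: float) -> tuple[int, int]:
    nb = int(round(360.0 / bin_width))
    i = min(int((phi + 180.0) // bin_width), nb - 1)
    j = min(int((psi + 180.0) // bin_width), nb - 1)
    return i, j


def chi_bin(angle: float) -> int:
    """0 = gauche+ [0,120), 1 = trans [120,240), 2 = gauche- [240,360)."""
    return int((angle % 360.0) // 120.0)


@dataclasses.dataclass
class RotamerTable:
    """Binned chi-combination frequencies per residue type.

    Counts are stored at full observed chi depth; queries marginalise by
    prefix so that structures with truncated side chains can still be
    scored consistently.
    """

    counts: dict[str, dict[tuple[int, ...], float]]
    pseudocount: float = 0.1

    def frequency(self, aa: str, bins: tuple[int, ...]) -> float:
        """Pseudocounted frequency of a chi-bin prefix for one residue type."""
        if not bins:
            return 1.0
        per_aa = self.counts.get(aa, {})
        total = sum(per_aa.values())
        hits = sum(c for t, c in per_aa.items() if t[:len(bins)] == bins)
        n_cells = 3 ** len(bins)
        return (hits + self.pseudocount) / (total + self.pseudocount * n_cells)

    def modal(self, aa: str, depth: int) -> Optional[tuple[int, ...]]:
        per_aa = self.counts.get(aa)
        if not per_aa:
            return None
        agg: dict[tuple[int, ...], float] = {}
        for t, c in per_aa.items():
            agg[t[:depth]] = agg.get(t[:depth], 0.0) + c
        return max(agg, key=lambda t: (agg[t], t))


def _normalise(counts: np.ndarray) -> np.ndarray:
    return counts / counts.sum()


@dataclasses.dataclass
class PreferenceTables:
    """Log-odds statistics for dihedral and accessibility preferences."""

    bin_width: float
    pseudocount: float
    n_structures: int
    dihedral_bg: np.ndarray                      # (nb, nb) probabilities
    dihedral_aa: dict[str, np.ndarray]
    dihedral_ss: dict[str, np.ndarray]
    dihedral_aa_ss: dict[tuple[str, str], np.ndarray]
    acc_bg: np.ndarray                           # (3,)
    acc_aa: dict[str, np.ndarray]
    acc_ss: dict[str, np.ndarray]
    acc_aa_ss: dict[tuple[str, str], np.ndarray]
    ss_propensity: dict[str, np.ndarray]         # P(ss | aa), order SS_CLASSES
    rotamers: RotamerTable

    @property
    def n_bins(self) -> int:
        return self.dihedral_bg.shape[0]

    # -- log-odds lookups ---------------------------------------------------

    def dihedral_logodds(self, context: str | tuple[str, str],
                         phi: float, psi: float) -> float:
        i, j = dihedral_bin(phi, psi, self.bin_width)
        table = self._dihedral_table(context)
        return math.log(table[i, j] / self.dihedral_bg[i, j])

    def _dihedral_table(self, context) -> np.ndarray:
        if isinstance(context, tuple):
            return self.dihedral_aa_ss[context]
        if context in SS_CLASSES:
            return self.dihedral_ss[context]
        return self.dihedral_aa[context]

    def _acc_table(self, context) -> np.ndarray:
        if isinstance(context, tuple):
            return self.acc_aa_ss[context]
        if context in SS_CLASSES:
            return self.acc_ss[context]
        return self.acc_aa[context]

    def acc_logodds(self, context, acc_class: int) -> float:
        table = self._acc_table(context)
        return math.log(table[acc_class] / self.acc_bg[acc_class])

    def acc_modal_class(self, context) -> int:
        return int(np.argmax(self._acc_table(context)))

    def favored_dihedral_mask(self, mass: float = 0.98) -> np.ndarray:
        """Boolean (nb, nb) mask of bins holding the top ``mass`` of the
        context-free Ramachandran distribution."""
        flat = self.dihedral_bg.ravel()
        order = np.argsort(flat)[::-1]
        cum = np.cumsum(flat[order])
        k = int(np.searchsorted(cum, mass)) + 1
        mask = np.zeros(flat.size, dtype=bool)
        mask[order[:k]] = True
        return mask.reshape(self.dihedral_bg.shape)

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive serialization: JSON header + binary arrays (npz)."""
        arrays: dict[str, np.ndarray] = {
            "dihedral_bg": self.dihedral_bg, "acc_bg": self.acc_bg}
        for aa in AA_ORDER:
            arrays[f"daa_{aa}"] = self.dihedral_aa[aa]
            arrays[f"aaa_{aa}"] = self.acc_aa[aa]
            arrays[f"ssp_{aa}"] = self.ss_propensity[aa]
            for ss in SS_CLASSES:
                arrays[f"dxs_{aa}_{ss}"] = self.dihedral_aa_ss[(aa, ss)]
                arrays[f"axs_{aa}_{ss}"] = self.acc_aa_ss[(aa, ss)]
        for ss in SS_CLASSES:
            arrays[f"dss_{ss}"] = self.dihedral_ss[ss]
            arrays[f"ass_{ss}"] = self.acc_ss[ss]
        header = {
            "format": _FORMAT,
            "bin_width": self.bin_width,
            "pseudocount": self.pseudocount,
            "n_structures": self.n_structures,
            "rotamer_pseudocount": self.rotamers.pseudocount,
            "rotamer_counts": {
                aa: [[list(t), c] for t, c in sorted(per.items())]
                for aa, per in self.rotamers.counts.items()},
        }
        arrays["__header__"] = np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8)
        np.savez_compressed(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "PreferenceTables":
        try:
            with np.load(str(path)) as data:
                header = json.loads(bytes(data["__header__"]).decode())
                if header.get("format") != _FORMAT:
                    raise TableError(f"{path}: unknown table format")
                rot = RotamerTable(
                    counts={aa: {tuple(t): c for t, c in per}
                            for aa, per in header["rotamer_counts"].items()},
                    pseudocount=header["rotamer_pseudocount"])
                return cls(
                    bin_width=header["bin_width"],
                    pseudocount=header["pseudocount"],
                    n_structures=header["n_structures"],
                    dihedral_bg=data["dihedral_bg"],
                    dihedral_aa={aa: data[f"daa_{aa}"] for aa in AA_ORDER},
                    dihedral_ss={ss: data[f"dss_{ss}"] for ss in SS_CLASSES},
                    dihedral_aa_ss={(aa, ss): data[f"dxs_{aa}_{ss}"]
                                    for aa in AA_ORDER for ss in SS_CLASSES},
                    acc_bg=data["acc_bg"],
                    acc_aa={aa: data[f"aaa_{aa}"] for aa in AA_ORDER},
                    acc_ss={ss: data[f"ass_{ss}"] for ss in SS_CLASSES},
                    acc_aa_ss={(aa, ss): data[f"axs_{aa}_{ss}"]
                               for aa in AA_ORDER for ss in SS_CLASSES},
                    ss_propensity={aa: data[f"ssp_{aa}"] for aa in AA_ORDER},
                    rotamers=rot,
                )
        except TableError:
            raise
        except Exception as exc:
            raise TableError(f"cannot load preference tables from {path}: {exc}") from exc


def build_preference_tables(
    reference_set: Iterable[Structure],
    bin_width: float = 20.0,
    pseudocount: float = 1.0,
) -> PreferenceTables:
    """Accumulate preference statistics over a reference structure set.

    Each structure contributes its defined (phi, psi) pairs, accessibility
    classes, secondary-structure string and chi-bin combinations; the pass
    is order-invariant.
    """
    structures = list(reference_set)
    if not structures:
        raise TableError("empty reference set")
    nb = int(round(360.0 / bin_width))
    if nb * bin_width != 360.0:
        raise TableError(f"bin width {bin_width} does not divide 360")

    d_bg = np.zeros((nb, nb))
    d_aa = {aa: np.zeros((nb, nb)) for aa in AA_ORDER}
    d_ss = {ss: np.zeros((nb, nb)) for ss in SS_CLASSES}
    d_aa_ss = {(aa, ss): np.zeros((nb, nb)) for aa in AA_ORDER for ss in SS_CLASSES}
    a_bg = np.zeros(N_ACC)
    a_aa = {aa: np.zeros(N_ACC) for aa in AA_ORDER}
    a_ss = {ss: np.zeros(N_ACC) for ss in SS_CLASSES}
    a_aa_ss = {(aa, ss): np.zeros(N_ACC) for aa in AA_ORDER for ss in SS_CLASSES}
    ss_counts = {aa: np.zeros(len(SS_CLASSES)) for aa in AA_ORDER}
    rot_counts: dict[str, dict[tuple[int, ...], float]] = {}

    for st in structures:
        torsions = backbone_dihedrals(st)
        ss_string = assign_secondary_structure(st)
        acc = accessibility_profile(st)
        for i, res in enumerate(st.residues):
            aa, ss = res.aa, ss_string[i]
            tor = torsions[i]
            if tor.phi is not None and tor.psi is not None:
                bi, bj = dihedral_bin(tor.phi, tor.psi, bin_width)
                d_bg[bi, bj] += 1
                d_aa[aa][bi, bj] += 1
                d_ss[ss][bi, bj] += 1
                d_aa_ss[(aa, ss)][bi, bj] += 1
            c = int(acc.classes[i])
            a_bg[c] += 1
            a_aa[aa][c] += 1
            a_ss[ss][c] += 1
            a_aa_ss[(aa, ss)][c] += 1
            ss_counts[aa][SS_CLASSES.index(ss)] += 1
            chis = side_chain_chis(res)
            if chis:
                bins = tuple(chi_bin(x) for x in chis)
                per = rot_counts.setdefault(aa, {})
                per[bins] = per.get(bins, 0.0) + 1.0

    def bg_prob(counts: np.ndarray) -> np.ndarray:
        return _normalise(counts + pseudocount)

    # Conditional tables use a Dirichlet prior centred on the background
    # (pseudocount mass spread proportionally to the context-free
    # distribution, total mass pseudocount * n_cells).  With little
    # context data the log-odds shrink towards 0 instead of towards the
    # uniform distribution, which keeps the sign of the preference signal
    # meaningful for small reference sets.
    def cond_prob(counts: np.ndarray, bg: np.ndarray) -> np.ndarray:
        prior_mass = pseudocount * counts.size
        return (counts + prior_mass * bg) / (counts.sum() + prior_mass)

    dihedral_bg = bg_prob(d_bg)
    acc_bg = bg_prob(a_bg)
    return PreferenceTables(
        bin_width=bin_width,
        pseudocount=pseudocount,
        n_structures=len(structures),
        dihedral_bg=dihedral_bg,
        dihedral_aa={aa: cond_prob(t, dihedral_bg) for aa, t in d_aa.items()},
        dihedral_ss={ss: cond_prob(t, dihedral_bg) for ss, t in d_ss.items()},
        dihedral_aa_ss={k: cond_prob(t, dihedral_bg) for k, t in d_aa_ss.items()},
        acc_bg=acc_bg,
        acc_aa={aa: cond_prob(t, acc_bg) for aa, t in a_aa.items()},
        acc_ss={ss: cond_prob(t, acc_bg) for ss, t in a_ss.items()},
        acc_aa_ss={k: cond_prob(t, acc_bg) for k, t in a_aa_ss.items()},
        ss_propensity={aa: bg_prob(t) for aa, t in ss_counts.items()},
        rotamers=RotamerTable(counts=rot_counts),
    )
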