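"""C-terminal and target residue definition and primary-pair selection.

For every polypeptide chain the last resolved standard amino acid is the
"C-terminal" residue (backbone atoms C, CA, N participate).  Targets are
every lysine (side-chain Nε, PDB name NZ) plus the first resolved
standard residue (its α-amine, the backbone N of that residue, written
``aN`` here).  One *primary distance* is chosen per Ct/target pair by a
fixed fallback order — priority, not minimality:

lysine            C–Nε > CA–Nε > N–Nε > C–CA > CA–CA > N–CA > C–N > CA–N > N–N
N-terminus        C–αN > CA–αN > N–αN > C–CA > CA–CA > N–CA
N-terminal lysine as N-terminus, but at each of the first three ranks αN
                  or Nε is taken, whichever available and shorter
                  (exact tie: αN).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

from .structure_io import ChainInstance, Residue

#: atom label for the α-amine: the backbone N of a chain's first residue
ALPHA_N = "aN"

SOURCE_ATOMS = ("C", "CA", "N")


class TargetKind(str, enum.Enum):
    LYSINE = "lysine"
    N_TERMINUS = "n_terminus"
    N_TERMINAL_LYSINE = "n_terminal_lysine"


#: target atoms participating per kind, in report order
TARGET_ATOMS = {
    TargetKind.LYSINE: ("NZ", "CA", "N"),
    TargetKind.N_TERMINUS: (ALPHA_N, "CA"),
    TargetKind.N_TERMINAL_LYSINE: (ALPHA_N, "NZ", "CA"),
}

#: literal priority lists; for N_TERMINAL_LYSINE "aN|NZ" marks the
#: choose-shorter rule at that rank
PRIORITY = {
    TargetKind.LYSINE: [
        ("C", "NZ"), ("CA", "NZ"), ("N", "NZ"),
        ("C", "CA"), ("CA", "CA"), ("N", "CA"),
        ("C", "N"), ("CA", "N"), ("N", "N"),
    ],
    TargetKind.N_TERMINUS: [
        ("C", ALPHA_N), ("CA", ALPHA_N), ("N", ALPHA_N),
        ("C", "CA"), ("CA", "CA"), ("N", "CA"),
    ],
    TargetKind.N_TERMINAL_LYSINE: [
        ("C", "aN|NZ"), ("CA", "aN|NZ"), ("N", "aN|NZ"),
        ("C", "CA"), ("CA", "CA"), ("N", "CA"),
    ],
}


@dataclass
class TerminalResidue:
    chain: ChainInstance
    residue: Residue
    residue_index: int
    available_atoms: dict[str, np.ndarray]  # subset of {C, CA, N}


@dataclass
class TargetSite:
    chain: ChainInstance
    residue: Residue
    residue_index: int
    kind: TargetKind
    available_atoms: dict[str, np.ndarray]


@dataclass
class PrimaryDistance:
    source_atom: str
    target_atom: str
    distance: float
    priority_rank: int  # 1 = most preferred pair that was available


def euclidean(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite coordinates")
    return float(np.linalg.norm(a - b))


def find_c_terminal(chain: ChainInstance) -> TerminalResidue | None:
    """Last resolved standard residue with its available backbone atoms.

    Returns ``None`` when the chain has no standard residue or its last
    standard residue resolved none of C/CA/N (no distance can be formed).
    """
    for idx in range(len(chain.residues) - 1, -1, -1):
        res = chain.residues[idx]
        if not res.is_standard:
            continue
        avail = {n: res.atoms[n].coords for n in SOURCE_ATOMS if n in res.atoms}
        if not avail:
            return None
        return TerminalResidue(chain=chain, residue=res, residue_index=idx,
                               available_atoms=avail)
    return None


def _site_atoms(res: Residue, kind: TargetKind) -> dict[str, np.ndarray]:
    avail: dict[str, np.ndarray] = {}
    for atom in TARGET_ATOMS[kind]:
        phys = "N" if atom == ALPHA_N else atom
        if phys in res.atoms:
            avail[atom] = res.atoms[phys].coords
    return avail


def find_targets(chain: ChainInstance) -> list[TargetSite]:
    """All target sites of a chain, in polymer order.

    Exactly one N-terminal site (the first resolved standard residue;
    kind ``n_terminal_lysine`` when it is a lysine) plus one ``lysine``
    site per non-first LYS.  The first residue's backbone N is exposed as
    ``aN`` — it is physically the α-amine.
    """
    first_idx = next(
        (i for i, r in enumerate(chain.residues) if r.is_standard), None)
    if first_idx is None:
        return []
    sites: list[TargetSite] = []
    for idx, res in enumerate(chain.residues):
        if not res.is_standard:
            continue
        if idx == first_idx:
            kind = (TargetKind.N_TERMINAL_LYSINE if res.name == "LYS"
                    else TargetKind.N_TERMINUS)
        elif res.name == "LYS":
            kind = TargetKind.LYSINE
        else:
            continue
        atoms = _site_atoms(res, kind)
        if atoms:
            sites.append(TargetSite(chain=chain, residue=res,
                                    residue_index=idx, kind=kind,
                                    available_atoms=atoms))
    return sites


def all_pair_distances(ct: TerminalResidue,
                       target: TargetSite) -> list[tuple[str, str, float]]:
    """Every available (source, target) atom distance for the pair."""
    out = []
    for s in SOURCE_ATOMS:
        if s not in ct.available_atoms:
            continue
        for t in TARGET_ATOMS[target.kind]:
            if t not in target.available_atoms:
                continue
            out.append((s, t, euclidean(ct.available_atoms[s],
                                        target.available_atoms[t])))
    return out


def select_primary_pair(ct: TerminalResidue,
                        target: TargetSite) -> PrimaryDistance | None:
    """First available pair in the kind-appropriate priority list.

    For an N-terminal lysine, ranks 1–3 pair the source atom with
    whichever of αN/Nε is available; if both are, the shorter distance
    wins and an exact tie goes to αN.
    """
    src = ct.available_atoms
    tgt = target.available_atoms
    for rank, (s, t) in enumerate(PRIORITY[target.kind], start=1):
        if s not in src:
            continue
        if t == "aN|NZ":
            candidates = [a for a in (ALPHA_N, "NZ") if a in tgt]
            if not candidates:
                continue
            best = min(candidates,
                       key=lambda a: (euclidean(src[s], tgt[a]), a != ALPHA_N))
            return PrimaryDistance(s, best, euclidean(src[s], tgt[best]), rank)
        if t in tgt:
            return PrimaryDistance(s, t, euclidean(src[s], tgt[t]), rank)
    return None


def round_report(distance: float, ndigits: int = 1) -> float:
    """Report rounding: round-half-away-from-zero at *ndigits* decimals."""
    factor = 10 ** ndigits
    return math.floor(abs(distance) * factor + 0.5) / factor * (1 if distance >= 0 else -1)
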