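"""Single-complex candidate assessment for covalent-probe design.

Given one structure and a binder/target chain pair, ranks the target
protein's reactive amines (every lysine Nε plus the α-amine of the first
resolved residue) by primary distance to the binder's C-terminus, and
measures the binder's own nearest amine — the self-reaction ("own-goal")
risk, where the activated C-terminus cyclises onto the binder instead of
ligating the target.  Steric accessibility of the site and linker
occlusion of the interface are not computed; they remain a manual
inspection step and the report says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ScanConfig
from .structure_io import Assembly, ChainInstance, RawStructure, build_assemblies
from .terminus_target import (
    TargetKind,
    TerminalResidue,
    find_c_terminal,
    find_targets,
    round_report,
    select_primary_pair,
)

MANUAL_CHECK_NOTE = (
    "manual inspection required: steric accessibility of the nearest amine "
    "and linker occlusion of the binder/target interface are not computed")


@dataclass
class RankedAmine:
    residue_label: str     # e.g. "K92"
    kind: TargetKind
    source_atom: str
    target_atom: str       # "NZ" or "aN" (or backbone fallback)
    distance: float        # Å, full precision

    @property
    def distance_1dp(self) -> float:
        return round_report(self.distance, 1)


@dataclass
class ScreenReport:
    structure_id: str
    assembly_id: str
    binder_chain: str
    ct_label: str
    ranked_targets: list[RankedAmine]
    self_nearest: RankedAmine | None
    target_cutoff: float
    self_cutoff: float
    notes: str = MANUAL_CHECK_NOTE

    @property
    def nearest_target(self) -> RankedAmine | None:
        return self.ranked_targets[0] if self.ranked_targets else None

    def target_within(self, cutoff: float | None = None) -> bool:
        cutoff = self.target_cutoff if cutoff is None else cutoff
        return (self.nearest_target is not None
                and self.nearest_target.distance < cutoff)

    def self_clash(self, cutoff: float | None = None) -> bool:
        cutoff = self.self_cutoff if cutoff is None else cutoff
        return (self.self_nearest is not None
                and self.self_nearest.distance < cutoff)

    def to_dict(self) -> dict:
        return {
            "structure_id": self.structure_id,
            "assembly_id": self.assembly_id,
            "binder_chain": self.binder_chain,
            "ct_residue": self.ct_label,
            "ranked_target_amines": [
                {"residue": a.residue_label, "kind": a.kind.value,
                 "atom_pair": f"{a.source_atom}-{a.target_atom}",
                 "distance_A": a.distance_1dp}
                for a in self.ranked_targets],
            "self_nearest": None if self.self_nearest is None else {
                "residue": self.self_nearest.residue_label,
                "atom_pair": (f"{self.self_nearest.source_atom}-"
                              f"{self.self_nearest.target_atom}"),
                "distance_A": self.self_nearest.distance_1dp},
            "target_within_cutoff": self.target_within(),
            "self_clash": self.self_clash(),
            "target_cutoff_A": self.target_cutoff,
            "self_cutoff_A": self.self_cutoff,
            "notes": self.notes,
        }


def _ranked_amines(ct: TerminalResidue, chain: ChainInstance,
                   exclude_residue_index: int | None = None) -> list[RankedAmine]:
    out = []
    for site in find_targets(chain):
        if site.residue_index == exclude_residue_index:
            continue
        primary = select_primary_pair(ct, site)
        if primary is None:
            continue
        out.append(RankedAmine(
            residue_label=site.residue.label, kind=site.kind,
            source_atom=primary.source_atom, target_atom=primary.target_atom,
            distance=primary.distance))
    out.sort(key=lambda a: (a.distance, a.residue_label))
    return out


def _pick_assembly(structure: RawStructure, config: ScanConfig,
                   chain_ids: set[str], assembly_id: str | None) -> Assembly:
    assemblies = build_assemblies(structure, config)
    if assembly_id is not None:
        for asm in assemblies:
            if asm.assembly_id == assembly_id:
                return asm
        raise ValueError(f"no assembly {assembly_id!r} in "
                         f"{structure.structure_id}")
    for asm in assemblies:
        present = {c.auth_asym_id for c in asm.chains}
        if chain_ids <= present:
            return asm
    raise ValueError(
        f"{structure.structure_id}: no assembly contains chains "
        f"{sorted(chain_ids)}")


def screen_complex(structure: RawStructure, binder_chain_id: str,
                   target_chain_id: str, config: ScanConfig | None = None,
                   target_cutoff: float = 10.0, self_cutoff: float = 10.0,
                   assembly_id: str | None = None) -> ScreenReport:
    """Assess one binder/target complex against the design criteria.

    The target chain's amines are ranked by primary distance to the
    binder's C-terminus; ``self_nearest`` is the nearest amine on the
    binder chain itself (excluding the C-terminal residue).  Flags use
    strict comparison against the cutoffs (default 10 Å).
    """
    config = config or ScanConfig()
    asm = _pick_assembly(structure, config,
                         {binder_chain_id, target_chain_id}, assembly_id)

    def first_chain(auth_id: str) -> ChainInstance:
        for ch in asm.chains:
            if ch.auth_asym_id == auth_id:
                return ch
        raise ValueError(f"chain {auth_id!r} not in assembly {asm.assembly_id}")

    binder = first_chain(binder_chain_id)
    target = first_chain(target_chain_id)
    ct = find_c_terminal(binder)
    if ct is None:
        raise ValueError(
            f"binder chain {binder_chain_id!r} has no resolved C-terminus")

    ranked = _ranked_amines(ct, target)
    self_ranked = _ranked_amines(ct, binder,
                                 exclude_residue_index=ct.residue_index)
    return ScreenReport(
        structure_id=structure.structure_id,
        assembly_id=asm.assembly_id,
        binder_chain=binder_chain_id,
        ct_label=ct.residue.label,
        ranked_targets=ranked,
        self_nearest=self_ranked[0] if self_ranked else None,
        target_cutoff=target_cutoff,
        self_cutoff=self_cutoff,
    )


def self_reaction_distance(structure: RawStructure, binder_chain_id: str,
                           config: ScanConfig | None = None,
                           assembly_id: str | None = None,
                           ) -> tuple[str, float] | None:
    """Nearest amine on the binder chain to its own C-terminus.

    Returns ``(residue label, distance Å)`` or ``None`` when the chain
    has no amine besides the C-terminal residue itself.
    """
    config = config or ScanConfig()
    asm = _pick_assembly(structure, config, {binder_chain_id}, assembly_id)
    for ch in asm.chains:
        if ch.auth_asym_id == binder_chain_id:
            ct = find_c_terminal(ch)
            if ct is None:
                return None
            ranked = _ranked_amines(ct, ch,
                                    exclude_residue_index=ct.residue_index)
            if not ranked:
                return None
            return (ranked[0].residue_label, ranked[0].distance)
    raise ValueError(f"chain {binder_chain_id!r} not found")
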