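"""Full per-structure scan, record classification, covalent filter, minima.

Every ordered (Ct-chain, target-chain) combination inside one assembly and
one model yields one record per target site, categorised as
intramolecular (same chain instance), intermolecular homomeric (identical
polymer sequences) or intermolecular heteromeric (different sequences).
Per-structure minima are taken per category across all assemblies and
models; a single overall shortest distance follows from those.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .config import ScanConfig
from .structure_io import Assembly, ChainInstance, RawStructure, build_assemblies
from .terminus_target import (
    PrimaryDistance,
    TargetKind,
    TargetSite,
    all_pair_distances,
    find_c_terminal,
    find_targets,
    select_primary_pair,
)

log = logging.getLogger("neissdist")


class Category(str, enum.Enum):
    INTRAMOLECULAR = "intramolecular"
    HOMOMERIC = "intermolecular_homomeric"
    HETEROMERIC = "intermolecular_heteromeric"


@dataclass
class DistanceRecord:
    structure_id: str
    assembly_id: str
    model_number: int
    source_chain: tuple[str, str, str]   # (label_asym, auth_asym, operator)
    ct_label: str                        # e.g. "E219"
    target_chain: tuple[str, str, str]
    target_label: str                    # e.g. "K92"
    target_kind: TargetKind
    primary: PrimaryDistance
    all_distances: list[tuple[str, str, float]]
    category: Category
    covalent: bool
    same_residue: bool

    #: deterministic ordering / tie-break key
    @property
    def order_key(self):
        return (self.assembly_id, self.model_number, self.source_chain,
                self.target_chain, self.target_label)


@dataclass
class StructureSummary:
    structure_id: str
    minima: dict[Category, DistanceRecord] = field(default_factory=dict)
    record_count: dict[Category, int] = field(default_factory=dict)

    @property
    def overall_shortest(self) -> DistanceRecord | None:
        if not self.minima:
            return None
        return min(self.minima.values(),
                   key=lambda r: (r.primary.distance, r.order_key))


def classify_pair(source: ChainInstance, target: ChainInstance) -> Category:
    """Intramolecular for the same chain instance, otherwise homomeric iff
    the two polymer sequences are exactly equal, else heteromeric."""
    if (source.assembly_id, source.model_number) != (
            target.assembly_id, target.model_number):
        raise ValueError("chains must come from the same assembly and model")
    if source.instance_key == target.instance_key:
        return Category.INTRAMOLECULAR
    if source.sequence == target.sequence:
        return Category.HOMOMERIC
    return Category.HETEROMERIC


def scan_assembly(assembly: Assembly,
                  config: ScanConfig) -> list[DistanceRecord]:
    records: list[DistanceRecord] = []
    by_model: dict[int, list[ChainInstance]] = {}
    for ch in assembly.chains:
        by_model.setdefault(ch.model_number, []).append(ch)
    for model_number in sorted(by_model):
        chains = by_model[model_number]
        for source in chains:
            ct = find_c_terminal(source)
            if ct is None:
                continue
            for target_chain in chains:
                category = classify_pair(source, target_chain)
                for site in find_targets(target_chain):
                    same_residue = (
                        source.instance_key == target_chain.instance_key
                        and site.residue_index == ct.residue_index)
                    primary = select_primary_pair(ct, site)
                    if primary is None:
                        continue
                    records.append(DistanceRecord(
                        structure_id=assembly.structure_id,
                        assembly_id=assembly.assembly_id,
                        model_number=model_number,
                        source_chain=(source.label_asym_id,
                                      source.auth_asym_id,
                                      source.operator_id),
                        ct_label=ct.residue.label,
                        target_chain=(target_chain.label_asym_id,
                                      target_chain.auth_asym_id,
                                      target_chain.operator_id),
                        target_label=site.residue.label,
                        target_kind=site.kind,
                        primary=primary,
                        all_distances=all_pair_distances(ct, site),
                        category=category,
                        covalent=primary.distance < config.covalent_cutoff,
                        same_residue=same_residue,
                    ))
    return records


def scan_structure(structure: RawStructure,
                   config: ScanConfig | None = None) -> list[DistanceRecord]:
    """All distance records of a structure, deterministically ordered
    (assembly, model, source chain, target chain, target residue)."""
    config = config or ScanConfig()
    records: list[DistanceRecord] = []
    for assembly in build_assemblies(structure, config):
        records.extend(scan_assembly(assembly, config))
    return records


def filter_covalent(records: list[DistanceRecord],
                    config: ScanConfig | None = None) -> list[DistanceRecord]:
    """Drop records below the covalent cutoff (existing linkages such as
    ubiquitination, not candidate reaction geometry).  Strict ``<``: a
    record at exactly the cutoff survives."""
    config = config or ScanConfig()
    kept = [r for r in records if r.primary.distance >= config.covalent_cutoff]
    removed = len(records) - len(kept)
    if removed:
        log.info("covalent filter removed %d record(s) < %.2f Å",
                 removed, config.covalent_cutoff)
    return kept


def aggregate_minima(records: list[DistanceRecord],
                     structure_id: str | None = None,
                     include_same_residue: bool = True) -> StructureSummary:
    """Per-category minimum across assemblies and models, plus counts.

    Ties are broken by the deterministic record ordering so repeated
    scans and shuffled inputs aggregate identically.
    """
    ids = {r.structure_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records from multiple structures: {sorted(ids)}")
    if structure_id is None:
        structure_id = next(iter(ids)) if ids else ""
    summary = StructureSummary(structure_id=structure_id)
    for rec in records:
        if rec.same_residue and not include_same_residue:
            continue
        summary.record_count[rec.category] = (
            summary.record_count.get(rec.category, 0) + 1)
        best = summary.minima.get(rec.category)
        if best is None or (rec.primary.distance, rec.order_key) < (
                best.primary.distance, best.order_key):
            summary.minima[rec.category] = rec
    return summary
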