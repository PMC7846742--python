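"""Structure parsing, pre-filters and biological-assembly generation.

mmCIF (preferred) and legacy PDB files are parsed with gemmi into a
light-weight :class:`RawStructure`.  Biological assemblies are produced by
expanding the deposited ``_pdbx_struct_assembly_gen`` operator expressions
(including parenthesized cartesian products such as ``(1)(2)`` and ranges
``1-60``) against ``_pdbx_struct_oper_list`` matrices.  Legacy PDB input
falls back to the asymmetric unit; REMARK 350 is deliberately not expanded
because mmCIF is the authoritative assembly source here.

Waters, other non-polymer components and hydrogens never enter a chain.
Alternate conformations are reduced to one atom per name: highest
occupancy wins, ties go to the lexicographically first altloc id.
"""

from __future__ import annotations

import gzip
import logging
import os
import re
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .config import ScanConfig

log = logging.getLogger("neissdist")

#: canonical 20 amino-acid three-letter codes
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ParseError(ValueError):
    """The file could not be interpreted as a structure."""


class EmptyStructureError(ValueError):
    """The file contains no polypeptide chains; structure is skipped."""


class AssemblyError(ValueError):
    """Assembly definitions are inconsistent; structure is skipped."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Atom:
    name: str
    coords: np.ndarray  # shape (3,), Å
    occupancy: float = 1.0
    altloc: str | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    name: str
    auth_number: str            # author residue number + insertion code, e.g. "219" or "52A"
    label_number: int | None    # label_seq_id (polymer position) when known
    is_standard: bool
    atoms: dict[str, Atom]

    @property
    def label(self) -> str:
        """Author-style residue label, e.g. ``K92`` or ``E219``."""
        return ONE_LETTER.get(self.name, "X") + self.auth_number


@dataclass
class ChainData:
    """An untransformed polymer chain of the deposited coordinates."""

    label_asym_id: str
    auth_asym_id: str
    entity_id: str
    residues: list[Residue]


@dataclass
class Model:
    number: int
    chains: list[ChainData]


@dataclass
class AssemblyDefinition:
    assembly_id: str
    #: (oper_expression, affected label_asym ids) in deposition order
    generators: list[tuple[str, list[str]]]


@dataclass
class RawStructure:
    structure_id: str
    models: list[Model]
    entities: dict[str, str]                   # entity id -> one-letter sequence
    assembly_definitions: list[AssemblyDefinition]
    operators: dict[str, np.ndarray]           # operator id -> 4x4 affine
    source_format: str                         # "mmcif" | "pdb"
    file_bytes: int


@dataclass
class ChainInstance:
    """One chain copy inside one biological assembly of one model."""

    structure_id: str
    assembly_id: str
    model_number: int
    label_asym_id: str
    auth_asym_id: str
    operator_id: str        # "*"-joined product of applied operator ids
    entity_id: str
    sequence: str
    residues: list[Residue]

    @property
    def instance_key(self) -> tuple[str, str, str]:
        return (self.assembly_id, self.label_asym_id, self.operator_id)


@dataclass
class Assembly:
    structure_id: str
    assembly_id: str
    chains: list[ChainInstance]


# ---------------------------------------------------------------------------
# parsing


def check_size_gate(source: str | os.PathLike, config: ScanConfig) -> bool:
    """True iff the file is strictly below the configured size limit.

    The limit is applied to the input file as a proxy for assembly size;
    oversized files (e.g. whole virus capsids) are skipped, never raised on.
    """
    if config.max_file_bytes is None:
        return True
    size = os.path.getsize(source)
    ok = size < config.max_file_bytes
    if not ok:
        log.info("size gate: %s is %d bytes (limit %d), skipping",
                 source, size, config.max_file_bytes)
    return ok


def _sniff_format(path: str) -> str:
    name = str(path).lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".cif", ".mmcif")):
        return "mmcif"
    if name.endswith((".pdb", ".ent")):
        return "pdb"
    # sniff content
    opener = gzip.open if str(path).lower().endswith(".gz") else open
    with opener(path, "rt", errors="replace") as fh:
        head = fh.read(4096)
    if re.search(r"^data_", head, re.M):
        return "mmcif"
    if re.search(r"^(ATOM|HETATM|HEADER|REMARK)", head, re.M):
        return "pdb"
    raise ParseError(f"{path}: neither mmCIF nor PDB content recognised")


def _select_altlocs(raw_atoms: list[Atom]) -> dict[str, Atom]:
    """One atom per name: highest occupancy, ties to first altloc id."""
    chosen: dict[str, Atom] = {}
    for atom in raw_atoms:
        prev = chosen.get(atom.name)
        if prev is None:
            chosen[atom.name] = atom
            continue
        if atom.occupancy > prev.occupancy or (
            atom.occupancy == prev.occupancy
            and (atom.altloc or "") < (prev.altloc or "")
        ):
            chosen[atom.name] = atom
    return chosen


def _one_letter(seq3: list[str]) -> str:
    out = []
    for mon in seq3:
        mon = mon.split(",")[0]  # microheterogeneity: take first
        out.append(ONE_LETTER.get(mon, "X"))
    return "".join(out)


def _convert_chains(model: gemmi.Model, st: gemmi.Structure,
                    config: ScanConfig,
                    use_auth_label: bool = False) -> list[ChainData]:
    sub_to_entity: dict[str, gemmi.Entity] = {}
    for ent in st.entities:
        for sub in ent.subchains:
            sub_to_entity[sub] = ent
    chains: list[ChainData] = []
    for chain in model:
        for span in chain.subchains():
            sub_id = span.subchain_id()
            ent = sub_to_entity.get(sub_id)
            if ent is not None and ent.entity_type != gemmi.EntityType.Polymer:
                continue
            if ent is not None and ent.polymer_type not in (
                gemmi.PolymerType.PeptideL, gemmi.PolymerType.PeptideD,
                gemmi.PolymerType.Unknown,
            ):
                continue
            residues: list[Residue] = []
            seen_ids: set[tuple[int, str]] = set()
            for res in span:
                if res.is_water():
                    continue
                rid = (res.seqid.num, res.seqid.icode.strip())
                if rid in seen_ids:
                    continue  # residue-level altloc heterogeneity: first wins
                name = res.name
                if config.map_mse and name == "MSE":
                    name = "MET"
                atoms = []
                for a in res:
                    if a.element.is_hydrogen:
                        continue
                    atoms.append(Atom(
                        name=a.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        altloc=a.altloc if a.altloc != "\0" else None,
                    ))
                if not atoms:
                    continue
                seen_ids.add(rid)
                residues.append(Residue(
                    name=name,
                    auth_number=f"{res.seqid.num}{res.seqid.icode.strip()}",
                    label_number=res.label_seq if res.label_seq else None,
                    is_standard=name in STANDARD_RESIDUES,
                    atoms=_select_altlocs(atoms),
                ))
            if not residues:
                continue
            # skip subchains with no amino-acid content at all (ligands, NA)
            if not any(r.is_standard for r in residues) and ent is None:
                continue
            chains.append(ChainData(
                label_asym_id=chain.name if use_auth_label else (sub_id or chain.name),
                auth_asym_id=chain.name,
                entity_id=ent.name if ent is not None else chain.name,
                residues=residues,
            ))
    return chains


def _read_assembly_tables(block: gemmi.cif.Block):
    """Assembly generators and operator matrices straight from the CIF tables.

    gemmi's structure-level assembly object is not used: it drops
    assemblies with unrecognised ``details`` strings and does not expand
    operator products, so the raw categories are authoritative here.
    """
    defs: list[AssemblyDefinition] = []
    by_id: dict[str, AssemblyDefinition] = {}
    for row in block.find("_pdbx_struct_assembly_gen.",
                          ["assembly_id", "oper_expression", "asym_id_list"]):
        aid = gemmi.cif.as_string(row[0])
        expr = gemmi.cif.as_string(row[1])
        asyms = [s.strip() for s in gemmi.cif.as_string(row[2]).split(",") if s.strip()]
        if aid not in by_id:
            by_id[aid] = AssemblyDefinition(assembly_id=aid, generators=[])
            defs.append(by_id[aid])
        by_id[aid].generators.append((expr, asyms))

    tags = ["id"]
    for i in (1, 2, 3):
        tags += [f"matrix[{i}][1]", f"matrix[{i}][2]", f"matrix[{i}][3]", f"vector[{i}]"]
    opers: dict[str, np.ndarray] = {}
    for row in block.find("_pdbx_struct_oper_list.", tags):
        mat = np.eye(4)
        for i in range(3):
            for j in range(3):
                mat[i, j] = gemmi.cif.as_number(row[1 + 4 * i + j])
            mat[i, 3] = gemmi.cif.as_number(row[4 + 4 * i])
        opers[gemmi.cif.as_string(row[0])] = mat
    return defs, opers


def parse_structure(source: str | os.PathLike | bytes,
                    config: ScanConfig | None = None) -> RawStructure:
    """Parse an mmCIF or legacy PDB file into a :class:`RawStructure`.

    Models beyond ``config.max_models`` are dropped (file order is kept).
    Hydrogens, waters and non-polymer components never appear in chains.
    """
    config = config or ScanConfig()
    if isinstance(source, bytes):
        text = source.decode("utf-8", errors="replace")
        is_cif = bool(re.search(r"^data_", text, re.M))
        file_bytes = len(source)
        try:
            if is_cif:
                block = gemmi.cif.read_string(text).sole_block()
                st = gemmi.make_structure_from_block(block)
                fmt = "mmcif"
            else:
                st = gemmi.read_pdb_string(text)
                block = None
                fmt = "pdb"
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"<bytes>: {exc}") from exc
        structure_id = (st.name or "structure").lower()
    else:
        path = str(source)
        fmt = _sniff_format(path)
        file_bytes = os.path.getsize(path)
        try:
            if fmt == "mmcif":
                doc = gemmi.cif.read(path)
                block = doc.sole_block()
                st = gemmi.make_structure_from_block(block)
            else:
                st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
                block = None
        except (RuntimeError, ValueError) as exc:
            raise ParseError(f"{path}: {exc}") from exc
        structure_id = (st.name or Path(path).stem).lower()

    if len(st) == 0:
        raise EmptyStructureError(f"{structure_id}: no coordinate models")
    if not st.entities:
        st.setup_entities()

    entities = {}
    for ent in st.entities:
        if ent.entity_type == gemmi.EntityType.Polymer or not ent.entity_type.name:
            if ent.full_sequence:
                entities[ent.name] = _one_letter(list(ent.full_sequence))

    models: list[Model] = []
    for gmodel in st:
        if len(models) >= config.max_models:
            break
        chains = _convert_chains(gmodel, st, config,
                                 use_auth_label=(fmt == "pdb"))
        models.append(Model(number=gmodel.num, chains=chains))

    # derive sequences for entities without SEQRES/entity_poly from coordinates
    for model in models:
        for ch in model.chains:
            if ch.entity_id not in entities:
                entities[ch.entity_id] = "".join(
                    ONE_LETTER.get(r.name, "X") for r in ch.residues if r.is_standard
                )

    if fmt == "mmcif" and block is not None:
        defs, opers = _read_assembly_tables(block)
    else:
        defs, opers = [], {}
        log.info("%s: legacy PDB input, REMARK 350 assemblies are not "
                 "expanded; asymmetric unit will be used", structure_id)

    raw = RawStructure(
        structure_id=structure_id,
        models=models,
        entities=entities,
        assembly_definitions=defs,
        operators=opers,
        source_format=fmt,
        file_bytes=file_bytes,
    )
    if not any(any(r.is_standard for r in c.residues)
               for m in raw.models for c in m.chains):
        raise EmptyStructureError(f"{structure_id}: no polypeptide chains")
    return raw


# ---------------------------------------------------------------------------
# assembly expansion


def expand_oper_expression(expr: str) -> list[tuple[str, ...]]:
    """Expand a ``pdbx_struct_assembly_gen.oper_expression`` string.

    Supports comma lists (``"1,2,5"``), numeric ranges (``"1-60"``) and
    parenthesized cartesian products (``"(X0)(1-10)"``).  A product
    ``(A)(B)`` means operator B is applied first, then A, so the returned
    id tuples are ordered left-to-right as printed.
    """
    expr = expr.strip()

    def factor(ids: str) -> list[str]:
        out: list[str] = []
        for token in ids.split(","):
            token = token.strip()
            if not token:
                continue
            m = re.fullmatch(r"(\d+)-(\d+)", token)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                out.extend(str(i) for i in range(lo, hi + 1))
            else:
                out.append(token)
        return out

    if expr.startswith("("):
        groups = re.findall(r"\(([^()]*)\)", expr)
        rebuilt = "".join(f"({g})" for g in groups)
        if rebuilt != re.sub(r"\s+", "", expr):
            raise AssemblyError(f"cannot parse oper_expression {expr!r}")
        factors = [factor(g) for g in groups]
    else:
        factors = [factor(expr)]
    combos: list[tuple[str, ...]] = [()]
    for f in factors:
        combos = [c + (op,) for c in combos for op in f]
    return combos


def _transform_residues(residues: list[Residue], mat: np.ndarray) -> list[Residue]:
    rot, vec = mat[:3, :3], mat[:3, 3]
    out = []
    for r in residues:
        atoms = {
            n: Atom(name=a.name, coords=rot @ a.coords + vec,
                    occupancy=a.occupancy, altloc=a.altloc)
            for n, a in r.atoms.items()
        }
        out.append(Residue(name=r.name, auth_number=r.auth_number,
                           label_number=r.label_number,
                           is_standard=r.is_standard, atoms=atoms))
    return out


def build_assemblies(structure: RawStructure,
                     config: ScanConfig | None = None) -> list[Assembly]:
    """Generate biological assemblies by applying deposited operators.

    Returns one :class:`Assembly` per assembly definition, each holding
    transformed :class:`ChainInstance` objects for every model.  Without
    assembly definitions (legacy PDB, or ``assembly_mode="asymmetric_unit"``)
    a single pseudo-assembly ``"AU"`` with untransformed chains is returned.
    Only polypeptide chains (≥1 standard residue) are included.
    """
    config = config or ScanConfig()

    def instances_for(assembly_id: str, chain: ChainData, model_num: int,
                      op_id: str, mat: np.ndarray | None) -> ChainInstance:
        residues = (chain.residues if mat is None
                    else _transform_residues(chain.residues, mat))
        return ChainInstance(
            structure_id=structure.structure_id,
            assembly_id=assembly_id,
            model_number=model_num,
            label_asym_id=chain.label_asym_id,
            auth_asym_id=chain.auth_asym_id,
            operator_id=op_id,
            entity_id=chain.entity_id,
            sequence=structure.entities.get(chain.entity_id, ""),
            residues=residues,
        )

    def is_polypeptide(chain: ChainData) -> bool:
        return any(r.is_standard for r in chain.residues)

    if config.assembly_mode == "asymmetric_unit" or not structure.assembly_definitions:
        chains = [
            instances_for("AU", ch, m.number, "1", None)
            for m in structure.models for ch in m.chains if is_polypeptide(ch)
        ]
        return [Assembly(structure.structure_id, "AU", chains)]

    assemblies: list[Assembly] = []
    for adef in structure.assembly_definitions:
        chains: list[ChainInstance] = []
        for expr, asym_ids in adef.generators:
            for combo in expand_oper_expression(expr):
                mat = np.eye(4)
                for op_id in combo:
                    if op_id not in structure.operators:
                        raise AssemblyError(
                            f"{structure.structure_id}: assembly {adef.assembly_id} "
                            f"references undefined operator {op_id!r}")
                    mat = mat @ structure.operators[op_id]
                op_label = "*".join(combo)
                identity = np.allclose(mat, np.eye(4), atol=1e-12)
                for model in structure.models:
                    for ch in model.chains:
                        if ch.label_asym_id not in asym_ids or not is_polypeptide(ch):
                            continue
                        chains.append(instances_for(
                            adef.assembly_id, ch, model.number, op_label,
                            None if identity else mat))
        n_atoms = sum(len(r.atoms) for c in chains for r in c.residues)
        if n_atoms > config.assembly_max_atoms:
            log.warning("%s: assembly %s has %d atoms (cap %d), skipping",
                        structure.structure_id, adef.assembly_id, n_atoms,
                        config.assembly_max_atoms)
            continue
        assemblies.append(Assembly(structure.structure_id, adef.assembly_id, chains))
    return assemblies


def extract_polymer_chains(assembly: Assembly) -> list[ChainInstance]:
    """Chains with at least one resolved standard amino acid."""
    kept = []
    for ch in assembly.chains:
        if any(r.is_standard for r in ch.residues):
            kept.append(ch)
        else:
            log.info("%s: chain %s/%s has no standard residues, dropped",
                     ch.structure_id, ch.auth_asym_id, ch.operator_id)
    return kept


# ---------------------------------------------------------------------------
# fetching

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.cif"


def fetch_structure(pdb_id: str, cache_dir: str | os.PathLike = ".",
                    timeout: float = 30.0) -> Path:
    """Download an mmCIF by 4-character PDB accession into *cache_dir*.

    Returns the cached path without re-downloading when already present.
    """
    pdb_id = pdb_id.lower()
    if not re.fullmatch(r"[0-9][a-z0-9]{3}", pdb_id):
        raise ValueError(f"not a PDB accession: {pdb_id!r}")
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{pdb_id}.cif"
    if dest.exists():
        return dest
    url = RCSB_URL.format(pdb_id=pdb_id.upper())
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    dest.write_bytes(data)
    return dest
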