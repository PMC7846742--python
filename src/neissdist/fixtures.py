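"""Synthetic mmCIF structure generator with exactly known geometry.

Stands in for PDB entries so the whole pipeline is testable at desk
scale: two-chain complexes where the distance from the binder chain's
C-terminal carbonyl carbon to the target lysine's Nε is placed exactly,
a homodimer generated purely by an assembly operator, and multi-model
entries whose cross-model minimum is known by construction.  Residues
use an idealized template backbone (plausible local bond geometry, no
rotamer physics) — only inter-atomic distances are under test.

All output is deterministic for a fixed seed, valid mmCIF, and parses
back through :mod:`neissdist.structure_io` unchanged.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .structure_io import ONE_LETTER

THREE_LETTER = {v: k for k, v in ONE_LETTER.items()}

#: translation between consecutive residue origins, Å
RESIDUE_SPACING = 3.3

#: template backbone offsets from the residue origin, Å
BACKBONE = {
    "N": (0.0, 0.0, 0.0),
    "CA": (1.458, 0.0, 0.0),
    "C": (2.3, 1.1, 0.0),
    "O": (2.0, 2.25, 0.0),
}

#: lysine side chain, extended into -y
LYS_SIDE = {
    "CB": (1.458, -1.53, 0.0),
    "CG": (2.0, -2.6, 0.8),
    "CD": (1.5, -3.9, 1.3),
    "CE": (2.1, -5.1, 2.0),
    "NZ": (1.6, -6.3, 2.5),
}


class FixtureError(ValueError):
    """Requested geometry cannot be generated."""


class Layout(str, enum.Enum):
    HETERODIMER = "heterodimer"
    MONOMER = "monomer"
    HOMODIMER_BY_OPERATOR = "homodimer_by_operator"
    MULTIMODEL = "multimodel"


@dataclass
class FixtureSpec:
    layout: Layout = Layout.HETERODIMER
    #: exact distance (Å) from binder Ct C to the target lysine NZ
    ct_to_nz_distance: float = 3.5
    n_models: int = 1
    #: place a lysine on the binder whose NZ sits exactly this far (Å)
    #: from the binder's own Ct C (self-reaction fixture); None = no lysine
    include_binder_self_lysine_at: float | None = None
    seed: int = 0
    #: gaussian coordinate jitter amplitude (Å); exact-distance
    #: constraints are re-imposed after jittering
    jitter: float = 0.0
    #: override the data-block / entry id (default: per-layout name)
    structure_id: str | None = None

    def __post_init__(self) -> None:
        self.layout = Layout(self.layout)
        if self.ct_to_nz_distance <= 0:
            raise FixtureError("ct_to_nz_distance must be positive")
        if self.jitter > 0 and self.ct_to_nz_distance < 4 * self.jitter:
            raise FixtureError(
                "requested distance is below the hard-sphere limit implied "
                f"by jitter {self.jitter} Å")
        if self.n_models < 1:
            raise FixtureError("n_models must be >= 1")
        if (self.include_binder_self_lysine_at is not None
                and self.include_binder_self_lysine_at <= 0):
            raise FixtureError("self-lysine distance must be positive")


# ---------------------------------------------------------------------------
# chain construction


def _build_chain(seq1: str, rng: np.random.Generator | None,
                 jitter: float) -> list[tuple[str, int, dict[str, np.ndarray]]]:
    """Residues [(name3, number, {atom: xyz})] along +x."""
    residues = []
    for i, aa in enumerate(seq1):
        name3 = THREE_LETTER[aa]
        origin = np.array([i * RESIDUE_SPACING, 0.0, 0.0])
        atoms = {n: origin + np.asarray(off) for n, off in BACKBONE.items()}
        if name3 == "LYS":
            atoms.update({n: origin + np.asarray(off)
                          for n, off in LYS_SIDE.items()})
        if rng is not None and jitter > 0:
            atoms = {n: xyz + rng.normal(0.0, jitter, 3)
                     for n, xyz in atoms.items()}
        residues.append((name3, i + 1, atoms))
    return residues


def _translate(residues, shift: np.ndarray):
    return [(n, num, {a: xyz + shift for a, xyz in atoms.items()})
            for n, num, atoms in residues]


def _ct_carbon(residues) -> np.ndarray:
    return residues[-1][2]["C"]


def _lysine_nz(residues) -> np.ndarray:
    for name3, _num, atoms in residues:
        if name3 == "LYS":
            return atoms["NZ"]
    raise FixtureError("chain has no lysine")


# ---------------------------------------------------------------------------
# mmCIF writing


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def _write_cif(structure_id: str,
               entities: dict[str, str],
               chains: list[tuple[str, str]],
               models: list[dict[str, list]],
               assemblies: list[tuple[str, str, list[str]]],
               operators: dict[str, np.ndarray]) -> str:
    """Compose mmCIF text.

    ``chains``: (label_asym_id, entity_id).  ``models``: one dict per
    model mapping label_asym_id -> residue list.  ``assemblies``:
    (assembly_id, oper_expression, asym_id_list).
    """
    lines = [f"data_{structure_id}", f"_entry.id {structure_id}",
             "_struct.title 'synthetic fixture with exactly known geometry'",
             "#"]
    lines += ["loop_", "_entity.id", "_entity.type", "_entity.pdbx_description"]
    for eid in entities:
        lines.append(f"{eid} polymer 'synthetic chain {eid}'")
    lines.append("#")
    lines += ["loop_", "_entity_poly.entity_id", "_entity_poly.type",
              "_entity_poly.pdbx_seq_one_letter_code",
              "_entity_poly.pdbx_strand_id"]
    for eid, seq in entities.items():
        strands = ",".join(asym for asym, e in chains if e == eid)
        lines.append(f"{eid} 'polypeptide(L)' {seq} {strands}")
    lines.append("#")
    lines += ["loop_", "_entity_poly_seq.entity_id", "_entity_poly_seq.num",
              "_entity_poly_seq.mon_id"]
    for eid, seq in entities.items():
        for i, aa in enumerate(seq, start=1):
            lines.append(f"{eid} {i} {THREE_LETTER[aa]}")
    lines.append("#")
    lines += ["loop_", "_struct_asym.id", "_struct_asym.entity_id"]
    for asym, eid in chains:
        lines.append(f"{asym} {eid}")
    lines.append("#")
    if assemblies:
        lines += ["loop_", "_pdbx_struct_assembly.id",
                  "_pdbx_struct_assembly.details"]
        for aid in dict.fromkeys(a for a, _, _ in assemblies):
            lines.append(f"{aid} author_defined_assembly")
        lines.append("#")
        lines += ["loop_", "_pdbx_struct_assembly_gen.assembly_id",
                  "_pdbx_struct_assembly_gen.oper_expression",
                  "_pdbx_struct_assembly_gen.asym_id_list"]
        for aid, expr, asyms in assemblies:
            lines.append(f"{aid} '{expr}' {','.join(asyms)}")
        lines.append("#")
        lines += ["loop_", "_pdbx_struct_oper_list.id",
                  "_pdbx_struct_oper_list.type"]
        for i in (1, 2, 3):
            lines += [f"_pdbx_struct_oper_list.matrix[{i}][1]",
                      f"_pdbx_struct_oper_list.matrix[{i}][2]",
                      f"_pdbx_struct_oper_list.matrix[{i}][3]",
                      f"_pdbx_struct_oper_list.vector[{i}]"]
        for oid, mat in operators.items():
            kind = ("'identity operation'" if np.allclose(mat, np.eye(4))
                    else "'point symmetry operation'")
            nums = []
            for i in range(3):
                nums += [f"{mat[i, 0]:.6f}", f"{mat[i, 1]:.6f}",
                         f"{mat[i, 2]:.6f}", f"{mat[i, 3]:.6f}"]
            lines.append(f"{oid} {kind} " + " ".join(nums))
        lines.append("#")
    lines += ["loop_", "_atom_site.group_PDB", "_atom_site.id",
              "_atom_site.type_symbol", "_atom_site.label_atom_id",
              "_atom_site.label_alt_id", "_atom_site.label_comp_id",
              "_atom_site.label_asym_id", "_atom_site.label_entity_id",
              "_atom_site.label_seq_id", "_atom_site.pdbx_PDB_ins_code",
              "_atom_site.Cartn_x", "_atom_site.Cartn_y", "_atom_site.Cartn_z",
              "_atom_site.occupancy", "_atom_site.B_iso_or_equiv",
              "_atom_site.auth_seq_id", "_atom_site.auth_asym_id",
              "_atom_site.pdbx_PDB_model_num"]
    entity_of = dict(chains)
    serial = 0
    atom_order = ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"]
    for model_num, model in enumerate(models, start=1):
        for asym, _eid in chains:
            for name3, num, atoms in model[asym]:
                for aname in atom_order:
                    if aname not in atoms:
                        continue
                    serial += 1
                    x, y, z = atoms[aname]
                    elem = "N" if aname.startswith("N") else (
                        "O" if aname.startswith("O") else "C")
                    lines.append(
                        f"ATOM {serial} {elem} {aname} . {name3} {asym} "
                        f"{entity_of[asym]} {num} ? {_fmt(x)} {_fmt(y)} "
                        f"{_fmt(z)} 1.00 10.00 {num} {asym} {model_num}")
    lines.append("#")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# layouts

BINDER_SEQ = "GASAGE"
BINDER_SEQ_SELF_LYS = "GAKAGE"
TARGET_SEQ = "GAKAG"
HOMODIMER_SEQ = "GAKAGE"


def _binder_chain(spec: FixtureSpec, rng) -> list:
    seq = (BINDER_SEQ_SELF_LYS if spec.include_binder_self_lysine_at
           else BINDER_SEQ)
    chain = _build_chain(seq, rng, spec.jitter)
    if spec.include_binder_self_lysine_at:
        # pin the binder's own lysine NZ at the requested self-reaction
        # distance, on the -z side (the target chain sits at +z)
        ct_c = _ct_carbon(chain)
        want = ct_c + np.array([0.0, 0.0, -spec.include_binder_self_lysine_at])
        for name3, _num, atoms in chain:
            if name3 == "LYS":
                atoms["NZ"] = want
    return chain


def _placed_target(spec: FixtureSpec, rng, ct_c: np.ndarray,
                   distance: float) -> list:
    target = _build_chain(TARGET_SEQ, rng, spec.jitter)
    want = ct_c + np.array([0.0, 0.0, distance])
    return _translate(target, want - _lysine_nz(target))


def make_toy_complex(spec: FixtureSpec) -> str:
    """Heterodimer (or monomer) with exact binder-Ct-C -> target-K-Nε distance."""
    rng = np.random.default_rng(spec.seed) if spec.jitter > 0 else None
    binder = _binder_chain(spec, rng)
    if spec.layout is Layout.MONOMER:
        return _write_cif(
            "toymono",
            entities={"1": (BINDER_SEQ_SELF_LYS
                            if spec.include_binder_self_lysine_at
                            else BINDER_SEQ)},
            chains=[("A", "1")],
            models=[{"A": binder}],
            assemblies=[("1", "1", ["A"])],
            operators={"1": np.eye(4)},
        )
    target = _placed_target(spec, rng, _ct_carbon(binder),
                            spec.ct_to_nz_distance)
    return _write_cif(
        spec.structure_id or "toyhet",
        entities={"1": (BINDER_SEQ_SELF_LYS
                        if spec.include_binder_self_lysine_at else BINDER_SEQ),
                  "2": TARGET_SEQ},
        chains=[("A", "1"), ("B", "2")],
        models=[{"A": binder, "B": target}],
        assemblies=[("1", "1", ["A", "B"])],
        operators={"1": np.eye(4)},
    )


def make_homodimer_fixture(spec: FixtureSpec) -> str:
    """One deposited chain; assembly = identity + rotated copy placed so the
    copy's lysine Nε is exactly ``ct_to_nz_distance`` from the deposited
    chain's Ct carbonyl carbon."""
    if spec.layout is not Layout.HOMODIMER_BY_OPERATOR:
        raise FixtureError("spec.layout must be homodimer_by_operator")
    rng = np.random.default_rng(spec.seed) if spec.jitter > 0 else None
    chain = _build_chain(HOMODIMER_SEQ, rng, spec.jitter)
    ct_c = _ct_carbon(chain)
    nz = _lysine_nz(chain)
    rot = np.eye(4)
    rot[0, 0] = rot[1, 1] = -1.0  # 180° about z
    want = ct_c + np.array([0.0, spec.ct_to_nz_distance, 0.0])
    rot[:3, 3] = want - rot[:3, :3] @ nz
    return _write_cif(
        spec.structure_id or "toyhomo",
        entities={"1": HOMODIMER_SEQ},
        chains=[("A", "1")],
        models=[{"A": chain}],
        assemblies=[("1", "1,2", ["A"])],
        operators={"1": np.eye(4), "2": rot},
    )


def make_multimodel_fixture(spec: FixtureSpec) -> str:
    """``n_models`` models of the heterodimer; model k places the key
    Ct->Nε distance at (3.0 + k) Å, so the cross-model minimum is known."""
    if spec.layout is not Layout.MULTIMODEL:
        raise FixtureError("spec.layout must be multimodel")
    rng = np.random.default_rng(spec.seed) if spec.jitter > 0 else None
    models = []
    for k in range(1, spec.n_models + 1):
        binder = _binder_chain(spec, rng)
        target = _placed_target(spec, rng, _ct_carbon(binder), 3.0 + k)
        models.append({"A": binder, "B": target})
    seq_a = (BINDER_SEQ_SELF_LYS if spec.include_binder_self_lysine_at
             else BINDER_SEQ)
    return _write_cif(
        spec.structure_id or "toymulti",
        entities={"1": seq_a, "2": TARGET_SEQ},
        chains=[("A", "1"), ("B", "2")],
        models=models,
        assemblies=[("1", "1", ["A", "B"])],
        operators={"1": np.eye(4)},
    )


def generate(spec: FixtureSpec) -> str:
    """Dispatch on ``spec.layout``."""
    if spec.layout in (Layout.HETERODIMER, Layout.MONOMER):
        return make_toy_complex(spec)
    if spec.layout is Layout.HOMODIMER_BY_OPERATOR:
        return make_homodimer_fixture(spec)
    return make_multimodel_fixture(spec)


def as_legacy_pdb(cif_text: str) -> str:
    """The same content re-expressed in legacy PDB format (via gemmi)."""
    import gemmi

    block = gemmi.cif.read_string(cif_text).sole_block()
    st = gemmi.make_structure_from_block(block)
    st.setup_entities()
    return st.make_pdb_string()
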