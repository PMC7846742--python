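import numpy as np
import pytest

from neissdist import ScanConfig, parse_structure
from neissdist.fixtures import FixtureSpec, generate
from neissdist.structure_io import (
    Atom,
    ChainInstance,
    ONE_LETTER,
    Residue,
    STANDARD_RESIDUES,
)


@pytest.fixture
def config():
    return ScanConfig()


@pytest.fixture
def write_fixture(tmp_path):
    """Generate a synthetic mmCIF and return its path."""

    def _write(name="toy.cif", **spec_kwargs):
        path = tmp_path / name
        path.write_text(generate(FixtureSpec(**spec_kwargs)))
        return path

    return _write


@pytest.fixture
def parse_fixture(write_fixture):
    def _parse(config=None, **spec_kwargs):
        return parse_structure(write_fixture(**spec_kwargs),
                               config or ScanConfig())

    return _parse


def make_chain(residue_specs, *, label_asym="A", auth_asym="A",
               operator="1", assembly="AU", entity="1",
               structure_id="synthetic", model=1, sequence=None,
               start_number=1):
    """Build a ChainInstance directly from (name3, {atom: xyz}) tuples."""
    residues = []
    for i, (name, atoms) in enumerate(residue_specs):
        residues.append(Residue(
            name=name,
            auth_number=str(start_number + i),
            label_number=start_number + i,
            is_standard=name in STANDARD_RESIDUES,
            atoms={n: Atom(name=n, coords=np.asarray(c, dtype=float))
                   for n, c in atoms.items()},
        ))
    if sequence is None:
        sequence = "".join(ONE_LETTER.get(r.name, "X")
                           for r in residues if r.is_standard)
    return ChainInstance(
        structure_id=structure_id, assembly_id=assembly, model_number=model,
        label_asym_id=label_asym, auth_asym_id=auth_asym,
        operator_id=operator, entity_id=entity, sequence=sequence,
        residues=residues,
    )


def backbone(origin, with_lysine_nz=None):
    """Minimal backbone atom dict at *origin*; optional explicit NZ."""
    o = np.asarray(origin, dtype=float)
    atoms = {"N": o, "CA": o + (1.46, 0, 0), "C": o + (2.3, 1.1, 0)}
    if with_lysine_nz is not None:
        atoms["NZ"] = np.asarray(with_lysine_nz, dtype=float)
    return atoms
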