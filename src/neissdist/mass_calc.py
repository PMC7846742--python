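"""Intact-mass bookkeeping for autoproteolysis and conjugation products.

Average (not monoisotopic) masses are the default, matching intact-protein
ESI deconvolution.  The chemistry being tracked: a self-processing module
cleaves at an Asp-Pro bond leaving the upstream fragment as a C-terminal
aspartic anhydride; hydration of the anhydride adds one water, and amide
formation with a target amine releases one water.  All printed-mass
comparisons therefore reduce to sums and differences of sequence masses
and the water constant.
"""

from __future__ import annotations

from dataclasses import dataclass

#: average mass of water, Da (reports often print the rounded 18.01)
WATER_AVERAGE = 18.0153
#: monoisotopic mass of water, Da
WATER_MONO = 18.010565

#: ExPASy-style average residue masses, Da (monomer minus water)
RESIDUE_AVERAGE = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: monoisotopic residue masses, Da
RESIDUE_MONO = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}


@dataclass
class ProteinSpecies:
    """A protein identified either by sequence or by a known mass."""

    label: str
    sequence: str | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        if self.sequence is None and self.mass is None:
            raise ValueError(f"{self.label}: need a sequence or a mass")
        if self.mass is not None and self.mass <= 0:
            raise ValueError(f"{self.label}: mass must be positive")

    def resolved_mass(self, remove_fmet: bool = False,
                      monoisotopic: bool = False) -> float:
        if self.sequence is not None:
            return average_mass(self.sequence, remove_fmet=remove_fmet,
                                monoisotopic=monoisotopic)
        return self.mass


@dataclass
class CleavageProducts:
    """Masses of the two autoproteolysis fragments.

    ``n_fragment_anhydride`` is the upstream fragment carrying the
    reactive anhydride; adding one water gives the hydrolyzed (linear)
    form observed after quenching.
    """

    n_fragment_anhydride: float
    n_fragment_hydrolyzed: float
    c_fragment: float
    water: float = WATER_AVERAGE


def average_mass(sequence: str, remove_fmet: bool = False,
                 monoisotopic: bool = False) -> float:
    """Protein mass from a one-letter sequence: Σ residue masses + water.

    ``remove_fmet=True`` drops one leading methionine first (bacterial
    N-terminal Met excision); it is an error if the sequence does not
    start with M.  The empty sequence returns the mass of water.
    """
    table = RESIDUE_MONO if monoisotopic else RESIDUE_AVERAGE
    water = WATER_MONO if monoisotopic else WATER_AVERAGE
    sequence = sequence.strip().upper()
    if remove_fmet:
        if not sequence.startswith("M"):
            raise ValueError("remove_fmet requires a leading methionine")
        sequence = sequence[1:]
    total = water
    for aa in sequence:
        try:
            total += table[aa]
        except KeyError:
            raise ValueError(f"non-canonical residue letter {aa!r}") from None
    return total


def cleavage_masses(precursor: ProteinSpecies | float,
                    c_fragment: ProteinSpecies | float,
                    monoisotopic: bool = False) -> CleavageProducts:
    """Fragment masses from precursor and C-terminal fragment masses.

    The hydrolyzed upstream fragment is precursor − C-fragment + water;
    the anhydride form is one water lighter (= precursor − C-fragment).
    """
    water = WATER_MONO if monoisotopic else WATER_AVERAGE
    pm = (precursor.resolved_mass(monoisotopic=monoisotopic)
          if isinstance(precursor, ProteinSpecies) else float(precursor))
    cm = (c_fragment.resolved_mass(monoisotopic=monoisotopic)
          if isinstance(c_fragment, ProteinSpecies) else float(c_fragment))
    if cm >= pm:
        raise ValueError(
            f"C-fragment mass {cm:.2f} must be below precursor {pm:.2f}")
    return CleavageProducts(
        n_fragment_anhydride=pm - cm,
        n_fragment_hydrolyzed=pm - cm + water,
        c_fragment=cm,
        water=water,
    )


def conjugate_mass(binder_fragment_hydrolyzed: float, target: float,
                   monoisotopic: bool = False) -> float:
    """Mass of the covalent conjugate: binder + target − one water.

    Amide (or ester) bond formation between the binder fragment's
    C-terminal carboxyl and a target amine releases one water, so the
    component masses are added and the mass of water subtracted.
    """
    if binder_fragment_hydrolyzed <= 0 or target <= 0:
        raise ValueError("component masses must be positive")
    water = WATER_MONO if monoisotopic else WATER_AVERAGE
    return binder_fragment_hydrolyzed + target - water


def read_fasta_sequences(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence} (via Bio.SeqIO)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
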