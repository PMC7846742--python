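"""Scan configuration shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScanConfig:
    """Tunable limits and conventions for a distance scan.

    Defaults encode the screening protocol: input files larger than 10 MB
    are skipped (large viral assemblies are not informative for probe
    design and dominate compute), at most the first 10 coordinate models
    of an NMR-style entry are analysed, primary distances below 1.6 Å are
    treated as existing covalent linkages (e.g. ubiquitination) rather
    than candidate reaction geometry, and per-category minima are
    interrogated in 0.1 Å steps over [0, 50) Å then binned at 1 Å.
    """

    #: input file size gate in bytes; ``None`` disables the gate
    max_file_bytes: int | None = 10_485_760
    #: number of leading coordinate models analysed per structure
    max_models: int = 10
    #: distances below this (Å) are flagged as covalent linkage
    covalent_cutoff: float = 1.6
    #: closed-open distance interval (Å) for histograms
    histogram_range: tuple[float, float] = (0.0, 50.0)
    #: interrogation step (Å)
    fine_step: float = 0.1
    #: histogram bin width (Å)
    bin_width: float = 1.0
    #: keep records where the C-terminal residue is itself the target
    include_same_residue: bool = True
    #: "assemblies" expands deposited assembly operators; "asymmetric_unit"
    #: scans the deposited coordinates as a single pseudo-assembly
    assembly_mode: str = "assemblies"
    #: treat selenomethionine (MSE) as standard MET
    map_mse: bool = False
    #: guard against pathological operator products after expansion
    assembly_max_atoms: int = 500_000

    def __post_init__(self) -> None:
        if self.max_file_bytes is not None and self.max_file_bytes <= 0:
            raise ValueError("max_file_bytes must be positive or None")
        if self.max_models < 1:
            raise ValueError("max_models must be >= 1")
        lo, hi = self.histogram_range
        if not (0 < self.covalent_cutoff < hi):
            raise ValueError("covalent_cutoff must lie inside the histogram range")
        if self.fine_step > self.bin_width:
            raise ValueError("fine_step must not exceed bin_width")
        if self.assembly_mode not in ("assemblies", "asymmetric_unit"):
            raise ValueError(f"unknown assembly_mode {self.assembly_mode!r}")
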