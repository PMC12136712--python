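"""Physicochemical constant tables used by the featurizer.

All tables are published reference data: the Kyte-Doolittle hydropathy
scale, the Guruprasad dipeptide instability weights (DIWV), Expasy average
amino-acid masses, Bjellqvist pKa values, the Pace-Schmid molar extinction
coefficients and the ProtParam secondary-structure residue sets.  They are
collected here (sourced from Biopython's data modules where available) so
that an alternate convention can be swapped in one place.
"""

from __future__ import annotations

from Bio.Data.IUPACData import protein_weights as _AA_WEIGHTS
from Bio.SeqUtils.ProtParamData import DIWV, kd as KYTE_DOOLITTLE  # noqa: F401

#: The 20 standard residues, alphabetical; fixes feature ordering everywhere.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Average mass of one water molecule (Da), released per peptide bond.
WATER_MASS: float = 18.0153

#: Average (not monoisotopic) masses of the free amino acids, Da.
#: Residue mass in a chain = free mass - one water.
AA_AVERAGE_MASS: dict[str, float] = {aa: _AA_WEIGHTS[aa] for aa in AMINO_ACIDS}

#: Bjellqvist pKa set (flat variant: no N-terminal-residue-specific table).
#: Basic groups are protonated (charge +1) below their pKa.
PKA_POSITIVE: dict[str, float] = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
#: Acidic groups are deprotonated (charge -1) above their pKa.
PKA_NEGATIVE: dict[str, float] = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}

#: Molar extinction coefficients at 280 nm, M^-1 cm^-1, cysteines reduced.
EXTINCTION_W: int = 5500
EXTINCTION_Y: int = 1490

#: ProtParam secondary-structure propensity sets.  Leucine deliberately
#: belongs to both the helix and the sheet set.
HELIX_SET: frozenset[str] = frozenset("VIYFWL")
TURN_SET: frozenset[str] = frozenset("NPGS")
SHEET_SET: frozenset[str] = frozenset("EMAL")

#: Aromatic residues counted by the aromaticity descriptor.
AROMATIC_SET: frozenset[str] = frozenset("FWY")

#: Minimum sequence length accepted after sanitization.
MIN_PROTEIN_LENGTH: int = 30


def descriptor_constants() -> dict:
    """Serializable snapshot of every constant the featurizer consumes.

    Written as a sidecar JSON next to feature matrices so a matrix is
    interpretable without the package version that produced it.
    """
    return {
        "amino_acid_order": AMINO_ACIDS,
        "water_mass_Da": WATER_MASS,
        "aa_average_mass_Da": AA_AVERAGE_MASS,
        "hydropathy_scale": "Kyte-Doolittle",
        "hydropathy_values": {aa: KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS},
        "instability_weights": "Guruprasad DIWV",
        "pka_set": "Bjellqvist (flat)",
        "pka_positive": PKA_POSITIVE,
        "pka_negative": PKA_NEGATIVE,
        "extinction_W": EXTINCTION_W,
        "extinction_Y": EXTINCTION_Y,
        "helix_set": sorted(HELIX_SET),
        "turn_set": sorted(TURN_SET),
        "sheet_set": sorted(SHEET_SET),
        "min_length": MIN_PROTEIN_LENGTH,
    }
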