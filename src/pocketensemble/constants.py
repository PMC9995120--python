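"""Physical constants and element tables shared across modules."""

# Gas constant in kcal mol^-1 K^-1.
R_KCAL_PER_MOL_K: float = 1.987204e-3

# Simulation temperature (K); all RT factors default to this.
DEFAULT_TEMPERATURE_K: float = 310.0

# Van der Waals radii (Angstrom) used for protein-exclusion tests on the
# pocket grid.  Values are conventional Bondi-style radii; unknown elements
# fall back to carbon.
VDW_RADII_A: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
VDW_DEFAULT_A: float = 1.70

# Residue names excluded from "protein" selections: solvent, common ions and
# cryo additives.  Configurable at the call sites that use it.
NON_PROTEIN_RESNAMES: frozenset[str] = frozenset(
    {
        "HOH", "WAT", "TIP", "TIP3", "SOL", "DOD",
        "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "SO4", "PO4",
        "GOL", "EDO", "PEG", "ACT", "DMS",
    }
)


def vdw_radius(element: str) -> float:
    """Van der Waals radius (A) for an element symbol, with a carbon fallback."""
    return VDW_RADII_A.get(element.upper().strip(), VDW_DEFAULT_A)
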