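"""Physical constants and reference values shared across the package.

All energies are in kcal/mol, lengths in Å, temperatures in K.
"""

#: Boltzmann constant, kcal/mol/K.
KB = 0.0019872041

#: Volume per molecule at 1 mol/L standard concentration, Å^3.
#: (1 M corresponds to one molecule per 1660.54 Å^3.)
STANDARD_VOLUME_A3 = 1660.54

#: Mean per-molecule energy of neat water for the OPC water model,
#: kcal/mol — the bulk reference against which hydration-site energies
#: are scored.
E_BULK_DEFAULT = -12.24

#: Default temperature for standard-state and K_i conversions, K.
T_DEFAULT = 298.15

#: Bondi van der Waals radii, Å, by element symbol.
BONDI_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol at the given temperature (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB * temperature


def vdw_radius(element: str, overrides: dict | None = None) -> float:
    """Bondi van der Waals radius for an element symbol (case-insensitive).

    Unknown elements fall back to 1.70 Å (carbon-like), a conventional
    choice for heavy atoms absent from the Bondi set.
    """
    key = element.strip().upper()
    if overrides:
        up = {k.strip().upper(): v for k, v in overrides.items()}
        if key in up:
            return up[key]
    return BONDI_RADII.get(key, 1.70)
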