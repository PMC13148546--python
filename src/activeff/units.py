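"""Unit system and physical constants.

The package works in a fixed unit system throughout: Ångström for length,
femtosecond for time, eV for energy, eV/Å for forces, Kelvin for temperature
and unified atomic mass units (amu) for masses.
"""

from __future__ import annotations

#: Boltzmann constant in eV/K.
KB = 8.617333262e-5

#: Conversion factor: (eV/Å) / amu  ->  Å/fs².  Used as a = F/m * FORCE_TO_ACC.
FORCE_TO_ACC = 9.64853322e-3

#: Conversion factor: amu·(Å/fs)² -> eV.  Kinetic energy = 0.5*m*v²*KE_TO_EV.
KE_TO_EV = 1.0 / FORCE_TO_ACC

#: Atomic masses (amu) for the elements the toy systems and tests use.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "Be": 9.0122,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.90,
    "Cs": 132.91,
    "Pb": 207.2,
}


def mass_of(symbol: str) -> float:
    """Atomic mass in amu; raises ``KeyError`` for unknown element symbols."""
    try:
        return ATOMIC_MASSES[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None
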