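"""Physical constants and the bundled element table.

Atomic masses are CODATA/IUPAC conventional values. Mean excitation
energies follow the ICRU-37 / ESTAR convention: elements H-O carry
individually recommended values for the condensed/compound phase, and
elements with Z > 8 use the generic condensed-phase adjustment
I_adj = 1.13 * I_elem.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant (1/mol)
N_AVOGADRO = 6.02214076e23
#: electron rest energy (MeV)
ELECTRON_REST_MEV = 0.511
#: classical electron radius (cm)
R_ELECTRON_CM = 2.8179403262e-13
#: Thomson cross-section (cm^2)
SIGMA_THOMSON_CM2 = 0.66524587e-24
#: leading constant of the Bethe mass collision stopping power,
#: 2*pi*r_e^2*m_ec^2*N_A  (MeV cm^2 / mol); divide by A, multiply by Z.
STOPPING_K_MEV_CM2_G = 0.1535
#: plasma-energy coefficient: hbar*omega_p = 28.8159 * sqrt(rho * Z/A) eV
PLASMA_ENERGY_COEFF_EV = 28.8159
#: fine-structure constant
FINE_STRUCTURE = 1.0 / 137.035999


@dataclass(frozen=True)
class ElementRecord:
    """Per-element constants used throughout the package.

    Attributes
    ----------
    symbol : chemical symbol
    Z : atomic number
    A : atomic mass (g/mol)
    I_elem : elemental mean excitation energy (eV), isolated/gas convention
    I_adj : compound-adjusted mean excitation energy (eV) used in
        Bragg-additivity for mixtures (ICRU-37 condensed-phase values)
    """

    symbol: str
    Z: int
    A: float
    I_elem: float
    I_adj: float

    def __post_init__(self) -> None:
        if self.Z < 1:
            raise ValueError(f"{self.symbol}: Z must be >= 1")
        if self.A <= 0:
            raise ValueError(f"{self.symbol}: A must be positive")
        if not (self.I_adj >= self.I_elem > 0):
            raise ValueError(f"{self.symbol}: need I_adj >= I_elem > 0")


def _el(symbol: str, Z: int, A: float, I_elem: float, I_adj: float | None = None) -> ElementRecord:
    if I_adj is None:
        I_adj = 1.13 * I_elem if Z > 8 else I_elem
    return ElementRecord(symbol, Z, A, I_elem, I_adj)


#: Bundled element table. Covers every element appearing in the reference
#: material compositions (H, C, N, O, Si, Cl, Ca) plus a few common
#: phantom-material constituents for synthetic compositions.
ELEMENTS: dict[str, ElementRecord] = {
    rec.symbol: rec
    for rec in [
        _el("H", 1, 1.008, 19.2, 19.2),
        _el("C", 6, 12.011, 78.0, 81.0),
        _el("N", 7, 14.007, 82.0, 82.0),
        _el("O", 8, 15.999, 95.0, 106.0),
        _el("F", 9, 18.998, 115.0),
        _el("Na", 11, 22.990, 149.0),
        _el("Mg", 12, 24.305, 156.0),
        _el("Al", 13, 26.982, 166.0),
        _el("Si", 14, 28.085, 173.0),
        _el("P", 15, 30.974, 173.0),
        _el("S", 16, 32.06, 180.0),
        _el("Cl", 17, 35.45, 174.0),
        _el("K", 19, 39.098, 190.0),
        _el("Ca", 20, 40.078, 191.0),
    ]
}


def element(symbol: str) -> ElementRecord:
    """Look up an element record, raising ``KeyError`` with a clear message."""
    try:
        return ELEMENTS[symbol]
    except KeyError:
        raise KeyError(
            f"unknown element symbol {symbol!r}; bundled table has "
            f"{sorted(ELEMENTS)}"
        ) from None
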