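"""Stoichiometric constants for carboxylate products and dry biomass.

Products are the even-chain carboxylic acids formed by acetogenesis and chain
elongation from CO2. For a saturated monocarboxylate CnH(2n)O2 the number of
electrons needed to form one mole from CO2 is 6n - 4 (acetate 8, butyrate 20,
hexanoate 32). Dry biomass is treated on a C-mol basis with the standard
composition CH1.8O0.5N0.2: nitrogen content 0.2 mol-N per C-mol, molar mass
25.25 g per C-mol, and a degree of reduction of 4.2 electrons per C-mol when
ammonium is the nitrogen source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Faraday constant, C mol^-1.
FARADAY = 96485.0


@dataclass(frozen=True)
class Product:
    carbon_number: int
    electrons_per_mol: int
    molar_mass: float  # g mol^-1, free acid


#: Default product table (free-acid molar masses).
PRODUCTS: dict[str, Product] = {
    "acetate": Product(2, 8, 60.05),
    "butyrate": Product(4, 20, 88.11),
    "hexanoate": Product(6, 32, 116.16),
}


@dataclass(frozen=True)
class StoichiometryTable:
    """Electron and carbon bookkeeping for products and biomass.

    Parameters
    ----------
    products
        Map product name -> :class:`Product`.
    gamma_x
        Degree of reduction of biomass, electrons per C-mol (default 4.2).
    nu_nx
        Nitrogen content of biomass, mol-N per C-mol (default 0.2).
    mw_x
        Biomass molar mass, g per C-mol (default 25.25).
    """

    products: dict[str, Product] = field(default_factory=lambda: dict(PRODUCTS))
    gamma_x: float = 4.2
    nu_nx: float = 0.2
    mw_x: float = 25.25

    def __post_init__(self) -> None:
        for name, p in self.products.items():
            if p.electrons_per_mol <= 0 or p.carbon_number <= 0 or p.molar_mass <= 0:
                raise ValueError(f"non-positive stoichiometry for product {name!r}")

    def carbon_number(self, product: str) -> int:
        return self.products[product].carbon_number

    def electrons(self, product: str) -> int:
        return self.products[product].electrons_per_mol

    def molar_mass(self, product: str) -> float:
        return self.products[product].molar_mass

    def g_to_mol(self, product: str, value_g_per_l: float) -> float:
        """Convert a product concentration from g/L to mol/L."""
        return value_g_per_l / self.molar_mass(product)

    def mol_to_g(self, product: str, value_mol_per_l: float) -> float:
        return value_mol_per_l * self.molar_mass(product)


DEFAULT_STOICHIOMETRY = StoichiometryTable()
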